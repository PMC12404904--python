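"""Exact-mass arithmetic for small-molecule mass spectrometry.

Monoisotopic masses of molecular formulas (deuterium-aware), adduct m/z
values, neutral-loss product m/z, and ppm tolerance tests. Everything in
this module is pure computation; it underpins query evaluation, MS/MS
profiling and the synthetic fixtures.

Masses are CODATA/NIST monoisotopic values. Charged-species m/z accounts
for the electron: the ``[M+H]+`` adduct adds the proton mass
(1.007276466 Da), not the hydrogen atom mass — required to reproduce
literature [M+H]+ values at 4 decimal places.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, Mapping

__all__ = [
    "ElementComposition",
    "AdductSpec",
    "ToleranceSpec",
    "ADDUCTS",
    "PROTON_MASS",
    "ELECTRON_MASS",
    "parse_formula",
    "monoisotopic_mass",
    "adduct_mz",
    "neutral_loss_product_mz",
    "ppm_error",
    "within_tolerance",
]

#: Monoisotopic isotope masses, Da (NIST). "D" is deuterium, a first-class symbol.
ISOTOPE_MASS: dict[str, float] = {
    "H": 1.00782503207,
    "D": 2.01410177785,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
    "P": 30.97376163,
    "Na": 22.9897692809,
    "K": 38.96370668,
    "Cl": 34.96885268,
    "F": 18.99840322,
    "Br": 78.9183371,
    "I": 126.904473,
    "Si": 27.9769265325,
    "Se": 73.9224764,
    "B": 11.0093054,
}

PROTON_MASS = 1.007276466
ELECTRON_MASS = 0.000548579909

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Malformed molecular formula or unknown element symbol."""


@dataclass(frozen=True)
class ElementComposition:
    """Element -> count mapping with element-wise arithmetic.

    Counts are non-negative integers; absent elements count as zero.
    Subtraction that would drive any count negative raises ``ValueError``.
    """

    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean = {el: int(n) for el, n in self.counts.items() if n != 0}
        for el, n in clean.items():
            if n < 0:
                raise ValueError(f"negative count for element {el!r}: {n}")
            if el not in ISOTOPE_MASS:
                raise FormulaError(f"unknown element symbol {el!r}")
        object.__setattr__(self, "counts", clean)

    def __getitem__(self, element: str) -> int:
        return self.counts.get(element, 0)

    def __iter__(self) -> Iterator[tuple[str, int]]:
        return iter(sorted(self.counts.items()))

    def __bool__(self) -> bool:
        return bool(self.counts)

    def __add__(self, other: "ElementComposition") -> "ElementComposition":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            merged[el] = merged.get(el, 0) + n
        return ElementComposition(merged)

    def __sub__(self, other: "ElementComposition") -> "ElementComposition":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            merged[el] = merged.get(el, 0) - n
            if merged[el] < 0:
                raise ValueError(
                    f"subtraction yields negative count for element {el!r}"
                )
        return ElementComposition(merged)

    @property
    def n_atoms(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class AdductSpec:
    """Ionization adduct: mass delta (Da, electron-corrected) and charge."""

    label: str
    mass_delta: float
    charge: int

    def __post_init__(self) -> None:
        if self.charge == 0:
            raise ValueError("adduct charge must be nonzero")


#: Built-in adducts. Deltas include the electron correction.
ADDUCTS: dict[str, AdductSpec] = {
    "[M+H]+": AdductSpec("[M+H]+", PROTON_MASS, +1),
    "[M+Na]+": AdductSpec(
        "[M+Na]+", ISOTOPE_MASS["Na"] - ELECTRON_MASS, +1
    ),
    "[M-H]-": AdductSpec("[M-H]-", -PROTON_MASS, -1),
}


@dataclass(frozen=True)
class ToleranceSpec:
    """m/z matching tolerance: relative (ppm) or absolute (Da).

    Exactly one mode is active; boundaries are inclusive, so a peak at
    exactly the stated ppm offset still matches.
    """

    mode: str  # "ppm" | "absolute_mz"
    value: float

    def __post_init__(self) -> None:
        if self.mode not in ("ppm", "absolute_mz"):
            raise ValueError(f"unknown tolerance mode {self.mode!r}")
        if not self.value > 0:
            raise ValueError("tolerance value must be positive")

    def half_window_da(self, reference: float) -> float:
        """Absolute half-window in Da around *reference*."""
        if self.mode == "ppm":
            return reference * self.value * 1e-6
        return self.value


def parse_formula(text: str) -> ElementComposition:
    """Parse a Hill-style molecular formula into an :class:`ElementComposition`.

    Deuterium is written ``D`` (the ``²H`` prefix notation is accepted and
    normalized to ``D``). Symbols are case-sensitive; repeated symbols
    accumulate (``"C2C3"`` == ``"C5"``).
    """
    if not isinstance(text, str) or not text.strip():
        raise FormulaError("empty formula")
    text = text.strip().replace("²H", "D").replace("[2H]", "D")
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(text):
        m = _FORMULA_TOKEN.match(text, pos)
        if m is None or not m.group(1):
            raise FormulaError(f"malformed formula at position {pos}: {text!r}")
        symbol, digits = m.group(1), m.group(2)
        if symbol not in ISOTOPE_MASS:
            raise FormulaError(f"unknown element symbol {symbol!r} in {text!r}")
        n = int(digits) if digits else 1
        if n <= 0:
            raise FormulaError(f"non-positive count for {symbol!r} in {text!r}")
        counts[symbol] = counts.get(symbol, 0) + n
        pos = m.end()
    return ElementComposition(counts)


def monoisotopic_mass(comp: ElementComposition) -> float:
    """Monoisotopic mass in Da: sum of count x isotope mass. Additive."""
    return sum(ISOTOPE_MASS[el] * n for el, n in comp.counts.items())


def adduct_mz(comp: ElementComposition, adduct: AdductSpec | str = "[M+H]+") -> float:
    """m/z of *comp* ionized as *adduct*: (M + delta) / |z|."""
    if isinstance(adduct, str):
        try:
            adduct = ADDUCTS[adduct]
        except KeyError:
            raise KeyError(f"unknown adduct label {adduct!r}") from None
    return (monoisotopic_mass(comp) + adduct.mass_delta) / abs(adduct.charge)


def neutral_loss_product_mz(
    precursor_mz: float, loss: ElementComposition | str
) -> float:
    """Product-ion m/z after loss of the neutral *loss* from a 1+ precursor."""
    if isinstance(loss, str):
        loss = parse_formula(loss)
    loss_mass = monoisotopic_mass(loss)
    if loss_mass >= precursor_mz and loss:
        raise ValueError(
            f"neutral loss ({loss_mass:.4f} Da) not lighter than precursor "
            f"m/z {precursor_mz:.4f}"
        )
    return precursor_mz - loss_mass


def ppm_error(observed: float, reference: float) -> float:
    """Signed relative mass error in ppm, anchored at *reference*."""
    if reference <= 0:
        raise ValueError("reference m/z must be positive")
    return (observed - reference) / reference * 1e6


def within_tolerance(observed: float, reference: float, tol: ToleranceSpec) -> bool:
    """Inclusive tolerance test in the spec'd mode (ppm or absolute Da)."""
    if tol.mode == "ppm":
        return abs(ppm_error(observed, reference)) <= tol.value
    return abs(observed - reference) <= tol.value
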