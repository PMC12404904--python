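"""MS/MS system-suitability evaluation.

Selects product-ion (MS2) scans per analyte from DDA runs, normalizes
product-ion or neutral-loss intensities per scan to the scan's total ion
current, and aggregates mean +/- sample SD by activation type (HCD/CID)
x normalized collision energy across runs/days. TIC normalization bounds
every value to [0, 1] and absorbs the scan-to-scan variation in total
signal along the chromatographic elution; base-peak normalization is
available as an option.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .formula_mass import ToleranceSpec, monoisotopic_mass, parse_formula
from .mzml_io import RunData, SpectrumRecord

__all__ = [
    "MSMSTarget",
    "select_ms2_scans",
    "normalized_product_intensity",
    "aggregate_profiles",
    "PROFILE_COLUMNS",
]

log = logging.getLogger("sstlab")

#: NCE values are grouped by stated value; floats match within this tolerance.
NCE_MATCH_TOL = 1e-3

PROFILE_COLUMNS = [
    "query_name",
    "activation",
    "nce",
    "target_kind",
    "target_value",
    "n_scans",
    "mean_norm_intensity",
    "sd_norm_intensity",
]


@dataclass(frozen=True)
class MSMSTarget:
    """Per-analyte MS/MS profiling request.

    ``targets`` holds (kind, value) pairs: kind ``product`` with a product
    m/z, or ``neutral_loss`` with either a loss value in Da or a molecular
    formula (e.g. trimethylamine ``C3H9N`` vs its d3 analog ``C3H6D3N``,
    configured per analyte — never auto-inferred).
    """

    query_name: str
    precursor_mz: float
    targets: tuple[tuple[str, float], ...]
    rt_window: Optional[tuple[float, float]] = None
    tolerance: ToleranceSpec = field(default_factory=lambda: ToleranceSpec("ppm", 10.0))

    @staticmethod
    def loss_value(formula_or_value: str | float) -> float:
        if isinstance(formula_or_value, str):
            return monoisotopic_mass(parse_formula(formula_or_value))
        return float(formula_or_value)


def select_ms2_scans(
    run: RunData,
    precursor_mz: float,
    tol: ToleranceSpec,
    rt_window: Optional[tuple[float, float]] = None,
) -> list[SpectrumRecord]:
    """MS2 scans whose recorded precursor m/z is within tolerance of
    *precursor_mz* (and inside *rt_window* when given)."""
    out = []
    for scan in run.scans:
        if scan.ms_level < 2 or scan.precursor_mz is None:
            continue
        if rt_window is not None and not (
            rt_window[0] <= scan.rt_minutes <= rt_window[1]
        ):
            continue
        if abs(scan.precursor_mz - precursor_mz) <= tol.half_window_da(precursor_mz):
            out.append(scan)
    return out


def normalized_product_intensity(
    scan: SpectrumRecord,
    target: float,
    tol: ToleranceSpec,
    kind: str = "product",
    denominator: str = "tic",
) -> Optional[float]:
    """Fraction of the scan's signal carried by peaks matching *target*.

    ``kind='product'`` matches peak m/z directly; ``kind='neutral_loss'``
    matches the difference (recorded precursor m/z - peak m/z) against the
    loss value. Denominator is the scan TIC (default, bounds the result to
    [0, 1]) or the base-peak intensity. A zero-TIC scan yields None with a
    warning and is excluded from aggregation.
    """
    if scan.ms_level < 2:
        raise ValueError("normalized_product_intensity requires an MS2 scan")
    tic = scan.tic
    if tic <= 0:
        log.warning("scan %s: zero TIC, normalized intensity undefined", scan.scan_id)
        return None
    if kind == "product":
        values = scan.mz_array
    elif kind == "neutral_loss":
        if scan.precursor_mz is None:
            raise ValueError("neutral-loss normalization requires a precursor m/z")
        values = scan.precursor_mz - scan.mz_array
    else:
        raise ValueError(f"unknown target kind {kind!r}")
    mask = np.abs(values - target) <= tol.half_window_da(target)
    matched = float(scan.intensity_array[mask].sum())
    if denominator == "tic":
        return matched / tic
    if denominator == "base_peak":
        return matched / float(scan.intensity_array.max())
    raise ValueError(f"unknown denominator {denominator!r}")


def _group_key(scan: SpectrumRecord) -> tuple[str, object]:
    if scan.activation in ("HCD", "CID") and scan.collision_energy is not None:
        # snap floating NCE values onto the stated grid
        nce = scan.collision_energy
        rounded = round(nce)
        if abs(nce - rounded) <= NCE_MATCH_TOL:
            nce = float(rounded)
        return scan.activation, nce
    return "unknown", "unknown"


def aggregate_profiles(
    runs: Sequence[RunData],
    panel: Sequence[MSMSTarget],
    denominator: str = "tic",
) -> pd.DataFrame:
    """Mean +/- sample SD of normalized target intensity per
    (analyte x activation x NCE x target) over all qualifying scans.

    Scans with unknown activation or missing NCE are aggregated under the
    ``unknown`` group and reported separately, never dropped silently.
    The result is invariant to run order and to splitting one run's scans
    across files.
    """
    rows = []
    for spec in panel:
        scans: list[SpectrumRecord] = []
        for run in runs:
            scans.extend(
                select_ms2_scans(run, spec.precursor_mz, spec.tolerance, spec.rt_window)
            )
        for kind, value in spec.targets:
            by_group: dict[tuple, list[float]] = {}
            for scan in scans:
                frac = normalized_product_intensity(
                    scan, value, spec.tolerance, kind=kind, denominator=denominator
                )
                if frac is None:
                    continue
                by_group.setdefault(_group_key(scan), []).append(frac)
            for (activation, nce), fracs in sorted(
                by_group.items(), key=lambda kv: (kv[0][0], str(kv[0][1]))
            ):
                arr = np.asarray(fracs)
                rows.append(
                    {
                        "query_name": spec.query_name,
                        "activation": activation,
                        "nce": nce,
                        "target_kind": kind,
                        "target_value": value,
                        "n_scans": arr.size,
                        "mean_norm_intensity": float(arr.mean()),
                        "sd_norm_intensity": float(arr.std(ddof=1)) if arr.size >= 2 else None,
                    }
                )
    return pd.DataFrame(rows, columns=PROFILE_COLUMNS)
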