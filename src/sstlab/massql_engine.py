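"""Parser and evaluator for the mass-spectrometry query-language subset
used in system suitability testing.

Supported grammar::

    QUERY <action>(<source>) WHERE <cond> [AND <cond>]*

with ``action`` one of ``scansum``/``scaninfo``, ``source`` one of
``MS1DATA``/``MS2DATA``, and conditions drawn from ``MS1MZ``, ``MS2PREC``,
``MS2PROD``, ``MS2NL``, ``RTMIN``, ``RTMAX``, ``TOLERANCEPPM``,
``TOLERANCEMZ`` (each ``KEYWORD = number``). Keywords are
case-insensitive and whitespace is not significant. The full published
language (variables, isotope-pattern, intensity and ion-mobility
conditions) is deliberately out of scope; the condition enumeration is
the extension point.

Evaluation is per scan: a scan matches when its MS level agrees with the
source, its retention time falls in the (inclusive) RT window, and every
m/z condition is satisfied within tolerance (default 10 ppm). Matched
peak intensities are summed per scan; scans with no match are omitted.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .formula_mass import ToleranceSpec, ppm_error
from .mzml_io import RunData, SpectrumRecord

__all__ = [
    "QueryAST",
    "ConditionSpec",
    "QueryParseError",
    "parse_query",
    "render_query",
    "evaluate_query",
    "MATCH_COLUMNS",
]

ACTIONS = ("scaninfo", "scansum")
SOURCES = ("MS1DATA", "MS2DATA")
MZ_CONDITIONS = ("MS1MZ", "MS2PREC", "MS2PROD", "MS2NL")
RT_CONDITIONS = ("RTMIN", "RTMAX")
#: conditions evaluated against individual centroid peaks of a scan
PEAK_CONDITIONS = ("MS1MZ", "MS2PROD", "MS2NL")

DEFAULT_TOLERANCE = ToleranceSpec("ppm", 10.0)

MATCH_COLUMNS = [
    "run_id",
    "scan_id",
    "rt_minutes",
    "matched_intensity",
    "observed_mz",
    "ppm_error",
]


class QueryParseError(ValueError):
    """Raised when query text does not follow the supported grammar."""


@dataclass(frozen=True)
class ConditionSpec:
    kind: str  # MS1MZ | MS2PREC | MS2PROD | MS2NL | RTMIN | RTMAX
    value: float

    def __post_init__(self) -> None:
        if self.kind not in MZ_CONDITIONS + RT_CONDITIONS:
            raise QueryParseError(f"unknown condition kind {self.kind!r}")
        if self.kind in MZ_CONDITIONS and not self.value > 0:
            raise QueryParseError(f"{self.kind} requires a positive m/z")
        if self.kind in RT_CONDITIONS and self.value < 0:
            raise QueryParseError(f"{self.kind} requires a non-negative RT")


@dataclass(frozen=True)
class QueryAST:
    action: str
    source: str
    conditions: tuple[ConditionSpec, ...] = ()
    tolerance: ToleranceSpec = DEFAULT_TOLERANCE

    def __post_init__(self) -> None:
        if self.action not in ACTIONS:
            raise QueryParseError(f"unknown action {self.action!r}")
        if self.source not in SOURCES:
            raise QueryParseError(f"unknown data source {self.source!r}")
        object.__setattr__(self, "conditions", tuple(self.conditions))
        kinds = [c.kind for c in self.conditions]
        for kind in ("MS2PREC", "MS2PROD", "MS2NL"):
            if kind in kinds and self.source != "MS2DATA":
                raise QueryParseError(f"{kind} requires MS2DATA source")
        if "MS1MZ" in kinds and self.source != "MS1DATA":
            raise QueryParseError("MS1MZ requires MS1DATA source")
        for kind in RT_CONDITIONS:
            if kinds.count(kind) > 1:
                raise QueryParseError(f"at most one {kind} condition allowed")
        lo, hi = self.rt_window
        if lo is not None and hi is not None and lo > hi:
            raise QueryParseError(f"RTMIN ({lo}) exceeds RTMAX ({hi})")

    @property
    def rt_window(self) -> tuple[Optional[float], Optional[float]]:
        lo = hi = None
        for c in self.conditions:
            if c.kind == "RTMIN":
                lo = c.value
            elif c.kind == "RTMAX":
                hi = c.value
        return lo, hi

    @property
    def ms_level(self) -> int:
        return 1 if self.source == "MS1DATA" else 2

    def peak_conditions(self) -> list[ConditionSpec]:
        return [c for c in self.conditions if c.kind in PEAK_CONDITIONS]

    def with_tolerance(self, tol: ToleranceSpec) -> "QueryAST":
        return replace(self, tolerance=tol)


_QUERY_RE = re.compile(
    r"^\s*QUERY\s+(?P<action>[A-Za-z]+)\s*\(\s*(?P<source>[A-Za-z0-9]+)\s*\)"
    r"\s*(?:WHERE\s*(?P<where>.*?))?\s*$",
    re.IGNORECASE | re.DOTALL,
)
_NUMBER_RE = re.compile(r"^[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?$")


def parse_query(text: str) -> QueryAST:
    """Parse query text into a :class:`QueryAST` (see module grammar)."""
    if not isinstance(text, str) or not text.strip():
        raise QueryParseError("empty query")
    m = _QUERY_RE.match(text)
    if m is None:
        raise QueryParseError(f"query does not match 'QUERY action(source) WHERE ...': {text!r}")
    action = m.group("action").lower()
    source = m.group("source").upper()
    if action not in ACTIONS:
        raise QueryParseError(f"unknown action {m.group('action')!r}")
    if source not in SOURCES:
        raise QueryParseError(f"unknown data source {m.group('source')!r}")

    conditions: list[ConditionSpec] = []
    tolerance: Optional[ToleranceSpec] = None
    where = m.group("where")
    if where is None and "WHERE" in text.upper():
        raise QueryParseError("WHERE clause present but empty")
    if where:
        for clause in re.split(r"\s+AND\s+", where.strip(), flags=re.IGNORECASE):
            if not clause.strip():
                raise QueryParseError("empty condition in WHERE clause")
            if "=" not in clause:
                raise QueryParseError(f"condition missing '=': {clause.strip()!r}")
            keyword, _, raw = clause.partition("=")
            keyword = keyword.strip().upper()
            raw = raw.strip()
            if not _NUMBER_RE.match(raw):
                raise QueryParseError(f"invalid numeric value {raw!r} for {keyword}")
            value = float(raw)
            if keyword == "TOLERANCEPPM":
                new = ToleranceSpec("ppm", value)
            elif keyword == "TOLERANCEMZ":
                new = ToleranceSpec("absolute_mz", value)
            elif keyword in MZ_CONDITIONS + RT_CONDITIONS:
                conditions.append(ConditionSpec(keyword, value))
                continue
            else:
                raise QueryParseError(f"unknown keyword {keyword!r}")
            if tolerance is not None:
                raise QueryParseError("multiple tolerance clauses; exactly one mode allowed")
            tolerance = new
    return QueryAST(action, source, tuple(conditions), tolerance or DEFAULT_TOLERANCE)


def render_query(ast: QueryAST) -> str:
    """Render an AST back to canonical single-line text.

    ``parse_query(render_query(ast)) == ast`` for every valid AST.
    """
    clauses = [f"{c.kind}={c.value:.12g}" for c in ast.conditions]
    if ast.tolerance.mode == "ppm":
        clauses.append(f"TOLERANCEPPM={ast.tolerance.value:.12g}")
    else:
        clauses.append(f"TOLERANCEMZ={ast.tolerance.value:.12g}")
    where = " AND ".join(clauses)
    return f"QUERY {ast.action}({ast.source}) WHERE {where}"


def _match_scan(scan: SpectrumRecord, ast: QueryAST) -> Optional[tuple[float, float, float]]:
    """Evaluate all conditions against one scan.

    Returns (matched_intensity, observed_mz, ppm_error) or None if the
    scan does not satisfy every condition. observed_mz is the
    intensity-weighted mean of the peaks matched by the first peak-level
    condition (the precursor m/z for a pure MS2PREC query); ppm_error is
    computed from it against that condition's query value.
    """
    lo, hi = ast.rt_window
    if lo is not None and scan.rt_minutes < lo:
        return None
    if hi is not None and scan.rt_minutes > hi:
        return None

    tol = ast.tolerance
    for c in ast.conditions:
        if c.kind == "MS2PREC":
            if scan.precursor_mz is None or not _within(scan.precursor_mz, c.value, tol):
                return None

    peak_conds = ast.peak_conditions()
    if not peak_conds:
        # precursor/RT-only query: the whole scan is the match
        obs = scan.precursor_mz
        ref = next((c.value for c in ast.conditions if c.kind == "MS2PREC"), None)
        ppm = ppm_error(obs, ref) if (obs is not None and ref) else 0.0
        tic = scan.tic
        if tic <= 0:
            return None
        return tic, (obs if obs is not None else float("nan")), ppm

    matched = np.zeros(scan.mz_array.size, dtype=bool)
    first_mask = None
    first_values = None  # m/z-like values matched by the first peak condition
    for c in peak_conds:
        if c.kind in ("MS1MZ", "MS2PROD"):
            values = scan.mz_array
        else:  # MS2NL: neutral-loss value of each peak vs recorded precursor
            if scan.precursor_mz is None:
                return None
            values = scan.precursor_mz - scan.mz_array
        half = tol.half_window_da(c.value)
        mask = np.abs(values - c.value) <= half
        if not mask.any():
            return None
        matched |= mask
        if first_mask is None:
            first_mask, first_values = mask, values

    inten = scan.intensity_array[matched]
    total = float(inten.sum())
    if total <= 0:
        return None
    w = scan.intensity_array[first_mask]
    observed = float(np.average(first_values[first_mask], weights=w)) if w.sum() > 0 else float("nan")
    ppm = ppm_error(observed, peak_conds[0].value)
    return total, observed, ppm


def _within(observed: float, reference: float, tol: ToleranceSpec) -> bool:
    return abs(observed - reference) <= tol.half_window_da(reference)


def evaluate_query(run: RunData, ast: QueryAST) -> pd.DataFrame:
    """Apply *ast* to every scan of *run*; one row per matching scan.

    Rows are ordered by retention time regardless of storage order. An
    empty frame (with the standard columns) is a valid result.
    """
    rows = []
    for scan in run.scans:
        if ast.source == "MS1DATA":
            if scan.ms_level != 1:
                continue
        elif scan.ms_level < 2:
            continue
        hit = _match_scan(scan, ast)
        if hit is None:
            continue
        intensity, observed, ppm = hit
        rows.append((run.run_id, scan.scan_id, scan.rt_minutes, intensity, observed, ppm))
    df = pd.DataFrame(rows, columns=MATCH_COLUMNS)
    return df.sort_values("rt_minutes", kind="stable", ignore_index=True)
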