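"""Extracted ion chromatograms and chromatographic peak integration.

An EIC is the per-scan matched intensity of one query laid out on the
run's scan grid (at the query's MS level) restricted to the query RT
window, zero-filled where the query matched nothing. Peak detection is
deliberately simple — one analyte per query window — the peak is the
contiguous nonzero segment containing the global intensity maximum, and
its area is the trapezoidal integral in intensity·minutes. No smoothing,
baseline correction or shape fitting is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .massql_engine import QueryAST
from .mzml_io import RunData

__all__ = ["EIC", "ChromPeak", "build_eic", "integrate_peak"]


@dataclass
class EIC:
    query_name: str
    run_id: str
    rt: np.ndarray         # minutes, strictly ascending
    intensity: np.ndarray  # non-negative, zero-filled

    def __post_init__(self) -> None:
        self.rt = np.asarray(self.rt, dtype=np.float64)
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if self.rt.shape != self.intensity.shape:
            raise ValueError("rt and intensity length mismatch")
        if self.rt.size > 1 and not np.all(np.diff(self.rt) > 0):
            raise ValueError("EIC retention times must be strictly ascending")
        if np.any(self.intensity < 0):
            raise ValueError("negative EIC intensity")


@dataclass
class ChromPeak:
    """Detected chromatographic peak; ``found=False`` leaves numerics None."""

    found: bool
    apex_rt: Optional[float] = None
    apex_intensity: Optional[float] = None
    area: Optional[float] = None          # intensity * minutes
    rt_start: Optional[float] = None
    rt_end: Optional[float] = None
    n_scans: Optional[int] = None

    @classmethod
    def not_found(cls) -> "ChromPeak":
        return cls(found=False)


def build_eic(matches: pd.DataFrame, run: RunData, ast: QueryAST) -> EIC:
    """Lay query matches onto the run's scan grid inside the RT window.

    The grid is every scan RT of *run* at the query's MS level within
    [RTMIN, RTMAX] (the whole run when no window is given); MS2 scans
    interleaved by DDA never alter an MS1 grid. Intensity is the
    matched_intensity of the corresponding scan, else zero.
    """
    lo, hi = ast.rt_window
    if ast.source == "MS1DATA":
        grid_scans = [s for s in run.scans if s.ms_level == 1]
    else:
        grid_scans = [s for s in run.scans if s.ms_level >= 2]
    grid_scans = [
        s
        for s in grid_scans
        if (lo is None or s.rt_minutes >= lo) and (hi is None or s.rt_minutes <= hi)
    ]
    if not grid_scans:
        raise ValueError(
            f"run {run.run_id!r}: no MS{ast.ms_level} scans inside RT window "
            f"[{lo}, {hi}] — cannot distinguish 'no signal' from 'no scans'"
        )
    by_scan = dict(zip(matches["scan_id"], matches["matched_intensity"]))
    rt = np.array([s.rt_minutes for s in grid_scans])
    intensity = np.array([by_scan.get(s.scan_id, 0.0) for s in grid_scans])
    # scans sharing an RT would break strict ascent; nudge is not attempted
    return EIC(query_name="", run_id=run.run_id, rt=rt, intensity=intensity)


def integrate_peak(
    eic: EIC, min_scans: int = 3, apex_floor: float = 0.0
) -> ChromPeak:
    """Detect and integrate the chromatographic peak of an EIC.

    The apex is the global intensity maximum (earliest RT wins ties). The
    peak segment is the contiguous nonzero run containing the apex plus
    the first zero sample on either side (the baseline touch points),
    clipped to the EIC. A peak is *found* when the apex exceeds
    ``apex_floor`` and the segment spans at least ``min_scans`` points;
    the area is the trapezoidal integral over the segment. Not-found is
    a result, never an error.
    """
    if eic.rt.size == 0:
        return ChromPeak.not_found()
    apex_idx = int(np.argmax(eic.intensity))  # argmax returns first maximum
    apex_intensity = float(eic.intensity[apex_idx])
    if apex_intensity <= apex_floor or apex_intensity <= 0:
        return ChromPeak.not_found()
    lo = apex_idx
    while lo > 0 and eic.intensity[lo - 1] > 0:
        lo -= 1
    hi = apex_idx
    while hi < eic.intensity.size - 1 and eic.intensity[hi + 1] > 0:
        hi += 1
    # include the baseline touch point on each side where one exists
    if lo > 0:
        lo -= 1
    if hi < eic.intensity.size - 1:
        hi += 1
    n_scans = hi - lo + 1
    if n_scans < min_scans:
        return ChromPeak.not_found()
    area = float(np.trapezoid(eic.intensity[lo : hi + 1], eic.rt[lo : hi + 1]))
    return ChromPeak(
        found=True,
        apex_rt=float(eic.rt[apex_idx]),
        apex_intensity=apex_intensity,
        area=area,
        rt_start=float(eic.rt[lo]),
        rt_end=float(eic.rt[hi]),
        n_scans=n_scans,
    )
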