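"""Batch system-suitability orchestration.

Loads a configuration and a named-query set, applies every query to
every mzML run in a directory (query evaluation -> EIC -> peak
integration), tabulates one record per (run x query), computes
cross-run retention-time and peak-area statistics, and flags
instrument-performance deficiencies (missing analytes, retention-time
shifts, elution-order inversions).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import kendalltau

from .chromatogram import build_eic, integrate_peak
from .formula_mass import ppm_error
from .massql_engine import QueryAST, parse_query, render_query
from .mzml_io import RunData, read_run

__all__ = [
    "SSTConfig",
    "NamedQuery",
    "ReferenceRT",
    "load_config",
    "load_queryset",
    "discover_runs",
    "run_batch",
    "summarize",
    "flag_deviations",
    "reference_from_queries",
    "export_results",
    "rt_rsd_benchmark",
    "RECORD_COLUMNS",
    "SUMMARY_COLUMNS",
    "FLAG_COLUMNS",
]

log = logging.getLogger("sstlab")

RECORD_COLUMNS = [
    "run_id",
    "run_index",
    "query_name",
    "found",
    "apex_rt",
    "apex_intensity",
    "area",
    "observed_mz",
    "ppm_error",
]
SUMMARY_COLUMNS = [
    "query_name",
    "n_runs",
    "n_found",
    "rt_mean",
    "rt_sd",
    "rt_rsd_pct",
    "area_mean",
    "area_sd",
    "area_rsd_pct",
]
FLAG_COLUMNS = ["run_id", "query_name", "flag", "detail"]


@dataclass
class SSTConfig:
    """Batch configuration, normally loaded from a JSON file."""

    mzml_directory: Path
    query_file: Path
    output_directory: Path
    tolerance_ppm_default: float = 10.0
    min_scans: int = 3
    apex_floor: float = 0.0
    rt_shift_margin: float = 0.1  # minutes added to each side of the RT window
    reference_file: Optional[Path] = None

    def __post_init__(self) -> None:
        self.mzml_directory = Path(self.mzml_directory)
        self.query_file = Path(self.query_file)
        self.output_directory = Path(self.output_directory)
        if self.reference_file is not None:
            self.reference_file = Path(self.reference_file)


def load_config(path: str | Path) -> SSTConfig:
    with open(path) as fh:
        raw = json.load(fh)
    known = {f for f in SSTConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return SSTConfig(**raw)


@dataclass(frozen=True)
class NamedQuery:
    """A named, pre-parsed query; optional MS/MS targets for profiling."""

    name: str
    query: str
    ast: QueryAST = field(compare=False, default=None)  # type: ignore[assignment]
    product_mz: Optional[float] = None
    neutral_loss_formula: Optional[str] = None

    def __post_init__(self) -> None:
        if self.ast is None:
            object.__setattr__(self, "ast", parse_query(self.query))


def _compose_query(row: Mapping) -> str:
    """Build query text from per-argument columns (name, mz, tolerance_ppm, rt_min, rt_max)."""
    clauses = [f"MS1MZ={float(row['mz'])}"]
    if row.get("tolerance_ppm") not in (None, ""):
        clauses.append(f"TOLERANCEPPM={float(row['tolerance_ppm'])}")
    if row.get("rt_min") not in (None, ""):
        clauses.append(f"RTMIN={float(row['rt_min'])}")
    if row.get("rt_max") not in (None, ""):
        clauses.append(f"RTMAX={float(row['rt_max'])}")
    return "QUERY scansum(MS1DATA) WHERE " + " AND ".join(clauses)


def load_queryset(path: str | Path) -> list[NamedQuery]:
    """Load named queries from a .json array or the first sheet of an .xlsx.

    Accepts either full query strings (columns/keys ``name``, ``query``)
    or per-argument columns (``name``, ``mz``, optional ``tolerance_ppm``,
    ``rt_min``, ``rt_max``) composed into scansum MS1 queries. All queries
    parse eagerly; duplicate names are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            entries = json.load(fh)
        if not isinstance(entries, list):
            raise ValueError(f"{path}: query JSON must be an array of objects")
    elif path.suffix.lower() == ".xlsx":
        frame = pd.read_excel(path, sheet_name=0)
        entries = frame.where(pd.notna(frame), None).to_dict(orient="records")
    else:
        raise ValueError(f"unsupported query file type: {path.suffix!r}")

    queries: list[NamedQuery] = []
    seen: set[str] = set()
    for i, entry in enumerate(entries):
        name = entry.get("name")
        if not name:
            raise ValueError(f"query entry {i}: missing name")
        if name in seen:
            raise ValueError(f"duplicate query name {name!r} (entry {i})")
        seen.add(name)
        text = entry.get("query") or _compose_query(entry)
        try:
            nq = NamedQuery(
                name=name,
                query=text,
                product_mz=entry.get("product_mz"),
                neutral_loss_formula=entry.get("neutral_loss_formula"),
            )
        except Exception as exc:
            raise ValueError(f"query {name!r} (entry {i}) failed to parse: {exc}") from exc
        queries.append(nq)
    if not queries:
        log.warning("%s: empty query set", path)
    return queries


def discover_runs(mzml_directory: str | Path) -> list[Path]:
    d = Path(mzml_directory)
    if not d.is_dir():
        raise FileNotFoundError(f"mzML directory not found: {d}")
    paths = sorted(
        p for p in d.iterdir() if p.name.lower().endswith((".mzml", ".mzml.gz"))
    )
    if not paths:
        raise FileNotFoundError(f"no mzML files in {d}")
    return paths


def _order_runs(runs: list[RunData]) -> list[RunData]:
    # acquisition order: startTimeStamp when every run has one, else file name
    if all(r.acquisition_date for r in runs):
        return sorted(runs, key=lambda r: (r.acquisition_date, r.run_id))
    return sorted(runs, key=lambda r: r.run_id)


def process_run(
    run: RunData, queries: Sequence[NamedQuery], config: SSTConfig
) -> list[dict]:
    """All per-(run x query) records for one loaded run."""
    from .massql_engine import evaluate_query

    records = []
    for nq in queries:
        matches = evaluate_query(run, nq.ast)
        eic = build_eic(matches, run, nq.ast)
        eic.query_name = nq.name
        peak = integrate_peak(eic, min_scans=config.min_scans, apex_floor=config.apex_floor)
        observed_mz = ppm = None
        if peak.found and not matches.empty:
            apex_rows = matches[np.isclose(matches["rt_minutes"], peak.apex_rt)]
            if not apex_rows.empty:
                observed_mz = float(apex_rows["observed_mz"].iloc[0])
                ppm = float(apex_rows["ppm_error"].iloc[0])
        records.append(
            {
                "run_id": run.run_id,
                "query_name": nq.name,
                "found": peak.found,
                "apex_rt": peak.apex_rt,
                "apex_intensity": peak.apex_intensity,
                "area": peak.area,
                "observed_mz": observed_mz,
                "ppm_error": ppm,
            }
        )
    return records


def run_batch(
    config: SSTConfig, queries: Optional[Sequence[NamedQuery]] = None
) -> tuple[pd.DataFrame, list[str]]:
    """Apply every query to every run in the configured directory.

    Returns ``(records, errors)``: a frame with exactly one row per
    (readable run x query), and per-file error strings for runs that
    failed to load or process — a bad file never aborts the batch.
    """
    if queries is None:
        queries = load_queryset(config.query_file)
    if not queries:
        raise ValueError("no queries to apply")
    paths = discover_runs(config.mzml_directory)

    runs: list[RunData] = []
    errors: list[str] = []
    for p in paths:
        try:
            runs.append(read_run(p))
        except Exception as exc:
            errors.append(f"{p.name}: {exc}")
            log.error("failed to read %s: %s", p.name, exc)
    all_records: list[dict] = []
    for idx, run in enumerate(_order_runs(runs)):
        try:
            recs = process_run(run, queries, config)
        except Exception as exc:
            errors.append(f"{run.run_id}: {exc}")
            log.error("failed to process %s: %s", run.run_id, exc)
            continue
        for r in recs:
            r["run_index"] = idx
        all_records.extend(recs)
    records = pd.DataFrame(all_records, columns=RECORD_COLUMNS)
    return records, errors


def _rsd(mean: float, sd: float) -> Optional[float]:
    if mean > 0:
        return sd / mean * 100.0
    return None


def summarize(records: pd.DataFrame) -> pd.DataFrame:
    """Per-query cross-run statistics over *found* records only.

    Sample (n-1) standard deviations; RSD = sd/mean x 100, reported only
    when n_found >= 2 and the mean is positive. ``n_found`` makes
    missingness visible rather than distorting the means.
    """
    rows = []
    for name, grp in records.groupby("query_name", sort=False):
        found = grp[grp["found"].astype(bool)]
        row: dict = {
            "query_name": name,
            "n_runs": int(len(grp)),
            "n_found": int(len(found)),
            "rt_mean": None, "rt_sd": None, "rt_rsd_pct": None,
            "area_mean": None, "area_sd": None, "area_rsd_pct": None,
        }
        if len(found) >= 1:
            row["rt_mean"] = float(found["apex_rt"].mean())
            row["area_mean"] = float(found["area"].mean())
        if len(found) >= 2:
            row["rt_sd"] = float(found["apex_rt"].std(ddof=1))
            row["area_sd"] = float(found["area"].std(ddof=1))
            row["rt_rsd_pct"] = _rsd(row["rt_mean"], row["rt_sd"])
            row["area_rsd_pct"] = _rsd(row["area_mean"], row["area_sd"])
        rows.append(row)
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


@dataclass(frozen=True)
class ReferenceRT:
    """Expected elution behaviour of one analyte for deficiency flagging."""

    expected_rt: float
    rt_min: Optional[float] = None
    rt_max: Optional[float] = None


def reference_from_queries(queries: Sequence[NamedQuery]) -> dict[str, ReferenceRT]:
    """Expected RTs from the queries' own RT windows (midpoints).

    Queries without an RT window are skipped (no expectation available).
    """
    ref = {}
    for nq in queries:
        lo, hi = nq.ast.rt_window
        if lo is not None and hi is not None:
            ref[nq.name] = ReferenceRT(expected_rt=(lo + hi) / 2, rt_min=lo, rt_max=hi)
    return ref


def reference_from_summary(summary: pd.DataFrame, window_halfwidth: float = 0.165) -> dict[str, ReferenceRT]:
    """Expected RTs from a historical cross-run summary (means +/- halfwidth)."""
    ref = {}
    for _, row in summary.iterrows():
        if row["rt_mean"] is not None and not pd.isna(row["rt_mean"]):
            m = float(row["rt_mean"])
            ref[row["query_name"]] = ReferenceRT(m, m - window_halfwidth, m + window_halfwidth)
    return ref


def flag_deviations(
    records: pd.DataFrame,
    reference: Mapping[str, ReferenceRT],
    rt_shift_margin: float = 0.1,
) -> pd.DataFrame:
    """Per-run deficiency flags against expected retention behaviour.

    ``MISSING_ANALYTE``: query found no peak in that run. ``RT_SHIFT``:
    apex outside the analyte's expected RT window widened by
    ``rt_shift_margin`` minutes on each side (falls back to
    expected_rt +/- margin when the reference has no window).
    ``ELUTION_ORDER``: the rank order of apex RTs across analytes in a
    run is discordant with the reference order (any discordant pair
    triggers; a full inversion is reported as a reversal). Queries
    missing from the reference are skipped with a warning.
    """
    flags: list[dict] = []
    for name in records["query_name"].unique():
        if name not in reference:
            log.warning("flagging: no reference RT for query %r; skipped", name)
    for run_id, grp in records.groupby("run_id", sort=False):
        observed: dict[str, float] = {}
        for _, rec in grp.iterrows():
            name = rec["query_name"]
            if not rec["found"]:
                flags.append(
                    {"run_id": run_id, "query_name": name, "flag": "MISSING_ANALYTE",
                     "detail": "no chromatographic peak found"}
                )
                continue
            if name not in reference:
                continue
            ref = reference[name]
            observed[name] = float(rec["apex_rt"])
            lo = ref.rt_min if ref.rt_min is not None else ref.expected_rt
            hi = ref.rt_max if ref.rt_max is not None else ref.expected_rt
            lo -= rt_shift_margin
            hi += rt_shift_margin
            if not (lo <= rec["apex_rt"] <= hi):
                flags.append(
                    {"run_id": run_id, "query_name": name, "flag": "RT_SHIFT",
                     "detail": (
                         f"apex_rt {rec['apex_rt']:.3f} outside expected "
                         f"[{lo:.3f}, {hi:.3f}] (expected {ref.expected_rt:.3f})"
                     )}
                )
        # elution-order check over analytes found in this run with references
        names = [n for n in observed if n in reference]
        if len(names) >= 2:
            obs_rt = [observed[n] for n in names]
            exp_rt = [reference[n].expected_rt for n in names]
            tau, _ = kendalltau(exp_rt, obs_rt)
            n = len(names)
            n_pairs = n * (n - 1) // 2
            n_discordant = sum(
                1
                for i in range(n)
                for j in range(i + 1, n)
                if (exp_rt[i] - exp_rt[j]) * (obs_rt[i] - obs_rt[j]) < 0
            )
            if n_discordant > 0:
                detail = f"{n_discordant}/{n_pairs} analyte pairs discordant (kendall tau {tau:.2f})"
                if n_discordant == n_pairs:
                    detail += "; full elution-order reversal"
                flags.append(
                    {"run_id": run_id, "query_name": "", "flag": "ELUTION_ORDER",
                     "detail": detail}
                )
    return pd.DataFrame(flags, columns=FLAG_COLUMNS)


def rt_rsd_benchmark(summary: pd.DataFrame, max_rsd_pct: float = 2.3) -> bool:
    """Longitudinal RT-reproducibility benchmark: every analyte's
    retention-time RSD at or below ``max_rsd_pct`` percent.

    Intended for historical datasets spanning many acquisition days;
    returns False when any analyte exceeds the bound or no RSD is
    defined.
    """
    rsd = summary["rt_rsd_pct"].dropna()
    if rsd.empty:
        return False
    return bool((rsd <= max_rsd_pct).all())


def export_results(
    records: pd.DataFrame,
    summary: pd.DataFrame,
    flags: pd.DataFrame,
    output_directory: str | Path,
) -> dict[str, Path]:
    """Write records/summary/flags as CSVs plus a single XLSX workbook.

    Column names and order are the module-level ``*_COLUMNS`` constants.
    Re-exporting identical inputs produces byte-identical CSVs.
    """
    out = Path(output_directory)
    out.mkdir(parents=True, exist_ok=True)
    tables = {
        "records": records.reindex(columns=RECORD_COLUMNS),
        "summary": summary.reindex(columns=SUMMARY_COLUMNS),
        "flags": flags.reindex(columns=FLAG_COLUMNS),
    }
    paths: dict[str, Path] = {}
    for name, frame in tables.items():
        p = out / f"{name}.csv"
        frame.to_csv(p, index=False)
        paths[name] = p
    xlsx = out / "sst_results.xlsx"
    with pd.ExcelWriter(xlsx, engine="openpyxl") as writer:
        for name, frame in tables.items():
            frame.to_excel(writer, sheet_name=name, index=False)
    paths["xlsx"] = xlsx
    return paths
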