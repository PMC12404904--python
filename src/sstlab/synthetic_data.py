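"""Deterministic synthetic LC-MS runs emulating a six-analyte
deuterated-acylcarnitine system-suitability panel.

MS1 runs carry one Gaussian chromatographic elution profile per analyte
(centroid peak at the precursor m/z, optional multiplicative log-normal
intensity noise and ppm m/z jitter). DDA runs interleave, inside each
analyte's elution window, a ladder of MS2 scans after every survey scan:
HCD at each normalized collision energy ascending, then CID ascending,
with fragment intensities realizing configured fractions of a constant
nominal TIC (the precursor survivor peak absorbs the remainder, so
per-scan normalization recovers the configured fractions exactly in the
noiseless case).

Everything is seeded; identical (spec, seed) reproduces identical runs.
Variant fixtures emulate instrument deficiencies: ``reversed`` permutes
the apex RTs into reverse elution order (wrong column/method scenario),
``shifted`` moves the late-eluting analytes +0.3 min (column lot-shift
scenario).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .formula_mass import adduct_mz, parse_formula
from .mzml_io import RunData, SpectrumRecord, write_run
from .sst_batch import NamedQuery, ReferenceRT

__all__ = [
    "AnalyteSpec",
    "GeneratorSpec",
    "FixtureBundle",
    "DEFAULT_NCES",
    "default_panel",
    "default_sst_fixture",
    "synth_ms1_run",
    "synth_dda_run",
    "write_fixture",
]

DEFAULT_NCES = (10.0, 20.0, 30.0, 40.0, 50.0, 60.0)

#: diagnostic product ion common to all acylcarnitines (C4H5O2+)
COMMON_PRODUCT_MZ = 85.0284

# per-(activation, NCE) fraction of MS2 TIC for the two fragment channels:
# the common m/z 85.0284 ion and the trimethylamine(-d3) neutral-loss product.
# Beam-type activation (HCD) favors the low-mass ion at all energies; resonant
# activation (CID) yields the neutral-loss product predominantly above NCE 30.
_FRAC_85 = {
    "HCD": {10.0: 0.05, 20.0: 0.15, 30.0: 0.30, 40.0: 0.50, 50.0: 0.65, 60.0: 0.75},
    "CID": {10.0: 0.02, 20.0: 0.05, 30.0: 0.10, 40.0: 0.18, 50.0: 0.25, 60.0: 0.30},
}
_FRAC_NL = {
    "HCD": {10.0: 0.02, 20.0: 0.02, 30.0: 0.02, 40.0: 0.02, 50.0: 0.02, 60.0: 0.02},
    "CID": {10.0: 0.02, 20.0: 0.05, 30.0: 0.10, 40.0: 0.30, 50.0: 0.40, 60.0: 0.45},
}

# name, molecular formula, elution window (min), analyte-specific product ion
# m/z, neutral-loss formula where that product corresponds to loss of
# trimethylamine or its d3 analog (deuteration site differs per analyte)
_PANEL_TABLE = [
    ("acetylcarnitine_d3", "C9H14D3NO4", (1.11, 1.44), 148.0684, "C3H9N"),
    ("propionylcarnitine_d3", "C10H16D3NO4", (3.28, 3.61), 159.0650, "C3H6D3N"),
    ("valerylcarnitine_d3", "C12H20D3NO4", (4.13, 4.46), 190.1154, "C3H9N"),
    ("octanoylcarnitine_d3", "C15H26D3NO4", (5.74, 6.07), 229.1435, "C3H6D3N"),
    ("lauroylcarnitine_d3", "C19H34D3NO4", (7.44, 7.77), 183.1744, None),
    ("oleoylcarnitine_d3", "C25H44D3NO4", (9.27, 9.59), 367.2804, None),
]


@dataclass(frozen=True)
class AnalyteSpec:
    name: str
    precursor_mz: float
    apex_rt: float       # minutes
    sigma_rt: float      # minutes, Gaussian elution width
    amplitude: float     # apex MS1 intensity
    rt_window: tuple[float, float]  # DDA trigger / expected elution window
    #: (activation, nce) -> ((product m/z, fraction of MS2 TIC), ...)
    fragments: Mapping[tuple[str, float], tuple[tuple[float, float], ...]] = field(
        default_factory=dict
    )
    product_mz: Optional[float] = None
    neutral_loss_formula: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.sigma_rt > 0:
            raise ValueError("sigma_rt must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        for key, frags in self.fragments.items():
            total = sum(f for _, f in frags)
            if total > 1.0 + 1e-12:
                raise ValueError(
                    f"{self.name} {key}: fragment fractions sum to {total} > 1"
                )


@dataclass(frozen=True)
class GeneratorSpec:
    analytes: tuple[AnalyteSpec, ...]
    ms1_interval: float = 0.02       # minutes between survey scans
    run_length: float = 10.0         # minutes
    intensity_noise_sd: float = 0.0  # multiplicative log-normal sigma
    mz_jitter_ppm_sd: float = 0.0
    seed: int = 0
    ms2_tic: float = 1.0e5
    isolation_width_mz: float = 1.5
    nces: tuple[float, ...] = DEFAULT_NCES

    def __post_init__(self) -> None:
        if not self.ms1_interval > 0 or not self.run_length > 0:
            raise ValueError("ms1_interval and run_length must be positive")


def _analyte_fragments(precursor_mz: float, product_mz: Optional[float]) -> dict:
    """Fragment table over the NCE x activation grid for one analyte."""
    table = {}
    for activation in ("HCD", "CID"):
        for nce in DEFAULT_NCES:
            frags = [(COMMON_PRODUCT_MZ, _FRAC_85[activation][nce])]
            if product_mz is not None:
                frags.append((product_mz, _FRAC_NL[activation][nce]))
            table[(activation, nce)] = tuple(frags)
    return table


def default_panel(amplitude: float = 1.0e6, sigma_rt: float = 0.05) -> tuple[AnalyteSpec, ...]:
    """The six-analyte deuterated-acylcarnitine panel.

    Apex RTs sit at the midpoint of each analyte's published elution
    window; the Gaussian width (default sigma 0.05 min) keeps >99.9% of
    the peak inside the ~0.33 min window.
    """
    analytes = []
    for name, formula, window, product_mz, nl_formula in _PANEL_TABLE:
        mz = adduct_mz(parse_formula(formula), "[M+H]+")
        analytes.append(
            AnalyteSpec(
                name=name,
                precursor_mz=mz,
                apex_rt=(window[0] + window[1]) / 2,
                sigma_rt=sigma_rt,
                amplitude=amplitude,
                rt_window=window,
                fragments=_analyte_fragments(mz, product_mz),
                product_mz=product_mz,
                neutral_loss_formula=nl_formula,
            )
        )
    return tuple(analytes)


def _apply_variant(analytes: Sequence[AnalyteSpec], variant: str) -> tuple[AnalyteSpec, ...]:
    if variant == "default":
        return tuple(analytes)
    if variant == "reversed":
        # wrong column/method: elution order fully inverted
        apexes = [a.apex_rt for a in analytes]
        return tuple(
            replace(a, apex_rt=apex, rt_window=(apex - 0.165, apex + 0.165))
            for a, apex in zip(analytes, reversed(apexes))
        )
    if variant == "shifted":
        # column lot issue: late eluters (RT >= 5 min) shifted +0.3 min
        return tuple(
            replace(
                a,
                apex_rt=a.apex_rt + 0.3,
                rt_window=(a.rt_window[0] + 0.3, a.rt_window[1] + 0.3),
            )
            if a.apex_rt >= 5.0
            else a
            for a in analytes
        )
    raise ValueError(f"unknown variant {variant!r}; use default|reversed|shifted")


def _run_scale_factors(spec: GeneratorSpec, rng: np.random.Generator) -> dict[str, float]:
    """One multiplicative log-normal factor per analyte per run: emulates
    day-to-day intensity variation, so over n runs the batch area RSD
    converges to 100*sqrt(exp(s^2)-1)."""
    if spec.intensity_noise_sd <= 0:
        return {a.name: 1.0 for a in spec.analytes}
    return {
        a.name: float(np.exp(rng.normal(0.0, spec.intensity_noise_sd)))
        for a in spec.analytes
    }


def _ms1_peaks(
    spec: GeneratorSpec, t: float, rng: np.random.Generator, scale: dict[str, float]
) -> tuple[np.ndarray, np.ndarray]:
    mz_list, int_list = [], []
    for a in spec.analytes:
        if a.amplitude == 0:
            continue
        intensity = (
            a.amplitude
            * scale[a.name]
            * float(np.exp(-((t - a.apex_rt) ** 2) / (2 * a.sigma_rt**2)))
        )
        if intensity < 1e-6 * a.amplitude * scale[a.name]:
            continue
        mz = a.precursor_mz
        if spec.mz_jitter_ppm_sd > 0:
            mz *= 1.0 + rng.normal(0.0, spec.mz_jitter_ppm_sd) * 1e-6
        mz_list.append(mz)
        int_list.append(intensity)
    if not mz_list:
        return np.array([]), np.array([])
    order = np.argsort(mz_list)
    mz_arr = np.asarray(mz_list)[order]
    int_arr = np.asarray(int_list)[order]
    # coinciding m/z from two analytes: intensities summed
    uniq, inverse = np.unique(mz_arr, return_inverse=True)
    summed = np.zeros_like(uniq)
    np.add.at(summed, inverse, int_arr)
    return uniq, summed


def synth_ms1_run(spec: GeneratorSpec, run_id: str = "synthetic_ms1") -> RunData:
    """MS1-only run: survey scans on the configured interval."""
    rng = np.random.default_rng(spec.seed)
    scale = _run_scale_factors(spec, rng)
    scans = []
    times = np.arange(0.0, spec.run_length + 1e-9, spec.ms1_interval)
    for i, t in enumerate(times):
        mz, inten = _ms1_peaks(spec, float(t), rng, scale)
        scans.append(
            SpectrumRecord(
                scan_id=f"scan={i + 1}",
                ms_level=1,
                rt_minutes=float(t),
                mz_array=mz,
                intensity_array=inten,
            )
        )
    return RunData(run_id=run_id, scans=scans)


def _ms2_scan(
    spec: GeneratorSpec,
    analyte: AnalyteSpec,
    rt: float,
    scan_id: str,
    activation: str,
    nce: float,
) -> SpectrumRecord:
    frags = analyte.fragments.get((activation, nce), ())
    assigned = sum(f for _, f in frags)
    peaks = [(mz, frac * spec.ms2_tic) for mz, frac in frags]
    # survivor precursor absorbs the unassigned fraction: constant scan TIC
    peaks.append((analyte.precursor_mz, (1.0 - assigned) * spec.ms2_tic))
    peaks = [(mz, i) for mz, i in peaks if i > 0]
    peaks.sort()
    mz_arr = np.array([p[0] for p in peaks])
    int_arr = np.array([p[1] for p in peaks])
    return SpectrumRecord(
        scan_id=scan_id,
        ms_level=2,
        rt_minutes=rt,
        mz_array=mz_arr,
        intensity_array=int_arr,
        precursor_mz=analyte.precursor_mz,
        isolation_width_mz=spec.isolation_width_mz,
        activation=activation,
        collision_energy=nce,
    )


def synth_dda_run(spec: GeneratorSpec, run_id: str = "synthetic_dda") -> RunData:
    """DDA run: each survey scan is followed, per in-window analyte, by
    HCD MS2 scans at ascending NCE then CID MS2 scans at ascending NCE."""
    rng = np.random.default_rng(spec.seed)
    scale = _run_scale_factors(spec, rng)
    scans: list[SpectrumRecord] = []
    times = np.arange(0.0, spec.run_length + 1e-9, spec.ms1_interval)
    counter = 0
    for t in times:
        counter += 1
        mz, inten = _ms1_peaks(spec, float(t), rng, scale)
        scans.append(
            SpectrumRecord(
                scan_id=f"scan={counter}",
                ms_level=1,
                rt_minutes=float(t),
                mz_array=mz,
                intensity_array=inten,
            )
        )
        triggered = [
            a for a in spec.analytes if a.rt_window[0] <= t <= a.rt_window[1]
        ]
        ladder = [("HCD", n) for n in spec.nces] + [("CID", n) for n in spec.nces]
        n_ms2 = len(triggered) * len(ladder)
        if n_ms2 == 0:
            continue
        dt = spec.ms1_interval / (n_ms2 + 1)
        k = 0
        for a in triggered:
            for activation, nce in ladder:
                k += 1
                counter += 1
                scans.append(
                    _ms2_scan(
                        spec, a, float(t) + k * dt, f"scan={counter}", activation, nce
                    )
                )
    return RunData(run_id=run_id, scans=scans)


@dataclass(frozen=True)
class FixtureBundle:
    """Ready-to-run desk-scale fixture: generator spec + query set + flagging reference."""

    generator: GeneratorSpec
    queries: tuple[NamedQuery, ...]
    reference: Mapping[str, ReferenceRT]
    variant: str = "default"


def _panel_queries(analytes: Sequence[AnalyteSpec], tolerance_ppm: float = 10.0) -> tuple[NamedQuery, ...]:
    # deliberately un-windowed so displaced peaks are still detected and
    # deficiency flags (not missing analytes) describe the failure
    out = []
    for a in analytes:
        text = f"QUERY scansum(MS1DATA) WHERE MS1MZ={a.precursor_mz:.4f} AND TOLERANCEPPM={tolerance_ppm:g}"
        out.append(
            NamedQuery(
                name=a.name,
                query=text,
                product_mz=COMMON_PRODUCT_MZ,
                neutral_loss_formula=a.neutral_loss_formula,
            )
        )
    return tuple(out)


def default_sst_fixture(seed: int = 0, variant: str = "default") -> FixtureBundle:
    """Desk-scale emulation of the six-analyte panel.

    The flagging reference always carries the *default* (expected)
    elution windows, so the reversed and shifted variants are judged
    against the healthy panel exactly as a historical reference would be.
    """
    healthy = default_panel()
    analytes = _apply_variant(healthy, variant)
    spec = GeneratorSpec(analytes=analytes, seed=seed)
    reference = {
        a.name: ReferenceRT(
            expected_rt=(a.rt_window[0] + a.rt_window[1]) / 2,
            rt_min=a.rt_window[0],
            rt_max=a.rt_window[1],
        )
        for a in healthy
    }
    return FixtureBundle(
        generator=spec,
        queries=_panel_queries(analytes),
        reference=reference,
        variant=variant,
    )


def write_fixture(
    out_dir: str | Path,
    seed: int = 0,
    variant: str = "default",
    n_runs: int = 3,
    dda: bool = False,
    intensity_noise_sd: float = 0.0,
    mz_jitter_ppm_sd: float = 0.0,
) -> Path:
    """Write a complete fixture bundle: mzML runs, queries.json, config.json.

    Runs are dated on consecutive days so acquisition ordering is
    exercised. Returns the path of the config file, ready for
    :func:`sstlab.sst_batch.run_batch` or the CLI.
    """
    out = Path(out_dir)
    mzml_dir = out / "mzml"
    mzml_dir.mkdir(parents=True, exist_ok=True)
    bundle = default_sst_fixture(seed=seed, variant=variant)
    for i in range(n_runs):
        spec = replace(
            bundle.generator,
            seed=seed + i,
            intensity_noise_sd=intensity_noise_sd,
            mz_jitter_ppm_sd=mz_jitter_ppm_sd,
            ms1_interval=0.05 if dda else bundle.generator.ms1_interval,
        )
        run_id = f"sst_{variant}_{i + 1:02d}"
        run = synth_dda_run(spec, run_id) if dda else synth_ms1_run(spec, run_id)
        run.acquisition_date = f"2024-09-{i + 1:02d}T08:00:00Z"
        write_run(run, mzml_dir / f"{run_id}.mzML")

    queries_path = out / "queries.json"
    with open(queries_path, "w") as fh:
        json.dump(
            [
                {
                    "name": q.name,
                    "query": q.query,
                    "product_mz": q.product_mz,
                    "neutral_loss_formula": q.neutral_loss_formula,
                }
                for q in bundle.queries
            ],
            fh,
            indent=1,
        )
    reference_path = out / "reference.json"
    with open(reference_path, "w") as fh:
        json.dump(
            {
                name: {"expected_rt": r.expected_rt, "rt_min": r.rt_min, "rt_max": r.rt_max}
                for name, r in bundle.reference.items()
            },
            fh,
            indent=1,
        )
    config_path = out / "config.json"
    with open(config_path, "w") as fh:
        json.dump(
            {
                "mzml_directory": str(mzml_dir),
                "query_file": str(queries_path),
                "output_directory": str(out / "results"),
                "reference_file": str(reference_path),
            },
            fh,
            indent=1,
        )
    return config_path
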