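# Methods

## Scope and model

`sstlab` implements system suitability testing (SST) as a batch
computation over centroided LC–MS runs in mzML: a set of named queries
in a small query-language dialect is applied to every run in a
directory, each (run × query) result is reduced to one chromatographic
peak record, and cross-run statistics plus rule-based deficiency flags
summarize instrument health. The statistical model is deliberately
minimal — SST review is about detecting gross departures from expected
behaviour, not estimation — so the package computes means, sample
standard deviations and relative standard deviations (RSD), and uses
rank statistics only for elution-order checks.

## Exact-mass arithmetic

Monoisotopic masses use NIST values to ≥ 6 decimals; deuterium is a
first-class element symbol `D` (input `²H` is normalized). Charged
species account for the electron: the `[M+H]+` adduct adds the proton
mass 1.007276466 Da rather than the hydrogen-atom mass — the two differ
by the electron mass (0.000549 Da), which is visible at the fourth
decimal of m/z and required to reproduce published four-decimal adduct
values for the acylcarnitine panel. Cation m/z for a radical-free
fragment formula (e.g. C₄H₅O₂⁺ = 85.0284) is the neutral-composition
mass minus one electron mass.

ppm error is anchored at the *query* (reference) m/z, not the observed
value: the query is the fixed reference in longitudinal use, and the
asymmetry between the two conventions is below 10⁻⁴ ppm at 10 ppm
offsets. Tolerance boundaries are inclusive in both ppm and absolute
mode, so a peak at exactly the stated tolerance still matches.

Published product-ion m/z values for the panel are treated as query
*inputs*, not derivable ground truth: several of them differ from
strict isotope-mass arithmetic in the fourth decimal, and one
(oleoylcarnitine-d3, 367.2804) is ~0.004 Da from any trimethylamine(-d3)
loss. Where a printed product ion does correspond to a trimethylamine
or trimethylamine-d3 loss within 10 ppm, the per-analyte neutral-loss
formula is configured accordingly (acetyl/valeryl: C3H9N;
propionyl/octanoyl: C3H6D3N — the deuteration site differs by analyte);
lauroyl and oleoyl carry no neutral-loss target by default.

## mzML I/O

Retention time is canonically **minutes** everywhere inside the
package; second- and millisecond-annotated scan start times are
converted at the I/O boundary only. The reader is a streaming lxml
parser for mzML 1.1.x (plain, indexed, or gzipped; 32/64-bit float
arrays, zlib or uncompressed); the writer emits schema-valid plain mzML
1.1.0 with uncompressed 64-bit arrays. Both are intentionally narrow:
no vendor formats, no mzXML, no SRM chromatogram elements, no
ion-mobility arrays.

Reader behaviour at the edges: scans are never reordered (RT
monotonicity violations produce a warning); profile-mode spectra are
loaded with a warning and their points treated as centroid peaks, which
degrades gracefully under tolerance matching; an unsupported schema
version is an error rather than a silent skip; TIC is always recomputed
from the peak list, never trusted from file metadata; zero-peak scans
are retained because EIC zero-filling depends on them. Activation
controlled-vocabulary terms map beam-type collision-induced
dissociation → HCD and resonant collision-induced dissociation → CID;
any other dissociation term → `other`, absent metadata → `unknown`.

## Query engine

The grammar is the SST-relevant subset: `QUERY action(source) WHERE
cond AND cond ...` with actions `scansum`/`scaninfo`, sources
`MS1DATA`/`MS2DATA`, and the conditions listed in the README. The full
published language (variables, isotope-pattern, intensity and
ion-mobility conditions) is out of scope; `ConditionSpec` is the
extension point. `scansum` and `scaninfo` share matching semantics —
`scansum` feeds EIC construction, `scaninfo` carries scan metadata to
reports; no other semantic difference is implemented.

Per-scan evaluation: RT window closed on both ends; `MS1MZ`/`MS2PROD`
match any centroid peak within tolerance; `MS2NL` matches a peak whose
difference from the *recorded* precursor m/z (never a recomputed one)
is within tolerance of the loss value; `MS2PREC` gates on the recorded
precursor. Matched intensity sums every qualifying peak in the scan;
the reported observed m/z is the intensity-weighted mean of the matched
peaks (the convention is unstated upstream; the weighted mean is stable
under centroid splitting), and the per-scan ppm error derives from it.
Rows are emitted only for matching scans and sorted by RT, making
results invariant to storage order.

## EIC and peak integration

The EIC grid is every scan RT at the query's MS level inside the RT
window (the whole run without a window); matched intensities land on
their scans and everything else is zero-filled. Interleaved MS2 scans
never perturb an MS1 grid. An empty grid is an error distinct from an
all-zero EIC ("no scans in window" vs "no signal").

The peak is the contiguous nonzero segment containing the global apex
(earliest RT wins intensity ties), extended by the first baseline-zero
sample on each side so that the leading and trailing flanks contribute
to the integral; a peak is *found* when the apex exceeds `apex_floor`
(default 0) and the segment spans ≥ `min_scans` points (default 3).
Area is the trapezoidal integral over the segment in intensity·minutes
— exact for piecewise-linear signals and within 1% of the analytic
value for a Gaussian sampled at σ/10. There is no smoothing, baseline
subtraction, deconvolution, or peak-shape metric, and multiple local
maxima in one window are never split: the design assumes one analyte
per query window. Integration is over the detected segment, not the
full query window; for a well-windowed analyte the two agree except for
zero-intensity flanking samples, which contribute nothing.

## Batch statistics and deficiency flags

Runs are ordered by the mzML `startTimeStamp` when every run has one,
else by filename, and the order is recorded in `run_index`. One record
per (run × query) always exists — a failure to find a peak is a
`found=false` record, and a file that fails to read is logged and
skipped without aborting the batch.

Summaries use the sample (n−1) SD, appropriate for small-n longitudinal
QC; statistics cover found records only, with `n_found` surfaced so
missingness is visible rather than silently distorting means. RSD is
defined only for n_found ≥ 2 and positive mean.

Flags, evaluated per run against a reference of expected apex RTs
(historical means, or the elution-window midpoints of the panel):

- `MISSING_ANALYTE` — no peak found for the query.
- `RT_SHIFT` — apex outside the expected window widened by
  `rt_shift_margin` (default 0.1 min per side; the margin keeps
  ordinary scan-grid and gradient jitter from alarming while still
  catching sub-window shifts of ~0.15 min and larger).
- `ELUTION_ORDER` — any discordant pair between observed and expected
  apex-RT rank order (Kendall-style); a fully discordant run is
  annotated as a complete reversal. Rank comparison rather than
  absolute RT is used because the characteristic failure (wrong column
  or method) reorders analytes wholesale.

The fixture query set deliberately omits RT windows so that displaced
peaks are still *detected* and the flags — not missing-analyte records
— describe the failure; the expected windows live in the flagging
reference instead. A windowed query set remains fully supported and is
the right choice when co-eluting interferences are a concern.

Mass accuracy is reported implicitly: the ppm error at the apex scan is
carried in every record, and scans beyond tolerance never match in the
first place; there is no separate mass-accuracy pass.

`rt_rsd_benchmark(summary, max_rsd_pct=2.3)` encodes the longitudinal
acceptance bound for retention-time RSD per analyte. Long-horizon
(multi-month) instrument datasets are external to this repository, so
within the test suite the benchmark is exercised on synthetic
longitudinal batches; against real historical exports it is a one-line
check.

## MS/MS consistency profiling

MS2 scans are selected per analyte by recorded precursor m/z within
tolerance (plus an optional RT window). Normalization divides the
summed matched product-ion (or neutral-loss) intensity by the scan TIC,
bounding every value to [0, 1] and absorbing the total-signal variation
as spectra are triggered across the elution profile; "intensity of the
product-ion scan" could also be read as base-peak intensity, so a
`base_peak` denominator is available as an option, but TIC is the
default precisely because of the [0, 1] bound. Zero-TIC scans yield a
null with a warning and are excluded from aggregation.

Aggregation groups by (analyte × activation × NCE × target) with
sample SD across all qualifying scans over all supplied runs; grouping
is therefore invariant to run order and to splitting scans across
files. NCE values are grouped by stated value with a 10⁻³ matching
tolerance; scans with unknown activation or missing NCE aggregate under
an explicit `unknown` group rather than being dropped.

## Synthetic data generator

The generator emulates the six-analyte deuterated-acylcarnitine panel:
Gaussian elution peaks at the panel's protonated m/z values, apexes at
the midpoints of the published elution windows (1.275 … 9.43 min),
σ = 0.05 min (≈ 3.3σ half-window: > 99.9% of area inside the window),
amplitude 10⁶, survey scans every 0.02 min over a 10-min run (0.05 min
in DDA mode, reflecting the MS1 cadence cost of MS2 ladders). DDA runs
follow each in-window survey scan with HCD MS2 scans at NCE
10/20/30/40/50/60 ascending, then CID likewise — the inclusion-list
pattern of the emulated acquisition. MS2 fragment fractions are fixed
per (activation, NCE): the m/z 85.0284 channel rises monotonically with
NCE and is larger under HCD than CID at every energy, while the
trimethylamine(-d3) neutral-loss channel is substantial only for CID
above NCE 30 — qualitatively the behaviour of beam-type vs resonant
activation for these compounds. The precursor survivor peak absorbs the
unassigned fraction so every MS2 scan has the same TIC and
normalization recovers the configured fractions exactly.

Noise model: one multiplicative log-normal factor per analyte per run
(day-to-day intensity variation; over n runs the area RSD converges to
100·√(exp(s²)−1)) and optional per-peak Gaussian m/z jitter in ppm.
Defaults are noiseless, because the acceptance properties are exact
recovery checks. Deliberately absent, and therefore untested here:
chemical background, peak tailing/fronting, detector saturation,
isotope envelopes, co-eluting interferences, and mass-calibration
drift. Passing tests on this generator demonstrate correctness of the
pipeline's bookkeeping and numerics, not robustness to real
chromatography.

Variants for deficiency testing: `reversed` permutes apex RTs into
reverse elution order (wrong column/method scenario); `shifted` moves
the three late eluters (apex ≥ 5 min) +0.3 min (column lot scenario,
chosen to clear the window + 0.1 min margin by 0.035 min). All
randomness is seeded and confined to this module; identical
(spec, seed) produces byte-identical mzML.

## Problem sizes and determinism

The shipped tests run the full pipeline on 3-run batches (501 survey
scans per run) and 5-day DDA sets (~680 scans per run), sizes at which
every acceptance property is exact or analytic; the pipeline itself is
deterministic end-to-end, and re-exporting identical inputs produces
byte-identical CSV tables. `scripts/acceptance.py` reports the
panel's exact-mass reference quantities, which involve no sampling at
all; its `--seed` argument is accepted for interface uniformity.

## Known limitations

- The query dialect is the SST subset, not the full published language.
- One peak per query window; overlapping analytes sharing an m/z
  tolerance window are summed, not resolved.
- The mzML writer targets the package's own fixtures (centroid, 64-bit,
  uncompressed); it is not a general converter.
- `scansum`/`scaninfo` differ only in downstream use, not matching
  semantics.
- Flag thresholds (`rt_shift_margin`, elution-order discordance) are
  rule-based and panel-agnostic; labs with very tight or very loose
  gradients should tune the margin in the batch configuration.
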