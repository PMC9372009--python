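# Methods

This note documents the models and algorithms implemented in `gcscreen`,
the parameters that matter, what the synthetic-data generator does and does
not emulate, and the numerical choices made where the design was open.

## Data model and centroiding

A run is a strictly RT-ordered list of scans (profile or centroid) with the
scan period inferred as the median inter-scan interval (up to ~10% jitter is
tolerated). Units are seconds, Da, and detector counts throughout.

Profile scans are centroided by segmenting the points above an intensity
floor into local-maximum regions and taking, per region, the
intensity-weighted mean m/z and the apex intensity. Two segmentation rules:

* regions split at interior valleys (strict local minima), so partially
  resolved profile peaks yield one centroid each;
* regions also split at m/z gaps wider than 5× the scan's median sampling
  step. Instrument profile data on a continuous raster is unaffected; the
  rule exists because sparse profile representations (including the ones
  this package simulates) carry no explicit zero baseline between peaks.

No parabolic fit is attempted. Profile-to-centroid interpolation differs
between software packages and is a known source of inter-software mass
discrepancies of tens of ppm; the weighted mean is simple, deterministic,
and its systematic behavior can be modeled explicitly in the AMT sweep.

## EIC extraction

`mz_delta` (default 0.05 Da) is interpreted as the **full** trace window:
any two peaks assigned to one EIC differ by at most `mz_delta`. Membership
is greedy in decreasing intensity order — a centroid joins the nearest
existing trace whose running intensity-weighted mean is within
`mz_delta / 2`, ties toward lower m/z, else it seeds a new trace. Every
centroid is assigned to exactly one trace, so the per-scan total ion current
is conserved exactly (this is asserted in the tests to ~1e-16 relative).

Each EIC keeps a per-scan intensity-weighted m/z trace. Chromatographic
peaks measure their ion m/z from their *own* scans, not from the whole
trace: one trace may legitimately collect near-isobaric ions of different
compounds eluting minutes apart, and the whole-trace mean would bias both.

## Peak detection and components

Traces are smoothed with a Savitzky–Golay filter (window 7 scans, order 2 by
default), local maxima are found (plateaus resolve to their midpoint —
relevant for saturated peaks), boundaries are the smoothed minima between
adjacent apexes (valley-to-valley), and areas are trapezoidal integrals of
the raw trace in counts·s. Peaks with area < `min_area` (default 10,000) are
discarded.

Components are built greedily: the tallest unclustered peak seeds a
component and collects every unclustered peak whose apex lies within

    dt = rt_window_size_factor × scan_period / 100

(factor 100 ≈ one scan period, i.e. 0.2 s at 5 Hz; the useful range spans
roughly 25–200) *and* whose fixed-length shape vector (raw trace on apex
± 12 scans, max-normalized) has Pearson correlation ≥ `shape_corr_min`
(default 0.9, a package choice) with the seed's shape. Each peak joins at
most one component; up to `max_shapes_stored` (10) shapes are retained per
component for bookkeeping only — the spectrum keeps all ions. Ion abundance
is the peak **area** (consistent with the area threshold); components with
fewer than `min_ion_peaks` (3) ions are dropped. Component spectra are
normalized to the classic EI convention, base ion = 999.

The proprietary integrator this pipeline stands in for is not public; what
downstream code depends on — the area threshold semantics, apex locations,
deterministic grouping — is specified and tested instead.

## Library matching

Ion pairing: ions below `min_mz` (30 Da) are removed from both sides; each
library ion pairs with query ions within `amt_ppm` (default 50 ppm, relative
to the library mass); conflicts resolve by smallest ppm error, ties toward
higher query intensity; pairing is one-to-one.

Scores use Stein–Scott weights w = I^0.5 · m^1.3 (exponents configurable).
With matched pairs aligned at the library m/z:

* reverse R = weighted cosine over the library's ions (unmatched library
  ions count against it; query-only ions are ignored);
* forward F = weighted cosine over the union (unmatched ions on either side
  count against it);
* match factor = 100 · (pwf·F + (1−pwf)·R).

This reproduces the documented endpoint semantics (0 = reverse, 1 = forward,
convex combination between); the exact vendor formula is unpublished, so the
score family is exposed through its exponents. The score is scale-invariant
and affine in the PWF by construction.

Retention penalty: the library RI is converted to an expected RT through the
batch's own alkane calibration, and Δ = |apex − expected| enters as

* Δ ≤ `penalty_free_s` → multiplier 1;
* Δ ≤ `rt_range_s` → penalty ramps linearly to `max_rt_penalty` score
  points, multiplier = (100 − penalty)/100;
* Δ > `rt_range_s` → the hit is rejected (a finite search range listed
  separately from the penalty ceiling implies a hard window; a soft mode
  applying the maximum penalty instead is available via `hard_reject=False`).

Entries with neither RI nor RT are scored with multiplier 1 and flagged as
lacking retention evidence. The `min_match_factor` cutoff (75) applies to
the post-penalty score by default (`threshold_on_final=False` switches to
pre-penalty, since either convention is defensible). Per-library parameters
allow the in-house/pesticide-library split (20 s vs 30 s windows); at most
`max_hits` (1) hits survive per component, ties broken by raw match, then
|ΔRT|, then name.

## Retention indices

The temperature-programmed linear convention (van den Dool–Kratz) is the
default: RI(t) = 100·n + 100·(t − t_n)/(t_{n+1} − t_n) between alkanes, with
end-segment linear extrapolation outside C7–C40 (flag via
`AlkaneCalibration.covers_rt`). The isothermal logarithmic form sits behind
`log_form=True`. The mapping is strictly increasing, piecewise linear with
knots exactly at the alkane RTs, shift-invariant, and exactly invertible.

RT-annotated libraries are migrated by ordinary least squares
rt_exp = a·rt_lib + b over anchor compounds (≥ 2; 12 in the standard
protocol), applied to every entry **before** RI conversion — correction
first, index second. The fit is exact for exactly affine anchors; slope and
intercept standard errors are reported for noisy ones.

## Evaluation machinery

Detection is name-based: a truth compound with ≥ 1 identification of the
same name is a TP, with none an FN; identifications named outside the truth
set are FPs (so matrix features matching a non-spiked library entry count as
FPs). `cutoff_for_fn_rate` returns the largest integer cutoff c with
fraction(scores < c) ≤ target, where the scores are the per-(compound,
replicate) best final scores with misses entered as 0; the integer floor
matches the convention of published cutoff tables and is verified against
exhaustive search.

The two-stage protocol (`run_experiment`): per PWF, cutoffs for 0/1/5% FN
are calibrated on the high spike level; the low level is then re-screened at
each PWF with that PWF's 5% cutoff and FP/FN tabulated. The retention
penalty is disabled during this optimization so the trade-off is purely
spectral; FP counts are reported as absolute means per sample along with
rates, since the natural denominator of an FP percentage is ambiguous.

SDL: the lowest level with detection fraction ≥ 95% *whose every higher
tested level also reaches 95%*; otherwise "not determined". With 5
replicates the 95% rule means 5/5.

## The synthetic-data generator

What it emulates, with defaults chosen once as study conditions:

* acquisition: 5 spectra/s, m/z 40–1000; profile peak FWHM = m/R(m) with
  R(m) linear between (68 Da, 5700) and (502 Da, 8400), flat outside — only
  two calibration points are available, so a two-point linear model is the
  honest choice;
* chromatography: Gaussian peaks of 3 s FWHM (exponentially-modified
  Gaussian with time constant `tailing_tau_s` for tailing compounds); a
  linear C7–C40 alkane schedule (36 s per carbon from 60 s) as the default
  oven program surrogate;
* mass error: systematic `ppm_bias` plus per-scan N(0, `ppm_sigma`); the
  centroid of a peak therefore reproduces the planted mass within
  bias ± 3σ/√(points), which the tests assert;
* spectra: 3–40 fragment ions on CHNOClBrS-plausible mass defects, base
  peak 999, RIs on a jittered grid so compounds do not co-elute by accident;
* matrix background, two adversarial ingredients by design: **analog**
  features (a non-spiked entry's full fragment set with lognormally
  perturbed intensities, σ = 0.15, plus 4–8 extra own ions at rel. 300–900)
  that a reverse search cannot distinguish from the real compound, and
  **co-eluting contaminants** (3–6 random ions at fixed absolute intensity,
  within ±0.08 s of an analyte, 60% prevalence) that ride into low-level
  analyte components and depress forward scores; plus constant
  siloxane-like column-bleed ions at 207.0323/281.0511;
* replicate variability: per-ion lognormal area jitter σ = 0.35 at both
  levels. This value represents trace-level variability of deconvoluted ion
  areas in matrix extracts (extraction + injection + detection +
  integration); materially smaller values compress all match factors into
  97–100, where integer cutoffs are coarser than the score spread and no
  realistic cutoff calibration is possible.

The standard benchmark (`standard_benchmark`): 60-entry library, 26 spiked,
levels 1× and 10× (50/500 ng/mL-equivalent), 5 replicates per level, 12
analog features, shared matrix profile across runs, per-replicate noise and
mass-error draws, all deterministic under one seed. A full benchmark is 10
runs of ~3,100 scans (≈ 630 ion peaks per run), sized so simulation plus
two-stage screening completes in about a minute on one CPU.

**What it does not emulate** — and hence what passing tests do not show
about real data: physically realistic EI fragmentation (spectra are random,
so true inter-compound spectral similarity structure is absent), isotope
fine structure, detector saturation, baseline drift, real mussel-extract
chemistry, and retention shifts between replicates (all replicates share
exact planted RTs). The generator demonstrates that the *mechanisms* —
reverse-search false positives from shared-fragment features, forward-search
false negatives from co-eluting contamination, AMT failure under centroiding
bias, RI-based isomer resolution — behave correctly, not that any specific
published rate will be reproduced on an instrument.

## Numerical choices and degenerate inputs

* Ties in EIC assignment break toward lower m/z; component seeding breaks
  ties by (height, m/z, RT); hit selection by (final score, raw match,
  |ΔRT|, name). Identical inputs give byte-identical outputs.
* Shape correlation of constant (zero-variance) shape vectors is defined as
  1 for identical vectors, else 0.
* Empty spectra, empty runs, empty component lists and empty libraries are
  legal and round-trip through all formats.
* `cutoff_for_fn_rate` requires a non-empty score list and target < 1; a
  target of 1 (reject everything) is refused rather than capped.
* Saturated (flat-top) peaks take their apex at the plateau midpoint.
* MSP files are written with 4-decimal m/z and integer intensities 1–999;
  reading sorts ions by m/z and validates `Num Peaks` with line-numbered
  errors.
* mzML I/O is a minimal self-contained implementation (64-bit float, no
  compression on write; zlib and 32-bit float accepted on read) sufficient
  for profile/centroid MS1 runs with scan times in seconds or minutes.

## Problem sizes used in the shipped checks

Self-match and AMT-bias runs use 26 compounds at the high level; the
trade-off benchmark is the full 10-run standard benchmark; deconvolution
recovery uses 20 well-separated compounds (≥ 4 ions, SNR ≥ 10); cutoff
calibration is cross-checked on 1,000 random score lists; RI round trips on
500 points over RI 700–4000. These sizes were chosen so the complete
acceptance computation stays in the minutes range on a single CPU while
every mechanism is exercised at realistic scale.
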