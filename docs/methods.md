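# Methods

## The measurand

QLUSS quantifies the fraction of the pleural line affected by B-line
artifacts on a still lung-ultrasound frame. The physical rationale: B-lines
are vertical reverberation artifacts that originate at the pleura and extend
to the bottom of the screen without fading, so in a transverse linear-probe
scan they appear as bright, roughly rectangular vertical bands in the
sub-pleural image. A column of the sub-pleural region that is mostly bright
therefore belongs to a B-line; the percentage of such columns measures
pleural involvement. The patient score is the mean over the 12 standard
intercostal frames (anterior/lateral/posterior × upper/lower × left/right).
The method assumes an intact pleural-line echo and is not valid over pleural
effusion or consolidated (tissue-like) lung; exams containing tissue-like
regions carry a reliability flag on the aggregated score.

## Pipeline stages and parameters

| parameter | default | meaning |
|---|---|---|
| `search_fraction` | 0.4 | top fraction of the frame searched for the pleural line |
| `roi_offset` | 2 px | rows skipped below the pleural row before the ROI starts |
| `low/high_percentile` | 1 / 99 | contrast-stretch clip percentiles |
| `asf_max_gap` | 10 px | largest axial gap the filter must close |
| `white_fraction_threshold` | 0.50 | minimum white fraction for a B-line column |
| `depth_fraction` | 0.70 | fraction of ROI depth scanned (from the top) |

**Pleural-line detection.** The pleural line is the row with maximal mean
intensity within the top 40% of the frame, ties broken toward the shallowest
row (a thick pleural band is anchored at its top). This is a design choice —
the line is the dominant horizontal reflector in linear-probe transverse
scans — and a manual per-frame override exists for atypical frames. The ROI
runs from `pleural_row + offset` to the bottom of the frame; the bottom is
not truncated. A placement leaving fewer than 8 rows is an error.

**Contrast.** Percentile-clip linear stretch: the 1% quantile maps to 0, the
99% to 255. A constant ROI is passed through with a warning rather than
dividing by zero; the full pipeline then classifies the constant against a
frame-level threshold (a uniformly dark field scores 0%, a uniformly bright
one — full-width coalescence — scores 100%).

**Binarization.** One-dimensional 2-means on pixel intensity. With k = 2 in
one dimension the optimal clustering is an interval split of the sorted
values, so the global within-cluster-sum-of-squares minimum is found exactly
by scanning the ≤ 255 distinct-value cuts on the intensity histogram
(prefix-sum evaluation). This removes all initialization randomness: the
stage is deterministic by construction and is verified in the tests against
a naive exhaustive-threshold oracle. The brighter cluster is foreground.
Ties between cuts resolve to the smallest cut value.

**Alternated sequential filter.** Opening-then-closing with vertical line
structuring elements of odd lengths 3, 5, 7, 9, 11. The terminal closing
(length 11) fills axial gaps of up to 10 px inside a column; the openings
remove white runs shorter than the element and sever 1-px-tall horizontal
bridges, isolating objects laterally. Border handling follows standard
artifact-free practice: erosion ignores out-of-image positions, dilation
treats them as background, so a full-height column is a fixed point of the
filter. The schedule is configurable (`asf_lengths`); the filter is
idempotent at a fixed schedule, which the tests check on random masks.

**Column scan.** The white fraction is evaluated over the uppermost
`ceil(0.70 × depth)` rows of the ROI — B-lines arise at the pleura and may
attenuate at depth — and a column is flagged when the fraction is ≥ 0.50
(inclusive). An alternative reading of the rule (fraction over the full
column combined with a 70% vertical-span requirement) exists; it is *not*
implemented, and both numbers are configuration parameters rather than
constants so the behavior is explicit.

**Rounding.** Percentages are carried at full precision and rounded half-up
to 2 decimals only when serialized.

## Semi-quantitative scores

nLUSS sums the per-region B-line counts (fused B-lines count once). %LUSS
sums `confluent_percent / 10 + discrete B-lines` per region, with white lung
fixed at 10. cLUSS grades each region 0–3 (A-lines or < 2 B-lines: 0; spaced
B-lines: 1; coalescent: 2; tissue-like: 3) and sums. qLUSS is cLUSS with the
coalescent grade split at 50% pleural involvement (≤ 50%: 1; > 50%: 2;
white lung: 2). Two boundary conventions are deliberate and isolated in
single functions: exactly 2 spaced B-lines grades 1 (the 0/1 anchors leave
the case unstated; aeration loss is present), and qLUSS inherits cLUSS
grades for all non-coalescent patterns (consistent with qLUSS ≤ cLUSS on
every patient of the validation table). The region count is fixed at 12 but
parameterized for partial exams in research use.

## Statistics

**Regression.** OLS via the standard closed form; robust estimators: Huber M
(k = 1.345), LAD (median regression), LMS (least *median* of squares — the
high-breakdown estimator of that name, not a synonym of OLS — minimized over
elemental pairs with the h-th order statistic, h = ⌊n/2⌋ + 1), LTS
(h = ⌊(n+p+1)/2⌋; exact by exhaustive h-subset enumeration for n ≤ 20, since
the LTS minimizer is the OLS fit of the h-subset with the smallest own RSS;
seeded elemental starts with concentration steps for larger n), S
(50%-breakdown Tukey biweight M-scale, c = 1.548) and MM (S start, bisquare
M-step at 85% Gaussian efficiency, c = 3.444).

**Robust R².** There is no canonical robust R²; every fit names its
convention in its metadata. LTS/LMS report the *trimmed R²* — 1 −
SS_res(h)/SS_tot(h) on the h retained observations — plus the OLS-style R²
on all points for transparency. Huber/S/MM report a robustness-weighted R²;
LAD reports the L1 analogue 1 − Σ|res|/Σ|y − median(y)|. On the packaged
validation table the trimmed-R² convention gives 0.96 for the LTS fit of
EVLW on QLUSS, not the 0.86 of the original report, whose supplementary
material defining the convention is unavailable; no trimming fraction or
standard alternative convention we evaluated reproduces the reported triple
(0.86, 0.85, 0.72) for QLUSS/qLUSS/%LUSS, so the documented definition is
kept and the discrepancy is reported rather than fitted around.

**Correlation.** Spearman uses midranks and the t approximation with n − 2
df for the two-sided p (adequate at n = 12; an exact permutation p is
available for n ≤ 8). Dependent overlapping correlations sharing one
variable are compared with Dunn & Clark's z using the Hittner–May–Silver
modification: the covariance term is evaluated at the backtransformed
average of the two Fisher transforms; the p-value is two-sided normal. From
the packaged table this gives p = 0.041 and p = 0.073 for the two reported
comparisons (printed: 0.037 and 0.071); the residual gap is consistent with
the source data having more precision than its printed table, as is the
Spearman r of QLUSS with %LUSS (computed 0.743 vs printed 0.757 — no
standard tie-handling variant of the printed values yields 0.757, while all
other printed correlations and every regression R² reproduce exactly).

**Agreement.** Two-way crossed absolute-agreement ICC, single-measure by
default (each rater contributes one score; the average-measure form is a
flag), from the subjects/raters/error mean-squares decomposition, with the
F-based 95% CI using a Satterthwaite degrees-of-freedom approximation. The
implementation matches an independent reference implementation to machine
precision in the tests. Strength labels partition the scale with inclusive
lower bounds: < 0.30 poor, 0.30–0.49 fair, 0.50–0.69 moderate, 0.70–0.89
strong, ≥ 0.90 almost perfect. A perfect-agreement table (zero error mean
square) returns a collapsed CI.

**Power.** The two-sided zero-correlation test's power uses the Fisher-z
approximation with the small-sample bias term: z_r = atanh(r) + r/(2(n−1)),
critical correlation from the t quantile at n − 2 df, power =
Φ((z_r − atanh(r_c))·√(n−3)). This formula is pinned because it reproduces
both reference values (0.924 at r = 0.8 and 0.85 at r = 0.75, n = 12,
α = 0.05) exactly.

## Synthetic phantoms

The phantom generator emulates exactly the features the pipeline relies on:
a bright pleural row, rectangular vertical bands of configurable position,
width, intensity and penetration depth over a darker background
(defaults: background 40, bands 190, pleura 250 on the 0–255 scale),
optional axial dropouts inside bands, and multiplicative log-normal speckle
(band/background separation stays reliable up to roughly σ ≈ 0.2).
Overlapping bands merge into one coalescent truth interval. It does **not**
simulate field propagation, scan conversion, beam-width blur (available only
as an optional lateral Gaussian), attenuation, rib shadows, A-lines,
effusion or consolidation — so passing phantom tests demonstrates the
algorithm's correctness on its geometric model of a B-line, not clinical
performance on real scans, which requires real annotated frames.

Rater tables for agreement testing come from the two-way random-effects
model score(i,j) = μ + subject_i + rater_j + ε_ij with configurable normal
variance components, giving the closed-form target ICC
σ²_subj/(σ²_subj + σ²_rater + σ²_err). With 2 raters the rater component is
estimated from a single contrast, so individual ICC estimates scatter widely
even at 500 subjects; recovery checks therefore compare the *mean* estimate
over independent replicates (40 tables of 500 subjects) against the
closed form.

## Problem sizes and determinism

Validation statistics run on the packaged 12-patient table (exhaustive LTS
enumerates C(12,7) = 792 subsets). Phantom-based property checks use 50
random 128×128 specs noiseless and 50 at speckle σ = 0.15, plus 100 random
64×64 images for the binarization oracle. All randomness flows through
explicit seeds (`numpy.random.default_rng`); identical inputs, configuration
and seed give byte-identical outputs.

## Known limitations

- Single still frame per region; no cine/multi-frame analysis.
- Not valid over pleural effusion or consolidation; tissue-like regions only
  flag the aggregate, they are not excluded.
- The pleural-line detector assumes the line is the brightest horizontal
  structure in the upper frame; curvilinear geometry and rib shadows are out
  of scope (override available).
- The robust-R² and dependent-correlation values reproduce the original
  report only up to the precision limits discussed above.
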