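# Methods

## Scope

`placmorph` quantifies six indices of placental villous structure from
calibrated brightfield histology fields, compares condition cohorts with a
nonparametric test battery, and classifies per-sample morphometric
profiles against a fetal-growth-restriction (FGR) reference pattern.
Because no public image set with per-object annotation exists for this
problem, the package ships a synthetic histology generator whose complete
ground truth makes every measurement operator testable by exact recovery.

## The six indices

All indices are pooled ratios over a placenta's fields (sums of tallies,
not means of per-field ratios — unbiased when fields contain unequal
tissue):

| index | definition | stain |
|---|---|---|
| `sna_per_mm2` | syncytial nuclear aggregates (SNAs) per mm² of villous tissue | H&E |
| `proliferative_index` | Ki67+ nuclei / total nuclei | Ki67 DAB |
| `vessels_per_villus` | CD31+ capillary profiles per villus | CD31 DAB |
| `avascular_pct` | % of villi with no CD31+ capillary | CD31 DAB |
| `trophoblast_fraction` | CK7+ area / villous area | CK7 DAB |
| `cd45_per_1000` | CD45+ cells per 1000 nuclei | CD45 DAB |

## Stain model and deconvolution

Rendering and measurement share one physical model: Beer-Lambert
transmission, `I = I0·exp(−OD)`, with per-pixel OD a non-negative mixture
of two absorbance unit vectors (haematoxylin plus eosin or DAB; standard
published vectors, configurable). Deconvolution converts pixels to OD
(`−log(I/I0)`, clipped to [0, 3.0] — the dynamic range of an 8-bit sensor)
and projects onto the stain basis with the pseudo-inverse, clipping
negative concentrations. Because rendering keeps float pixels (8-bit
quantisation happens only on file write), the render→deconvolve round trip
is exact to ~1e-15 at zero noise; the documented guarantee is 1e-6.

Masks:

* **tissue**: summed OD ≥ 0.15, specks < 60 µm² removed, holes < 300 µm²
  (capillary lumens) filled. The threshold is a config surface — no
  acquisition thresholds are anchored in published work.
* **positivity** (DAB): Otsu on the channel's OD within tissue by default
  (fixed threshold available); a constant channel falls back to the fixed
  threshold with a warning. Otsu's threshold is floored at half the fixed
  threshold so an all-negative slide yields an empty mask rather than a
  split of background noise.

## Measurement operators

* **Villus segmentation**: connected tissue components; touching profiles
  are split by a watershed seeded at h-maxima of the interior distance
  transform (prominence 12 µm), and a split is kept only if the shared
  boundary is shorter than 0.7× the smaller fragment's equivalent diameter
  — a genuine neck is short, a false cut through a lobed profile is long.
  This keeps solitary lobed villi intact (0 false splits in simulation)
  while separating overlapping profiles. Terminal villi: equivalent
  diameter < 100 µm (configurable; the field has no canonical cutoff).
* **Nucleus detection**: local maxima of the lightly smoothed (σ = 0.8 µm)
  haematoxylin OD above 0.55, minimum separation 2.5 µm; marker positivity
  from the smoothed DAB OD at the nucleus (≥ 0.35) for Ki67/CD45 kinds.
* **SNA counting**: single-linkage clusters (radius 7 µm) of detected
  nuclei with ≥ K = 10 members whose centroid lies within 14 µm of a
  villous boundary. K and the radius are configuration, not biology-book
  constants: no consensus operational definition of an SNA exists, so both
  are exposed and recorded in run metadata.
* **Vessel counting**: connected CD31-positive components ≥ 20 µm² inside
  a villus mask (the floor rejects single-pixel noise); a villus is
  avascular iff it has none. Only the immunostain arm of the avascular
  definition is implemented; calling vessels from H&E morphology alone
  would require registered serial sections the pipeline does not assume.
* **Field sampling protocol**: random windows per section; a window is
  rejected unless it holds tissue (≥ 5 % of its area) and is *mostly of
  terminal villi* (terminal-villus area ≥ 50 % of its tissue, configurable);
  five accepted fields per section, three sections per placenta.
  Exhausting the rejection budget raises an explicit error. Observer
  blinding is modelled by a bijective recoding of condition labels with a
  separately stored key.

## Synthetic data

**Fields.** Villi are perturbed ellipses (radial harmonics ≤ 15 %) placed
without overlap (≥ 8 µm clearance); each carries a 6 µm CK7+
syncytiotrophoblast rim, rim nuclei (~10 µm spacing), stromal nuclei
(0.004/µm²), and capillaries (zero-truncated Poisson, mean 4, CD31+ walls)
unless flagged avascular. SNAs are planted at
`round(density × villous area)`: clusters of K = 10 rim nuclei grown
connected-by-construction (links 4.8–5.5 µm) inside a 12 µm disc
protruding from the rim. Default rates (15 SNAs/mm², 5 % Ki67+, 5 %
avascular, 10 CD45+/1000, trophoblast fraction ≈ 0.3) are plausible values
for healthy term placenta chosen once as simulation defaults. All
randomness flows from one seeded generator; identical parameters give
byte-identical output.

What the generator does **not** emulate: fixation and maceration
artefacts, intra-observer focus variation, colour variation across
scanners, touching/overlapping villi in compact sections, and non-villous
structures (decidua, fibrin, chorionic plate). Passing recovery tests
therefore demonstrates correctness of the measurement logic under the
stated forward model, not robustness to every property of clinical
material.

**Cohorts.** Per-sample indices are log-normal (positive, right-skewed)
per condition, parameterised by median and log-sd. The default cohort
mirrors the emulated study's arms and group sizes (control 10, preterm 7,
cord accident 8, diabetes 5, hypertension 8, infection 8, FGR 10, unknown
10; paired pre/post perfusion 7) and encodes the reported effect
*directions* — e.g. FGR: SNAs ×2, proliferation ×0.5, vessels ×0.6,
avascular ×3, trophoblast ×1.4, leukocytes ×0.5. The magnitudes are
generator choices (group-level distributions were published only as
figures); they are documented here and in `synthetic/cohort.py` as
arbitrary defaults. Paired arms share sample ids and are generated from
their partner's log-values plus the median shift and a 0.15 log-sd
residual.

## Statistics

Group sizes of 5–13 put the analyses squarely in exact-test territory:

* one-sample Wilcoxon signed-rank vs the control median (zeros dropped —
  classic Wilcoxon, not Pratt; recorded in each result), exact two-sided p
  by full sign enumeration for n ≤ 12 non-zero differences, tie-aware
  normal approximation with continuity correction above;
* Mann-Whitney U, exact via the rank-sum counting recursion when tie-free
  and n·m ≤ 400, tie-corrected normal approximation otherwise;
* Wilcoxon matched-pairs (same exactness policy; the reported statistic is
  the antisymmetric signed rank sum W⁺ − W⁻);
* Kruskal-Wallis (tie-corrected H, χ² p) with Dunn's pairwise z tests;
  multiplicity adjustment none by default (mirroring per-comparison
  reporting), Holm/Bonferroni available.

Two-sided p doubles the smaller tail, capped at 1. No correction is
applied across the 6-index × condition grid by default; `holm=True` adds
Holm-adjusted p-values.

**Calibration caveat.** The cohort battery literally re-tests each
condition against a *median estimated from the control sample*. With 10
controls that estimation noise inflates the apparent rejection rate under
the null well above α (quantified by `analysis/03_cohort_stats.py`, which
runs the null both ways). The calibration harness therefore evaluates the
battery against the generator's true medians, isolating the tests' own
level (≈ 0.05, slightly conservative from discreteness); the
estimated-reference inflation is reported alongside as a property of the
study design, not of the tests. `compare_all_conditions(...,
ref_medians=)` exposes the same switch to users.

## Profile matching

Each index is classified HIGH / LOW / UNCHANGED against the control
cohort. Default rule: outside the observed control range (a null sample is
UNCHANGED with probability (n−1)/(n+1), 9/11 for ten controls); a
percentile rule is available, and the rule in force is recorded in output.
The FGR reference pattern is SNAs High, proliferation Low, vascularity
Low, avascular High, trophoblast High, leukocytes Low. A sample is
"similar to FGR" when all **required** features match; leukocytes are
advisory (not required) because the published unknown-cause samples judged
similar to FGR show unchanged leukocytes. A brute-force audit over all 2⁶
required subsets (`consistent_required_sets`) confirms the five-feature
rule reproduces all ten published verdicts and reports the alternatives —
every consistent subset contains "proliferation Low", which alone would
already separate the published rows; the five-feature rule is kept because
it encodes the full biological pattern rather than the minimal
discriminator.

## Problem sizes and numerical choices

* Recovery validation: 20 placentas × 3 fields × 5 stain renders at 600 µm
  / 1 µm px⁻¹, chosen to exercise every operator while keeping the default
  suite fast; observed recovery error is ≪ the documented ±10 % (±0.02
  absolute for the two fractions).
* Null calibration: 1000 replicate cohorts (two null arms × six indices).
* Exact-test verification: full enumeration oracles at n ≤ 10 written
  independently in the tests (itertools, not the package's DP).
* Degenerate inputs fail loudly: all-zero differences, empty groups, zero
  villous area or zero nuclei raise typed errors rather than propagate NaN.
* Ties use mid-ranks throughout; tie-aware variances use Σr²/4 (signed
  rank) and the standard tie term (Mann-Whitney, Kruskal-Wallis).

## Known limitations

* The avascular call ignores the "morphological evidence of vessels"
  clause (H&E-only vessels are invisible to the CD31 arm).
* The serial-section idealisation renders all five stains from the same
  ground-truth field; real immunostains come from adjacent sections with
  slightly different villous profiles.
* The High/Low/Unchanged rule behind the published per-sample levels is
  not stated in the source literature; transcription-based matching
  reproduces the published verdicts exactly, but image-to-profile runs
  depend on the pluggable level rule.
* One-sample comparisons against an estimated control median inherit the
  calibration caveat above; the package reports it rather than hiding it.
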