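# Methods

## The analysis model

`dimsmark` treats a direct-infusion experiment as a set of per-sample,
per-technical-replicate centroid lists. There is no chromatographic
dimension, so identification rests entirely on mass accuracy, and the
analysis is deliberately presence/absence rather than quantitative: a
metabolite is "detected" in a sample when at least one consensus ion
annotates to it, and group-level inference is carried out on detection
frequencies, not intensities. This reflects how low-abundance endogenous
metabolites behave in infusion spectra of plasma, where run-to-run
intensity is far less reproducible than the mere occurrence of an ion.

Assumptions the pipeline makes:

- Ions are singly charged adducts of intact molecules: [M+H]+, [M+Na]+ or
  [M+K]+. Adduct m/z is (M + cation mass) / z with electron-corrected
  cation masses (1.007276, 22.989218, 38.963158 Da); neutral-atom masses
  would be wrong by ~1 ppm at m/z 550, half the annotation window.
  Isotope envelopes, multiply charged species, in-source fragments and
  neutral losses are out of scope.
- Element monoisotopic masses are embedded at 6–7 decimal places (CIAAW /
  AME2020 most-abundant-isotope values); at 2 ppm and m/z ≤ 1000 the table
  contributes < 0.01 ppm of the error budget.
- Annotation is putative: every (compound, adduct) candidate within the
  ppm window is kept. Collapsing to a best hit would manufacture
  confidence that accurate mass alone cannot provide. Library rows whose
  nominal mass fits no H/Na/K adduct of any observed ion are simply never
  annotated — they are not special-cased or forced to match.

## Stages and their numerical choices

**Peak detection.** Local maxima in the profile trace with ≥ 2 contiguous
points above the local noise, apex SNR ≥ 1, and apex intensity above both
an absolute cutoff (100 counts) and a relative cutoff (0.01 % of the base
peak). Of the two published-style cutoff numbers, 0.01 % is mapped to the
relative and 100 to the absolute threshold (the only dimensionally
sensible assignment); both are exposed in `PeakDetectionParams`. Noise is
the scaled median absolute deviation (×1.4826) over ~500-point blocks,
interpolated — robust when peaks are sparse. Apex m/z is refined by
3-point parabolic interpolation, which recovers sub-grid centroids exactly
for symmetric peaks.

**Recalibration.** Matched (observed, reference) pairs give signed ppm
errors; a straight line in ppm vs m/z is fit by least squares and divided
out (a constant shift when only one reference matches). References are the
top-k (default 5) highest-intensity ions matching known library or
internal-standard masses within 5 ppm. The correction is rejected — input
returned unchanged — if it would increase the mean absolute reference
error, so the stage is non-damaging by construction. A linear model is
sufficient for the small (≤ 6 ppm) drifts this stage targets; residuals on
noiseless references are < 0.01 ppm.

**Normalization.** Intensities are divided by the internal-standard
intensity (ion nearest the IS m/z within 5 ppm; most intense match if
several) or by total ion current. Both are scale-invariant, so detector
gain differences between replicates cancel. m/z is never altered. The
packaged IS is losartan: monoisotopic mass 422.1622 from C22H23ClN6O,
[M+H]+ = 423.169.

**Replicate consensus.** Candidate pairs are ions whose m/z agree within a
tolerance (default 5 ppm — above the ~3 ppm instrument accuracy, far below
typical peak spacing); pairs are ranked by relative deviation in ppm of
the pair mean (a symmetric quantity) and accepted greedily, each ion
pairing at most once. On well-separated data this equals the
assignment-problem optimum (verified against `linear_sum_assignment` in
the tests). The consensus m/z is the intensity-weighted mean, so it always
lies between its contributors. The rule generalizes to R replicates by
folding: an ion must appear in all R (R = 2 by default).

**Annotation.** Theoretical m/z values for all (compound, adduct) pairs
are precomputed and sorted once; each ion then takes an interval query
(binary search) over that index. The tests assert exact equivalence with a
brute-force all-pairs scan, and that tightening the tolerance never adds
annotations. Default tolerance: 2 ppm.

**Frequencies and selection.** Frequencies are stored at full precision;
reports round to 2 dp (so 2/3 prints as 0.67). The selection rule is
thresholded rather than literal: frequency ≤ `max_control_frequency` in
every control group and ≥ `min_case_frequency` in every case group. The
strict "absent from controls" reading is the default
(`max_control_frequency = 0`), but real panels of this kind include rows
with small nonzero control frequencies, so the threshold is a parameter.
Defaults compare first-trimester controls (`group1`) against
first-trimester pre-symptomatic cases (`group2`) — the prediction setting —
with both group sets configurable. The optional exact test is a two-sided
Fisher test computed by exhaustive hypergeometric enumeration in integer
arithmetic (exact for all practical group sizes; cross-checked against
`scipy.stats.fisher_exact` in the tests). No multiple-testing correction
is applied by default; Benjamini–Hochberg is available
(`correct_fdr=True`) when the test is run across many compounds.
Replicate-level frequencies (each technical replicate an independent
measurement, denominator = group size × replicates) are available as
`analysis_level="replicate"` for reproducibility analyses; sample-level is
the default because panel reporting counts samples.

## The synthetic cohort generator

`generate_cohort` emulates the cohort structure the analysis targets:

- **Groups** — four groups of 25/3/20/31 samples (first/third trimester ×
  control/case); labels and sizes configurable.
- **Replicates** — 2 per sample; presence of a panel metabolite is drawn
  once per sample from its group probability, and each replicate then
  independently *misses* a truly present ion with probability 0.1
  (default). Sample-level truth plus replicate dropout is what makes the
  consensus rule meaningful.
- **Mass error** — Gaussian, 1 ppm SD (default), inside a ≤ 3 ppm
  instrument specification; optional linear ppm drift across the m/z range
  feeds the recalibration stage.
- **Panel** — the default panel is nine HMDB-accession metabolites with
  group-specific detection probabilities spanning 0–1 and H/Na/K adducts;
  arbitrary panels are configurable.
- **Noise** — 150 peaks per spectrum (default), uniform in m/z 50–1000,
  with intensities from the low tail of a log-normal. Intensity
  distributions (metabolite median 10⁴, σ = 1; IS 10⁵, σ = 0.1; noise
  median 500) are synthetic assumptions: no instrument model is claimed,
  they exist to exercise cutoffs and normalization.
- **Internal standard** — in every replicate, like a spiked compound.

Identical designs (including the seed) produce byte-identical written
cohorts. What the generator does **not** emulate: isotope envelopes,
detector saturation, correlated (matrix) noise, electrospray suppression,
and real metabolite co-occurrence structure. Passing tests therefore
demonstrate that the *pipeline logic* is correct under the stated
statistical model, not that the thresholds are optimal for any particular
instrument.

## Statistical properties verified

- Planted-marker recovery: on the 25/3/20/31 design with markers at
  control probability 0 and case (group4) probability 0.9, the full
  pipeline with the thresholded rule plus exact-test filter (α = 0.05)
  recovers markers in ≥ 95 % of seeded runs and selects
  equal-prevalence nulls in ≤ 5 %. With the n = 3 group as the case group
  the same rule loses power (a 0.67-prevalence marker survives the
  replicate-dropout chain in only ~40 % of runs) — an inherent
  small-sample property, visible in the demo, not a defect.
- Exact-test correctness: enumeration matches an independent
  rational-arithmetic oracle exactly for every 2×2 table with both group
  sizes ≤ 40.
- Determinism: one config + seed → byte-identical reports.

Problem sizes used in the shipped checks (full-pipeline runs at the
default 79-sample design, 100 seeds; annotation oracles at ≤ 500
compounds; consensus oracles at ≤ 20 ions) were chosen to make the
properties statistically meaningful while keeping a complete run of the
suite and acceptance script fast on a laptop.

## Known limitations

- Accurate-mass-only annotation cannot distinguish isomers; detection
  matrices count *compounds with at least one candidate*, so panels should
  be read as candidate sets, not identifications.
- The greedy consensus pairing can differ from the global optimum when
  peak spacing approaches the tolerance (not the regime DIMS centroids at
  2–5 ppm occupy).
- The exact test conditions on group sizes; it is not a longitudinal or
  severity model, and no clinical risk interpretation is attempted.
- mzML support reads the first centroided spectrum of a file only;
  profile-mode mzML and vendor formats are out of scope.
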