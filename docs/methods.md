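# Methods

This note documents the models, parameter choices and numerical conventions
behind `raquant`, and what the synthetic-data generators do and do not
emulate.

## rG4 motif model

A canonical RNA G-quadruplex is modelled as four G-tracts of at least
`min_tract_len` (default 3) consecutive guanines separated by three loops of
`loop_min`–`loop_max` nt (default 1–7). Sequences may be DNA or RNA; U maps
to T internally, N never joins a run, and all coordinates are 0-based
half-open.

**Chaining.** Maximal G-runs are chained leftmost-greedily: scanning runs
left to right, the first window of four consecutive runs whose gaps all lie
in the loop range is emitted as a motif and its runs are consumed. Every run
therefore belongs to at most one motif, which makes per-gene motif counts
reproducible and avoids the combinatorial explosion of overlapping
assignments. The greedy choice is validated against exhaustive enumeration
in tests; it attains the maximum number of disjoint chains on run lists
where gaps are uniform, and is deterministic everywhere.

**Scoring.** The neural rG4 probability predictors used in practice are not
reimplemented here. Instead each motif gets a deterministic G4Hunter-style
window score: every base inside a G-run of length L contributes +min(L, 4),
every base in a C-run −min(L, 4), other bases 0; the mean over the motif
span — extended symmetrically to at least `window` nt (default 20),
truncated at sequence ends without compensation — is divided by 4 and
clamped to [0, 1]. Runs are decomposed within the evaluated window only, so
the score is provably independent of bases outside it. The score keeps the
probability-like threshold semantics (positive at ≥ 0.5, sensitivity sweep
0.4–0.6) so every downstream statistic remains computable, but it is a
stand-in on the same scale, not an emulation of any particular predictor's
values.

**Region assignment.** A motif is assigned to the transcript region (5′UTR
/ CDS / 3′UTR) containing the majority of its span; exact ties go to the
more downstream region. This matches a per-base overlap count by
construction and is property-tested against one.

**Structural summaries.** Tetrad layers per motif = the shortest tract
length in the motif (binned 2/3/4/≥5 in summaries); with the default
`min_tract_len` of 3 a layer count of 2 is only representable under relaxed
scanning (`min_tract_len = 2`), which is why the option exists. The
per-motif representative loop length is the median of its three loops.
Per-gene motif counts are binned 1/2/≥3. Percentages are rounded half-up to
two decimals — the convention of printed clinical tables — at the
presentation layer only; all internal arithmetic is full precision.

**Threshold sweep.** Because motif scores do not depend on the threshold,
positive sets at increasing thresholds are nested by construction; the sweep
reports raw counts, the positivity rate, the intersection with the
default-threshold positive set (rate relative to the default positive
count), and retention of a designated core subset (by default the 15
top-scoring positive genes).

## Differential-expression screen

The screen's contribution is its thresholding and intersection logic:
a gene is a DEG iff |log₂FC| ≥ 1.5 (inclusive) **and** FDR < 0.01 (strict),
and an irDEG iff it is a DEG and its symbol is in the inflammation core gene
set (case-insensitive after whitespace stripping; aliases out of scope).
The test statistic behind it is deliberately simple and documented as such:
counts are normalised to log₂ counts-per-million with a 0.5 pseudocount
(library size = raw column sum), each gene is tested with a Welch two-sample
t-test (Satterthwaite df; p = 1 by convention when both groups are constant
and equal), and p-values are Benjamini–Hochberg adjusted (statsmodels, with
a brute-force step-up oracle in tests). This is a stand-in for
negative-binomial Wald testing; effect-size estimates on log-CPM are
conservative when many genes shift in the same direction, because CPM
normalisation absorbs part of a shared mean shift. Under the global null
the screen is strongly conservative: across 200 simulated replicates
(2,000 genes, 20 vs 20 samples) the mean fraction of genes passing
FDR < 0.01 is on the order of 10⁻⁶–10⁻⁵.

## Bone-erosion severity model

Lesions are connected components of the binary erosion mask under
26-connectivity by default (6/18 configurable; the choice is not dictated by
the clinical rule, so it is explicit configuration), ordered by the per-axis
minima of their voxel sets. The pathological-erosion rule keeps lesions
occupying ≥ 2 *consecutive* axial slices, a mask-level proxy that excludes
physiological cortical defects and vascular channels; morphology checks
requiring intensity data are out of scope. Diameters are Euclidean distances
between voxel centres in mm: *axial* is the maximum within any single
z-plane; *vertical* is operationalised as the maximum within any plane
containing the z-axis (voxels sharing an x or a y index) — an
interpretation, stated as such. Distances are exact all-pairs up to 5,000
voxels with convex-hull acceleration above.

The severity score is a linear composite with fixed expert-derived weights
0.3 (lesion count) / 0.4 (mean maximum diameter) / 0.3 (erosion-to-bone
volume ratio). Count and diameter are normalised by configurable caps
(defaults 10 lesions, 10 mm); the volume ratio is clamped to [0, 1]. The
caps and the severity grade cut-offs are **not** published constants: the
defaults (cut-offs 33.3/66.7, boundary scores taking the higher grade,
"none" requiring zero score with zero lesions) are configuration that every
output records. Rapid progression requires an annual score growth rate
`100·(last−first)/first` per year elapsed of ≥ 30 %/yr **and** ≥ 3 follow-ups
with every consecutive interval ≥ 6 months (times are months since
baseline); a zero baseline leaves the rate undefined and the flag false.
The special-site flag fires when site erosion volume reaches 40 % of site
bone volume (inclusive).

## Evaluation statistics

Confusion-derived metrics use an ε = 10⁻⁶ guard in the Dice ratio, so two
empty masks score DSC 1 and are flagged; sensitivity/specificity are absent
(None) when their denominators vanish. The training-loss formula is the
equally weighted sum of soft Dice loss and mean binary cross-entropy with
clipped logs. ICC is fixed to ICC(2,1) — two-way random effects, absolute
agreement, single measure — computed from the two-way ANOVA mean squares
with the McGraw–Wong F-based 95 % CI; the form is stated in outputs because
"ICC" alone is ambiguous. Pearson r carries a Fisher-z CI and a two-sided
t-based p-value. Bootstrap intervals are percentile intervals over 1,000
seeded resamples of pairs; a seed is mandatory.

## Synthetic data: what it emulates, and what it does not

**Transcripts.** Default cohort: 67 genes, 42 carrying 1–3 planted motifs,
with regions drawn 18/37/45 % across 5′UTR/CDS/3′UTR (spans 200/900/500 nt).
Plants have 4-G tracts and loops of 1–5 nt drawn from {A, U}; with the
window score this puts every plant at ≥ 0.5 (worst case 64/124 ≈ 0.516), so
gene-level truth is exact at the default threshold, while long-loop plants
fall below 0.6 and produce non-trivially nested sweep sets. The background
is sampled G-depleted and then every G-run of length ≥ 3 outside plants is
broken, with hard non-G flanks around each plant — the background is
therefore *provably* scan-negative and planted coordinates are exact, which
is what makes scanner precision and recall measurable as exactly 1.0.
Real transcriptomes have G-rich non-canonical motifs, bulged tracts and
compositional heterogeneity that this construction deliberately lacks:
passing tests certify the scanner's contract, not its behaviour on real
UTRs.

**Counts.** Negative-binomial with mean–dispersion parameterisation
(var = μ + αμ², α = 0.1 default), baseline means log-uniform in [20, 500],
group AG means scaled by 2^log₂FC for planted genes. No gene–gene
correlation, batch structure or length bias is simulated. In the demo
pipeline the planted core magnitudes are drawn from ±[2.2, 3.0] so that the
CPM-normalisation shift cannot push a planted effect below the 1.5
threshold.

**Volumes.** A solid bone block (4-voxel margin) with axis-aligned box
lesions (default) or voxelised ellipsoids, pairwise separated by > 1 voxel
so components stay distinct under 26-connectivity; spacing defaults to
0.625 mm isotropic, matching thin-slice CT. Box truth metrics are closed
form; ellipsoid truth is measured on the voxelisation by an independent
all-pairs routine. Optional single-slice decoys exercise the pathological
filter. Real erosions are neither boxes nor isolated; the phantoms certify
the measurement chain, not anatomy.

**Predicted masks.** To hit a target Dice t, `perturb_mask` removes
r = round(G·(1−t)) random gold voxels and adds r random voxels from the
dilation shell, giving DSC = 1 − r/G exactly (within 1/G of the request,
far inside the ±0.02 contract on any realistic mask).

**Demo cohort wiring.** The pipeline plants 67 core DE genes (52 up, 15
down, rG4 plants on 31 up + 11 down) plus 61 non-core DE genes among 2,000,
so the demo reproduces the structure of a real irDEG screen end to end;
patient volumes vary lesion count (1–10) and size (up to 12 voxels) to
spread severity scores across grades, follow-up growth rates are uniform on
[−10 %, +40 %]/yr, and simulated DAS28 is linear in the severity score plus
Gaussian noise. These are study-condition choices made once, not tuning
knobs.

## Problem sizes and determinism

All randomness flows through explicit integer seeds (numpy `default_rng`);
stage seeds in the pipeline are derived from the run seed and kept below
2³¹. The test and acceptance workloads use the cohort sizes stated above
(100 seeded transcript cohorts, 100 random 32³ volumes against brute-force
oracles, 200 null replicates at 2,000 genes × 20/20, 10 perturbation seeds
on a 64³ phantom), chosen as the smallest sizes at which each property is a
meaningful population statement rather than a single lucky draw.

## Known limitations

- The motif score is a transparent surrogate on the probability scale, not
  a trained predictor; absolute score values should not be compared against
  any neural tool's probabilities.
- The DE stand-in tests log-CPM means, not NB dispersion-shrunk Wald
  statistics; it is conservative and its fold-change estimates are biased
  toward zero under asymmetric global shifts.
- Severity caps and grade cut-offs are configuration; scores are comparable
  only under a fixed configuration (every output records the config hash).
- The vertical-diameter definition is one defensible reading of
  "measured in the vertical plane"; alternatives (e.g. any plane containing
  the principal axis) would differ on anisotropic lesions.
- Synthetic data certifies contracts, not clinical performance; none of the
  reported synthetic agreement statistics transfer to real cohorts.
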