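# Methods

This note records the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic data do and do not emulate,
and the numerical conventions a reanalysis would need to reproduce
results exactly.

## Screen model and normalization

A well's raw value is modelled additively:

    value = plate_offset + global_mean + effect(content) + ε,   ε ~ N(0, σ_well)

with an independent plate offset per plate × replicate × screen
(σ_plate = 0.5 by default) and well noise σ_well = 0.3. Per-miR library
effects are drawn once per miR (shared across replicates) from
N(−1.0, 1.0) for migration and N(−0.7, 1.0) for eccentricity: the
negative means encode that a highly migratory, spindle-shaped cell line
leaves far more headroom for inhibition than promotion, which is what
places negative controls near Z ≈ +1 and the strong epithelial-driving
positive control below Z ≈ −1.5 — the control separation this class of
screen reports. These σ values are free parameters (no published screen
we emulate states its noise magnitudes); they were fixed once at values
that give realistic replicate concordance (Pearson r ≈ 0.92) and were
not revisited.

Normalization is per plate and replicate against negative controls. The
**location** is always the plate's own negative-control median — that is
the step that removes plate/batch offsets. For the **robust scale** we
depart from a fully per-plate estimate: a 96-well plate carries only six
negative controls, and the sampling error of a 6-well MAD is so large
(and so heavy-tailed in 1/MAD) that dividing by it visibly decorrelates
replicates (expected pairwise r drops from ≈0.92 to ≈0.6). The default
therefore pools negative-control residuals across the plates of a
replicate before taking the scaled MAD (`scale_scope="pooled"`); the
strict per-plate variant remains available (`scale_scope="plate"`). Zero
MAD raises an error naming the offending plate or replicate.

Z-scores use the library wells only as the reference distribution
(controls are scored against it but do not shape it — whether positive
controls belong in the reference is genuinely open; excluding them keeps
the reference a property of the library). Replicates are averaged
*after* Z-scoring. All cutoffs are strict inequalities: Z < −1, Z > +1,
0.8 < viability < 1.2, |log2FC| > 1.

## Planted design of the default run

The default pipeline plants, against a 1,253-miR library:

- two named positives carrying the true mature sequences of miR-373-3p
  and miR-302d-3p (both AAGUGC seed carriers), with strong migration and
  eccentricity effects;
- 23 further seed carriers (of 40 total) as hits, so the seed is
  enriched in every hit set;
- 100 lethal confounders (viability 0.35–0.7) with strong apparent
  phenotypes — these exercise the viability filter, which must remove
  them; 30 over-proliferative miRs (viability 1.25–1.6);
- six "clinical" migration hits that are also down-shifted (−2.5 log2
  units) in metastatic cohort samples, three of them with a planted
  hazard ratio of 4 for the low-expression group.

Raw effect units are calibrated to the Z scale *a posteriori of the
model, not of any test*: with ~13% of the library planted, the library
median sits near −1.15 and the robust SD near 1.3 (migration), so a
planted shift of −3.2 lands near averaged Z −1.5 and the miR-302d-like
shift of −2.9 near −1.35, safely beyond the −1 cutoff given replicate
noise of ≈0.15 Z.

## Images

Scratch images are confluent monolayers of non-overlapping ellipse
cells placed on a jittered, brick-staggered grid (guaranteed
non-overlap keeps segmentation ground truth exact), with a central
vertical cell-free band of width `max(0, w0 − r·t)`; the band cuts
through cells the way a physical scratch wipes them, so the cell-free
area equals the band geometry to within a few percent. Morphology
images place sparse non-overlapping ellipses with the planted
eccentricity by bounding-circle rejection sampling with capped retries.
Intensities are binary-like (background 0, cells ≈200 on 8-bit), since
GFP-channel segmentation is thresholding-dominated; no PSF, shading or
camera-noise model is attempted, so passing image tests says nothing
about robustness to real microscope artifacts.

Wound area is the largest 4-connected background component spanning top
to bottom after morphologically closing the thresholded foreground
(default Otsu; closing radius 4 px bridges inter-cell gaps). Objects
are 8-connected components, background/holes 4-connected (the standard
duality that keeps the Euler number consistent). Perimeter is the
weighted contour-length estimator of `skimage.regionprops`; the Crofton
alternative was rejected because it pushes a rasterized disc's
FormFactor above 1. Axis lengths are 4·√eigenvalue of the second
central moment matrix; Compactness is defined as Perimeter²/(4π·Area),
the reciprocal of FormFactor (=1 for a disc) — the feature name alone
does not pin down a formula, so this one is fixed and used
consistently. Default object-size filter: 50–5000 px at a 10X-like
scale (configurable; the analytic-shape tests widen it).

## Image-free morphology features

The fast path (`gen_well_features`) maps each well's latent morphology
— its planted eccentricity effect — through smooth feature response
curves (e.g. Eccentricity ≈ 0.80 + 0.06·effect) with small Gaussian
feature noise, plus an uninformative Area and a rare-hole EulerNumber.
Feature noise (0.01 on the eccentricity feature, i.e. ≈0.17 latent
units) is deliberately smaller than screen noise: it represents the
averaging of hundreds of cells per well, and keeps the LDA's epithelial
calls consistent with the single-feature eccentricity hits (≥90%
agreement), which is the property this stage exists to demonstrate.

## LDA

Class means plus pooled within-class covariance Σ_c Σ_i
(x−μ_c)(x−μ_c)ᵀ/(N−K), ridge-regularized by 1e-6·trace/p on the
diagonal (seven shape features are near-collinear); priors uniform
(control replication is an experimental choice, not a prevalence);
prediction by the linear discriminant with ties broken by the fixed
class order epithelial < intermediate < mesenchymal. Fewer than p+1
samples in a class warns rather than fails.

## NB differential expression

A deliberately compact two-group Wald procedure rather than a clone of
a full DE framework (no dispersion-trend shrinkage, no outlier
filtering, no fold-change shrinkage): counts are normalized by
median-of-ratios size factors (geometric-mean reference over rows with
no zeros; a pseudo-reference option rescues zero-heavy matrices);
log2FC is reported with a half pseudo-count per group mean; per-miR
dispersion is method-of-moments on normalized counts, **floored at the
library-wide median of positive estimates** — with three replicates the
raw per-miR estimate underestimates dispersion for a large fraction of
miRs and would roughly double the null false-positive rate (measured
0.10 raw vs 0.044 moderated at nominal 0.05); the Wald SE comes from
the NB Fisher information of the two-group log-mean model,
`Var(Δlogμ) = 1/Σ_E μ/(1+αμ) + 1/Σ_M μ/(1+αμ)`. A group mean of exactly
zero gets a half-count stabilizer (only then), keeping the statistic
finite with the correct sign. BH adjustment across tested miRs;
all-zero rows are excluded and reported. Sample PCA runs on centered
log2(normalized+1) profiles.

## Seed analysis

The seed is positions 2–7 (1-based) of the mature RNA sequence;
sequences are normalized to uppercase U-alphabet (T→U) and validated.
Motif categories: a match starting at 2 is `pos2_7` with priority over
3 (`pos3_8`), then `other_position` / `absent` — the priority rule makes
the categories a partition even for self-overlapping motifs. Fisher's
exact test is the two-sided "probability at most that of the observed
table" convention, computed by hypergeometric enumeration over the
support with a 1+1e-7 relative slack for ties; under a null it is
conservative (super-uniform p), which the tests assert instead of exact
uniformity. Consensus profiles truncate to the shortest sequence and
call a position at ≥0.8 modal frequency.

## Clinical stage

Expression contrast: Welch t-test per miR on log2 expression, logFC =
mean(primary) − mean(metastasis) so that miRs *down* in metastases have
*positive* logFC, matching the reporting convention of the tables this
stage feeds. Survival: expression is dichotomized at the median (ties
go low — deterministic), the Cox indicator codes 1 = low expression so
HR > 1 reads "low expression worse", and the univariate Cox model is
fitted by Newton–Raphson on the Efron-tie-corrected partial likelihood
(tolerance 1e-8 on |Δβ|, max 25 iterations; Efron because
dichotomization produces heavy ties). SE from observed information;
two-sided Wald p; Bonferroni across the screened miRs. Monotone
likelihood (complete separation) is flagged and the p-value falls back
to the score test at β=0, whose statistic equals the log-rank statistic
in the untied two-group case (asserted against an independent log-rank
oracle to 1e-6). The analysis subset defaults to primary tumours with
follow-up; which samples belong in survival analysis is genuinely
ambiguous, so it is a parameter. The KM estimator is the plain
product-limit curve.

The synthetic cohort is 99 primary + 14 metastatic samples (the shape
of the public prostate cohort this stage is designed around), Gaussian
log2 expression (mean 8, sd 1.5), exponential event times with hazard
0.015/month × exp(Σ loghr·I[x > median]) and independent exponential
censoring at 0.01/month (≈40–60% events). A planted *negative* loghr on
the high-expression half makes low expression the worse group.

## Problem sizes and determinism

Default end-to-end run: 1,253 miRs × 16 plates × 3 replicates × 2
screens, 3+3 count samples at 1e6 depth, 113-sample cohort — a few
seconds on one core; simulation-based tests use 200–2,000 units and
300 replicates where coverage or error rates are asserted. Every
generator and the pipeline are deterministic given their seed (child
seeds derive from one `SeedSequence`), and a re-run with the same seed
produces a byte-identical report.

## Known limitations

- The generator's additive plate-offset model cannot represent
  multiplicative batch effects or spatial gradients within a plate
  (edge effects are tested, not modelled).
- The NB procedure tests a single two-group contrast; no multi-factor
  designs, isomiR handling or count-matrix construction from reads.
- LDA classifies wells, not single cells; quadratic boundaries and
  cross-validated model selection are out of scope.
- Passing tests on synthetic data demonstrates correctness of the
  decision rules and estimators under the stated models, not robustness
  to the pathologies of real screens (uneven seeding, transfection
  gradients, segmentation failures on clumped cells).
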