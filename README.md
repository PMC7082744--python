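# mirscreen

Integrative analysis of high-throughput miRNA phenotypic screens in
prostate-cancer cells: scratch-assay **migration** quantification,
high-content **morphology** (eccentricity) profiling, plate-normalized
robust Z-score hit calling, LDA phenotype classification, small-RNA
**negative-binomial differential expression**, positional **AAGUGC
seed-motif enrichment**, and median-split **Cox survival screening** of
a clinical cohort — all driven by a synthetic-data generator so the
entire pipeline runs and is testable offline.

The package is aimed at computational biologists who want a compact,
fully tested reimplementation of this kind of integrative screen
analysis, either to reanalyse their own plate/count/cohort tables or to
study the statistical behaviour of the decision rules on data with
known ground truth.

## The analysis in brief

**Screens.** Each well's raw readout (gap area closed for migration;
mean cell eccentricity for morphology) is normalized per plate against
negative-control wells, `x' = (x − median(neg)) / (1.4826·MAD)`, then
converted to robust Z-scores against the library distribution per
replicate, `Z = (x' − median(lib)) / (1.4826·MAD(lib))`, and averaged
over replicates. Hits are `Z < −1` (inhibiting migration / rounding
cells) or `Z > +1`, with a viability window `0.8 < v < 1.2` removing
miRs whose phenotype is confounded by cell death or over-proliferation.

**Morphology classes.** An LDA model with pooled within-class
covariance is trained on control wells (negative/mock = mesenchymal,
miR-373 = epithelial, siPTK6/miCon = intermediate) over seven shape
features (Area, Compactness, Eccentricity, EulerNumber, Extent,
FormFactor, Solidity) and applied to library wells.

**Expression.** miR counts for an epithelial-vs-mesenchymal 3+3 design
are tested with a two-group NB Wald procedure: median-of-ratios size
factors, moderated method-of-moments dispersion, SE from the NB Fisher
information, BH adjustment; DE sets use `|log2FC| > 1`, adj. p < 0.05.

**Integration.** miRs that inhibit migration AND induce rounding (both
viability-filtered) AND are up in the epithelial line form the triple
intersection. The seed (nucleotides 2–7 from the 5′ end) of every
library miR is tested for AAGUGC over-representation in each hit set
with a two-sided Fisher's exact test, distinguishing seed-position
(2–7) from shifted (3–8) carriers.

**Clinic.** For a primary/metastatic cohort, Welch t-tests find miRs
down in metastases; their overlap with migration hits is screened by a
univariate Cox proportional-hazards model (Efron ties, Newton–Raphson)
on median-dichotomized expression with Bonferroni correction; HR > 1
means low expression carries worse survival.

## Worked example

```python
from mirscreen.pipeline import PipelineConfig, run_pipeline

report = run_pipeline(PipelineConfig(), rng_seed=42, outdir="run42")
p = report.payload
print(p["triple_intersection"][:2])
print(p["seed_enrichment"]["migration_low"]["pvalue"])
print(p["lda"]["agreement_with_eccentricity"])
```

prints (seed 42):

```
['syn-miR-302d-3p', 'syn-miR-373-3p']
8.49273693243724e-22
0.9453551912568307
```

The two planted positives — synthetic miRs carrying the real mature
sequences of miR-373-3p and miR-302d-3p, and hence the AAGUGC seed —
are recovered in the triple intersection together with the other
planted seed-carrier hits. The Fisher p-value says the AAGUGC seed is
heavily over-represented among viability-filtered migration hits
(27 of 40 planted carriers were called and filtered through), and 95%
of wells the LDA calls epithelial are also eccentricity hits
(Z < −1). The report also carries QC (replicate Pearson r ≈ 0.92,
control separation: positive controls Z ≈ −1.5 vs negative ≈ +0.9,
per-plate edge tests), DE counts, positional seed-group means
(AAGUGC at 2–7: mean migration Z ≈ −0.93 vs ≈ 0.02 for non-carriers)
and the survival table. All stage artifacts (layout, measurements,
scores, hits, counts, DE results, cohort, KM-ready survival columns,
report JSON) are written under `run42/`.

The same run is available from the shell:

```bash
mirscreen run --seed 42 --out run42
mirscreen synth --preset images --seed 1 --out imgs   # scratch/morphology PNGs
```

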