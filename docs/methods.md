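# Methods

This note documents the models and procedures implemented in `immunotime`,
the parameter choices behind the shipped defaults, and what the synthetic
cohort generator does and does not emulate.

## Study design the package targets

The package implements the analysis chain of a two-arm tumor-immune-
microenvironment study: a cohort of OPSCC patients split by transforming
HPV infection (HPV-positive ⇔ detectable HPV DNA **and** p16^INK4a
immunostaining in ≥70% of tumor cells — the inclusive threshold is a
deliberate reading of "at least 70%"), each patient contributing a primary
tumor and a lymph-node metastasis imaged as ≥20 mIF fields, a 770-gene
immune expression panel with 40 housekeeping genes measured on primary
tumors, and disease-free survival (months from last treatment to death or
relapse, censored at last follow-up). The shipped synthetic cohort mirrors
the reference composition: 39 patients, 24 HPV-positive (21 HPV16, 2
HPV33, 1 HPV18; 12 women) and 15 HPV-negative (4 women).

## Coordinates, compartments, phenotypes

Cell tables carry micrometre coordinates in a per-field local frame with
origin at the field's top-left corner; the acquisition frame of the
upstream imaging platform is not modelled. Fields default to 650 × 500 μm
(configurable) — a plausible 20× multispectral field; no instrument value
is assumed. Densities convert μm² to mm² by 10⁻⁶.

Marker calls are consumed as binary: the intensity thresholding that
produces them is upstream of this package (Non-goal), because the analysis
itself operates on phenotype calls, not intensities.

Phenotype rules are conjunctions of required-positive and
required-negative markers, and labels are **non-exclusive** — a
CD8⁺CD103⁺PD-1⁺ cell simultaneously carries the CTL, T_RM and
triple-positive labels, which is what makes "percentage among parent"
denominators meaningful (the child rule must provably refine the parent
rule). Two definitional choices are declared rather than inferred, and are
editable in the YAML rule set:

* Treg = FoxP3⁺ **CD8⁻**, to avoid double-counting FoxP3-expressing
  activated CTL;
* Th (6-color panel) = CD4⁺ **CK⁻**, to exclude CK/CD4 co-staining
  artifacts.

The tumor compartment is the union of pan-cytokeratin-defined nest
polygons clipped to the field rectangle; a cell on the nest boundary
counts as intra-tumoral (inclusive point-in-polygon). Tumor + stroma area
always equals the field area, to polygon-clipping precision.

## Quantification

Per-lesion statistics pool cells and compartment areas across all fields
(total count / total area) rather than averaging per-field values: this is
robust to empty fields and consistent with count-based ratios; pooling is
a declared choice, as field-level aggregation conventions differ between
labs. Zero-denominator results (no parent cells, zero compartment area
with zero cells) propagate as missing values, are logged, and are excluded
pairwise from group tests — never silently reported as 0.

## Spatial statistics

Both statistics use Euclidean centre-to-centre distances (cell shapes are
not modelled), are restricted to pairs within the same field, and exclude
a cell from being its own neighbor when it carries both the reference and
the query label.

* **Mean nearest-neighbor distance**: per reference cell, distance to the
  nearest query cell in its field; mean over all reference cells whose
  field contains ≥1 query cell. References in fields without any query
  cell are *excluded* from the mean (not assigned an infinite distance)
  and counted in the reported exclusion tally.
* **Count-within** (`pct_within_radius`): percentage of reference cells
  with ≥1 query cell at distance ≤ r (closed ball; r = 20 μm default).
  "Within a 20 μm radius" is read as boundary-inclusive.

The compartment scope filters **reference cells only**; query cells are
taken field-wide. No edge correction is applied: cells near field borders
have truncated neighborhoods, biasing the count-within statistic downward
by a small amount (≈1–2 percentage points at the default field size and
calibration); this matches the behavior of the common upstream tooling and
is deliberately left uncorrected.

The production implementation proposes neighbors with a KD-tree and then
recomputes candidate distances with plain vectorized arithmetic, so its
output is bit-identical to a brute-force O(n²) scan (asserted over random
instances up to 2,000 cells in the test suite).

## Synthetic cohort generator

The generative model is the package's own construction — the minimal
spatial model expressing the measured quantities (densities, NN distances,
count-within), not a model taken from any study:

* **Geometry**: tumor nests are random discs (radius ~ Normal(80, 20) μm,
  floored at 10 μm) added until the clipped union reaches the target tumor
  area fraction (default 0.35).
* **Cells**: each phenotype class (tumor/CK, CD8, Treg/FoxP3, macrophage/
  CD68) is a homogeneous Poisson process with compartment-specific
  intensity λ (cells/mm²); co-expression markers (CD103 and PD-1 on CD8,
  CD163 and PD-L1 on CD68, PD-L1 on CK) are independent Bernoulli draws at
  arm-specific fractions. Under this model the count-within statistic has
  the closed form pct = 1 − exp(−λ_query·πr²/10⁶), which the test suite
  verifies on large fields.
* **Attraction**: a fraction ρ of an attracted class is relocated
  uniformly into a disc of radius r_attr around a uniformly chosen anchor
  cell (rejection keeps cells in-field). Relocation rather than a Gibbs
  process gives exact-ρ semantics and trivial sampling. Compartments are
  assigned from final positions. The shipped calibration uses ρ = 0
  everywhere: the printed contrasts are reproducible by compartment-
  specific intensities alone, and ρ is kept as a mechanism for sensitivity
  experiments.
* **Patient heterogeneity**: per patient and class, intensities are scaled
  by a log-normal multiplier (σ = 0.25 for immune classes, 0.05 for tumor
  cells) — enough between-patient spread to make Mann-Whitney contrasts
  realistic without destabilizing cohort means.
* **Calibration**: the default intensity table was derived by inverting
  the closed form at the reference contrasts (≈30% vs ≈4% of metastatic
  tumor cells with a CTL within 20 μm in HPV⁺ vs HPV⁻ lesions; ≈60/40%
  vs ≈20/10% of stromal/intra-tumoral M2-TAM near CTL in primaries) and
  then adjusted once by simulation for nest-edge blending and field-edge
  bias. CD8, CD68 and CD68⁺CD163⁺ densities are higher in the HPV⁺ arm;
  FoxP3 intensities are identical across arms ("comparable" by
  construction).
* **Expression**: counts ~ NegativeBinomial(mean, dispersion 0.1), gene
  baseline means log-uniform on [50, 1000] (housekeeping on [200, 2000],
  one mean per gene shared by all samples — no group effect by
  construction); a configurable number of endogenous genes (default 30)
  receives a signed log₂ fold change drawn uniformly from the configured
  range (type default [1.2, 2.0]) applied to the positive-group mean.
* **Survival**: DFS ~ Exponential with log-hazard = log(0.02/month) +
  Σ β·z over standardized latent immune covariates; the default links the
  patient's latent CD8 multiplier with β = −0.9 (more infiltrated →
  longer DFS). Administrative censoring is uniform on [0.5·horizon,
  horizon] (horizon 72 months), yielding mixed censoring like a real
  follow-up window.

All randomness flows from one integer seed through
`numpy.random.SeedSequence.spawn` (spatial, expression, survival streams
in fixed order); identical seeds give bit-identical cohorts, and a truth
record retains every injected parameter for recovery tests.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: cell morphology and segmentation error,
intensity-level noise and gating uncertainty, spatial correlation beyond
first-order intensity + optional pairwise attraction (no clustering of
immune cells among themselves, no exclusion zones), per-sample variation
in field counts ("at least 20" is fixed at exactly 20), linkage between
the spatial and expression layers beyond the shared HPV label, nest-shape
realism (discs, not infiltrative fronts), and the 6-color panel
(CD4/CTLA-4/HLA-I rules ship for ingested tables but are not simulated).

## Expression analysis

Raw counts are floored at 1, divided per sample by the geometric mean of
that sample's housekeeping genes, and log₂ transformed. This per-sample
self-normalization implements the ratio-to-housekeeping definition
literally; the platform-vendor variant (rescaling to the cohort mean of
housekeeping geometric means) differs only by a per-cohort constant on the
log₂ scale and changes neither differential expression nor score
differences. Background subtraction from negative-control probes is not
reproduced.

Differential expression regresses each endogenous gene's log₂ value on
the binary HPV indicator by OLS — with a single binary covariate this is
exactly the equal-variance two-sample t-test (df = n − 2). Housekeeping
genes are never tested. Genes with zero residual variance get a missing p
and are excluded from the BH family (m = endogenous genes with a valid p).
DEG calling uses |log₂FC| > 1 (strict) and BH-adjusted p < 0.05.

Signature scores are unweighted means of a sample's log₂ values over the
member genes present (missing members are counted and logged); proprietary
per-gene weights of commercial scoring modules are not available, so the
unweighted mean is declared as an approximation. Signature "ratios" are
score differences, i.e. log₂ of the linear ratio. The shipped signature
lists are editable placeholders; real analyses should supply curated YAML.

## Survival analysis

Each immune variable is dichotomized at its median (midpoint of central
order statistics for even n); values equal to the median go to the **low**
group — the tie rule is a declared convention, chosen to be deterministic.
The split is therefore invariant under strictly increasing transforms.
Kaplan-Meier estimation, the two-group log-rank (Mantel-Cox) test and
univariate Cox regression are delegated to lifelines; Cox ties are handled
by Efron's method (appropriate for month-resolution times, which tie
heavily). Complete separation is surfaced as a flagged result with an
unbounded hazard ratio rather than a silent non-convergence (detected via
a convergence error or an effectively unbounded coefficient, |β| > 15).
Subjects with DFS time 0 are shifted to 0.01 months to avoid risk-set
degeneracy, with a warning.

The per-variable survival screen reports **raw** log-rank and Wald
p-values, matching the descriptive-screening convention of this study
type; a BH-adjusted column is emitted alongside for transparency but is
not used for calling.

## Group statistics

* Mann-Whitney is two-tailed; exact enumeration when n₁ + n₂ ≤ 20 with no
  ties, otherwise the normal approximation with mid-rank tie correction
  and continuity correction. The approximation tracks the exact p to
  ≤ 0.02 wherever the exact p ≤ 0.1 (verified exhaustively for n ≤ 8);
  in the middle of the distribution the continuity-corrected
  approximation can differ from the exact value by up to ≈0.13, which is
  irrelevant for significance decisions.
* Spearman correlation uses mid-ranks on pairwise-complete observations
  (n ≥ 3); constant vectors yield a missing coefficient with a warning.
* Fisher's exact test enumerates all tables with the observed margins
  (total ≤ 200) and sums the probabilities of tables no more probable
  than the observed one, within relative tolerance 10⁻⁷ — the
  point-probability two-sided definition shared by R and SPSS. Published
  contingency-table p-values computed with other software (e.g. Pearson
  chi-square) will not generally match this definition.
* Significance stars follow the usual figure-legend levels
  (\*p < 0.05, \*\*p < 0.01, \*\*\*p < 0.001, \*\*\*\*p < 0.0001).

## Numerical and degenerate-input conventions

* Missing results are NaN, never 0; every exclusion is logged.
* CSV floats are parsed with round-trip precision so write→read→analyze
  reproduces bit-identical proximity and DE outputs; geometry persisted as
  full-precision WKT reproduces areas to ≤1 ulp (re-clipping may reorder
  polygon vertices).
* Nearest-neighbor candidates from the KD-tree are re-scored with the same
  arithmetic as the brute-force oracle, making the accelerated and naive
  paths bit-equal.
* The rejection sampler for in-region cell placement and the nest
  generator both have bounded attempts and raise a generation error rather
  than looping forever on unreachable targets (e.g. tumor area fraction
  near 1 with small discs).

## Problem sizes

Defaults were chosen so a full study runs interactively on one CPU: a
full synthetic cohort (39 patients × 2 lesions × 20 fields, ≈650k cells)
plus the complete pipeline takes ≈80 s; the acceptance script (four
24/15-lesion spatial arms at 20 fields plus 20 replicate 770 × 39
expression cohorts) ≈15 s; the test suite ≈1 min, using reduced field
counts and gene counts where full scale adds nothing to the property
under test.

## Known limitations

* No edge correction for spatial statistics (documented negative bias).
* No Ripley's K / pair-correlation functions or permutation-based spatial
  null models; no multivariate Cox, competing risks, or PH diagnostics.
* Signature scores are unweighted means over placeholder gene lists.
* The generator's independence assumptions (Bernoulli co-expression,
  independent Poisson classes) are stronger than real tissue biology;
  effect sizes recovered from it bound what the pipeline can do under
  ideal conditions, not what it will achieve on real sections.
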