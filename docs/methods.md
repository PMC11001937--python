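# Methods

## Synthetic study generator

The generator reproduces the *structure* of a three-generation fecal
multi-omics study, not any particular cohort's values.

**Cohort and worklist.** Defaults: 67 Infants, 67 Mothers, 63
Grandmothers drawn from 67 families (so some triads are incomplete),
analysed in three single-generation batches — Mothers in batch 1,
Grandmothers in batch 2, Infants in batch 3. Each batch opens with 3
equilibrium QCs (excluded from all statistics), carries 8 interspersed
QCs placed every 9–10 injections by splitting the randomized study
samples into eight near-equal stretches, and has blanks after
equilibration and at the end of the run. Injection orders are contiguous
within a batch.

**Metabolome.** Intensities are log-normal: feature `f` in sample `i`
has `log level = μ_f + β_{f,g(i)} + u_{fam(i),f} + ε`, with generation
effects `β` additive on the log scale, family intercepts
`u ~ N(0, 0.25²)` and residual sd 0.5. The observed value multiplies
this level by a drift factor, a per-feature batch factor
(log-sd 0.3) and analytical noise (CV 2%, the reproducibility of a
well-behaved pooled QC). Drift is multiplicative in injection order:
`d(o) = 1 + a·(o/n) + s·sin(2π o/n + φ)` with `|a| ∈ [0.3, 0.8]` (the
drift moves intensities by 30–80% across a run — a realistic range for
long GC-MS sequences; the magnitude is a parameter, not an asserted
study value) and a small smooth component `s`, constrained strictly
positive. QC injections carry the pooled mean of the three generation
base levels times drift/batch/noise; blanks carry only the background
signal, which is non-zero for 8 designated contaminant features whose
study-sample signal is mostly that same background (giving blank
subtraction a designed set to remove). Missingness is left-censoring
below a per-feature detection quantile (up to 15% on a quarter of the
features) plus 0.5% random dropout. About 30% of generic features carry
true generation effects of 0.5–1.5 log units, concentrated in three
"driven" pathways so over-representation has a planted signal; the named
fatty acids follow the expected biology (acetic acid high and
infant-elevated; longer SCFAs, all BCFAs and the MUFA feature rising
with age) and two internal standards are effect-free with tight noise.

**Taxa and KOs.** ASV counts are Dirichlet-multinomial: per-generation
base compositions put >50% of infant mass on *Bifidobacterium*,
*Escherichia/Shigella* and *Veillonella* while adult compositions are
flatter (higher expected Shannon); the Dirichlet precision (default 50)
controls sample-to-sample overdispersion and library size defaults to
20 000. KO counts are multinomial draws from the taxa-abundance-weighted
mixture of per-genus genome profiles (a shared core plus genus-specific
KOs, 40% specific mass), which builds the taxa–function correlation in
by construction. A BRITE-like two-level hierarchy is attached, with
~15% of KOs belonging to two level-C entries.

**What the generator does not emulate:** chromatographic peak shape and
co-elution, retention-index drift, compositional sequencing artifacts
(GC bias, contamination), strain-level variation, or covariates such as
diet and birth mode. Tests passing on these simulations demonstrate the
*algorithms* behave as specified under the designed data-generating
process; they do not certify performance on any particular real cohort.

## QA

Stage order is blank subtraction → presence filter → RSD filter; each
stage is idempotent and the report reconciles counts with one reason
code per removed feature. "Present" means non-missing and > 0. The
presence filter requires ≥50% QC presence AND ≥70% study-sample presence
within a batch (the strict conjunction; an `"or"` toggle exists),
applied per batch with a feature kept if it passes anywhere. The RSD
filter keeps a feature whose interspersed-QC RSD is below 30% in at
least one batch; the stricter all-batch count is always reported because
it is the sensitive indicator of drift correction. The blank-ratio
default is 3 — the conventional signal-to-blank margin.

## Drift correction

QC-SVRC fits an RBF support-vector regression of QC intensity versus
normalized injection order, per feature and batch, requiring ≥5
interspersed QCs. The grid is cost ∈ {1, 10, 100} × max|y| and
ε ∈ {0.05, 0.1, 0.25, 0.5, 1} × MAD(QC intensities), selected by
leave-one-QC-out squared error; the MAD mixes drift amplitude with
noise, so the grid reaches well below one MAD and the CV picks the tube
width. Correction divides by predicted/reference (reference = batch QC
median) — a multiplicative drift model, consistent with the generator
and with how instrument response decays. Orders outside the QC span get
the nearest-edge prediction. A fitted curve that is non-positive
anywhere on the batch range, or a constant/degenerate QC series, falls
back to a flat batch-median model and is flagged. QC-Norm scales each
batch per feature by grand-QC-median / batch-QC-median (medians for
robustness); features with a non-positive batch median are excluded and
flagged. KNN imputation (default k = 5, Euclidean distance on
unit-variance-scaled shared-observed features, mean of neighbors) is
used for the targeted-panel use case and to complete matrices entering
multivariate models; observed entries are never modified.

## Chemometrics

UV scaling is mean 0 / sd 1 (ddof = 1) with constant features dropped.
PCA is an SVD of the centered matrix with a fixed sign convention (the
largest-magnitude loading of each component is positive). PLS-DA uses
NIPALS (via the standard PLS2 implementation) on a dummy-coded,
centered class matrix; R² is the per-component increment of explained
dummy variance and Q² = 1 − PRESS/TSS over stratified venetian-blind
folds (default 7 — a conventional choice; the fold count for the
supervised chemometrics is a free parameter here). The QC-dispersion
diagnostic is the mean squared distance of QC scores to their centroid
divided by the same quantity for study samples.

## Mixed models

The per-feature model is `y = μ + generation + family intercept + ε`.
For a single random intercept the marginal covariance is block-diagonal
`σ²(I + θ J)` per family with `θ = τ²/σ²`, so the (RE)ML problem
profiles to a 1-D optimization over θ with closed-form GLS pieces; the
solver optimizes log θ by bounded scalar minimization and checks the
θ = 0 boundary explicitly. This exact solver was written for speed
(thousands of per-feature fits in simulations) and is held to agreement
with a general-purpose REML implementation in the test suite. The
response is standardized internally for conditioning and estimates are
rescaled. The overall generation test is a likelihood-ratio χ² (2 df)
of nested ML fits; contrasts are Wald tests on the REML fit; BH FDR is
applied per contrast across features. Subjects with no recorded family
become singleton groups. Boundary fits (τ² = 0) are flagged, never
silent. The same engine backs the functional-profile linear-model
screen at adjusted p ≤ 0.10, with constant columns excluded and
flagged.

## Ratios, ecology, functional profiles, associations

The SCFA/BCFA ratio is (acetic + propionic + valeric + caproic) over
the seven BCFAs; MUFA/PUFA is the single co-eluting "Linoleic
Acid/Oleic Acid" feature (treated as one feature, not a quotient) over
(arachidonic + eicosatrienoic + docosahexaenoic). Name matching is
exact with a user alias map. Shannon uses the natural log; no
rarefaction is applied and richness is on raw counts. Minor-taxon
lumping uses means of per-sample proportions within groups and lumps a
taxon only when below the cut (0.1% phyla, 2% genera) in *all* groups.
TMM follows the canonical definition (reference = library with
upper-quartile closest to the mean; 30% M-trim, 5% A-trim, precision
weights; factors centered to geometric mean 1) and the functional screen
runs on TMM-normalized abundances. ORA's default background universe is
the annotated, measured feature set (standard practice; a full reference
metabolome can be supplied as the universe instead). Spearman p-values
switch to the exact n! permutation distribution at n ≤ 9 where the t
approximation is poor; correlations pool all samples.

## Multiblock integration

The model maximizes `Σ_{k≠l} D_{kl} cov(t_k, t_l) + Σ_k cov(t_k, u)`
over unit loading vectors, where `t_k = X_k a_k`, `u` is the outcome
score of the centered dummy matrix, and `D` is the block design (default
full design with off-diagonal 1; the outcome is always weighted 1). Each
update soft-thresholds the loading at the (keepX+1)-th largest
magnitude, so exactly keepX entries per block per component are nonzero,
with ties broken by variable index. Initialization is the dominant
singular direction of `X_kᵀY` (deterministic, sign-fixed); convergence
is a 1e-6 max loading change with a 500-iteration cap (non-convergence
raises). Blocks are deflated by regression on their own score, so
within-block scores are orthogonal; the outcome is deflated by its own
score. Prediction maps new data through `R = A(PᵀA)⁻¹`, classifies per
block by nearest class centroid in score space, and majority-votes
across blocks (ties to the alphabetically first class). CV is
stratified k-fold with reshuffled folds per repeat. AUROC uses the
mid-rank Mann–Whitney statistic on the least-squares prediction of each
one-vs-all dummy column from the block's scores. The similarity matrix
projects each selected variable onto the components as its correlation
with the averaged block scores and takes inner products of those
projection vectors, emitting signed values above the cutoff
(cross-block pairs by default). The CIM uses complete-linkage
agglomeration with Euclidean distance on both axes via the standard
hierarchical-clustering routine (deterministic for fixed input order);
dendrograms can be exported as Newick.

## Pipeline

`run_pipeline` executes simulate → QA → normalize → chemometrics →
mixed-model stats → ratios → ecology → functional → correlate → enrich
→ integrate, writing every stage output as TSV with fixed float
formatting and a manifest of SHA-256 checksums and counts; a rerun with
the same config and seed reproduces the manifest byte-for-byte. The
master seed fans out through `SeedSequence` substreams so stages are
individually reproducible. The functional screen runs at BRITE level B;
correlation pairs default to the eight most abundant genera × eight
named metabolites.

## Problem sizes and numerical choices in the test suite

Simulation-backed tests use the study-scale defaults (197 study
samples, 150 features) where the claim concerns the default conditions,
and smaller cohorts (12–24 subjects per generation, 20–60 features)
for replicated properties, chosen to keep replicate counts high; the
determinism check runs the full pipeline at 14/14/12 subjects and 40
features twice. Mixed-model calibration uses 1000 simulated features on
60 three-member families. Monte-Carlo acceptance bands follow binomial
intervals at those sizes. Tolerances: 1e-6 loading convergence, 1e-8
variance-boundary threshold, exact-arithmetic oracles asserted at
1e-9–1e-12.

## Known limitations

- The SVR drift model assumes smooth drift; abrupt step changes within
  a batch are absorbed only partially (QC-Norm handles between-batch
  steps).
- The LMM engine covers exactly one random intercept; nested or crossed
  random effects are out of scope.
- PLS-DA R²/Q² conventions differ across software; values here follow
  the definitions above and are not expected to reproduce any
  commercial package's numbers exactly.
- The multiblock design matrix and component count are user choices;
  defaults (full design, 2 components) are documented, not optimized.
- ORA ignores pathway topology; only membership is used.
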