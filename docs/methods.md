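# Methods

This note documents the models and procedures implemented in `gutage`, the
assumptions behind them, the defaults and why they were chosen, and what the
synthetic cohort does and does not emulate.

## The analysis chain

The package re-implements, as tested desk-scale code, the bespoke
computations of a multi-omics aging analysis linking the gut metagenome,
the serum metabolome, renal function and age:

1. gene-level relative abundance profiles → co-abundance gene groups
   (CAGs) and metagenomic species (MGSs) by canopy clustering;
2. rule-based taxonomy of genes and MGSs from best-alignment-hit tables;
3. diversity, enterotypes, and PERMANOVA effect-size decomposition;
4. random-forest forward selection linking MGS abundances to metabolites,
   scored by leave-one-out Q²;
5. bidirectional mediation screening of microbe → metabolite → age chains;
6. clinical formulas: four-branch CKD-EPI eGFR and qPCR telomere T/S.

All stages run on a synthetic cohort with planted ground truth, so every
recovery claim in the test suite is checked against a known answer.

## Canopy clustering (`gutage.canopy`)

Genes whose abundance profiles co-vary across samples are grouped greedily:
seeds are visited in descending order of total abundance (ties broken by
gene id — the seed rule is a design choice; high-abundance genes have the
most reliable correlation estimates), and a gene joins the canopy iff its
profile has Pearson r > 0.9 **and** Spearman ρ > 0.6 against the canopy
profile. After capture the canopy profile is recentered to the member
median and membership re-captured (`recenter_iters`, default 1). Clustered
genes leave the seed pool, so canopies are disjoint. Canopies whose median
profiles correlate at r ≥ 0.97 are merged transitively (union–find; the
closure is order-independent). The 0.97 value is interpreted as a
*correlation* threshold, not a distance: a distance reading (1 − r ≤ 0.97)
would merge nearly everything and defeat the method. Evidence filters then
discard canopies with ≤ 2 genes, canopies whose three strongest samples
hold ≥ 90 % of the summed signal, canopies detected in < 4 samples, and
canopies with ≥ 90 % of signal in one sample. Survivors are CAGs; CAGs
with **more than 700** member genes are MGSs, and MGS abundance is the
per-sample median of member-gene abundances (even counts: midpoint).

Numerical details: Spearman uses average ranks; zero-variance profiles
have undefined correlation and are neither seeds nor capturable. The
implementation is fully deterministic. Target scale is ≤ ~10⁵ genes;
bit-level replication of the original external clustering binary is out of
scope.

## Taxonomy rules (`gutage.taxonomy`)

Hits under 70 % query coverage are discarded; the best hit is the maximal
bit score. Gene ranks follow best-hit identity with *inclusive* thresholds
(≥ 95 % species, ≥ 85 % genus, ≥ 65 % phylum, else unassigned). Bit-score
ties across species are resolved by frequency, then mean identity, then
lexicographic name (the last step is our documented tie-break). An MGS is
a species if ≥ 90 % of its member genes hit that species at ≥ 95 %
identity and ≥ 70 % coverage, else a genus at ≥ 80 % / ≥ 85 %; fractions
are computed over *all* member genes including unannotated ones
(conservative). Hit tables carry a single (DNA) identity column; a
protein-identity criterion for the genus rule is deliberately not modelled.

## Ecology (`gutage.ecology`)

* Shannon entropy H′ = −Σ aᵢ ln aᵢ in nats, renormalized internally.
* Bray–Curtis d(i,j) = Σ|xᵢ−xⱼ| / Σ(xᵢ+xⱼ). BC is not metric; the
  triangle inequality is neither used nor enforced.
* Enterotypes: distance = √JSD between genus profiles (natural log), PAM
  (BUILD + SWAP, deterministic) around medoids, k chosen by the
  distance-based Calinski–Harabasz index; the cluster driver is the genus
  with the highest mean relative abundance. All three choices are
  configurable because the upstream description fixes none of them.
* PERMANOVA: with G = −½·C·D²·C (C the centering matrix) and hat matrix H
  of the design (numeric regression or one-hot), R² = tr(HGH)/tr(G) and
  pseudo-F is compared against label permutations; sampled p-values use
  the add-one convention (never 0), and an exact mode enumerates all n!
  permutations for small n. The effect-size decomposition keeps covariates
  with marginal p < 0.05, removes redundancy greedily in descending R²
  (drop when |Pearson r| > 0.5 with a retained variable — keeping the
  higher-R² member preserves explanatory power deterministically), and
  reports the combined effect as the total model R² of the retained set,
  which is invariant to input order and ≥ the largest single R²
  (nested models).

## Random-forest forward selection (`gutage.models`)

Q² = 1 − RSS/TSS on held-out predictions. LOOCV trains one forest per
held-out sample with a deterministic per-fold seed (`seed + fold`).
Forward selection takes the first variable by permutation importance
(increase in MSE) of a forest on all candidates — a single-variable-Q²
mode is also provided — then adds, at each step, the unselected variable
with the largest LOOCV Q² of the augmented set, stopping when the best
candidate fails to improve Q² by more than `tol = 1e-6` (ties are "no
increase"), so the trajectory is strictly increasing by construction.
"Variance explained" for a metabolite is the final LOOCV Q² × 100.
Forest defaults: 500 trees, mtry = ⌊p/3⌋ (the classic regression
defaults); analysis drivers and some tests use smaller forests and
restricted candidate sets to keep LOOCV loops at desk scale.

Correlation power uses the Fisher-z approximation:
power = Φ(√(n−3)·atanh|r| − z₁₋α/₂) + Φ(−√(n−3)·atanh|r| − z₁₋α/₂), which
equals α exactly at r = 0 and is monotone in |r| and n.

## Mediation (`gutage.mediation`)

Mediator model m ~ x, outcome model y ~ x + m + x·m, both least squares.
ACME and ADE come from the quasi-Bayesian simulation approach: parameter
vectors are drawn from the fitted models' asymptotic normals, potential
outcomes contrasted at control = mean(x) and treat = mean(x) + 1 SD (a 0/1
contrast is meaningless for relative abundances; the contrast is
configurable), and with an interaction both effects are averaged over the
two arms, which makes total = ACME + ADE an exact identity for the point
estimates. p is the two-sided simulation p with an add-one correction;
1000 draws by default; fixed seeds reproduce CIs bit-for-bit. Collinear
exposure/mediator pairs (|r| > 0.999) are rejected.

**Direction of the inverse run.** The screen tests every Spearman-passing
(microbe, metabolite) pair forward (x = microbe, m = metabolite, y = age)
and inversely with **exposure and mediator swapped** (x = metabolite,
m = microbe, y = age); a linkage passes iff p_fwd < 0.05 and p_inv > 0.05.
The seemingly natural alternative — swapping mediator and outcome
(microbe → age → metabolite) — cannot separate direction in a linear
chain: the mediator's residual noise reaches the outcome, and the inverse
z-statistic equals z_fwd/√(1−ρ²) ≥ z_fwd (ρ = partial mediator–outcome
correlation), so a true forward chain is flagged "inverse-significant"
whenever it is forward-significant. The exposure–mediator swap instead
probes whether the microbe carries any effect on age beyond the
metabolite, which is exactly null for a complete chain (zero direct
effect) and strongly non-null when the true chain runs
microbe → age → metabolite. Both modes are available
(`inverse_mode=`); the exposure–mediator swap is the default. Consequence:
for partially-mediated chains (c′ ≠ 0) the default inverse run will
reject genuine linkages — the screen is conservative by design.

## Clinical formulas (`gutage.clinical`)

CKD-EPI (no race coefficient):
female SCr ≤ 0.7: 144·0.993^age·(SCr/0.7)^−0.329; female SCr > 0.7:
…^−1.209; male SCr ≤ 0.9: 141·0.993^age·(SCr/0.9)^−0.411; male SCr > 0.9:
…^−1.209. The male low-creatinine exponent is sometimes printed as
−0.4111; the published CKD-EPI −0.411 is the default and the exponent is
overridable (`male_low_exponent=`). The function is continuous at the
knots and strictly decreasing in age and creatinine. Telomere T/S =
2^−ΔΔCt with ΔCt = Ct(T) − Ct(S), ΔΔCt relative to an inter-batch
standard; replicates are averaged by arithmetic mean of Ct (standard ΔΔCt
practice), and the ratio is invariant to a constant shift of all Ct
values.

## Association statistics (`gutage.assoc`)

Spearman ρ with average ranks; two-sided p by exact permutation
enumeration for n < 10 and the t approximation (n−2 df) otherwise.
Age-adjusted partial Spearman uses the precision matrix of the rank
correlation matrix (p on n−2−k df); with no covariates it *is* the plain
Spearman, bit-for-bit, and a covariate rank-identical to x or y returns
(0, 1) rather than inverting a singular matrix (the association is zero by
definition). It matches `pingouin.partial_corr(method="spearman")` to
machine precision. BH FDR is the step-up q-value in input order, capped at
1. Group tests wrap the standard two-sided Wilcoxon rank-sum (exact when
sizes ≤ 25 and no ties), Kruskal–Wallis, and Fisher exact tests. A
"local FDR" estimator is not provided (no defined estimator to follow).

## The synthetic cohort (`gutage.synthetic`)

What it emulates, per draw from one integer seed (bit-identical reruns):

* **Subjects**: age uniform on 20–111 years (a helper bins the four age
  groups at 60/90/100); serum creatinine SCr = 0.6 + 0.004·age + N(0,0.1)
  mg/dL floored at 0.3 — invented solely to exercise both sides of the
  sex-specific eGFR knots; a few auxiliary covariates (urea, hsCRP).
* **Species**: log-abundance = species intercept (N(0, 1.5²)) + N(0, 1)
  per sample; designated species add slope·(age − mean age) on the log
  scale (default 6 species at ±0.02/yr). Exponentiation + renormalization
  gives compositional, heavy-tailed profiles.
* **Genes**: species abundance × fixed per-gene log-normal multiplier
  (SD 0.5) × multiplicative log-normal noise (SD 0.2), then
  *detection-limit dropout*: an entry is zeroed with probability
  2·p·(1 − rank fraction), i.e. low-abundance entries are preferentially
  lost at marginal rate p (default 0.1), then per-sample renormalization.
  Uniform at-random dropout was rejected: on heavy-tailed profiles it caps
  within-species gene correlations near 0.8, which no clustering could
  survive, and it is also not how detection limits behave.
* **Metabolites**: baseline + Σ coeff·(producer species relative
  abundance) + N(0, 0.1); default one producer per metabolite for the
  first third of metabolites, coefficient 10.
* **Mediation chains**: x ~ N(0,1), m = a·x + ε_m, y = b·m + c′·x + ε_y
  (defaults a = 1, b = 0.5, c′ = 0, σ_m = σ_y = 1; population
  ACME = a·b). Inside a cohort, age already exists, so the chain's
  exposure log-abundance and mediator metabolite are sampled from the
  chain-implied conditional law of (x, m) given standardized age; the
  triplet's second-moment structure — which is all the linear mediation
  estimators see — then matches the chain exactly in population.
* **Hit tables**: each gene's best hit points to its true species
  (identity ≈ 97 %, coverage 75–100 %) with lower-identity decoys and
  optional injected bit-score ties (majority stays with the true
  species). **qPCR plates**: 3 replicates per target, Ct differences
  consistent with the planted T/S ratio around an inter-batch standard.

What it does **not** emulate: read-level noise, assembly artifacts,
phylogeny, realistic inter-species correlation structure,
non-Gaussian metabolite error, batch effects, or covariate-dependent
missingness. Passing recovery tests therefore demonstrates correctness of
the implementations under the stated generative assumptions, not
performance on real cohorts.

## Problem sizes and determinism

Tests and drivers run at desk scale chosen as: clustering recovery at
150 samples × 6000 genes (30 species × 200 genes); PERMANOVA exactness at
n ≤ 7 (5040 permutations) and calibration over 200 null simulations;
mediation calibration over 1000 null replicates and 100 forward/reverse
chains at n = 150; forest recovery over 50 seeds at n = 60, p = 10.
Every stochastic component takes an explicit integer seed (per-fold,
per-pair and per-covariate sub-seeds are derived additively); there is no
wall-clock seeding anywhere.

## Known limitations

* The canopy pass is O(seeds × genes × samples) dense linear algebra;
  fine to ~10⁵ genes, not engineered for the multi-million-gene scale.
* PERMANOVA recomputes tr(HG) per permutation (O(n³)); adequate for
  cohort-sized n, not for thousands of samples.
* The mediation screen assumes linear models with Gaussian errors and no
  unmeasured confounding; no sensitivity analysis is provided.
* The exact Spearman p enumerates n! permutations and is limited to n < 10.
* Enterotype PAM is exact but O(k·(n−k)²) per swap sweep.
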