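# gutage

Tested building blocks for a multi-omics aging analysis: how age-dependent
changes in the gut microbiome relate to serum metabolites — in particular
uremic solutes such as p-cresol, phenylacetylglutamine and indole
derivatives, which gut bacteria produce from aromatic amino acids and a
failing kidney no longer clears — and to renal function and age itself.
It is written for computational-biology practitioners who want each
analytic step as an importable, seedable, unit-tested function rather
than a one-off script.

The package covers:

* **Co-abundance clustering** of gene profiles into CAGs/MGSs by a
  deterministic canopy pass (capture at Pearson > 0.9 ∧ Spearman > 0.6,
  transitive merge at r ≥ 0.97, evidence filters, MGS call at > 700
  genes; MGS abundance = median of member genes).
* **Rule-based taxonomy** from best-hit tables (coverage ≥ 70 %; identity
  ≥ 95/85/65 % for species/genus/phylum; frequency → mean identity →
  lexicographic tie-breaks; MGS species rule at 90 % member agreement).
* **Ecology**: Shannon H′ = −Σ aᵢ ln aᵢ, Bray–Curtis, within-group
  β-diversity, enterotyping (√JSD + PAM + Calinski–Harabasz), and a
  PERMANOVA effect-size decomposition (R² = tr(HGH)/tr(G), permutation
  p, redundancy filter at |r| > 0.5, combined R²).
* **Forest forward selection** of species predicting a metabolite,
  scored by leave-one-out Q² = 1 − RSS/TSS, stopping when Q² stops
  increasing; "variance explained" = final Q² × 100.
* **Bidirectional mediation screening** (m ~ x; y ~ x + m + x·m;
  quasi-Bayesian ACME/ADE; a linkage microbe → metabolite → age passes
  iff p_fwd < 0.05 and the inverse run is null).
* **Clinical formulas**: four-branch CKD-EPI eGFR and the qPCR telomere
  T/S = 2^−ΔΔCt ratio.
* A **synthetic cohort generator** that plants co-abundant gene blocks,
  age-trending species, producer-driven metabolites, mediation chains and
  CKD-EPI-consistent creatinine/age/sex fields, so every downstream claim
  is testable against known truth.

See `docs/methods.md` for models, defaults and assumptions.

## Worked example

```python
from gutage import synthetic, canopy, mediation, clinical
from sklearn.metrics import adjusted_rand_score
import numpy as np

cfg = synthetic.GeneratorConfig(n_samples=120, n_species=20,
                                genes_per_species=(50, 70),
                                n_metabolites=30, seed=2024)
cohort = synthetic.generate_cohort(cfg)

# cluster genes into co-abundance groups and compare with planted species
tab = canopy.cluster_genes(cohort.gene_abundance)
truth = cohort.species_truth.loc[tab.gene_id]
print(tab.cag_id.nunique(), adjusted_rand_score(truth, tab.cag_id))

# screen one planted chain: microbe -> metabolite -> age
chain = cohort.truth["mediation"].iloc[0]
links = mediation.bidirectional_screen(
    np.log(cohort.species_abundance.loc[[chain.exposure_species]]),
    cohort.metabolites.loc[[chain.mediator_metabolite]],
    cohort.subjects.age.to_numpy(), seed=0)
print(links[["p_forward", "p_inverse", "passes"]])

print(clinical.egfr_ckd_epi(scr=0.7, age=0, sex="female"))
```

prints (seed 2024):

```
23 0.9934655626259056
   p_forward  p_inverse  passes
0   0.001998   0.539461    True
144.0
```

23 co-abundance groups recover the 20 planted species almost perfectly
(adjusted Rand index 0.9935; a couple of species split and survive as
separate groups). The planted chain is forward-significant and
inverse-null, so it passes the bidirectional filter. The eGFR call
evaluates the female CKD-EPI branch at its creatinine knot and age 0,
where both power-law factors are unity, leaving the leading coefficient
144 mL/min/1.73 m².

The `analysis/` directory walks the full study as numbered drivers
(`01_simulate_cohort.py` … `07_mediation_screen.py`), each a thin
narrative over the library that writes its tables under `results/`.

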