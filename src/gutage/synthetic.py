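"""Synthetic multi-omics cohort generator with known ground truth.

Emulates the statistical structure the downstream stages assume, so the
whole pipeline is exercisable without any external download:

* species abundances are log-normal per sample and compositional after
  renormalization; designated species have log-abundance linear in age;
* genes inherit their species' abundance times a fixed per-gene multiplier
  and multiplicative log-normal noise, then random dropout (detection
  limit), then per-sample renormalization — planted co-abundant blocks;
* metabolites are linear functions of producer-species relative abundance
  plus Gaussian noise;
* explicit mediation chains (exposure species -> mediator metabolite ->
  age) are planted by sampling exposure and mediator from the
  chain-implied conditional law given standardized age, so the triplet's
  second-moment structure matches the causal chain even though age itself
  is drawn uniform;
* serum creatinine increases with age (SCr = 0.6 + 0.004*age + noise,
  floored at 0.3) purely to exercise both sides of the sex-specific
  CKD-EPI knots.

Everything is driven by one integer seed; identical seeds give
bit-identical cohorts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import profiles

__all__ = [
    "MediationChainSpec",
    "GeneratorConfig",
    "SyntheticCohort",
    "generate_cohort",
    "generate_mediation_chain",
    "generate_hit_table",
    "generate_qpcr_plate",
    "age_groups",
    "write_cohort",
]


@dataclass
class MediationChainSpec:
    """A planted exposure -> mediator -> outcome(age) chain.

    ``a`` is the exposure->mediator slope, ``b`` the mediator->outcome
    slope, ``c_prime`` the direct exposure->outcome slope; noise SDs apply
    to the mediator and outcome equations. With the defaults the chain is
    strongly detectable in the forward direction at cohort sample sizes
    while the direct path is exactly zero, so the bidirectional screen's
    inverse analysis stays null (see docs/methods.md).
    """

    exposure_species: int = 0
    mediator_metabolite: int = 0
    a: float = 1.0
    b: float = 0.5
    c_prime: float = 0.0
    noise_m: float = 1.0
    noise_y: float = 1.0

    def population_acme(self) -> float:
        return self.a * self.b


def _default_chains() -> list[MediationChainSpec]:
    return [
        MediationChainSpec(exposure_species=0, mediator_metabolite=0),
        MediationChainSpec(exposure_species=1, mediator_metabolite=1),
    ]


@dataclass
class GeneratorConfig:
    n_samples: int = 150
    n_species: int = 30
    genes_per_species: tuple[int, int] = (150, 250)
    age_range: tuple[float, float] = (20.0, 111.0)
    n_age_linked_species: int = 6
    species_age_slopes: tuple[float, ...] = (0.02, -0.02, 0.02, -0.02, 0.02, -0.02)
    n_metabolites: int = 60
    producer_map: dict[int, dict[int, float]] | None = None
    producer_coefficient: float = 10.0
    metabolite_noise_sd: float = 0.1
    mediation_chains: list[MediationChainSpec] = field(default_factory=_default_chains)
    dropout_prob: float = 0.1
    gene_noise_sd: float = 0.2
    species_log_sd: float = 1.0
    gene_mult_sd: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 1 or self.n_species < 1 or self.n_metabolites < 1:
            raise ValueError("counts must be positive")
        lo, hi = self.genes_per_species
        if lo < 1 or hi < lo:
            raise ValueError("invalid genes_per_species range")
        if not self.age_range[0] < self.age_range[1]:
            raise ValueError("age_range min must be < max")
        if not 0 <= self.dropout_prob < 1:
            raise ValueError("dropout_prob must lie in [0, 1)")
        for sd in (self.gene_noise_sd, self.metabolite_noise_sd,
                   self.species_log_sd, self.gene_mult_sd):
            if sd < 0:
                raise ValueError("noise SDs must be >= 0")
        if len(self.species_age_slopes) < self.n_age_linked_species:
            raise ValueError("need a slope for every age-linked species")
        for c in self.mediation_chains:
            if not (0 <= c.exposure_species < self.n_species):
                raise ValueError("chain exposure species out of range")
            if not (0 <= c.mediator_metabolite < self.n_metabolites):
                raise ValueError("chain mediator metabolite out of range")

    def default_producers(self) -> dict[int, dict[int, float]]:
        """One producer species per metabolite for the first third of them."""
        if self.producer_map is not None:
            return self.producer_map
        chain_mets = {c.mediator_metabolite for c in self.mediation_chains}
        out = {}
        for j in range(self.n_metabolites // 3):
            if j in chain_mets:
                continue
            out[j] = {j % self.n_species: self.producer_coefficient}
        return out


@dataclass
class SyntheticCohort:
    gene_abundance: pd.DataFrame       # genes x samples, columns sum to 1
    species_truth: pd.Series           # gene_id -> species name
    species_abundance: pd.DataFrame    # species x samples, columns sum to 1
    metabolites: pd.DataFrame          # metabolites x samples
    subjects: pd.DataFrame             # one row per sample
    truth: dict                        # planted slopes / producers / chains
    config: GeneratorConfig


def _species_name(s: int) -> str:
    return f"Species_{s:03d}"


def _chain_conditional_moments(chain: MediationChainSpec):
    """Joint covariance of (x, m, y) under the chain, with y scaled to unit
    variance; returns the conditional mean coefficients and covariance of
    (x, m) given the standardized y."""
    a, b, cp = chain.a, chain.b, chain.c_prime
    sm2, sy2 = chain.noise_m**2, chain.noise_y**2
    vx = 1.0
    vm = a**2 + sm2
    cxm = a
    cxy = cp + a * b
    cmy = b * vm + cp * a
    vy = b**2 * vm + cp**2 + 2 * b * cp * a + sy2
    sd_y = np.sqrt(vy)
    # scale y to unit variance
    cxy /= sd_y
    cmy /= sd_y
    S_xm = np.array([[vx, cxm], [cxm, vm]])
    s_y = np.array([cxy, cmy])
    cond_cov = S_xm - np.outer(s_y, s_y)  # var(y)=1 after scaling
    return s_y, cond_cov, sd_y


def generate_cohort(config: GeneratorConfig | None = None) -> SyntheticCohort:
    """Draw a full synthetic cohort from the configured generative model."""
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed)
    n, S = config.n_samples, config.n_species

    # ------------------------------------------------------------- subjects
    lo, hi = config.age_range
    ages = rng.uniform(lo, hi, size=n)
    sexes = rng.choice(["female", "male"], size=n)
    scr = np.maximum(0.3, 0.6 + 0.004 * ages + rng.normal(0, 0.1, size=n))
    sample_ids = [f"S{i:04d}" for i in range(n)]
    subjects = pd.DataFrame(
        {"sample_id": sample_ids, "age": ages, "sex": sexes, "scr": scr,
         "urea": 4.0 + 0.03 * ages + rng.normal(0, 1.0, size=n),
         "hscrp": np.exp(rng.normal(0.3 + 0.01 * ages / 10, 0.5))}
    ).set_index("sample_id")

    age_std = (ages - ages.mean()) / ages.std()

    # ------------------------------------------------- species log-abundance
    base_mu = rng.normal(0.0, 1.5, size=S)
    log_ab = base_mu[:, None] + rng.normal(0, config.species_log_sd, size=(S, n))
    slopes = np.zeros(S)
    # age-linked species come after the chain exposures to keep roles disjoint
    chain_species = {c.exposure_species for c in config.mediation_chains}
    linked = [s for s in range(S) if s not in chain_species][: config.n_age_linked_species]
    for k, s in enumerate(linked):
        slopes[s] = config.species_age_slopes[k]
        log_ab[s] += slopes[s] * (ages - ages.mean())

    # ------------------------------------------------------ mediation chains
    chain_truth = []
    chain_latent = {}  # species index -> planted x; metabolite index -> m
    for c in config.mediation_chains:
        s_y, cond_cov, sd_y = _chain_conditional_moments(c)
        L = np.linalg.cholesky(cond_cov + 1e-12 * np.eye(2))
        eps = rng.standard_normal((2, n))
        xm = s_y[:, None] * age_std[None, :] + L @ eps
        x, m = xm[0], xm[1]
        log_ab[c.exposure_species] = base_mu[c.exposure_species] + x
        chain_latent[("species", c.exposure_species)] = x
        chain_latent[("metabolite", c.mediator_metabolite)] = m
        chain_truth.append(
            {"exposure_species": _species_name(c.exposure_species),
             "mediator_metabolite": f"MET_{c.mediator_metabolite:03d}",
             "a": c.a, "b": c.b, "c_prime": c.c_prime,
             "noise_m": c.noise_m, "noise_y": c.noise_y,
             "population_acme": c.population_acme(), "age_scale": sd_y}
        )

    species_raw = np.exp(log_ab)
    species_rel = species_raw / species_raw.sum(axis=0, keepdims=True)
    species_names = [_species_name(s) for s in range(S)]
    species_abundance = pd.DataFrame(species_rel, index=species_names,
                                     columns=sample_ids)

    # ---------------------------------------------------------------- genes
    gene_counts = rng.integers(config.genes_per_species[0],
                               config.genes_per_species[1] + 1, size=S)
    gene_rows, gene_ids, gene_species = [], [], []
    for s in range(S):
        mult = np.exp(rng.normal(0, config.gene_mult_sd, size=gene_counts[s]))
        noise = np.exp(rng.normal(0, config.gene_noise_sd,
                                  size=(gene_counts[s], n)))
        block = species_raw[s][None, :] * mult[:, None] * noise
        if config.dropout_prob > 0:
            # detection-limit dropout: zero probability decreases linearly
            # with the entry's within-gene abundance rank, so zeros land on
            # low-abundance entries (marginal zero rate = dropout_prob)
            from scipy.stats import rankdata as _rankdata
            frac = (_rankdata(block, axis=1) - 0.5) / n
            p_zero = 2.0 * config.dropout_prob * (1.0 - frac)
            keep = rng.random((gene_counts[s], n)) >= p_zero
            block = block * keep
        gene_rows.append(block)
        gene_ids.extend(f"G_{s:03d}_{g:04d}" for g in range(gene_counts[s]))
        gene_species.extend([species_names[s]] * gene_counts[s])
    genes = np.vstack(gene_rows)
    col_sums = genes.sum(axis=0)
    col_sums[col_sums == 0] = 1.0
    gene_abundance = pd.DataFrame(genes / col_sums, index=gene_ids,
                                  columns=sample_ids)
    species_truth = pd.Series(gene_species, index=gene_ids, name="species")

    # ----------------------------------------------------------- metabolites
    producers = config.default_producers()
    met = np.zeros((config.n_metabolites, n))
    prod_rows = []
    for j in range(config.n_metabolites):
        if ("metabolite", j) in chain_latent:
            met[j] = 10.0 + chain_latent[("metabolite", j)]
            continue
        met[j] = 1.0
        for s, coeff in producers.get(j, {}).items():
            met[j] = met[j] + coeff * species_rel[s]
            prod_rows.append({"metabolite": f"MET_{j:03d}",
                              "species": _species_name(s), "coefficient": coeff})
        met[j] = met[j] + rng.normal(0, config.metabolite_noise_sd, size=n)
    metabolites = pd.DataFrame(
        met, index=[f"MET_{j:03d}" for j in range(config.n_metabolites)],
        columns=sample_ids,
    )

    truth = {
        "age_slopes": pd.DataFrame(
            {"species": species_names, "slope": slopes}
        ).set_index("species"),
        "producers": pd.DataFrame(
            prod_rows, columns=["metabolite", "species", "coefficient"]
        ),
        "mediation": pd.DataFrame(chain_truth),
    }
    return SyntheticCohort(
        gene_abundance=gene_abundance, species_truth=species_truth,
        species_abundance=species_abundance, metabolites=metabolites,
        subjects=subjects, truth=truth, config=config,
    )


def generate_mediation_chain(
    n: int,
    a: float,
    b: float,
    c_prime: float,
    noise_m: float,
    noise_y: float,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Draw one (x, m, y) triplet: x ~ N(0,1), m = a*x + eps_m,
    y = b*m + c_prime*x + eps_y. Returns (data, truth)."""
    if n < 10:
        raise ValueError("n must be >= 10")
    if noise_m < 0 or noise_y < 0:
        raise ValueError("noise SDs must be >= 0")
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    m = a * x + rng.normal(0, noise_m, size=n)
    y = b * m + c_prime * x + rng.normal(0, noise_y, size=n)
    data = pd.DataFrame({"x": x, "m": m, "y": y})
    truth = {"a": a, "b": b, "c_prime": c_prime,
             "population_acme": a * b,
             "population_ade": c_prime,
             "population_total": a * b + c_prime}
    return data, truth


def _genus_name(species: str) -> str:
    # two species per genus, five genera per phylum
    s = int(species.rsplit("_", 1)[1])
    return f"Genus_{s // 2:03d}"


def _phylum_name(species: str) -> str:
    s = int(species.rsplit("_", 1)[1])
    return f"Phylum_{s // 10:02d}"


def generate_hit_table(
    species_truth: pd.Series,
    identity_noise: float = 0.0,
    coverage_range: tuple[float, float] = (75.0, 100.0),
    mean_identity: float = 97.0,
    n_decoys: int = 1,
    tie_genes: tuple[str, ...] = (),
    seed: int = 0,
) -> pd.DataFrame:
    """Best-hit alignment table for each gene against its true species.

    Each gene's top hit points to its true species with identity around
    ``mean_identity``; decoy hits to other species sit 12 identity points
    and 60 bit-score points lower. Genes listed in ``tie_genes`` get two
    extra hits at exactly the top bit score: one more to the true species
    and one to a decoy species, exercising frequency-based tie resolution
    (the true species then holds the majority among tied hits).
    """
    if len(species_truth) == 0:
        raise ValueError("species_truth must be nonempty")
    rng = np.random.default_rng(seed)
    all_species = sorted(species_truth.unique())
    rows = []
    for gene, sp in species_truth.items():
        ident = float(np.clip(mean_identity + rng.normal(0, identity_noise)
                              if identity_noise > 0 else mean_identity, 40, 100))
        cov = float(rng.uniform(*coverage_range))
        bit = float(500 + rng.uniform(0, 10))
        rows.append({"gene_id": gene, "subject_species": sp,
                     "subject_genus": _genus_name(sp),
                     "subject_phylum": _phylum_name(sp),
                     "identity": ident, "coverage": cov, "bitscore": bit})
        for _ in range(n_decoys):
            other = all_species[rng.integers(len(all_species))]
            if other == sp and len(all_species) > 1:
                other = all_species[(all_species.index(sp) + 1) % len(all_species)]
            rows.append({"gene_id": gene, "subject_species": other,
                         "subject_genus": _genus_name(other),
                         "subject_phylum": _phylum_name(other),
                         "identity": max(40.0, ident - 12.0),
                         "coverage": cov, "bitscore": bit - 60.0})
        if gene in tie_genes and len(all_species) > 1:
            decoy = all_species[(all_species.index(sp) + 1) % len(all_species)]
            rows.append({"gene_id": gene, "subject_species": sp,
                         "subject_genus": _genus_name(sp),
                         "subject_phylum": _phylum_name(sp),
                         "identity": ident, "coverage": cov, "bitscore": bit})
            rows.append({"gene_id": gene, "subject_species": decoy,
                         "subject_genus": _genus_name(decoy),
                         "subject_phylum": _phylum_name(decoy),
                         "identity": min(100.0, ident + 1.0),
                         "coverage": cov, "bitscore": bit})
    return pd.DataFrame(rows)


def generate_qpcr_plate(
    n_samples: int,
    true_ts,
    replicate_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Long-format Ct table (sample, target in {T, S}, replicate, ct) with
    3 replicates per target plus a ``standard`` sample.

    Ct differences satisfy dCt_sample = dCt_standard - log2(true_ts), so
    the recovered T/S ratio equals ``true_ts`` when ``replicate_sd`` is 0.
    """
    ts = np.broadcast_to(np.asarray(true_ts, dtype=float), (n_samples,))
    if (ts <= 0).any():
        raise ValueError("true T/S ratios must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    std_ct_s, std_ct_t = 18.0, 21.0           # standard dCt = 3.0
    for rep in range(3):
        rows.append({"sample_id": "standard", "target": "T", "replicate": rep,
                     "ct": std_ct_t + rng.normal(0, replicate_sd)})
        rows.append({"sample_id": "standard", "target": "S", "replicate": rep,
                     "ct": std_ct_s + rng.normal(0, replicate_sd)})
    for i in range(n_samples):
        base_s = rng.uniform(16, 20)
        dct = (std_ct_t - std_ct_s) - np.log2(ts[i])
        for rep in range(3):
            rows.append({"sample_id": f"S{i:04d}", "target": "S",
                         "replicate": rep,
                         "ct": base_s + rng.normal(0, replicate_sd)})
            rows.append({"sample_id": f"S{i:04d}", "target": "T",
                         "replicate": rep,
                         "ct": base_s + dct + rng.normal(0, replicate_sd)})
    return pd.DataFrame(rows)


def age_groups(ages) -> pd.Series:
    """Bin ages into the four cohort groups at 60 / 90 / 100 years."""
    ages = pd.Series(np.asarray(ages, dtype=float))
    bins = [-np.inf, 60, 90, 100, np.inf]
    labels = ["young", "elderly", "nonagenarian", "centenarian"]
    return pd.cut(ages, bins=bins, labels=labels, right=False).astype(str)


def write_cohort(cohort: SyntheticCohort, outdir) -> dict:
    """Write the cohort's TSV files plus a manifest JSON; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    profiles.write_matrix(cohort.gene_abundance, outdir / "gene_abundance.tsv")
    paths["gene_abundance"] = str(outdir / "gene_abundance.tsv")
    cohort.species_truth.rename_axis("gene_id").to_frame().to_csv(
        outdir / "species_truth.tsv", sep="\t")
    paths["species_truth"] = str(outdir / "species_truth.tsv")
    profiles.write_matrix(cohort.species_abundance, outdir / "species_abundance.tsv")
    paths["species_abundance"] = str(outdir / "species_abundance.tsv")
    profiles.write_matrix(cohort.metabolites, outdir / "metabolites.tsv")
    paths["metabolites"] = str(outdir / "metabolites.tsv")
    cohort.subjects.to_csv(outdir / "subjects.tsv", sep="\t")
    paths["subjects"] = str(outdir / "subjects.tsv")
    hits = generate_hit_table(cohort.species_truth, seed=cohort.config.seed)
    hits.to_csv(outdir / "hits.tsv", sep="\t", index=False)
    paths["hits"] = str(outdir / "hits.tsv")
    qpcr = generate_qpcr_plate(cohort.config.n_samples, 1.0,
                               replicate_sd=0.1, seed=cohort.config.seed)
    qpcr.to_csv(outdir / "qpcr.tsv", sep="\t", index=False)
    paths["qpcr"] = str(outdir / "qpcr.tsv")
    cfg = {k: v for k, v in vars(cohort.config).items()
           if k not in ("mediation_chains", "producer_map")}
    cfg["mediation_chains"] = [vars(c) for c in cohort.config.mediation_chains]
    manifest = {"config": cfg, "seed": cohort.config.seed, "files": paths}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return paths
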