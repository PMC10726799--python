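"""End-to-end orchestration of the analysis stages on one cohort.

``run_pipeline`` executes, in dependency order: simulate (or load inputs)
-> gene clustering -> cluster abundance -> taxonomy -> ecology effect
sizes -> clinical eGFR -> microbe/metabolite associations -> forest
forward selection -> mediation screen. Every stage logs a structured line
with a parameter digest and the output file hash, and a stage is skipped
on re-run when its recorded digest and input hashes are unchanged
(delete an intermediate to force recomputation downstream of it).
Seeds are explicit in the config; there is no wall-clock seeding.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assoc, canopy, clinical, ecology, mediation, models, profiles, synthetic

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("gutage.pipeline")


@dataclass
class PipelineConfig:
    outdir: str
    generator: synthetic.GeneratorConfig | None = None
    inputs: dict | None = None  # paths: gene_abundance, subjects, metabolites
    canopy_params: canopy.CanopyParams = field(default_factory=canopy.CanopyParams)
    n_perm: int = 199
    n_sims: int = 200
    rf_trees: int = 100
    rf_target: str | None = None     # metabolite to model; default: first
    seed: int = 0

    def __post_init__(self):
        if (self.generator is None) == (self.inputs is None):
            raise ValueError("exactly one of generator config or input paths required")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        gen = raw.pop("generator", None)
        if gen is not None:
            chains = [synthetic.MediationChainSpec(**c)
                      for c in gen.pop("mediation_chains", [])]
            gen = synthetic.GeneratorConfig(**gen, mediation_chains=chains) \
                if chains else synthetic.GeneratorConfig(**gen)
        cp = raw.pop("canopy_params", None)
        cfg = cls(generator=gen, **raw)
        if cp:
            cfg.canopy_params = canopy.CanopyParams(**cp)
        return cfg


def _digest(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


class _Manifest:
    def __init__(self, path: Path):
        self.path = path
        self.data = json.loads(path.read_text()) if path.exists() else {}

    def fresh(self, stage: str, digest: str, outputs: list[Path]) -> bool:
        rec = self.data.get(stage)
        if rec is None or rec["digest"] != digest:
            return False
        for p in outputs:
            if not p.exists() or _file_hash(p) != rec["outputs"].get(p.name):
                return False
        return True

    def record(self, stage: str, digest: str, outputs: list[Path]) -> None:
        self.data[stage] = {
            "digest": digest,
            "outputs": {p.name: _file_hash(p) for p in outputs},
        }
        self.path.write_text(json.dumps(self.data, indent=2))
        hashes = ",".join(f"{p.name}:{self.data[stage]['outputs'][p.name]}"
                          for p in outputs)
        log.info("stage=%s digest=%s outputs=%s", stage, digest, hashes)


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage; returns the run directory."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out / "run_manifest.json")

    # ------------------------------------------------------------- stage: data
    stage = "data"
    data_files = [out / n for n in
                  ("gene_abundance.tsv", "subjects.tsv", "metabolites.tsv")]
    if config.generator is not None:
        digest = _digest(["simulate", vars(config.generator) | {
            "mediation_chains": [vars(c) for c in config.generator.mediation_chains]}])
        if not manifest.fresh(stage, digest, data_files):
            synthetic.write_cohort(synthetic.generate_cohort(config.generator), out)
            manifest.record(stage, digest, data_files)
    else:
        digest = _digest(["load", {k: _file_hash(Path(v))
                                   for k, v in sorted(config.inputs.items())}])
        if not manifest.fresh(stage, digest, data_files):
            for key, name in (("gene_abundance", "gene_abundance.tsv"),
                              ("subjects", "subjects.tsv"),
                              ("metabolites", "metabolites.tsv")):
                if key not in config.inputs:
                    raise ValueError(f"stage data: missing input {key!r}")
                (out / name).write_bytes(Path(config.inputs[key]).read_bytes())
            manifest.record(stage, digest, data_files)

    genes = profiles.read_matrix(out / "gene_abundance.tsv")
    subjects = pd.read_csv(out / "subjects.tsv", sep="\t", index_col=0)
    metabolites = profiles.read_matrix(out / "metabolites.tsv")
    if list(metabolites.columns) != list(subjects.index):
        raise ValueError("stage data: metabolite samples do not match subjects")

    # -------------------------------------------------------- stage: cluster
    stage = "cluster"
    cags_path = out / "cags.tsv"
    digest = _digest(["cluster", vars(config.canopy_params),
                      _file_hash(out / "gene_abundance.tsv")])
    if not manifest.fresh(stage, digest, [cags_path]):
        cags = canopy.cluster_genes(genes, config.canopy_params)
        cags.to_csv(cags_path, sep="\t", index=False)
        manifest.record(stage, digest, [cags_path])
    cags = pd.read_csv(cags_path, sep="\t")

    # -------------------------------------------------- stage: mgs abundance
    stage = "abundance"
    mgs_path = out / "cluster_abundance.tsv"
    digest = _digest(["abundance", _file_hash(cags_path),
                      _file_hash(out / "gene_abundance.tsv")])
    if not manifest.fresh(stage, digest, [mgs_path]):
        if len(cags) == 0:
            raise ValueError("stage abundance: no clusters produced upstream")
        ab = profiles.mgs_abundance(genes, cags[["gene_id", "cag_id"]])
        profiles.write_matrix(ab, mgs_path)
        manifest.record(stage, digest, [mgs_path])
    cluster_ab = profiles.read_matrix(mgs_path)

    # -------------------------------------------------------- stage: ecology
    stage = "ecology"
    eff_path = out / "effects.tsv"
    covars = subjects[[c for c in ("age", "sex", "scr", "urea", "hscrp")
                       if c in subjects.columns]]
    digest = _digest(["ecology", config.n_perm, config.seed,
                      _file_hash(mgs_path), _file_hash(out / "subjects.tsv")])
    if not manifest.fresh(stage, digest, [eff_path]):
        dist = ecology.bray_curtis(cluster_ab)
        eff = ecology.effect_size_decomposition(
            dist, covars, n_perm=config.n_perm, seed=config.seed)
        eff.to_csv(eff_path, sep="\t", index=False)
        manifest.record(stage, digest, [eff_path])

    # ------------------------------------------------------- stage: clinical
    stage = "clinical"
    egfr_path = out / "egfr.tsv"
    digest = _digest(["clinical", _file_hash(out / "subjects.tsv")])
    if not manifest.fresh(stage, digest, [egfr_path]):
        clinical.egfr_table(subjects).to_frame().to_csv(egfr_path, sep="\t")
        manifest.record(stage, digest, [egfr_path])

    # ----------------------------------------------------------- stage: assoc
    stage = "assoc"
    assoc_path = out / "assoc.tsv"
    digest = _digest(["assoc", _file_hash(mgs_path),
                      _file_hash(out / "metabolites.tsv")])
    if not manifest.fresh(stage, digest, [assoc_path]):
        rows = []
        agev = subjects["age"].to_numpy(dtype=float)
        for ci in cluster_ab.index:
            for mj in metabolites.index:
                rho, p = assoc.partial_spearman(
                    cluster_ab.loc[ci], metabolites.loc[mj], [agev])
                rows.append({"feature_a": ci, "feature_b": mj,
                             "rho": rho, "p": p, "adjusted_for": "age"})
        tab = pd.DataFrame(rows)
        tab["q"] = assoc.bh_fdr(tab["p"].clip(lower=1e-300))
        tab.to_csv(assoc_path, sep="\t", index=False)
        manifest.record(stage, digest, [assoc_path])

    # -------------------------------------------------------- stage: rfselect
    stage = "rfselect"
    sel_path = out / "selection.json"
    target = config.rf_target or metabolites.index[0]
    digest = _digest(["rfselect", target, config.rf_trees, config.seed,
                      _file_hash(mgs_path), _file_hash(out / "metabolites.tsv")])
    if not manifest.fresh(stage, digest, [sel_path]):
        res = models.forward_select_rf(
            cluster_ab.T, metabolites.loc[target].to_numpy(dtype=float),
            n_trees=config.rf_trees, seed=config.seed)
        sel_path.write_text(json.dumps({
            "target": str(target), "selected": list(res.selected),
            "q2_trajectory": res.q2_trajectory, "final_q2": res.final_q2,
            "variance_explained_pct": res.variance_explained_pct,
            "importances": res.importances.to_dict(),
        }, indent=2))
        manifest.record(stage, digest, [sel_path])

    # ------------------------------------------------------- stage: mediation
    stage = "mediation"
    link_path = out / "linkages.tsv"
    digest = _digest(["mediation", config.n_sims, config.seed,
                      _file_hash(mgs_path), _file_hash(out / "metabolites.tsv"),
                      _file_hash(out / "subjects.tsv")])
    if not manifest.fresh(stage, digest, [link_path]):
        links = mediation.bidirectional_screen(
            np.log(cluster_ab.replace(0, np.nan)).fillna(
                np.log(cluster_ab[cluster_ab > 0].min().min())),
            metabolites, subjects["age"].to_numpy(dtype=float),
            n_sims=config.n_sims, seed=config.seed)
        links.to_csv(link_path, sep="\t", index=False)
        manifest.record(stage, digest, [link_path])

    return out
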