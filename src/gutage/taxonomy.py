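"""Rule-based taxonomy for genes (from best alignment hits) and for MGSs.

Gene assignment: hits below 70% query coverage are discarded; the best hit
is the one with the maximal bit score; the assigned rank follows the
best-hit percent identity with inclusive thresholds: >=95 species,
>=85 genus, >=65 phylum, else unassigned. When several hits tie on the
maximal bit score across different species, the tie is resolved by species
frequency among tied hits, then mean identity, then lexicographic order.

MGS assignment: species if >=90% of member genes hit one species at >=95%
identity and >=70% coverage; otherwise genus if >=80% of member genes hit
one genus at >=85% identity (and >=70% coverage); otherwise unclassified.
Membership fractions are computed over all member genes, including
unannotated ones (conservative).

Hit tables are BLAST outfmt-6-like TSVs with named taxon columns:
(gene_id, subject_species, subject_genus, subject_phylum, identity,
coverage, bitscore).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TaxonomyThresholds",
    "assign_gene_taxonomy",
    "resolve_best_hit_ties",
    "assign_mgs_taxonomy",
]

HIT_COLUMNS = [
    "gene_id", "subject_species", "subject_genus", "subject_phylum",
    "identity", "coverage", "bitscore",
]


@dataclass
class TaxonomyThresholds:
    min_coverage: float = 70.0
    species_identity: float = 95.0
    genus_identity: float = 85.0
    phylum_identity: float = 65.0
    mgs_species_frac: float = 0.90
    mgs_genus_frac: float = 0.80


def _validate_hits(hits: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in HIT_COLUMNS if c not in hits.columns]
    if missing:
        raise ValueError(f"hit table missing columns: {missing}")
    bad = hits[(hits.identity < 0) | (hits.identity > 100)
               | (hits.coverage < 0) | (hits.coverage > 100)
               | (hits.bitscore < 0)]
    if len(bad):
        raise ValueError("identity/coverage must lie in [0, 100], bitscore >= 0")
    return hits


def resolve_best_hit_ties(tied_hits: pd.DataFrame) -> str:
    """Pick a species among hits tied on the maximal bit score.

    Precedence: highest frequency, then highest mean identity, then
    lexicographic species name.
    """
    if len(tied_hits) == 0:
        raise ValueError("no tied hits to resolve")
    grp = tied_hits.groupby("subject_species")["identity"].agg(["size", "mean"])
    grp = grp.sort_values(["size", "mean"], ascending=[False, False])
    best_size, best_mean = grp.iloc[0]
    winners = grp[(grp["size"] == best_size) & (grp["mean"] == best_mean)]
    return sorted(winners.index)[0]


def _rank_for_identity(identity: float, thr: TaxonomyThresholds) -> str:
    if identity >= thr.species_identity:
        return "species"
    if identity >= thr.genus_identity:
        return "genus"
    if identity >= thr.phylum_identity:
        return "phylum"
    return "unassigned"


def assign_gene_taxonomy(
    hits: pd.DataFrame,
    thresholds: TaxonomyThresholds | None = None,
) -> pd.DataFrame:
    """Per-gene taxonomic annotation from an alignment hit table.

    Returns one row per gene: (gene_id, assigned_rank, taxon, best_identity).
    Genes with no hit surviving the coverage filter are unassigned.
    """
    thr = thresholds or TaxonomyThresholds()
    hits = _validate_hits(hits)
    surviving = hits[hits.coverage >= thr.min_coverage]
    rows = []
    for gene in pd.unique(hits.gene_id):
        sub = surviving[surviving.gene_id == gene]
        if len(sub) == 0:
            rows.append({"gene_id": gene, "assigned_rank": "unassigned",
                         "taxon": None, "best_identity": np.nan})
            continue
        top = sub[sub.bitscore == sub.bitscore.max()]
        if top.subject_species.nunique() > 1:
            species = resolve_best_hit_ties(top)
            best = top[top.subject_species == species].sort_values(
                "identity", ascending=False).iloc[0]
        else:
            best = top.sort_values("identity", ascending=False).iloc[0]
        rank = _rank_for_identity(best.identity, thr)
        taxon = {"species": best.subject_species, "genus": best.subject_genus,
                 "phylum": best.subject_phylum}.get(rank)
        rows.append({"gene_id": gene, "assigned_rank": rank, "taxon": taxon,
                     "best_identity": float(best.identity)})
    return pd.DataFrame(rows, columns=["gene_id", "assigned_rank", "taxon",
                                       "best_identity"])


def assign_mgs_taxonomy(
    mgs_members: list[str],
    gene_hits: pd.DataFrame,
    thresholds: TaxonomyThresholds | None = None,
) -> tuple[str | None, str]:
    """Taxon and rank for one MGS from its member genes' hits.

    Returns ``(taxon, rank)`` with rank in {"species", "genus",
    "unclassified"}.
    """
    thr = thresholds or TaxonomyThresholds()
    if len(mgs_members) == 0:
        raise ValueError("MGS has no member genes")
    gene_hits = _validate_hits(gene_hits)
    sub = gene_hits[gene_hits.gene_id.isin(mgs_members)
                    & (gene_hits.coverage >= thr.min_coverage)]
    n = len(mgs_members)

    sp = sub[sub.identity >= thr.species_identity]
    if len(sp):
        counts = sp.groupby("subject_species")["gene_id"].nunique()
        counts = counts.sort_values(ascending=False)
        if counts.iloc[0] / n >= thr.mgs_species_frac:
            tied = counts[counts == counts.iloc[0]]
            if len(tied) == 1:
                return str(counts.index[0]), "species"

    gn = sub[sub.identity >= thr.genus_identity]
    if len(gn):
        counts = gn.groupby("subject_genus")["gene_id"].nunique()
        counts = counts.sort_values(ascending=False)
        if counts.iloc[0] / n >= thr.mgs_genus_frac:
            tied = counts[counts == counts.iloc[0]]
            if len(tied) == 1:
                return str(counts.index[0]), "genus"
    return None, "unclassified"
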