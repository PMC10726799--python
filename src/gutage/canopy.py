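"""Canopy-based co-abundance clustering of gene profiles into CAGs/MGSs.

Genes whose abundance profiles co-vary across samples are grouped by a
deterministic greedy canopy pass: seeds are taken in descending order of
total abundance (ties broken by gene id); a gene joins the seed's canopy
iff its profile has Pearson r > ``capture_pearson`` AND Spearman rho >
``capture_spearman`` against the canopy profile. After capture the canopy
profile is recentered to the member median and membership is re-captured
for ``recenter_iters`` rounds. Clustered genes leave the seed pool, so
canopies never overlap.

Canopies whose median profiles correlate at Pearson >= ``merge_pearson``
are merged transitively (union-find). Canopies are then filtered on
supporting evidence and the survivors are CAGs; CAGs with more than 700
member genes are MGSs.

Zero-variance profiles have undefined correlation and are treated as
non-capturable (and skipped as seeds).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "CanopyParams",
    "Canopy",
    "build_canopies",
    "merge_canopies",
    "filter_canopies",
    "call_mgs",
    "cluster_genes",
]


@dataclass
class CanopyParams:
    capture_pearson: float = 0.9
    capture_spearman: float = 0.6
    merge_pearson: float = 0.97
    min_genes_cag: int = 3           # canopies with fewer members are discarded
    mgs_min_genes: int = 701         # "more than 700 genes"
    top3_signal_frac: float = 0.9
    min_detected_samples: int = 4
    single_sample_frac: float = 0.9
    recenter_iters: int = 1

    def __post_init__(self):
        for name in ("capture_pearson", "capture_spearman", "merge_pearson"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")
        for name in ("min_genes_cag", "mgs_min_genes", "min_detected_samples"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.recenter_iters < 0:
            raise ValueError("recenter_iters must be >= 0")


@dataclass
class Canopy:
    seed_gene: str
    members: list = field(default_factory=list)
    median_profile: np.ndarray | None = None
    is_mgs: bool = False

    def __len__(self):
        return len(self.members)


def _standardize_rows(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center/scale rows to unit norm; returns (Z, zero_variance_mask)."""
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.sqrt((Xc * Xc).sum(axis=1))
    zero = norms == 0
    safe = np.where(zero, 1.0, norms)
    return Xc / safe[:, None], zero


def _standardize_vector(v: np.ndarray) -> np.ndarray | None:
    vc = v - v.mean()
    norm = np.sqrt(vc @ vc)
    if norm == 0:
        return None
    return vc / norm


def build_canopies(genes: pd.DataFrame, params: CanopyParams | None = None) -> list[Canopy]:
    """Greedy non-overlapping canopy capture over gene profiles."""
    params = params or CanopyParams()
    n_samples = genes.shape[1]
    if n_samples < 4:
        raise ValueError("need at least 4 samples for correlation clustering")
    ids = np.asarray(genes.index.astype(str))
    X = genes.to_numpy(dtype=float)

    Z, zero_var = _standardize_rows(X)                     # Pearson space
    R, _ = _standardize_rows(rankdata(X, axis=1))          # Spearman space

    totals = X.sum(axis=1)
    order = np.lexsort((ids, -totals))  # descending abundance, then gene id
    unclustered = np.ones(len(ids), dtype=bool)
    canopies: list[Canopy] = []

    for si in order:
        if not unclustered[si] or zero_var[si]:
            continue
        profile = X[si]
        members = np.array([si])
        for _ in range(params.recenter_iters + 1):
            zp = _standardize_vector(profile)
            rp = _standardize_vector(rankdata(profile))
            if zp is None or rp is None:
                members = np.array([si])
                break
            cand = np.flatnonzero(unclustered & ~zero_var)
            rpear = Z[cand] @ zp
            rspear = R[cand] @ rp
            hit = cand[(rpear > params.capture_pearson) & (rspear > params.capture_spearman)]
            members = np.union1d(hit, [si])  # seed always stays a member
            profile = np.median(X[members], axis=0)
        unclustered[members] = False
        canopies.append(
            Canopy(seed_gene=ids[si], members=[ids[m] for m in members],
                   median_profile=np.median(X[members], axis=0))
        )
    return canopies


class _UnionFind:
    def __init__(self, n):
        self.parent = list(range(n))

    def find(self, i):
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i, j):
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def merge_canopies(
    canopies: list[Canopy],
    genes: pd.DataFrame | None = None,
    params: CanopyParams | None = None,
) -> list[Canopy]:
    """Merge canopies whose median profiles have Pearson >= merge threshold.

    Merging is transitive (union-find closure), hence order-independent.
    Merged medians are recomputed from member genes when the gene matrix is
    supplied, else elementwise from the component medians.
    """
    params = params or CanopyParams()
    if not canopies:
        return []
    M = np.vstack([c.median_profile for c in canopies])
    Z, zero = _standardize_rows(M)
    corr = Z @ Z.T
    uf = _UnionFind(len(canopies))
    n = len(canopies)
    for i in range(n):
        for j in range(i + 1, n):
            if not zero[i] and not zero[j] and corr[i, j] >= params.merge_pearson:
                uf.union(i, j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(uf.find(i), []).append(i)

    merged: list[Canopy] = []
    for root in sorted(groups):
        idxs = groups[root]
        members: list[str] = []
        for i in idxs:
            members.extend(canopies[i].members)
        if genes is not None:
            profile = np.median(genes.loc[members].to_numpy(dtype=float), axis=0)
        else:
            profile = np.median(M[idxs], axis=0)
        merged.append(
            Canopy(seed_gene=canopies[idxs[0]].seed_gene, members=members,
                   median_profile=profile)
        )
    return merged


def filter_canopies(
    canopies: list[Canopy],
    genes: pd.DataFrame,
    params: CanopyParams | None = None,
) -> list[Canopy]:
    """Discard canopies with insufficient supporting evidence; keep CAGs.

    A canopy is discarded if it has fewer than ``min_genes_cag`` members
    (i.e. 2 or fewer at the default), if its three strongest samples hold
    >= ``top3_signal_frac`` of the summed member signal, if its median
    profile is detected (nonzero) in fewer than ``min_detected_samples``
    samples, or if a single sample holds >= ``single_sample_frac`` of the
    summed signal.
    """
    params = params or CanopyParams()
    cags = []
    for c in canopies:
        if len(c) < params.min_genes_cag:
            continue
        signal = genes.loc[c.members].to_numpy(dtype=float).sum(axis=0)
        total = signal.sum()
        if total <= 0:
            continue
        top3 = np.sort(signal)[-3:].sum()
        if top3 / total >= params.top3_signal_frac:
            continue
        if int((c.median_profile > 0).sum()) < params.min_detected_samples:
            continue
        if signal.max() / total >= params.single_sample_frac:
            continue
        cags.append(c)
    return cags


def call_mgs(cags: list[Canopy], params: CanopyParams | None = None) -> list[Canopy]:
    """Flag CAGs with more than 700 member genes as metagenomic species."""
    params = params or CanopyParams()
    mgss = []
    for c in cags:
        c.is_mgs = len(c) >= params.mgs_min_genes
        if c.is_mgs:
            mgss.append(c)
    return mgss


def cluster_genes(genes: pd.DataFrame, params: CanopyParams | None = None) -> pd.DataFrame:
    """Full build -> merge -> filter -> MGS pass.

    Returns a tidy table with one row per clustered gene:
    (gene_id, cag_id, is_mgs, seed_gene).
    """
    params = params or CanopyParams()
    canopies = build_canopies(genes, params)
    merged = merge_canopies(canopies, genes, params)
    cags = filter_canopies(merged, genes, params)
    call_mgs(cags, params)
    rows = []
    for i, c in enumerate(cags):
        for g in c.members:
            rows.append({"gene_id": g, "cag_id": f"CAG{i:04d}",
                         "is_mgs": c.is_mgs, "seed_gene": c.seed_gene})
    return pd.DataFrame(rows, columns=["gene_id", "cag_id", "is_mgs", "seed_gene"])
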