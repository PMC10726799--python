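#!/usr/bin/env python
"""Annotate genes and clusters taxonomically from the best-hit table.

Gene ranks follow the identity cutoffs (>=95% species, >=85% genus,
>=65% phylum, coverage >= 70%); each cluster from step 02 is then assigned
a species if >=90% of its member genes agree at >=95% identity, falling
back to genus at >=80% / >=85%. Writes results/taxonomy_genes.tsv and
results/taxonomy_clusters.tsv and reports agreement with the planted
species labels.
"""

from pathlib import Path

import pandas as pd

from gutage import taxonomy

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    hits = pd.read_csv(ROOT / "cohort" / "hits.tsv", sep="\t")
    truth = pd.read_csv(ROOT / "cohort" / "species_truth.tsv", sep="\t",
                        index_col=0)["species"]
    cags = pd.read_csv(ROOT / "cags.tsv", sep="\t")

    genes = taxonomy.assign_gene_taxonomy(hits)
    genes.to_csv(ROOT / "taxonomy_genes.tsv", sep="\t", index=False)
    sp = genes[genes.assigned_rank == "species"].set_index("gene_id")
    correct = (sp.taxon == truth.loc[sp.index]).mean()
    print(f"gene annotations: {len(sp)}/{len(genes)} at species rank, "
          f"{100 * correct:.1f}% matching the planted species")

    rows = []
    for cag_id, members in cags.groupby("cag_id").gene_id:
        taxon, rank = taxonomy.assign_mgs_taxonomy(list(members), hits)
        rows.append({"cag_id": cag_id, "taxon": taxon, "rank": rank,
                     "n_genes": len(members)})
    out = pd.DataFrame(rows)
    out.to_csv(ROOT / "taxonomy_clusters.tsv", sep="\t", index=False)
    print(f"cluster annotations: {(out['rank'] == 'species').sum()} species, "
          f"{(out['rank'] == 'genus').sum()} genus, "
          f"{(out['rank'] == 'unclassified').sum()} unclassified")


if __name__ == "__main__":
    main()
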