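#!/usr/bin/env python
"""Do microbes influence aging through serum metabolites?

Runs the bidirectional mediation screen over all (species, metabolite)
pairs: Spearman prefilter (p < 0.05), forward run
microbe -> metabolite -> age and inverse run with exposure and mediator
swapped; a linkage passes iff p_forward < 0.05 and p_inverse > 0.05.
Species abundances enter on the log scale. Writes results/linkages.tsv
and reports whether the planted chains are among the flagged linkages.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from gutage import mediation, profiles

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    species = profiles.read_matrix(ROOT / "cohort" / "species_abundance.tsv")
    mets = profiles.read_matrix(ROOT / "cohort" / "metabolites.tsv")
    subjects = pd.read_csv(ROOT / "cohort" / "subjects.tsv", sep="\t",
                           index_col=0)
    chains = pd.read_csv(ROOT / "cohort" / "truth_mediation.tsv", sep="\t")

    floor = species[species > 0].min().min()
    logsp = np.log(species.where(species > 0, floor))
    links = mediation.bidirectional_screen(
        logsp, mets, subjects.age.to_numpy(), n_sims=1000, seed=0)
    links.to_csv(ROOT / "linkages.tsv", sep="\t", index=False)

    flagged = links[links.passes]
    print(f"{len(links)} pairs passed the Spearman prefilter, "
          f"{len(flagged)} linkages passed the bidirectional filter")
    planted = set(zip(chains.exposure_species, chains.mediator_metabolite))
    found = set(zip(flagged.microbe, flagged.metabolite))
    print(f"planted chains recovered: {len(planted & found)}/{len(planted)}")
    for mi, mj in sorted(planted):
        row = links[(links.microbe == mi) & (links.metabolite == mj)]
        if len(row):
            r = row.iloc[0]
            print(f"  {mi} -> {mj} -> age: p_fwd={r.p_forward:.3f} "
                  f"p_inv={r.p_inverse:.3f} passes={bool(r.passes)}")


if __name__ == "__main__":
    main()
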