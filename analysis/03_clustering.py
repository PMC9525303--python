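#!/usr/bin/env python
"""Hierarchical Bayesian clustering of the aligned sequences.

Reads results/data/alignment.fasta; writes per-sequence cluster labels
(two nested levels) to results/clusters.csv.
"""

import sys

import pandas as pd

from phylogeo.io import load_alignment
from phylogeo.popclust import locus_matrix, search_partition

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1


def main() -> None:
    aln = load_alignment("results/data/alignment.fasta")
    mat, ids = locus_matrix(aln)
    part = search_partition(mat, ids=ids, k_max=10, levels=2, n_runs=3, seed=SEED)
    pd.DataFrame(
        {"id": part.ids,
         "level1": [part.level1[i] for i in part.ids],
         "level2": [part.level2[i] for i in part.ids]}
    ).to_csv("results/clusters.csv", index=False)
    print(f"{mat.shape[1]} variable loci; K = {part.k[1]} clusters at level 1, "
          f"{part.k[2]} at level 2 (log marginal {part.log_marginal[1]:.2f} / "
          f"{part.log_marginal[2]:.2f}; best level {part.best_level})")


if __name__ == "__main__":
    main()
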