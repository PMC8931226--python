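#!/usr/bin/env python
"""Topological discordance between a gene tree and its species tree.

A biosynthesis gene spread by horizontal transfer yields a gene tree
that disagrees with the species tree almost as much as a random tree
does, while vertically inherited conserved genes stay close. Emulated
here with a 32-leaf species tree, a gene tree scrambled by 20
subtree-prune-regraft moves, five conserved trees perturbed by 1 move
each, and a 100-tree random baseline, using the mutual-clustering-
information distance.
"""

import sys
from pathlib import Path

import numpy as np

from phoscycle import io, synthio, treedist

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"

SEED = 47
N_LEAVES = 32


def main() -> None:
    leaves = [f"t{i:02d}" for i in range(N_LEAVES)]
    sp = synthio.random_tree_newick(leaves, seed=SEED)
    gene = synthio.spr_perturb(sp, 20, seed=SEED + 1)
    conserved = [synthio.spr_perturb(sp, 1, seed=SEED + 2 + k) for k in range(5)]

    rep = treedist.hgt_report(sp, gene, conserved, n_random=100, seed=SEED + 10)

    RESULTS.mkdir(exist_ok=True)
    io.write_json(rep, RESULTS / "06_tree_discordance.json")
    print(f"gene-tree distance to species tree:     {rep['gene_distance']:.3f}")
    print(f"median conserved-gene distance:          {rep['median_conserved']:.3f}")
    print(f"gene / conserved ratio:                  {rep['gene_to_conserved_ratio']:.2f}")
    print(f"random-tree baseline:                    "
          f"{rep['random_mean']:.3f} +- {rep['random_sd']:.3f}")
    print(
        "\nThe scrambled gene tree sits several times beyond the conserved "
        "trees and within the random baseline's reach - the transfer "
        "signature."
    )


if __name__ == "__main__":
    sys.exit(main())
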