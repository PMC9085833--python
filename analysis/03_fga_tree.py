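#!/usr/bin/env python
"""Stage 3 — functional genomic alignment tree of the connectome.

Takes the same synthetic matrix as stage 2 (same seed), symmetrizes the two
distance directions by their mean, and clusters the 168 connectome genes with
neighbour joining. The tree is a functional grouping, not a phylogeny. As a
summary of how the novel candidates sit among the known genes, the script
reports for each candidate leaf the class of its nearest leaf by path length:
a high known-neighbour fraction means candidates interleave with known genes
rather than forming their own clade.

Writes results/03_tree.nwk and results/03_leaf_classes.tsv.
"""

import argparse
import json
from pathlib import Path

from batconnectome.distances import partition_connectome
from batconnectome.fga import nj_tree, symmetrize, write_leaf_annotations, write_newick
from batconnectome.synthetic import (
    bundled_gene_lists,
    published_connectome_spec,
    simulate_distance_matrix,
)

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    known_list, candidates, _ = bundled_gene_lists()
    connectome = set(known_list) | set(candidates)
    part = partition_connectome(connectome, known_list, "UCP1")
    dm, _ = simulate_distance_matrix(published_connectome_spec(n_genes=2000, seed=args.seed))

    tree = nj_tree(symmetrize(dm), sorted(connectome))
    n_leaves = sum(1 for _ in tree.tips())
    internal = sum(1 for _ in tree.non_tips(include_self=True))
    print(f"tree: {n_leaves} leaves ({len(part.known)} known, "
          f"{len(part.candidates)} candidates, core UCP1), {internal} internal nodes")

    tt = tree.tip_tip_distances()
    ids = list(tt.ids)
    known_neighbour = 0
    for cand in sorted(part.candidates):
        others = [(float(tt[cand, g]), g) for g in ids if g != cand]
        nearest = min(others)[1]
        known_neighbour += nearest in part.known or nearest == "UCP1"
    frac = known_neighbour / len(part.candidates)
    expected = (len(part.known) + 1) / (n_leaves - 1)
    print(f"{known_neighbour}/{len(part.candidates)} candidates "
          f"({frac:.0%}) have a known gene (or UCP1) as nearest leaf, vs "
          f"{expected:.0%} expected under even mixing - candidates "
          "interleave with known genes rather than forming their own clade")

    RESULTS.mkdir(exist_ok=True)
    write_newick(tree, RESULTS / "03_tree.nwk")
    write_leaf_annotations(part, RESULTS / "03_leaf_classes.tsv")
    (RESULTS / "03_tree_summary.json").write_text(
        json.dumps(
            {"n_leaves": n_leaves, "internal_nodes": internal,
             "candidate_known_neighbour_frac": frac, "seed": args.seed},
            indent=2,
        ) + "\n"
    )


if __name__ == "__main__":
    main()
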