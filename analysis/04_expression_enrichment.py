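#!/usr/bin/env python
"""Stage 4 — top-percentile expression enrichment.

Two parts:

(a) Synthetic end-to-end run: two biopsy-like studies over the same 2000-gene
    universe as stages 2-3, with the 167 connectome genes planted high in
    expression. Probes are collapsed to per-gene medians, each study's top set
    is everything strictly above its 95th percentile, and the enrichment test
    asks whether the connectome (and the candidate/known subsets) hits the
    union of top sets more than size-matched random gene sets do. The planted
    signal uses the generator default (+6 log-units), so enrichment is
    essentially total - far stronger than any real tissue contrast.

(b) The one expression number the published tables pin down exactly: the
    candidate genes flagged as above the 95th percentile in either biopsy
    study. Building top sets whose union is the flagged genes reproduces the
    flag tally via the same union-membership counter.

Writes results/04_expression.json.
"""

import argparse
import json
from pathlib import Path

from batconnectome.distances import partition_connectome
from batconnectome.expression import (
    TopSets,
    build_top_sets,
    collapse_probes,
    expression_enrichment_test,
    union_membership_count,
)
from batconnectome.synthetic import (
    ExpressionSimSpec,
    bundled_gene_lists,
    published_connectome_spec,
    simulate_expression_study,
)

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-perm", type=int, default=10_000)
    args = ap.parse_args()

    known_list, candidates, flags = bundled_gene_lists()
    connectome = set(known_list) | set(candidates)
    part = partition_connectome(connectome, known_list, "UCP1")
    spec = published_connectome_spec(n_genes=2000, seed=args.seed)
    names = spec.names

    studies = []
    for k in range(2):
        study, _ = simulate_expression_study(
            ExpressionSimSpec(
                n_genes=len(names), gene_names=names, n_probes=2400, n_samples=6,
                planted_genes=tuple(sorted(connectome - {"UCP1"})),
                seed=args.seed + 10 * (k + 1), study_id=f"biopsy_like_{k + 1}",
            )
        )
        studies.append(study)
    tops = build_top_sets([collapse_probes(s) for s in studies], 95.0)

    results = {}
    for name, query in [
        ("connectome", connectome - {"UCP1"}),
        ("known", set(part.known)),
        ("candidates", set(part.candidates)),
    ]:
        res = expression_enrichment_test(query, tops, args.n_perm, seed=args.seed + 99)
        results[name] = res.to_dict()
        print(f"{name}: {int(res.observed)}/{res.set_sizes['query']} genes in the "
              f"top-expression union; {res.p_report}")

    flagged = frozenset(g for g, f in flags.items() if f == 1)
    flag_tops = TopSets(
        95.0, {"biopsy_flags": flagged}, frozenset(candidates) | flagged
    )
    flag_count = union_membership_count(flag_tops, candidates)
    print(f"published biopsy flags: {flag_count}/{len(candidates)} candidates above "
          "the 95th percentile in either biopsy study")

    RESULTS.mkdir(exist_ok=True)
    (RESULTS / "04_expression.json").write_text(
        json.dumps(
            {"synthetic_enrichment": results,
             "published_flagged_candidates": flag_count,
             "seed": args.seed},
            indent=2,
        ) + "\n"
    )


if __name__ == "__main__":
    main()
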