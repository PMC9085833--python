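"""Generators: determinism, planted structure, and the bundled gene lists."""

import numpy as np
import pandas as pd
import pytest

from batconnectome.distances import pair_distances
from batconnectome.errors import InputError
from batconnectome.expression import collapse_probes, top_expression_set
from batconnectome.synthetic import (
    DistanceSimSpec,
    ExpressionSimSpec,
    bundled_gene_lists,
    null_distance_spec,
    random_additive_tree,
    simulate_core_ranking,
    simulate_distance_matrix,
    simulate_expression_study,
)


class TestDistanceGenerator:
    def test_seed_determinism(self):
        spec = DistanceSimSpec(n_genes=100, module_size=10, seed=5)
        a, truth_a = simulate_distance_matrix(spec)
        b, truth_b = simulate_distance_matrix(spec)
        assert np.array_equal(a.values, b.values)
        assert truth_a == truth_b
        c, _ = simulate_distance_matrix(DistanceSimSpec(n_genes=100, module_size=10, seed=6))
        assert not np.array_equal(a.values, c.values)

    @pytest.mark.parametrize("seed", range(20))
    def test_planted_module_median_below_background(self, seed):
        spec = DistanceSimSpec(n_genes=300, module_size=20, seed=seed)
        dm, module = simulate_distance_matrix(spec)
        within = pair_distances(dm, sorted(module), sorted(module), "ordered_within")
        background = sorted(set(dm.genes) - module - {spec.core})
        cross = pair_distances(dm, sorted(module), background, "cross")
        assert np.median(within) < np.median(cross)

    def test_null_spec_has_no_planted_structure(self):
        spec = null_distance_spec(n_genes=300, module_size=20, seed=1)
        dm, module = simulate_distance_matrix(spec)
        within = pair_distances(dm, sorted(module), sorted(module), "ordered_within")
        background = sorted(set(dm.genes) - module - {spec.core})
        cross = pair_distances(dm, sorted(module), background, "cross")
        # same distribution: medians agree within a few percent of the scale
        assert abs(np.median(within) - np.median(cross)) < 1.0

    def test_module_of_two_has_two_ordered_pairs(self):
        dm, module = simulate_distance_matrix(DistanceSimSpec(n_genes=50, module_size=2, seed=0))
        assert len(module) == 2
        vals = pair_distances(dm, sorted(module), sorted(module), "ordered_within")
        assert vals.size == 2

    def test_distances_non_negative_with_heavy_direction_noise(self):
        spec = DistanceSimSpec(n_genes=80, module_size=5, asymmetry_sd=5.0, seed=2)
        dm, _ = simulate_distance_matrix(spec)
        assert np.all(dm.values >= 0)

    def test_invalid_specs_rejected(self):
        with pytest.raises(InputError):
            DistanceSimSpec(n_genes=10, module_size=10)
        with pytest.raises(InputError):
            DistanceSimSpec(n_genes=10, module_size=2, within_sigma=-1)


class TestRankingGenerator:
    def test_sizes_and_core_position(self):
        ranking = simulate_core_ranking(16_800, core="UCP1", seed=3)
        assert ranking.n == 16_800
        assert ranking.core == "UCP1"
        top = ranking.table.iloc[0]
        assert top["gene"] == "UCP1" and top["rank"] == 1 and top["distance"] == 0.0

    def test_p_order_equals_distance_order(self):
        ranking = simulate_core_ranking(500, seed=4)
        t = ranking.table
        assert (t.sort_values("p_value")["gene"] == t.sort_values("distance")["gene"]).all()


class TestExpressionGenerator:
    def test_seed_determinism(self):
        spec = ExpressionSimSpec(n_genes=50, n_probes=60, n_samples=3, seed=9)
        a, _ = simulate_expression_study(spec)
        b, _ = simulate_expression_study(spec)
        pd.testing.assert_frame_equal(a.values, b.values)
        assert a.probe_map == b.probe_map

    def test_no_multi_gene_probes_keeps_every_gene(self):
        spec = ExpressionSimSpec(
            n_genes=40, n_probes=40, n_samples=3, multi_gene_probe_frac=0.0, seed=1
        )
        study, _ = simulate_expression_study(spec)
        assert collapse_probes(study).genes == set(spec.names)

    def test_strong_planted_shift_puts_most_planted_genes_in_top(self):
        """A 6-log-unit shift puts ≥80% of a small planted set above the 95th
        percentile (normal-tail bound: P(N(13,2) > q95 of N(7,2)) ≈ 0.91;
        aggregated over seeds to tame the small-sample binomial noise)."""
        in_top = measured_total = 0
        for seed in range(5):
            base = ExpressionSimSpec(n_genes=1000, n_probes=1200, n_samples=4, seed=seed)
            planted = tuple(base.names[:20])
            study, truth = simulate_expression_study(
                ExpressionSimSpec(
                    n_genes=1000, n_probes=1200, n_samples=4, seed=seed,
                    planted_genes=planted, planted_shift=6.0, noise_sd=0.5,
                )
            )
            summary = collapse_probes(study)
            top = top_expression_set(summary, 95.0)
            measured = truth & summary.genes
            in_top += len(top & measured)
            measured_total += len(measured)
        assert in_top >= 0.8 * measured_total

    def test_planted_genes_must_exist(self):
        with pytest.raises(InputError):
            simulate_expression_study(
                ExpressionSimSpec(n_genes=10, n_probes=10, planted_genes=("NOPE",))
            )


class TestBundledLists:
    def test_counts_and_membership(self):
        known, candidates, flags = bundled_gene_lists()
        assert len(known) == 61 and "UCP1" in known
        assert len(set(known) - {"UCP1"}) == 60
        assert len(candidates) == 107
        assert not set(known) & set(candidates)
        assert len(set(candidates)) == 107

    def test_flags_are_binary_and_tally_matches_file(self):
        _, candidates, flags = bundled_gene_lists()
        assert set(flags.values()) <= {0, 1}
        assert set(flags) == set(candidates)
        assert sum(flags.values()) == sum(1 for g in candidates if flags[g] == 1)
        # spot-check genes the study's discussion singles out as highly expressed
        assert flags["IGFBP7"] == 1 and flags["ITGAV"] == 1 and flags["GAB2"] == 0

    def test_checksums_validate(self):
        from batconnectome.synthetic import _verify_checksums

        _verify_checksums()


class TestAdditiveTrees:
    def test_tree_and_matrix_agree(self):
        rng = np.random.default_rng(0)
        tree, dm = random_additive_tree(7, rng)
        assert {t.name for t in tree.tips()} == set(dm.genes)
        assert dm.is_symmetric()
        assert np.all(dm.values[~np.eye(dm.n, dtype=bool)] > 0)
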