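"""Distance matrices, rankings, connectome extraction, and pair enumeration."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from batconnectome.distances import (
    CoreRanking,
    DistanceMatrix,
    extract_connectome,
    pair_distances,
    partition_connectome,
    present_genes,
    read_distance_matrix,
    read_gene_list,
    write_distance_matrix,
)
from batconnectome.errors import FormatError, InputError
from batconnectome.synthetic import bundled_gene_lists


def random_matrix(n: int, seed: int, symmetric: bool = False) -> DistanceMatrix:
    rng = np.random.default_rng(seed)
    v = rng.uniform(0.0, 20.0, size=(n, n))
    if symmetric:
        v = (v + v.T) / 2
    np.fill_diagonal(v, 0.0)
    return DistanceMatrix(tuple(f"g{i}" for i in range(n)), v)


class TestMatrixIO:
    @pytest.mark.parametrize("dialect", ["square", "long"])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_round_trip_is_bit_exact(self, tmp_path, dialect, seed):
        dm = random_matrix(7, seed)
        path = tmp_path / f"m.{dialect}.tsv"
        write_distance_matrix(dm, path, dialect)
        back = read_distance_matrix(path, dialect)
        assert back.genes == dm.genes
        assert np.array_equal(back.values, dm.values)

    def test_uniform_square_matrix(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text(
            "gene\ta\tb\tc\na\t0\t1.0\t1.0\nb\t1.0\t0\t1.0\nc\t1.0\t1.0\t0\n"
        )
        dm = read_distance_matrix(path, "square")
        off = dm.values[~np.eye(3, dtype=bool)]
        assert off.size == 6 and np.all(off == 1.0)

    def test_long_single_direction_is_mirrored(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("gene_a\tgene_b\tdistance\na\tb\t2.0\n")
        dm = read_distance_matrix(path, "long")
        assert dm.get("a", "b") == dm.get("b", "a") == 2.0

    def test_long_asymmetric_pairs_are_retained(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("gene_a\tgene_b\tdistance\na\tb\t1.0\nb\ta\t3.0\n")
        dm = read_distance_matrix(path, "long")
        assert dm.get("a", "b") == 1.0 and dm.get("b", "a") == 3.0

    @pytest.mark.parametrize(
        "content, dialect",
        [
            ("gene\ta\ta\na\t0\t1\na\t1\t0\n", "square"),  # duplicate symbol
            ("gene\ta\tb\na\t0\t-1\nb\t1\t0\n", "square"),  # negative distance
            ("gene\ta\tb\na\t0\tx\nb\t1\t0\n", "square"),  # non-numeric
            ("gene_a\tgene_b\tdistance\na\tb\t1\na\tb\t2\n", "long"),  # dup pair
            ("gene_a\tgene_b\tdistance\na\tb\tNaN\n", "long"),  # non-finite
        ],
    )
    def test_malformed_files_raise_format_errors(self, tmp_path, content, dialect):
        path = tmp_path / "bad.tsv"
        path.write_text(content)
        with pytest.raises(InputError):
            read_distance_matrix(path, dialect)

    def test_long_missing_pair_after_mirroring(self, tmp_path):
        # (a,b) both ways plus (a,c) mirrored leaves (b,c) undefined
        path = tmp_path / "m.tsv"
        path.write_text(
            "gene_a\tgene_b\tdistance\na\tb\t1\nb\ta\t2\na\tc\t3\nc\tb\t4\n"
        )
        dm = read_distance_matrix(path, "long")  # (b,c) mirrored from (c,b)
        assert dm.get("b", "c") == 4.0
        path.write_text("gene_a\tgene_b\tdistance\na\tb\t1\nc\td\t2\n")
        with pytest.raises(InputError):
            read_distance_matrix(path, "long")

    def test_gene_list_reader_skips_comments(self, tmp_path):
        path = tmp_path / "genes.txt"
        path.write_text("# header\nUCP1\n  PPARG  \n\nCIDEA # inline\n")
        assert read_gene_list(path) == ("UCP1", "PPARG", "CIDEA")


class TestExtraction:
    def make_ranking(self, n: int, seed: int = 0) -> CoreRanking:
        rng = np.random.default_rng(seed)
        dist = np.concatenate([[0.0], rng.uniform(1, 50, n - 1)])
        p = np.argsort(np.argsort(dist)) / n + 1e-9
        genes = [f"g{i}" for i in range(n)]
        return CoreRanking.from_frame(
            pd.DataFrame({"gene": genes, "distance": dist, "p_value": p}), core="g0"
        )

    @pytest.mark.parametrize("fraction", [0.002, 0.01, 0.05, 0.25, 1.0])
    def test_cut_matches_brute_force_sort(self, fraction):
        ranking = self.make_ranking(500, seed=3)
        result = extract_connectome(ranking, fraction)
        k = math.ceil(fraction * 500)
        t = ranking.table.sort_values("p_value", kind="mergesort")
        expected = set(t["gene"].head(k))
        assert result == expected and len(result) == k

    def test_fraction_one_returns_everything(self):
        ranking = self.make_ranking(41)
        assert extract_connectome(ranking, 1.0) == set(ranking.table["gene"])

    def test_core_is_rank_one(self):
        ranking = self.make_ranking(50)
        top = ranking.table.loc[ranking.table["rank"] == 1].iloc[0]
        assert top["gene"] == "g0" and top["distance"] == 0.0

    def test_invalid_fraction_rejected(self):
        ranking = self.make_ranking(10)
        for bad in (0.0, -0.1, 1.5):
            with pytest.raises(InputError):
                extract_connectome(ranking, bad)

    def test_ranking_without_core_row_rejected(self):
        df = pd.DataFrame(
            {"gene": ["a", "b"], "distance": [1.0, 2.0], "p_value": [0.1, 0.2]}
        )
        with pytest.raises(InputError):
            CoreRanking.from_frame(df)


class TestPartition:
    def test_published_lists_split_sixty_known(self):
        known_list, candidates, _ = bundled_gene_lists()
        connectome = set(known_list) | set(candidates)
        part = partition_connectome(connectome, known_list, "UCP1")
        assert len(part.known) == 60
        assert len(part.candidates) == 107
        assert len(part.connectome) - 1 == 167

    def test_disjoint_known_list_yields_all_candidates(self):
        part = partition_connectome({"c", "x", "y"}, {"q"}, "c")
        assert part.known == frozenset()
        assert part.candidates == frozenset({"x", "y"})

    def test_core_only_connectome(self):
        part = partition_connectome({"c"}, {"c", "x"}, "c")
        assert part.known == part.candidates == frozenset()

    def test_core_absent_raises(self):
        with pytest.raises(InputError):
            partition_connectome({"x", "y"}, set(), "c")


class TestPairDistances:
    @given(st.integers(min_value=2, max_value=8), st.integers(min_value=0, max_value=10))
    @settings(max_examples=25, deadline=None)
    def test_ordered_within_matches_double_loop(self, k, seed):
        dm = random_matrix(10, seed)
        group = list(dm.genes[:k])
        got = sorted(pair_distances(dm, group, group, "ordered_within"))
        expected = sorted(
            dm.get(a, b) for a in group for b in group if a != b
        )
        assert got == expected and len(got) == k * (k - 1)

    def test_cross_count_and_direction_invariance_on_symmetric(self, sym4):
        a, b = ["a", "b"], ["c", "d"]
        fwd = pair_distances(sym4, a, b, "cross")
        rev = pair_distances(sym4, b, a, "cross")
        assert fwd.size == rev.size == 4
        assert sorted(fwd) == sorted(rev)

    def test_two_gene_ordered_within(self):
        dm = DistanceMatrix(("a", "b"), np.array([[0.0, 1.0], [3.0, 0.0]]))
        vals = pair_distances(dm, ["a", "b"], ["a", "b"], "ordered_within")
        assert sorted(vals) == [1.0, 3.0] and np.median(vals) == 2.0

    def test_preconditions(self, asym5):
        with pytest.raises(InputError):
            pair_distances(asym5, ["A"], ["A"], "ordered_within")
        with pytest.raises(InputError):
            pair_distances(asym5, ["A", "B"], ["B", "C"], "cross")
        with pytest.raises(InputError):
            pair_distances(asym5, ["A"], [], "cross")

    def test_missing_genes_dropped_with_warning(self, asym5, caplog):
        with caplog.at_level("WARNING"):
            kept = present_genes(asym5, ["A", "B", "NOT_THERE"], "test list")
        assert kept == ["A", "B"]
        assert "absent" in caplog.text


class TestMatrixValidation:
    def test_nonzero_diagonal_rejected(self):
        v = np.array([[0.5, 1.0], [1.0, 0.0]])
        with pytest.raises(FormatError):
            DistanceMatrix(("a", "b"), v)

    def test_empty_symbol_rejected(self):
        with pytest.raises(FormatError):
            DistanceMatrix(("a", " "), np.zeros((2, 2)))
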