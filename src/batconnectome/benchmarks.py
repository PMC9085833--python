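"""Self-contained benchmark computations: fixture arithmetic, sampling
oracles, type-I calibration, power on planted synthetic data, NJ recovery,
and pipeline determinism.

Each function recomputes its quantity from scratch by running the package on
generated (or bundled) inputs and returns plain numbers. The acceptance
script and the acceptance test suite both call these, so the measured
behaviour is identical in both places. All randomness flows from one integer
seed per function.

Problem sizes are chosen for a single-CPU desk run: calibration uses a
400-gene null matrix with a 15-gene group (the test statistic's calibration
does not depend on scale once pair counts are in the hundreds); power uses
the generator defaults (2000 genes, 60-gene planted module) at n_perm = 2000,
the smallest permutation count at which the adjusted p-value can reach the
1e-3 threshold.
"""

from __future__ import annotations

import itertools
from pathlib import Path

import numpy as np
from scipy import stats

from .distances import pair_distances, partition_connectome
from .expression import (
    build_top_sets,
    collapse_probes,
    expression_enrichment_test,
    sample_null_counts,
    top_expression_set,
)
from .fga import nj_tree, rf_distance, tip_distance_error, to_newick
from .permtest import NullPool, empirical_p, sample_null_medians, within_group_closeness_test
from .pipeline import run_pipeline
from .synthetic import (
    DistanceSimSpec,
    ExpressionSimSpec,
    bundled_gene_lists,
    null_distance_spec,
    published_connectome_spec,
    random_additive_tree,
    simulate_distance_matrix,
    simulate_expression_study,
)


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(s) & 0x7FFFFFFF for s in np.random.SeedSequence(seed).generate_state(n)]


# ---------------------------------------------------------------------------
# Fixture arithmetic
# ---------------------------------------------------------------------------

def fixture_counts(seed: int = 0) -> dict:
    """Partition and pair-enumeration counts for the published gene lists.

    The connectome is the union of the published known and candidate lists
    (the core UCP1 sits in the known list); pair counts are enumerated on a
    simulated matrix whose genes include the full connectome, since the
    counts depend only on set sizes.
    """
    known_list, candidates, _ = bundled_gene_lists()
    core = "UCP1"
    connectome = set(known_list) | set(candidates)
    part = partition_connectome(connectome, known_list, core)
    dm, _ = simulate_distance_matrix(published_connectome_spec(n_genes=300, seed=seed))
    within = pair_distances(dm, sorted(part.known), sorted(part.known), "ordered_within")
    cross = pair_distances(dm, sorted(part.candidates), sorted(part.known), "cross")
    return {
        "known": len(part.known),
        "candidates": len(part.candidates),
        "connectome_excl_core": len(connectome) - 1,
        "within_known_pairs": int(within.size),
        "candidate_known_pairs": int(cross.size),
    }


# ---------------------------------------------------------------------------
# Permutation-sampling oracle (exhaustive enumeration at tiny pool size)
# ---------------------------------------------------------------------------

def permutation_oracle(seed: int, n_perm: int = 100_000, pool_size: int = 8) -> dict:
    """Compare the sampled p-value against exact subset enumeration.

    With a pool of 8 distances and sets of size 2, the null distribution is
    fully enumerable (C(8,2) = 28 equally likely medians); the Monte-Carlo
    p_raw must agree within Monte-Carlo error.
    """
    s_pool, s_draw = _child_seeds(seed, 2)
    rng = np.random.default_rng(s_pool)
    values = rng.lognormal(1.5, 0.6, size=pool_size)
    pool = NullPool(values, "oracle pool")
    exact_medians = np.array(
        [np.median([values[i], values[j]]) for i, j in itertools.combinations(range(pool_size), 2)]
    )
    observed = float(np.quantile(exact_medians, 0.30))
    p_exact = float(np.mean(exact_medians <= observed))
    draws = sample_null_medians(pool, 2, n_perm, np.random.default_rng(s_draw))
    res = empirical_p(observed, draws, "le", test="oracle", seed=s_draw)
    se = float(np.sqrt(p_exact * (1 - p_exact) / n_perm))
    return {
        "p_exact": p_exact,
        "p_sampled": res.p_raw,
        "z": abs(res.p_raw - p_exact) / se,
        "n_perm": n_perm,
    }


# ---------------------------------------------------------------------------
# Type-I calibration under exchangeable nulls
# ---------------------------------------------------------------------------

def within_calibration(seed: int, n_rep: int = 500, n_perm: int = 2000) -> dict:
    """Rejection rate of the within-group test when nothing is planted.

    The null generator draws every ordered pair from one distribution, so the
    group's median and the pool medians are exchangeable; p_adj ≤ 0.05 should
    occur in about 5% of replicates.
    """
    sim_seeds = _child_seeds(seed, n_rep)
    test_seeds = _child_seeds(seed + 1, n_rep)
    hits = 0
    for i in range(n_rep):
        spec = null_distance_spec(n_genes=400, module_size=15, seed=sim_seeds[i])
        dm, module = simulate_distance_matrix(spec)
        complement = set(dm.genes) - module - {spec.core}
        res = within_group_closeness_test(dm, module, complement, n_perm, test_seeds[i])
        hits += res.p_adj <= 0.05
    return {"rate_pct": 100.0 * hits / n_rep, "n_rep": n_rep, "n_perm": n_perm}


def expression_calibration(seed: int, n_rep: int = 500, n_perm: int = 2000) -> dict:
    """Rejection rate of the enrichment test for uniformly random queries."""
    sim_seeds = _child_seeds(seed, n_rep)
    test_seeds = _child_seeds(seed + 1, n_rep)
    hits = 0
    for i in range(n_rep):
        spec = ExpressionSimSpec(
            n_genes=1000, n_probes=1200, n_samples=4, seed=sim_seeds[i],
            study_id=f"null_{i}",
        )
        study, _ = simulate_expression_study(spec)
        tops = build_top_sets([collapse_probes(study)], 95.0)
        universe = sorted(tops.universe)
        rng = np.random.default_rng(test_seeds[i])
        query = list(rng.choice(universe, size=100, replace=False))
        res = expression_enrichment_test(query, tops, n_perm, test_seeds[i])
        hits += res.p_adj <= 0.05
    return {"rate_pct": 100.0 * hits / n_rep, "n_rep": n_rep, "n_perm": n_perm}


def hypergeometric_oracle(seed: int, n_perm: int = 100_000, query_size: int = 30) -> dict:
    """The enrichment null must be hypergeometric for a single study.

    Drawing q genes from a universe of N of which K are in the top set, the
    membership count is Hypergeom(N, K, q); the empirical frequencies from
    the sampler are compared to the pmf in Monte-Carlo standard-error units
    at every support point with expected count ≥ 5.
    """
    s_sim, s_draw = _child_seeds(seed, 2)
    study, _ = simulate_expression_study(
        ExpressionSimSpec(n_genes=400, n_probes=480, n_samples=4, seed=s_sim)
    )
    tops = build_top_sets([collapse_probes(study)], 95.0)
    n_universe, k_top = len(tops.universe), len(tops.union)
    counts = sample_null_counts(tops, query_size, n_perm, np.random.default_rng(s_draw))
    dist = stats.hypergeom(n_universe, k_top, query_size)
    max_z = 0.0
    for k in range(query_size + 1):
        pmf = float(dist.pmf(k))
        if pmf * n_perm < 5:
            continue
        emp = float(np.mean(counts == k))
        se = float(np.sqrt(pmf * (1 - pmf) / n_perm))
        max_z = max(max_z, abs(emp - pmf) / se)
    return {
        "max_z": max_z,
        "n_perm": n_perm,
        "universe": n_universe,
        "top": k_top,
    }


# ---------------------------------------------------------------------------
# Power on planted synthetic data
# ---------------------------------------------------------------------------

def within_power(seed: int, n_seeds: int = 100, n_perm: int = 2000) -> dict:
    """Detection rate of the default planted module (within-group test).

    Uses the generator defaults (2000 genes, 60-gene module, within median
    ≈ 4.7 vs background ≈ 9); reports the fraction of seeds with
    p_adj ≤ 1e-3 and the mean observed within-module median.
    """
    sim_seeds = _child_seeds(seed, n_seeds)
    test_seeds = _child_seeds(seed + 1, n_seeds)
    hits = 0
    observed = []
    for i in range(n_seeds):
        spec = DistanceSimSpec(seed=sim_seeds[i])
        dm, module = simulate_distance_matrix(spec)
        complement = set(dm.genes) - module - {spec.core}
        res = within_group_closeness_test(dm, module, complement, n_perm, test_seeds[i])
        hits += res.p_adj <= 1e-3
        observed.append(res.observed)
    return {
        "rate_pct": 100.0 * hits / n_seeds,
        "mean_observed_median": float(np.mean(observed)),
        "n_seeds": n_seeds,
        "n_perm": n_perm,
    }


def expression_power(seed: int, n_seeds: int = 100, n_perm: int = 2000) -> dict:
    """Detection rate of a planted expression module (default 6-log-unit
    shift on 100 of 2000 genes); fraction of seeds with p_adj ≤ 0.01."""
    sim_seeds = _child_seeds(seed, n_seeds)
    test_seeds = _child_seeds(seed + 1, n_seeds)
    hits = 0
    for i in range(n_seeds):
        base = ExpressionSimSpec(seed=0)
        planted = tuple(base.names[:100])
        spec = ExpressionSimSpec(planted_genes=planted, seed=sim_seeds[i])
        study, truth = simulate_expression_study(spec)
        tops = build_top_sets([collapse_probes(study)], 95.0)
        res = expression_enrichment_test(truth, tops, n_perm, test_seeds[i])
        hits += res.p_adj <= 0.01
    return {"rate_pct": 100.0 * hits / n_seeds, "n_seeds": n_seeds, "n_perm": n_perm}


# ---------------------------------------------------------------------------
# NJ additive-metric recovery
# ---------------------------------------------------------------------------

def nj_recovery(seed: int, n_trees: int = 50, leaf_range: tuple[int, int] = (5, 40)) -> dict:
    """Reconstruct random additive trees; topology and path lengths must be
    recovered exactly (RF = 0, path error at numerical precision)."""
    rng = np.random.default_rng(seed)
    total_rf = 0
    max_err = 0.0
    for _ in range(n_trees):
        n_leaves = int(rng.integers(leaf_range[0], leaf_range[1] + 1))
        true_tree, dm = random_additive_tree(n_leaves, rng)
        recon = nj_tree(dm)
        total_rf += rf_distance(to_newick(true_tree), to_newick(recon))
        max_err = max(max_err, tip_distance_error(recon, dm))
    return {"total_rf": total_rf, "max_path_error": max_err, "n_trees": n_trees}


# ---------------------------------------------------------------------------
# Quantile behaviour
# ---------------------------------------------------------------------------

def quantile_top_count(n: int = 1000, percentile: float = 95.0) -> dict:
    """Size of the top set for n distinct integer expression values."""
    import pandas as pd

    from .expression import GeneExpressionSummary

    values = pd.Series(
        np.arange(1, n + 1, dtype=float), index=[f"g{i:04d}" for i in range(1, n + 1)]
    )
    summary = GeneExpressionSummary("quantile_check", values)
    top = top_expression_set(summary, percentile)
    return {"top_size": len(top), "n": n, "percentile": percentile}


# ---------------------------------------------------------------------------
# End-to-end determinism
# ---------------------------------------------------------------------------

def demo_config(seed: int, known_list_path: str, n_perm: int = 2000) -> dict:
    """A small fully synthetic pipeline configuration."""
    return {
        "seed": seed,
        "core": "CORE",
        "fraction": 0.1,
        "percentile": 95.0,
        "n_perm": n_perm,
        "known_list": known_list_path,
        "distances": {"simulate": {"n_genes": 400, "module_size": 40}},
        "expression": {
            "simulate": [
                {"planted": "connectome", "n_samples": 4},
                {"planted": "connectome", "n_samples": 4},
            ],
            "queries": ["connectome", "candidates", "known"],
        },
    }


def pipeline_determinism(seed: int, workdir) -> dict:
    """Run the demo pipeline twice with one root seed; artifacts must be
    byte-identical."""
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    spec = DistanceSimSpec(n_genes=400, module_size=40, core="CORE", seed=0)
    module = list(spec.names[1:41])
    known_path = workdir / "known.txt"
    known_path.write_text("\n".join(module[:20]) + "\n")
    cfg = demo_config(seed, str(known_path))
    out_a = run_pipeline(cfg, workdir / "run_a")
    out_b = run_pipeline(cfg, workdir / "run_b")
    files_a = sorted(p.name for p in out_a.iterdir())
    files_b = sorted(p.name for p in out_b.iterdir())
    identical = files_a == files_b and all(
        (out_a / name).read_bytes() == (out_b / name).read_bytes() for name in files_a
    )
    return {"identical": bool(identical), "n_artifacts": len(files_a)}
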