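"""Monte-Carlo closeness tests on median biological distances.

The question both tests answer: is the observed median of a set of pair
distances smaller than the median of equally sized sets of distances drawn at
random from a null pool? The null pool holds the distances between the group
of interest and a complement set of genes; each permutation draws ``set_size``
distances from the pool without replacement (within a set — draws are
independent across sets) and records their median. The p-value is the
proportion of null medians at least as extreme as the observed one, ties
counting as extreme.

Three p-value flavours are reported: the raw proportion b/n (the classical
estimator), the bias-adjusted (b+1)/(n+1) which can never be exactly zero,
and a display string that renders "p < 1/n" when no null draw was as extreme.
Uncertainty on b/n is a 95% Clopper–Pearson interval.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np
from scipy import stats

from .distances import DistanceMatrix, pair_distances
from .errors import InputError

Tail = Literal["le", "ge"]
CrossDirection = Literal["a_to_b", "b_to_a", "average"]


@dataclass(frozen=True)
class NullPool:
    """Pool of biological distances a null set is drawn from."""

    values: np.ndarray
    description: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float).ravel()
        if v.size == 0:
            raise InputError("empty null pool")
        if not np.all(np.isfinite(v)) or np.any(v < 0):
            raise InputError("null pool must contain finite non-negative values")
        object.__setattr__(self, "values", v)

    @property
    def size(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class PermutationResult:
    """Outcome of one Monte-Carlo permutation test; fully seed-reproducible."""

    test: str
    observed: float
    n_perm: int
    n_extreme: int
    tail: Tail
    seed: int
    set_sizes: dict = field(default_factory=dict)

    @property
    def p_raw(self) -> float:
        return self.n_extreme / self.n_perm

    @property
    def p_adj(self) -> float:
        return (self.n_extreme + 1) / (self.n_perm + 1)

    @property
    def ci95(self) -> tuple[float, float]:
        return clopper_pearson(self.n_extreme, self.n_perm)

    @property
    def p_report(self) -> str:
        if self.n_extreme == 0:
            return f"p < {1 / self.n_perm:.3g}"
        return f"p = {self.p_raw:.3g}"

    def to_dict(self) -> dict:
        lo, hi = self.ci95
        return {
            "test": self.test,
            "observed": self.observed,
            "n_perm": self.n_perm,
            "n_extreme": self.n_extreme,
            "p_raw": self.p_raw,
            "p_adj": self.p_adj,
            "p_report": self.p_report,
            "ci95": [lo, hi],
            "tail": self.tail,
            "seed": self.seed,
            "set_sizes": dict(self.set_sizes),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def clopper_pearson(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Exact binomial confidence interval for a proportion k/n."""
    if not 0 <= k <= n or n <= 0:
        raise InputError(f"invalid counts k={k}, n={n}")
    alpha = 1.0 - conf
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


# ---------------------------------------------------------------------------
# Null pools and median sampling
# ---------------------------------------------------------------------------

def build_null_pool(
    dm: DistanceMatrix,
    group: Iterable[str],
    complement: Iterable[str],
    both_directions: bool = False,
) -> NullPool:
    """Distances between a gene group and a complement set.

    Default is the group→complement direction only, keeping null draws on the
    same one-direction-per-pair footing as the observed cross statistics;
    ``both_directions`` pools d(g, c) and d(c, g).
    """
    group = sorted(set(group))
    complement = sorted(set(complement))
    if not group or not complement:
        raise InputError("group and complement must be non-empty")
    if set(group) & set(complement):
        raise InputError("group and complement overlap")
    values = pair_distances(dm, group, complement, "cross")
    desc = f"{len(group)} group x {len(complement)} complement"
    if both_directions:
        values = np.concatenate([values, pair_distances(dm, complement, group, "cross")])
        desc += " (both directions)"
    return NullPool(values, desc)


def sample_null_medians(
    pool: NullPool,
    set_size: int,
    n_perm: int,
    rng: np.random.Generator,
    replace: bool = False,
) -> np.ndarray:
    """Medians of ``n_perm`` random distance sets drawn from the pool.

    Each set of ``set_size`` distances is drawn without replacement (draws are
    with replacement *across* sets); ``replace=True`` switches to
    with-replacement sampling within sets.
    """
    if set_size < 1:
        raise InputError("set_size must be positive")
    if n_perm < 1:
        raise InputError("n_perm must be positive")
    v = pool.values
    n = v.size
    if replace:
        idx = rng.integers(0, n, size=(n_perm, set_size))
        return np.median(v[idx], axis=1)
    if set_size > n:
        raise InputError(
            f"set_size {set_size} exceeds pool size {n} for sampling without replacement"
        )
    out = np.empty(n_perm)
    for i in range(n_perm):
        out[i] = np.median(v[rng.choice(n, set_size, replace=False)])
    return out


def sample_null_median(
    pool: NullPool, set_size: int, rng: np.random.Generator, replace: bool = False
) -> float:
    """Median of one random distance set (see :func:`sample_null_medians`)."""
    return float(sample_null_medians(pool, set_size, 1, rng, replace=replace)[0])


# ---------------------------------------------------------------------------
# Empirical p-values
# ---------------------------------------------------------------------------

def empirical_p(
    observed: float,
    null_draws: Iterable[float],
    tail: Tail,
    test: str = "",
    seed: int = 0,
    set_sizes: dict | None = None,
) -> PermutationResult:
    """Monte-Carlo p-value from a stream of null statistics.

    ``tail='le'`` counts draws ≤ observed (closeness tests); ``'ge'`` counts
    draws ≥ observed (enrichment counts). Ties count as extreme.
    """
    null = np.asarray(list(null_draws) if not isinstance(null_draws, np.ndarray) else null_draws,
                      dtype=float)
    if null.size == 0:
        raise InputError("empty null stream")
    if tail == "le":
        n_extreme = int(np.sum(null <= observed))
    elif tail == "ge":
        n_extreme = int(np.sum(null >= observed))
    else:
        raise InputError(f"unknown tail {tail!r}")
    return PermutationResult(
        test=test,
        observed=float(observed),
        n_perm=int(null.size),
        n_extreme=n_extreme,
        tail=tail,
        seed=seed,
        set_sizes=set_sizes or {},
    )


# ---------------------------------------------------------------------------
# The two closeness tests
# ---------------------------------------------------------------------------

def within_group_closeness_test(
    dm: DistanceMatrix,
    group: Iterable[str],
    complement: Iterable[str],
    n_perm: int,
    seed: int,
    replace: bool = False,
    both_directions: bool = False,
) -> PermutationResult:
    """Are group members closer to each other than to the complement genes?

    Observed statistic: median over all ordered within-group pairs
    (|G|·(|G|−1) distances). Null: medians of equally many distances drawn
    from the group×complement pool. Small medians are extreme (tail 'le').
    """
    group = sorted(set(group))
    if len(group) < 2:
        raise InputError("within-group test needs at least 2 genes")
    within = pair_distances(dm, group, group, "ordered_within")
    observed = float(np.median(within))
    pool = build_null_pool(dm, group, complement, both_directions=both_directions)
    rng = np.random.default_rng(seed)
    null = sample_null_medians(pool, within.size, n_perm, rng, replace=replace)
    return empirical_p(
        observed, null, "le",
        test="within_group_closeness",
        seed=seed,
        set_sizes={"group": len(group), "pool": pool.size, "set_size": int(within.size)},
    )


def cross_group_closeness_test(
    dm: DistanceMatrix,
    candidates: Iterable[str],
    known: Iterable[str],
    outside: Iterable[str],
    n_perm: int,
    seed: int,
    replace: bool = False,
    direction: CrossDirection = "a_to_b",
    both_directions: bool = False,
) -> PermutationResult:
    """Are the known genes closer to the candidates than to outside genes?

    Observed: median of the |candidates|·|known| cross distances (direction
    candidates→known by default; ``direction`` can flip or average the two).
    Null: medians of equally sized sets from the known×outside pool.
    """
    candidates = sorted(set(candidates))
    known = sorted(set(known))
    outside = sorted(set(outside))
    for name, s in (("candidates", candidates), ("known", known), ("outside", outside)):
        if not s:
            raise InputError(f"{name} set is empty")
    if (set(candidates) & set(known)) or (set(candidates) & set(outside)) or (
        set(known) & set(outside)
    ):
        raise InputError("candidates, known, and outside sets must be pairwise disjoint")
    fwd = pair_distances(dm, candidates, known, "cross")
    if direction == "a_to_b":
        cross = fwd
    elif direction == "b_to_a":
        cross = pair_distances(dm, known, candidates, "cross")
    elif direction == "average":
        rev = pair_distances(dm, known, candidates, "cross").reshape(len(known), len(candidates))
        cross = ((fwd.reshape(len(candidates), len(known)) + rev.T) / 2).ravel()
    else:
        raise InputError(f"unknown direction {direction!r}")
    observed = float(np.median(cross))
    pool = build_null_pool(dm, known, outside, both_directions=both_directions)
    rng = np.random.default_rng(seed)
    null = sample_null_medians(pool, cross.size, n_perm, rng, replace=replace)
    return empirical_p(
        observed, null, "le",
        test="cross_group_closeness",
        seed=seed,
        set_sizes={
            "candidates": len(candidates),
            "known": len(known),
            "outside": len(outside),
            "pool": pool.size,
            "set_size": int(cross.size),
        },
    )
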