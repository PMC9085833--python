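"""Synthetic benchmark generators and the packaged in-paper gene lists.

The real analysis consumed two inputs that cannot ship with the package: the
genome-wide human-gene-connectome distance matrix and four processed
microarray studies. The generators here produce stand-ins with the
statistical structure the method assumes — a planted low-distance module
around a core gene inside an otherwise exchangeable asymmetric matrix, and
expression studies with a planted excess of module genes in the upper tail —
so every downstream stage is testable end to end, with known ground truth.

Distances are log-normal: HGC-style distances are non-negative sums of
positive edge weights, so a right-skewed positive distribution is the natural
shape. Defaults plant a 60-gene module (the size of the known-gene set) whose
within-module median sits near 4.7 against a background median near 9,
echoing the scale of real connectome distances; a small additive direction
noise makes the matrix asymmetric, as HGC matrices are.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

from .distances import CoreRanking, DistanceMatrix
from .errors import InputError
from .expression import ExpressionStudy

_WITHIN_MU = float(np.log(4.7))
_BACKGROUND_MU = float(np.log(9.0))


@dataclass(frozen=True)
class DistanceSimSpec:
    """Parameters of a planted-module distance matrix.

    ``within_mu``/``within_sigma`` are the log-scale parameters of the
    log-normal distances among module genes (and between the core and the
    module); ``background_mu``/``background_sigma`` govern every other ordered
    pair. ``asymmetry_sd`` is the standard deviation of independent additive
    per-direction noise (distances are truncated at 0 afterwards). Setting
    ``within_mu == background_mu`` (and equal sigmas) yields an exchangeable
    null matrix with no planted structure.
    """

    n_genes: int = 2000
    module_size: int = 60
    core: str = "CORE"
    within_mu: float = _WITHIN_MU
    within_sigma: float = 0.35
    background_mu: float = _BACKGROUND_MU
    background_sigma: float = 0.35
    asymmetry_sd: float = 0.25
    seed: int = 0
    gene_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_genes < 2:
            raise InputError("n_genes must be at least 2")
        if not 1 <= self.module_size < self.n_genes:
            raise InputError("module_size must be in [1, n_genes)")
        if min(self.within_sigma, self.background_sigma, self.asymmetry_sd) < 0:
            raise InputError("sigmas must be non-negative")
        if self.gene_names is not None:
            names = tuple(self.gene_names)
            if len(names) != self.n_genes:
                raise InputError("gene_names length must equal n_genes")
            if names[0] != self.core:
                raise InputError("gene_names[0] must be the core gene")
            object.__setattr__(self, "gene_names", names)

    @property
    def names(self) -> tuple[str, ...]:
        if self.gene_names is not None:
            return self.gene_names
        return (self.core,) + tuple(f"G{i:05d}" for i in range(1, self.n_genes))


def null_distance_spec(**overrides) -> DistanceSimSpec:
    """A no-planted-structure spec (within ≡ background) for calibration runs."""
    base = dict(
        within_mu=_BACKGROUND_MU,
        within_sigma=0.35,
        background_mu=_BACKGROUND_MU,
        background_sigma=0.35,
    )
    base.update(overrides)
    return DistanceSimSpec(**base)


def simulate_distance_matrix(spec: DistanceSimSpec) -> tuple[DistanceMatrix, set[str]]:
    """Simulate an asymmetric distance matrix with a planted module.

    Genes are ``spec.names``; the first is the core and the next
    ``module_size`` form the planted module (returned as ground truth,
    excluding the core, mirroring the known-gene convention). All ordered
    pairs within {core} ∪ module draw from the within distribution, every
    other ordered pair from the background; independent N(0, asymmetry_sd)
    direction noise is added and the result truncated at 0.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_genes
    m = spec.module_size
    v = rng.lognormal(spec.background_mu, spec.background_sigma, size=(n, n))
    block = rng.lognormal(spec.within_mu, spec.within_sigma, size=(m + 1, m + 1))
    v[: m + 1, : m + 1] = block
    if spec.asymmetry_sd > 0:
        v += rng.normal(0.0, spec.asymmetry_sd, size=(n, n))
    np.clip(v, 0.0, None, out=v)
    np.fill_diagonal(v, 0.0)
    names = spec.names
    return DistanceMatrix(names, v), set(names[1 : m + 1])


def simulate_core_ranking(
    n_genes: int,
    core: str = "CORE",
    module_size: int = 0,
    seed: int = 0,
    gene_names: Sequence[str] | None = None,
    within_mu: float = _WITHIN_MU,
    background_mu: float = _BACKGROUND_MU,
    sigma: float = 0.35,
) -> CoreRanking:
    """Simulate a genome-scale core-gene ranking without building a matrix.

    Distances to the core are log-normal (module genes, if any, from the
    lower within distribution); p-values are the empirical right-open rank
    fraction of each distance, so ordering by p equals ordering by distance.
    Useful for exercising the top-fraction cut at realistic genome sizes
    (~17k genes) where a dense matrix would be wasteful.
    """
    if n_genes < 2:
        raise InputError("n_genes must be at least 2")
    if not 0 <= module_size < n_genes:
        raise InputError("module_size must be in [0, n_genes)")
    rng = np.random.default_rng(seed)
    if gene_names is None:
        names = [core] + [f"G{i:05d}" for i in range(1, n_genes)]
    else:
        names = [str(g) for g in gene_names]
        if len(names) != n_genes or names[0] != core:
            raise InputError("gene_names must have length n_genes and start with the core")
    dist = rng.lognormal(background_mu, sigma, size=n_genes)
    if module_size:
        dist[1 : module_size + 1] = rng.lognormal(within_mu, sigma, size=module_size)
    dist[0] = 0.0
    order = np.argsort(dist, kind="stable")
    p = np.empty(n_genes)
    p[order] = np.arange(1, n_genes + 1) / n_genes
    df = pd.DataFrame({"gene": names, "distance": dist, "p_value": p})
    return CoreRanking.from_frame(df, core=core)


@dataclass(frozen=True)
class ExpressionSimSpec:
    """Parameters of a simulated processed microarray study.

    Per-gene baseline log-intensities are N(7, 2); ``planted_genes`` are
    shifted up by ``planted_shift`` log-units. Probes are assigned to genes
    round-robin (so every gene has at least one probe when
    n_probes ≥ n_genes); a ``multi_gene_probe_frac`` fraction of probes is
    additionally annotated to a second gene, and is therefore dropped by the
    collapsing step. Every probe × sample value gets N(0, noise_sd) noise.
    """

    n_genes: int = 2000
    n_probes: int = 2400
    n_samples: int = 6
    multi_gene_probe_frac: float = 0.1
    planted_genes: tuple[str, ...] = ()
    planted_shift: float = 6.0
    noise_sd: float = 0.5
    seed: int = 0
    study_id: str = "synthetic_study"
    baseline_mean: float = 7.0
    baseline_sd: float = 2.0
    gene_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_samples < 1:
            raise InputError("n_genes and n_samples must be positive")
        if self.n_probes < self.n_genes:
            raise InputError("n_probes must be at least n_genes")
        if not 0 <= self.multi_gene_probe_frac < 1:
            raise InputError("multi_gene_probe_frac must be in [0, 1)")
        if self.noise_sd < 0 or self.baseline_sd < 0:
            raise InputError("standard deviations must be non-negative")
        object.__setattr__(self, "planted_genes", tuple(self.planted_genes))
        if self.gene_names is not None:
            names = tuple(str(g) for g in self.gene_names)
            if len(names) != self.n_genes:
                raise InputError("gene_names length must equal n_genes")
            object.__setattr__(self, "gene_names", names)

    @property
    def names(self) -> list[str]:
        if self.gene_names is not None:
            return list(self.gene_names)
        return [f"G{i:05d}" for i in range(self.n_genes)]


def simulate_expression_study(spec: ExpressionSimSpec) -> tuple[ExpressionStudy, set[str]]:
    """Simulate one study; returns it with the planted gene set as truth."""
    rng = np.random.default_rng(spec.seed)
    genes = spec.names
    planted = set(spec.planted_genes)
    unknown = planted - set(genes)
    if unknown:
        raise InputError(f"planted genes not in the simulated gene set: {sorted(unknown)[:5]}")
    baseline = rng.normal(spec.baseline_mean, spec.baseline_sd, size=spec.n_genes)
    for i, g in enumerate(genes):
        if g in planted:
            baseline[i] += spec.planted_shift
    probe_gene = np.arange(spec.n_probes) % spec.n_genes
    n_multi = int(round(spec.multi_gene_probe_frac * spec.n_probes))
    multi_idx = rng.choice(spec.n_probes, size=n_multi, replace=False) if n_multi else np.array([], dtype=int)
    is_multi = np.zeros(spec.n_probes, dtype=bool)
    is_multi[multi_idx] = True
    probe_ids = [f"P{i:06d}" for i in range(spec.n_probes)]
    probe_map: dict[str, frozenset[str]] = {}
    signal = np.empty(spec.n_probes)
    for i in range(spec.n_probes):
        g1 = probe_gene[i]
        if is_multi[i]:
            g2 = (g1 + 1) % spec.n_genes
            probe_map[probe_ids[i]] = frozenset({genes[g1], genes[g2]})
            signal[i] = (baseline[g1] + baseline[g2]) / 2.0
        else:
            probe_map[probe_ids[i]] = frozenset({genes[g1]})
            signal[i] = baseline[g1]
    values = signal[:, None] + rng.normal(0.0, spec.noise_sd, size=(spec.n_probes, spec.n_samples))
    frame = pd.DataFrame(
        values, index=pd.Index(probe_ids, name="probe"),
        columns=[f"S{j + 1}" for j in range(spec.n_samples)],
    )
    return ExpressionStudy(spec.study_id, frame, probe_map), planted


# ---------------------------------------------------------------------------
# Random additive trees (oracle inputs for the NJ recovery benchmark)
# ---------------------------------------------------------------------------

def random_additive_tree(
    n_leaves: int, rng: np.random.Generator, length_range: tuple[float, float] = (0.1, 2.0)
):
    """Random unrooted binary tree with leaf labels L001.. and uniform branch
    lengths; returns (skbio TreeNode, DistanceMatrix of exact path lengths).

    Because the resulting leaf-to-leaf distances are exactly additive on the
    tree, neighbour joining must recover the topology and every path length —
    this is the independent oracle for the NJ implementation.
    """
    from skbio.tree import TreeNode  # local import keeps module load light

    if n_leaves < 4:
        raise InputError("need at least 4 leaves for a non-trivial unrooted tree")
    lo, hi = length_range
    nodes = [TreeNode(name=f"L{i:03d}") for i in range(1, n_leaves + 1)]
    for node in nodes:
        node.length = float(rng.uniform(lo, hi))
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        parent = TreeNode(children=[a, b])
        parent.length = float(rng.uniform(lo, hi))
        nodes.append(parent)
    root = TreeNode(children=nodes)
    root.length = None
    tt = root.tip_tip_distances()
    ids = sorted(tt.ids)
    n = len(ids)
    v = np.zeros((n, n))
    for x, a in enumerate(ids):
        for y, b in enumerate(ids):
            if x != y:
                v[x, y] = float(tt[a, b])
    return root, DistanceMatrix(tuple(ids), v)


# ---------------------------------------------------------------------------
# Packaged gene lists (transcribed from the published tables)
# ---------------------------------------------------------------------------

def published_connectome_spec(n_genes: int = 2000, seed: int = 0) -> DistanceSimSpec:
    """A planted-module spec whose module is the published 167-gene connectome.

    The matrix genes are UCP1, the 167 known+candidate genes from the
    published tables, and synthetic background genes up to ``n_genes``; the
    planted low-distance module is exactly the connectome, so the published
    gene lists can be pushed through every pipeline stage at full pair counts
    (3540 within-known, 6420 candidate×known).
    """
    known, candidates, _ = bundled_gene_lists()
    connectome = sorted((set(known) | set(candidates)) - {"UCP1"})
    names = ("UCP1",) + tuple(connectome)
    if n_genes < len(names) + 1:
        raise InputError(f"n_genes must exceed {len(names)}")
    names = names + tuple(f"BG{i:05d}" for i in range(n_genes - len(names)))
    return DistanceSimSpec(
        n_genes=n_genes, module_size=len(connectome), core="UCP1",
        gene_names=names, seed=seed,
    )


class PackagingError(RuntimeError):
    """A bundled fixture failed its checksum."""


def _data_bytes(name: str) -> bytes:
    return resources.files("batconnectome.data").joinpath(name).read_bytes()


def _verify_checksums() -> None:
    manifest = _data_bytes("checksums.sha256").decode().strip().splitlines()
    for line in manifest:
        digest, name = line.split()
        actual = hashlib.sha256(_data_bytes(name)).hexdigest()
        if actual != digest:
            raise PackagingError(f"fixture {name} corrupted: sha256 {actual} != {digest}")


def bundled_gene_lists() -> tuple[tuple[str, ...], tuple[str, ...], dict[str, int]]:
    """The published gene lists shipped with the package.

    Returns ``(known, candidates, biopsy_flags)``: the 61 literature-known
    BAT genes (UCP1 included), the 107 novel candidates, and the per-candidate
    binary flag marking expression above the 95th percentile in either of the
    two BAT-biopsy studies. Checksummed against the packaged manifest.
    """
    _verify_checksums()
    known = tuple(
        line.strip()
        for line in _data_bytes("known_bat_genes.txt").decode().splitlines()
        if line.strip() and not line.startswith("#")
    )
    flags: dict[str, int] = {}
    lines = _data_bytes("bat_candidate_genes.tsv").decode().strip().splitlines()
    for line in lines[1:]:
        gene, flag = line.split("\t")
        flags[gene] = int(flag)
    return known, tuple(flags), flags
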