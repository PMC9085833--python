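"""Gene-labelled biological distance matrices, core-gene rankings, and the
set operations built on them.

The central object is :class:`DistanceMatrix`: a dense, possibly *asymmetric*
matrix of non-negative biological distances between genes (dimensionless HGC
units — shortest-path costs over a protein-interaction network, consumed here
as input, never computed). Asymmetry is meaningful: d(a, b) is the cost of
the best route from a to b and need not equal d(b, a).

On top of it sit the operations of the prioritisation pipeline: reading and
writing the two TSV dialects, cutting a core gene's connectome at a top
fraction of the genome, partitioning the connectome into known and candidate
genes, and enumerating pair distances for the median statistics.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, InputError

logger = logging.getLogger(__name__)

Dialect = Literal["square", "long"]
PairMode = Literal["ordered_within", "cross"]


def _clean_symbols(symbols: Iterable[str]) -> tuple[str, ...]:
    cleaned = tuple(str(s).strip() for s in symbols)
    if any(not s for s in cleaned):
        raise FormatError("empty gene symbol")
    if len(set(cleaned)) != len(cleaned):
        dupes = sorted({s for s in cleaned if list(cleaned).count(s) > 1})
        raise FormatError(f"duplicate gene symbols: {dupes[:5]}")
    return cleaned


@dataclass(frozen=True)
class DistanceMatrix:
    """Dense gene × gene biological distance matrix.

    ``values[i, j]`` is d(genes[i], genes[j]); the diagonal is implicitly 0
    and stored as 0. The matrix need not be symmetric.
    """

    genes: tuple[str, ...]
    values: np.ndarray
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        genes = _clean_symbols(self.genes)
        object.__setattr__(self, "genes", genes)
        v = np.asarray(self.values, dtype=float)
        n = len(genes)
        if v.shape != (n, n):
            raise InputError(f"matrix shape {v.shape} does not match {n} genes")
        if not np.all(np.isfinite(v)):
            raise FormatError("non-finite distance")
        if np.any(v < 0):
            raise FormatError("negative distance")
        if np.any(np.diag(v) != 0):
            raise FormatError("nonzero diagonal: self-distances must be 0")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "_index", {g: i for i, g in enumerate(genes)})

    @property
    def n(self) -> int:
        return len(self.genes)

    def index(self, gene: str) -> int:
        try:
            return self._index[gene]
        except KeyError:
            raise InputError(f"gene {gene!r} not in matrix") from None

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.index(a), self.index(b)])

    def __contains__(self, gene: str) -> bool:
        return gene in self._index

    def is_symmetric(self, atol: float = 0.0) -> bool:
        return bool(np.allclose(self.values, self.values.T, rtol=0.0, atol=atol))

    def subset(self, genes: Sequence[str]) -> "DistanceMatrix":
        idx = [self.index(g) for g in genes]
        return DistanceMatrix(tuple(genes), self.values[np.ix_(idx, idx)])

    @classmethod
    def from_pairs(
        cls, pairs: dict[tuple[str, str], float], genes: Sequence[str] | None = None
    ) -> "DistanceMatrix":
        """Build from a {(gene_a, gene_b): distance} mapping over ordered pairs."""
        if genes is None:
            seen: dict[str, None] = {}
            for a, b in pairs:
                seen.setdefault(a)
                seen.setdefault(b)
            genes = list(seen)
        genes = _clean_symbols(genes)
        idx = {g: i for i, g in enumerate(genes)}
        n = len(genes)
        v = np.full((n, n), np.nan)
        np.fill_diagonal(v, 0.0)
        for (a, b), d in pairs.items():
            v[idx[a], idx[b]] = d
        if np.any(np.isnan(v)):
            missing = int(np.isnan(v).sum())
            raise InputError(f"{missing} ordered pairs missing from pair mapping")
        return cls(genes, v)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def read_distance_matrix(path, dialect: Dialect = "square") -> DistanceMatrix:
    """Read a distance matrix TSV.

    ``square``: header row and first column hold the gene symbols (same order).
    ``long``: columns gene_a, gene_b, distance; pairs present in only one
    direction are mirrored; after mirroring every ordered pair must exist.
    """
    if dialect == "square":
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
        cols = _clean_symbols(df.columns)
        rows = _clean_symbols(df.index)
        if cols != rows:
            raise FormatError("square matrix row and column labels differ")
        try:
            v = df.to_numpy(dtype=float)
        except ValueError as exc:
            raise FormatError(f"non-numeric distance: {exc}") from None
        return DistanceMatrix(cols, v)
    if dialect == "long":
        df = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str, "distance": str})
        required = {"gene_a", "gene_b", "distance"}
        if not required.issubset(df.columns):
            raise FormatError(f"long dialect requires columns {sorted(required)}")
        pairs: dict[tuple[str, str], float] = {}
        order: dict[str, None] = {}
        for a, b, d in df[["gene_a", "gene_b", "distance"]].itertuples(index=False):
            a, b = str(a).strip(), str(b).strip()
            try:
                d = float(d)
            except (TypeError, ValueError):
                raise FormatError(f"non-numeric distance for pair ({a}, {b})") from None
            if d < 0 or not math.isfinite(d):
                raise FormatError(f"invalid distance {d} for pair ({a}, {b})")
            if a == b:
                if d != 0:
                    raise FormatError(f"nonzero self-distance for {a}")
                order.setdefault(a)
                continue
            if (a, b) in pairs:
                raise FormatError(f"duplicate pair ({a}, {b})")
            pairs[(a, b)] = d
            order.setdefault(a)
            order.setdefault(b)
        # mirror pairs listed in one direction only
        for (a, b), d in list(pairs.items()):
            pairs.setdefault((b, a), d)
        try:
            return DistanceMatrix.from_pairs(pairs, genes=list(order))
        except InputError as exc:
            raise InputError(f"incomplete long-format matrix: {exc}") from None
    raise InputError(f"unknown dialect {dialect!r}")


def write_distance_matrix(dm: DistanceMatrix, path, dialect: Dialect = "square") -> None:
    """Write a matrix TSV; floats use shortest round-trip (repr) formatting so
    a read-back is bit-exact."""
    with open(path, "w", encoding="utf-8") as fh:
        if dialect == "square":
            fh.write("gene\t" + "\t".join(dm.genes) + "\n")
            for i, g in enumerate(dm.genes):
                fh.write(g + "\t" + "\t".join(repr(float(x)) for x in dm.values[i]) + "\n")
        elif dialect == "long":
            fh.write("gene_a\tgene_b\tdistance\n")
            for i, a in enumerate(dm.genes):
                for j, b in enumerate(dm.genes):
                    if i != j:
                        fh.write(f"{a}\t{b}\t{float(dm.values[i, j])!r}\n")
        else:
            raise InputError(f"unknown dialect {dialect!r}")


def read_gene_list(path) -> tuple[str, ...]:
    """Plain-text gene list: one symbol per line, '#' comments ignored."""
    out: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                out.append(line)
    return _clean_symbols(out)


def write_gene_list(genes: Iterable[str], path, header: str | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if header:
            fh.write(f"# {header}\n")
        for g in genes:
            fh.write(g + "\n")


# ---------------------------------------------------------------------------
# Core-gene rankings and connectome extraction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CoreRanking:
    """All genes ranked by biological proximity to one core gene.

    ``table`` has columns gene, distance, p_value, rank; rows sorted by
    ascending p-value with ties broken by ascending distance then gene symbol.
    The core itself is row one (rank 1, distance 0).
    """

    core: str
    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        required = ["gene", "distance", "p_value", "rank"]
        if list(t.columns) != required:
            raise InputError(f"ranking table must have columns {required}")
        if t.empty:
            raise InputError("empty ranking")
        if t["gene"].duplicated().any():
            raise FormatError("duplicate gene in ranking")
        if (t["distance"] < 0).any() or not np.isfinite(t["distance"]).all():
            raise FormatError("invalid distance in ranking")
        if ((t["p_value"] < 0) | (t["p_value"] > 1)).any():
            raise FormatError("p_value outside [0, 1]")
        if sorted(t["rank"]) != list(range(1, len(t) + 1)):
            raise InputError("ranks are not a permutation of 1..N")
        top = t.loc[t["rank"] == 1].iloc[0]
        if top["gene"] != self.core or top["distance"] != 0:
            raise InputError("core gene must hold rank 1 with distance 0")

    @property
    def n(self) -> int:
        return len(self.table)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, core: str | None = None) -> "CoreRanking":
        """Derive ranks from a (gene, distance, p_value) frame.

        Ties in p-value break by ascending distance, then gene symbol, making
        the top-fraction cut deterministic. If ``core`` is omitted it is taken
        as the zero-distance gene.
        """
        df = df.copy()
        df["gene"] = df["gene"].astype(str).str.strip()
        df = df.sort_values(
            ["p_value", "distance", "gene"], kind="mergesort"
        ).reset_index(drop=True)
        df["rank"] = np.arange(1, len(df) + 1)
        if core is None:
            zero = df.loc[df["distance"] == 0, "gene"]
            if zero.empty:
                raise InputError("no zero-distance row to identify the core gene")
            core = str(zero.iloc[0])
        return cls(core, df[["gene", "distance", "p_value", "rank"]])


def read_core_ranking(path, core: str | None = None) -> CoreRanking:
    df = pd.read_csv(path, sep="\t", dtype={"gene": str})
    required = {"gene", "distance", "p_value"}
    if not required.issubset(df.columns):
        raise FormatError(f"ranking requires columns {sorted(required)}")
    return CoreRanking.from_frame(df[["gene", "distance", "p_value"]], core=core)


def write_core_ranking(ranking: CoreRanking, path) -> None:
    ranking.table.to_csv(path, sep="\t", index=False)


def extract_connectome(ranking: CoreRanking, fraction: float) -> set[str]:
    """Genes in the top ``fraction`` of the ranking by p-value, core included.

    The cut keeps ranks ≤ ceil(fraction · N). Reported connectome sizes
    conventionally exclude the core; this function returns it so the caller
    controls that convention.
    """
    if not 0 < fraction <= 1:
        raise InputError(f"fraction must be in (0, 1], got {fraction}")
    k = math.ceil(fraction * ranking.n)
    t = ranking.table
    return set(t.loc[t["rank"] <= k, "gene"])


@dataclass(frozen=True)
class GenePartition:
    """Connectome split into the core gene, known genes, and novel candidates."""

    core: str
    known: frozenset[str]
    candidates: frozenset[str]

    def __post_init__(self) -> None:
        if self.known & self.candidates:
            raise InputError("known and candidate sets overlap")
        if self.core in self.known or self.core in self.candidates:
            raise InputError("core gene must not appear in known or candidate sets")

    @property
    def connectome(self) -> frozenset[str]:
        return self.known | self.candidates | {self.core}


def partition_connectome(
    connectome: set[str], known_list: Iterable[str], core: str
) -> GenePartition:
    """Split a connectome into literature-known genes and novel candidates."""
    if core not in connectome:
        raise InputError(f"core gene {core!r} not in connectome")
    known_list = set(known_list)
    rest = set(connectome) - {core}
    known = rest & known_list
    return GenePartition(core, frozenset(known), frozenset(rest - known))


# ---------------------------------------------------------------------------
# Pair-distance enumeration
# ---------------------------------------------------------------------------

def present_genes(dm: DistanceMatrix, genes: Iterable[str], label: str = "gene list") -> list[str]:
    """Filter a gene list to matrix members, warning about the rest.

    Published lists routinely name genes absent from a partial matrix; those
    are dropped (with a logged warning), not fatal.
    """
    genes = list(genes)
    present = [g for g in genes if g in dm]
    missing = [g for g in genes if g not in dm]
    if missing:
        logger.warning(
            "%s: %d of %d genes absent from the distance matrix (e.g. %s)",
            label, len(missing), len(genes), ", ".join(missing[:5]),
        )
    return present


def pair_distances(
    dm: DistanceMatrix,
    group_a: Iterable[str],
    group_b: Iterable[str],
    mode: PairMode,
) -> np.ndarray:
    """Enumerate pair distances between gene sets.

    ``ordered_within`` (A must equal B, |A| ≥ 2): d(a, b) for every ordered
    pair a ≠ b — |A|·(|A|−1) values, covering both directions of an
    asymmetric matrix. ``cross`` (A, B disjoint, non-empty): d(a, b) for all
    a ∈ A, b ∈ B — |A|·|B| values in the A→B direction only.
    """
    a = sorted(set(group_a))
    b = sorted(set(group_b))
    ia = np.array([dm.index(g) for g in a], dtype=int)
    ib = np.array([dm.index(g) for g in b], dtype=int)
    if mode == "ordered_within":
        if set(a) != set(b):
            raise InputError("ordered_within requires identical gene sets")
        if len(a) < 2:
            raise InputError("ordered_within requires at least 2 genes")
        block = dm.values[np.ix_(ia, ia)]
        mask = ~np.eye(len(a), dtype=bool)
        return block[mask]
    if mode == "cross":
        if not a or not b:
            raise InputError("cross mode requires two non-empty sets")
        if set(a) & set(b):
            raise InputError("cross mode requires disjoint sets")
        return dm.values[np.ix_(ia, ib)].ravel()
    raise InputError(f"unknown mode {mode!r}")
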