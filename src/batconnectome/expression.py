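"""Top-percentile expression sets and the random-gene-set enrichment test.

Processed microarray studies enter as probe × sample matrices plus a
probe→gene map. Probes that map to zero genes or to several genes are
discarded (ambiguous annotation); the rest are collapsed to one scalar per
gene by a two-stage median (across samples per probe, then across probes per
gene). A study's "top of expression" is the set of genes strictly above the
95th percentile (linear-interpolation quantile) of its per-gene summaries.

The enrichment question: does a query gene set (the connectome, or just the
candidates) hit the union of the studies' top sets more often than random
gene sets of the same size drawn from the universe of summarised genes?
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import FormatError, InputError
from .permtest import PermutationResult, empirical_p

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExpressionStudy:
    """Processed probe-level study: log-intensity matrix plus probe→gene map."""

    study_id: str
    values: pd.DataFrame  # rows = probes, columns = samples
    probe_map: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        v = self.values
        if v.shape[1] < 1:
            raise InputError("study needs at least one sample")
        if v.index.duplicated().any():
            raise FormatError("duplicate probe identifiers")
        if not np.isfinite(v.to_numpy(dtype=float)).all():
            raise FormatError("non-finite expression value")
        object.__setattr__(self, "values", v.rename_axis("probe"))
        object.__setattr__(
            self,
            "probe_map",
            {str(p): frozenset(gs) for p, gs in self.probe_map.items()},
        )


@dataclass(frozen=True)
class GeneExpressionSummary:
    """One expression scalar per gene for a study (same units as input)."""

    study_id: str
    values: pd.Series  # index = gene, value = summary expression

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise InputError("duplicate gene in summary")

    @property
    def genes(self) -> set[str]:
        return set(self.values.index)


@dataclass(frozen=True)
class TopSets:
    """Per-study top-expression gene sets and the resampling universe."""

    percentile: float
    per_study: dict  # study_id -> frozenset of genes
    universe: frozenset

    def __post_init__(self) -> None:
        if not 0 < self.percentile < 100:
            raise InputError("percentile must be in (0, 100)")
        for sid, top in self.per_study.items():
            if not top <= self.universe:
                raise InputError(f"top set of study {sid!r} not within the universe")

    @property
    def union(self) -> frozenset:
        out: frozenset = frozenset()
        for top in self.per_study.values():
            out = out | top
        return out


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_expression_study(matrix_path, probe_map_path, study_id: str) -> ExpressionStudy:
    """Matrix TSV (first column probe id, remaining columns samples) plus a
    probe map TSV (probe TAB comma-separated gene symbols; second field may be
    empty for unannotated probes)."""
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    try:
        values = values.astype(float)
    except ValueError as exc:
        raise FormatError(f"non-numeric expression value: {exc}") from None
    pm: dict[str, frozenset[str]] = {}
    raw = pd.read_csv(probe_map_path, sep="\t", header=0, dtype=str, keep_default_na=False)
    if raw.shape[1] < 2:
        raise FormatError("probe map needs columns: probe, genes")
    for probe, genes in raw.iloc[:, :2].itertuples(index=False):
        probe = str(probe).strip()
        if probe in pm:
            raise FormatError(f"duplicate probe {probe!r} in probe map")
        symbols = frozenset(s.strip() for s in str(genes).split(",") if s.strip())
        pm[probe] = symbols
    return ExpressionStudy(study_id, values, pm)


def write_expression_study(study: ExpressionStudy, matrix_path, probe_map_path) -> None:
    study.values.rename_axis("probe").to_csv(matrix_path, sep="\t")
    with open(probe_map_path, "w", encoding="utf-8") as fh:
        fh.write("probe\tgenes\n")
        for probe in study.values.index:
            genes = ",".join(sorted(study.probe_map.get(probe, frozenset())))
            fh.write(f"{probe}\t{genes}\n")


# ---------------------------------------------------------------------------
# Collapsing and top sets
# ---------------------------------------------------------------------------

def collapse_probes(study: ExpressionStudy, pooled: bool = False) -> GeneExpressionSummary:
    """Collapse a probe × sample matrix to one value per gene.

    Probes annotated to zero or to several genes are dropped. Default is the
    two-stage median (median across samples per probe, then median across a
    gene's probes); ``pooled=True`` instead takes a single median over all of
    a gene's probe × sample values.
    """
    keep = [p for p in study.values.index if len(study.probe_map.get(p, frozenset())) == 1]
    if not keep:
        raise InputError("no unambiguous single-gene probes remain after filtering")
    gene_of = {p: next(iter(study.probe_map[p])) for p in keep}
    sub = study.values.loc[keep]
    genes = pd.Series([gene_of[p] for p in keep], index=sub.index, name="gene")
    if pooled:
        stacked = sub.stack()
        summary = stacked.groupby(stacked.index.get_level_values(0).map(gene_of)).median()
    else:
        per_probe = sub.median(axis=1)
        summary = per_probe.groupby(genes).median()
    summary = summary.sort_index()
    summary.name = study.study_id
    return GeneExpressionSummary(study.study_id, summary)


def top_expression_set(summary: GeneExpressionSummary, percentile: float = 95.0) -> set[str]:
    """Genes strictly above the study's expression percentile.

    The threshold is the linear-interpolation quantile of the per-gene
    summaries (order statistic h = (N−1)·p + 1); membership requires a value
    strictly greater than the threshold, so a constant study has an empty top.
    """
    if not 0 < percentile < 100:
        raise InputError("percentile must be in (0, 100)")
    if summary.values.empty:
        raise InputError("empty expression summary")
    threshold = float(np.quantile(summary.values.to_numpy(dtype=float), percentile / 100.0))
    return set(summary.values.index[summary.values.to_numpy(dtype=float) > threshold])


def build_top_sets(
    summaries: Iterable[GeneExpressionSummary], percentile: float = 95.0
) -> TopSets:
    per_study: dict[str, frozenset] = {}
    universe: set[str] = set()
    for s in summaries:
        per_study[s.study_id] = frozenset(top_expression_set(s, percentile))
        universe |= s.genes
    if not per_study:
        raise InputError("no studies provided")
    return TopSets(percentile, per_study, frozenset(universe))


def union_membership_count(tops: TopSets, query: Iterable[str]) -> int:
    """How many query genes are in the top of expression of *any* study."""
    return len(set(query) & tops.union)


# ---------------------------------------------------------------------------
# Enrichment permutation test
# ---------------------------------------------------------------------------

def sample_null_counts(
    tops: TopSets, query_size: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Union-membership counts of ``n_perm`` random gene sets of the given
    size drawn (without replacement within a set) from the universe."""
    universe = np.array(sorted(tops.universe))
    if query_size > universe.size:
        raise InputError("query size exceeds universe size")
    member = np.isin(universe, np.array(sorted(tops.union)))
    counts = np.empty(n_perm, dtype=int)
    for i in range(n_perm):
        counts[i] = int(member[rng.choice(universe.size, query_size, replace=False)].sum())
    return counts


def expression_enrichment_test(
    query: Iterable[str],
    tops: TopSets,
    n_perm: int,
    seed: int,
    restrict_query: bool = True,
) -> PermutationResult:
    """Is the query set over-represented in the studies' top expression?

    Null sets are drawn from the universe of genes that *have* expression
    summaries, matching the resampling frame of the observed count. Query
    genes outside that universe are dropped with a warning when
    ``restrict_query`` (default), since they can never be counted.
    """
    query = set(query)
    missing = query - tops.universe
    if missing:
        if not restrict_query:
            raise InputError(f"{len(missing)} query genes outside the expression universe")
        logger.warning(
            "query: %d of %d genes have no expression summary and were dropped",
            len(missing), len(query),
        )
        query -= missing
    if not query:
        raise InputError("query set empty after restriction to the universe")
    observed = union_membership_count(tops, query)
    rng = np.random.default_rng(seed)
    null = sample_null_counts(tops, len(query), n_perm, rng)
    return empirical_p(
        observed, null, "ge",
        test="expression_enrichment",
        seed=seed,
        set_sizes={
            "query": len(query),
            "universe": len(tops.universe),
            "top_union": len(tops.union),
            "n_studies": len(tops.per_study),
        },
    )
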