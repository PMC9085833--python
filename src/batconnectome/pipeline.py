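"""End-to-end orchestration of the five analysis stages.

A run is driven by a single configuration mapping (usually loaded from YAML)
and writes every artifact into one output directory:

    connectome.txt               extracted top-fraction gene list
    partition.json               core / known / candidate split with counts
    within_test.json             within-known closeness permutation test
    cross_test.json              candidate→known closeness permutation test
    tree.nwk, leaf_classes.tsv   functional genomic alignment tree
    expression_enrichment.json   top-percentile enrichment per query set
    run_log.txt                  config echo, library versions, stage seeds

All randomness derives from one root seed, so a repeated run over identical
inputs reproduces every artifact byte for byte.
"""

from __future__ import annotations

import json
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .distances import (
    CoreRanking,
    extract_connectome,
    pair_distances,
    partition_connectome,
    present_genes,
    read_core_ranking,
    read_distance_matrix,
    read_gene_list,
    write_gene_list,
)
from .errors import InputError, StageError
from .expression import (
    build_top_sets,
    collapse_probes,
    expression_enrichment_test,
    read_expression_study,
    union_membership_count,
)
from .fga import nj_tree, symmetrize, write_leaf_annotations, write_newick
from .permtest import cross_group_closeness_test, within_group_closeness_test
from .synthetic import (
    DistanceSimSpec,
    ExpressionSimSpec,
    bundled_gene_lists,
    simulate_core_ranking,
    simulate_distance_matrix,
    simulate_expression_study,
)

DEFAULTS: dict = {
    "seed": 0,
    "core": "UCP1",
    "fraction": 0.01,
    "percentile": 95.0,
    "n_perm": 1_000_000,
    "known_list": None,  # path; None -> bundled published list
    "distances": {"matrix": None, "dialect": "square", "simulate": None},
    "ranking": {"path": None, "simulate": None},  # neither -> derived from matrix
    "options": {
        "within_pool": "all",  # or "outside": restrict pool to non-connectome genes
        "both_directions": False,
        "cross_direction": "a_to_b",
        "replace": False,
        "clamp_negative": True,
        "collapse_pooled": False,
    },
    "expression": {
        "studies": None,   # [{id, matrix, probe_map}, ...]
        "simulate": None,  # [{ExpressionSimSpec fields, planted: connectome|candidates|none}]
        "queries": ["connectome", "candidates", "known"],
    },
}


def _merged(config: dict) -> dict:
    out = json.loads(json.dumps(DEFAULTS))
    for key, value in (config or {}).items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key].update(value)
        else:
            out[key] = value
    return out


def load_config(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise InputError("config file must contain a mapping")
    return _merged(raw)


def ranking_from_matrix(dm, core: str) -> CoreRanking:
    """Derive a core ranking from matrix distances d(core, ·); p-values are
    the empirical rank fractions, so the p-order equals the distance order."""
    i = dm.index(core)
    dist = dm.values[i].astype(float).copy()
    order = np.argsort(dist, kind="stable")
    p = np.empty(dm.n)
    p[order] = np.arange(1, dm.n + 1) / dm.n
    df = pd.DataFrame({"gene": list(dm.genes), "distance": dist, "p_value": p})
    return CoreRanking.from_frame(df, core=core)


def _stage(name):
    def decorator(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(name, exc) from exc
        return wrapped
    return decorator


def run_pipeline(config: dict, out_dir) -> Path:
    """Execute extract → partition → tests → tree → expression enrichment."""
    cfg = _merged(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    root = int(cfg["seed"])
    stage_seeds = [int(s) & 0x7FFFFFFF for s in np.random.SeedSequence(root).generate_state(8)]
    seeds = dict(zip(["sim_matrix", "sim_ranking", "within", "cross", "expr"], stage_seeds))
    opts = cfg["options"]
    core = cfg["core"]

    # -- distances -----------------------------------------------------------
    @_stage("distances")
    def load_distances():
        dc = cfg["distances"]
        if dc.get("matrix"):
            return read_distance_matrix(dc["matrix"], dc.get("dialect", "square"))
        if dc.get("simulate") is not None:
            sim = dict(dc["simulate"])
            sim.setdefault("seed", seeds["sim_matrix"])
            sim.setdefault("core", core)
            if "gene_names" in sim and sim["gene_names"] is not None:
                sim["gene_names"] = tuple(sim["gene_names"])
            dm, _ = simulate_distance_matrix(DistanceSimSpec(**sim))
            return dm
        raise InputError("config must provide distances.matrix or distances.simulate")

    dm = load_distances()

    # -- ranking and connectome extraction -----------------------------------
    @_stage("ranking")
    def load_ranking():
        rc = cfg["ranking"]
        if rc.get("path"):
            return read_core_ranking(rc["path"], core=core)
        if rc.get("simulate") is not None:
            sim = dict(rc["simulate"])
            sim.setdefault("seed", seeds["sim_ranking"])
            sim.setdefault("core", core)
            return simulate_core_ranking(**sim)
        return ranking_from_matrix(dm, core)

    ranking = load_ranking()

    @_stage("extract")
    def do_extract():
        conn = extract_connectome(ranking, float(cfg["fraction"]))
        write_gene_list(
            sorted(conn), out / "connectome.txt",
            header=f"connectome of {core}: {len(conn)} genes incl. core, "
                   f"{len(conn) - 1} excluding it (fraction {cfg['fraction']})",
        )
        return conn

    connectome = do_extract()

    @_stage("partition")
    def do_partition():
        if cfg.get("known_list"):
            known_list = read_gene_list(cfg["known_list"])
        else:
            known_list, _, _ = bundled_gene_lists()
        part = partition_connectome(connectome, known_list, core)
        payload = {
            "core": part.core,
            "known": sorted(part.known),
            "candidates": sorted(part.candidates),
            "counts": {
                "connectome_excl_core": len(connectome) - 1,
                "known": len(part.known),
                "candidates": len(part.candidates),
            },
        }
        (out / "partition.json").write_text(json.dumps(payload, indent=2) + "\n")
        return part

    partition = do_partition()

    # -- closeness permutation tests -----------------------------------------
    matrix_genes = set(dm.genes)
    known_in = set(present_genes(dm, sorted(partition.known), "known genes"))
    cand_in = set(present_genes(dm, sorted(partition.candidates), "candidate genes"))
    outside = matrix_genes - set(connectome) - {core}

    @_stage("test_within")
    def do_within():
        complement = (
            outside if opts["within_pool"] == "outside"
            else matrix_genes - known_in - {core}
        )
        res = within_group_closeness_test(
            dm, known_in, complement, int(cfg["n_perm"]), seeds["within"],
            replace=bool(opts["replace"]), both_directions=bool(opts["both_directions"]),
        )
        (out / "within_test.json").write_text(res.to_json(indent=2) + "\n")
        return res

    within_res = do_within()

    @_stage("test_cross")
    def do_cross():
        res = cross_group_closeness_test(
            dm, cand_in, known_in, outside, int(cfg["n_perm"]), seeds["cross"],
            replace=bool(opts["replace"]), direction=opts["cross_direction"],
            both_directions=bool(opts["both_directions"]),
        )
        (out / "cross_test.json").write_text(res.to_json(indent=2) + "\n")
        return res

    cross_res = do_cross()

    # -- functional genomic alignment tree -----------------------------------
    @_stage("tree")
    def do_tree():
        leaves = sorted(present_genes(dm, sorted(connectome), "connectome"))
        tree = nj_tree(symmetrize(dm), leaves, clamp_negative=bool(opts["clamp_negative"]))
        write_newick(tree, out / "tree.nwk")
        write_leaf_annotations(partition, out / "leaf_classes.tsv")
        return tree

    do_tree()

    # -- expression enrichment ------------------------------------------------
    @_stage("expression")
    def do_expression():
        ec = cfg["expression"]
        studies = []
        if ec.get("studies"):
            for entry in ec["studies"]:
                studies.append(
                    read_expression_study(entry["matrix"], entry["probe_map"], entry["id"])
                )
        elif ec.get("simulate"):
            planted_sets = {
                "connectome": sorted(set(connectome) - {core}),
                "candidates": sorted(partition.candidates),
                "known": sorted(partition.known),
                "none": [],
            }
            for k, entry in enumerate(ec["simulate"]):
                sim = dict(entry)
                planted_key = sim.pop("planted", "none")
                names = tuple(sorted(matrix_genes))
                sim.setdefault("gene_names", names)
                sim.setdefault("n_genes", len(sim["gene_names"]))
                sim.setdefault("n_probes", int(sim["n_genes"] * 1.2))
                sim.setdefault("seed", (seeds["expr"] + 104729 * k) & 0x7FFFFFFF)
                sim.setdefault("study_id", f"sim_study_{k + 1}")
                sim["planted_genes"] = tuple(
                    g for g in planted_sets[planted_key] if g in sim["gene_names"]
                )
                study, _ = simulate_expression_study(ExpressionSimSpec(**sim))
                studies.append(study)
        else:
            return None
        summaries = [collapse_probes(s, pooled=bool(opts["collapse_pooled"])) for s in studies]
        tops = build_top_sets(summaries, float(cfg["percentile"]))
        queries = {
            "connectome": set(connectome) - {core},
            "candidates": set(partition.candidates),
            "known": set(partition.known),
        }
        payload = {"percentile": float(cfg["percentile"]), "studies": sorted(tops.per_study),
                   "results": {}}
        for name in ec.get("queries") or []:
            q = queries[name]
            res = expression_enrichment_test(
                q, tops, int(cfg["n_perm"]),
                (seeds["expr"] + zlib.crc32(name.encode()) % 1000) & 0x7FFFFFFF,
            )
            payload["results"][name] = res.to_dict()
            payload["results"][name]["observed_count"] = union_membership_count(tops, q)
        (out / "expression_enrichment.json").write_text(json.dumps(payload, indent=2) + "\n")
        return payload

    expr_payload = do_expression()

    # -- run log --------------------------------------------------------------
    log_lines = [
        f"batconnectome {__version__}",
        f"numpy {np.__version__}  pandas {pd.__version__}",
        f"root_seed {root}",
        "stage_seeds " + json.dumps(seeds, sort_keys=True),
        "config:",
        yaml.safe_dump(cfg, sort_keys=True).rstrip(),
        f"within: {within_res.p_report} (observed median {within_res.observed:.4g})",
        f"cross: {cross_res.p_report} (observed median {cross_res.observed:.4g})",
    ]
    if expr_payload:
        for name, res in expr_payload["results"].items():
            log_lines.append(
                f"expression[{name}]: {res['p_report']} (observed count {res['observed_count']})"
            )
    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    return out


def pair_count_summary(dm, partition) -> dict:
    """Counts of the enumerated pair distances for a partition (the within-known
    and candidate×known multiset sizes)."""
    known = sorted(partition.known)
    cand = sorted(partition.candidates)
    return {
        "within_known": int(pair_distances(dm, known, known, "ordered_within").size),
        "candidate_known": int(pair_distances(dm, cand, known, "cross").size),
    }
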