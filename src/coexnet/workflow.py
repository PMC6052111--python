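"""Grid orchestration: dataset x distance x threshold sweeps.

``run_grid`` evaluates every dataset x distance combination: score matrix ->
top-K edge list (the implied dynamic threshold is logged) -> one network per
threshold fraction -> evaluation row (topology, NV/global/degree AUROC,
enriched-term count) and, per pathway, a PLC report. Artifacts are written
under an output directory with JSON sidecars recording config, seed and
stage so any row can be traced back to its inputs. A stage failure is
recorded and the grid continues.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from coexnet.annotation import AnnotationSet
from coexnet.distance import (
    ScoreMatrix,
    hrr_matrix,
    mutual_information_matrix,
    partial_correlation_shrinkage,
    pearson_matrix,
    spearman_matrix,
)
from coexnet.errors import ParameterError
from coexnet.evaluate import (
    degree_auroc,
    global_auroc,
    neighbor_voting_auroc,
    pair_enrichment,
)
from coexnet.expression import ExpressionMatrix, filter_zero_variance
from coexnet.network import (
    Network,
    build_graph,
    intersect_networks,
    subset_fraction,
    top_pairs,
    topology_stats,
    trim_to_vertex_count,
)
from coexnet.pathway import PathwayDefinition
from coexnet.plc import plc_report

#: Threshold ladder used throughout: best 1..80% of the top-K list.
DEFAULT_FRACTIONS = (0.01, 0.05, 0.10, 0.20, 0.40, 0.60, 0.80)

#: Cap on top-K as a share of all possible pairs (the 10-million-pair lists
#: among 33,604 transcripts cover < 2% of all pairs).
TOP_K_PAIR_SHARE_CAP = 0.02

_DISTANCES = ("pcc", "scc", "hrr_pcc", "hrr_scc", "mi", "pc")


@dataclass
class RunConfig:
    """Validated configuration of one grid run."""

    datasets: dict[str, ExpressionMatrix]
    distances: tuple[str, ...] = _DISTANCES
    top_k: int = 10_000_000
    fractions: tuple[float, ...] = DEFAULT_FRACTIONS
    folds: int = 3
    alpha: float = 0.05
    correction: str = "bh"
    replicates: int = 2000
    seed: int = 0
    pathways: dict[str, PathwayDefinition] = field(default_factory=dict)
    annotations: AnnotationSet | None = None
    out_dir: Path | None = None

    def __post_init__(self) -> None:
        unknown = set(self.distances) - set(_DISTANCES)
        if unknown:
            raise ParameterError(f"unknown distances: {sorted(unknown)}")
        if any(not 0 < f <= 1 for f in self.fractions):
            raise ParameterError("fractions must lie in (0, 1]")


def capped_top_k(requested: int, n_genes: int) -> int:
    """Requested K limited to the 2%-of-all-pairs cap."""
    total = n_genes * (n_genes - 1) // 2
    cap = max(1, int(TOP_K_PAIR_SHARE_CAP * total))
    return min(requested, cap, total)


def score_matrix(mat: ExpressionMatrix, distance: str,
                 seed: int = 0, mi_k: int = 3) -> ScoreMatrix:
    """One dataset x distance score matrix (zero-variance genes dropped)."""
    mat = filter_zero_variance(mat)
    if distance == "pcc":
        return pearson_matrix(mat)
    if distance == "scc":
        return spearman_matrix(mat)
    if distance == "hrr_pcc":
        return hrr_matrix(pearson_matrix(mat))
    if distance == "hrr_scc":
        return hrr_matrix(spearman_matrix(mat))
    if distance == "mi":
        return mutual_information_matrix(mat, k=mi_k, seed=seed)
    if distance == "pc":
        return partial_correlation_shrinkage(mat)
    raise ParameterError(f"unknown distance {distance!r}")


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps({
        "datasets": sorted(config.datasets),
        "distances": list(config.distances),
        "top_k": config.top_k,
        "fractions": list(config.fractions),
        "folds": config.folds,
        "alpha": config.alpha,
        "correction": config.correction,
        "replicates": config.replicates,
        "seed": config.seed,
    }, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _sidecar(path: Path, config: RunConfig, stage: str, **extra) -> None:
    meta = {"stage": stage, "seed": config.seed,
            "config_hash": _config_hash(config), **extra}
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(meta, indent=1, sort_keys=True))


def evaluate_network(net: Network, ann: AnnotationSet, *, folds: int = 3,
                     alpha: float = 0.05, correction: str = "bh",
                     seed: int = 0) -> dict:
    """One evaluation row: topology plus the three AUROCs and enrichment."""
    ts = topology_stats(net)
    row = {
        "vertices": ts.n_vertices,
        "edges": ts.n_edges,
        "mean_degree": ts.mean_degree,
        "nv_auroc": float("nan"),
        "global_auroc": float("nan"),
        "degree_auroc": float("nan"),
        "n_enriched_terms": 0,
    }
    try:
        _, row["nv_auroc"] = neighbor_voting_auroc(net, ann, folds=folds,
                                                   seed=seed)
        row["global_auroc"] = global_auroc(net, ann)
        row["degree_auroc"] = degree_auroc(net, ann)
        _, row["n_enriched_terms"] = pair_enrichment(
            net, ann, alpha=alpha, correction=correction)
    except Exception as exc:
        row["error"] = str(exc)
    return row


def run_grid(config: RunConfig) -> pd.DataFrame:
    """Evaluate every dataset x distance x fraction combination.

    Returns the evaluation table (one row per combination x fraction, plus
    one PLC row per pathway at the full top-K network) and, when
    ``config.out_dir`` is set, writes edge lists, evaluation tables and
    JSON sidecars there. Failures are recorded in an ``error`` column and
    do not stop the sweep.
    """
    out = None
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
    rows = []
    plc_rows = []
    for ds_name, mat in sorted(config.datasets.items()):
        for distance in config.distances:
            combo = f"{ds_name}__{distance}"
            try:
                scores = score_matrix(mat, distance, seed=config.seed)
                k = capped_top_k(config.top_k, scores.n_genes)
                edges = top_pairs(scores, k)
                if out is not None:
                    epath = out / f"{combo}.edges.tsv"
                    edges.write(epath)
                    _sidecar(epath, config, "edge_list",
                             dataset=ds_name, distance=distance,
                             top_k=k, threshold=edges.threshold)
            except Exception as exc:
                rows.append({"dataset": ds_name, "distance": distance,
                             "fraction": float("nan"), "error": str(exc)})
                continue
            for frac in config.fractions:
                try:
                    net = build_graph(
                        subset_fraction(edges, frac),
                        provenance={"dataset": ds_name,
                                    "distance": distance,
                                    "fraction": frac},
                    )
                    row = {"dataset": ds_name, "distance": distance,
                           "fraction": frac, "threshold": edges.threshold}
                    if config.annotations is not None:
                        row.update(evaluate_network(
                            net, config.annotations, folds=config.folds,
                            alpha=config.alpha,
                            correction=config.correction,
                            seed=config.seed))
                    else:
                        ts = topology_stats(net)
                        row.update({"vertices": ts.n_vertices,
                                    "edges": ts.n_edges,
                                    "mean_degree": ts.mean_degree})
                    rows.append(row)
                except Exception as exc:
                    rows.append({"dataset": ds_name, "distance": distance,
                                 "fraction": frac, "error": str(exc)})
            for pw_name, pathway in sorted(config.pathways.items()):
                try:
                    net = build_graph(edges,
                                      provenance={"dataset": ds_name,
                                                  "distance": distance})
                    rep = plc_report(net, pathway,
                                     ann=config.annotations,
                                     seed=config.seed,
                                     replicates=config.replicates,
                                     folds=config.folds)
                    prow = {"dataset": ds_name, "distance": distance}
                    prow.update(rep.to_row())
                    plc_rows.append(prow)
                except Exception as exc:
                    plc_rows.append({"dataset": ds_name,
                                     "distance": distance,
                                     "pathway": pw_name,
                                     "error": str(exc)})
    table = pd.DataFrame(rows)
    if out is not None:
        tpath = out / "evaluation.tsv"
        table.to_csv(tpath, sep="\t", index=False)
        _sidecar(tpath, config, "evaluation")
        if plc_rows:
            ppath = out / "plc_reports.tsv"
            pd.DataFrame(plc_rows).to_csv(ppath, sep="\t", index=False)
            _sidecar(ppath, config, "plc_reports")
    if plc_rows:
        table.attrs["plc_reports"] = pd.DataFrame(plc_rows)
    return table


def run_intersection(net_a: Network, net_b: Network,
                     pathway: PathwayDefinition,
                     ann: AnnotationSet | None = None,
                     target_vertices: int = 1000, seed: int = 0,
                     replicates: int = 2000):
    """Score the co-occurrence network of two platforms on one pathway.

    Both inputs are trimmed best-edge-first to ``target_vertices``,
    intersected edge-wise, and the intersection is scored with the full PLC
    report (guide representation, modularity, normalized Chi², NV AUROC).
    Returns ``(report_or_None, intersection_counts)``; an empty
    intersection yields ``None`` with the counts.
    """

    def _edge_list(net: Network):
        from coexnet.network import EdgeList
        lower = False
        recs = sorted(
            ((min(u, v), max(u, v), d.get("score", 0.0))
             for u, v, d in net.graph.edges(data=True)),
            key=lambda r: (-r[2], r[0], r[1]),
        )
        prov = net.provenance.get("distance", "")
        if str(prov).startswith("hrr"):
            lower = True
            recs.sort(key=lambda r: (r[2], r[0], r[1]))
        return EdgeList(records=recs,
                        orientation="lower_better" if lower
                        else "higher_better")

    a_trim = trim_to_vertex_count(_edge_list(net_a), target_vertices)
    b_trim = trim_to_vertex_count(_edge_list(net_b), target_vertices)
    inter, counts = intersect_networks(a_trim, b_trim)
    if inter.n_edges == 0:
        return None, counts
    rep = plc_report(inter, pathway, ann=ann, seed=seed,
                     replicates=replicates)
    return rep, counts
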