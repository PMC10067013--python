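"""End-to-end benchmark driver and fixture generation.

``run_benchmark`` wires the whole framework together: load or simulate a
sample, run every configured DR method through the failure-isolating
registry, compute all applicable metric categories against the
original-space data and clustering, and aggregate the results into
hierarchical ranks. A method that aborts contributes a row of NAs and is
ranked last, never aborting the run.

All randomness derives from a single master seed through stable
per-stage/per-method child seeds, so adding a method to the config does
not perturb any other method's results.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np

from . import cytomulate, io_prep
from ._types import Embedding, ExpressionMatrix, LabelVector, as_labels, as_matrix
from .aggregate import DEFAULT_TREE, MetricSpec, RankTable, ScoreTable, aggregate_scores
from .dr_registry import child_seed, run_dr, subsample_fit_map
from .metrics_concordance import (
    cluster_distance,
    common_cell_types,
    concordance_emd,
    gating_concordance,
    rank_distance_centroids,
)
from .metrics_downstream import (
    ari,
    calinski_harabasz,
    cluster_embedding,
    davies_bouldin,
    nmi,
    rf_cluster_prediction,
    silhouette,
)
from .metrics_structure import (
    build_neighbors,
    compute_pcd,
    global_emd,
    global_spearman,
    knn_score,
    npe,
)

logger = logging.getLogger("cytobench")

__all__ = ["BenchmarkConfig", "BenchmarkResult", "run_benchmark", "make_fixture",
           "score_embedding"]


@dataclass
class BenchmarkConfig:
    """Everything one benchmark run needs.

    Either ``expression``/``cell_types`` are given directly, or a
    simulation is requested via ``simulate_kwargs`` (forwarded to
    :func:`cytomulate.default_model` plus ``n_cells``).
    """

    methods: list[str]
    expression: ExpressionMatrix | None = None
    cell_types: LabelVector | None = None
    simulate_kwargs: dict | None = None
    method_params: dict[str, dict] = field(default_factory=dict)
    subsample: dict[str, float] = field(default_factory=dict)  # method -> fraction
    k_neighbors: int = 100
    n_clusters_hint: int | None = None
    clustering_algorithm: str = "kmeans"
    rna_expression: ExpressionMatrix | None = None
    rna_cell_types: LabelVector | None = None
    seed: int = 0

    def __post_init__(self):
        if not self.methods:
            raise ValueError("at least one DR method required")


@dataclass
class BenchmarkResult:
    scores: ScoreTable
    ranks: RankTable
    embeddings: dict[str, Embedding | None]
    failures: dict[str, str]
    labels: LabelVector
    cell_types: LabelVector


def _metric_tree(with_scrna: bool) -> list[MetricSpec]:
    if with_scrna:
        return list(DEFAULT_TREE)
    return [m for m in DEFAULT_TREE if m.major != "scrna"]


def score_embedding(
    X,
    emb,
    labels,
    cell_types=None,
    k: int = 100,
    n_clusters_hint: int | None = None,
    clustering_algorithm: str = "kmeans",
    rna_expression=None,
    rna_cell_types=None,
    seed: int = 0,
    nb_orig=None,
    pcd_orig=None,
) -> dict[str, float]:
    """Compute every applicable metric for one embedding.

    ``labels`` is the original-space clustering; ``cell_types`` the
    annotated types (defaults to the clustering). Precomputed
    original-space neighbor sets / PCD can be passed to avoid
    recomputation across methods.
    """
    data = as_matrix(X)
    lab = as_labels(labels)
    ct = as_labels(cell_types) if cell_types is not None else lab
    hint = n_clusters_hint or len(np.unique(lab))

    if pcd_orig is None:
        pcd_orig = compute_pcd(data, labels=lab)
    if nb_orig is None:
        nb_orig = build_neighbors(data, k=k, seed=child_seed(seed, "nn", "orig"))

    def safe(fn, *args, **kwargs):
        # one metric failing (degenerate geometry, singleton class, ...)
        # becomes an NA for that metric only
        try:
            return fn(*args, **kwargs)
        except Exception:  # noqa: BLE001
            return float("nan")

    out: dict[str, float] = {}
    pcd_emb = compute_pcd(emb, labels=lab)
    out["cor"] = safe(global_spearman, pcd_orig, pcd_emb)
    out["emd"] = safe(global_emd, pcd_orig, pcd_emb)

    nb_emb = build_neighbors(emb, k=k, seed=child_seed(seed, "nn", "emb"))
    out["knn"] = safe(knn_score, nb_orig, nb_emb)
    out["npe"] = safe(npe, nb_orig, nb_emb, lab)

    out["silhouette"] = safe(silhouette, emb, lab)
    out["dbi"] = safe(davies_bouldin, emb, lab)
    out["chi"] = safe(calinski_harabasz, emb, lab)
    out["rf"] = safe(rf_cluster_prediction, emb, lab, seed=child_seed(seed, "rf"))

    emb_clusters = cluster_embedding(
        emb, hint, algorithm=clustering_algorithm, seed=child_seed(seed, "clust")
    )
    out["cc_ari"] = safe(ari, lab, emb_clusters)
    out["cc_nmi"] = safe(nmi, lab, emb_clusters)
    out["ct_ari"] = safe(ari, ct, emb_clusters)
    out["ct_nmi"] = safe(nmi, ct, emb_clusters)

    if rna_expression is not None and rna_cell_types is not None:
        # embedding-space cell typing: majority type within each
        # embedding-space cluster
        emb_types = _majority_types(emb_clusters, ct)
        common = common_cell_types(emb_types, rna_cell_types)
        if len(common) >= 2:
            rv_cytof = rank_distance_centroids(emb, emb_types, common)
            rv_rna = rank_distance_centroids(rna_expression, rna_cell_types, common)
            out["cluster_distance"] = cluster_distance(rv_cytof, rv_rna)
            out["concordance_emd"] = concordance_emd(
                emb, emb_types, rna_expression, rna_cell_types, common
            )
        else:
            out["cluster_distance"] = float("nan")
            out["concordance_emd"] = float("nan")
        gate = gating_concordance(ct, emb_types)
        out["gating_ari"] = gate["ari"]
        out["gating_nmi"] = gate["nmi"]
    return out


def _majority_types(clusters, cell_types) -> np.ndarray:
    cl = as_labels(clusters)
    ct = as_labels(cell_types)
    out = np.empty(len(cl), dtype=object)
    for c in np.unique(cl):
        mask = cl == c
        vals, counts = np.unique(ct[mask], return_counts=True)
        out[mask] = vals[np.argmax(counts)]
    return out


def run_benchmark(config: BenchmarkConfig) -> BenchmarkResult:
    """Run every configured method and aggregate their metric ranks."""
    t0 = time.time()
    if config.expression is not None:
        X = config.expression
        ct = config.cell_types
        if ct is None:
            raise ValueError("cell_types required with explicit expression input")
    else:
        sim_kwargs = dict(config.simulate_kwargs or {})
        n_cells = sim_kwargs.pop("n_cells", 5000)
        model = cytomulate.default_model(
            seed=child_seed(config.seed, "simulate", "model"), **sim_kwargs
        )
        sample = cytomulate.simulate(
            model, n_cells, seed=child_seed(config.seed, "simulate", "draw")
        )
        X, ct = sample.expression, sample.cell_types
    lab = ct  # original-space clustering defaults to the provided typing
    logger.info("stage=input n_cells=%d n_markers=%d", X.n_cells, X.n_markers)

    data = as_matrix(X)
    pcd_orig = compute_pcd(data, labels=as_labels(lab))
    nb_orig = build_neighbors(
        data, k=config.k_neighbors, seed=child_seed(config.seed, "nn", "orig")
    )

    with_scrna = config.rna_expression is not None and config.rna_cell_types is not None
    tree = _metric_tree(with_scrna)
    names = [m.name for m in tree]

    values = np.full((len(config.methods), len(tree)), np.nan)
    embeddings: dict[str, Embedding | None] = {}
    failures: dict[str, str] = {}
    for i, method in enumerate(config.methods):
        seed_m = child_seed(config.seed, "dr", method)
        params = config.method_params.get(method)
        t_m = time.time()
        if method in config.subsample:
            res = subsample_fit_map(
                method, data, fraction=config.subsample[method], params=params, seed=seed_m
            )
        else:
            res = run_dr(method, data, params=params, seed=seed_m)
        if not res.ok:
            embeddings[method] = None
            failures[method] = res.message
            logger.info("stage=dr method=%s status=error msg=%r", method, res.message)
            continue
        embeddings[method] = res.embedding
        try:
            scores = score_embedding(
                data,
                res.embedding,
                lab,
                cell_types=ct,
                k=config.k_neighbors,
                n_clusters_hint=config.n_clusters_hint,
                clustering_algorithm=config.clustering_algorithm,
                rna_expression=config.rna_expression,
                rna_cell_types=config.rna_cell_types,
                seed=child_seed(config.seed, "metrics", method),
                nb_orig=nb_orig,
                pcd_orig=pcd_orig,
            )
            values[i] = [scores.get(n, np.nan) for n in names]
        except Exception as exc:  # noqa: BLE001 - metric failure = NA row
            failures[method] = f"{type(exc).__name__}: {exc}"
        logger.info(
            "stage=metrics method=%s elapsed=%.2fs", method, time.time() - t_m
        )

    if all(m in failures for m in config.methods):
        raise RuntimeError("all DR methods failed; nothing to rank")

    scores = ScoreTable(methods=list(config.methods), metrics=tree, values=values)
    ranks = aggregate_scores(scores)
    logger.info("stage=done elapsed=%.2fs", time.time() - t0)
    return BenchmarkResult(
        scores=scores,
        ranks=ranks,
        embeddings=embeddings,
        failures=failures,
        labels=lab,
        cell_types=ct,
    )


def make_fixture(
    kind: str,
    out_dir: str,
    n_cells: int = 3000,
    n_types: int = 3,
    n_markers: int = 20,
    seed: int = 0,
    jitter: float = 0.0,
) -> dict[str, str]:
    """Write a small ground-truthed dataset to ``out_dir``.

    ``blobs`` — childless types (pure Gaussian mixture); ``trajectory``
    — one differentiation tree with pseudotime recorded; ``two_modality``
    — a blobs sample plus a jittered copy sharing cell types, for
    exercising the cross-modality metrics (jitter 0 makes the second
    modality an exact copy).
    """
    import os

    os.makedirs(out_dir, exist_ok=True)
    paths: dict[str, str] = {}
    if kind == "blobs":
        model = cytomulate.default_model(n_types, n_markers, n_trees=n_types, seed=seed)
        sample = cytomulate.simulate(model, n_cells, seed=child_seed(seed, "fixture", kind))
    elif kind == "trajectory":
        model = cytomulate.default_model(n_types, n_markers, n_trees=1, seed=seed)
        sample = cytomulate.simulate(model, n_cells, seed=child_seed(seed, "fixture", kind))
        paths["pseudotime"] = os.path.join(out_dir, "pseudotime.csv")
        np.savetxt(
            paths["pseudotime"],
            sample.pseudotimes,
            delimiter=",",
            header=",".join(sample.expression.marker_names),
            comments="",
        )
    elif kind == "two_modality":
        model = cytomulate.default_model(n_types, n_markers, n_trees=n_types, seed=seed)
        sample = cytomulate.simulate(model, n_cells, seed=child_seed(seed, "fixture", kind))
        rng = np.random.default_rng(child_seed(seed, "fixture", "jitter"))
        second = sample.expression.values + (
            rng.normal(0.0, jitter, sample.expression.values.shape) if jitter > 0 else 0.0
        )
        paths["rna_expression"] = os.path.join(out_dir, "rna_expression.csv")
        io_prep.write_expression(
            ExpressionMatrix(second, sample.expression.marker_names),
            paths["rna_expression"],
        )
        paths["rna_types"] = os.path.join(out_dir, "rna_types.csv")
        io_prep.write_labels(sample.cell_types, paths["rna_types"], name="cell_type")
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")

    paths["expression"] = os.path.join(out_dir, "expression.csv")
    io_prep.write_expression(sample.expression, paths["expression"])
    paths["labels"] = os.path.join(out_dir, "labels.csv")
    io_prep.write_labels(sample.cell_types, paths["labels"], name="cell_type")
    return paths
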