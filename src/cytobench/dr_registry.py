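"""Uniform adapter layer over dimension-reduction back-ends.

Every registered method reduces a cells x markers matrix to a cells x 2
embedding through the same interface. Back-end exceptions are captured in
the returned :class:`DRResult` rather than propagated, so one aborting
method never takes down a benchmark run. Methods exposing an
out-of-sample mapping additionally support the subsample-fit-then-map
policy used for back-ends that cannot handle full CyTOF sample sizes:
fit on a 10% subsample (without replacement), map the remaining cells
onto the learned embedding.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Callable

import numpy as np

from ._types import Embedding, ExpressionMatrix, as_matrix

__all__ = [
    "DRResult",
    "register",
    "registered_methods",
    "run_dr",
    "subsample_fit_map",
    "child_seed",
]


@dataclass
class DRResult:
    """Outcome of one DR invocation: an embedding or a captured failure."""

    method_name: str
    status: str  # "ok" | "error"
    embedding: Embedding | None = None
    message: str = ""

    @property
    def ok(self) -> bool:
        return self.status == "ok"


# An adapter is a factory (params, seed) -> object with fit(X) returning a
# fitted state exposing transform(X) -> (n, 2); can_map says whether
# transform works on cells outside the training set.
_REGISTRY: dict[str, dict] = {}


def register(name: str, factory: Callable, can_map: bool = False) -> None:
    """Register a DR back-end under ``name`` (plug-in hook)."""
    _REGISTRY[name] = {"factory": factory, "can_map": can_map}


def registered_methods() -> list[str]:
    return sorted(_REGISTRY)


def child_seed(master: int | None, *tags: str) -> int:
    """Derive a stable child seed from a master seed and string tags.

    Hash-based so that adding or removing one method/stage never perturbs
    the seeds of the others. Result is in [0, 2^31).
    """
    base = 0 if master is None else int(master)
    h = zlib.crc32(":".join(tags).encode("utf-8"))
    return (base * 1_000_003 + h) % (2**31)


class _SklearnAdapter:
    """Wrap an estimator with fit/transform into the adapter protocol."""

    def __init__(self, est, preprocess: Callable | None = None):
        self.est = est
        self.preprocess = preprocess
        self._offset = None

    def _prep(self, X: np.ndarray) -> np.ndarray:
        if self.preprocess is None:
            return X
        return self.preprocess(self, X)

    def fit(self, X: np.ndarray) -> "_SklearnAdapter":
        self.est.fit(self._prep(X))
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(self.est.transform(self._prep(X)), dtype=float)


class _FitTransformOnly:
    """Adapter for back-ends without out-of-sample mapping (e.g. t-SNE)."""

    def __init__(self, est):
        self.est = est
        self._emb = None

    def fit(self, X: np.ndarray) -> "_FitTransformOnly":
        self._emb = np.asarray(self.est.fit_transform(X), dtype=float)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self._emb is None or len(self._emb) != len(X):
            raise RuntimeError("back-end has no out-of-sample mapping")
        return self._emb


def _shift_nonneg(adapter: _SklearnAdapter, X: np.ndarray) -> np.ndarray:
    # NMF requires non-negative input; shift each column by the training
    # minima (frozen at fit time so mapped cells use the same shift).
    if adapter._offset is None:
        adapter._offset = X.min(axis=0)
    return np.clip(X - adapter._offset, 0.0, None)


def _make_pca(params, seed):
    from sklearn.decomposition import PCA

    return _SklearnAdapter(PCA(n_components=2, **params))


def _make_ica(params, seed):
    from sklearn.decomposition import FastICA

    params.setdefault("max_iter", 500)
    return _SklearnAdapter(FastICA(n_components=2, random_state=seed, **params))


def _make_fa(params, seed):
    from sklearn.decomposition import FactorAnalysis

    return _SklearnAdapter(FactorAnalysis(n_components=2, random_state=seed, **params))


def _make_nmf(params, seed):
    from sklearn.decomposition import NMF

    params.setdefault("init", "nndsvda")
    params.setdefault("max_iter", 500)
    return _SklearnAdapter(
        NMF(n_components=2, random_state=seed, **params), preprocess=_shift_nonneg
    )


def _make_kpca(kernel):
    def make(params, seed):
        from sklearn.decomposition import KernelPCA

        return _SklearnAdapter(
            KernelPCA(n_components=2, kernel=kernel, random_state=seed, **params)
        )

    return make


def _make_isomap(params, seed):
    from sklearn.manifold import Isomap

    return _SklearnAdapter(Isomap(n_components=2, **params))


def _make_lle(params, seed):
    from sklearn.manifold import LocallyLinearEmbedding

    return _SklearnAdapter(
        LocallyLinearEmbedding(n_components=2, random_state=seed, **params)
    )


def _make_spectral(params, seed):
    from sklearn.manifold import SpectralEmbedding

    return _FitTransformOnly(SpectralEmbedding(n_components=2, random_state=seed, **params))


def _make_tsne(params, seed):
    from sklearn.manifold import TSNE

    params.setdefault("init", "pca")
    return _FitTransformOnly(TSNE(n_components=2, random_state=seed, **params))


def _make_umap(params, seed):
    import umap

    return _SklearnAdapter(umap.UMAP(n_components=2, random_state=seed, **params))


class _ShuffledProjection:
    """Negative-control 'DR': random 2-D projection with shuffled rows.

    Projects onto a random orthonormal 2-D basis, then permutes the rows,
    destroying any correspondence between a cell and its coordinates.
    Serves as a floor for accuracy and stability comparisons.
    """

    def __init__(self, seed):
        self.rng = np.random.default_rng(seed)
        self.basis = None

    def fit(self, X: np.ndarray) -> "_ShuffledProjection":
        q, _ = np.linalg.qr(self.rng.normal(size=(X.shape[1], 2)))
        self.basis = q
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        emb = X @ self.basis
        return emb[self.rng.permutation(len(emb))]


register("pca", _make_pca, can_map=True)
register("ica", _make_ica, can_map=True)
register("fa", _make_fa, can_map=True)
register("nmf", _make_nmf, can_map=True)
register("kpca_rbf", _make_kpca("rbf"), can_map=True)
register("kpca_poly", _make_kpca("poly"), can_map=True)
register("isomap", _make_isomap, can_map=True)
register("lle", _make_lle, can_map=True)
register("spectral", _make_spectral, can_map=False)
register("tsne", _make_tsne, can_map=False)
register("umap", _make_umap, can_map=True)
register("shuffled_projection", lambda params, seed: _ShuffledProjection(seed), can_map=False)


def run_dr(
    method_name: str,
    X: ExpressionMatrix | np.ndarray,
    params: dict | None = None,
    seed: int | None = None,
) -> DRResult:
    """Run one registered method on the full matrix, capturing failures."""
    if method_name not in _REGISTRY:
        raise KeyError(f"unregistered DR method {method_name!r}")
    data = as_matrix(X)
    try:
        adapter = _REGISTRY[method_name]["factory"](dict(params or {}), seed)
        coords = adapter.fit(data).transform(data)
        return DRResult(method_name, "ok", embedding=Embedding(coords=coords))
    except Exception as exc:  # noqa: BLE001 - failure isolation is the contract
        return DRResult(method_name, "error", message=f"{type(exc).__name__}: {exc}")


def subsample_fit_map(
    method_name: str,
    X: ExpressionMatrix | np.ndarray,
    fraction: float = 0.1,
    params: dict | None = None,
    seed: int | None = None,
) -> DRResult:
    """Fit on a random subsample, map all cells onto the embedding.

    ``floor(fraction * N)`` cells are sampled without replacement for
    fitting; the returned embedding covers all N cells in original row
    order. Requires a back-end with out-of-sample mapping.
    """
    if method_name not in _REGISTRY:
        raise KeyError(f"unregistered DR method {method_name!r}")
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    if not _REGISTRY[method_name]["can_map"]:
        raise ValueError(f"method {method_name!r} has no out-of-sample mapping")
    data = as_matrix(X)
    n = len(data)
    n_fit = max(2, int(np.floor(fraction * n)))
    rng = np.random.default_rng(seed)
    idx = rng.choice(n, size=min(n_fit, n), replace=False)
    try:
        adapter = _REGISTRY[method_name]["factory"](dict(params or {}), seed)
        adapter.fit(data[idx])
        coords = adapter.transform(data)
        return DRResult(method_name, "ok", embedding=Embedding(coords=coords))
    except Exception as exc:  # noqa: BLE001
        return DRResult(method_name, "error", message=f"{type(exc).__name__}: {exc}")
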