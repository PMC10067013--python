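"""Probabilistic CyTOF simulator with ground-truth cell types and lineage.

The generative model works on the arcsinh scale. A sample of N cells over
M protein markers and P cell types is produced as follows:

1. Each cell draws a type from ``Categorical(pi)``.
2. Without differentiation or noise, marker m of a type-p cell is
   ``x_m ~ Normal(mu[p, m], sigma[p, m]^2)``. Each type carries a null
   set of unexpressed markers for which ``mu = sigma = 0``.
3. Cell types are arranged in a differentiation forest. A cell whose type
   has children picks one child uniformly; for each marker a
   differentiation path ``g`` with ``g(0) = 0`` and
   ``g(1) = mu_child - mu_parent`` is evaluated at a per-marker
   pseudotime ``t ~ Beta(0.4, 1)``, interpolating the cell between the
   parent and child expression programs.
4. Measurement noise ``e ~ Normal(0, noise_sd^2)`` is added per marker:
   ``Y = x + g(t) + e``.

The Beta(0.4, 1) pseudotime prior concentrates cells near the parent
state with a thinning tail toward the child, mimicking the density decay
seen along real differentiation trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import yaml

from ._types import ExpressionMatrix, LabelVector

PSEUDOTIME_ALPHA = 0.4
PSEUDOTIME_BETA = 1.0

__all__ = [
    "SimulationModel",
    "SimulatedSample",
    "sample_cell_types",
    "sample_pseudotime",
    "differentiation_path",
    "simulate",
    "default_model",
    "load_model",
    "save_model",
    "PSEUDOTIME_ALPHA",
    "PSEUDOTIME_BETA",
]


@dataclass
class SimulationModel:
    """Parameters of the generative model.

    Attributes
    ----------
    pi
        Length-P cell-type prior; non-negative, sums to 1.
    mu, sigma
        P x M matrices of per-type marker means and SDs (arcsinh scale).
    null_sets
        Per-type sets of marker indices the type does not express; the
        model forces ``mu = sigma = 0`` there.
    children
        Per-type lists of child type indices defining the
        differentiation forest (each type has at most one parent, no
        cycles). Types are indexed 0..P-1.
    noise_sd
        SD of the additive background noise e.
    path_kind
        ``"linear"`` for the straight path between parent and child
        means, ``"bridge"`` for a Brownian-bridge perturbation of it
        (scale ``bridge_sd``) pinned at both endpoints.
    shared_pseudotime
        If True, one pseudotime per cell is shared across markers;
        default draws an independent pseudotime per marker.
    """

    pi: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray
    null_sets: list[set[int]] = field(default_factory=list)
    children: list[list[int]] = field(default_factory=list)
    noise_sd: float = 0.2
    path_kind: str = "linear"
    bridge_sd: float = 0.0
    shared_pseudotime: bool = False

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        self.mu = np.atleast_2d(np.asarray(self.mu, dtype=float))
        self.sigma = np.atleast_2d(np.asarray(self.sigma, dtype=float))
        P = self.pi.size
        if not self.null_sets:
            self.null_sets = [set() for _ in range(P)]
        self.null_sets = [set(int(i) for i in s) for s in self.null_sets]
        if not self.children:
            self.children = [[] for _ in range(P)]
        self.children = [[int(c) for c in ch] for ch in self.children]
        self.validate()

    @property
    def n_types(self) -> int:
        return int(self.pi.size)

    @property
    def n_markers(self) -> int:
        return int(self.mu.shape[1])

    def validate(self) -> None:
        P, M = self.mu.shape
        if self.pi.size != P or self.sigma.shape != (P, M):
            raise ValueError("pi / mu / sigma dimensions disagree")
        if np.any(self.pi < 0) or abs(self.pi.sum() - 1.0) > 1e-12:
            raise ValueError("pi must be non-negative and sum to 1")
        if np.any(self.sigma < 0):
            raise ValueError("sigma must be non-negative")
        if self.noise_sd < 0 or self.bridge_sd < 0:
            raise ValueError("noise_sd and bridge_sd must be non-negative")
        if self.path_kind not in ("linear", "bridge"):
            raise ValueError(f"unknown path_kind {self.path_kind!r}")
        if len(self.null_sets) != P or len(self.children) != P:
            raise ValueError("null_sets and children must have one entry per type")
        for p, s in enumerate(self.null_sets):
            for m in s:
                if not (0 <= m < M):
                    raise ValueError("null-set marker index out of range")
                if self.mu[p, m] != 0 or self.sigma[p, m] != 0:
                    raise ValueError(
                        "null markers must have mu = sigma = 0 "
                        f"(type {p}, marker {m})"
                    )
        # forest check: at most one parent per type, no cycles
        parent = [-1] * P
        for p, ch in enumerate(self.children):
            for c in ch:
                if not (0 <= c < P):
                    raise ValueError("child index out of range")
                if parent[c] != -1:
                    raise ValueError(f"type {c} has more than one parent")
                parent[c] = p
        for start in range(P):
            node, hops = start, 0
            while parent[node] != -1:
                node = parent[node]
                hops += 1
                if hops > P:
                    raise ValueError("children relation contains a cycle")

    def to_dict(self) -> dict:
        return {
            "pi": self.pi.tolist(),
            "mu": self.mu.tolist(),
            "sigma": self.sigma.tolist(),
            "null_sets": [sorted(s) for s in self.null_sets],
            "children": [list(c) for c in self.children],
            "noise_sd": float(self.noise_sd),
            "path": {"kind": self.path_kind, "bridge_sd": float(self.bridge_sd)},
            "shared_pseudotime": bool(self.shared_pseudotime),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationModel":
        path = d.get("path", {})
        return cls(
            pi=np.asarray(d["pi"], dtype=float),
            mu=np.asarray(d["mu"], dtype=float),
            sigma=np.asarray(d["sigma"], dtype=float),
            null_sets=[set(s) for s in d.get("null_sets", [])],
            children=[list(c) for c in d.get("children", [])],
            noise_sd=float(d.get("noise_sd", 0.2)),
            path_kind=path.get("kind", "linear"),
            bridge_sd=float(path.get("bridge_sd", 0.0)),
            shared_pseudotime=bool(d.get("shared_pseudotime", False)),
        )


@dataclass
class SimulatedSample:
    """Output of :func:`simulate`, with full ground truth retained."""

    expression: ExpressionMatrix
    cell_types: LabelVector
    child_targets: np.ndarray  # child type index per cell, -1 when none
    pseudotimes: np.ndarray  # cells x markers in [0, 1]


def load_model(path: str) -> SimulationModel:
    with open(path) as fh:
        return SimulationModel.from_dict(yaml.safe_load(fh))


def save_model(model: SimulationModel, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(model.to_dict(), fh)


def sample_cell_types(
    model: SimulationModel, n_cells: int, seed: int | None = None
) -> LabelVector:
    """Draw cell-type indices (0-based) from Categorical(pi)."""
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    return LabelVector(labels=rng.choice(model.n_types, size=n_cells, p=model.pi))


def sample_pseudotime(
    n: int, seed: int | None = None, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Draw n pseudotime values from the Beta(0.4, 1) differentiation prior."""
    if rng is None:
        rng = np.random.default_rng(seed)
    return rng.beta(PSEUDOTIME_ALPHA, PSEUDOTIME_BETA, size=n)


def differentiation_path(
    delta_mu: float,
    path_kind: str = "linear",
    bridge_sd: float = 0.0,
    seed: int | None = None,
    n_knots: int = 101,
) -> Callable[[np.ndarray], np.ndarray]:
    """Realize one differentiation path g: [0,1] -> R.

    Always satisfies ``g(0) = 0`` and ``g(1) = delta_mu`` exactly. The
    linear kind is the straight interpolation ``g(t) = t * delta_mu``;
    the bridge kind adds a Brownian bridge (scale ``bridge_sd``) realized
    on ``n_knots`` equispaced knots and linearly interpolated, so it is
    continuous and pinned at both endpoints. ``bridge_sd = 0`` reproduces
    the linear path.
    """
    if path_kind == "linear" or bridge_sd == 0.0:
        return lambda t: np.asarray(t, dtype=float) * float(delta_mu)
    if path_kind != "bridge":
        raise ValueError(f"unknown path_kind {path_kind!r}")
    rng = np.random.default_rng(seed)
    grid = np.linspace(0.0, 1.0, n_knots)
    dt = 1.0 / (n_knots - 1)
    steps = rng.normal(0.0, bridge_sd * np.sqrt(dt), size=n_knots - 1)
    walk = np.concatenate([[0.0], np.cumsum(steps)])
    bridge = walk - grid * walk[-1]
    knots = grid * float(delta_mu) + bridge
    knots[0], knots[-1] = 0.0, float(delta_mu)
    return lambda t: np.interp(np.asarray(t, dtype=float), grid, knots)


def simulate(
    model: SimulationModel, n_cells: int, seed: int | None = None
) -> SimulatedSample:
    """Generate a ground-truthed sample of ``n_cells`` cells.

    Identical (model, n_cells, seed) triples yield bit-identical samples.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    model.validate()
    rng = np.random.default_rng(seed)
    P, M = model.mu.shape

    types = rng.choice(P, size=n_cells, p=model.pi)
    child_targets = np.full(n_cells, -1, dtype=int)
    for p in range(P):
        ch = model.children[p]
        if not ch:
            continue
        mask = types == p
        child_targets[mask] = rng.choice(ch, size=int(mask.sum()))

    x = rng.normal(model.mu[types], model.sigma[types])

    if model.shared_pseudotime:
        t = np.repeat(sample_pseudotime(n_cells, rng=rng)[:, None], M, axis=1)
    else:
        t = sample_pseudotime(n_cells * M, rng=rng).reshape(n_cells, M)

    drift = np.zeros((n_cells, M))
    path_rng = np.random.default_rng(rng.integers(0, 2**31))
    for p in range(P):
        for c in model.children[p]:
            mask = (types == p) & (child_targets == c)
            if not mask.any():
                continue
            for m in range(M):
                g = differentiation_path(
                    model.mu[c, m] - model.mu[p, m],
                    path_kind=model.path_kind,
                    bridge_sd=model.bridge_sd,
                    seed=int(path_rng.integers(0, 2**31)),
                )
                drift[mask, m] = g(t[mask, m])

    e = rng.normal(0.0, model.noise_sd, size=(n_cells, M)) if model.noise_sd > 0 else 0.0
    y = x + drift + e

    names = [f"m{i + 1}" for i in range(M)]
    return SimulatedSample(
        expression=ExpressionMatrix(values=y, marker_names=names),
        cell_types=LabelVector(labels=types),
        child_targets=child_targets,
        pseudotimes=t,
    )


def default_model(
    n_types: int,
    n_markers: int,
    n_trees: int = 1,
    seed: int | None = None,
    noise_sd: float = 0.2,
    null_fraction: float = 0.3,
    path_kind: str = "linear",
    bridge_sd: float = 0.0,
    pi_floor: float = 0.02,
) -> SimulationModel:
    """Build a randomized but valid model for fixtures and benchmarks.

    Types are partitioned into ``n_trees`` differentiation trees; within
    a tree each non-root type attaches to a uniformly chosen earlier
    type. Root marker means are Normal(3, 1) truncated at zero — typical
    arcsinh-scale magnitudes for expressed CyTOF markers — and child
    means perturb their parent's by Normal(0, 1). Marker SDs are
    Uniform(0.2, 0.6). Each type silences a ``null_fraction`` share of
    markers (at least one marker stays expressed). The cell-type prior is
    Dirichlet(1, ..., 1) mixed toward uniform so that every type keeps at
    least ``pi_floor`` abundance and is observable in modest samples.
    """
    if not (1 <= n_trees <= n_types):
        raise ValueError("need 1 <= n_trees <= n_types")
    if n_markers < 1:
        raise ValueError("n_markers must be >= 1")
    rng = np.random.default_rng(seed)

    order = rng.permutation(n_types)
    tree_of = np.zeros(n_types, dtype=int)
    tree_of[order[:n_trees]] = np.arange(n_trees)
    if n_types > n_trees:
        tree_of[order[n_trees:]] = rng.integers(0, n_trees, size=n_types - n_trees)
    children: list[list[int]] = [[] for _ in range(n_types)]
    placed: dict[int, list[int]] = {k: [] for k in range(n_trees)}
    for p in order:
        k = int(tree_of[p])
        if placed[k]:
            parent = int(placed[k][rng.integers(0, len(placed[k]))])
            children[parent].append(int(p))
        placed[k].append(int(p))

    parent_of = {c: p for p, ch in enumerate(children) for c in ch}
    mu = np.zeros((n_types, n_markers))
    for p in order:  # parents are placed before children within a tree
        if int(p) in parent_of:
            base = mu[parent_of[int(p)]] + rng.normal(0.0, 1.0, n_markers)
        else:
            base = rng.normal(3.0, 1.0, n_markers)
        mu[p] = np.clip(base, 0.0, None)
    sigma = rng.uniform(0.2, 0.6, size=(n_types, n_markers))

    null_sets: list[set[int]] = []
    for p in range(n_types):
        null = set(np.nonzero(rng.random(n_markers) < null_fraction)[0].tolist())
        if len(null) == n_markers:
            null.discard(int(rng.integers(0, n_markers)))
        mu[p, list(null)] = 0.0
        sigma[p, list(null)] = 0.0
        null_sets.append(null)

    if not (0 <= pi_floor <= 1.0 / n_types):
        raise ValueError("pi_floor must lie in [0, 1/n_types]")
    pi = rng.dirichlet(np.ones(n_types))
    pi = pi * (1.0 - n_types * pi_floor) + pi_floor
    pi = pi / pi.sum()
    return SimulationModel(
        pi=pi,
        mu=mu,
        sigma=sigma,
        null_sets=null_sets,
        children=children,
        noise_sd=noise_sd,
        path_kind=path_kind,
        bridge_sd=bridge_sd,
    )
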