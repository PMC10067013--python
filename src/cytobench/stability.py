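"""Bootstrap stability of a dimension-reduction method.

A method is stable if perturbing the input barely changes the structure
of its output. The sample is bootstrapped B times (size-N draws with
replacement); the method is re-run on each resample with the same tuning
parameters; each resample's embedding is summarized by its flattened
Point-Cluster Distance vector (cluster labels carried through by
resampled index — re-clustering would confound method stability with
clustering stochasticity); and the min-max-normalized PCD vector is
compared with the reference embedding's via the 1-D Wasserstein
distance. The mean over bootstraps is the stability score (lower =
more stable).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._types import as_labels, as_matrix
from .dr_registry import child_seed, run_dr
from .metrics_structure import compute_pcd, minmax_normalize

__all__ = ["StabilityResult", "bootstrap_stability", "embedding_emd"]


@dataclass
class StabilityResult:
    per_bootstrap_emd: np.ndarray
    mean_emd: float
    b: int  # completed (non-failed) bootstrap iterations
    failures: int = 0


def embedding_emd(pcd_ref_flat: np.ndarray, pcd_boot_flat: np.ndarray) -> float:
    """Wasserstein distance between min-max-normalized flattened PCDs."""
    return float(
        stats.wasserstein_distance(
            minmax_normalize(pcd_ref_flat), minmax_normalize(pcd_boot_flat)
        )
    )


def bootstrap_stability(
    X,
    labels,
    dr_method: str,
    b: int = 100,
    seed: int | None = None,
    params: dict | None = None,
) -> StabilityResult:
    """Average embedding-distribution shift over ``b`` bootstrap resamples.

    The reference embedding is computed on the full sample. A method
    failure on the reference is a hard error; failures on individual
    bootstrap iterations are excluded from the mean and counted.
    """
    data = as_matrix(X)
    lab = as_labels(labels)
    n = len(data)
    ref = run_dr(dr_method, data, params=params, seed=child_seed(seed, "stability", "ref"))
    if not ref.ok:
        raise RuntimeError(f"reference embedding failed: {ref.message}")
    pcd_ref = compute_pcd(ref.embedding, labels=lab).flatten()

    rng = np.random.default_rng(child_seed(seed, "stability", "resample"))
    emds, failures = [], 0
    for i in range(b):
        idx = rng.integers(0, n, size=n)
        res = run_dr(
            dr_method,
            data[idx],
            params=params,
            seed=child_seed(seed, "stability", f"boot{i}"),
        )
        if not res.ok:
            failures += 1
            continue
        pcd_boot = compute_pcd(res.embedding, labels=lab[idx]).flatten()
        emds.append(embedding_emd(pcd_ref, pcd_boot))
    emds = np.asarray(emds, dtype=float)
    mean = float(emds.mean()) if len(emds) else float("nan")
    return StabilityResult(
        per_bootstrap_emd=emds, mean_emd=mean, b=len(emds), failures=failures
    )
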