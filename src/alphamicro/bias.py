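"""Selection-bias correction via inter-cell distance reweighting.

Manually chosen high-resolution fields oversample dense cell clusters.  The
correction compares the pairwise inter-cell distance distribution of the
acquired sample with an unbiased reference (from automated overview scans in
the real experiment; from the full synthetic population here) and fits
nonnegative per-cell weights c_j so the reweighted distribution matches the
reference.  The weights then enter every population average (mean dose,
colony surviving fraction) as frequency weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.spatial.distance import pdist


@dataclass
class DistanceDistribution:
    """Histogram of pairwise inter-cell distances."""

    bin_edges: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if len(self.counts) != len(self.bin_edges) - 1:
            raise ValueError("need one count per bin")
        if np.any(self.counts < 0):
            raise ValueError("frequencies must be nonnegative")

    @property
    def density(self) -> np.ndarray:
        total = self.counts.sum()
        return self.counts / total if total > 0 else self.counts


def pairwise_distance_distribution(
    positions: np.ndarray, bins: np.ndarray
) -> DistanceDistribution:
    """Histogram of all n(n−1)/2 Euclidean pairwise distances."""
    positions = np.asarray(positions, dtype=float)
    if positions.ndim != 2 or len(positions) < 2:
        raise ValueError("need at least two positions")
    d = pdist(positions)
    counts, edges = np.histogram(d, bins=np.asarray(bins, dtype=float))
    return DistanceDistribution(bin_edges=edges, counts=counts.astype(float))


def per_cell_distance_profiles(
    positions: np.ndarray, bins: np.ndarray
) -> np.ndarray:
    """Per-cell histograms of distances to every other cell in the field.

    Returns an (n_cells, n_bins) matrix H; the pooled pairwise histogram is
    H.sum(0) / 2 (each pair appears in both cells' profiles).
    """
    positions = np.asarray(positions, dtype=float)
    if positions.ndim != 2 or len(positions) < 2:
        raise ValueError("need at least two positions")
    bins = np.asarray(bins, dtype=float)
    n = len(positions)
    H = np.empty((n, len(bins) - 1))
    for j in range(n):
        d = np.linalg.norm(positions - positions[j], axis=1)
        d = np.delete(d, j)
        H[j], _ = np.histogram(d, bins=bins)
    return H


def fit_selection_weights(
    profiles: np.ndarray,
    target: DistanceDistribution,
    method: str = "powell",
    warm_start: bool = True,
    tol: float = 1e-6,
    maxfev: int = 10_000,
) -> tuple[np.ndarray, bool]:
    """Fit nonnegative per-cell weights matching the target distance distribution.

    The objective is the L2 distance between the normalized reweighted
    histogram Σ_j c_j h_j and the normalized target.  A derivative-free
    Powell search (the field-standard choice for this fit) runs from a
    nonnegative least-squares warm start; if it fails to beat uniform
    weights, uniform weights are returned with the convergence flag False.
    Weights are normalized to mean 1.

    Returns ``(weights, converged)``.
    """
    H = np.asarray(profiles, dtype=float)
    if H.ndim != 2:
        raise ValueError("profiles must be (n_cells, n_bins)")
    n_cells = H.shape[0]
    t_hat = target.density
    if H.shape[1] != len(t_hat):
        raise ValueError("profiles and target must share bins")
    if n_cells == 1:
        return np.ones(1), True

    def objective(c: np.ndarray) -> float:
        c = np.clip(c, 0.0, None)
        mix = H.T @ c
        total = mix.sum()
        if total <= 0:
            return np.inf
        return float(np.linalg.norm(mix / total - t_hat))

    uniform = np.ones(n_cells)
    f_uniform = objective(uniform)
    if f_uniform <= tol:  # acquired sample already matches the target
        return uniform, True

    x0 = uniform.copy()
    if warm_start:
        c_nnls, _ = optimize.nnls(H.T, t_hat)
        if c_nnls.sum() > 0:
            x0 = c_nnls / c_nnls.mean()
        if objective(x0) <= tol:
            return x0 / x0.mean(), True

    res = optimize.minimize(
        objective,
        x0=x0,
        method=method,
        bounds=[(0.0, None)] * n_cells,
        options={"ftol": tol, "maxfev": maxfev} if method == "powell" else None,
    )
    best = np.clip(res.x, 0.0, None)
    converged = bool(res.success)
    if objective(best) > f_uniform:
        best, converged = uniform, False
    if best.sum() == 0:
        best = uniform
    return best / best.mean(), converged


def weighted_mean(values: np.ndarray, weights: np.ndarray) -> float:
    """Bias-corrected population average Σ c_j v_j / Σ c_j."""
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if values.shape != weights.shape:
        raise ValueError("values and weights must align")
    if np.any(weights < 0):
        raise ValueError("weights must be nonnegative")
    total = weights.sum()
    if total <= 0:
        raise ValueError("weights must have positive sum")
    return float(np.dot(weights, values) / total)
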