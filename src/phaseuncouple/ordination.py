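"""Non-metric multidimensional scaling (NMDS) of a dissimilarity matrix.

SMACOF majorization alternated with isotonic (monotone) regression of the
configuration distances on the dissimilarity order; fit quality is Kruskal
stress-1.  The best solution over seeded random restarts is returned, so
results are deterministic given the seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.isotonic import IsotonicRegression

from .chardist import DistanceMatrix


@dataclass
class OrdinationResult:
    """NMDS solution: centered coordinates plus Kruskal stress-1."""

    coords: np.ndarray          # (n, k), column means 0
    stress: float               # Kruskal stress-1 in [0, 1]
    k: int
    seed: int
    n_iter: int
    species: list[str] | None = None
    stress_path: np.ndarray = field(default=None, repr=False)


def _stress_and_disparities(d: np.ndarray, delta: np.ndarray,
                            delta_order: np.ndarray,
                            iso: IsotonicRegression) -> tuple[float, np.ndarray]:
    """Kruskal stress-1 for configuration distances d (condensed form).

    Regressing on the dissimilarity values themselves (not their rank
    positions) makes tied dissimilarities share one disparity (the
    tie-averaging "secondary" approach), so ties do constrain the fit.
    """
    dhat = np.empty_like(d)
    dhat[delta_order] = iso.fit_transform(
        delta[delta_order], d[delta_order]
    )
    denom = float(np.sum(d * d))
    if denom <= 0:
        return 1.0, dhat
    stress = np.sqrt(np.sum((d - dhat) ** 2) / denom)
    return float(stress), dhat


def _condensed(M: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(M.shape[0], 1)
    return M[iu]


def kruskal_stress(coords: np.ndarray, D) -> float:
    """Kruskal stress-1 of a configuration against a dissimilarity matrix."""
    M = D.matrix if isinstance(D, DistanceMatrix) else np.asarray(D, float)
    X = np.asarray(coords, dtype=float)
    iu = np.triu_indices(M.shape[0], 1)
    diff = X[:, None, :] - X[None, :, :]
    d = np.sqrt((diff ** 2).sum(-1))[iu]
    delta = M[iu]
    order = np.argsort(delta, kind="stable")
    stress, _ = _stress_and_disparities(d, delta, order,
                                        IsotonicRegression(increasing=True))
    return stress


def fit_nmds(D, k: int = 2, seed: int = 0, restarts: int = 20,
             max_iter: int = 500, tol: float = 1e-6) -> OrdinationResult:
    """Fit NMDS; returns the lowest-stress solution over ``restarts``."""
    species = None
    if isinstance(D, DistanceMatrix):
        species = list(D.species)
        M = D.matrix
    else:
        M = np.asarray(D, dtype=float)
    n = M.shape[0]
    if M.shape != (n, n) or not np.allclose(M, M.T):
        raise ValueError("D must be a symmetric square matrix")
    if np.isnan(M).any():
        raise ValueError("D contains NaN (use a complete distance matrix)")
    if n < k + 2:
        raise ValueError("need at least k+2 objects")
    delta = _condensed(M)
    if np.all(delta == 0):
        raise ValueError("degenerate distance matrix (all zeros)")
    delta_order = np.argsort(delta, kind="stable")
    iso = IsotonicRegression(increasing=True)
    iu = np.triu_indices(n, 1)

    best = None
    master = np.random.default_rng(seed)
    for _ in range(max(1, restarts)):
        rng = np.random.default_rng(master.integers(2**31))
        X = rng.normal(size=(n, k))
        prev = np.inf
        path = []
        for it in range(1, max_iter + 1):
            diff = X[:, None, :] - X[None, :, :]
            dmat = np.sqrt((diff ** 2).sum(-1))
            d = dmat[iu]
            stress, dhat = _stress_and_disparities(d, delta, delta_order, iso)
            path.append(stress)
            if prev - stress < tol:
                prev = stress
                break
            prev = stress
            # Guttman transform toward the disparities
            W = np.zeros((n, n))
            W[iu] = dhat
            W += W.T
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(dmat > 0, W / np.where(dmat > 0, dmat, 1.0), 0.0)
            B = -ratio
            np.fill_diagonal(B, ratio.sum(1))
            X = (B @ X) / n
            X -= X.mean(0)
        X -= X.mean(0)
        # unit RMS pairwise distance: stress is scale-free, downstream
        # trait analyses want a stable coordinate scale
        diff = X[:, None, :] - X[None, :, :]
        rms = np.sqrt((diff ** 2).sum(-1)[iu].mean())
        if rms > 0:
            X = X / rms
        if best is None or prev < best.stress - 1e-12:
            best = OrdinationResult(X, float(prev), k, seed, it,
                                    species, np.asarray(path))
    return best


def axis_variance_order(result: OrdinationResult) -> OrdinationResult:
    """Reorder axes by decreasing variance with a deterministic sign rule.

    Ties keep the original axis order; each axis is flipped, if needed, so
    its largest-magnitude loading is positive.
    """
    var = result.coords.var(axis=0)
    order = np.argsort(-var, kind="stable")
    coords = result.coords[:, order].copy()
    for j in range(coords.shape[1]):
        i = np.argmax(np.abs(coords[:, j]))
        if coords[i, j] < 0:
            coords[:, j] = -coords[:, j]
    return OrdinationResult(coords, result.stress, result.k, result.seed,
                            result.n_iter, result.species, result.stress_path)
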