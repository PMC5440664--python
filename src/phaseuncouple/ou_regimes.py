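"""Multi-optimum Ornstein-Uhlenbeck regime-shift detection.

A regime painting assigns every branch to a selective regime; shifts sit on
branches and apply to the whole descendant clade until overridden by a more
recent shift.  For each trait axis the model has one attraction strength
``alpha`` (1/Myr), one diffusion ``sigma2`` and a per-regime optimum
``theta``; all axes share a single painting.  The forward search adds, one
at a time, the shift that most decreases the summed-across-axes AICc; the
backward phase merges ("collapses") regime pairs toward convergent optima;
the significance of the number of collapses is assessed against simulations
from the fitted non-convergent model.

The root state equals the root-regime optimum.  With alpha -> 0 the model
tends to Brownian motion.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .phylo_io import Phylogeny
from .traits import simulate_ou

LOG2PI = np.log(2.0 * np.pi)


# ---------------------------------------------------------------------------
# paintings
# ---------------------------------------------------------------------------

@dataclass
class RegimePainting:
    """Branch -> regime map derived from a set of shift branches.

    Regime 0 is the root regime; shift ``i`` (in the stored order) creates
    regime ``i + 1``.  ``branch_regime`` is node-indexed (entry at the root
    gives the root regime).
    """

    tree: Phylogeny
    shift_branches: list[int]
    branch_regime: np.ndarray = field(default=None)

    def __post_init__(self):
        shifts = list(self.shift_branches)
        if len(set(shifts)) != len(shifts):
            raise ValueError("duplicate shift branches")
        for b in shifts:
            if b == self.tree.root or not 0 <= b < self.tree.n_nodes:
                raise ValueError(f"invalid shift branch {b}")
        regime_of_shift = {b: i + 1 for i, b in enumerate(shifts)}
        reg = np.zeros(self.tree.n_nodes, dtype=np.int64)
        for node in self.tree.preorder():
            if node == self.tree.root:
                reg[node] = 0
            else:
                reg[node] = regime_of_shift.get(node, reg[self.tree.parent[node]])
        self.branch_regime = reg

    @property
    def n_regimes(self) -> int:
        return len(self.shift_branches) + 1

    @property
    def shift_nodes(self) -> list[int]:
        """Parent nodes of the shift branches (the nodes where regimes split)."""
        return [int(self.tree.parent[b]) for b in self.shift_branches]


def painting_from_shifts(tree: Phylogeny, shifts) -> RegimePainting:
    return RegimePainting(tree, [int(b) for b in shifts])


# ---------------------------------------------------------------------------
# Hansen model likelihood
# ---------------------------------------------------------------------------

def _design_matrix(tree: Phylogeny, painting: RegimePainting, alpha: float,
                   regime_map=None) -> np.ndarray:
    """Tip-mean weights W with E[x_i] = W_i . theta (root optimum included).

    ``regime_map`` optionally relabels regimes (for backward merges): an
    array mapping original regime id -> effective optimum index.
    """
    n_reg = painting.n_regimes if regime_map is None else (
        int(np.max(regime_map)) + 1)
    reg = painting.branch_regime if regime_map is None else \
        np.asarray(regime_map)[painting.branch_regime]
    T = tree.T
    W = np.zeros((tree.n_tips, n_reg))
    pos = {int(t): k for k, t in enumerate(tree.tips)}
    for t in tree.tips:
        i = pos[int(t)]
        v = int(t)
        while v != tree.root:
            d0 = tree.depth[tree.parent[v]]
            d1 = tree.depth[v]
            w = np.exp(-alpha * (T - d1)) - np.exp(-alpha * (T - d0))
            W[i, reg[v]] += w
            v = int(tree.parent[v])
        # root state = root-regime optimum
        W[i, reg[tree.root]] += np.exp(-alpha * T)
    return W


def _cov_unit(tree_s: np.ndarray, tree_d: np.ndarray, alpha: float) -> np.ndarray:
    """OU tip covariance for sigma2 = 1 (fixed root):
    exp(-alpha d_ij) (1 - exp(-2 alpha s_ij)) / (2 alpha)."""
    return np.exp(-alpha * tree_d) * (-np.expm1(-2.0 * alpha * tree_s)) \
        / (2.0 * alpha)


def hansen_loglik(tree: Phylogeny, painting: RegimePainting, alpha: float,
                  sigma2: float, theta, x) -> float:
    """Dense multivariate-normal OU log-likelihood for one trait axis."""
    if alpha <= 0 or sigma2 <= 0:
        raise ValueError("alpha and sigma2 must be positive")
    theta = np.asarray(theta, dtype=float)
    x = np.asarray(x, dtype=float)
    W = _design_matrix(tree, painting, alpha)
    mean = W @ theta
    V = sigma2 * _cov_unit(tree.shared_depth_matrix(),
                           tree.patristic_matrix(), alpha)
    L = np.linalg.cholesky(V)
    resid = np.linalg.solve(L, x - mean)
    logdet = 2.0 * np.log(np.diag(L)).sum()
    return float(-0.5 * (tree.n_tips * LOG2PI + logdet + resid @ resid))


# ---------------------------------------------------------------------------
# fitting: alpha profiled over a grid + polish; theta by GLS; sigma2 analytic
# ---------------------------------------------------------------------------

class _HansenWorkspace:
    """Caches tree matrices and Cholesky factors per alpha."""

    def __init__(self, tree: Phylogeny):
        self.tree = tree
        self.S = tree.shared_depth_matrix()
        self.D = tree.patristic_matrix()
        self._chol: dict[float, np.ndarray] = {}

    def chol(self, alpha: float) -> np.ndarray:
        key = float(alpha)
        if key not in self._chol:
            V = _cov_unit(self.S, self.D, key)
            self._chol[key] = np.linalg.cholesky(
                V + 1e-12 * np.eye(V.shape[0]))
        return self._chol[key]


def _profile_axis(ws: _HansenWorkspace, painting: RegimePainting, x: np.ndarray,
                  alpha: float, regime_map=None):
    """theta by GLS and sigma2 analytic at fixed alpha; returns
    (logL, sigma2, theta)."""
    tree = ws.tree
    n = tree.n_tips
    L = ws.chol(alpha)
    W = _design_matrix(tree, painting, alpha, regime_map)
    Wt = np.linalg.solve(L, W)
    xt = np.linalg.solve(L, x)
    theta, *_ = np.linalg.lstsq(Wt, xt, rcond=None)
    resid = xt - Wt @ theta
    ss = float(resid @ resid)
    sigma2 = max(ss / n, 1e-12)
    logdet = 2.0 * np.log(np.diag(L)).sum()
    logL = -0.5 * (n * (LOG2PI + np.log(sigma2)) + logdet + n)
    return logL, sigma2, theta


def _fit_axis(ws: _HansenWorkspace, painting: RegimePainting, x: np.ndarray,
              alpha_grid: np.ndarray, regime_map=None, polish: bool = True):
    """Maximize the alpha profile over a grid, then polish the best point."""
    best = None
    for a in alpha_grid:
        logL, s2, th = _profile_axis(ws, painting, x, a, regime_map)
        if best is None or logL > best[0]:
            best = (logL, float(a), s2, th)
    if polish:
        lo = np.log(alpha_grid[0])
        hi = np.log(alpha_grid[-1])

        def neg(la):
            return -_profile_axis(ws, painting, x, np.exp(la), regime_map)[0]

        res = minimize_scalar(neg, bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-3})
        if np.isfinite(res.fun) and -res.fun > best[0]:
            a = float(np.exp(res.x))
            logL, s2, th = _profile_axis(ws, painting, x, a, regime_map)
            best = (logL, a, s2, th)
    return best  # (logL, alpha, sigma2, theta)


def _default_alpha_grid(tree: Phylogeny) -> np.ndarray:
    # alpha*T from 0.01 (essentially BM) to 500 (half-life ~ T/700)
    return np.geomspace(0.01, 500.0, 16) / tree.T


@dataclass
class OUFit:
    """Fitted multi-optimum OU model across one or more trait axes.

    ``aicc`` carries the placement-corrected criterion used for model
    selection; ``aicc_explore`` is the plain AICc (no multiplicity term)
    that drives the greedy exploration phase of the forward search.
    """

    painting: RegimePainting
    alpha: np.ndarray            # per axis (1/Myr)
    sigma2: np.ndarray           # per axis
    theta: list                  # per axis: optimum per effective regime
    logL: np.ndarray             # per axis
    aicc: float
    aicc_explore: float
    K: int
    regime_map: np.ndarray       # regime id -> effective optimum index

    @property
    def n_regimes(self) -> int:
        """Number of distinct optima after any backward merges."""
        return int(np.max(self.regime_map)) + 1

    def half_lives(self) -> np.ndarray:
        return np.log(2.0) / self.alpha


def half_life(alpha: float) -> float:
    """Phylogenetic half-life ln(2)/alpha (Myr)."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    return float(np.log(2.0) / alpha)


def _ou_aicc(logL_sum: float, n_optima: int, n_axes: int, n_shifts: int,
             n_tips: int) -> tuple[float, int]:
    """Multiplicity-corrected AICc for a shift configuration.

    K = axes*(optima + alpha + sigma2) + shifts, n = tips*axes observations.
    Because every shift is *selected* among all ~2*tips candidate branches,
    each placement additionally costs 2*ln(#branches); without this term a
    stepwise search accepts spurious shifts on null data almost surely
    (the best of B chi-square(1) improvements easily exceeds a flat
    2-unit penalty).
    """
    K = n_axes * (n_optima + 2) + n_shifts
    n = n_tips * n_axes
    if n - K - 1 <= 0:
        return np.inf, np.inf, K
    penalty = 2.0 * K * (K + 1) / (n - K - 1)
    n_branches = 2 * n_tips - 2
    placement = 2.0 * n_shifts * np.log(n_branches)
    base = -2.0 * logL_sum + 2.0 * K + penalty
    return base + placement, base, K


def _fit_painting(ws: _HansenWorkspace, painting: RegimePainting,
                  X: np.ndarray, alpha_grid, regime_map=None) -> OUFit:
    n_axes = X.shape[1]
    if regime_map is None:
        regime_map = np.arange(painting.n_regimes)
    alphas, s2s, thetas, logLs = [], [], [], []
    for j in range(n_axes):
        logL, a, s2, th = _fit_axis(ws, painting, X[:, j], alpha_grid,
                                    regime_map)
        alphas.append(a)
        s2s.append(s2)
        thetas.append(th)
        logLs.append(logL)
    n_optima = int(np.max(regime_map)) + 1
    aicc, aicc_explore, K = _ou_aicc(sum(logLs), n_optima, n_axes,
                                     len(painting.shift_branches),
                                     ws.tree.n_tips)
    return OUFit(painting, np.array(alphas), np.array(s2s), thetas,
                 np.array(logLs), aicc, aicc_explore, K,
                 np.asarray(regime_map))


def surface_forward(tree: Phylogeny, traits, max_shifts: int | None = None,
                    alpha_grid=None) -> list[OUFit]:
    """Stepwise regime-shift search: greedy exploration, then pruning.

    ``traits`` is (n_tips, k) in ``tree.tips`` order.  Exploration adds, one
    at a time, the shift that most decreases the summed-across-axes plain
    AICc (``aicc_explore``), stopping when no addition decreases it;
    candidates are screened at the incumbent per-axis alpha (theta by GLS)
    and the winner fully refitted, scanning branches in preorder so ties
    break deterministically.  Because each accepted shift is the best of
    ~2n candidate placements, the final model is then selected by backward
    elimination under the placement-corrected AICc (``aicc``), followed by
    a local relocation polish.  Returns the accepted exploration sequence
    with the pruned final model appended.
    """
    X = np.atleast_2d(np.asarray(traits, dtype=float))
    if X.shape[0] != tree.n_tips:
        X = X.T
    if X.shape[0] != tree.n_tips:
        raise ValueError("traits must have one row per tip")
    ws = _HansenWorkspace(tree)
    if alpha_grid is None:
        alpha_grid = _default_alpha_grid(tree)
    if max_shifts is None:
        max_shifts = max(2, tree.n_tips // 4)
    fits = [_fit_painting(ws, RegimePainting(tree, []), X, alpha_grid)]
    shifts: list[int] = []
    preorder_branches = [int(b) for b in tree.branches()]
    n_axes = X.shape[1]
    while len(shifts) < max_shifts:
        incumbent = fits[-1]
        best_b, best_screen = None, -np.inf
        for b in preorder_branches:
            if b in shifts:
                continue
            try:
                painting = RegimePainting(tree, shifts + [b])
                score = sum(
                    _profile_axis(ws, painting, X[:, j],
                                  float(incumbent.alpha[j]))[0]
                    for j in range(n_axes))
            except np.linalg.LinAlgError:
                warnings.warn(f"candidate shift at branch {b} skipped")
                continue
            if score > best_screen + 1e-12:
                best_screen, best_b = score, b
        if best_b is None:
            break
        cand = _fit_painting(ws, RegimePainting(tree, shifts + [best_b]),
                             X, alpha_grid)
        if cand.aicc_explore >= fits[-1].aicc_explore:
            break
        fits.append(cand)
        shifts = list(cand.painting.shift_branches)
    final = _relocate_shifts(ws, fits[-1], X, alpha_grid)
    final = _prune_shifts(ws, final, X, alpha_grid)
    final = _relocate_shifts(ws, final, X, alpha_grid)
    fits.append(final)
    return fits


def _prune_shifts(ws: _HansenWorkspace, fit: OUFit, X: np.ndarray,
                  alpha_grid) -> OUFit:
    """Backward elimination of shifts under the placement-corrected AICc."""
    tree = ws.tree
    current = fit
    while current.painting.shift_branches:
        shifts = list(current.painting.shift_branches)
        best = None
        for i in range(len(shifts)):
            trial = shifts[:i] + shifts[i + 1:]
            cand = _fit_painting(ws, RegimePainting(tree, trial), X,
                                 alpha_grid)
            if best is None or cand.aicc < best.aicc - 1e-12:
                best = cand
        if best is None or best.aicc >= current.aicc:
            break
        current = best
    return current


def _relocate_shifts(ws: _HansenWorkspace, fit: OUFit, X: np.ndarray,
                     alpha_grid) -> OUFit:
    """Local polish: try moving each shift to a neighbouring branch."""
    tree = ws.tree
    improved = True
    current = fit
    while improved:
        improved = False
        shifts = list(current.painting.shift_branches)
        for i, b in enumerate(shifts):
            neighbours = [int(tree.parent[b])] + [int(c) for c in
                                                  tree.children[b]]
            for nb in neighbours:
                if nb == tree.root or nb in shifts:
                    continue
                trial = shifts[:i] + [nb] + shifts[i + 1:]
                try:
                    cand = _fit_painting(ws, RegimePainting(tree, trial), X,
                                         alpha_grid)
                except np.linalg.LinAlgError:
                    continue
                if cand.aicc < current.aicc - 1e-9:
                    current = cand
                    shifts = trial
                    improved = True
    return current


def surface_backward(tree: Phylogeny, fit: OUFit, traits,
                     alpha_grid=None) -> tuple[OUFit, int]:
    """Iteratively collapse the regime pair whose merge most lowers AICc.

    Returns (final fit, number of collapses).  Collapsed regimes share one
    optimum per axis (convergence) while the painting keeps its shifts.
    """
    X = np.atleast_2d(np.asarray(traits, dtype=float))
    if X.shape[0] != tree.n_tips:
        X = X.T
    ws = _HansenWorkspace(tree)
    if alpha_grid is None:
        alpha_grid = _default_alpha_grid(tree)
    current = fit
    regime_map = np.asarray(current.regime_map).copy()
    n_collapses = 0
    while True:
        n_opt = int(np.max(regime_map)) + 1
        if n_opt < 2:
            break
        best = None
        for r1 in range(n_opt):
            for r2 in range(r1 + 1, n_opt):
                trial = regime_map.copy()
                trial[trial == r2] = r1
                trial[trial > r2] -= 1
                cand = _fit_painting(ws, current.painting, X, alpha_grid,
                                     regime_map=trial)
                if best is None or cand.aicc < best[0].aicc - 1e-12:
                    best = (cand, trial)
        if best is None or best[0].aicc >= current.aicc:
            break
        current, regime_map = best[0], best[1]
        n_collapses += 1
    return current, n_collapses


def convergence_pvalue(tree: Phylogeny, forward_fit: OUFit, traits,
                       nrep: int = 100, seed: int = 0,
                       alpha_grid=None) -> dict:
    """Randomization p-value for the observed number of regime collapses.

    Simulates ``nrep`` datasets under non-convergent versions of the fitted
    forward model — same painting, alpha and sigma2, but each regime's
    optimum redrawn from a normal distribution with the mean and SD of the
    fitted optima, so every simulated regime has its own optimum — reruns
    the forward+backward procedure on each, and reports
    ``p = (1 + #{sim collapses >= observed}) / (nrep + 1)``.
    """
    if nrep < 10:
        raise ValueError("nrep must be >= 10")
    X = np.atleast_2d(np.asarray(traits, dtype=float))
    if X.shape[0] != tree.n_tips:
        X = X.T
    _, observed = surface_backward(tree, forward_fit, X, alpha_grid)
    painting = forward_fit.painting
    n_axes = X.shape[1]
    k_obs = len(painting.shift_branches)
    rng = np.random.default_rng(seed)
    null = np.zeros(nrep, dtype=int)
    for rep in range(nrep):
        sim = np.empty_like(X)
        for j in range(n_axes):
            fitted = np.asarray(forward_fit.theta[j])[forward_fit.regime_map]
            mu = float(np.mean(fitted))
            sd = float(np.std(fitted, ddof=1)) if fitted.size > 1 else 0.0
            theta_r = rng.normal(mu, sd, size=painting.n_regimes)
            theta_b = theta_r[painting.branch_regime]
            sim[:, j] = simulate_ou(
                tree, rng, float(forward_fit.alpha[j]),
                float(forward_fit.sigma2[j]), theta_b,
                root_value=float(theta_b[tree.root]))
        fwd = surface_forward(tree, sim, max_shifts=max(k_obs, 2),
                              alpha_grid=alpha_grid)[-1]
        _, null[rep] = surface_backward(tree, fwd, sim, alpha_grid)
    p = (1 + int((null >= observed).sum())) / (nrep + 1)
    return {"p": p, "observed_collapses": int(observed),
            "null_collapses": null, "nrep": nrep, "seed": seed}
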