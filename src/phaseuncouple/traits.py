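"""Continuous-trait building blocks: Brownian-motion pruning likelihood,
maximum-likelihood rate estimation, and fast seeded simulators for BM and
Ornstein-Uhlenbeck processes along a time tree.

Conventions: traits are indexed in ``tree.tips`` order; a branch is
identified by its child node id; per-branch arrays are indexed by node id
(entries at the root and at unused slots are ignored).
"""
from __future__ import annotations

import numpy as np

from .phylo_io import Phylogeny

LOG2PI = np.log(2.0 * np.pi)


def bm_contrasts(tree: Phylogeny, x: np.ndarray, branch_rates=None):
    """Felsenstein pruning for BM with unit base rate.

    Returns ``(ss, logdet, mu_root, v_root)`` where the log-likelihood with
    overall rate ``sigma2`` and fixed root state ``m0`` is::

        -0.5 * (n*log(2*pi*sigma2) + logdet + (ss + (mu_root-m0)^2/v_root)/sigma2)

    ``x`` may carry leading batch dimensions: shape (..., n_tips).
    ``branch_rates`` multiplies each branch's length (rate heterogeneity).
    """
    x = np.asarray(x, dtype=float)
    n_tips = tree.n_tips
    if x.shape[-1] != n_tips:
        raise ValueError("trait vector does not match tip count")
    if branch_rates is None:
        blen = tree.length
    else:
        branch_rates = np.asarray(branch_rates, dtype=float)
        if np.any(branch_rates[tree.branches()] <= 0):
            raise ValueError("branch rates must be positive")
        blen = tree.length * branch_rates
    mu = np.zeros(x.shape[:-1] + (tree.n_nodes,))
    pos = {int(t): k for k, t in enumerate(tree.tips)}
    for t in tree.tips:
        mu[..., t] = x[..., pos[int(t)]]
    v = np.zeros(tree.n_nodes)  # extra variance above each node
    ss = np.zeros(x.shape[:-1])
    logdet = 0.0
    for node in tree.postorder():
        if tree.is_tip(node):
            continue
        kids = tree.children[node]
        m_acc = mu[..., kids[0]]
        v_acc = v[kids[0]] + blen[kids[0]]
        for c in kids[1:]:
            vc = v[c] + blen[c]
            tot = v_acc + vc
            contrast = m_acc - mu[..., c]
            ss = ss + contrast * contrast / tot
            logdet += np.log(tot)
            m_acc = (m_acc * vc + mu[..., c] * v_acc) / tot
            v_acc = v_acc * vc / tot
        mu[..., node] = m_acc
        v[node] = v_acc
    return ss, logdet, mu[..., tree.root], v[tree.root]


def bm_loglik(tree: Phylogeny, x, sigma2: float = 1.0, m0: float | None = None,
              branch_rates=None) -> float:
    """BM log-likelihood; root state ``m0`` profiled out (ML) if None."""
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    ss, logdet, mu_root, v_root = bm_contrasts(tree, x, branch_rates)
    n = tree.n_tips
    if m0 is not None:
        ss = ss + (mu_root - m0) ** 2 / v_root
    return -0.5 * (n * (LOG2PI + np.log(sigma2)) + logdet
                   + np.log(v_root) + ss / sigma2)


def bm_mle(tree: Phylogeny, x) -> tuple[float, float, float]:
    """ML estimates (sigma2, root state, logL) for single-rate BM."""
    ss, logdet, mu_root, v_root = bm_contrasts(tree, x)
    n = tree.n_tips
    sigma2 = float(ss) / n
    if sigma2 <= 0:
        raise ValueError("degenerate trait vector (zero variance)")
    logL = -0.5 * (n * (LOG2PI + np.log(sigma2)) + logdet
                   + np.log(v_root) + n)
    return sigma2, float(mu_root), float(logL)


def simulate_bm(tree: Phylogeny, rng: np.random.Generator, sigma2: float = 1.0,
                nsim: int | None = None, branch_rates=None,
                root_value: float = 0.0) -> np.ndarray:
    """Simulate BM tip values; shape (n_tips,) or (nsim, n_tips)."""
    squeeze = nsim is None
    m = 1 if squeeze else int(nsim)
    blen = tree.length if branch_rates is None else tree.length * np.asarray(
        branch_rates, dtype=float)
    state = np.zeros((m, tree.n_nodes))
    state[:, tree.root] = root_value
    for node in tree.preorder():
        if node == tree.root:
            continue
        sd = np.sqrt(sigma2 * blen[node])
        state[:, node] = state[:, tree.parent[node]] + rng.normal(0.0, sd, m)
    out = state[:, tree.tips]
    return out[0] if squeeze else out


def simulate_ou(tree: Phylogeny, rng: np.random.Generator, alpha: float,
                sigma2: float, branch_theta: np.ndarray, root_value: float,
                nsim: int | None = None) -> np.ndarray:
    """Simulate an OU process with per-branch optima (regime painting).

    Transition along a branch of length L toward optimum theta:
    ``x' = x e^{-aL} + theta (1 - e^{-aL}) + N(0, s2/(2a) (1 - e^{-2aL}))``.
    """
    if alpha <= 0 or sigma2 <= 0:
        raise ValueError("alpha and sigma2 must be positive")
    squeeze = nsim is None
    m = 1 if squeeze else int(nsim)
    theta = np.asarray(branch_theta, dtype=float)
    state = np.zeros((m, tree.n_nodes))
    state[:, tree.root] = root_value
    for node in tree.preorder():
        if node == tree.root:
            continue
        L = tree.length[node]
        w = np.exp(-alpha * L)
        var = sigma2 / (2.0 * alpha) * (1.0 - np.exp(-2.0 * alpha * L))
        state[:, node] = (state[:, tree.parent[node]] * w
                          + theta[node] * (1.0 - w)
                          + rng.normal(0.0, np.sqrt(var), m))
    out = state[:, tree.tips]
    return out[0] if squeeze else out
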