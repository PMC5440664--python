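"""Correlated evolution of binary character pairs on a phylogeny.

For each adult/tadpole character pair, the dependent model (8 transition
rates: each character's gain/loss rate may depend on the other character's
state) is compared with the independent model (4 rates) by a likelihood
ratio test with 4 degrees of freedom.  Characters are binarized (state 0
vs state > 0) before pairing; tips missing either character are pruned for
that pair.  Likelihoods use the pruning algorithm on the joint 4-state
chain with the root weighted by the stationary distribution of the fitted
rate matrix.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.optimize import minimize
from scipy.stats import chi2, qmc
from statsmodels.stats.multitest import multipletests

from .phylo_io import MISSING, Phylogeny

# joint states of (charA, charB): 00, 01, 10, 11
STATES = [(0, 0), (0, 1), (1, 0), (1, 1)]
STATE_INDEX = {s: i for i, s in enumerate(STATES)}

RATE_BOUNDS = (1e-5, 1e3)


def build_q(rates: np.ndarray, dependent: bool) -> np.ndarray:
    """Rate matrix on the joint state space; no double transitions.

    Independent rates: (a01, a10, b01, b10).
    Dependent rates: (a01|b=0, a01|b=1, a10|b=0, a10|b=1,
                      b01|a=0, b01|a=1, b10|a=0, b10|a=1).
    """
    r = np.asarray(rates, dtype=float)
    if dependent:
        a01 = {0: r[0], 1: r[1]}
        a10 = {0: r[2], 1: r[3]}
        b01 = {0: r[4], 1: r[5]}
        b10 = {0: r[6], 1: r[7]}
    else:
        a01 = {0: r[0], 1: r[0]}
        a10 = {0: r[1], 1: r[1]}
        b01 = {0: r[2], 1: r[2]}
        b10 = {0: r[3], 1: r[3]}
    Q = np.zeros((4, 4))
    for (a, b), i in STATE_INDEX.items():
        ja = STATE_INDEX[(1 - a, b)]
        Q[i, ja] = (a01 if a == 0 else a10)[b]
        jb = STATE_INDEX[(a, 1 - b)]
        Q[i, jb] = (b01 if b == 0 else b10)[a]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def stationary_distribution(Q: np.ndarray) -> np.ndarray:
    """Left null vector of Q normalized to a probability vector."""
    A = np.vstack([Q.T, np.ones(4)])
    b = np.concatenate([np.zeros(4), [1.0]])
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


class _ExpmCache:
    """Transition matrices P(L) = expm(Q L) via one eigendecomposition."""

    def __init__(self, Q: np.ndarray):
        self.Q = Q
        try:
            w, V = np.linalg.eig(Q)
            Vinv = np.linalg.inv(V)
            if np.linalg.cond(V) < 1e8:
                self.w, self.V, self.Vinv = w, V, Vinv
            else:
                self.w = None
        except np.linalg.LinAlgError:
            self.w = None

    def P(self, L: float) -> np.ndarray:
        if self.w is not None:
            P = (self.V * np.exp(self.w * L)) @ self.Vinv
            P = np.real(P)
        else:
            P = expm(self.Q * L)
        return np.clip(P, 0.0, None)

    def P_many(self, lengths: np.ndarray) -> np.ndarray:
        """Transition matrices for a vector of branch lengths: (n, 4, 4)."""
        if self.w is None:
            return np.stack([self.P(float(L)) for L in lengths])
        E = np.exp(np.multiply.outer(lengths, self.w))       # (n, 4)
        P = np.einsum("ij,nj,jk->nik", self.V, E, self.Vinv)
        return np.clip(np.real(P), 0.0, None)


def _prune_pair(tree: Phylogeny, char_a, char_b):
    """Drop tips missing either character; returns (tree, a, b)."""
    a = np.asarray(char_a)
    b = np.asarray(char_b)
    ok = (a != MISSING) & (b != MISSING)
    if ok.all():
        return tree, a, b
    labels = [l for l, keep in zip(tree.tip_labels, ok) if keep]
    sub = tree.prune_to(labels)
    order = [tree.tip_labels.index(l) for l in sub.tip_labels]
    return sub, a[order], b[order]


def ctmc_loglik(tree: Phylogeny, char_a, char_b, rates,
                dependent: bool) -> float:
    """Pruning log-likelihood of the joint 4-state chain at the given rates,
    root weighted by the stationary distribution."""
    a = np.asarray(char_a)
    b = np.asarray(char_b)
    if set(np.unique(a)) - {0, 1} or set(np.unique(b)) - {0, 1}:
        raise ValueError("characters must be binary (recode first)")
    Q = build_q(np.asarray(rates, dtype=float), dependent)
    cache = _ExpmCache(Q)
    P_all = cache.P_many(tree.length)
    partial = np.ones((tree.n_nodes, 4))
    pos = {int(t): k for k, t in enumerate(tree.tips)}
    for t in tree.tips:
        k = pos[int(t)]
        partial[t] = 0.0
        partial[t, STATE_INDEX[(int(a[k]), int(b[k]))]] = 1.0
    scale = 0.0
    for node in tree.postorder():
        if tree.is_tip(node):
            continue
        for c in tree.children[node]:
            partial[node] *= P_all[c] @ partial[c]
        s = partial[node].sum()
        if s <= 0:
            return -np.inf
        partial[node] /= s
        scale += np.log(s)
    pi = stationary_distribution(Q)
    like = float(pi @ partial[tree.root])
    if like <= 0:
        return -np.inf
    return float(np.log(like) + scale)


def _fit(tree, a, b, dependent: bool, starts: int, seed: int,
         extra_starts=()) -> tuple[float, np.ndarray]:
    n_par = 8 if dependent else 4
    lo, hi = np.log(RATE_BOUNDS[0]), np.log(RATE_BOUNDS[1])
    sampler = qmc.LatinHypercube(d=n_par, seed=seed)
    # start around one expected change per total tree length
    total = tree.length.sum()
    center = np.log(max(2.0 / total, RATE_BOUNDS[0] * 10))
    pts = center + (sampler.random(starts) - 0.5) * 4.0
    x0s = [np.clip(p, lo, hi) for p in pts] + [np.asarray(e) for e in extra_starts]

    def nll(logr):
        ll = ctmc_loglik(tree, a, b, np.exp(logr), dependent)
        return -ll if np.isfinite(ll) else 1e10

    best = None
    for x0 in x0s:
        res = minimize(nll, x0, method="L-BFGS-B",
                       bounds=[(lo, hi)] * n_par)
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("rate optimization failed from every start")
    return -float(best.fun), np.exp(best.x)


@dataclass
class PairTestResult:
    """Likelihood-ratio test of dependent vs independent evolution."""

    pair: tuple
    logl_indep: float
    logl_dep: float
    lr: float
    df: int
    p: float
    significant: bool
    degenerate: bool = False


def pair_lrt(tree: Phylogeny, char_a, char_b, starts: int = 3, seed: int = 0,
             alpha: float = 0.05, pair_id=None) -> PairTestResult:
    """Fit both models by multi-start ML and test with chi-square (df=4).

    Pairs in which either character is invariant across the retained tips
    are flagged degenerate and excluded from summaries.
    """
    sub, a, b = _prune_pair(tree, char_a, char_b)
    pid = pair_id if pair_id is not None else ("A", "B")
    if len(np.unique(a)) < 2 or len(np.unique(b)) < 2:
        return PairTestResult(pid, np.nan, np.nan, np.nan, 4, np.nan,
                              False, degenerate=True)
    ll_i, rates_i = _fit(sub, a, b, dependent=False, starts=starts, seed=seed)
    # seed the dependent fit with the independent optimum (guarantees nesting)
    dup = np.log(np.repeat(rates_i, 2))
    ll_d, _ = _fit(sub, a, b, dependent=True, starts=starts, seed=seed + 1,
                   extra_starts=[dup])
    lr = max(2.0 * (ll_d - ll_i), 0.0)
    p = float(chi2.sf(lr, df=4))
    return PairTestResult(pid, ll_i, ll_d, lr, 4, p, p < alpha)


def summarize_pairs(results, alpha: float = 0.05) -> dict:
    """Fraction of significantly correlated pairs, with BH-FDR q-values.

    ``percent`` is 100 * n_significant / n_total rounded to one decimal.
    Degenerate pairs are excluded.
    """
    usable = [r for r in results if not r.degenerate]
    if not usable:
        raise ValueError("no non-degenerate pair results")
    pvals = np.array([r.p for r in usable])
    n_sig = int((pvals < alpha).sum())
    n_total = len(usable)
    _, qvals, *_ = multipletests(pvals, method="fdr_bh")
    table = pd.DataFrame({
        "pair": [r.pair for r in usable],
        "logl_indep": [r.logl_indep for r in usable],
        "logl_dep": [r.logl_dep for r in usable],
        "lr": [r.lr for r in usable],
        "p": pvals,
        "q_bh": qvals,
        "significant": pvals < alpha,
    })
    return {
        "n_significant": n_sig,
        "n_total": n_total,
        "percent": round(100.0 * n_sig / n_total, 1),
        "n_significant_bh": int((qvals < alpha).sum()),
        "table": table,
    }


def binarize(states: np.ndarray) -> np.ndarray:
    """Map 0 -> 0 and any positive state -> 1, preserving missing."""
    out = np.asarray(states).copy()
    out[out > 0] = 1
    return out


def all_pairs_lrt(tree: Phylogeny, matrix_a, matrix_b, starts: int = 3,
                  seed: int = 0) -> list[PairTestResult]:
    """LRT for every (adult character, tadpole character) pair; characters
    are binarized first and the tree pruned per pair for missing data.
    Matrix rows are aligned to the tree's tip order by taxon label."""
    rows_a = [matrix_a.taxa.index(l) for l in tree.tip_labels]
    rows_b = [matrix_b.taxa.index(l) for l in tree.tip_labels]
    results = []
    k = 0
    for i in range(matrix_a.n_characters):
        for j in range(matrix_b.n_characters):
            a = binarize(matrix_a.states[rows_a, i])
            b = binarize(matrix_b.states[rows_b, j])
            results.append(pair_lrt(tree, a, b, starts=starts,
                                    seed=seed + k, pair_id=(i, j)))
            k += 1
    return results
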