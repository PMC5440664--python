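"""Reversible-jump MCMC for branch-specific Brownian-motion rate variation.

The model partitions branches into rate classes defined by a set of shift
branches: a branch belongs to the class of its nearest ancestral shift
(itself included), or to the background class.  The sampler explores the
number and placement of shifts (Poisson prior on the shift count), the
per-class rates (lognormal prior) and the root state, using a move mixture
of rate updates, root updates, and dimension-changing split/merge moves
whose acceptance ratios are Jacobian-correct (new rates are drawn from the
prior, so the proposal density cancels the prior density exactly).

Branch rates are summarized as the geometric mean over post-burn-in samples,
plus the arithmetic mean and the per-branch posterior shift probability.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .phylo_io import Phylogeny
from .traits import bm_mle

MOVE_PROBS = {"rate": 0.4, "root": 0.1, "split": 0.25, "merge": 0.25}


# ---------------------------------------------------------------------------
# fast scalar pruning likelihood
# ---------------------------------------------------------------------------

class _TreeCache:
    def __init__(self, tree: Phylogeny, x: np.ndarray):
        self.n_nodes = tree.n_nodes
        self.n_tips = tree.n_tips
        self.root = tree.root
        self.postorder = [int(v) for v in tree.postorder()]
        self.preorder = [int(v) for v in tree.preorder()]
        self.children = [list(c) for c in tree.children]
        self.parent = [int(p) for p in tree.parent]
        self.length = [float(l) for l in tree.length]
        self.branches = [v for v in self.preorder if v != self.root]
        self.x_by_node = [0.0] * tree.n_nodes
        for k, t in enumerate(tree.tips):
            self.x_by_node[int(t)] = float(np.asarray(x)[k])


def _loglik(tc: _TreeCache, branch_rate: list, m0: float) -> float:
    """BM log-likelihood with per-branch rates and fixed root state."""
    mu = [0.0] * tc.n_nodes
    var = [0.0] * tc.n_nodes
    ss = 0.0
    logdet = 0.0
    for node in tc.postorder:
        kids = tc.children[node]
        if not kids:
            mu[node] = tc.x_by_node[node]
            var[node] = 0.0
            continue
        c0 = kids[0]
        m_acc = mu[c0]
        v_acc = var[c0] + tc.length[c0] * branch_rate[c0]
        for c in kids[1:]:
            vc = var[c] + tc.length[c] * branch_rate[c]
            tot = v_acc + vc
            d = m_acc - mu[c]
            ss += d * d / tot
            logdet += math.log(tot)
            m_acc = (m_acc * vc + mu[c] * v_acc) / tot
            v_acc = v_acc * vc / tot
        mu[node] = m_acc
        var[node] = v_acc
    d = mu[tc.root] - m0
    ss += d * d / var[tc.root]
    logdet += math.log(var[tc.root])
    return -0.5 * (tc.n_tips * math.log(2.0 * math.pi) + logdet + ss)


def _branch_rates(tc: _TreeCache, shifts: dict, rates: dict) -> list:
    """Per-branch rate from the nearest ancestral shift (class 0 = background)."""
    cls = [0] * tc.n_nodes
    for node in tc.preorder:
        if node == tc.root:
            continue
        cls[node] = shifts.get(node, cls[tc.parent[node]])
    return [rates[cls[v]] for v in range(tc.n_nodes)], cls


# ---------------------------------------------------------------------------
# rj moves: dimension-change bookkeeping (exposed for algebraic testing)
# ---------------------------------------------------------------------------

def split_log_accept_terms(k: int, n_branches: int,
                           shift_prior_mean: float = 1.0) -> float:
    """Non-likelihood part of log A for a split from k to k+1 shifts.

    Prior: shift count Poisson(shift_prior_mean); placements uniform over
    the C(B, k) subsets of branches; the new rate is drawn from its prior,
    so its density cancels.  The placement-prior ratio (k+1)/(B-k) cancels
    the uniform-branch-choice Hastings factor (B-k)/(k+1) exactly, leaving
    the Poisson ratio and the move-probability ratio.
    """
    return (math.log(shift_prior_mean / (k + 1))
            + math.log(MOVE_PROBS["merge"] / MOVE_PROBS["split"]))


def merge_log_accept_terms(k: int, n_branches: int,
                           shift_prior_mean: float = 1.0) -> float:
    """Non-likelihood part of log A for a merge from k to k-1 shifts."""
    return (math.log(k / shift_prior_mean)
            + math.log(MOVE_PROBS["split"] / MOVE_PROBS["merge"]))


# ---------------------------------------------------------------------------
# sampler
# ---------------------------------------------------------------------------

@dataclass
class PosteriorRates:
    """Posterior branch-rate summaries from the rjMCMC."""

    geo_mean: np.ndarray        # per-branch geometric-mean rate (node-indexed)
    arith_mean: np.ndarray
    shift_prob: np.ndarray      # per-branch posterior shift probability
    shift_count: np.ndarray     # sampled number of shifts
    mean_rate: float            # mean over branches of geometric means
    acceptance: dict
    generations: int
    burn_in: float
    n_samples: int
    chains: int
    per_chain_geo_mean: np.ndarray  # (chains, n_nodes) for convergence checks


def run_rjmcmc(tree: Phylogeny, trait, generations: int = 1_000_000,
               burn_in: float = 0.5, chains: int = 2, seed: int = 0,
               shift_prior_mean: float = 1.0, rate_prior_sd: float = 6.0,
               thin: int | None = None) -> PosteriorRates:
    """Sample branch-rate configurations; defaults follow the two-chain,
    half-discarded convention with one shift expected a priori."""
    if generations < 1000:
        raise ValueError("generations must be >= 1000")
    x = np.asarray(trait, dtype=float)
    tc = _TreeCache(tree, x)
    B = len(tc.branches)
    sigma2_hat, m0_hat, _ = bm_mle(tree, x)
    log_r0 = math.log(sigma2_hat)
    m0_scale = max(float(np.std(x)), 1e-8)
    if thin is None:
        thin = max(1, generations // 2000)

    def log_rate_prior(r):
        z = (math.log(r) - log_r0) / rate_prior_sd
        return -0.5 * z * z - math.log(r * rate_prior_sd) \
            - 0.5 * math.log(2 * math.pi)

    def log_m0_prior(m):
        z = (m - float(np.mean(x))) / (10.0 * m0_scale)
        return -0.5 * z * z

    move_names = list(MOVE_PROBS)
    move_p = np.array([MOVE_PROBS[m] for m in move_names])

    sum_log = np.zeros((chains, tc.n_nodes))
    sum_lin = np.zeros(tc.n_nodes)
    shift_hits = np.zeros(tc.n_nodes)
    k_samples: list[int] = []
    accept = {m: 0 for m in move_names}
    tries = {m: 0 for m in move_names}
    total_samples = 0
    per_chain_samples = np.zeros(chains)

    master = np.random.default_rng(seed)
    for chain in range(chains):
        rng = np.random.default_rng(master.integers(2**31))
        shifts: dict[int, int] = {}           # branch -> class id
        rates: dict[int, float] = {0: sigma2_hat}
        next_class = 1
        m0 = m0_hat
        br, _ = _branch_rates(tc, shifts, rates)
        logL = _loglik(tc, br, m0)
        burn_gen = int(generations * burn_in)
        for gen in range(generations):
            move = move_names[rng.choice(4, p=move_p)]
            tries[move] += 1
            k = len(shifts)
            if move == "rate":
                cid = list(rates)[rng.integers(len(rates))]
                r_old = rates[cid]
                r_new = r_old * math.exp(rng.uniform(-0.7, 0.7))
                rates[cid] = r_new
                br2, _ = _branch_rates(tc, shifts, rates)
                logL2 = _loglik(tc, br2, m0)
                logA = (logL2 - logL + log_rate_prior(r_new)
                        - log_rate_prior(r_old)
                        + math.log(r_new / r_old))   # log-scale proposal
                if math.log(rng.uniform()) < logA:
                    logL, br = logL2, br2
                    accept[move] += 1
                else:
                    rates[cid] = r_old
            elif move == "root":
                m_new = m0 + rng.normal(0.0, 0.5 * m0_scale)
                logL2 = _loglik(tc, br, m_new)
                logA = logL2 - logL + log_m0_prior(m_new) - log_m0_prior(m0)
                if math.log(rng.uniform()) < logA:
                    logL, m0 = logL2, m_new
                    accept[move] += 1
            elif move == "split":
                free = [b for b in tc.branches if b not in shifts]
                if free:
                    b = free[rng.integers(len(free))]
                    r_new = math.exp(log_r0 + rate_prior_sd * rng.normal())
                    shifts[b] = next_class
                    rates[next_class] = r_new
                    br2, _ = _branch_rates(tc, shifts, rates)
                    logL2 = _loglik(tc, br2, m0)
                    logA = (logL2 - logL
                            + split_log_accept_terms(k, B, shift_prior_mean))
                    if math.log(rng.uniform()) < logA:
                        logL, br = logL2, br2
                        next_class += 1
                        accept[move] += 1
                    else:
                        del shifts[b], rates[next_class]
            else:  # merge
                if shifts:
                    branches = list(shifts)
                    b = branches[rng.integers(len(branches))]
                    cid = shifts.pop(b)
                    r_old = rates.pop(cid)
                    br2, _ = _branch_rates(tc, shifts, rates)
                    logL2 = _loglik(tc, br2, m0)
                    logA = (logL2 - logL
                            + merge_log_accept_terms(k, B, shift_prior_mean))
                    if math.log(rng.uniform()) < logA:
                        logL, br = logL2, br2
                        accept[move] += 1
                    else:
                        shifts[b] = cid
                        rates[cid] = r_old
            if gen >= burn_gen and (gen - burn_gen) % thin == 0:
                lb = np.log(br)
                sum_log[chain] += lb
                sum_lin += br
                for b in shifts:
                    shift_hits[b] += 1
                k_samples.append(len(shifts))
                total_samples += 1
                per_chain_samples[chain] += 1

    if min(accept[m] / max(tries[m], 1) for m in move_names) < 0.01:
        import warnings
        warnings.warn("rjMCMC acceptance below 1% for at least one move; "
                      "the chain may not be mixing", RuntimeWarning)
    per_chain_geo = np.exp(sum_log / per_chain_samples[:, None])
    geo = np.exp(sum_log.sum(0) / total_samples)
    branch_ids = np.array(tc.branches)
    mean_rate = float(geo[branch_ids].mean())
    return PosteriorRates(
        geo_mean=geo, arith_mean=sum_lin / total_samples,
        shift_prob=shift_hits / total_samples,
        shift_count=np.array(k_samples), mean_rate=mean_rate,
        acceptance={m: accept[m] / max(tries[m], 1) for m in move_names},
        generations=generations, burn_in=burn_in, n_samples=total_samples,
        chains=chains, per_chain_geo_mean=per_chain_geo,
    )


# ---------------------------------------------------------------------------
# cross-phase comparisons
# ---------------------------------------------------------------------------

def compare_phase_rates(rates_a, rates_b) -> dict:
    """Kruskal-Wallis on the two rate samples and Pearson correlation on
    per-branch z-scored ("standardized") rates."""
    a = np.asarray(rates_a, dtype=float)
    b = np.asarray(rates_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("rate vectors must cover the same branches")
    H, p_kw = stats.kruskal(a, b)
    za = (a - a.mean()) / a.std(ddof=1)
    zb = (b - b.mean()) / b.std(ddof=1)
    r, p_r = stats.pearsonr(za, zb)
    return {"kw_h": float(H), "kw_p": float(p_kw),
            "pearson_r": float(r), "pearson_p": float(p_r)}


def bin_rates_by_time(tree: Phylogeny, rates, width: float = 4.0) -> dict:
    """Mean branch rate per time interval [0,w), [4,8)... anchored at present.

    Each branch contributes to an interval in proportion to the branch
    length falling inside it; intervals crossed by no lineage are NaN.
    """
    if width <= 0:
        raise ValueError("width must be > 0")
    rates = np.asarray(rates, dtype=float)
    n_bins = int(np.ceil(tree.T / width)) or 1
    num = np.zeros(n_bins)
    den = np.zeros(n_bins)
    for c in tree.branches():
        young, old = tree.age[c], tree.age[tree.parent[c]]
        for i in range(n_bins):
            lo, hi = i * width, (i + 1) * width
            overlap = max(0.0, min(old, hi) - max(young, lo))
            if overlap > 0:
                num[i] += rates[c] * overlap
                den[i] += overlap
    mean = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    edges = np.arange(n_bins + 1) * width
    return {"edges": edges, "mean_rate": mean}
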