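"""Time-dependent birth-death diversification models and AICc selection.

Six nested models of the reconstructed birth-death process are fitted by
maximum likelihood on an ultrametric tree and compared by the small-sample
Akaike criterion (AICc):

====== ============================================================ ===
model  description                                                   K
====== ============================================================ ===
1      no extinction, constant speciation (Yule)                     1
2      constant speciation and extinction                            2
3      no extinction, exponential speciation through time            2
4      exponential speciation, constant extinction                   3
5      constant speciation, exponential extinction                   3
6      exponential speciation and extinction                         4
====== ============================================================ ===

Time ``t`` runs from the present (t=0) into the past, so with
``lambda(t) = lambda0 * exp(a*t)`` a positive ``a`` means speciation rates
increase toward the past (an early burst).  The likelihood is conditioned
on the crown age and on survival of both crown lineages.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import minimize
from scipy.stats import qmc

from .phylo_io import Phylogeny

# parameter names per model id
MODEL_PARAMS = {
    1: ("lambda0",),
    2: ("lambda0", "mu0"),
    3: ("lambda0", "a"),
    4: ("lambda0", "a", "mu0"),
    5: ("lambda0", "mu0", "b"),
    6: ("lambda0", "a", "mu0", "b"),
}

MODEL_DESCRIPTIONS = {
    1: "no extinction, constant speciation",
    2: "constant speciation and extinction",
    3: "no extinction, exponential variation in speciation",
    4: "exponential speciation, constant extinction",
    5: "constant speciation, exponential variation in extinction",
    6: "exponential variation in speciation and extinction",
}

BOUNDS = {
    "lambda0": (1e-6, 10.0),
    "mu0": (0.0, 10.0 - 1e-9),
    "a": (-2.0, 2.0),
    "b": (-2.0, 2.0),
}


@dataclass
class DiversificationModel:
    """One of the six birth-death models, with its free parameters."""

    model_id: int

    def __post_init__(self):
        if self.model_id not in MODEL_PARAMS:
            raise ValueError("model id must be 1..6")

    @property
    def param_names(self) -> tuple[str, ...]:
        return MODEL_PARAMS[self.model_id]

    @property
    def K(self) -> int:
        return len(self.param_names)

    def rates(self, params: dict):
        """Return callables lambda(t), mu(t) and the growth integral rho(t).

        ``rho(t) = int_0^t (lambda - mu) du`` has a closed form for
        exponential rate functions.
        """
        lam0 = params["lambda0"]
        a = params.get("a", 0.0)
        mu0 = params.get("mu0", 0.0)
        b = params.get("b", 0.0)
        if lam0 <= 0:
            raise ValueError("lambda0 must be > 0")
        if mu0 < 0:
            raise ValueError("mu0 must be >= 0")

        def lam(t):
            return lam0 * np.exp(a * t)

        def mu(t):
            return mu0 * np.exp(b * t)

        def cum(r0, c, t):
            t = np.asarray(t, dtype=float)
            if c == 0.0:
                return r0 * t
            return r0 * np.expm1(c * t) / c

        def rho(t):
            return cum(lam0, a, t) - cum(mu0, b, t)

        return lam, mu, rho


def _log1pJ(lam, rho, times: np.ndarray, constant: bool,
            lam0: float, mu0: float, T: float) -> np.ndarray:
    """G(t) = log(1 + int_0^t lambda(s) e^{rho(s)} ds) at the given times.

    For constant rates the integral is closed-form; otherwise G solves
    ``dG/dt = lambda(t) exp(rho(t) - G)`` with ``G(0) = 0``, which is
    numerically stable even when the raw integral overflows.
    """
    if constant:
        r = lam0 - mu0
        t = np.asarray(times, dtype=float)
        if abs(r) < 1e-12:
            J = lam0 * t
        else:
            J = lam0 * np.expm1(r * t) / r
        return np.log1p(J)

    def grad(t, G):
        return [lam(t) * np.exp(rho(t) - G[0])]

    sol = solve_ivp(grad, (0.0, float(T) * (1 + 1e-12)), [0.0],
                    t_eval=np.asarray(times, dtype=float), rtol=1e-8,
                    atol=1e-10, dense_output=False, method="LSODA")
    if not sol.success:
        raise RuntimeError(f"survival integration failed: {sol.message}")
    return sol.y[0]


def bd_loglik(tree: Phylogeny, model: DiversificationModel,
              params: dict) -> float:
    """Log-likelihood of the reconstructed birth-death process.

    Conditioned on the crown age and survival of both crown lineages;
    complete species sampling is assumed.
    """
    lam, mu, rho = model.rates(params)
    ages = tree.age
    T = tree.T
    internal = [v for v in range(tree.n_nodes)
                if not tree.is_tip(v) and v != tree.root]
    branch_child = tree.branches()
    times = np.unique(np.concatenate([
        ages[branch_child], ages[tree.parent[branch_child]], [0.0, T]
    ]))
    constant = params.get("a", 0.0) == 0.0 and params.get("b", 0.0) == 0.0
    G = _log1pJ(lam, rho, times, constant, params["lambda0"],
                params.get("mu0", 0.0), T)
    Gof = dict(zip(times.tolist(), G.tolist()))
    rho_t = dict(zip(times.tolist(), np.asarray(rho(times)).tolist()))

    logL = 0.0
    for v in internal:
        logL += np.log(lam(ages[v]))
    for c in branch_child:
        p = tree.parent[c]
        logL += (rho_t[ages[p]] - rho_t[ages[c]]
                 + 2.0 * (Gof[ages[c]] - Gof[ages[p]]))
    # conditioning: both crown lineages survive;  log(1-E(T)) = rho(T) - G(T)
    logL -= 2.0 * (rho_t[T] - Gof[T])
    return float(logL)


@dataclass
class DiversificationFit:
    """Maximum-likelihood fit of one diversification model."""

    model: DiversificationModel
    params: dict
    logL: float
    aicc: float
    n_tips: int
    delta_aicc: float | None = None

    @property
    def description(self) -> str:
        return MODEL_DESCRIPTIONS[self.model.model_id]


def aicc(logL: float, K: int, n: int) -> float:
    """Small-sample Akaike information criterion."""
    if n - K - 1 <= 0:
        raise ValueError("n too small for AICc")
    return -2.0 * logL + 2.0 * K + 2.0 * K * (K + 1) / (n - K - 1)


def fit_model(tree: Phylogeny, model: DiversificationModel | int,
              starts: int = 10, seed: int = 0) -> DiversificationFit:
    """Fit one model by bounded multi-start quasi-Newton ML.

    Start points are a Latin-hypercube over the parameter box (log scale
    for lambda0); the best converged optimum is returned.
    """
    if isinstance(model, int):
        model = DiversificationModel(model)
    names = model.param_names
    lo = np.array([BOUNDS[p][0] for p in names])
    hi = np.array([BOUNDS[p][1] for p in names])
    # optimize lambda0 on log scale
    lo_t = lo.copy()
    hi_t = hi.copy()
    lo_t[0], hi_t[0] = np.log(lo[0]), np.log(hi[0])

    def unpack(x):
        vals = x.copy()
        vals[0] = np.exp(vals[0])
        return dict(zip(names, vals))

    def nll(x):
        try:
            return -bd_loglik(tree, model, unpack(x))
        except (FloatingPointError, OverflowError, RuntimeError):
            return 1e10

    sampler = qmc.LatinHypercube(d=len(names), seed=seed)
    pts = lo_t + sampler.random(starts) * (hi_t - lo_t)
    best = None
    for x0 in pts:
        with np.errstate(over="ignore", invalid="ignore"):
            res = minimize(nll, x0, method="L-BFGS-B",
                           bounds=list(zip(lo_t, hi_t)))
        if not np.isfinite(res.fun):
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise RuntimeError("optimizer failed to converge from every start")
    params = unpack(best.x)
    logL = -float(best.fun)
    return DiversificationFit(model, params, logL,
                              aicc(logL, model.K, tree.n_tips), tree.n_tips)


def fit_all_models(tree: Phylogeny, models=(1, 2, 3, 4, 5, 6),
                   starts: int = 10, seed: int = 0):
    return [fit_model(tree, m, starts=starts, seed=seed + m) for m in models]


def selection_table(fits) -> pd.DataFrame:
    """Rank fits by AICc (ascending, stable) and attach delta-AICc."""
    if len(fits) < 2:
        raise ValueError("need at least two fits to compare")
    rows = []
    for f in fits:
        rows.append({
            "model": f.model.model_id,
            "description": f.description,
            "K": f.model.K,
            "logL": f.logL,
            "AICc": f.aicc,
        })
    df = pd.DataFrame(rows)
    df = df.sort_values("AICc", kind="stable").reset_index(drop=True)
    df["dAICc"] = df["AICc"] - df["AICc"].min()
    return df
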