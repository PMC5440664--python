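"""Seeded generators for every input the pipeline consumes.

Trees come from a birth-death process conditioned on the number of extant
tips; discrete characters from Mk (optionally dependent-pair) chains;
continuous two-phase traits from BM with planted clade rate multipliers or
OU with planted regime shifts, in coupled (shared shift branches) or
uncoupled (independently placed) configurations; expression tables from
lognormal FPKM with planted phase effects and morphology-flag enrichment.
Every generator takes a :class:`numpy.random.Generator` or an integer seed
and is fully deterministic given it.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field

import numpy as np
import pandas as pd
import yaml
from scipy.linalg import expm

from .phylo_io import CharacterMatrix, MISSING, Phylogeny, write_newick, \
    write_nexus_matrix
from .ou_regimes import RegimePainting

MORPH_TERMS = [
    "osteoclast", "skeletal", "limb morphogenesis", "cartilage", "keratin",
    "fin development", "cranial", "muscle organ development", "pigmentation",
    "epidermis development",
]
NEUTRAL_TERMS = [
    "ribosome", "translation", "proteolysis", "ion transport", "cell cycle",
    "dna repair", "rna splicing", "oxidation-reduction", "vesicle",
    "signal transduction",
]


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)


@dataclass
class ScenarioSpec:
    """Study conditions for a full synthetic two-phase scenario."""

    n_tips: int = 64
    birth: float = 1.0                 # events/lineage/Myr
    death: float = 0.0
    decline: float = 0.0               # forward-time exponential decline of birth
    # continuous traits
    trait_model: str = "ou"            # 'bm' or 'ou'
    n_axes: int = 1                    # trait axes per phase (shared painting)
    bm_sigma2: float = 1.0
    rate_multiplier: float = 10.0      # planted BM clade rate multiplier
    n_rate_shifts: int = 1
    ou_alpha: float = 1.5              # 1/Myr; half-life well inside tree depth
    ou_sigma2: float = 1.0
    n_shifts: int = 8
    theta_offset_sd: float = 4.0       # optimum offsets in stationary SDs
    convergent_regimes: bool = False   # all planted regimes share one optimum
    coupling: str = "uncoupled"        # 'coupled' or 'uncoupled'
    min_clade: int = 2                 # smallest clade a planted shift may hit
    # discrete characters
    n_characters: int = 20
    n_states: int = 3
    mk_rate: float = 0.1               # events/Myr per state pair
    ordered_fraction: float = 0.25
    missing_fraction: float = 0.05
    dependent_pairs: int = 0
    dependence_strength: float = 10.0
    # expression
    n_genes: int = 2000
    frac_adult_biased: float = 0.15
    frac_tadpole_biased: float = 0.15
    expression_effect: float = 4.0
    expression_noise_sd: float = 0.15
    morph_flag_biased: float = 0.35
    morph_flag_even: float = 0.15
    seed: int = 0

    def __post_init__(self):
        if self.frac_adult_biased + self.frac_tadpole_biased > 1:
            raise ValueError("biased fractions must sum to <= 1")
        for name in ("birth", "death", "mk_rate", "bm_sigma2", "ou_alpha",
                     "ou_sigma2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.coupling not in ("coupled", "uncoupled"):
            raise ValueError("coupling must be 'coupled' or 'uncoupled'")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioSpec":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

def simulate_tree(n_tips: int, birth: float = 1.0, death: float = 0.0,
                  decline: float = 0.0, seed=0, max_retries: int = 1000
                  ) -> Phylogeny:
    """Birth-death tree conditioned on the number of extant tips.

    Forward simulation from the two crown lineages; the present is the
    moment the (n+1)-th event would occur, so the holding period with
    exactly n lineages is included in the tree height.  ``decline > 0``
    makes the speciation rate decay exponentially (an early burst):
    ``birth * exp(-decline * s)`` in forward time ``s``.  Runs that die out
    before reaching ``n_tips`` extant lineages are retried.
    """
    if n_tips < 3:
        raise ValueError("need n_tips >= 3")
    if decline < 0:
        raise ValueError("decline must be >= 0 (rates may only decay forward)")
    rng = _rng(seed)
    for _ in range(max_retries):
        out = _simulate_once(n_tips, birth, death, decline, rng)
        if out is not None:
            return out
    raise RuntimeError("birth-death process died out in every retry")


def _simulate_once(n_tips, birth, death, decline, rng):
    parent = [-1, 0, 0]
    start = [0.0, 0.0, 0.0]   # forward time each lineage began
    end = [0.0, None, None]   # None = alive (root "lineage" 0 is the crown node)
    alive = [1, 2]
    t = 0.0
    while True:
        k = len(alive)
        if k < 2:
            return None
        lam_bound = birth * np.exp(-decline * t)
        total = k * (lam_bound + death)
        if total < 1e-9:  # stalled: rates have decayed to nothing
            return None
        t = t + rng.exponential(1.0 / total)
        lam_t = birth * np.exp(-decline * t)
        u = rng.uniform()
        if u < k * lam_t / total:
            event = "birth"
        elif u < k * (lam_t + death) / total:
            event = "death"
        else:
            continue  # thinning rejection of the decayed birth rate
        if k == n_tips:
            break  # present = first event after reaching n lineages
        idx = alive[rng.integers(k)]
        if event == "birth":
            end[idx] = t
            for _ in range(2):
                parent.append(idx)
                start.append(t)
                end.append(None)
                alive.append(len(parent) - 1)
            alive.remove(idx)
        else:
            end[idx] = t
            alive.remove(idx)
    present = t
    lengths, labels = [], []
    tip_no = 0
    for i in range(len(parent)):
        e = end[i] if end[i] is not None else present
        lengths.append(max(e - start[i], 1e-12) if i else 0.0)
        if end[i] is None:
            tip_no += 1
            labels.append(f"t{tip_no}")
        else:
            # extinct/internal lineages get unique placeholder labels so the
            # full tree is a valid Phylogeny before pruning to the survivors
            labels.append(f"ext{i}")
    full = Phylogeny(parent, lengths, labels, check=False)
    survivors = [full.labels[i] for i in full.tips if end[i] is None]
    if len(survivors) != n_tips:
        return None
    return full.prune_to(survivors)


# ---------------------------------------------------------------------------
# continuous traits
# ---------------------------------------------------------------------------

def _plant_shifts(tree: Phylogeny, n_shifts: int, min_clade: int,
                  rng, min_age: float = 0.0) -> list[int]:
    # planted regimes target identifiable subclades: at least min_clade tips
    # but no more than half the tree (a shift covering nearly every tip is
    # indistinguishable from the background regime).  For OU regimes,
    # min_age requires the shift to originate deep enough that the clade
    # has had time to approach its optimum.
    cap = max(min_clade, tree.n_tips // 2)
    # children of the root are excluded: a regime covering one side of the
    # basal split is confounded with the root state
    pool = [int(b) for b in tree.branches()
            if min_clade <= tree.clade_tips(b).size <= cap
            and tree.parent[b] != tree.root]
    if n_shifts > len(pool):
        raise ValueError("not enough eligible branches for planted shifts")
    aged = [b for b in pool if tree.age[tree.parent[b]] >= min_age]
    if len(aged) < n_shifts:  # fall back to the oldest available onsets
        aged = sorted(pool, key=lambda b: -tree.age[tree.parent[b]])[
            :max(n_shifts, len(pool) // 2)]
    # planted regimes are disjoint adaptive zones: a shift nested inside an
    # already-shifted clade can share its optimum and become unidentifiable
    chosen: list[int] = []
    taken: set[int] = set()
    for b in rng.permutation(aged):
        clade = set(tree.clade_tips(int(b)).tolist())
        if clade & taken:
            continue
        chosen.append(int(b))
        taken |= clade
        if len(chosen) == n_shifts:
            break
    if len(chosen) < n_shifts:
        raise ValueError("cannot place the requested number of disjoint shifts")
    return sorted(chosen)


def simulate_traits(tree: Phylogeny, spec: ScenarioSpec, seed=None) -> dict:
    """Two-phase continuous traits with planted rate or regime structure.

    Returns ``{"adult": ..., "tadpole": ..., "truth": {...}}``; in coupled
    mode both phases share the planted shift branches, in uncoupled mode
    they are placed independently.
    """
    rng = _rng(spec.seed if seed is None else seed)
    phases = ("adult", "tadpole")
    n_planted = (spec.n_rate_shifts if spec.trait_model == "bm"
                 else spec.n_shifts)
    # OU shifts must predate the present by ~2 half-lives so the planted
    # optimum is effectively reached; BM rate shifts have no such scale
    min_age = (2.0 * np.log(2.0) / spec.ou_alpha
               if spec.trait_model == "ou" else 0.0)
    shift_sets = {}
    first = _plant_shifts(tree, n_planted, spec.min_clade, rng, min_age)
    for ph in phases:
        if spec.coupling == "coupled":
            shift_sets[ph] = list(first)
        else:
            shift_sets[ph] = (first if ph == phases[0] else
                              _plant_shifts(tree, n_planted, spec.min_clade,
                                            rng, min_age))
    out = {"truth": {"shift_branches": shift_sets, "model": spec.trait_model}}
    from .traits import simulate_bm, simulate_ou
    if spec.trait_model == "bm":
        rates_truth = {}
        for ph in phases:
            painting = RegimePainting(tree, shift_sets[ph])
            mult = np.ones(painting.n_regimes)
            mult[1:] = spec.rate_multiplier
            branch_rates = mult[painting.branch_regime]
            x = np.stack([simulate_bm(tree, rng, sigma2=spec.bm_sigma2,
                                      branch_rates=branch_rates)
                          for _ in range(spec.n_axes)], axis=1)
            out[ph] = x[:, 0] if spec.n_axes == 1 else x
            rates_truth[ph] = branch_rates
        out["truth"]["branch_rates"] = rates_truth
    elif spec.trait_model == "ou":
        sd_stat = np.sqrt(spec.ou_sigma2 / (2.0 * spec.ou_alpha))
        thetas_truth = {}
        for ph in phases:
            painting = RegimePainting(tree, shift_sets[ph])
            theta = np.zeros(painting.n_regimes)
            if spec.convergent_regimes:
                # every planted clade converges on one shared optimum
                theta[1:] = spec.theta_offset_sd * sd_stat
            else:
                # alternating signs keep every planted optimum distinct from
                # the background and from each other (non-convergent regimes)
                signs = np.array([(-1.0) ** i
                                  for i in range(painting.n_regimes - 1)])
                theta[1:] = signs * spec.theta_offset_sd * sd_stat
            branch_theta = theta[painting.branch_regime]
            x = np.stack([simulate_ou(tree, rng, spec.ou_alpha, spec.ou_sigma2,
                                      branch_theta, root_value=theta[0])
                          for _ in range(spec.n_axes)], axis=1)
            out[ph] = x[:, 0] if spec.n_axes == 1 else x
            thetas_truth[ph] = theta
        out["truth"]["theta"] = thetas_truth
        out["truth"]["alpha"] = spec.ou_alpha
        out["truth"]["sigma2"] = spec.ou_sigma2
    else:
        raise ValueError("trait_model must be 'bm' or 'ou'")
    return out


def simulate_shift_sets(tree: Phylogeny, n_shifts: int, coupling: str,
                        seed=0, phases=("adult", "tadpole")):
    """Two phases' shift-node sets for concordance testing.

    Shift nodes are placed uniformly without replacement on all non-root
    nodes — the same mechanism the concordance randomization null assumes.
    Coupled mode shares one placement between the phases; uncoupled mode
    draws them independently.  Directions (which child carries the new
    optimum) are drawn uniformly per node; in coupled mode the direction of
    the second phase is redrawn independently, matching a scenario where
    shift positions, not directions, are shared.
    """
    from .shift_concordance import ShiftSet, eligible_nodes
    rng = _rng(seed)
    pool = eligible_nodes(tree)
    if n_shifts > pool.size:
        raise ValueError("more shifts than eligible nodes")
    first = rng.choice(pool, n_shifts, replace=False)
    out = {}
    for i, ph in enumerate(phases):
        if coupling == "coupled" or i == 0:
            nodes = first
        else:
            nodes = rng.choice(pool, n_shifts, replace=False)
        directions = {}
        for v in nodes:
            kids = tree.children[int(v)]
            if kids:
                directions[int(v)] = int(kids[rng.integers(len(kids))])
        out[ph] = ShiftSet(ph, [int(v) for v in nodes], directions)
    return out


# ---------------------------------------------------------------------------
# discrete characters
# ---------------------------------------------------------------------------

def _mk_q(n_states: int, rate: float, ordered: bool) -> np.ndarray:
    """Mk rate matrix: all-pairs rate, or nearest-neighbour steps if ordered."""
    Q = np.zeros((n_states, n_states))
    for i in range(n_states):
        for j in range(n_states):
            if i == j:
                continue
            if ordered and abs(i - j) != 1:
                continue
            Q[i, j] = rate
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def _simulate_chain(tree: Phylogeny, Q: np.ndarray, rng,
                    root_state: int | None = None) -> np.ndarray:
    """One character down the tree: per-branch transition sampling."""
    n_states = Q.shape[0]
    P = {}
    state = np.zeros(tree.n_nodes, dtype=np.int64)
    state[tree.root] = (rng.integers(n_states) if root_state is None
                        else root_state)
    for node in tree.preorder():
        if node == tree.root:
            continue
        L = float(tree.length[node])
        if L not in P:
            P[L] = np.clip(expm(Q * L), 0.0, None)
        probs = P[L][state[tree.parent[node]]]
        probs = probs / probs.sum()
        state[node] = rng.choice(n_states, p=probs)
    return state[tree.tips]


def simulate_mk(tree: Phylogeny, spec: ScenarioSpec, seed=None
                ) -> CharacterMatrix:
    """Independent Mk characters with optional missing cells; ordered
    characters evolve by nearest-neighbour steps."""
    rng = _rng(spec.seed if seed is None else seed)
    n_char = spec.n_characters
    ordered = np.zeros(n_char, dtype=bool)
    n_ord = int(round(spec.ordered_fraction * n_char))
    ordered[:n_ord] = True
    S = np.empty((tree.n_tips, n_char), dtype=np.int64)
    for j in range(n_char):
        Q = _mk_q(spec.n_states, spec.mk_rate, bool(ordered[j]))
        S[:, j] = _simulate_chain(tree, Q, rng)
    if spec.missing_fraction > 0:
        mask = rng.uniform(size=S.shape) < spec.missing_fraction
        S[mask] = MISSING
    return CharacterMatrix(tree.tip_labels, S, ordered)


def simulate_binary_pair(tree: Phylogeny, rate: float, dependence: float,
                         seed=0) -> tuple[np.ndarray, np.ndarray]:
    """A pair of binary characters, independent (dependence=1) or coevolving.

    Under dependence ``d`` the second character switches toward matching the
    first at ``d * rate`` and away at ``rate / d``.
    """
    from .discrete_correlation import build_q, STATES
    rng = _rng(seed)
    r = rate
    d = dependence
    # rates: a01|b0, a01|b1, a10|b0, a10|b1, b01|a0, b01|a1, b10|a0, b10|a1
    rates = np.array([r, r, r, r,
                      r / d, r * d,   # b gains: favored when a=1
                      r * d, r / d])  # b losses: favored when a=0
    Q = build_q(rates, dependent=True)
    joint = _simulate_chain(tree, Q, rng)
    a = np.array([STATES[s][0] for s in joint])
    b = np.array([STATES[s][1] for s in joint])
    return a, b


# ---------------------------------------------------------------------------
# expression tables
# ---------------------------------------------------------------------------

def simulate_expression(spec: ScenarioSpec, seed=None) -> pd.DataFrame:
    """Lognormal FPKM table with planted phase-biased genes and enriched
    morphology annotations in the biased classes."""
    rng = _rng(spec.seed if seed is None else seed)
    n = spec.n_genes
    n_adult = int(round(spec.frac_adult_biased * n))
    n_tad = int(round(spec.frac_tadpole_biased * n))
    truth = np.array(["adult-biased"] * n_adult + ["tadpole-biased"] * n_tad
                     + ["even"] * (n - n_adult - n_tad))
    rng.shuffle(truth)
    base = rng.lognormal(mean=1.5, sigma=1.0, size=n)
    noise_a = rng.lognormal(0.0, spec.expression_noise_sd, size=n)
    noise_t = rng.lognormal(0.0, spec.expression_noise_sd, size=n)
    fa = base * noise_a
    ft = base * noise_t
    fa[truth == "adult-biased"] *= spec.expression_effect
    ft[truth == "tadpole-biased"] *= spec.expression_effect
    flag_p = np.where(truth == "even", spec.morph_flag_even,
                      spec.morph_flag_biased)
    morph = rng.uniform(size=n) < flag_p
    ann = []
    for flagged in morph:
        pool = MORPH_TERMS if flagged else NEUTRAL_TERMS
        terms = rng.choice(pool, size=rng.integers(1, 3), replace=False)
        extra = rng.choice(NEUTRAL_TERMS)
        ann.append("; ".join(list(terms) + [extra]))
    return pd.DataFrame({
        "gene": [f"g{i:05d}" for i in range(n)],
        "fpkm_adult": fa,
        "fpkm_tadpole": ft,
        "annotation": ann,
        "morph_flag": morph,
        "true_class": truth,
    })


# ---------------------------------------------------------------------------
# end-to-end scenario
# ---------------------------------------------------------------------------

def generate_scenario(spec: ScenarioSpec, out_dir=None) -> dict:
    """Generate every input of a scenario; optionally write them to disk
    (Newick tree, two NEXUS matrices, expression TSV, truth JSON)."""
    rng = _rng(spec.seed)
    tree = simulate_tree(spec.n_tips, spec.birth, spec.death, spec.decline,
                         seed=rng)
    traits = simulate_traits(tree, spec, seed=rng)
    chars = {ph: simulate_mk(tree, spec, seed=rng)
             for ph in ("adult", "tadpole")}
    expr = simulate_expression(spec, seed=rng)
    out = {"spec": spec, "tree": tree, "traits": traits, "characters": chars,
           "expression": expr}
    if out_dir is not None:
        from pathlib import Path
        d = Path(out_dir)
        d.mkdir(parents=True, exist_ok=True)
        write_newick(tree, d / "tree.nwk")
        write_nexus_matrix(chars["adult"], d / "adult.nex")
        write_nexus_matrix(chars["tadpole"], d / "tadpole.nex")
        expr.to_csv(d / "expression.tsv", sep="\t", index=False)
        spec.to_yaml(d / "scenario.yaml")
        truth = {
            "shift_branches": traits["truth"]["shift_branches"],
            "model": traits["truth"]["model"],
            "true_expression_class": expr["true_class"].tolist(),
        }
        with open(d / "truth.json", "w") as fh:
            json.dump(truth, fh, indent=1, default=str)
        for ph in ("adult", "tadpole"):
            pd.DataFrame({"species": tree.tip_labels,
                          "trait": traits[ph]}).to_csv(
                d / f"traits_{ph}.tsv", sep="\t", index=False)
    return out
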