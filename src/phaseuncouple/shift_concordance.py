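"""Randomization tests for concordance of regime shifts between two
life-history phases.

Two bespoke tests: (1) do shifts in the two phases sit on the *same nodes*
of the phylogeny more often than random placement predicts, and (2) at the
shared shift nodes, does the *same descendant sublineage* carry the new
optimum in both phases?  Both use the (k+1)/(n+1) randomization p-value so
a result at 1000 replicates is never reported as zero.  Shift counts can
also be binned into 4-Myr intervals (anchored at the present) and the
interval series of the two phases correlated.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .phylo_io import Phylogeny


@dataclass
class ShiftSet:
    """Shift nodes of one phase, with the child lineage carrying the new
    optimum at each shift node."""

    phase: str
    nodes: list[int]
    directions: dict[int, int] = field(default_factory=dict)

    def validate(self, tree: Phylogeny) -> "ShiftSet":
        for v in self.nodes:
            if not 0 <= v < tree.n_nodes:
                raise ValueError(f"shift node {v} not in tree")
        for v, child in self.directions.items():
            if tree.parent[child] != v:
                raise ValueError(
                    f"direction {child} is not a child of shift node {v}")
        return self

    @classmethod
    def from_painting(cls, phase: str, painting) -> "ShiftSet":
        """Build from a RegimePainting: shift node = parent of shift branch,
        direction = the shift branch itself."""
        nodes, directions = [], {}
        for b in painting.shift_branches:
            v = int(painting.tree.parent[b])
            nodes.append(v)
            directions[v] = int(b)
        return cls(phase, nodes, directions)


@dataclass
class RandomizationResult:
    statistic: float
    null: np.ndarray
    p: float
    nreps: int
    seed: int


def _pvalue(statistic: float, null: np.ndarray,
            rng: np.random.Generator | None = None) -> float:
    """Randomization p-value (1 + rank of the empirical statistic) / (n+1).

    Null replicates tying the empirical value are counted as larger with
    probability 1/2 each (a seeded uniform draw over the tie block): the
    statistics here are coarsely discrete, and counting every tie as
    "greater or equal" would make the test far too conservative to hold
    its nominal level.  Without ties this is (1 + #{null >= emp}) / (n+1).
    """
    greater = int((null > statistic + 1e-12).sum())
    ties = int((np.abs(null - statistic) <= 1e-12).sum())
    u = ties if rng is None else int(rng.integers(0, ties + 1))
    return (1 + greater + u) / (null.size + 1)


def shared_shift_ratio(shifts_a: ShiftSet, shifts_b: ShiftSet) -> float:
    """|A intersect B| / max(|A|, |B|) over shift nodes."""
    A, B = set(shifts_a.nodes), set(shifts_b.nodes)
    if not A or not B:
        raise ValueError("shift sets must be nonempty")
    return len(A & B) / max(len(A), len(B))


def eligible_nodes(tree: Phylogeny, internal_only: bool = False) -> np.ndarray:
    """Nodes on which a randomized shift may be placed (all non-root nodes
    by default)."""
    nodes = [v for v in range(tree.n_nodes) if v != tree.root]
    if internal_only:
        nodes = [v for v in nodes if not tree.is_tip(v)]
    return np.array(nodes, dtype=np.int64)


def node_concordance_test(tree: Phylogeny, shifts_a: ShiftSet,
                          shifts_b: ShiftSet, nreps: int = 1000,
                          seed: int = 0,
                          internal_only: bool = False) -> RandomizationResult:
    """Randomize both phases' shift placements and compare the shared-node
    ratio with the empirical one."""
    pool = eligible_nodes(tree, internal_only)
    na, nb = len(set(shifts_a.nodes)), len(set(shifts_b.nodes))
    if na > pool.size or nb > pool.size:
        raise ValueError("more shifts than eligible nodes")
    emp = shared_shift_ratio(shifts_a, shifts_b)
    rng = np.random.default_rng(seed)
    null = np.empty(nreps)
    denom = max(na, nb)
    for i in range(nreps):
        ra = rng.choice(pool, na, replace=False)
        rb = rng.choice(pool, nb, replace=False)
        null[i] = np.intersect1d(ra, rb, assume_unique=True).size / denom
    return RandomizationResult(emp, null, _pvalue(emp, null, rng), nreps, seed)


def direction_concordance_test(tree: Phylogeny, shifts_a: ShiftSet,
                               shifts_b: ShiftSet, nreps: int = 1000,
                               seed: int = 0) -> RandomizationResult:
    """At shared shift nodes, test whether the same child lineage shifted in
    both phases more often than independent uniform child choice predicts."""
    shared = sorted(set(shifts_a.nodes) & set(shifts_b.nodes))
    shared = [v for v in shared
              if v in shifts_a.directions and v in shifts_b.directions]
    if not shared:
        raise ValueError("no shared shift nodes with recorded directions")
    emp = np.mean([shifts_a.directions[v] == shifts_b.directions[v]
                   for v in shared])
    n_children = np.array([len(tree.children[v]) for v in shared])
    rng = np.random.default_rng(seed)
    # same child in both phases with prob 1/n_children at each node
    draws_a = rng.integers(0, n_children, size=(nreps, len(shared)))
    draws_b = rng.integers(0, n_children, size=(nreps, len(shared)))
    null = (draws_a == draws_b).mean(axis=1)
    return RandomizationResult(float(emp), null, _pvalue(emp, null, rng),
                               nreps, seed)


def bin_shifts_by_time(tree: Phylogeny, shifts: ShiftSet,
                       width: float = 4.0) -> dict:
    """Histogram of shift-node ages in intervals [0,w), [w,2w), ... Myr."""
    if width <= 0:
        raise ValueError("width must be > 0")
    n_bins = int(np.ceil(tree.T / width)) or 1
    counts = np.zeros(n_bins, dtype=np.int64)
    for v in shifts.nodes:
        b = min(int(tree.age[v] // width), n_bins - 1)
        counts[b] += 1
    return {"edges": np.arange(n_bins + 1) * width, "counts": counts}


def interval_correlation(series_a, series_b) -> tuple[float, float]:
    """Pearson correlation of paired per-interval values; incomplete pairs
    (NaN in either series) are dropped."""
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("series must have equal length")
    ok = ~(np.isnan(a) | np.isnan(b))
    if ok.sum() < 3:
        raise ValueError("need at least 3 complete interval pairs")
    r, p = stats.pearsonr(a[ok], b[ok])
    return float(r), float(p)
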