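"""Trees, character matrices, configuration and logging.

Shared data model for all downstream analyses: a rooted, ultrametric,
time-calibrated phylogeny with node ages in Myr measured backwards from the
present (tips at age 0, root at age T), and categorical character matrices
with ordered/unordered coding and explicit missing entries.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np
import yaml

#: missing-state marker inside integer character matrices
MISSING = -1

#: relative ultrametricity tolerance (times root age T)
ULTRAMETRIC_RTOL = 1e-6

logger = logging.getLogger("phaseuncouple")


def setup_logging(verbose: bool = False) -> None:
    level = logging.DEBUG if verbose else logging.INFO
    logging.basicConfig(format="%(levelname)s %(name)s: %(message)s", level=level)


def load_config(path) -> dict:
    """Read a YAML configuration file into a plain dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


class NotUltrametricError(ValueError):
    """Root-to-tip path lengths differ by more than the tolerance."""


class DuplicateTaxonError(ValueError):
    """A tip label or matrix row label occurs more than once."""


class Phylogeny:
    """Rooted ultrametric time tree stored as flat parent/length arrays.

    Node ids are 0..n_nodes-1.  Every non-root node carries the length of
    the branch subtending it, so a non-root node id doubles as a branch id.
    Tip ages are renormalized to exactly 0 on construction; internal node
    ages are ``T - depth``.
    """

    def __init__(self, parent, length, labels, check: bool = True):
        self.parent = np.asarray(parent, dtype=np.int64)
        self.length = np.asarray(length, dtype=float)
        self.labels = list(labels)
        n = self.parent.size
        if not (self.length.size == n and len(self.labels) == n):
            raise ValueError("parent, length, labels must have equal size")
        roots = np.flatnonzero(self.parent < 0)
        if roots.size != 1:
            raise ValueError("tree must have exactly one root")
        self.root = int(roots[0])
        self.children: list[list[int]] = [[] for _ in range(n)]
        for i in range(n):
            if i != self.root:
                self.children[self.parent[i]].append(i)
        self.tips = np.array(
            [i for i in range(n) if not self.children[i]], dtype=np.int64
        )
        if check:
            nonroot = np.arange(n) != self.root
            if not np.all(self.length[nonroot] > 0):
                raise ValueError("all branch lengths must be > 0")
        self._finish(check=check)

    # -- construction helpers -------------------------------------------------

    def _finish(self, check: bool) -> None:
        labels = [self.labels[i] for i in self.tips]
        if len(set(labels)) != len(labels):
            raise DuplicateTaxonError("duplicate tip labels")
        order = self._postorder()
        depth = np.zeros(self.n_nodes)
        for i in reversed(order):  # preorder
            if i != self.root:
                depth[i] = depth[self.parent[i]] + self.length[i]
        T = float(depth[self.tips].max())
        if check and T > 0:
            spread = depth[self.tips].max() - depth[self.tips].min()
            if spread > ULTRAMETRIC_RTOL * T:
                raise NotUltrametricError(
                    f"root-to-tip depths differ by {spread:.3g} "
                    f"(tolerance {ULTRAMETRIC_RTOL * T:.3g})"
                )
        # renormalize: stretch pendant branches so every tip sits at age 0
        for i in self.tips:
            self.length[i] += T - depth[i]
            depth[i] = T
        self.depth = depth
        self.T = T
        self.age = T - depth
        self._postorder_cache = order

    def _postorder(self) -> np.ndarray:
        order, stack = [], [self.root]
        while stack:
            node = stack.pop()
            order.append(node)
            stack.extend(self.children[node])
        return np.array(order[::-1], dtype=np.int64)

    # -- basic accessors ------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self.parent.size

    @property
    def n_tips(self) -> int:
        return self.tips.size

    @property
    def tip_labels(self) -> list[str]:
        return [self.labels[i] for i in self.tips]

    def postorder(self) -> np.ndarray:
        return self._postorder_cache

    def preorder(self) -> np.ndarray:
        return self._postorder_cache[::-1]

    def is_tip(self, node: int) -> bool:
        return not self.children[node]

    def branches(self) -> np.ndarray:
        """All branch ids (= non-root node ids), preorder."""
        return np.array([i for i in self.preorder() if i != self.root])

    def clade_tips(self, node: int) -> np.ndarray:
        """Tip ids descending from (and including) ``node``."""
        out, stack = [], [node]
        while stack:
            v = stack.pop()
            if self.is_tip(v):
                out.append(v)
            else:
                stack.extend(self.children[v])
        return np.array(sorted(out), dtype=np.int64)

    def tip_index(self) -> dict[str, int]:
        """Map tip label -> position in ``self.tips`` order."""
        return {self.labels[t]: k for k, t in enumerate(self.tips)}

    def mrca(self, nodes) -> int:
        paths = []
        for v in nodes:
            path = [v]
            while path[-1] != self.root:
                path.append(int(self.parent[path[-1]]))
            paths.append(set(path))
        common = set.intersection(*paths)
        return int(max(common, key=lambda v: self.depth[v]))

    # -- matrices used by Gaussian trait models -------------------------------

    def shared_depth_matrix(self) -> np.ndarray:
        """n_tips x n_tips matrix of MRCA depths (shared time from root)."""
        n = self.n_tips
        S = np.zeros((n, n))
        pos = {int(t): k for k, t in enumerate(self.tips)}
        tipsets: dict[int, list[int]] = {}
        for node in self.postorder():
            if self.is_tip(node):
                tipsets[node] = [pos[node]]
                S[pos[node], pos[node]] = self.depth[node]
                continue
            kids = self.children[node]
            for a in range(len(kids)):
                for b in range(a + 1, len(kids)):
                    ia = np.array(tipsets[kids[a]])[:, None]
                    ib = np.array(tipsets[kids[b]])[None, :]
                    S[ia, ib] = self.depth[node]
                    S[ib.T, ia.T] = self.depth[node]
            tipsets[node] = [k for c in kids for k in tipsets.pop(c)]
        return S

    def patristic_matrix(self) -> np.ndarray:
        """n_tips x n_tips patristic distances (2*(T - shared depth))."""
        S = self.shared_depth_matrix()
        d = self.depth[self.tips]
        return d[:, None] + d[None, :] - 2.0 * S

    # -- editing --------------------------------------------------------------

    def prune_to(self, keep_labels) -> "Phylogeny":
        """Restrict to the given tip labels, collapsing degree-2 nodes."""
        keep = set(keep_labels)
        missing = keep - set(self.tip_labels)
        if missing:
            raise ValueError(f"labels not in tree: {sorted(missing)}")
        keep_node = np.zeros(self.n_nodes, dtype=bool)
        for t in self.tips:
            if self.labels[t] in keep:
                v = int(t)
                while v >= 0 and not keep_node[v]:
                    keep_node[v] = True
                    v = int(self.parent[v])
        # count retained children to find collapsible degree-2 internals
        new_parent, new_length, new_labels = [], [], []
        remap: dict[int, int] = {}

        def n_kept_children(v):
            return sum(keep_node[c] for c in self.children[v])

        def effective(v):
            """Walk down through single-child retained nodes, summing lengths."""
            length = self.length[v] if v != self.root else 0.0
            while not self.is_tip(v) and n_kept_children(v) == 1:
                v = next(c for c in self.children[v] if keep_node[c])
                length += self.length[v]
            return v, length

        # find new root: first node (from old root) with >=2 kept children
        new_root, _ = effective(self.root)
        stack = [(new_root, -1, 0.0)]
        while stack:
            v, par_new, length = stack.pop()
            idx = len(new_parent)
            remap[v] = idx
            new_parent.append(par_new)
            new_length.append(length)
            new_labels.append(self.labels[v])
            for c in self.children[v]:
                if keep_node[c]:
                    ce, clen = effective(c)
                    stack.append((ce, idx, clen))
        return Phylogeny(new_parent, new_length, new_labels)

    # -- newick ---------------------------------------------------------------

    def to_newick(self) -> str:
        def rec(v):
            if self.is_tip(v):
                name = self.labels[v]
            else:
                name = ""
            if self.children[v]:
                name = "(" + ",".join(rec(c) for c in self.children[v]) + ")" + name
            if v == self.root:
                return name
            return f"{name}:{self.length[v]:.17g}"

        return rec(self.root) + ";"

    @classmethod
    def from_newick(cls, newick: str, check: bool = True) -> "Phylogeny":
        try:
            dt = dendropy.Tree.get(data=newick, schema="newick",
                                   suppress_internal_node_taxa=True)
        except Exception as exc:  # dendropy raises its own hierarchy
            if "duplicate" in str(exc).lower():
                raise DuplicateTaxonError(str(exc)) from exc
            raise
        return cls.from_dendropy(dt, check=check)

    @classmethod
    def from_dendropy(cls, dt: dendropy.Tree, check: bool = True) -> "Phylogeny":
        nodes = list(dt.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        parent, length, labels = [], [], []
        for nd in nodes:
            if nd.parent_node is None:
                parent.append(-1)
                length.append(0.0)
            else:
                parent.append(index[id(nd.parent_node)])
                if nd.edge.length is None:
                    raise ValueError("missing branch length in newick")
                length.append(float(nd.edge.length))
            labels.append(nd.taxon.label if nd.taxon is not None else "")
        return cls(parent, length, labels, check=check)


def read_newick(path, check: bool = True) -> Phylogeny:
    """Read a rooted ultrametric tree with branch lengths from a Newick file."""
    with open(path) as fh:
        text = fh.read()
    return Phylogeny.from_newick(text, check=check)


def write_newick(tree: Phylogeny, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")


# ---------------------------------------------------------------------------
# character matrices
# ---------------------------------------------------------------------------

@dataclass
class CharacterMatrix:
    """Species x categorical characters, states as small non-negative ints.

    ``states[i, j] == MISSING`` marks unscored cells (including polymorphic
    entries, which are treated as missing).  ``ordered[j]`` flags characters
    whose states form an ordered continuum so that a 0->2 change counts as
    two steps.
    """

    taxa: list[str]
    states: np.ndarray
    ordered: np.ndarray = field(default=None)

    def __post_init__(self):
        self.states = np.asarray(self.states, dtype=np.int64)
        if self.states.ndim != 2 or self.states.shape[0] != len(self.taxa):
            raise ValueError("states must be (n_taxa, n_characters)")
        if self.ordered is None:
            self.ordered = np.zeros(self.n_characters, dtype=bool)
        self.ordered = np.asarray(self.ordered, dtype=bool)
        if self.ordered.size != self.n_characters:
            raise ValueError("ordered flags must match character count")
        if len(set(self.taxa)) != len(self.taxa):
            raise DuplicateTaxonError("duplicate taxa in character matrix")
        bad = (self.states < MISSING) | (self.states > 9)
        if bad.any():
            raise ValueError("states must be 0..9 or the missing marker")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_characters(self) -> int:
        return self.states.shape[1]

    def subset_taxa(self, keep) -> "CharacterMatrix":
        keep = list(keep)
        idx = {t: i for i, t in enumerate(self.taxa)}
        rows = [idx[t] for t in keep]
        return CharacterMatrix(keep, self.states[rows], self.ordered.copy())


def read_nexus_matrix(path, ordering=None) -> CharacterMatrix:
    """Read a NEXUS DATA/CHARACTERS block into a CharacterMatrix.

    ``ordering`` is an optional boolean sequence of per-character ordered
    flags (the NEXUS file itself is not required to carry a TYPESET).
    Polymorphic (bracketed) entries are read as missing.
    """
    _check_duplicate_rows(path)
    dm = dendropy.StandardCharacterMatrix.get(path=str(path), schema="nexus")
    taxa = [t.label for t in dm.taxon_namespace]
    n_char = max(len(dm[t]) for t in dm.taxon_namespace)
    states = np.full((len(taxa), n_char), MISSING, dtype=np.int64)
    for i, taxon in enumerate(dm.taxon_namespace):
        row = dm[taxon]
        if len(row) != n_char:
            raise ValueError(f"row length mismatch for taxon {taxon.label}")
        for j, cell in enumerate(row):
            sym = cell.symbol
            # polymorphic/uncertain/missing cells expose member_states
            if sym is None or sym in ("?", "-") or \
                    cell.member_states is not None:
                continue
            if not sym.isdigit():
                raise ValueError(f"undeclared state symbol {sym!r}")
            states[i, j] = int(sym)
    ordered = None
    if ordering is not None:
        ordered = np.asarray(list(ordering), dtype=bool)
    return CharacterMatrix(taxa, states, ordered)


def _check_duplicate_rows(path) -> None:
    """dendropy silently merges duplicate taxa; reject them up front."""
    seen, in_matrix = set(), False
    with open(path) as fh:
        for line in fh:
            token = line.strip()
            if not token or token.startswith("["):
                continue
            if token.lower().startswith("matrix"):
                in_matrix = True
                continue
            if in_matrix:
                if token == ";" or token.lower().startswith("end"):
                    break
                name = token.split()[0].rstrip(";")
                if name in seen:
                    raise DuplicateTaxonError(f"taxon {name!r} repeated in matrix")
                seen.add(name)


def write_nexus_matrix(matrix: CharacterMatrix, path) -> None:
    symbols = "".join(
        str(s) for s in range(max(1, int(matrix.states.max(initial=0)) + 1))
    )
    width = max(len(t) for t in matrix.taxa) + 2
    with open(path, "w") as fh:
        fh.write("#NEXUS\nBEGIN DATA;\n")
        fh.write(
            f"  DIMENSIONS NTAX={matrix.n_taxa} NCHAR={matrix.n_characters};\n"
        )
        fh.write(f'  FORMAT DATATYPE=STANDARD SYMBOLS="{symbols}" MISSING=?;\n')
        fh.write("  MATRIX\n")
        for i, taxon in enumerate(matrix.taxa):
            row = "".join(
                "?" if s == MISSING else str(s) for s in matrix.states[i]
            )
            fh.write(f"    {taxon:<{width}}{row}\n")
        fh.write("  ;\nEND;\n")


def prune_to_common(tree: Phylogeny, matrices):
    """Restrict a tree and one or more character matrices to shared species.

    Returns ``(tree, [matrices...])`` with the tip set equal to the
    intersection of the tree's tips and every matrix's taxa.  Requires at
    least three shared species.
    """
    shared = set(tree.tip_labels)
    for m in matrices:
        shared &= set(m.taxa)
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared species (need >= 3)")
    keep = sorted(shared)
    pruned = tree.prune_to(keep) if set(tree.tip_labels) != shared else tree
    return pruned, [m.subset_taxa(keep) for m in matrices]
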