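"""Pairwise character-state transformation distances between species.

For every pair of species the distance is the number of character-state
transformations summed over the characters scored in both species:
``|i - j|`` steps for an ordered character, 1 for any difference in an
unordered character.  Missing data are handled by pairwise deletion.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phylo_io import MISSING, CharacterMatrix


@dataclass
class DistanceMatrix:
    """Symmetric species x species transformation counts.

    ``comparable[i, j]`` counts the characters scored in both species; it is
    the denominator used when distances are normalized.
    """

    species: list[str]
    matrix: np.ndarray
    comparable: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.comparable = np.asarray(self.comparable, dtype=np.int64)
        n = len(self.species)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match species list")
        if not np.allclose(self.matrix, self.matrix.T, equal_nan=True):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.matrix) != 0) or np.any(self.matrix < 0):
            raise ValueError("distances must be >= 0 with zero diagonal")

    @property
    def n(self) -> int:
        return len(self.species)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.species,
                            columns=self.species)


def pairwise_transformations(matrix: CharacterMatrix, normalize: bool = False,
                             missing_policy: str = "error") -> DistanceMatrix:
    """Count character-state transformations between all species pairs.

    ``normalize`` divides each pairwise count by the number of comparable
    characters.  A pair with zero comparable characters is an error unless
    ``missing_policy="skip-pair"``, which records NaN for that pair.
    """
    if matrix.n_taxa < 2:
        raise ValueError("need at least two species")
    if missing_policy not in ("error", "skip-pair"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    S = matrix.states
    n = matrix.n_taxa
    ordered = matrix.ordered
    D = np.zeros((n, n))
    C = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        for j in range(i + 1, n):
            both = (S[i] != MISSING) & (S[j] != MISSING)
            C[i, j] = C[j, i] = both.sum()
            diff = np.abs(S[i] - S[j]).astype(float)
            steps = np.where(ordered, diff, (diff > 0).astype(float))
            d = float(steps[both].sum())
            if C[i, j] == 0:
                if missing_policy == "error":
                    raise ValueError(
                        f"species {matrix.taxa[i]!r} and {matrix.taxa[j]!r} "
                        "share no scored characters"
                    )
                d = np.nan
            elif normalize:
                d = d / C[i, j]
            D[i, j] = D[j, i] = d
    return DistanceMatrix(list(matrix.taxa), D, C)


def recode(matrix: CharacterMatrix, scheme: str = "as-is") -> CharacterMatrix:
    """Recode characters: ``as-is``, ``all-unordered``, or ``binary``.

    ``binary`` maps state 0 to 0 and any state > 0 to 1 (missing preserved);
    ``all-unordered`` keeps states but clears the ordered flags.
    """
    if scheme == "as-is":
        return CharacterMatrix(list(matrix.taxa), matrix.states.copy(),
                               matrix.ordered.copy())
    if scheme == "all-unordered":
        return CharacterMatrix(list(matrix.taxa), matrix.states.copy(),
                               np.zeros(matrix.n_characters, dtype=bool))
    if scheme == "binary":
        S = matrix.states.copy()
        S[S > 0] = 1
        return CharacterMatrix(list(matrix.taxa), S,
                               np.zeros(matrix.n_characters, dtype=bool))
    raise ValueError(f"unknown recoding scheme {scheme!r}")


def jackknife_characters(matrix: CharacterMatrix, drop: int,
                         rng: np.random.Generator) -> CharacterMatrix:
    """Resampling helper: drop ``drop`` characters at random."""
    if not 0 < drop < matrix.n_characters:
        raise ValueError("drop must be in 1..n_characters-1")
    keep = np.sort(rng.choice(matrix.n_characters,
                              matrix.n_characters - drop, replace=False))
    return CharacterMatrix(list(matrix.taxa), matrix.states[:, keep],
                           matrix.ordered[keep])


def write_distance_tsv(dist: DistanceMatrix, path) -> None:
    dist.to_frame().to_csv(path, sep="\t")


def read_distance_tsv(path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    M = df.to_numpy(dtype=float)
    comparable = np.full(M.shape, -1, dtype=np.int64)
    return DistanceMatrix(list(df.index), M, comparable)
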