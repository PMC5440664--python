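"""Phase-biased expression classification from FPKM tables.

Genes are classified by the adult/tadpole FPKM ratio: above 1.6 they are
adult-biased, below 0.4 tadpole-biased, otherwise evenly expressed; genes
below the expression floor in both phases are unclassifiable.  Genes are
flagged as morphology-associated by case-insensitive keyword matching of
their annotation text, and the proportions of flagged genes across classes
are compared with two-sided two-proportion Z-tests.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

CLASSES = ("adult-biased", "tadpole-biased", "even", "unclassifiable")


def compute_fpkm(counts, transcript_length_bp, total_mapped) -> np.ndarray:
    """FPKM = counts * 1e9 / (length * total mapped fragments)."""
    counts = np.asarray(counts, dtype=float)
    length = np.asarray(transcript_length_bp, dtype=float)
    if np.any(length <= 0) or total_mapped <= 0:
        raise ValueError("transcript length and total mapped must be > 0")
    return counts * 1e9 / (length * float(total_mapped))


@dataclass
class PhaseClassification:
    """Per-gene class labels and per-class summaries."""

    table: pd.DataFrame          # input plus a 'phase_class' column
    counts: dict
    morph_fraction: dict
    hi: float
    lo: float
    min_fpkm: float

    def class_genes(self, cls: str) -> pd.DataFrame:
        return self.table[self.table["phase_class"] == cls]


def classify_phase_bias(table: pd.DataFrame, hi: float = 1.6, lo: float = 0.4,
                        min_fpkm: float = 1.0) -> PhaseClassification:
    """Classify genes by the adult/tadpole FPKM ratio.

    The expression floor guards against ratios of near-zero values: a gene
    below ``min_fpkm`` in both phases is unclassifiable; below the floor in
    exactly one phase, it is biased toward the expressed phase.
    """
    if not hi > lo > 0:
        raise ValueError("need hi > lo > 0")
    t = table.copy()
    fa = t["fpkm_adult"].to_numpy(dtype=float)
    ft = t["fpkm_tadpole"].to_numpy(dtype=float)
    if (fa < 0).any() or (ft < 0).any():
        raise ValueError("FPKM values must be >= 0")
    cls = np.full(len(t), "even", dtype=object)
    lo_a, lo_t = fa < min_fpkm, ft < min_fpkm
    cls[lo_a & lo_t] = "unclassifiable"
    cls[lo_t & ~lo_a] = "adult-biased"
    cls[lo_a & ~lo_t] = "tadpole-biased"
    both = ~lo_a & ~lo_t
    with np.errstate(divide="ignore"):
        ratio = np.where(ft > 0, fa / np.where(ft > 0, ft, 1.0), np.inf)
    cls[both & (ratio > hi)] = "adult-biased"
    cls[both & (ratio < lo)] = "tadpole-biased"
    t["phase_class"] = cls
    counts = {c: int((cls == c).sum()) for c in CLASSES}
    morph = {}
    if "morph_flag" in t.columns:
        for c in CLASSES:
            sel = t[t["phase_class"] == c]
            morph[c] = float(sel["morph_flag"].mean()) if len(sel) else np.nan
    return PhaseClassification(t, counts, morph, hi, lo, min_fpkm)


def keyword_flag(annotations, terms) -> np.ndarray:
    """Case-insensitive substring match of any term in each annotation."""
    terms = [str(t).lower() for t in terms]
    if not terms:
        raise ValueError("term list must be nonempty")
    out = np.zeros(len(annotations), dtype=bool)
    for i, ann in enumerate(annotations):
        text = ("" if ann is None or (isinstance(ann, float) and np.isnan(ann))
                else str(ann)).lower()
        out[i] = any(term in text for term in terms)
    return out


def proportion_ztest(k1: int, n1: int, k2: int, n2: int) -> dict:
    """Two-sided pooled-proportion Z-test for k1/n1 vs k2/n2."""
    if n1 <= 0 or n2 <= 0 or k1 > n1 or k2 > n2 or min(k1, k2) < 0:
        raise ValueError("need 0 <= k <= n and n > 0 in both groups")
    p1, p2 = k1 / n1, k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    if pooled <= 0 or pooled >= 1:
        return {"z": 0.0, "p": 1.0}
    se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    z = (p1 - p2) / se
    return {"z": float(z), "p": float(2.0 * norm.sf(abs(z)))}


def phase_bias_report(table: pd.DataFrame, terms=None, hi: float = 1.6,
                      lo: float = 0.4, min_fpkm: float = 1.0) -> dict:
    """Full expression summary: classification, morphology fractions, and
    Z-tests of each biased class against the evenly expressed genes."""
    t = table.copy()
    if terms is not None:
        t["morph_flag"] = keyword_flag(t["annotation"].tolist(), terms)
    result = classify_phase_bias(t, hi=hi, lo=lo, min_fpkm=min_fpkm)
    out = {"counts": result.counts, "morph_fraction": result.morph_fraction,
           "ztests": {}}
    if "morph_flag" in t.columns:
        tt = result.table
        even = tt[tt["phase_class"] == "even"]
        for c in ("adult-biased", "tadpole-biased"):
            sel = tt[tt["phase_class"] == c]
            if len(sel) and len(even):
                out["ztests"][f"{c}_vs_even"] = proportion_ztest(
                    int(sel["morph_flag"].sum()), len(sel),
                    int(even["morph_flag"].sum()), len(even))
    return out
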