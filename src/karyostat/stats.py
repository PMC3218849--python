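"""Shared statistical primitives.

Hypergeometric over-representation tails (exact, via scipy), the
Benjamini-Hochberg and Bonferroni corrections (via statsmodels), the
aberration-class enrichment table, and the confusion-matrix metrics used
by the trisomy-index classifier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


def hypergeom_tail(k: int, n: int, K: int, M: int) -> float:
    """One-sided over-representation tail P(X >= k), X ~ Hypergeom(M, K, n).

    M is the population size, K the number of marked items, n the draw
    size and k the observed overlap.  Exact computation, no normal
    approximation.
    """
    if not (0 <= k <= min(n, K)) or K > M or n > M:
        raise ValueError(f"inconsistent counts: k={k}, n={n}, K={K}, M={M}")
    return float(hypergeom.sf(k - 1, M, K, n))


def bh_fdr(pvalues, level: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up at ``level``; returns (reject, adjusted)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, adj, _, _ = multipletests(p, alpha=level, method="fdr_bh")
    return reject, adj


def bonferroni(pvalues, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Bonferroni: adjusted = min(1, p*m); reject iff adjusted < alpha."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    adj = np.minimum(1.0, p * p.size)
    return adj < alpha, adj


@dataclass(frozen=True)
class ConfusionMetrics:
    """Sensitivity, specificity, PPV and their F combination.

    F = 2 * PPV * Sensitivity / (PPV + Sensitivity); ratios with a zero
    denominator are reported as 0 with ``undefined=True``.
    """

    sensitivity: float
    specificity: float
    ppv: float
    f_score: float
    undefined: bool = False


def confusion_metrics(tp: int, fp: int, tn: int, fn: int) -> ConfusionMetrics:
    counts = (tp, fp, tn, fn)
    if any(c < 0 for c in counts):
        raise ValueError("counts must be non-negative")
    if sum(counts) == 0:
        raise ValueError("all counts are zero")
    undefined = False

    def ratio(num, den):
        nonlocal undefined
        if den == 0:
            undefined = True
            return 0.0
        return num / den

    sens = ratio(tp, tp + fn)
    spec = ratio(tn, tn + fp)
    ppv = ratio(tp, tp + fp)
    f = 0.0 if (sens == 0 or ppv == 0) else 2 * ppv * sens / (ppv + sens)
    return ConfusionMetrics(sens, spec, ppv, f, undefined)


def enrichment_table(
    aberration_table: pd.DataFrame,
    karyotypes: pd.DataFrame,
    fdr_level: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric enrichment of every observed aberration-class pair.

    ``aberration_table`` has columns record_id/canonical_id (one row per
    aberration occurrence); ``karyotypes`` has record_id/tumor_class.
    For each observed pair: M = total karyotypes, K = karyotypes in the
    class, n = karyotypes carrying the aberration, k = their overlap.
    The BH (q) and Bonferroni adjustments are computed over the single
    family of all observed pairs.
    """
    M = karyotypes["record_id"].nunique()
    class_of = karyotypes.set_index("record_id")["tumor_class"]
    occ = aberration_table.drop_duplicates(["record_id", "canonical_id"]).copy()
    occ["tumor_class"] = occ["record_id"].map(class_of)
    class_sizes = karyotypes.groupby("tumor_class")["record_id"].nunique()
    ab_support = occ.groupby("canonical_id")["record_id"].nunique()
    overlap = (
        occ.groupby(["canonical_id", "tumor_class"])["record_id"]
        .nunique()
        .reset_index(name="k")
    )
    rows = []
    for ab, cls, k in overlap.itertuples(index=False):
        K = int(class_sizes[cls])
        n = int(ab_support[ab])
        rows.append((ab, cls, M, K, n, int(k), hypergeom_tail(int(k), n, K, M)))
    out = pd.DataFrame(
        rows, columns=["aberration", "class", "M", "K", "n", "k", "p"]
    ).sort_values(["aberration", "class"], ignore_index=True)
    _, out["q"] = bh_fdr(out["p"].to_numpy(), level=fdr_level)
    _, out["p_bonferroni"] = bonferroni(out["p"].to_numpy())
    return out
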