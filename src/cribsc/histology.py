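"""Stain quantification scores and multi-group comparisons.

The RNAscope H-score summarises chromogenic staining intensity per region:
3 x %strong + 2 x %moderate + 1 x %weak, range 0-300.  The Halo-style
expression score multiplies the percent of positive stromal cells by the
relative mean expression per positive stromal cell (total intensity /
positive-cell count; 0 when no cell is positive).  Histology classes are
compared by one-way ANOVA with Tukey's multiple comparisons.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd


def h_score(pct_weak, pct_moderate, pct_strong) -> np.ndarray | float:
    """H-score = 3 x %strong + 2 x %moderate + 1 x %weak (range 0-300)."""
    w = np.asarray(pct_weak, dtype=float)
    m = np.asarray(pct_moderate, dtype=float)
    s = np.asarray(pct_strong, dtype=float)
    if np.any(w < 0) or np.any(m < 0) or np.any(s < 0):
        raise ValueError("bin percentages must be >= 0")
    if np.any(w + m + s > 100 + 1e-9):
        raise ValueError("bin percentages sum to more than 100")
    out = 3.0 * s + 2.0 * m + 1.0 * w
    return float(out) if out.ndim == 0 else out


def h_score_table(regions: pd.DataFrame) -> pd.Series:
    """H-score per row of a stain table (pct_weak/pct_moderate/pct_strong)."""
    return pd.Series(
        h_score(regions["pct_weak"], regions["pct_moderate"], regions["pct_strong"]),
        index=regions.index, name="h_score",
    )


def expression_score(n_stromal, n_positive, total_intensity) -> np.ndarray | float:
    """Percent positive stromal cells x mean intensity per positive cell.

    The relative mean expression is total intensity divided by the number
    of positive cells, defined as 0 when no cell is positive (continuity).
    """
    ns = np.asarray(n_stromal, dtype=float)
    npos = np.asarray(n_positive, dtype=float)
    ti = np.asarray(total_intensity, dtype=float)
    if np.any(ns <= 0):
        raise ValueError("n_stromal must be > 0")
    if np.any(npos > ns):
        raise ValueError("n_positive cannot exceed n_stromal")
    if np.any(ti < 0):
        raise ValueError("total_intensity must be >= 0")
    pct_pos = 100.0 * npos / ns
    rel = np.divide(ti, npos, out=np.zeros_like(ti), where=npos > 0)
    out = pct_pos * rel
    return float(out) if out.ndim == 0 else out


def expression_score_table(regions: pd.DataFrame) -> pd.Series:
    """Expression score per row (n_stromal/n_positive/total_intensity)."""
    return pd.Series(
        expression_score(regions["n_stromal"], regions["n_positive"],
                         regions["total_intensity"]),
        index=regions.index, name="expression_score",
    )


def group_compare(values: dict[str, np.ndarray]) -> tuple[float, float, pd.DataFrame]:
    """One-way ANOVA with Tukey HSD pairwise comparisons.

    ``values`` maps group label -> 1-d array of scores (each n >= 2).
    Returns (F statistic, ANOVA p, pairwise table with Tukey-adjusted p).
    """
    if len(values) < 2:
        raise ValueError("need at least 2 groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in sorted(values.items())}
    for k, v in arrays.items():
        if len(v) < 2:
            raise ValueError(f"group {k!r} has n < 2")
    pooled = np.concatenate(list(arrays.values()))
    if np.all(pooled == pooled[0]):
        raise ValueError("zero variance everywhere; ANOVA undefined")
    f_stat, p = stats.f_oneway(*arrays.values())
    labels = np.concatenate([[k] * len(v) for k, v in arrays.items()])
    tukey = pairwise_tukeyhsd(pooled, labels)
    g1_idx, g2_idx = np.triu_indices(len(arrays), k=1)
    names = list(arrays)
    pairwise = pd.DataFrame({
        "group1": [names[i] for i in g1_idx],
        "group2": [names[j] for j in g2_idx],
        "meandiff": tukey.meandiffs,
        "p_adj": tukey.pvalues,   # unrounded, unlike summary()
        "reject": tukey.reject,
    })
    return float(f_stat), float(p), pairwise
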