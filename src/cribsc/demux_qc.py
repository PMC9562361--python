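"""Hashtag demultiplexing, cell quality control and cluster composition.

Pooled benign-enriched and tumor-enriched specimens are distinguished by
two oligo-tagged hashing antibodies.  A cell is called for a specimen when
exactly one tag is positive; double-positive cells (intersample doublets)
and double-negative cells are removed before any downstream analysis.
Retained cells then pass the study's QC gate: 200-8000 unique genes
(inclusive), more than 500 total counts (strict), and at most 40%
mitochondrial content.
"""

from __future__ import annotations

import logging
import warnings

import anndata as ad
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# hashtag demultiplexing
# ---------------------------------------------------------------------------

def call_hashtags(
    pool: ad.AnnData, min_count: int = 10, dominance: float = 3.0
) -> ad.AnnData:
    """Assign each cell to benign/tumor/doublet/negative from hashtag counts.

    A tag is *positive* iff its count is >= ``min_count``.  Exactly one
    positive tag assigns the cell to that condition.  When both tags are
    positive the cell is still a singlet if one tag dominates (count >=
    ``dominance`` x the other's); otherwise it is a ``doublet``.  Neither
    tag positive -> ``negative``.  The four outcomes partition the pool.
    Returns a copy with ``obs['assigned']`` filled in.
    """
    for col in ("tag_benign", "tag_tumor"):
        if col not in pool.obs:
            raise ValueError(f"missing hashtag column {col!r}")
    if min_count <= 0 or dominance <= 0:
        raise ValueError("min_count and dominance must be positive")
    tb = pool.obs["tag_benign"].to_numpy(dtype=float)
    tt = pool.obs["tag_tumor"].to_numpy(dtype=float)
    pos_b = tb >= min_count
    pos_t = tt >= min_count
    benign = (pos_b & ~pos_t) | (pos_b & pos_t & (tb >= dominance * tt))
    tumor = (pos_t & ~pos_b) | (pos_b & pos_t & (tt >= dominance * tb))
    assigned = np.select(
        [benign, tumor, pos_b & pos_t],
        ["benign", "tumor", "doublet"],
        default="negative",
    )
    out = pool.copy()
    out.obs["assigned"] = pd.Categorical(
        assigned, categories=["benign", "tumor", "doublet", "negative"]
    )
    return out


def drop_unassigned(pool: ad.AnnData) -> ad.AnnData:
    """Remove doublet and negative cells, keeping benign/tumor singlets."""
    if "assigned" not in pool.obs or (pool.obs["assigned"] == "unset").any():
        raise ValueError("call_hashtags must run before drop_unassigned")
    assigned = pool.obs["assigned"].astype(str)
    keep = assigned.isin(["benign", "tumor"]).to_numpy()
    n_doub = int((assigned == "doublet").sum())
    n_neg = int((assigned == "negative").sum())
    logger.info(
        "drop_unassigned: removed %d doublets and %d negatives of %d cells",
        n_doub, n_neg, pool.n_obs,
    )
    return pool[keep].copy()


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def compute_qc(pool: ad.AnnData) -> pd.DataFrame:
    """Per-cell QC: unique genes detected, total counts, mitochondrial %.

    ``pct_mito`` is 100 x (mitochondrial counts / total counts); a cell
    with zero total counts gets ``pct_mito = 0`` and is flagged.
    """
    if "mito" not in pool.var or not pool.var["mito"].any():
        raise ValueError("var['mito'] flags must mark a non-empty gene subset")
    X = pool.X
    mito = pool.var["mito"].to_numpy()
    if not hasattr(X, "tocsr"):
        X = np.asarray(X)
        n_genes = (X > 0).sum(axis=1)
        total = X.sum(axis=1)
        mito_counts = X[:, mito].sum(axis=1)
    else:
        X = X.tocsr()
        n_genes = np.asarray((X > 0).sum(axis=1)).ravel()
        total = np.asarray(X.sum(axis=1)).ravel()
        mito_counts = np.asarray(X[:, mito].sum(axis=1)).ravel()
    zero = total == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(zero, 0.0, 100.0 * mito_counts / np.where(zero, 1, total))
    qc = pd.DataFrame(
        {
            "n_genes_detected": np.asarray(n_genes, dtype=int),
            "total_counts": np.asarray(total, dtype=int),
            "pct_mito": pct,
            "zero_counts_flag": zero,
        },
        index=pool.obs_names,
    )
    if zero.any():
        logger.warning("compute_qc: %d cells have zero total counts", int(zero.sum()))
    return qc


def qc_filter(
    pool: ad.AnnData,
    qc: pd.DataFrame,
    min_genes: int = 200,
    max_genes: int = 8000,
    min_counts_exclusive: int = 500,
    max_mito_pct: float = 40.0,
) -> ad.AnnData:
    """Retain cells passing the QC gate.

    Retained iff ``min_genes <= n_genes_detected <= max_genes`` (inclusive),
    ``total_counts > min_counts_exclusive`` (strict) and
    ``pct_mito <= max_mito_pct`` (inclusive).
    """
    qc = qc.loc[pool.obs_names]
    keep = (
        (qc["n_genes_detected"] >= min_genes)
        & (qc["n_genes_detected"] <= max_genes)
        & (qc["total_counts"] > min_counts_exclusive)
        & (qc["pct_mito"] <= max_mito_pct)
    ).to_numpy()
    logger.info("qc_filter: retained %d of %d cells", int(keep.sum()), pool.n_obs)
    return pool[keep].copy()


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------

def composition(pool: ad.AnnData) -> pd.DataFrame:
    """Percent of each (patient, condition, fraction) sample's cells per cluster.

    Within every (patient, condition, fraction) group the percentages sum
    to 100.  Empty groups produce no rows.
    """
    if "cluster" not in pool.obs:
        raise ValueError("cluster labels missing from obs")
    cond_col = "assigned" if "assigned" in pool.obs else "condition"
    obs = pool.obs[["patient", cond_col, "fraction", "cluster"]].copy()
    obs.columns = ["patient", "condition", "fraction", "cluster"]
    counts = (
        obs.astype(str)
        .groupby(["patient", "condition", "fraction", "cluster"], sort=True)
        .size()
        .rename("n_cells")
        .reset_index()
    )
    counts = counts[counts["n_cells"] > 0]
    totals = counts.groupby(["patient", "condition", "fraction"])["n_cells"].transform("sum")
    counts["percent"] = 100.0 * counts["n_cells"] / totals
    return counts.reset_index(drop=True)


# ---------------------------------------------------------------------------
# exact Wilcoxon matched-pair signed-rank test
# ---------------------------------------------------------------------------

def _signed_rank_distribution(ranks: np.ndarray) -> tuple[np.ndarray, int]:
    """Distribution of 2*W+ over all sign assignments, by convolution.

    Ranks may be half-integers (ties averaged), so everything is scaled by
    2 to stay integral.  Returns (counts over 0..M2, M2) with M2 = 2*sum(ranks).
    """
    r2 = np.rint(2.0 * ranks).astype(int)
    m2 = int(r2.sum())
    dist = np.zeros(m2 + 1, dtype=float)
    dist[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: m2 + 1 - r]
        dist = dist + shifted
    return dist, m2


def wilcoxon_paired(x, y) -> tuple[float, float]:
    """Exact two-tailed Wilcoxon matched-pair signed-rank test.

    ``x`` and ``y`` are paired per-patient values (e.g. benign and tumor).
    Zero differences are dropped (Wilcoxon's original treatment); the
    statistic is W+ = sum of ranks of positive differences ``y - x``.  For
    up to 25 nonzero differences the two-sided p-value is exact, computed
    from the full distribution of W+ over the ``2^m`` equiprobable sign
    assignments (via convolution over ranks); above that, a normal
    approximation with continuity and tie corrections is used.

    Returns ``(W+, p)``; all-zero differences give ``p = 1`` with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 1:
        raise ValueError("x and y must be equal-length 1-d arrays, n >= 1")
    d = y - x
    d = d[d != 0]
    m = len(d)
    if m == 0:
        warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
        return 0.0, 1.0
    absd = np.abs(d)
    order = np.argsort(absd, kind="stable")
    ranks = np.empty(m, dtype=float)
    sorted_abs = absd[order]
    i = 0
    rank_of_sorted = np.empty(m, dtype=float)
    while i < m:
        j = i
        while j + 1 < m and sorted_abs[j + 1] == sorted_abs[i]:
            j += 1
        rank_of_sorted[i:j + 1] = 0.5 * (i + j) + 1.0  # average rank, 1-based
        i = j + 1
    ranks[order] = rank_of_sorted
    w_plus = float(ranks[d > 0].sum())
    m_total = float(ranks.sum())

    if m <= 25:
        dist, m2 = _signed_rank_distribution(ranks)
        w2 = int(round(2.0 * w_plus))
        # two-sided: P(|W - M/2| >= |w - M/2|) over the 2^m assignments
        dev = abs(2 * w2 - m2)
        offsets = np.abs(2 * np.arange(m2 + 1) - m2)
        p = float(dist[offsets >= dev].sum() / dist.sum())
    else:
        mu = m_total / 2.0
        # variance with tie correction: sum(r_i^2)/4
        sigma2 = float(np.sum(ranks**2)) / 4.0
        z = (abs(w_plus - mu) - 0.5) / np.sqrt(sigma2)
        from scipy.stats import norm

        p = float(min(1.0, 2.0 * norm.sf(max(z, 0.0))))
    return w_plus, min(p, 1.0)
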