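"""Patient-paired tumor-vs-benign differential expression.

The study design pairs a benign-enriched and a tumor (ICC/IDC)-enriched
specimen within each patient.  Per cluster, cells are summed to a
pseudobulk profile per (patient, condition); genes pass the detection
rules (CPM >= 1 counts a gene as detected in a cell; the official gene set
keeps genes detected in more than 20% of cells); and a paired t-test on
log2(CPM + 1) across patient pairs yields per-gene log2 fold-changes and
Benjamini-Hochberg q-values.  Genes are then ranked by signed
significance, sign(log2FC) x (-log10 p), for preranked GSEA.
"""

from __future__ import annotations

import logging
import warnings

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# normalisation and detection
# ---------------------------------------------------------------------------

def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million normalisation of a genes x samples table.

    Every non-zero column is scaled to sum to 1e6.  All-zero columns are
    excluded with a warning.
    """
    totals = counts.sum(axis=0)
    zero = totals == 0
    if zero.any():
        warnings.warn(
            f"excluding {int(zero.sum())} all-zero columns from CPM",
            stacklevel=2,
        )
    kept = counts.loc[:, ~zero]
    return kept * (1e6 / totals[~zero])


def cell_cpm(pool: ad.AnnData) -> sp.csr_matrix:
    """Per-cell CPM (cells x genes, sparse). Zero-count cells stay zero."""
    X = pool.X.tocsr() if hasattr(pool.X, "tocsr") else sp.csr_matrix(pool.X)
    totals = np.asarray(X.sum(axis=1)).ravel()
    scale = np.divide(1e6, totals, out=np.zeros_like(totals, dtype=float),
                      where=totals > 0)
    return sp.diags(scale) @ X


def detected_mask(pool: ad.AnnData, threshold: float = 1.0) -> sp.csr_matrix:
    """Boolean cells x genes matrix: gene detected in cell iff CPM >= threshold.

    The detection rule is stated for TPM; with 3' UMI counts there is no
    transcript-length term, so CPM is the equivalent quantity.
    """
    c = cell_cpm(pool)
    return (c >= threshold).tocsr() if sp.issparse(c) else sp.csr_matrix(c >= threshold)


def select_preliminary(mask: sp.spmatrix, gene_ids, k: int = 10000) -> list[str]:
    """Top ``k`` genes by number of cells in which they are detected.

    Ties at the cutoff are broken lexicographically by gene id, making the
    selection deterministic.  ``k`` beyond the gene count returns all genes.
    """
    gene_ids = np.asarray(gene_ids, dtype=object)
    n_det = np.asarray(mask.sum(axis=0)).ravel()
    order = sorted(range(len(gene_ids)), key=lambda i: (-n_det[i], gene_ids[i]))
    return [str(gene_ids[i]) for i in order[: min(k, len(gene_ids))]]


def select_official(mask: sp.spmatrix, gene_ids, min_frac: float = 0.20) -> list[str]:
    """Genes detected in strictly more than ``min_frac`` of cells."""
    gene_ids = np.asarray(gene_ids, dtype=object)
    frac = np.asarray(mask.sum(axis=0)).ravel() / mask.shape[0]
    return [str(g) for g, f in zip(gene_ids, frac) if f > min_frac]


# ---------------------------------------------------------------------------
# pseudobulk and the paired test
# ---------------------------------------------------------------------------

def pseudobulk(pool: ad.AnnData, cluster) -> pd.DataFrame:
    """Sum counts over each (patient, condition)'s cells in ``cluster``.

    Returns a genes x (patient, condition) table of integer counts.  The
    condition column is ``assigned`` when demultiplexing has run, else
    ``condition``.
    """
    cond_col = "assigned" if (
        "assigned" in pool.obs
        and not (pool.obs["assigned"].astype(str) == "unset").any()
    ) else "condition"
    if cond_col not in pool.obs:
        raise ValueError("no condition assignment available (run call_hashtags)")
    in_cluster = pool.obs["cluster"].astype(str) == str(cluster)
    if not in_cluster.any():
        raise ValueError(f"cluster {cluster!r} has no cells")
    sub = pool[in_cluster.to_numpy()]
    conds = set(sub.obs[cond_col].astype(str))
    for c in ("benign", "tumor"):
        if c not in conds:
            raise ValueError(f"cluster {cluster!r} has no {c} cells in any patient")
    X = sub.X.tocsr() if hasattr(sub.X, "tocsr") else sp.csr_matrix(sub.X)
    keys = list(zip(sub.obs["patient"].astype(str), sub.obs[cond_col].astype(str)))
    columns = sorted(set(keys))
    data = {}
    keys = np.array(keys, dtype=object)
    for patient, cond in columns:
        rows = np.flatnonzero((keys[:, 0] == patient) & (keys[:, 1] == cond))
        data[(patient, cond)] = np.asarray(X[rows].sum(axis=0)).ravel().astype(int)
    pb = pd.DataFrame(data, index=pool.var_names)
    pb.columns = pd.MultiIndex.from_tuples(pb.columns, names=["patient", "condition"])
    return pb


def paired_test(pb: pd.DataFrame, genes=None) -> pd.DataFrame:
    """Paired t-test on log2(CPM + 1) pseudobulk across patient pairs.

    Only patients with both a benign and a tumor column contribute.  The
    per-gene log2 fold-change is the mean paired difference (tumor -
    benign); p-values come from the paired t-test and are BH-adjusted
    across the tested genes.  Zero-variance differences give p = 1 and are
    flagged.  Fewer than 3 complete pairs is an error.
    """
    patients = sorted(
        {p for p, _ in pb.columns}
        & {p for p, c in pb.columns if c == "benign"}
        & {p for p, c in pb.columns if c == "tumor"}
    )
    if len(patients) < 3:
        raise ValueError(f"need >= 3 complete patient pairs, have {len(patients)}")
    if genes is not None:
        pb = pb.loc[list(genes)]
    norm = cpm(pb)
    log = np.log2(norm + 1.0)
    benign = log.loc[:, [(p, "benign") for p in patients]].to_numpy()
    tumor = log.loc[:, [(p, "tumor") for p in patients]].to_numpy()
    diffs = tumor - benign
    lfc = diffs.mean(axis=1)
    zero_var = diffs.std(axis=1, ddof=1) == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_rel(tumor, benign, axis=1)
    p = np.where(zero_var, 1.0, p)
    p = np.clip(np.nan_to_num(p, nan=1.0), np.finfo(float).tiny, 1.0)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    out = pd.DataFrame(
        {
            "log2fc": lfc,
            "p": p,
            "q": q,
            "n_patients": len(patients),
            "zero_variance": zero_var,
        },
        index=pb.index,
    )
    out.index.name = "gene"
    return out


def rank_genes(de: pd.DataFrame) -> pd.DataFrame:
    """Signed-significance ranking: score = sign(log2FC) x (-log10 p).

    Ordered descending; ties broken by |log2FC| descending then gene id.
    p = 0 is clamped to the smallest positive float (logged).
    """
    p = de["p"].to_numpy(dtype=float)
    if (p == 0).any():
        logger.warning("rank_genes: clamping %d zero p-values", int((p == 0).sum()))
        p = np.clip(p, np.finfo(float).tiny, None)
    score = np.sign(de["log2fc"].to_numpy()) * (-np.log10(p))
    ranked = pd.DataFrame({"gene": de.index, "score": score,
                           "abs_lfc": de["log2fc"].abs().to_numpy()})
    ranked = ranked.sort_values(
        by=["score", "abs_lfc", "gene"], ascending=[False, False, True]
    ).reset_index(drop=True)
    return ranked[["gene", "score"]]
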