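"""Ligand-receptor screening between a source and a target cluster.

Significantly upregulated genes of the source (cancer-cell) comparison are
intersected with the ligand column of a ligand-receptor pair table; the
cognate receptors' expression is then summarised in a target cluster
(fraction of cells expressing, mean CPM).  The bundled pair table is a
small synthetic structural stand-in for a FANTOM5-style reference; a
full CSV with ``ligand``/``receptor`` columns can be supplied instead.
"""

from __future__ import annotations

import logging

import anndata as ad
import numpy as np
import pandas as pd

from .paired_de import cell_cpm

logger = logging.getLogger(__name__)

# Synthetic stand-in pair table (FANTOM5-style layout, not a reproduction):
# a handful of literature-familiar pairs plus generic placeholders.
_BUILTIN_PAIRS = [
    ("JAG1", "NOTCH1"), ("JAG1", "NOTCH2"), ("JAG1", "NOTCH3"),
    ("JAG1", "NOTCH4"), ("PDGFA", "PDGFRA"), ("FGF13", "FGFR1"),
    ("TGFB1", "TGFBR1"), ("CCL2", "CCR2"), ("VEGFA", "KDR"),
    ("DLL4", "NOTCH1"), ("WNT5A", "FZD5"), ("IL6", "IL6R"),
]


def builtin_lr_table() -> pd.DataFrame:
    """The bundled synthetic ligand-receptor pair table."""
    return pd.DataFrame(_BUILTIN_PAIRS, columns=["ligand", "receptor"])


def load_lr_table(source) -> pd.DataFrame:
    """Load and validate a ligand-receptor table (CSV path or DataFrame)."""
    lr = source.copy() if isinstance(source, pd.DataFrame) else pd.read_csv(source)
    for col in ("ligand", "receptor"):
        if col not in lr.columns:
            raise ValueError(f"ligand-receptor table needs a {col!r} column")
        if lr[col].astype(str).str.len().eq(0).any():
            raise ValueError(f"empty gene id in {col!r} column")
    if lr.empty:
        raise ValueError("ligand-receptor table is empty")
    before = len(lr)
    lr = lr.drop_duplicates(["ligand", "receptor"]).reset_index(drop=True)
    if len(lr) < before:
        logger.info("load_lr_table: dropped %d duplicate pairs", before - len(lr))
    return lr


def screen_ligands(
    de: pd.DataFrame, lr: pd.DataFrame, q_max: float = 0.05, logfc_min: float = 0.0
) -> list[str]:
    """Significantly upregulated genes that are known ligands.

    Selected iff q <= ``q_max``, log2FC > ``logfc_min`` and the gene
    appears in the table's ligand column; ordered by q ascending (ties by
    gene id).
    """
    if lr.empty:
        raise ValueError("ligand-receptor table is empty")
    ligands = set(lr["ligand"])
    hits = de[(de["q"] <= q_max) & (de["log2fc"] > logfc_min)
              & de.index.isin(ligands)]
    hits = hits.sort_values(by=["q"], kind="stable")
    hits = hits.iloc[np.lexsort((hits.index.to_numpy(), hits["q"].to_numpy()))]
    return list(hits.index)


def receptor_expression(
    ligands: list[str],
    lr: pd.DataFrame,
    pool: ad.AnnData,
    target_cluster,
    min_fraction: float | None = None,
) -> pd.DataFrame:
    """Cognate-receptor expression of selected ligands in a target cluster.

    Per (ligand, receptor) pair: the fraction of target-cluster cells with
    count > 0 for the receptor and its mean CPM there.  Receptors absent
    from the count matrix are reported with fraction 0 and flagged.  An
    optional ``min_fraction`` filters the rows (no filter by default).
    """
    in_cluster = (pool.obs["cluster"].astype(str) == str(target_cluster)).to_numpy()
    if not in_cluster.any():
        raise ValueError(f"target cluster {target_cluster!r} is empty")
    sub = pool[in_cluster]
    cpm_mat = cell_cpm(sub)
    var_index = {g: i for i, g in enumerate(sub.var_names)}
    X = sub.X.tocsr() if hasattr(sub.X, "tocsr") else np.asarray(sub.X)

    rows = []
    for lig in ligands:
        for rec in lr.loc[lr["ligand"] == lig, "receptor"]:
            if rec in var_index:
                j = var_index[rec]
                col = X[:, j]
                expr = np.asarray(col.todense()).ravel() if hasattr(col, "todense") \
                    else np.asarray(col).ravel()
                frac = float((expr > 0).mean())
                mean_cpm = float(np.asarray(cpm_mat[:, j].todense()).ravel().mean())
                absent = False
            else:
                frac, mean_cpm, absent = 0.0, 0.0, True
                logger.warning("receptor %s absent from count matrix", rec)
            rows.append(
                {"ligand": lig, "receptor": rec, "target_fraction": frac,
                 "target_mean_cpm": mean_cpm, "receptor_absent": absent}
            )
    out = pd.DataFrame(
        rows, columns=["ligand", "receptor", "target_fraction",
                       "target_mean_cpm", "receptor_absent"]
    )
    if min_fraction is not None:
        out = out[out["target_fraction"] >= min_fraction].reset_index(drop=True)
    return out
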