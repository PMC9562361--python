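"""TCR clonotype assembly, repertoire diversity and clonal dynamics.

Cells are grouped into clonotypes by the exact multiset of their
productive chains (chain type + CDR3 nucleotide sequence).  Cells with
more than 4 productive chains are removed beforehand; compositions of
2 alpha + 1 beta or 1 alpha + 2 beta chains are expected, and
2 alpha + 2 beta cells are retained but flagged.  Diversity is summarised
by Simpson clonality, the square root of Simpson's index sum(p_i^2) over
clonotype proportional abundances, and by richness (unique clonotypes as
a percent of clonotype-assigned cells).  A clonotype counts as expanded
when its tumor frequency is at least double its benign frequency (or it
is tumor-exclusive with >= 2 cells); contracted symmetrically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CONDITIONS = ("benign", "tumor")


@dataclass
class ClonotypeTable:
    """Clonotype assignments and per-condition counts.

    ``clonotypes``: one row per clonotype (key, n_cells, per-condition
    counts, 2a+2b flag).  ``cells``: one row per assigned barcode with its
    clonotype id and condition (and patient when available).
    """

    clonotypes: pd.DataFrame
    cells: pd.DataFrame

    def frequencies(self, condition: str) -> pd.Series:
        """Proportional abundances p_i in one condition.

        p_i = cells of clonotype i / all clonotype-assigned cells in that
        condition; clonotypes absent from the condition are omitted.
        """
        col = f"n_{condition}"
        counts = self.clonotypes[col]
        counts = counts[counts > 0]
        total = counts.sum()
        if total == 0:
            raise ValueError(f"no clonotype-assigned cells in {condition!r}")
        return counts / total


def filter_cells(chains: pd.DataFrame, max_productive: int = 4) -> pd.DataFrame:
    """Remove barcodes with more than ``max_productive`` productive chains.

    Non-productive chains never count toward the limit.
    """
    if "productive" not in chains.columns:
        raise ValueError("contig table must carry a 'productive' column")
    prod = chains[chains["productive"].astype(bool)]
    n_prod = prod.groupby("barcode").size()
    bad = set(n_prod[n_prod > max_productive].index)
    if bad:
        logger.info("filter_cells: removed %d cells with > %d productive chains",
                    len(bad), max_productive)
    return chains[~chains["barcode"].isin(bad)].reset_index(drop=True)


def assemble_clonotypes(chains: pd.DataFrame) -> ClonotypeTable:
    """Group cells into clonotypes by exact productive-chain multiset.

    The clonotype key is the sorted multiset of (chain, CDR3nt) tuples over
    a cell's productive chains; cells sharing a key share a clonotype.
    2 alpha + 2 beta keys are permitted but flagged.  Barcodes with no
    productive chain are excluded (logged).  Requires a ``condition``
    column on the contig table for per-condition counts.
    """
    prod = chains[chains["productive"].astype(bool)]
    all_bc = chains["barcode"].unique()
    no_prod = len(all_bc) - prod["barcode"].nunique()
    if no_prod:
        logger.info("assemble_clonotypes: %d barcodes without productive chains "
                    "excluded", no_prod)
    meta_cols = [c for c in ("condition", "patient") if c in chains.columns]

    keys = (
        prod.groupby("barcode")[["chain", "cdr3_nt"]]
        .apply(lambda df: tuple(sorted(map(tuple, df.to_numpy()))))
        .rename("key")
    )
    cells = keys.to_frame()
    if meta_cols:
        meta = chains.drop_duplicates("barcode").set_index("barcode")[meta_cols]
        cells = cells.join(meta)

    unique_keys = sorted(cells["key"].unique())
    key_to_id = {k: f"c{i:05d}" for i, k in enumerate(unique_keys)}
    cells["clonotype"] = [key_to_id[k] for k in cells["key"]]

    rows = []
    for key in unique_keys:
        cid = key_to_id[key]
        sub = cells[cells["key"] == key]
        chain_types = [c for c, _ in key]
        n_a, n_b = chain_types.count("TRA"), chain_types.count("TRB")
        row = {
            "clonotype": cid,
            "key": key,
            "n_cells": len(sub),
            "n_tra": n_a,
            "n_trb": n_b,
            "flag_2a2b": n_a == 2 and n_b == 2,
        }
        for cond in CONDITIONS:
            row[f"n_{cond}"] = (
                int((sub["condition"] == cond).sum()) if "condition" in sub else 0
            )
        rows.append(row)
    clonotypes = pd.DataFrame(rows).set_index("clonotype")
    return ClonotypeTable(clonotypes=clonotypes, cells=cells.drop(columns=["key"]))


def simpson_clonality(freqs) -> float:
    """Simpson clonality sqrt(sum p_i^2) of a frequency vector summing to 1."""
    p = np.asarray(freqs, dtype=float)
    if p.size == 0:
        raise ValueError("empty repertoire")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"frequencies must sum to 1, got {p.sum():.12g}")
    return float(np.sqrt(np.sum(p**2)))


def richness(table: ClonotypeTable, condition: str) -> float:
    """Percent of distinct clonotypes among clonotype-assigned cells."""
    col = f"n_{condition}"
    counts = table.clonotypes[col]
    counts = counts[counts > 0]
    n_cells = counts.sum()
    if n_cells == 0:
        raise ValueError(f"no clonotype-assigned cells in {condition!r}")
    return 100.0 * len(counts) / n_cells


def classify_dynamics(table: ClonotypeTable) -> pd.DataFrame:
    """Classify every clonotype as expanded / contracted / unchanged / unclassified.

    Shared clonotypes: expanded iff f_tumor >= 2 f_benign; contracted iff
    f_tumor <= 0.5 f_benign (both boundaries inclusive); else unchanged.
    Condition-exclusive clonotypes are expanded (tumor-only) or contracted
    (benign-only) iff they have >= 2 cells, else unclassified.
    """
    ct = table.clonotypes
    fb = pd.Series(0.0, index=ct.index)
    ft = pd.Series(0.0, index=ct.index)
    if (ct["n_benign"] > 0).any():
        f = table.frequencies("benign")
        fb.loc[f.index] = f
    if (ct["n_tumor"] > 0).any():
        f = table.frequencies("tumor")
        ft.loc[f.index] = f

    records = []
    for cid in ct.index:
        nb, nt = int(ct.at[cid, "n_benign"]), int(ct.at[cid, "n_tumor"])
        b, t = float(fb[cid]), float(ft[cid])
        if nb > 0 and nt > 0:
            if t >= 2.0 * b:
                cls = "expanded"
            elif t <= 0.5 * b:
                cls = "contracted"
            else:
                cls = "unchanged"
        elif nt > 0:
            cls = "expanded" if nt >= 2 else "unclassified"
        elif nb > 0:
            cls = "contracted" if nb >= 2 else "unclassified"
        else:
            cls = "unclassified"
        records.append(
            {"clonotype": cid, "freq_benign": b, "freq_tumor": t,
             "n_benign": nb, "n_tumor": nt, "class": cls}
        )
    return pd.DataFrame(records).set_index("clonotype")


def top_clonotypes(
    table: ClonotypeTable, n: int = 20, clusters: pd.Series | None = None
) -> pd.DataFrame:
    """The ``n`` clonotypes with most cells, with per-cluster/condition counts.

    Ordered by total cells descending, then tumor cells descending, then
    clonotype id.  ``clusters`` maps barcode -> cluster label (e.g. joined
    from the expression pool); per-cluster counts then sum to the
    clonotype size.  Requesting more clonotypes than exist returns all.
    """
    ct = table.clonotypes.reset_index()
    ct = ct.sort_values(
        by=["n_cells", "n_tumor", "clonotype"], ascending=[False, False, True]
    ).head(n)
    out = ct.set_index("clonotype")[["n_cells", "n_benign", "n_tumor"]].copy()
    if clusters is not None:
        cells = table.cells.join(clusters.rename("cluster"), how="left")
        pivot = (
            cells[cells["clonotype"].isin(out.index)]
            .groupby(["clonotype", "cluster"], observed=True)
            .size()
            .unstack(fill_value=0)
        )
        pivot.columns = [f"cluster_{c}" for c in pivot.columns]
        out = out.join(pivot).fillna(0)
    return out
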