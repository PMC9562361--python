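"""Readers and writers for the pipeline's plain-text interchange formats.

10x-style Matrix Market triplets (matrix.mtx + features.tsv +
barcodes.tsv, genes x cells on disk as Cell Ranger writes them), a
cell-metadata TSV, GMT gene-set files, two-column RNK rankings, contig
CSVs and survival/stain CSVs.  Matrix IO goes through
``scipy.io.mmread``/``mmwrite``.
"""

from __future__ import annotations

from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

from .gsea import GeneSet


def write_10x_mtx(pool: ad.AnnData, outdir) -> Path:
    """Write a 10x-style triplet plus a cell-metadata TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = pool.X.tocsr() if hasattr(pool.X, "tocsr") else sp.csr_matrix(pool.X)
    mmwrite(outdir / "matrix.mtx", X.T.tocoo(), field="integer")
    feats = pd.DataFrame({"gene_id": pool.var_names, "mito": pool.var["mito"]})
    feats.to_csv(outdir / "features.tsv", sep="\t", index=False, header=False)
    pd.Series(pool.obs_names).to_csv(
        outdir / "barcodes.tsv", sep="\t", index=False, header=False
    )
    pool.obs.to_csv(outdir / "cell_metadata.tsv", sep="\t")
    return outdir


def read_10x_mtx(indir) -> ad.AnnData:
    """Read a triplet written by :func:`write_10x_mtx`."""
    indir = Path(indir)
    X = sp.csr_matrix(mmread(indir / "matrix.mtx")).T.tocsr()
    feats = pd.read_csv(indir / "features.tsv", sep="\t", header=None,
                        names=["gene_id", "mito"])
    barcodes = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)[0]
    var = feats.set_index("gene_id")
    var["mito"] = var["mito"].astype(bool)
    meta_path = indir / "cell_metadata.tsv"
    if meta_path.exists():
        obs = pd.read_csv(meta_path, sep="\t", index_col=0)
        obs.index = obs.index.astype(str)
    else:
        obs = pd.DataFrame(index=barcodes.astype(str))
    return ad.AnnData(X=X.astype(np.int64), obs=obs, var=var)


def read_gmt(path) -> list[GeneSet]:
    """Parse a GMT file: name <tab> description <tab> gene1 <tab> ..."""
    sets = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets.append(GeneSet(parts[0], tuple(g for g in parts[2:] if g)))
    return sets


def write_gmt(sets: list[GeneSet], path) -> Path:
    path = Path(path)
    with path.open("w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, "na", *gs.members]) + "\n")
    return path


def write_rnk(ranked: pd.DataFrame, path) -> Path:
    """Two-column gene/score ranking, preranked-GSEA style."""
    path = Path(path)
    ranked[["gene", "score"]].to_csv(path, sep="\t", index=False, header=False)
    return path


def read_rnk(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None, names=["gene", "score"])


def write_contigs(chains: pd.DataFrame, path) -> Path:
    path = Path(path)
    chains.to_csv(path, index=False)
    return path


def read_contigs(path) -> pd.DataFrame:
    chains = pd.read_csv(path)
    chains["productive"] = chains["productive"].astype(bool)
    return chains
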