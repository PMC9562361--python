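#!/usr/bin/env python
"""Ligand-receptor screen from the paired DE results.

Intersects the significantly upregulated tumor genes with the ligand
column of a pair table and summarises cognate receptor expression
(fraction of cells expressing, mean CPM) in a target stromal cluster.
Writes ligrec.tsv under results/.
"""

import argparse
from pathlib import Path

import pandas as pd

from cribsc import io, pipeline
from cribsc.synth import TruthTables

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1,
                    help="unused; accepted for uniform invocation")
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()

kept = io.read_10x_mtx(args.out / "pool_filtered")
de = pd.read_csv(args.out / "de.tsv", sep="\t", index_col=0)
truth_genes = pd.read_csv(args.out / "pool" / "truth_genes.tsv", sep="\t",
                          index_col=0)
truth = TruthTables(cells=pd.DataFrame(), genes=truth_genes)

res = pipeline.run_ligrec(de, kept, truth)
res["receptor_expression"].to_csv(args.out / "ligrec.tsv", sep="\t", index=False)

n_up = len(truth_genes.query("is_de and log2fc > 0"))
print(f"Ligand screen: {len(res['ligands'])} of {n_up} planted upregulated "
      f"ligands pass q<=0.05.")
print(res["receptor_expression"].head(10).to_string(index=False))
print("Wrote ligrec.tsv.")
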