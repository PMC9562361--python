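"""End-to-end orchestration of the paired single-cell analysis.

One seeded call runs the full chain the package implements: synthetic
paired pool -> hashtag demultiplexing -> QC -> per-cluster pseudobulk
paired differential expression -> signed-significance ranking -> preranked
GSEA -> ligand-receptor screen, alongside the TCR repertoire, survival
and histology stages.  Used by the analysis drivers, the smoke tests and
the acceptance script so all three exercise identical code.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import demux_qc, gsea, histology, ligrec, paired_de, signatures, synth, tcr

#: cluster whose tumor cells carry the planted effects (an epithelial cluster)
DE_CLUSTER = 1


def default_config(seed: int) -> synth.SynthConfig:
    """Study-design defaults with planted DE in one epithelial cluster.

    15 genes are upregulated (log2FC +2) and 10 downregulated (log2FC -2)
    in tumor cells of cluster 1; everything else follows the generator
    defaults (7 patients, 30/25/45 sorted fractions, 30:70 benign:tumor).
    """
    up = [(DE_CLUSTER, f"g{i:04d}", 2.0) for i in range(400, 415)]
    down = [(DE_CLUSTER, f"g{i:04d}", -2.0) for i in range(430, 440)]
    return synth.SynthConfig(seed=seed, de_spec=up + down)


def run_scrna(config: synth.SynthConfig) -> dict:
    """Pool generation through demux, QC, paired DE and gene ranking."""
    pool, truth = synth.generate_paired_scrna(config)
    called = demux_qc.call_hashtags(pool)

    singlet = ~(truth.cells["is_doublet"] | truth.cells["is_negative"])
    agree = (
        called.obs.loc[singlet.to_numpy(), "assigned"].astype(str)
        == truth.cells.loc[singlet, "condition"]
    )
    demux_accuracy = float(agree.mean())

    assigned = demux_qc.drop_unassigned(called)
    qc = demux_qc.compute_qc(assigned)
    kept = demux_qc.qc_filter(assigned, qc)

    pb = paired_de.pseudobulk(kept, DE_CLUSTER)
    in_cluster = kept[(kept.obs["cluster"].astype(str) == str(DE_CLUSTER)).to_numpy()]
    mask = paired_de.detected_mask(in_cluster)
    official = paired_de.select_official(mask, kept.var_names)
    de = paired_de.paired_test(pb, genes=official)
    ranked = paired_de.rank_genes(de)
    return {
        "pool": pool,
        "truth": truth,
        "demux_accuracy": demux_accuracy,
        "n_cells_pooled": pool.n_obs,
        "n_assigned": assigned.n_obs,
        "n_qc_pass": kept.n_obs,
        "kept": kept,
        "qc": qc,
        "composition": demux_qc.composition(kept),
        "pseudobulk": pb,
        "n_official_genes": len(official),
        "de": de,
        "ranked": ranked,
    }


def run_gsea(ranked: pd.DataFrame, truth: synth.TruthTables,
             n_perm: int = 1000, seed: int = 17) -> pd.DataFrame:
    """GSEA of the planted up/down gene sets plus random control sets."""
    genes = truth.genes
    up = genes.index[(genes["is_de"]) & (genes["log2fc"] > 0)].tolist()
    down = genes.index[(genes["is_de"]) & (genes["log2fc"] < 0)].tolist()
    rng = np.random.default_rng(seed)
    in_list = [g for g in ranked["gene"]]
    sets = {
        "planted_up": up,
        "planted_down": down,
        "random_a": list(rng.choice(in_list, size=20, replace=False)),
        "random_b": list(rng.choice(in_list, size=20, replace=False)),
    }
    return gsea.gsea_preranked(ranked, sets, n_perm=n_perm, seed=seed)


def run_ligrec(de: pd.DataFrame, kept, truth: synth.TruthTables,
               target_cluster: int = 2) -> dict:
    """Ligand-receptor screen using planted up-DE genes as ligands.

    The pair table maps each planted upregulated gene to a marker-like
    receptor: a gene well expressed in the target cluster (here simply a
    highly expressed gene), so the screen has a known answer.
    """
    genes = truth.genes
    up = genes.index[(genes["is_de"]) & (genes["log2fc"] > 0)].tolist()
    in_target = kept[(kept.obs["cluster"].astype(str) == str(target_cluster)).to_numpy()]
    X = in_target.X
    mean_expr = np.asarray(X.mean(axis=0)).ravel()
    mean_expr[kept.var["mito"].to_numpy()] = -1  # mito genes are not receptors
    receptors = [str(g) for g in
                 np.asarray(kept.var_names)[np.argsort(-mean_expr)[: len(up)]]]
    lr = ligrec.load_lr_table(pd.DataFrame({"ligand": up, "receptor": receptors}))
    ligands = ligrec.screen_ligands(de, lr)
    expr = ligrec.receptor_expression(ligands, lr, kept, target_cluster)
    return {"lr_table": lr, "ligands": ligands, "receptor_expression": expr}


def run_tcr(seed: int, n_clonotypes: int = 60, n_cells: int = 800) -> dict:
    """Paired TCR repertoire with planted expansions/contractions."""
    rng = np.random.default_rng(seed)
    base = rng.dirichlet(np.full(n_clonotypes, 0.6))
    shift = np.ones(n_clonotypes)
    shift[:6] = 4.0     # expanded in tumor
    shift[6:12] = 0.25  # contracted in tumor
    ft = base * shift
    ft /= ft.sum()
    chains, truth = synth.generate_tcr(
        base, ft, {"benign": n_cells, "tumor": n_cells},
        violation_frac=0.02, seed=seed + 1,
    )
    kept = tcr.filter_cells(chains)
    table = tcr.assemble_clonotypes(kept)
    dyn = tcr.classify_dynamics(table)
    return {
        "chains": chains,
        "truth": truth,
        "table": table,
        "clonality_benign": tcr.simpson_clonality(table.frequencies("benign")),
        "clonality_tumor": tcr.simpson_clonality(table.frequencies("tumor")),
        "richness_benign": tcr.richness(table, "benign"),
        "richness_tumor": tcr.richness(table, "tumor"),
        "dynamics": dyn,
        "top20": tcr.top_clonotypes(table, 20),
    }


def run_survival(seed: int, n_a: int = 492, n_b: int = 131,
                 hazard_ratio: float = 3.0) -> dict:
    """Dual-cohort signature analysis with a 4-gene fibroblast signature.

    Cohort sizes default to those of the two public prostate cohorts the
    synthetic data stand in for (n=492 and n=131).
    """
    sig = ["CTHRC1", "ASPN", "FAP", "ENG"]
    candidates = sig + ["TGFB1", "TNC", "SFRP4", "CCL2"]
    cohort_a = synth.generate_survival_cohort(
        n_a, sig, hazard_ratio, seed=seed, n_noise_genes=4)
    cohort_b = synth.generate_survival_cohort(
        n_b, sig, hazard_ratio, seed=seed + 1, n_noise_genes=4)
    for c in (cohort_a, cohort_b):
        for g in candidates:
            if g not in c.columns:
                rng = np.random.default_rng(abs(hash(g)) % (2**31))
                c[g] = rng.normal(size=len(c))
    res_a = signatures.evaluate_signature(cohort_a, sig)
    res_b = signatures.evaluate_signature(cohort_b, sig)
    refined = signatures.refine_signature(candidates, cohort_a, cohort_b)
    return {"cohort_a": cohort_a, "cohort_b": cohort_b,
            "result_a": res_a, "result_b": res_b, "refined": refined}


def run_histology(seed: int, n_per_class: int = 12) -> dict:
    """Stain scoring and class comparison on a synthetic stain table."""
    params = {
        "benign": synth.StainClassParams(bin_alpha=(3.0, 1.0, 0.2, 8.0)),
        "G3": synth.StainClassParams(bin_alpha=(3.0, 2.0, 1.0, 6.0)),
        "ICC_IDC": synth.StainClassParams(bin_alpha=(1.0, 3.0, 4.0, 2.0)),
    }
    table = synth.generate_stain_table(
        {c: n_per_class for c in params}, params, seed=seed)
    table["h_score"] = histology.h_score_table(table)
    table["expr_score"] = histology.expression_score_table(table)
    groups = {c: sub["h_score"].to_numpy()
              for c, sub in table.groupby("histology")}
    f_stat, p, tukey = histology.group_compare(groups)
    return {"table": table, "anova_f": f_stat, "anova_p": p, "tukey": tukey}


def run_end_to_end(seed: int, config: synth.SynthConfig | None = None,
                   n_perm: int = 1000) -> dict:
    """The full pipeline from one seed; returns every stage's outputs."""
    config = config or default_config(seed)
    out = run_scrna(config)
    out["gsea"] = run_gsea(out["ranked"], out["truth"], n_perm=n_perm,
                           seed=seed + 17)
    out["ligrec"] = run_ligrec(out["de"], out["kept"], out["truth"])
    out["tcr"] = run_tcr(seed + 101)
    out["survival"] = run_survival(seed + 202)
    out["histology"] = run_histology(seed + 303)
    return out
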