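"""Synthetic data generators with known ground truth.

Every input the pipeline consumes is generated here: paired multiplexed
scRNA-seq count pools, TCR contig tables, survival cohorts and stain
quantification tables.  The defaults emulate the study design the package
analyses: 7 patients, each contributing a benign-enriched and a tumor
(ICC/IDC)-enriched specimen; three flow-sorted fractions (immune CD45+,
epithelial EpCAM+, other CD45-EpCAM-) recombined at 30/25/45%; benign and
tumor pools mixed 30:70; two specimen hashtags per cell with
negative-binomial on/off-target counts; cluster-structured cell types with
marker genes; a per-cell mitochondrial fraction; and clonotype frequency
distributions for the TCR repertoire.

All generators are fully determined by their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from ._alloc import largest_remainder

FRACTIONS = ("immune", "epithelial", "other")
CONDITIONS = ("benign", "tumor")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class SynthConfig:
    """Parameters of the paired multiplexed scRNA-seq generator.

    Counts are drawn gene-wise from a negative binomial with fixed
    dispersion and cluster-specific mean shifts for marker genes.  The
    mitochondrial fraction of each cell is imposed by rescaling the
    mitochondrial gene means (Beta-distributed target fraction).  Doublets
    carry on-target hashtag signal on both tags; negatives carry background
    on both.
    """

    n_patients: int = 7
    cells_per_patient: int = 600          # combined benign+tumor pool size
    fraction_mix: tuple[float, float, float] = (0.30, 0.25, 0.45)
    condition_mix: float = 0.30           # benign share of the combined pool
    n_genes: int = 1000
    n_clusters: int = 6
    markers_per_cluster: int = 10
    marker_fold: float = 8.0
    de_spec: list[tuple[int, str, float]] = field(default_factory=list)
    mito_gene_count: int = 13
    mito_beta: tuple[float, float] = (2.0, 8.0)
    hashtag_signal: float = 200.0         # NB mean, on-target tag
    hashtag_noise: float = 3.0            # NB mean, off-target tag
    doublet_rate: float = 0.03
    negative_rate: float = 0.02
    dispersion: float = 0.5               # NB dispersion (1/size)
    base_mean: float = 2.0                # scale of per-gene baseline means
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1 or self.cells_per_patient < 1:
            raise ValueError("n_patients and cells_per_patient must be >= 1")
        if self.n_genes < 1 or self.n_clusters < 1:
            raise ValueError("n_genes and n_clusters must be >= 1")
        if self.mito_gene_count < 0 or self.mito_gene_count >= self.n_genes:
            raise ValueError("mito_gene_count must be in [0, n_genes)")
        fm = np.asarray(self.fraction_mix, dtype=float)
        if fm.shape != (3,) or np.any(fm < 0) or np.any(fm > 1):
            raise ValueError("fraction_mix must be three proportions in [0, 1]")
        if abs(fm.sum() - 1.0) > 1e-9:
            raise ValueError("fraction_mix must sum to 1")
        for p in (self.condition_mix, self.doublet_rate, self.negative_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("proportions must lie in [0, 1]")
        if self.doublet_rate + self.negative_rate > 1.0:
            raise ValueError("doublet_rate + negative_rate must be <= 1")
        for cluster, gene, _ in self.de_spec:
            if not 0 <= cluster < self.n_clusters:
                raise ValueError(f"unknown cluster in de_spec: {cluster}")
            if not isinstance(gene, str):
                raise ValueError("de_spec genes must be gene-id strings")

    def with_(self, **kwargs) -> "SynthConfig":
        return replace(self, **kwargs)


@dataclass
class TruthTables:
    """Ground truth for one synthetic dataset.

    ``cells`` has one row per generated cell (true condition, fraction,
    cluster, doublet/negative status); ``genes`` one row per gene (DE
    status, planted effect, mito flag).
    """

    cells: pd.DataFrame
    genes: pd.DataFrame


def gene_names(config: SynthConfig) -> list[str]:
    """Gene ids: ordinary genes ``g0000``.., mitochondrial last, ``MT-m00``.."""
    n_ord = config.n_genes - config.mito_gene_count
    names = [f"g{i:04d}" for i in range(n_ord)]
    names += [f"MT-m{i:02d}" for i in range(config.mito_gene_count)]
    return names


def cluster_fraction_map(config: SynthConfig) -> dict[int, str]:
    """Clusters are dealt round-robin to the three sorted fractions."""
    return {c: FRACTIONS[c % 3] for c in range(config.n_clusters)}


def _nb_sample(rng: np.random.Generator, mean, dispersion: float):
    """Negative binomial draws parameterised by mean and dispersion (1/size)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + np.maximum(mean, 1e-12))
    return rng.negative_binomial(size, p)


def _baseline_means(rng: np.random.Generator, config: SynthConfig) -> np.ndarray:
    """Log-normal per-gene baseline means, scaled to ``base_mean`` on average."""
    mu = rng.lognormal(mean=0.0, sigma=1.0, size=config.n_genes)
    return mu * (config.base_mean / np.exp(0.5))


def generate_paired_scrna(config: SynthConfig) -> tuple[ad.AnnData, TruthTables]:
    """Generate the paired, hashtag-multiplexed single-cell count pool.

    Returns an :class:`anndata.AnnData` (cells x genes, sparse integer
    counts) whose ``obs`` carries the barcode, patient, sorted-fraction
    label, cluster label, two hashtag count columns (``tag_benign``,
    ``tag_tumor``) and an unset ``assigned`` condition column, plus the
    matching :class:`TruthTables`.

    Cell allocation to conditions and fractions is exact by count
    (largest-remainder rounding of the configured proportions) before the
    doublet/negative hashtag corruptions are injected; those corruptions
    alter hashtag counts only, never the transcriptome or the truth labels.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = gene_names(config)
    n_genes = config.n_genes
    mito_mask = np.array([g.startswith("MT-") for g in genes])
    clus_frac = cluster_fraction_map(config)
    frac_clusters = {
        f: [c for c, fr in clus_frac.items() if fr == f] for f in FRACTIONS
    }
    for f in FRACTIONS:
        if not frac_clusters[f]:
            raise ValueError(
                "n_clusters too small: every sorted fraction needs a cluster"
            )

    base = _baseline_means(rng, config)
    # marker genes: distinct non-mito genes per cluster, mean boosted in-cluster
    n_ord = n_genes - config.mito_gene_count
    need = config.markers_per_cluster * config.n_clusters
    if need > n_ord:
        raise ValueError("not enough ordinary genes for the requested markers")
    marker_pool = rng.choice(n_ord, size=need, replace=False)
    markers = {
        c: marker_pool[c * config.markers_per_cluster:(c + 1) * config.markers_per_cluster]
        for c in range(config.n_clusters)
    }

    gene_idx = {g: i for i, g in enumerate(genes)}
    de_effect = {}  # (cluster, gene_index) -> log2 fold-change tumor vs benign
    for cluster, gene, lfc in config.de_spec:
        if gene not in gene_idx:
            raise ValueError(f"unknown gene in de_spec: {gene}")
        de_effect[(cluster, gene_idx[gene])] = lfc

    # per-cell plan -----------------------------------------------------
    rows = []
    for p in range(config.n_patients):
        n_benign, n_tumor = largest_remainder(
            config.cells_per_patient,
            (config.condition_mix, 1.0 - config.condition_mix),
        )
        for cond, n_cond in zip(CONDITIONS, (n_benign, n_tumor)):
            frac_counts = largest_remainder(n_cond, config.fraction_mix)
            for f, nf in zip(FRACTIONS, frac_counts):
                clusters = rng.choice(frac_clusters[f], size=nf)
                for c in clusters:
                    rows.append((f"P{p + 1}", cond, f, int(c)))
    plan = pd.DataFrame(rows, columns=["patient", "condition", "fraction", "cluster"])
    n_cells = len(plan)
    plan.index = [f"BC{i:06d}" for i in range(n_cells)]
    plan.index.name = "barcode"

    # counts ------------------------------------------------------------
    # group cells by (cluster, condition): shared mean vector per group
    counts = np.zeros((n_cells, n_genes), dtype=np.int64)
    for (cluster, cond), sub in plan.groupby(["cluster", "condition"], sort=True):
        mu = base.copy()
        mu[markers[cluster]] *= config.marker_fold
        if cond == "tumor":
            for (c, gi), lfc in de_effect.items():
                if c == cluster:
                    mu[gi] *= 2.0 ** lfc
        idx = plan.index.get_indexer(sub.index)
        block = _nb_sample(
            rng, np.broadcast_to(mu, (len(idx), n_genes)), config.dispersion
        )
        counts[idx] = block

    # impose mitochondrial fraction per cell
    if config.mito_gene_count:
        target = rng.beta(*config.mito_beta, size=n_cells)
        nonmito_tot = counts[:, ~mito_mask].sum(axis=1)
        mito_budget = nonmito_tot * target / np.maximum(1.0 - target, 1e-6)
        w = base[mito_mask] / base[mito_mask].sum()
        mito_mu = mito_budget[:, None] * w[None, :]
        counts[:, mito_mask] = _nb_sample(rng, mito_mu, config.dispersion)
    else:
        target = np.zeros(n_cells)

    # hashtags ----------------------------------------------------------
    n_doub, n_neg, _ = largest_remainder(
        n_cells,
        (config.doublet_rate, config.negative_rate,
         1.0 - config.doublet_rate - config.negative_rate),
    )
    corrupted = rng.choice(n_cells, size=n_doub + n_neg, replace=False)
    is_doublet = np.zeros(n_cells, dtype=bool)
    is_negative = np.zeros(n_cells, dtype=bool)
    is_doublet[corrupted[:n_doub]] = True
    is_negative[corrupted[n_doub:]] = True

    on_b = (plan["condition"] == "benign").to_numpy()
    mean_b = np.where(on_b, config.hashtag_signal, config.hashtag_noise)
    mean_t = np.where(on_b, config.hashtag_noise, config.hashtag_signal)
    mean_b = np.where(is_doublet, config.hashtag_signal, mean_b)
    mean_t = np.where(is_doublet, config.hashtag_signal, mean_t)
    mean_b = np.where(is_negative, config.hashtag_noise, mean_b)
    mean_t = np.where(is_negative, config.hashtag_noise, mean_t)
    tag_benign = _nb_sample(rng, mean_b, config.dispersion)
    tag_tumor = _nb_sample(rng, mean_t, config.dispersion)

    obs = plan.copy()
    obs["tag_benign"] = tag_benign
    obs["tag_tumor"] = tag_tumor
    obs["assigned"] = "unset"
    # the pipeline must not see the truth condition; keep it in TruthTables only
    obs = obs.drop(columns=["condition"])

    var = pd.DataFrame(index=pd.Index(genes, name="gene_id"))
    var["mito"] = mito_mask

    adata = ad.AnnData(X=sp.csr_matrix(counts), obs=obs, var=var)

    truth_cells = plan.copy()
    truth_cells["is_doublet"] = is_doublet
    truth_cells["is_negative"] = is_negative
    truth_cells["target_mito_frac"] = target
    truth_genes = pd.DataFrame(index=pd.Index(genes, name="gene_id"))
    truth_genes["mito"] = mito_mask
    truth_genes["is_de"] = False
    truth_genes["de_cluster"] = -1
    truth_genes["log2fc"] = 0.0
    for (cluster, gi), lfc in de_effect.items():
        truth_genes.iloc[gi, truth_genes.columns.get_loc("is_de")] = True
        truth_genes.iloc[gi, truth_genes.columns.get_loc("de_cluster")] = cluster
        truth_genes.iloc[gi, truth_genes.columns.get_loc("log2fc")] = lfc

    return adata, TruthTables(cells=truth_cells, genes=truth_genes)


# ---------------------------------------------------------------------------
# TCR repertoires
# ---------------------------------------------------------------------------

_NT = np.array(list("ACGT"))
_CHAIN_COMPOSITIONS = (
    (("TRA",), ("TRB",)),                 # 1 alpha + 1 beta
    (("TRA", "TRA"), ("TRB",)),           # 2 alpha + 1 beta
    (("TRA",), ("TRB", "TRB")),           # 1 alpha + 2 beta
)


def _random_cdr3(rng: np.random.Generator, length: int = 36) -> str:
    return "".join(rng.choice(_NT, size=length))


def generate_tcr(
    freq_benign,
    freq_tumor,
    n_cells: dict[str, int],
    chain_mix: tuple[float, float, float] = (0.88, 0.07, 0.05),
    violation_frac: float = 0.0,
    nonproductive_rate: float = 0.1,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a paired TCR contig table with known clonotype truth.

    ``freq_benign`` / ``freq_tumor`` are clonotype frequency vectors of
    equal length (each summing to 1, or to 0 for an absent condition);
    ``n_cells`` maps condition -> number of T cells to draw.  Each
    clonotype is assigned a fixed productive chain composition drawn from
    ``chain_mix`` (1a+1b, 2a+1b, 1a+2b) with CDR3 nucleotide sequences
    generated once, so all cells of a clonotype share one chain multiset.
    A ``violation_frac`` share of cells receive extra productive chains
    (total > 4) to exercise the downstream chain filter, and cells may
    additionally carry non-productive chains that the pipeline must ignore.

    Returns ``(chains, truth)``: a contig table with columns ``barcode,
    chain, cdr3_nt, productive, condition`` and a per-cell truth table.
    """
    fb = np.asarray(freq_benign, dtype=float)
    ft = np.asarray(freq_tumor, dtype=float)
    if fb.shape != ft.shape:
        raise ValueError("frequency vectors must have equal length")
    for name, f in (("benign", fb), ("tumor", ft)):
        s = f.sum()
        if s > 0 and abs(s - 1.0) > 1e-9:
            raise ValueError(f"{name} frequencies must sum to 1, got {s:.12g}")
        if np.any(f < 0):
            raise ValueError("frequencies must be non-negative")
    if not 0.0 <= violation_frac <= 1.0:
        raise ValueError("violation_frac must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_clono = len(fb)

    comp_idx = rng.choice(3, size=n_clono, p=np.asarray(chain_mix) / np.sum(chain_mix))
    clono_chains = []
    for k in range(n_clono):
        alphas, betas = _CHAIN_COMPOSITIONS[comp_idx[k]]
        chains = [("TRA", _random_cdr3(rng)) for _ in alphas]
        chains += [("TRB", _random_cdr3(rng)) for _ in betas]
        clono_chains.append(chains)

    records = []
    truth_rows = []
    cell_no = 0
    for cond, freqs in (("benign", fb), ("tumor", ft)):
        n = n_cells.get(cond, 0)
        if n == 0 or freqs.sum() == 0:
            continue
        draws = rng.choice(n_clono, size=n, p=freqs)
        violate = rng.random(n) < violation_frac
        for i in range(n):
            bc = f"TC{cell_no:06d}"
            cell_no += 1
            k = int(draws[i])
            chains = list(clono_chains[k])
            if violate[i]:
                while len(chains) <= 4:
                    chains.append(("TRA", _random_cdr3(rng)))
            for chain, cdr3 in chains:
                records.append((bc, chain, cdr3, True, cond))
            if rng.random() < nonproductive_rate:
                records.append((bc, "TRA", _random_cdr3(rng), False, cond))
            truth_rows.append((bc, cond, k, bool(violate[i])))

    chains_df = pd.DataFrame(
        records, columns=["barcode", "chain", "cdr3_nt", "productive", "condition"]
    )
    truth = pd.DataFrame(
        truth_rows, columns=["barcode", "condition", "clonotype", "violates_chain_rule"]
    ).set_index("barcode")
    return chains_df, truth


# ---------------------------------------------------------------------------
# survival cohorts
# ---------------------------------------------------------------------------

def generate_survival_cohort(
    n_samples: int,
    signature_genes: list[str],
    hazard_ratio: float,
    censoring_rate: float = 0.2,
    baseline_rate: float = 0.02,
    n_noise_genes: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate a survival cohort whose hazard depends on a signature score.

    Per-gene expression values are standard normal.  The true signature
    score is the even mean of the signature genes' values; samples above
    the cohort median score have their exponential event rate multiplied
    by ``hazard_ratio``.  Censoring times are exponential with the rate
    chosen so roughly ``censoring_rate`` of samples are censored.  Times
    are in months.
    """
    if n_samples < 20:
        raise ValueError("n_samples must be >= 20")
    if hazard_ratio <= 0:
        raise ValueError("hazard_ratio must be > 0")
    if not signature_genes:
        raise ValueError("signature gene list must be non-empty")
    if not 0.0 <= censoring_rate < 1.0:
        raise ValueError("censoring_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    genes = list(signature_genes) + [f"noise{i:03d}" for i in range(n_noise_genes)]
    expr = pd.DataFrame(
        rng.normal(size=(n_samples, len(genes))),
        columns=genes,
        index=[f"S{i:04d}" for i in range(n_samples)],
    )
    score = expr[list(signature_genes)].mean(axis=1)
    high = (score > score.median()).to_numpy()
    rate = baseline_rate * np.where(high, hazard_ratio, 1.0)
    event_time = rng.exponential(1.0 / rate)
    if censoring_rate > 0:
        cens_rate = baseline_rate * censoring_rate / (1.0 - censoring_rate)
        cens_time = rng.exponential(1.0 / cens_rate, size=n_samples)
    else:
        cens_time = np.full(n_samples, np.inf)
    time = np.minimum(event_time, cens_time)
    event = (event_time <= cens_time).astype(int)

    cohort = expr.copy()
    cohort.insert(0, "time", time)
    cohort.insert(1, "event", event)
    cohort.index.name = "sample"
    cohort.attrs["true_high"] = pd.Series(high, index=cohort.index)
    return cohort


# ---------------------------------------------------------------------------
# stain tables
# ---------------------------------------------------------------------------

@dataclass
class StainClassParams:
    """Generator parameters for one histology class.

    ``bin_alpha`` are Dirichlet concentrations over (weak, moderate,
    strong, unstained); a zero component yields exactly 0% in that bin.
    """

    bin_alpha: tuple[float, float, float, float] = (2.0, 2.0, 1.0, 5.0)
    mean_stromal: float = 200.0
    positive_frac: float = 0.3
    intensity_per_positive: float = 2.0


def generate_stain_table(
    n_regions: dict[str, int],
    class_params: dict[str, StainClassParams] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate per-region stain quantification rows for histology classes.

    Each region gets intensity-bin percentages (weak/moderate/strong,
    summing to <= 100), stromal and positive-stromal cell counts, and a
    total staining intensity.  Zero requested regions yield an empty table.
    """
    rng = np.random.default_rng(seed)
    class_params = class_params or {}
    rows = []
    for cls in sorted(n_regions):
        n = n_regions[cls]
        params = class_params.get(cls, StainClassParams())
        alpha = np.asarray(params.bin_alpha, dtype=float)
        if np.any(alpha < 0):
            raise ValueError("bin_alpha components must be >= 0")
        if alpha.sum() == 0:
            raise ValueError("bin_alpha must have a positive component")
        for i in range(n):
            props = np.zeros(4)
            pos = alpha > 0
            if pos.sum() == 1:
                props[pos] = 1.0
            else:
                props[pos] = rng.dirichlet(alpha[pos])
            pct = 100.0 * props
            n_stromal = max(1, int(rng.poisson(params.mean_stromal)))
            n_positive = int(rng.binomial(n_stromal, params.positive_frac))
            intensity = float(
                rng.gamma(shape=2.0, scale=params.intensity_per_positive / 2.0)
                * n_positive
            )
            rows.append(
                {
                    "region": f"{cls}_{i:03d}",
                    "histology": cls,
                    "pct_weak": pct[0],
                    "pct_moderate": pct[1],
                    "pct_strong": pct[2],
                    "n_stromal": n_stromal,
                    "n_positive": n_positive,
                    "total_intensity": intensity,
                }
            )
    columns = [
        "region", "histology", "pct_weak", "pct_moderate", "pct_strong",
        "n_stromal", "n_positive", "total_intensity",
    ]
    return pd.DataFrame(rows, columns=columns)
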