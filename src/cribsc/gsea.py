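"""Preranked gene set enrichment analysis, implemented from scratch.

Given a signed-significance ranking of genes, the enrichment score of a
gene set is the signed maximum deviation of a weighted Kolmogorov-Smirnov
running sum: walking down the list, member genes ("hits") add
|score|^p / sum_hits |score|^p and non-members ("misses") subtract
1/(N - |S|).  Significance comes from a gene-label permutation null
(random member positions), with a normalised enrichment score (NES) and a
sign-stratified false-discovery estimate over the pooled permutation NES
distribution.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class GeneSet:
    """A named gene set; members unique and non-empty."""

    name: str
    members: tuple[str, ...]

    def __post_init__(self):
        members = tuple(dict.fromkeys(self.members))
        if not members:
            raise ValueError(f"gene set {self.name!r} is empty")
        object.__setattr__(self, "members", members)


@dataclass
class EnrichmentResult:
    set_name: str
    es: float
    nes: float
    p: float
    fdr: float
    leading_edge: list[str] = field(default_factory=list)
    size: int = 0
    n_perm: int = 0
    seed: int | None = None


# ---------------------------------------------------------------------------
# enrichment score
# ---------------------------------------------------------------------------

def _prepare(ranked) -> tuple[np.ndarray, np.ndarray]:
    """Accepts a (gene, score) DataFrame or a pair of arrays."""
    if isinstance(ranked, pd.DataFrame):
        genes = ranked["gene"].to_numpy(dtype=object)
        scores = ranked["score"].to_numpy(dtype=float)
    else:
        genes, scores = ranked
        genes = np.asarray(genes, dtype=object)
        scores = np.asarray(scores, dtype=float)
    if len(genes) != len(scores):
        raise ValueError("genes and scores must have equal length")
    return genes, scores


def enrichment_score(
    ranked, gene_set, weight: float = 1.0
) -> tuple[float, np.ndarray, list[str]]:
    """Weighted-KS enrichment score of one gene set against a ranked list.

    Returns ``(ES, running_sum, leading_edge)``.  ES is the running sum's
    signed maximum deviation from zero; the leading edge contains the set
    members up to the maximum (positive ES) or at/after the minimum
    (negative ES).  Members absent from the ranked list are dropped.
    """
    genes, scores = _prepare(ranked)
    members = gene_set.members if isinstance(gene_set, GeneSet) else tuple(gene_set)
    member_set = set(members)
    hit = np.fromiter((g in member_set for g in genes), dtype=bool, count=len(genes))
    n = len(genes)
    m = int(hit.sum())
    if m == 0:
        raise ValueError("gene set has no members in the ranked list")
    if m == n:
        raise ValueError("gene set covers the whole ranked list (no misses)")
    w = np.abs(scores) ** weight
    hit_w = np.where(hit, w, 0.0)
    denom = hit_w.sum()
    if denom == 0:
        # all member scores are zero: fall back to unweighted hits
        hit_w = hit.astype(float)
        denom = hit_w.sum()
    steps = hit_w / denom - (~hit) / (n - m)
    running = np.cumsum(steps)
    imax = int(np.argmax(running))
    imin = int(np.argmin(running))
    if abs(running[imax]) >= abs(running[imin]):
        es = float(running[imax])
        leading = [str(g) for g, h in zip(genes[: imax + 1], hit[: imax + 1]) if h]
    else:
        es = float(running[imin])
        leading = [str(g) for g, h in zip(genes[imin:], hit[imin:]) if h]
    return es, running, leading


def _es_from_positions(w_abs_p: np.ndarray, pos: np.ndarray, n: int) -> np.ndarray:
    """Vectorised ES for many hit-position sets.

    ``pos`` is (n_draws, m) of hit indices per draw (any order); ``w_abs_p``
    is |score|^p over the full list.  The extremum of the running sum is
    attained adjacent to a hit, so only 2m candidate values per draw are
    examined.
    """
    pos = np.sort(pos, axis=1)
    m = pos.shape[1]
    w = w_abs_p[pos]
    denom = w.sum(axis=1, keepdims=True)
    flat = denom.ravel() == 0
    if flat.any():
        w[flat] = 1.0
        denom = w.sum(axis=1, keepdims=True)
    cum = np.cumsum(w, axis=1) / denom
    miss = 1.0 / (n - m)
    k = np.arange(m)
    after = cum - (pos - k) * miss           # running sum just after each hit
    before = np.concatenate(
        [np.zeros((pos.shape[0], 1)), cum[:, :-1]], axis=1
    ) - (pos - k) * miss                      # just before each hit
    hi = after.max(axis=1)
    lo = np.minimum(before.min(axis=1), 0.0)
    return np.where(np.abs(hi) >= np.abs(lo), hi, lo)


# ---------------------------------------------------------------------------
# preranked GSEA with permutation null
# ---------------------------------------------------------------------------

def gsea_preranked(
    ranked,
    gene_sets,
    weight: float = 1.0,
    n_perm: int = 1000,
    min_size: int = 5,
    seed: int = 17,
) -> pd.DataFrame:
    """Preranked GSEA over a collection of gene sets.

    The null is a gene-label permutation: for each set size m, ``n_perm``
    random m-subsets of list positions.  Per set: nominal
    ``p = (1 + #{|null ES| >= |ES|}) / (1 + n_perm)``;
    ``NES = ES / mean(|null ES| of matching sign)``; FDR is the
    sign-stratified ratio of null-NES to observed-NES tail fractions,
    clipped to [0, 1].

    ``gene_sets`` may be a mapping name -> members or an iterable of
    :class:`GeneSet`.  Sets with fewer than ``min_size`` members present
    in the ranked list are skipped (logged).
    """
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is small; p-values will be coarse",
                      stacklevel=2)
    genes, scores = _prepare(ranked)
    n = len(genes)
    present = set(genes.tolist())
    if isinstance(gene_sets, dict):
        gene_sets = [GeneSet(k, tuple(v)) for k, v in gene_sets.items()]
    rng = np.random.default_rng(seed)

    results = []
    null_by_size: dict[int, np.ndarray] = {}
    w_abs_p = np.abs(scores) ** weight
    for gs in gene_sets:
        members_in = [g for g in gs.members if g in present]
        dropped = len(gs.members) - len(members_in)
        if dropped:
            logger.info("set %s: %d members absent from ranked list",
                        gs.name, dropped)
        m = len(members_in)
        if m < min_size or m >= n:
            logger.info("set %s skipped (size %d in list)", gs.name, m)
            continue
        es, _, leading = enrichment_score((genes, scores), members_in, weight)
        if m not in null_by_size:
            pos = np.argsort(rng.random((n_perm, n)), axis=1)[:, :m]
            null_by_size[m] = _es_from_positions(w_abs_p, pos, n)
        null = null_by_size[m]
        p = (1.0 + np.sum(np.abs(null) >= abs(es))) / (1.0 + n_perm)
        same_sign = null >= 0 if es >= 0 else null < 0
        if same_sign.any():
            nes = es / np.abs(null[same_sign]).mean()
            null_nes = np.where(
                null >= 0,
                null / max(np.abs(null[null >= 0]).mean(), np.finfo(float).tiny)
                if (null >= 0).any() else 0.0,
                null / max(np.abs(null[null < 0]).mean(), np.finfo(float).tiny)
                if (null < 0).any() else 0.0,
            )
        else:
            warnings.warn(f"set {gs.name}: no same-sign null ES; NES undefined",
                          stacklevel=2)
            nes = float("nan")
            null_nes = np.zeros(0)
        results.append(
            EnrichmentResult(
                set_name=gs.name, es=es, nes=float(nes), p=float(p), fdr=np.nan,
                leading_edge=leading, size=m, n_perm=n_perm, seed=seed,
            )
        )
        results[-1]._null_nes = null_nes  # kept for the FDR pass

    if not results:
        warnings.warn("all gene sets were filtered out", stacklevel=2)
        return pd.DataFrame(
            columns=["set", "es", "nes", "p", "fdr", "size", "leading_edge"]
        )

    # sign-stratified FDR over pooled normalised nulls
    obs_nes = np.array([r.nes for r in results])
    pooled = np.concatenate([r._null_nes for r in results]) if results else np.zeros(0)
    for r in results:
        if np.isnan(r.nes):
            r.fdr = np.nan
            continue
        if r.nes >= 0:
            null_tail = np.mean(pooled >= r.nes) if pooled.size else 0.0
            obs_pos = obs_nes[~np.isnan(obs_nes) & (obs_nes >= 0)]
            obs_tail = np.mean(obs_pos >= r.nes) if obs_pos.size else 1.0
        else:
            null_tail = np.mean(pooled <= r.nes) if pooled.size else 0.0
            obs_neg = obs_nes[~np.isnan(obs_nes) & (obs_nes < 0)]
            obs_tail = np.mean(obs_neg <= r.nes) if obs_neg.size else 1.0
        r.fdr = float(np.clip(null_tail / max(obs_tail, np.finfo(float).tiny), 0.0, 1.0))

    return pd.DataFrame(
        {
            "set": [r.set_name for r in results],
            "es": [r.es for r in results],
            "nes": [r.nes for r in results],
            "p": [r.p for r in results],
            "fdr": [r.fdr for r in results],
            "size": [r.size for r in results],
            "leading_edge": [",".join(r.leading_edge) for r in results],
        }
    )
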