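"""Gene-signature survival analysis: Z-scores, median split, KM, log-rank.

A signature score is the evenly weighted mean of its genes' per-cohort
Z-scores; the cohort is split at the median score and compared by
Kaplan-Meier estimation with a log-rank test.  The dual-cohort refinement
keeps a candidate gene only when its single-gene median split is both
significant and directionally "high score = worse outcome" in two
independent cohorts — the procedure that reduces an 8-gene candidate list
to the 4-gene CAFE CAF fibroblast signature (CTHRC1, ASPN, FAP, ENG).

The product-limit estimator and the log-rank statistic are delegated to
``lifelines``.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

logger = logging.getLogger(__name__)


def zscores(cohort: pd.DataFrame, gene_cols: list[str] | None = None) -> pd.DataFrame:
    """Standardise each gene column to mean 0, sample sd 1 within the cohort.

    ``gene_cols`` defaults to every column except ``time``/``event``.
    Samples with missing values in any gene column are excluded (logged);
    a zero-variance gene is an error naming the gene.
    """
    if gene_cols is None:
        gene_cols = [c for c in cohort.columns if c not in ("time", "event")]
    sub = cohort[gene_cols]
    missing = sub.isna().any(axis=1)
    if missing.any():
        logger.warning("zscores: excluding %d samples with missing values",
                       int(missing.sum()))
        sub = sub[~missing]
    sd = sub.std(ddof=1)
    zero = sd[sd == 0]
    if len(zero):
        raise ValueError(f"zero-variance gene(s): {', '.join(zero.index)}")
    return (sub - sub.mean()) / sd


def signature_score(z: pd.DataFrame, genes: list[str]) -> pd.Series:
    """Evenly weighted signature score: the mean Z across the listed genes."""
    missing = [g for g in genes if g not in z.columns]
    if missing:
        raise ValueError(f"signature genes missing from cohort: {', '.join(missing)}")
    return z[list(genes)].mean(axis=1).rename("score")


def median_split(scores: pd.Series) -> pd.Series:
    """Label samples 'high' (score > median) or 'low' (score <= median).

    Ties at the median go to the low group — deterministic and
    conservative for claims about the high-score group.
    """
    if len(scores) < 4:
        raise ValueError("median split needs n >= 4")
    if scores.nunique() == 1:
        raise ValueError("all scores identical; median split undefined")
    med = scores.median()
    return pd.Series(np.where(scores > med, "high", "low"),
                     index=scores.index, name="group")


def km_estimate(times, events) -> pd.DataFrame:
    """Kaplan-Meier product-limit estimate for one group.

    Returns a step table indexed by time with the survival estimate and
    at-risk counts; S(0) = 1 and S is nonincreasing, dropping only at
    event times.  A group with no events yields a flat curve at 1
    (warning).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if np.any(times < 0):
        raise ValueError("times must be non-negative")
    if events.sum() == 0:
        logger.warning("km_estimate: no events; survival stays at 1")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    out = kmf.survival_function_.rename(columns={"KM_estimate": "survival"})
    out["at_risk"] = kmf.event_table["at_risk"].reindex(out.index).ffill()
    out.index.name = "time"
    return out


def _surv_at(curve: pd.DataFrame, t: float) -> float:
    """Step-function evaluation of a KM curve at time ``t``."""
    upto = curve.loc[curve.index <= t, "survival"]
    return float(upto.iloc[-1]) if len(upto) else 1.0


def km_by_group(times, events, groups) -> dict[str, pd.DataFrame]:
    """KM estimate per group label."""
    groups = pd.Series(np.asarray(groups), name="group")
    return {
        g: km_estimate(np.asarray(times)[groups.to_numpy() == g],
                       np.asarray(events)[groups.to_numpy() == g])
        for g in sorted(groups.unique())
    }


def logrank_test(times, events, groups) -> tuple[float, float]:
    """Two-group log-rank test: (chi-square statistic, p from chi2 df=1)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if len(labels) != 2:
        raise ValueError(f"log-rank needs exactly 2 groups, got {len(labels)}")
    a = groups == labels[0]
    if a.all() or (~a).all():
        raise ValueError("one group is empty")
    if events.sum() == 0:
        raise ValueError("no events in either group")
    res = _ll_logrank(times[a], times[~a], events[a], events[~a])
    return float(res.test_statistic), float(res.p_value)


def evaluate_signature(
    cohort: pd.DataFrame, genes: list[str]
) -> dict:
    """Score a signature on a cohort: median split + KM + log-rank.

    Returns the per-sample scores and groups, the per-group KM curves, the
    log-rank chi-square and p, and whether the high group has the worse
    outcome (lower final KM estimate).
    """
    z = zscores(cohort, [g for g in genes if g in cohort.columns])
    score = signature_score(z, genes)
    group = median_split(score)
    idx = score.index
    times = cohort.loc[idx, "time"]
    events = cohort.loc[idx, "event"]
    chi2, p = logrank_test(times, events, group)
    curves = km_by_group(times, events, group)
    # compare the curves at the end of common follow-up: beyond the shorter
    # group's last observed time the estimates are not comparable
    horizon = min(float(c.index.max()) for c in curves.values())
    final = {g: _surv_at(c, horizon) for g, c in curves.items()}
    return {
        "genes": list(genes),
        "score": score,
        "group": group,
        "km": curves,
        "chi2": chi2,
        "p": p,
        "high_worse": final.get("high", 1.0) < final.get("low", 1.0),
        "n_high": int((group == "high").sum()),
        "n_low": int((group == "low").sum()),
    }


def refine_signature(
    candidates: list[str],
    cohort_a: pd.DataFrame,
    cohort_b: pd.DataFrame,
    alpha: float = 0.05,
) -> list[str]:
    """Dual-cohort per-gene refinement of a candidate signature.

    A gene is retained iff its single-gene median-split log-rank p < alpha
    AND the high-expression group has the worse outcome (lower final KM
    estimate) in BOTH cohorts.  A gene missing from a cohort is dropped
    with a warning rather than raising.
    """
    retained = []
    for gene in candidates:
        keep = True
        for name, cohort in (("A", cohort_a), ("B", cohort_b)):
            if gene not in cohort.columns:
                logger.warning("refine_signature: %s missing from cohort %s; "
                               "dropped", gene, name)
                keep = False
                break
            res = evaluate_signature(cohort, [gene])
            if not (res["p"] < alpha and res["high_worse"]):
                keep = False
                break
        if keep:
            retained.append(gene)
    return retained
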