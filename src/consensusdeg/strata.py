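"""Signature scoring, sample stratification, stratum-DE overlap and ORA.

Samples are scored against a gene signature as the mean per-gene z-score
(tumor subtype and proliferation stratification both use this), stratified
by score argmax (basal-like vs classical) or median split (proliferation
high/low), and stratum contrasts from several cohorts are overlapped at a
configurable support level.  Gene-set over-representation uses the
upper-tail hypergeometric test with BH adjustment across sets.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .deg import CohortDEResult, ExpressionCohort, bh_adjust

logger = logging.getLogger(__name__)

__all__ = [
    "score_samples",
    "assign_subtype",
    "split_by_median",
    "stratum_overlap",
    "ora_hypergeometric",
]


def score_samples(cohort: ExpressionCohort, signature: Sequence[str]) -> pd.Series:
    """Per-sample mean z-score over the signature genes present in the cohort.

    Each gene row is z-scored across samples; zero-variance genes are
    excluded (logged); signature genes missing from the platform are logged.
    """
    present = [g for g in signature if g in cohort.values.index]
    if not present:
        raise ValueError(
            f"cohort {cohort.name!r}: no signature gene present in universe"
        )
    missing = len(signature) - len(present)
    if missing:
        logger.info("score_samples: %d signature genes absent from %s",
                    missing, cohort.name)
    sub = cohort.values.loc[present]
    sd = sub.std(axis=1, ddof=1)
    usable = sd > 0
    if not usable.all():
        logger.info("score_samples: excluding %d zero-variance genes",
                    int((~usable).sum()))
    sub = sub.loc[usable]
    if sub.empty:
        raise ValueError(f"cohort {cohort.name!r}: all signature genes degenerate")
    z = sub.sub(sub.mean(axis=1), axis=0).div(sd[usable], axis=0)
    score = z.mean(axis=0)
    score.name = "score"
    return score


def assign_subtype(
    basal_scores: pd.Series, classical_scores: pd.Series
) -> pd.Series:
    """Label each sample by the larger of the two signature scores.

    Exact ties go to ``classical`` (with a warning), so the assignment is
    deterministic.
    """
    if not basal_scores.index.equals(classical_scores.index):
        if set(basal_scores.index) != set(classical_scores.index):
            raise ValueError("basal and classical scores cover different samples")
        classical_scores = classical_scores.reindex(basal_scores.index)
    ties = basal_scores == classical_scores
    if ties.any():
        logger.warning("assign_subtype: %d exact ties assigned to classical",
                       int(ties.sum()))
    labels = pd.Series(
        np.where(basal_scores > classical_scores, "basal_like", "classical"),
        index=basal_scores.index,
        name="subtype",
    )
    return labels


def split_by_median(scores: pd.Series) -> pd.Series:
    """Dichotomize at the median: strictly above -> ``high``, else ``low``
    (median-tied samples go low).

    When ties put the median at the maximum, the strict rule would empty
    the high stratum; the cut then falls back to ``>= median`` (logged) so
    both strata stay populated on any non-degenerate input.
    """
    if len(scores) < 2:
        raise ValueError("median split needs >=2 samples")
    arr = scores.to_numpy(dtype=float)
    if np.ptp(arr) == 0:
        raise ValueError("degenerate split: all scores identical")
    med = float(np.median(arr))
    high = arr > med
    if not high.any():
        logger.info("split_by_median: median equals maximum; using >= median")
        high = arr >= med
    labels = pd.Series(
        np.where(high, "high", "low"), index=scores.index, name="stratum"
    )
    return labels


def stratum_overlap(
    contrast_results: Sequence[CohortDEResult],
    consensus: pd.DataFrame,
    alpha: float = 0.05,
    support: int = 2,
) -> pd.DataFrame:
    """Overlap a stratum contrast (e.g. proliferation-high vs -low) across
    cohorts, cross-tabulated against consensus classes.

    A cohort supports a gene in a direction when the contrast's raw p is
    below ``alpha`` with the matching fold-change sign.  Columns:
    ``n_cohorts_up``, ``n_cohorts_down``, ``member_of``, ``qualified_up``,
    ``qualified_down``, ``qualified``.  ``support=1`` covers single-cohort
    contrasts (metastasis, grade, mutation comparisons).
    """
    if not contrast_results:
        raise ValueError("stratum_overlap needs >=1 contrast result")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0,1), got {alpha}")
    if support < 1:
        raise ValueError("support must be >=1")
    genes: set = set()
    for r in contrast_results:
        genes |= set(r.table.index)
    genes = pd.Index(sorted(genes), name="gene")
    n_up = pd.Series(0, index=genes, dtype=int)
    n_down = pd.Series(0, index=genes, dtype=int)
    for r in contrast_results:
        t = r.table.reindex(genes)
        sig = t["p_raw"] < alpha
        n_up += (sig & (t["log2fc"] > 0)).fillna(False).astype(int)
        n_down += (sig & (t["log2fc"] < 0)).fillna(False).astype(int)
    member = consensus["gene_class"].reindex(genes).fillna("none")
    q_up = n_up >= support
    q_down = n_down >= support
    return pd.DataFrame(
        {
            "n_cohorts_up": n_up,
            "n_cohorts_down": n_down,
            "member_of": member,
            "qualified_up": q_up,
            "qualified_down": q_down,
            "qualified": q_up | q_down,
        },
        index=genes,
    )


def ora_hypergeometric(
    query: Sequence[str],
    collection: Mapping[str, Sequence[str]],
    universe: Sequence[str],
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of ``query`` in each set.

    ``p = P(X >= k)`` for overlap ``k`` with a set of size ``K_s`` drawn from
    a universe of size ``N`` by a query of size ``n``; BH-adjusted across
    sets.  Gene sets are intersected with the universe first.
    """
    universe_set = set(universe)
    query_set = set(query)
    if not universe_set:
        raise ValueError("empty universe")
    if not query_set:
        raise ValueError("empty query")
    if not query_set <= universe_set:
        raise ValueError("query genes must be a subset of the universe")
    n = len(query_set)
    N = len(universe_set)
    rows = []
    for name, genes in collection.items():
        members = set(genes) & universe_set
        k = len(members & query_set)
        K_s = len(members)
        p = float(stats.hypergeom.sf(k - 1, N, K_s, n)) if K_s else 1.0
        rows.append(
            {
                "set": name,
                "k": k,
                "set_size": K_s,
                "query_size": n,
                "universe_size": N,
                "p": min(p, 1.0),
                "genes": ",".join(sorted(members & query_set)),
            }
        )
    out = pd.DataFrame(rows).set_index("set")
    out["q"] = bh_adjust(out["p"].to_numpy()) if len(out) else []
    return out[["k", "set_size", "query_size", "universe_size", "p", "q", "genes"]]
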