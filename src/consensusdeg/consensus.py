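"""Cross-cohort consensus gene calling and the signed rank score.

A gene is a consistently upregulated gene (CUG) when it is significantly up
(adjusted p below the discovery alpha) in at least ``m`` of the K cohorts,
and a consistently downregulated gene (CDG) in the mirrored case; ``m`` must
exceed K/2 so the classes are exclusive.  Genes reaching only the secondary
support level (default m-1) form a lower-confidence tier without a class.

Genes are ordered by a signed cross-cohort score: per cohort the product of
log2(fold change) and -log(p), summed over cohorts (a rank-sum variant is
also provided).  A cohort whose platform lacks the gene contributes nothing
to either support or score.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .deg import CohortDEResult

logger = logging.getLogger(__name__)

__all__ = [
    "call_consensus",
    "rank_score",
    "top_genes",
    "cross_cohort_concordance",
    "build_consensus_table",
]

P_FLOOR = 1e-300


def _union_index(results: Sequence[CohortDEResult]) -> pd.Index:
    genes: set = set()
    for r in results:
        genes |= set(r.table.index)
    return pd.Index(sorted(genes), name="gene")


def call_consensus(
    results: Sequence[CohortDEResult], m: int = 4, tier2: int = 3
) -> pd.DataFrame:
    """Count per-direction support over cohorts and assign tier and class.

    Returns a DataFrame indexed by the union of genes with columns
    ``n_up``, ``n_down``, ``n_tested``, ``tier`` in
    ``{"primary", "secondary", "none"}``, ``gene_class`` in
    ``{"CUG", "CDG", "none"}`` and a boolean ``discordant`` flag (secondary
    support in both directions; such genes are excluded from classes).
    """
    k = len(results)
    if k < 2:
        raise ValueError(f"need >=2 cohorts, got {k}")
    if not m > k / 2:
        raise ValueError(
            f"min support m={m} must exceed K/2={k / 2:g} so CUG/CDG are exclusive"
        )
    if not 1 <= tier2 < m:
        raise ValueError(f"tier2 support ({tier2}) must satisfy 1 <= tier2 < m ({m})")

    genes = _union_index(results)
    n_up = pd.Series(0, index=genes, dtype=int)
    n_down = pd.Series(0, index=genes, dtype=int)
    n_tested = pd.Series(0, index=genes, dtype=int)
    for r in results:
        d = r.table["direction"].reindex(genes)
        n_tested += d.notna().astype(int)
        n_up += (d == "up").astype(int)
        n_down += (d == "down").astype(int)

    gene_class = np.where(n_up >= m, "CUG", np.where(n_down >= m, "CDG", "none"))
    primary = (n_up >= m) | (n_down >= m)
    secondary = ~primary & ((n_up >= tier2) | (n_down >= tier2))
    tier = np.where(primary, "primary", np.where(secondary, "secondary", "none"))
    discordant = ~primary & (n_up >= tier2) & (n_down >= tier2)
    if discordant.any():
        logger.info("call_consensus: %d discordant genes excluded from classes",
                    int(discordant.sum()))

    return pd.DataFrame(
        {
            "n_up": n_up,
            "n_down": n_down,
            "n_tested": n_tested,
            "tier": tier,
            "gene_class": gene_class,
            "discordant": np.asarray(discordant),
        },
        index=genes,
    )


def rank_score(
    results: Sequence[CohortDEResult],
    log_base: float = 10.0,
    use_adjusted: bool = False,
    mode: str = "score_sum",
) -> tuple[pd.Series, pd.DataFrame]:
    """Signed cross-cohort score: sum over cohorts of log2fc * -log(p).

    Returns ``(score, components)`` where ``components`` is genes x cohorts.
    ``mode="score_sum"`` sums the per-cohort components; ``mode="rank_sum"``
    sums each component's within-cohort (ascending, average-tie) rank.
    Cohorts lacking a gene contribute 0.  P-values are floored at 1e-300.
    """
    if not results:
        raise ValueError("rank_score needs at least one cohort result")
    if mode not in {"score_sum", "rank_sum"}:
        raise ValueError(f"unknown mode {mode!r}")
    if log_base <= 1:
        raise ValueError("log_base must exceed 1")
    genes = _union_index(results)
    pcol = "p_adj" if use_adjusted else "p_raw"
    comps = pd.DataFrame(0.0, index=genes, columns=[r.cohort for r in results])
    for r in results:
        p = r.table[pcol]
        if (p < 0).any():
            raise ValueError(f"cohort {r.cohort!r}: negative p-values")
        p = np.maximum(p.to_numpy(dtype=float), P_FLOOR)
        comp = r.table["log2fc"].to_numpy() * (-np.log(p) / np.log(log_base))
        comps.loc[r.table.index, r.cohort] = comp

    if mode == "score_sum":
        score = comps.sum(axis=1)
    else:
        score = pd.Series(0.0, index=genes)
        for r in results:
            present = r.table.index
            ranks = stats.rankdata(comps.loc[present, r.cohort], method="average")
            score.loc[present] += ranks
    score.name = "score"
    return score, comps


def build_consensus_table(
    results: Sequence[CohortDEResult],
    m: int = 4,
    tier2: int = 3,
    log_base: float = 10.0,
    use_adjusted: bool = False,
    mode: str = "score_sum",
) -> pd.DataFrame:
    """Consensus calls merged with the rank score (convenience wrapper)."""
    table = call_consensus(results, m=m, tier2=tier2)
    score, _ = rank_score(results, log_base=log_base, use_adjusted=use_adjusted,
                          mode=mode)
    table = table.join(score)
    return table


def top_genes(table: pd.DataFrame, n: int, direction: str) -> list:
    """Top-n CUGs by descending score (up) or CDGs by ascending score (down).

    Ties on the score break lexicographically by gene symbol.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if direction not in {"up", "down"}:
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    if "score" not in table.columns:
        raise ValueError("consensus table lacks a 'score' column")
    cls = "CUG" if direction == "up" else "CDG"
    sub = table[table["gene_class"] == cls]
    if n > len(sub):
        logger.warning(
            "top_genes: requested %d but only %d %ss available", n, len(sub), cls
        )
    ascending = direction == "down"
    ordered = sub.assign(_symbol=sub.index).sort_values(
        by=["score", "_symbol"], ascending=[ascending, True]
    )
    return list(ordered.index[:n])


def cross_cohort_concordance(
    table: pd.DataFrame, independent_result: CohortDEResult
) -> dict:
    """Fraction of CUGs (CDGs) significant in the same direction in an
    independent cohort, restricted to genes on that cohort's platform.

    Returns ``{"CUG": {"fraction", "concordant", "testable"}, "CDG": ...}``.
    """
    universe = independent_result.universe
    if not (set(table.index) & universe):
        raise ValueError(
            "independent cohort shares no genes with the consensus table"
        )
    out = {}
    for cls, want in (("CUG", "up"), ("CDG", "down")):
        members = table.index[table["gene_class"] == cls]
        testable = [g for g in members if g in universe]
        directions = independent_result.table.loc[testable, "direction"]
        k = int((directions == want).sum())
        out[cls] = {
            "fraction": k / len(testable) if testable else float("nan"),
            "concordant": k,
            "testable": len(testable),
        }
    return out
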