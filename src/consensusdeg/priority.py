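"""Essentiality consensus across dependency screens and priority-target
derivation.

Each CRISPR/shRNA screen scores genes per cell line; a gene is called
essential in a screen when its score passes the screen's threshold in a
minimum fraction of measured lines (score polarity differs between
CERES-like screens, where negative means essential, and Bayes-factor
screens, where high means essential).  Genes essential in >= 3 of 4 screens
(restricted to consistently upregulated genes) form the interference
consensus.  A complementary multi-criteria rule — pancreas-low AND
proliferation-associated AND (basal-like-associated OR prognostic) — adds
genes that may not score in optimal culture conditions; the union is the
priority-target set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .strata import split_by_median
from .deg import bh_adjust

logger = logging.getLogger(__name__)

__all__ = [
    "ScreenPanel",
    "call_essential",
    "interference_consensus",
    "derive_priority",
    "PrioritySet",
    "stratify_cells_and_test_drugs",
]

DEFAULT_THRESHOLDS = {"negative_essential": -0.5, "positive_essential": 0.0}


@dataclass
class ScreenPanel:
    """Gene x cell-line dependency scores from one interference screen."""

    name: str
    scores: pd.DataFrame
    polarity: str  # negative_essential (CERES-like) | positive_essential (Bayes factor)
    essential_set: Optional[frozenset] = None

    def __post_init__(self) -> None:
        if self.polarity not in DEFAULT_THRESHOLDS:
            raise ValueError(
                f"screen {self.name!r}: polarity must be one of "
                f"{sorted(DEFAULT_THRESHOLDS)}, got {self.polarity!r}"
            )
        if self.scores.shape[1] < 1:
            raise ValueError(f"screen {self.name!r}: needs >=1 cell line")


def call_essential(
    screen: ScreenPanel,
    threshold: Optional[float] = None,
    line_fraction: float = 0.5,
) -> frozenset:
    """Genes whose score passes the threshold in >= line_fraction of the
    lines where they were measured.

    ``<= threshold`` for negative-essential screens, ``>= threshold`` for
    positive-essential (Bayes-factor) screens.
    """
    if threshold is None:
        threshold = DEFAULT_THRESHOLDS[screen.polarity]
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    if not 0 < line_fraction <= 1:
        raise ValueError(f"line_fraction must be in (0,1], got {line_fraction}")
    vals = screen.scores
    measured = vals.notna().sum(axis=1)
    if screen.polarity == "negative_essential":
        hits = (vals <= threshold).sum(axis=1)
    else:
        hits = (vals >= threshold).sum(axis=1)
    ok = measured > 0
    frac = hits[ok] / measured[ok]
    return frozenset(frac.index[frac >= line_fraction])


def interference_consensus(
    screens: Sequence[ScreenPanel],
    cug_set: Sequence[str],
    support: int = 3,
    line_fraction: float = 0.5,
) -> frozenset:
    """CUGs called essential in >= ``support`` screens.

    Screens with a precomputed ``essential_set`` use it; otherwise
    :func:`call_essential` runs at the screen's default threshold.
    """
    if support > len(screens):
        raise ValueError(
            f"support {support} exceeds number of screens {len(screens)}"
        )
    cugs = set(cug_set)
    counts: dict = {}
    for s in screens:
        ess = s.essential_set
        if ess is None:
            ess = call_essential(s, line_fraction=line_fraction)
        for g in ess:
            counts[g] = counts.get(g, 0) + 1
    hits = frozenset(g for g, c in counts.items() if c >= support and g in cugs)
    logger.info("interference_consensus: %d of %d CUGs essential in >=%d screens",
                len(hits), len(cugs), support)
    return hits


@dataclass
class PrioritySet:
    """Priority targets with per-gene provenance flags."""

    criteria_set: frozenset
    interference_set: frozenset
    provenance: pd.DataFrame = field(repr=False)

    @property
    def union_set(self) -> frozenset:
        return self.criteria_set | self.interference_set


def derive_priority(
    consensus: pd.DataFrame,
    specificity_call: pd.DataFrame,
    proliferation_overlap: pd.DataFrame,
    subtype_overlap: pd.DataFrame,
    survival_summary: Mapping[str, int],
    interference_set: Sequence[str],
    min_votes: int = 2,
) -> PrioritySet:
    """Multi-criteria priority rule over CUGs, united with the essentiality
    consensus.

    criteria_set = CUGs with pancreas-low votes >= min_votes AND
    upregulated in proliferation-high tumors (qualified) AND (upregulated in
    basal-like tumors (qualified) OR survival-predictive, worse-when-high,
    in >= 1 cohort).  ``survival_summary`` maps gene -> number of cohorts
    with log-rank p < 0.05 and worse outcome when the gene is high.
    """
    for nm, obj in (
        ("consensus", consensus),
        ("specificity_call", specificity_call),
        ("proliferation_overlap", proliferation_overlap),
        ("subtype_overlap", subtype_overlap),
    ):
        if obj is None:
            raise ValueError(f"derive_priority: missing input table {nm!r}")
    if survival_summary is None:
        raise ValueError("derive_priority: missing input table 'survival_summary'")
    if interference_set is None:
        raise ValueError("derive_priority: missing input 'interference_set'")

    cugs = consensus.index[consensus["gene_class"] == "CUG"]
    rows = []
    for g in cugs:
        votes = (
            int(specificity_call.loc[g, "pancreas_votes"])
            if g in specificity_call.index
            else 0
        )
        low_normal = votes >= min_votes
        prolif = (
            bool(proliferation_overlap.loc[g, "qualified_up"])
            if g in proliferation_overlap.index
            else False
        )
        basal = (
            bool(subtype_overlap.loc[g, "qualified_up"])
            if g in subtype_overlap.index
            else False
        )
        os_sig = int(survival_summary.get(g, 0)) >= 1
        in_criteria = low_normal and prolif and (basal or os_sig)
        in_interference = g in set(interference_set)
        rows.append(
            {
                "gene": g,
                "low_normal_pancreas": low_normal,
                "proliferation_up": prolif,
                "basal_like_up": basal,
                "os_predictive": os_sig,
                "criteria": in_criteria,
                "interference": in_interference,
                "priority": in_criteria or in_interference,
            }
        )
    prov = (
        pd.DataFrame(rows).set_index("gene")
        if rows
        else pd.DataFrame(
            columns=[
                "low_normal_pancreas", "proliferation_up", "basal_like_up",
                "os_predictive", "criteria", "interference", "priority",
            ]
        )
    )
    criteria_set = frozenset(prov.index[prov["criteria"]]) if len(prov) else frozenset()
    interference = frozenset(set(interference_set) & set(cugs))
    logger.info(
        "derive_priority: criteria=%d interference=%d union=%d",
        len(criteria_set), len(interference), len(criteria_set | interference),
    )
    return PrioritySet(
        criteria_set=criteria_set,
        interference_set=interference,
        provenance=prov,
    )


def stratify_cells_and_test_drugs(
    cellline_expression: pd.DataFrame,
    priority_genes: Sequence[str],
    drug_table: pd.DataFrame,
) -> pd.DataFrame:
    """Median-split cell lines by mean priority-gene z-score and rank-sum
    test each drug's sensitivity between high- and low-expressing lines.

    ``cellline_expression``: genes x cell lines (log2).  ``drug_table``:
    cell lines x drugs, lower values = more sensitive.  Returns per-drug
    ``p``, BH ``q``, group medians and the effect direction
    (``high_more_sensitive`` / ``low_more_sensitive`` / ``none``).
    """
    if cellline_expression.shape[1] < 4:
        raise ValueError("need >=4 cell lines")
    present = [g for g in priority_genes if g in cellline_expression.index]
    if not present:
        raise ValueError("no priority gene present in the expression universe")
    sub = cellline_expression.loc[present]
    sd = sub.std(axis=1, ddof=1)
    sub = sub.loc[sd > 0]
    z = sub.sub(sub.mean(axis=1), axis=0).div(sub.std(axis=1, ddof=1), axis=0)
    scores = z.mean(axis=0)
    labels = split_by_median(scores)
    high = labels.index[labels == "high"]
    low = labels.index[labels == "low"]
    if len(high) < 2 or len(low) < 2:
        raise ValueError("median split leaves <2 cell lines in a group")

    rows = []
    for drug in drug_table.columns:
        h = drug_table.loc[drug_table.index.intersection(high), drug].dropna()
        l = drug_table.loc[drug_table.index.intersection(low), drug].dropna()
        if len(h) < 2 or len(l) < 2:
            logger.warning("drug %s: <2 measured lines per group; skipped", drug)
            continue
        if np.ptp(np.concatenate([h, l])) == 0:
            p = 1.0
        else:
            p = float(stats.mannwhitneyu(h, l, alternative="two-sided").pvalue)
        mh, ml = float(h.median()), float(l.median())
        if mh < ml:
            direction = "high_more_sensitive"
        elif mh > ml:
            direction = "low_more_sensitive"
        else:
            direction = "none"
        rows.append(
            {"drug": drug, "p": p, "median_high": mh, "median_low": ml,
             "n_high": len(h), "n_low": len(l), "direction": direction}
        )
    out = pd.DataFrame(rows).set_index("drug")
    if len(out):
        out["q"] = bh_adjust(out["p"].to_numpy())
    else:
        out["q"] = []
    return out[["p", "q", "median_high", "median_low", "n_high", "n_low", "direction"]]
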