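"""Tumor-specificity of consensus genes: tissue-panel voting and
epithelium-vs-stroma compartment testing.

A consistently upregulated gene (CUG) is a candidate tumor-specific gene
when, across independent normal-tissue panels, the pancreas value lies below
the across-tissue median (one vote per panel, >= min_votes required) and the
gene is higher in microdissected tumor epithelium than in the matched
stroma.  Consistently downregulated genes (CDGs) use the mirrored criteria
(pancreas-high, stroma-high).  Combining both axes yields the "core
tumor-specific" category.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import deg

logger = logging.getLogger(__name__)

__all__ = [
    "TissuePanel",
    "vote_pancreas_level",
    "epithelium_stroma_de",
    "derive_core_sets",
]


@dataclass
class TissuePanel:
    """One aggregate expression value per gene per normal tissue type."""

    name: str
    values: pd.DataFrame  # genes x tissue types
    pancreas_label: str = "pancreas"

    def __post_init__(self) -> None:
        if self.values.shape[1] < 2:
            raise ValueError(f"panel {self.name!r}: needs >=2 tissues")
        if self.pancreas_label not in self.values.columns:
            raise ValueError(
                f"panel {self.name!r}: pancreas tissue {self.pancreas_label!r} missing"
            )
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError(f"panel {self.name!r}: non-finite values")


def vote_pancreas_level(
    panels: Sequence[TissuePanel], direction: str = "low_wanted"
) -> pd.Series:
    """Count panels where the pancreas value is strictly below (low_wanted)
    or strictly above (high_wanted) the across-tissue median.

    Genes absent from a panel collect no vote there.  The criterion depends
    only on within-panel ranks, so it is invariant to monotone per-panel
    transformations.
    """
    if not panels:
        raise ValueError("need >=1 tissue panel")
    if direction not in {"low_wanted", "high_wanted"}:
        raise ValueError(f"direction must be low_wanted/high_wanted, got {direction!r}")
    genes: set = set()
    for p in panels:
        genes |= set(p.values.index)
    genes = pd.Index(sorted(genes), name="gene")
    votes = pd.Series(0, index=genes, dtype=int)
    for p in panels:
        med = p.values.median(axis=1)
        panc = p.values[p.pancreas_label]
        if direction == "low_wanted":
            hit = panc < med
        else:
            hit = panc > med
        votes.loc[hit.index[hit]] += 1
    votes.name = "pancreas_votes"
    return votes


def epithelium_stroma_de(
    paired_cohort: deg.ExpressionCohort,
    alpha: float = 0.01,
    epithelium_label: str = "epithelium",
    stroma_label: str = "stroma",
) -> deg.CohortDEResult:
    """Paired moderated t of tumor epithelium vs matched stroma.

    ``direction == "up"`` means epithelium-high, ``"down"`` stroma-high.
    """
    if paired_cohort.pairing is None:
        raise ValueError("epithelium/stroma test requires paired samples")
    return deg.moderated_ttest(
        paired_cohort, epithelium_label, stroma_label, paired=True, alpha=alpha
    )


_CUG_CATEGORIES = {
    (True, True): "core_tumor_specific",
    (False, True): "epithelium_only",
    (True, False): "normal_low_only",
    (False, False): "none",
}
_CDG_CATEGORIES = {
    (True, True): "core_tumor_specific",
    (False, True): "stroma_only",
    (True, False): "normal_high_only",
    (False, False): "none",
}


def derive_core_sets(
    consensus: pd.DataFrame,
    votes_low: pd.Series,
    votes_high: pd.Series,
    epistroma: deg.CohortDEResult,
    min_votes: int = 2,
) -> pd.DataFrame:
    """Categorize CUGs/CDGs by tissue votes and compartment direction.

    CUGs: ``core_tumor_specific`` iff pancreas-low votes >= min_votes AND
    epithelium-high; ``epithelium_only`` / ``normal_low_only`` when only one
    criterion holds.  CDGs mirrored with pancreas-high votes and stroma-high.
    Genes without a consensus class are ignored (count logged).

    Returns a DataFrame over classed genes with columns ``gene_class``,
    ``pancreas_votes``, ``epistroma_direction``, ``category``.
    """
    classed = consensus[consensus["gene_class"].isin(["CUG", "CDG"])]
    skipped = len(consensus) - len(classed)
    if skipped:
        logger.info("derive_core_sets: ignoring %d unclassed genes", skipped)
    rows = []
    epi_dir = epistroma.table["direction"]
    for gene, row in classed.iterrows():
        cls = row["gene_class"]
        if cls == "CUG":
            v = int(votes_low.get(gene, 0))
            d = epi_dir.get(gene, "ns")
            compartment_hit = d == "up"
            category = _CUG_CATEGORIES[(v >= min_votes, compartment_hit)]
            label = {"up": "epi_high", "down": "stroma_high"}.get(d, "ns")
        else:
            v = int(votes_high.get(gene, 0))
            d = epi_dir.get(gene, "ns")
            compartment_hit = d == "down"
            category = _CDG_CATEGORIES[(v >= min_votes, compartment_hit)]
            label = {"up": "epi_high", "down": "stroma_high"}.get(d, "ns")
        rows.append(
            {
                "gene": gene,
                "gene_class": cls,
                "pancreas_votes": v,
                "epistroma_direction": label,
                "category": category,
            }
        )
    out = pd.DataFrame(rows).set_index("gene") if rows else pd.DataFrame(
        columns=["gene_class", "pancreas_votes", "epistroma_direction", "category"]
    )
    for cls in ("CUG", "CDG"):
        counts = out[out["gene_class"] == cls]["category"].value_counts().to_dict() if len(out) else {}
        logger.info("derive_core_sets %s categories: %s", cls, counts)
    return out
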