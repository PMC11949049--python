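"""Per-cohort differential expression with empirical-Bayes variance moderation.

The two-group (or paired) test implemented here is the moderated t-statistic:
per-gene residual variances are shrunk toward a common prior variance ``s0^2``
with prior degrees of freedom ``d0``, both estimated from the ensemble of
genes by fitting a scaled F distribution to the observed variances
(method-of-moments on log variances).  The moderated statistic

    t_g = log2fc_g / (s_tilde_g * c),   s_tilde_g^2 = (d0*s0^2 + d*s_g^2)/(d0 + d)

is referred to a t distribution with ``d + d0`` degrees of freedom.  With
``d0 = 0`` it reduces to the ordinary pooled two-sample t; with ``d0 = inf``
every gene uses the common variance ``s0^2``.

Raw p-values are adjusted with the Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionCohort",
    "CohortDEResult",
    "quantile_normalize",
    "collapse_probes",
    "moderated_ttest",
    "bh_adjust",
]


@dataclass
class ExpressionCohort:
    """A log2-scale gene x sample expression matrix with sample group labels.

    Parameters
    ----------
    name : str
        Cohort identifier (e.g. a GEO-style accession or a synthetic label).
    values : pandas.DataFrame
        Genes as rows (index = gene symbols), samples as columns, log2 units.
    sample_groups : pandas.Series
        Maps sample ID -> group label (e.g. ``tumor`` / ``normal``).
    pairing : pandas.Series, optional
        Maps sample ID -> pair identifier for paired designs
        (e.g. microdissected epithelium/stroma pairs).
    """

    name: str
    values: pd.DataFrame
    sample_groups: pd.Series
    pairing: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        missing = [s for s in self.values.columns if s not in self.sample_groups.index]
        if missing:
            raise ValueError(
                f"cohort {self.name!r}: samples without group labels: {missing}"
            )
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(
                f"cohort {self.name!r}: duplicate gene rows {dups}; "
                "collapse probes to genes first (deg.collapse_probes)"
            )
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError(f"cohort {self.name!r}: non-finite expression values")

    @property
    def universe(self) -> frozenset:
        """Genes measured on this cohort's platform."""
        return frozenset(self.values.index)

    def samples_in_group(self, group: str) -> list:
        labels = self.sample_groups.reindex(self.values.columns)
        return [s for s, g in labels.items() if g == group]


@dataclass
class CohortDEResult:
    """Per-gene differential-expression result for one cohort.

    ``table`` columns: ``log2fc`` (group A mean minus group B mean), ``t``,
    ``p_raw``, ``p_adj`` (Benjamini-Hochberg), ``direction`` in
    ``{"up", "down", "ns"}`` where up/down require ``p_adj < alpha``.
    """

    cohort: str
    table: pd.DataFrame
    alpha: float
    group_a: str = "tumor"
    group_b: str = "normal"
    prior_df: float = field(default=np.nan)
    prior_var: float = field(default=np.nan)

    @property
    def universe(self) -> frozenset:
        return frozenset(self.table.index)

    def genes_with_direction(self, direction: str) -> pd.Index:
        return self.table.index[self.table["direction"] == direction]


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def quantile_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Force every column to the same distribution (the rank-wise mean).

    Each column is replaced by the across-column means of the order
    statistics, indexed by that column's ranks; ties within a column receive
    the mean of the values in their rank slots (average-rank convention).
    """
    arr = values.to_numpy(dtype=float)
    if arr.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 columns")
    if not np.isfinite(arr).all():
        raise ValueError("quantile normalization requires finite values")
    order_means = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    n = arr.shape[0]
    for j in range(arr.shape[1]):
        ranks = stats.rankdata(arr[:, j], method="average")
        # fractional (tied) ranks interpolate between adjacent rank slots,
        # i.e. the mean of the slot values for a 2-way tie
        out[:, j] = np.interp(ranks, np.arange(1, n + 1), order_means)
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def collapse_probes(
    probe_values: pd.DataFrame, probe_to_gene: Mapping[str, str]
) -> pd.DataFrame:
    """Average probe rows mapping to the same gene; drop unmapped probes."""
    if not probe_to_gene:
        raise ValueError("empty probe-to-gene mapping")
    mapped = probe_values.index[probe_values.index.isin(probe_to_gene.keys())]
    if len(mapped) < len(probe_values.index):
        logger.info(
            "collapse_probes: dropping %d unmapped probes",
            len(probe_values.index) - len(mapped),
        )
    sub = probe_values.loc[mapped]
    genes = pd.Index([probe_to_gene[p] for p in sub.index], name="gene")
    collapsed = sub.groupby(genes).mean()
    return collapsed


# ---------------------------------------------------------------------------
# empirical-Bayes variance shrinkage
# ---------------------------------------------------------------------------

def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def _fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of (d0, s0^2) on log variances.

    Models s2 ~ s0^2 * F(df, d0).  Returns (d0, s0_squared); d0 may be inf
    (full shrinkage) when the observed spread of log-variances is no larger
    than expected from chi-square sampling alone.
    """
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    n = len(e)
    if n < 2:
        return np.inf, float(np.exp(emean))
    evar = float(((e - emean) ** 2).sum() / (n - 1)) - float(
        special.polygamma(1, df / 2.0)
    )
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = np.exp(
            emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)
        )
    else:
        d0 = np.inf
        s0_sq = np.exp(emean)
        logger.warning(
            "variance-prior moment estimate non-finite; "
            "falling back to full shrinkage (d0 = inf)"
        )
    return float(d0), float(s0_sq)


def moderated_ttest(
    cohort: ExpressionCohort,
    group_a: str,
    group_b: str,
    *,
    paired: bool = False,
    alpha: float = 0.05,
    prior_df: Optional[float] = None,
) -> CohortDEResult:
    """Two-group moderated t-test with BH adjustment.

    Parameters
    ----------
    cohort : ExpressionCohort
    group_a, group_b : str
        Group labels to contrast; log2fc = mean(A) - mean(B).
    paired : bool
        Test within-pair (A minus B) differences as a one-sample problem;
        requires ``cohort.pairing`` with >= 2 complete pairs.
    alpha : float
        Adjusted-p cutoff for the direction call.
    prior_df : float, optional
        Override the estimated prior degrees of freedom ``d0``; ``0``
        reproduces the ordinary t-test, ``inf`` the shared-variance limit.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0,1), got {alpha}")
    a_samples = cohort.samples_in_group(group_a)
    b_samples = cohort.samples_in_group(group_b)

    if paired:
        if cohort.pairing is None:
            raise ValueError(f"cohort {cohort.name!r}: paired test needs pairing ids")
        pairs: dict = {}
        for s in a_samples:
            pairs.setdefault(cohort.pairing[s], [None, None])[0] = s
        for s in b_samples:
            pairs.setdefault(cohort.pairing[s], [None, None])[1] = s
        complete = [v for v in pairs.values() if v[0] is not None and v[1] is not None]
        if len(complete) < 2:
            raise ValueError(
                f"cohort {cohort.name!r}: paired test needs >=2 complete pairs, "
                f"got {len(complete)}"
            )
        a_cols = [v[0] for v in complete]
        b_cols = [v[1] for v in complete]
        diffs = cohort.values[a_cols].to_numpy() - cohort.values[b_cols].to_numpy()
        n = diffs.shape[1]
        fc = diffs.mean(axis=1)
        s2 = diffs.var(axis=1, ddof=1)
        df = n - 1
        c2 = 1.0 / n
    else:
        if len(a_samples) < 2 or len(b_samples) < 2:
            raise ValueError(
                f"cohort {cohort.name!r}: both groups need >=2 samples "
                f"({group_a}: {len(a_samples)}, {group_b}: {len(b_samples)})"
            )
        a = cohort.values[a_samples].to_numpy()
        b = cohort.values[b_samples].to_numpy()
        na, nb = a.shape[1], b.shape[1]
        fc = a.mean(axis=1) - b.mean(axis=1)
        ssa = ((a - a.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        ssb = ((b - b.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        df = na + nb - 2
        s2 = (ssa + ssb) / df
        c2 = 1.0 / na + 1.0 / nb

    # zero-variance genes: substitute the smallest positive variance so the
    # statistic stays finite while the ranking stays sane
    positive = s2[s2 > 0]
    if len(positive) == 0:
        # fully degenerate input (e.g. identical compared samples): any
        # positive scale gives t = 0, p = 1 wherever fc = 0
        logger.warning("cohort %r: all genes have zero variance", cohort.name)
        s2 = np.ones_like(s2)
    else:
        s2 = np.where(s2 > 0, s2, positive.min())

    if prior_df is None:
        d0, s0_sq = _fit_variance_prior(s2, float(df))
    else:
        d0 = float(prior_df)
        _, s0_sq = _fit_variance_prior(s2, float(df))

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
        df_total = df + d0

    t = fc / np.sqrt(s2_post * c2)
    p_raw = 2.0 * stats.t.sf(np.abs(t), df_total)
    p_raw = np.clip(p_raw, 0.0, 1.0)
    p_adj = bh_adjust(p_raw)

    direction = np.where(
        (p_adj < alpha) & (fc > 0),
        "up",
        np.where((p_adj < alpha) & (fc < 0), "down", "ns"),
    )
    table = pd.DataFrame(
        {
            "log2fc": fc,
            "t": t,
            "p_raw": p_raw,
            "p_adj": p_adj,
            "direction": direction,
        },
        index=cohort.values.index,
    )
    return CohortDEResult(
        cohort=cohort.name,
        table=table,
        alpha=alpha,
        group_a=group_a,
        group_b=group_b,
        prior_df=d0,
        prior_var=s0_sq,
    )


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("bh_adjust expects a 1-D array")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out
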