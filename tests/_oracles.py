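"""Independent brute-force oracles used by the unit and acceptance tests.

Everything here is deliberately naive (loops, enumeration, literal rule
transcription) and shares no code with the package implementation.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np


def bh_stepup_bruteforce(p):
    """Literal Benjamini-Hochberg step-up definition:
    adj(i) = min over j with p_(j) >= p_(i) of min(1, p_(j) * m / j)."""
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj_sorted = [0.0] * m
    for i in range(m):
        candidates = [min(1.0, p[order[j]] * m / (j + 1)) for j in range(i, m)]
        adj_sorted[i] = min(candidates)
    out = [0.0] * m
    for i, idx in enumerate(order):
        out[idx] = adj_sorted[i]
    return np.array(out)


def consensus_bruteforce(directions, m, tier2):
    """directions: per-gene list over cohorts in {'up','down','ns',None}
    (None = gene absent from that cohort's platform).  Returns the
    (n_up, n_down, n_tested, tier, gene_class, discordant) tuple."""
    n_up = sum(1 for d in directions if d == "up")
    n_down = sum(1 for d in directions if d == "down")
    n_tested = sum(1 for d in directions if d is not None)
    if n_up >= m:
        gene_class = "CUG"
    elif n_down >= m:
        gene_class = "CDG"
    else:
        gene_class = "none"
    if n_up >= m or n_down >= m:
        tier = "primary"
    elif n_up >= tier2 or n_down >= tier2:
        tier = "secondary"
    else:
        tier = "none"
    discordant = tier != "primary" and n_up >= tier2 and n_down >= tier2
    return n_up, n_down, n_tested, tier, gene_class, discordant


def core_category_bruteforce(gene_class, votes, epistroma_direction, min_votes):
    """Literal specificity category rules (CUG and mirrored CDG)."""
    if gene_class == "CUG":
        normal_ok = votes >= min_votes
        comp_ok = epistroma_direction == "up"  # epithelium-high
        if normal_ok and comp_ok:
            return "core_tumor_specific"
        if comp_ok:
            return "epithelium_only"
        if normal_ok:
            return "normal_low_only"
        return "none"
    if gene_class == "CDG":
        normal_ok = votes >= min_votes
        comp_ok = epistroma_direction == "down"  # stroma-high
        if normal_ok and comp_ok:
            return "core_tumor_specific"
        if comp_ok:
            return "stroma_only"
        if normal_ok:
            return "normal_high_only"
        return "none"
    raise ValueError(gene_class)


def stratum_counts_bruteforce(per_cohort_stats, alpha):
    """per_cohort_stats: list of (p_raw, log2fc) or None (absent).
    Returns (n_up, n_down) counted over cohorts."""
    n_up = n_down = 0
    for entry in per_cohort_stats:
        if entry is None:
            continue
        p, fc = entry
        if p < alpha and fc > 0:
            n_up += 1
        if p < alpha and fc < 0:
            n_down += 1
    return n_up, n_down


def essential_bruteforce(scores, polarity, threshold, line_fraction):
    """scores: 2-D array with NaN for unmeasured lines.  Per-gene per-line
    recount of the essentiality criterion."""
    out = []
    for row in scores:
        measured = [v for v in row if not np.isnan(v)]
        if not measured:
            out.append(False)
            continue
        if polarity == "negative_essential":
            hits = sum(1 for v in measured if v <= threshold)
        else:
            hits = sum(1 for v in measured if v >= threshold)
        out.append(hits / len(measured) >= line_fraction)
    return np.array(out)


def priority_rule_bruteforce(low_normal, prolif, basal, os_sig, interference):
    """Literal multi-criteria priority rule on boolean flags."""
    criteria = low_normal and prolif and (basal or os_sig)
    return criteria, criteria or interference


def hypergeom_sf_enumeration(N, K_s, n, k):
    """P(overlap >= k) by exhaustive enumeration of all C(N, n) draws."""
    universe = list(range(N))
    in_set = set(range(K_s))
    total = comb(N, n)
    hits = sum(
        1 for draw in combinations(universe, n) if len(in_set & set(draw)) >= k
    )
    return hits / total


def logrank_chi2_bruteforce(times, events, group1_mask):
    """Textbook two-group log-rank statistic, re-derived independently."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    g1 = np.asarray(group1_mask, bool)
    o_minus_e = 0.0
    v = 0.0
    for t in sorted(set(times[events == 1])):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & g1).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & g1).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            v += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / v if v > 0 else 0.0
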