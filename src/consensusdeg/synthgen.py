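"""Synthetic multi-cohort PDAC-like data with planted ground truth.

Generates every input the pipeline consumes — K tumor/normal expression
cohorts sharing planted up/down genes with per-cohort effect sizes and
platform dropout, normal-tissue panels, paired tumor epithelium/stroma
samples, dependency screens with planted essential genes, survival tables
with proportional-hazards dependence on chosen genes, and a cell-line drug
response table — together with a :class:`SimTruth` record of what was
planted, so recovery can be measured at every stage.

Reproducibility: one global seed expands to per-operation substreams via
``default_rng([OP_CODE, seed])`` with fixed operation codes, so adding an
operation never perturbs the streams of earlier ones.  Identical config and
seed give bit-identical outputs.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .deg import ExpressionCohort
from .priority import ScreenPanel
from .specificity import TissuePanel

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_multicohort",
    "simulate_tissue_panels",
    "simulate_screens",
    "simulate_survival",
    "simulate_paired_epithelium_stroma",
    "simulate_subtyped_cohort",
    "simulate_drug_response",
]

# fixed per-operation substream codes (do not renumber)
_OP_MULTICOHORT = 1
_OP_TISSUE = 2
_OP_SCREENS = 3
_OP_SURVIVAL = 4
_OP_PAIRED = 5
_OP_DRUGS = 6
_OP_SUBTYPED = 7


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic generator.

    Defaults emulate the 5-cohort discovery design: 2,000 genes with 200
    planted up- and 200 down-regulated genes at a mean effect of 1.5 log2
    units (per-cohort sd 0.3), unit-sd sample noise, 40 tumors + 40 normals
    per cohort, and 10% platform dropout per cohort.
    """

    n_cohorts: int = 5
    genes_total: int = 2000
    n_true_up: int = 200
    n_true_down: int = 200
    n_inconsistent: int = 100
    effect_mean: float = 1.5
    effect_sd: float = 0.3
    noise_sd: float = 1.0
    n_tumor: int = 40
    n_normal: int = 40
    dropout_frac: float = 0.10
    seed: int = 0
    # baseline log2 intensity distribution (quantile-normalized microarray-like)
    baseline_mean: float = 7.0
    baseline_sd: float = 2.0
    # downstream planted structure (all subsets of the planted genes)
    n_independent: int = 1
    n_essential: int = 60
    n_common_essential: int = 30
    n_prognostic: int = 10
    prognostic_beta: float = 0.7
    pancreas_low_frac: float = 0.6
    n_subtype_genes: int = 25
    n_proliferation_genes: int = 10
    subtype_effect: float = 1.0
    proliferation_effect: float = 0.8
    # basal-like tumors run proliferation-higher (couples the two axes the
    # way the aggressive subtype behaves in real tumors)
    proliferation_subtype_coupling: float = 1.0
    paired_frac: float = 0.5
    censoring_rate: float = 0.3

    def validate(self) -> None:
        def bad(name, why):
            raise ValueError(f"invalid SimConfig.{name}: {why}")

        counts = [
            "n_cohorts", "genes_total", "n_true_up", "n_true_down",
            "n_inconsistent", "n_tumor", "n_normal", "n_independent",
            "n_essential", "n_common_essential", "n_prognostic",
            "n_subtype_genes", "n_proliferation_genes",
        ]
        for name in counts:
            if getattr(self, name) < 0:
                bad(name, "must be >= 0")
        if self.n_cohorts < 1:
            bad("n_cohorts", "must be >= 1")
        if self.n_true_up + self.n_true_down + self.n_inconsistent > self.genes_total:
            bad("genes_total", "planted sets exceed the gene universe")
        if not 0 <= self.dropout_frac < 1:
            bad("dropout_frac", "must satisfy 0 <= dropout_frac < 1")
        if self.noise_sd <= 0:
            bad("noise_sd", "must be > 0")
        if self.effect_sd < 0:
            bad("effect_sd", "must be >= 0")
        if self.n_tumor < 2 or self.n_normal < 2:
            bad("n_tumor/n_normal", "each compared group needs >= 2 samples")
        if self.n_essential > self.n_true_up:
            bad("n_essential", "cannot exceed n_true_up")
        if self.n_prognostic > self.n_true_up:
            bad("n_prognostic", "cannot exceed n_true_up")
        if 2 * self.n_subtype_genes + self.n_proliferation_genes > max(self.n_true_up, 0):
            if self.n_subtype_genes or self.n_proliferation_genes:
                bad("n_subtype_genes", "subtype+proliferation genes exceed n_true_up")
        if not 0 <= self.pancreas_low_frac <= 1:
            bad("pancreas_low_frac", "must be in [0, 1]")
        if not 0 <= self.paired_frac <= 1:
            bad("paired_frac", "must be in [0, 1]")
        if self.censoring_rate < 0 or self.censoring_rate >= 1:
            bad("censoring_rate", "must satisfy 0 <= rate < 1")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SimTruth:
    """Ground truth of the planted structure."""

    true_up: frozenset
    true_down: frozenset
    inconsistent: frozenset
    essential: frozenset
    common_essential: frozenset
    pancreas_low: frozenset
    pancreas_high: frozenset
    prognostic: frozenset
    epithelium_high: frozenset
    stroma_high: frozenset
    basal_genes: frozenset
    classical_genes: frozenset
    proliferation_genes: frozenset
    effects: pd.DataFrame = field(repr=False)  # genes x cohorts, log2 units
    prognostic_betas: pd.Series = field(repr=False)
    subtype_labels: dict = field(default_factory=dict, repr=False)
    proliferation_level: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.true_up & self.true_down:
            raise ValueError("true_up and true_down overlap")

    def to_json_dict(self) -> dict:
        keys = [
            "true_up", "true_down", "inconsistent", "essential",
            "common_essential", "pancreas_low", "pancreas_high", "prognostic",
            "epithelium_high", "stroma_high", "basal_genes", "classical_genes",
            "proliferation_genes",
        ]
        return {k: sorted(getattr(self, k)) for k in keys}


def _rng(seed: int, op_code: int, tag: str = "") -> np.random.Generator:
    entropy = [op_code, int(seed)]
    if tag:
        entropy.append(zlib.crc32(tag.encode()))
    return np.random.default_rng(entropy)


def _gene_names(g: int) -> list[str]:
    width = max(4, len(str(g)))
    return [f"G{i:0{width}d}" for i in range(g)]


def simulate_multicohort(
    config: SimConfig,
) -> tuple[list[ExpressionCohort], SimTruth]:
    """K discovery cohorts (+ independent validation cohorts) with planted
    differential genes, plus the ground truth.

    Returns ``(cohorts, truth)``: the first ``config.n_cohorts`` cohorts are
    the discovery set, the remaining ``config.n_independent`` (named
    ``independent*``) share the same planted genes with freshly drawn
    per-cohort effects — the validation role.
    """
    config.validate()
    rng = _rng(config.seed, _OP_MULTICOHORT)
    genes = _gene_names(config.genes_total)
    baseline = pd.Series(
        rng.normal(config.baseline_mean, config.baseline_sd, config.genes_total),
        index=genes,
    )

    perm = rng.permutation(config.genes_total)
    up = [genes[i] for i in perm[: config.n_true_up]]
    down = [genes[i] for i in perm[config.n_true_up: config.n_true_up + config.n_true_down]]
    incons = [
        genes[i]
        for i in perm[
            config.n_true_up + config.n_true_down:
            config.n_true_up + config.n_true_down + config.n_inconsistent
        ]
    ]

    # downstream planted subsets, all drawn from the sorted planted lists so
    # selection is independent of permutation order
    up_sorted = sorted(up)
    down_sorted = sorted(down)
    basal = list(up_sorted[: config.n_subtype_genes])
    classical = list(
        up_sorted[config.n_subtype_genes: 2 * config.n_subtype_genes]
    )
    prolif = list(
        up_sorted[
            2 * config.n_subtype_genes:
            2 * config.n_subtype_genes + config.n_proliferation_genes
        ]
    )
    essential = (
        sorted(rng.choice(up_sorted, size=config.n_essential, replace=False))
        if config.n_essential
        else []
    )
    prognostic = (
        sorted(rng.choice(up_sorted, size=config.n_prognostic, replace=False))
        if config.n_prognostic
        else []
    )
    n_plow = int(round(config.pancreas_low_frac * len(up_sorted)))
    pancreas_low = (
        sorted(rng.choice(up_sorted, size=n_plow, replace=False)) if n_plow else []
    )
    n_phigh = int(round(config.pancreas_low_frac * len(down_sorted)))
    pancreas_high = (
        sorted(rng.choice(down_sorted, size=n_phigh, replace=False)) if n_phigh else []
    )
    n_epi = int(round(config.paired_frac * len(up_sorted)))
    epithelium_high = (
        sorted(rng.choice(up_sorted, size=n_epi, replace=False)) if n_epi else []
    )
    n_str = int(round(config.paired_frac * len(down_sorted)))
    stroma_high = (
        sorted(rng.choice(down_sorted, size=n_str, replace=False)) if n_str else []
    )
    non_up = sorted(set(genes) - set(up))
    common_essential = (
        sorted(rng.choice(non_up, size=config.n_common_essential, replace=False))
        if config.n_common_essential
        else []
    )

    total = config.n_cohorts + config.n_independent
    cohort_names = [f"cohort{k + 1}" for k in range(config.n_cohorts)] + [
        f"independent{k + 1}" for k in range(config.n_independent)
    ]
    effects = pd.DataFrame(0.0, index=genes, columns=cohort_names)
    for name in cohort_names:
        mag_up = np.abs(rng.normal(config.effect_mean, config.effect_sd, len(up)))
        mag_down = np.abs(rng.normal(config.effect_mean, config.effect_sd, len(down)))
        mag_inc = np.abs(rng.normal(config.effect_mean, config.effect_sd, len(incons)))
        sign_inc = rng.choice([-1.0, 1.0], size=len(incons))
        effects.loc[up, name] = mag_up
        effects.loc[down, name] = -mag_down
        effects.loc[incons, name] = sign_inc * mag_inc

    truth = SimTruth(
        true_up=frozenset(up),
        true_down=frozenset(down),
        inconsistent=frozenset(incons),
        essential=frozenset(essential),
        common_essential=frozenset(common_essential),
        pancreas_low=frozenset(pancreas_low),
        pancreas_high=frozenset(pancreas_high),
        prognostic=frozenset(prognostic),
        epithelium_high=frozenset(epithelium_high),
        stroma_high=frozenset(stroma_high),
        basal_genes=frozenset(basal),
        classical_genes=frozenset(classical),
        proliferation_genes=frozenset(prolif),
        effects=effects,
        prognostic_betas=pd.Series(config.prognostic_beta, index=sorted(prognostic)),
    )

    n_drop = int(round(config.dropout_frac * config.genes_total))
    cohorts: list[ExpressionCohort] = []
    for name in cohort_names:
        keep = genes
        if n_drop:
            dropped = set(rng.choice(genes, size=n_drop, replace=False))
            keep = [g for g in genes if g not in dropped]
        nt, nn = config.n_tumor, config.n_normal
        cols = [f"{name}_T{i + 1:03d}" for i in range(nt)] + [
            f"{name}_N{i + 1:03d}" for i in range(nn)
        ]
        mat = (
            baseline.loc[keep].to_numpy()[:, None]
            + rng.normal(0.0, config.noise_sd, (len(keep), nt + nn))
        )
        eff = effects.loc[keep, name].to_numpy()
        mat[:, :nt] += eff[:, None]

        # latent tumor structure: subtype clusters and a proliferation axis
        subtype = np.array(
            ["basal_like"] * (nt // 2) + ["classical"] * (nt - nt // 2)
        )
        keep_set = set(keep)
        b_idx = [i for i, g in enumerate(keep) if g in set(basal) & keep_set]
        c_idx = [i for i, g in enumerate(keep) if g in set(classical) & keep_set]
        p_idx = [i for i, g in enumerate(keep) if g in set(prolif) & keep_set]
        tum_basal = np.where(subtype == "basal_like")[0]
        tum_classical = np.where(subtype == "classical")[0]
        if b_idx:
            mat[np.ix_(b_idx, tum_basal)] += config.subtype_effect
        if c_idx:
            mat[np.ix_(c_idx, tum_classical)] += config.subtype_effect
        prolif_level = rng.normal(0.0, 1.0, nt) + (
            config.proliferation_subtype_coupling * (subtype == "basal_like")
        )
        if p_idx:
            mat[np.ix_(p_idx, np.arange(nt))] += (
                config.proliferation_effect * prolif_level[None, :]
            )

        values = pd.DataFrame(mat, index=pd.Index(keep, name="gene"), columns=cols)
        groups = pd.Series(
            ["tumor"] * nt + ["normal"] * nn, index=cols, name="group"
        )
        cohorts.append(ExpressionCohort(name=name, values=values, sample_groups=groups))
        truth.subtype_labels[name] = pd.Series(subtype, index=cols[:nt], name="subtype")
        truth.proliferation_level[name] = pd.Series(
            prolif_level, index=cols[:nt], name="proliferation"
        )
    return cohorts, truth


def simulate_tissue_panels(
    config: SimConfig,
    truth: SimTruth,
    n_panels: int = 3,
    n_tissues: int = 12,
) -> list[TissuePanel]:
    """Normal-tissue panels (pancreas + other tissues, one value per tissue).

    Planted pancreas-low genes sit strictly below the across-tissue median
    in every panel (and pancreas-high genes strictly above); all other genes
    have exchangeable pancreas values.
    """
    config.validate()
    if n_tissues < 2:
        raise ValueError("tissue panels need >=2 tissues")
    rng = _rng(config.seed, _OP_TISSUE)
    genes = _gene_names(config.genes_total)
    tissues = ["pancreas"] + [f"tissue{i + 1:02d}" for i in range(n_tissues - 1)]
    panels = []
    plow = sorted(truth.pancreas_low)
    phigh = sorted(truth.pancreas_high)
    for p in range(n_panels):
        vals = rng.normal(
            config.baseline_mean, 1.5, (config.genes_total, n_tissues)
        )
        df = pd.DataFrame(vals, index=pd.Index(genes, name="gene"), columns=tissues)
        margin = rng.uniform(0.5, 1.5, len(plow))
        df.loc[plow, "pancreas"] = (
            df.loc[plow, tissues[1:]].min(axis=1).to_numpy() - margin
        )
        margin_h = rng.uniform(0.5, 1.5, len(phigh))
        df.loc[phigh, "pancreas"] = (
            df.loc[phigh, tissues[1:]].max(axis=1).to_numpy() + margin_h
        )
        panels.append(
            TissuePanel(name=f"panel{p + 1}", values=df, pancreas_label="pancreas")
        )
    return panels


def simulate_screens(
    config: SimConfig,
    truth: SimTruth,
    n_screens: int = 4,
    n_lines: Sequence[int] = (24, 24, 8, 20),
) -> list[ScreenPanel]:
    """Dependency screens: three CERES-like (negative = essential) and one
    Bayes-factor screen (positive = essential).

    Each planted essential gene is active (strongly scoring in effectively
    all lines) in 3 or 4 of the screens; planted common-essential genes
    (non-CUG housekeeping dependencies) are active in every screen.
    """
    config.validate()
    if len(n_lines) != n_screens:
        raise ValueError("n_lines must list one line count per screen")
    rng = _rng(config.seed, _OP_SCREENS)
    genes = _gene_names(config.genes_total)
    ess = sorted(truth.essential)
    common = sorted(truth.common_essential)
    # per essential gene: active in 3 or 4 screens
    active: dict[str, set] = {}
    for g in ess:
        k = int(rng.integers(3, n_screens + 1))
        active[g] = set(rng.choice(n_screens, size=k, replace=False))
    panels = []
    for s in range(n_screens):
        polarity = "positive_essential" if s == n_screens - 1 else "negative_essential"
        nl = n_lines[s]
        cols = [f"line{s + 1}_{j + 1:02d}" for j in range(nl)]
        if polarity == "negative_essential":
            vals = rng.normal(0.0, 0.15, (config.genes_total, nl))
            hit_shift = -1.0
        else:
            vals = rng.normal(-8.0, 2.0, (config.genes_total, nl))
            hit_shift = 16.0
        df = pd.DataFrame(vals, index=pd.Index(genes, name="gene"), columns=cols)
        hits = [g for g in ess if s in active[g]] + common
        df.loc[hits] += hit_shift
        panels.append(ScreenPanel(name=f"screen{s + 1}", scores=df, polarity=polarity))
    return panels


def simulate_survival(
    config: SimConfig,
    truth: SimTruth,
    cohort: ExpressionCohort,
    betas: Union[float, Mapping[str, float], None] = None,
    censoring_rate: Optional[float] = None,
    baseline_rate: float = 1.0 / 500.0,
    extra_genes: Sequence[str] = (),
) -> pd.DataFrame:
    """Exponential event times with log-hazard linear in the standardized
    expression of the prognostic genes; independent exponential censoring.

    Returns a table indexed by tumor sample with ``time`` (days), ``event``
    and one expression column per prognostic/extra gene.  The censoring rate
    is the probability a baseline-hazard subject is censored before its
    event; ``0`` disables censoring (all events observed).
    """
    config.validate()
    if censoring_rate is None:
        censoring_rate = config.censoring_rate
    if censoring_rate < 0:
        raise ValueError("censoring rate must be >= 0")
    if censoring_rate >= 1:
        raise ValueError("censoring rate must be < 1")
    rng = _rng(config.seed, _OP_SURVIVAL, tag=cohort.name)

    samples = cohort.samples_in_group("tumor") or list(cohort.values.columns)
    prog = [g for g in sorted(truth.prognostic) if g in cohort.values.index]
    if betas is None:
        beta_map = {g: truth.prognostic_betas.get(g, 0.0) for g in prog}
    elif isinstance(betas, Mapping):
        beta_map = {g: betas.get(g, 0.0) for g in prog}
    else:
        beta_map = {g: float(betas) for g in prog}

    lp = np.zeros(len(samples))
    for g in prog:
        x = cohort.values.loc[g, samples].to_numpy(dtype=float)
        sd = x.std()
        z = (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)
        lp += beta_map[g] * z
    rate = baseline_rate * np.exp(lp)
    t_event = rng.exponential(1.0 / rate)
    if censoring_rate > 0:
        rate_c = baseline_rate * censoring_rate / (1.0 - censoring_rate)
        t_cens = rng.exponential(1.0 / rate_c, len(samples))
    else:
        t_cens = np.full(len(samples), np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)

    out = pd.DataFrame(
        {"time": np.maximum(time, 1e-6), "event": event},
        index=pd.Index(samples, name="sample"),
    )
    for g in prog + [g for g in extra_genes if g in cohort.values.index and g not in prog]:
        out[g] = cohort.values.loc[g, samples].to_numpy(dtype=float)
    return out


def simulate_paired_epithelium_stroma(
    config: SimConfig,
    truth: SimTruth,
    n_pairs: int = 65,
    n_samples: Optional[int] = None,
    pair_effect_sd: float = 0.7,
) -> ExpressionCohort:
    """Paired tumor-epithelium / stroma samples with a shared pair effect.

    ``truth.epithelium_high`` genes are elevated in the epithelium sample of
    each pair and ``truth.stroma_high`` genes in the stroma sample.  If
    ``n_samples`` is given it must be even (two compartments per pair).
    """
    config.validate()
    if n_samples is not None:
        if n_samples % 2:
            raise ValueError("paired design needs an even sample count")
        n_pairs = n_samples // 2
    if n_pairs < 2:
        raise ValueError("need >=2 pairs")
    rng = _rng(config.seed, _OP_PAIRED)
    genes = _gene_names(config.genes_total)
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, config.genes_total)
    epi_cols = [f"epi{i + 1:03d}" for i in range(n_pairs)]
    str_cols = [f"str{i + 1:03d}" for i in range(n_pairs)]
    pair_ids = [f"pair{i + 1:03d}" for i in range(n_pairs)]

    pair_fx = rng.normal(0.0, pair_effect_sd, n_pairs)
    mat = (
        baseline[:, None]
        + np.tile(pair_fx, 2)[None, :]
        + rng.normal(0.0, config.noise_sd, (config.genes_total, 2 * n_pairs))
    )
    epi_set = sorted(truth.epithelium_high)
    str_set = sorted(truth.stroma_high)
    gene_pos = {g: i for i, g in enumerate(genes)}
    fx_epi = np.abs(rng.normal(config.effect_mean, config.effect_sd, len(epi_set)))
    for g, f in zip(epi_set, fx_epi):
        mat[gene_pos[g], :n_pairs] += f
    fx_str = np.abs(rng.normal(config.effect_mean, config.effect_sd, len(str_set)))
    for g, f in zip(str_set, fx_str):
        mat[gene_pos[g], n_pairs:] += f

    cols = epi_cols + str_cols
    values = pd.DataFrame(mat, index=pd.Index(genes, name="gene"), columns=cols)
    groups = pd.Series(
        ["epithelium"] * n_pairs + ["stroma"] * n_pairs, index=cols, name="group"
    )
    pairing = pd.Series(pair_ids + pair_ids, index=cols, name="pair")
    return ExpressionCohort(
        name="epistroma", values=values, sample_groups=groups, pairing=pairing
    )


def simulate_subtyped_cohort(
    config: SimConfig,
    basal_genes: Sequence[str],
    classical_genes: Sequence[str],
    n_basal: int = 30,
    n_classical: int = 30,
    effect: float = 1.5,
) -> tuple[ExpressionCohort, pd.Series]:
    """Standalone two-cluster tumor cohort for subtype-recovery tests."""
    config.validate()
    rng = _rng(config.seed, _OP_SUBTYPED)
    genes = _gene_names(config.genes_total)
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, config.genes_total)
    cols = [f"sub_T{i + 1:03d}" for i in range(n_basal + n_classical)]
    mat = baseline[:, None] + rng.normal(
        0.0, config.noise_sd, (config.genes_total, n_basal + n_classical)
    )
    pos = {g: i for i, g in enumerate(genes)}
    b_idx = [pos[g] for g in basal_genes if g in pos]
    c_idx = [pos[g] for g in classical_genes if g in pos]
    if b_idx:
        mat[np.ix_(b_idx, np.arange(n_basal))] += effect
    if c_idx:
        mat[np.ix_(c_idx, np.arange(n_basal, n_basal + n_classical))] += effect
    values = pd.DataFrame(mat, index=pd.Index(genes, name="gene"), columns=cols)
    groups = pd.Series(["tumor"] * len(cols), index=cols, name="group")
    labels = pd.Series(
        ["basal_like"] * n_basal + ["classical"] * n_classical,
        index=cols,
        name="subtype",
    )
    return (
        ExpressionCohort(name="subtyped", values=values, sample_groups=groups),
        labels,
    )


def simulate_drug_response(
    config: SimConfig,
    truth: SimTruth,
    n_lines: int = 16,
    n_drugs: int = 8,
    n_sensitive_drugs: int = 2,
    expression_shift: float = 1.5,
    sensitivity_shift: float = -2.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cell-line expression plus a drug-sensitivity table.

    Half of the lines express the planted essential/priority genes highly;
    the first ``n_sensitive_drugs`` drugs are more effective (lower
    sensitivity metric) in those high-expressing lines.
    """
    config.validate()
    rng = _rng(config.seed, _OP_DRUGS)
    genes = _gene_names(config.genes_total)
    lines = [f"cell{j + 1:02d}" for j in range(n_lines)]
    n_high = n_lines // 2
    expr = rng.normal(config.baseline_mean, 1.0, (config.genes_total, n_lines))
    expr_df = pd.DataFrame(expr, index=pd.Index(genes, name="gene"), columns=lines)
    marker = sorted(truth.essential) or sorted(truth.true_up)
    expr_df.loc[marker, lines[:n_high]] += expression_shift

    drugs = [f"drug{j + 1:02d}" for j in range(n_drugs)]
    sens = rng.normal(0.0, 0.5, (n_lines, n_drugs))
    sens_df = pd.DataFrame(sens, index=pd.Index(lines, name="cell_line"), columns=drugs)
    for d in drugs[:n_sensitive_drugs]:
        sens_df.loc[lines[:n_high], d] += sensitivity_shift
    return expr_df, sens_df
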