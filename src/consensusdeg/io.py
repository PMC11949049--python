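"""Readers/writers for the pipeline's plain-text formats and run configuration.

Formats: TSV expression matrices (first column = gene symbol, header row of
sample IDs), two/three-column sample label tables, GMT gene-set files, TSV
tissue panels / screens / survival / drug tables, JSON results.  Missing
values are written as ``NA`` and propagated as absent-from-cohort; a bare
``.`` is rejected as a number.  Gene identifiers are case-sensitive symbols;
no alias resolution is attempted.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .deg import ExpressionCohort
from .priority import ScreenPanel
from .specificity import TissuePanel

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSetCollection",
    "RunConfig",
    "read_expression",
    "write_expression",
    "read_gmt",
    "write_gmt",
    "read_tissue_panel",
    "write_tissue_panel",
    "read_screen",
    "write_screen",
    "read_survival_table",
    "write_survival_table",
    "read_drug_table",
    "write_drug_table",
]

FLOAT_FORMAT = "%.10g"


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT dialect): name -> (description, ordered genes)."""

    sets: dict
    descriptions: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
        for name in self.sets:
            self.descriptions.setdefault(name, "")

    def __getitem__(self, name: str) -> list:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def __len__(self) -> int:
        return len(self.sets)

    def items(self):
        return self.sets.items()


@dataclass
class RunConfig:
    """Pipeline thresholds; defaults mirror the study's printed cutoffs."""

    alpha_discovery: float = 0.05      # adjusted-p cutoff, tumor/normal DE
    alpha_epistroma: float = 0.01      # adjusted-p cutoff, epithelium/stroma
    min_support: int = 4               # cohorts required for CUG/CDG (of K)
    tier2_support: int = 3             # secondary consistency tier
    specificity_min_votes: int = 2     # tissue panels (of 3) for pancreas-low
    stratum_alpha: float = 0.05        # raw-p cutoff for stratum contrasts
    stratum_support: int = 2           # cohorts for stratum overlap
    screen_support: int = 3            # screens (of 4) for essentiality
    essential_threshold_negative: float = -0.5
    essential_threshold_positive: float = 0.0
    essential_line_fraction: float = 0.5
    score_log_base: float = 10.0
    score_use_adjusted: bool = False
    score_mode: str = "score_sum"
    survival_alpha: float = 0.05
    survival_min_count: int = 3
    seed: int = 0

    def validate(self) -> None:
        for name in ("alpha_discovery", "alpha_epistroma", "stratum_alpha",
                     "survival_alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"RunConfig.{name} must be in (0,1), got {v}")
        if self.min_support < 1:
            raise ValueError("RunConfig.min_support must be >= 1")
        if not 1 <= self.tier2_support < self.min_support:
            raise ValueError(
                "RunConfig.tier2_support must satisfy 1 <= tier2 < min_support"
            )
        for name in ("essential_threshold_negative", "essential_threshold_positive",
                     "score_log_base"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"RunConfig.{name} must be finite")
        if not 0 < self.essential_line_fraction <= 1:
            raise ValueError("RunConfig.essential_line_fraction must be in (0,1]")
        if self.score_mode not in {"score_sum", "rank_sum"}:
            raise ValueError(f"unknown score_mode {self.score_mode!r}")

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown RunConfig keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# expression matrices + labels
# ---------------------------------------------------------------------------

def _parse_numeric(df: pd.DataFrame, path: Union[str, Path]) -> pd.DataFrame:
    """String matrix -> float matrix; 'NA' means missing, anything else
    non-numeric (including a bare '.') is an error naming row and column."""
    out = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        raw = df[col].to_numpy()
        vals = pd.to_numeric(pd.Series(raw).replace("NA", np.nan), errors="coerce")
        bad = vals.isna().to_numpy() & (raw != "NA")
        if bad.any():
            i = int(np.nonzero(bad)[0][0])
            raise ValueError(
                f"{path}: non-numeric value {raw[i]!r} at gene "
                f"{df.index[i]!r}, sample {col!r}"
            )
        out[:, j] = vals.to_numpy()
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def read_labels(path: Union[str, Path]) -> tuple[pd.Series, Optional[pd.Series]]:
    tbl = pd.read_csv(path, sep="\t", dtype=str)
    if "sample" not in tbl.columns or "group" not in tbl.columns:
        raise ValueError(f"{path}: label table needs 'sample' and 'group' columns")
    tbl = tbl.set_index("sample")
    groups = tbl["group"]
    pairing = tbl["pair"] if "pair" in tbl.columns else None
    return groups, pairing


def read_expression(
    path: Union[str, Path],
    label_path: Union[str, Path],
    name: Optional[str] = None,
) -> ExpressionCohort:
    """Read a genes x samples TSV plus its sample-label table.

    Duplicate gene rows are rejected (collapse probes upstream); rows with
    any missing (``NA``) value are dropped from the cohort's universe.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate gene rows {dups[:5]}")
    groups, pairing = read_labels(label_path)
    missing = [s for s in df.columns if s not in groups.index]
    if missing:
        raise ValueError(f"{path}: samples without labels: {missing}")
    values = _parse_numeric(df, path)
    n_missing = int(values.isna().any(axis=1).sum())
    if n_missing:
        logger.info("%s: dropping %d genes with missing values", path, n_missing)
        values = values.dropna(axis=0)
    return ExpressionCohort(
        name=name or path.stem,
        values=values,
        sample_groups=groups,
        pairing=pairing,
    )


def write_expression(
    cohort: ExpressionCohort,
    path: Union[str, Path],
    label_path: Union[str, Path],
) -> None:
    df = cohort.values.copy()
    df.index.name = "gene"
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, na_rep="NA")
    labels = pd.DataFrame({"sample": df.columns})
    labels["group"] = cohort.sample_groups.reindex(df.columns).to_numpy()
    if cohort.pairing is not None:
        labels["pair"] = cohort.pairing.reindex(df.columns).to_numpy()
    labels.to_csv(label_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: Union[str, Path]) -> GeneSetCollection:
    """Parse GMT: one set per line, ``name TAB description TAB gene...``."""
    sets: dict = {}
    descriptions: dict = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{ln}: GMT line needs name, description, >=1 gene")
        name, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
        if name in sets:
            raise ValueError(f"{path}:{ln}: duplicate set name {name!r}")
        if not genes:
            raise ValueError(f"{path}:{ln}: empty gene list for set {name!r}")
        sets[name] = genes
        descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path: Union[str, Path]) -> None:
    lines = [
        "\t".join([name, collection.descriptions.get(name, "")] + list(genes))
        for name, genes in collection.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# panels, screens, survival, drugs
# ---------------------------------------------------------------------------

def read_tissue_panel(
    path: Union[str, Path],
    pancreas_label: str = "pancreas",
    name: Optional[str] = None,
) -> TissuePanel:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    values = _parse_numeric(df, path).dropna(axis=0)
    return TissuePanel(
        name=name or Path(path).stem, values=values, pancreas_label=pancreas_label
    )


def write_tissue_panel(panel: TissuePanel, path: Union[str, Path]) -> None:
    out = panel.values.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def read_screen(
    path: Union[str, Path], polarity: str, name: Optional[str] = None
) -> ScreenPanel:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    scores = _parse_numeric(df, path)  # NaN = not measured in that line
    return ScreenPanel(name=name or Path(path).stem, scores=scores, polarity=polarity)


def write_screen(screen: ScreenPanel, path: Union[str, Path]) -> None:
    out = screen.scores.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, na_rep="NA")


def read_survival_table(path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    for col in ("time", "event"):
        if col not in df.columns:
            raise ValueError(f"{path}: survival table needs a {col!r} column")
    df["event"] = df["event"].astype(int)
    return df


def write_survival_table(table: pd.DataFrame, path: Union[str, Path]) -> None:
    out = table.copy()
    out.index.name = "sample"
    out.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def read_drug_table(path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    return _parse_numeric(df, path)


def write_drug_table(table: pd.DataFrame, path: Union[str, Path]) -> None:
    out = table.copy()
    out.index.name = "cell_line"
    out.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, na_rep="NA")


def write_gene_list(genes: Sequence[str], path: Union[str, Path]) -> None:
    Path(path).write_text("\n".join(genes) + ("\n" if len(genes) else ""))


def read_gene_list(path: Union[str, Path]) -> list:
    return [g for g in Path(path).read_text().splitlines() if g.strip()]
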