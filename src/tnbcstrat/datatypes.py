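"""Core shared data containers for the stratification pipeline.

Everything downstream operates on a small set of typed containers: an
expression matrix with an explicit processing-stage tag, named gene sets,
a clinical/survival table, per-sample score vectors and per-sample group
assignments. The stage tag makes the normalization contract checkable:
operations declare which stage they require and refuse anything else, so
the three-step normalization can never be applied twice or skipped
silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: Allowed processing stages, in their mandatory order.
STAGES = ("raw", "log2", "centered", "normalized")


class StageError(ValueError):
    """Raised when an operation receives a matrix at the wrong stage."""


@dataclass
class ExpressionMatrix:
    """Genes x samples expression table with a processing-stage tag.

    Parameters
    ----------
    values : pandas.DataFrame
        Numeric table, index = gene symbols, columns = sample ids.
    stage : str
        One of ``raw``, ``log2``, ``centered``, ``normalized``.
    """

    values: pd.DataFrame
    stage: str = "raw"

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise StageError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        if self.values.size == 0:
            raise ValueError("empty expression table")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups[:5]}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("expression values must be numeric")
        if np.isnan(arr).any():
            r, c = np.argwhere(np.isnan(arr))[0]
            raise ValueError(
                f"missing value at gene {self.values.index[r]!r}, "
                f"sample {self.values.columns[c]!r}; drop or impute explicitly"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def require_stage(self, stage: str, op: str) -> None:
        if self.stage != stage:
            raise StageError(
                f"{op} requires a {stage!r}-stage matrix, got {self.stage!r}"
            )

    def with_values(self, values: pd.DataFrame, stage: str) -> "ExpressionMatrix":
        """Return a new matrix at `stage`; transitions must move forward."""
        if STAGES.index(stage) < STAGES.index(self.stage):
            raise StageError(f"stage cannot move backwards: {self.stage} -> {stage}")
        return ExpressionMatrix(values, stage=stage)


@dataclass(frozen=True)
class GeneSet:
    """A named list of gene symbols."""

    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("gene set name must be non-empty")
        genes = tuple(self.genes)
        if len(genes) == 0:
            raise ValueError(f"gene set {self.name!r} is empty")
        if len(set(genes)) != len(genes):
            raise ValueError(f"gene set {self.name!r} has duplicate genes")
        object.__setattr__(self, "genes", genes)

    def __len__(self) -> int:
        return len(self.genes)

    def present_in(self, m: ExpressionMatrix) -> list[str]:
        idx = set(m.values.index)
        return [g for g in self.genes if g in idx]


@dataclass
class GeneSetCollection:
    """Ordered collection of gene sets, as read from a GMT file."""

    sets: list[GeneSet]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        for gs in self.sets:
            if gs.name == name:
                return gs
        raise KeyError(name)

    def names(self) -> list[str]:
        return [gs.name for gs in self.sets]


@dataclass
class ClinicalTable:
    """Per-sample clinical annotation with optional survival columns.

    Columns: ``age`` (years), ``tumor_size``, ``followup_time`` (months),
    ``event`` (boolean). Fields may be individually missing, but
    followup_time and event must co-occur.
    """

    data: pd.DataFrame

    COLUMNS = ("age", "tumor_size", "followup_time", "event")

    def __post_init__(self) -> None:
        df = self.data.copy()
        for col in self.COLUMNS:
            if col not in df.columns:
                df[col] = np.nan
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids in clinical table: {dups[:5]}")
        ft = df["followup_time"]
        if (ft.dropna() < 0).any():
            bad = df.index[ft < 0].tolist()
            raise ValueError(f"negative followup_time for samples {bad[:5]}")
        has_t, has_e = ft.notna(), df["event"].notna()
        if (has_t != has_e).any():
            bad = df.index[has_t != has_e].tolist()
            raise ValueError(
                f"followup_time and event must co-occur; mismatched for {bad[:5]}"
            )
        self.data = df[list(self.COLUMNS)]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def survival(self) -> pd.DataFrame:
        """Rows with complete (followup_time, event) pairs."""
        mask = self.data["followup_time"].notna()
        out = self.data.loc[mask, ["followup_time", "event"]].copy()
        out["event"] = out["event"].astype(bool)
        return out


@dataclass
class ScoreVector:
    """A named scalar score per sample, with provenance."""

    name: str
    values: pd.Series
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        s = pd.Series(self.values, dtype=float) if not isinstance(
            self.values, pd.Series
        ) else self.values.astype(float)
        if s.index.has_duplicates:
            raise ValueError(f"duplicate sample ids in score {self.name!r}")
        if not np.isfinite(s.to_numpy()).all():
            raise ValueError(f"non-finite values in score {self.name!r}")
        self.values = s

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class GroupAssignment:
    """Per-sample label from a declared finite label set.

    `params` records the construction parameters (fractions, tie rule,
    boundary values) so the assignment is reproducible from them.
    """

    name: str
    labels: pd.Series
    label_set: tuple[str, ...]
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = pd.Series(self.labels)
        extra = set(labels.unique()) - set(self.label_set)
        if extra:
            raise ValueError(f"labels outside declared set: {sorted(extra)}")
        if labels.index.has_duplicates:
            raise ValueError("duplicate sample ids in group assignment")
        self.labels = labels

    @property
    def sample_ids(self) -> list[str]:
        return list(self.labels.index)

    def members(self, label: str) -> list[str]:
        return list(self.labels.index[self.labels == label])

    def counts(self) -> dict[str, int]:
        vc = self.labels.value_counts()
        return {lab: int(vc.get(lab, 0)) for lab in self.label_set}
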