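"""Core in-memory containers shared across the pipeline.

Expression data travel as a genes × samples pandas DataFrame of log2
values, paired with a per-sample annotation table. Gene sets carry
provenance so a derived signature records where it came from.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

#: Pan-hematopoietic marker used as the per-sample immune-infiltration
#: estimate throughout the pipeline.
CD45 = "PTPRC"

#: Required annotation columns for cohort matrices.
ANNOTATION_COLUMNS = ("tissue", "sample_class")


class ParainflamError(ValueError):
    """Base class for input/contract violations raised by this package."""


@dataclass
class ExpressionMatrix:
    """log2 expression, genes as rows, samples as columns.

    ``annotations`` is indexed by sample id and may carry ``tissue``,
    ``sample_class`` (``tumor``/``normal``/``cell_line``), ``p53_status``,
    ``time`` and ``event`` columns depending on the cohort type.
    """

    values: pd.DataFrame
    annotations: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ParainflamError("duplicate gene symbols in expression matrix")
        if self.annotations is not None:
            missing = self.annotations.index.difference(self.values.columns)
            if len(missing):
                raise ParainflamError(
                    f"annotations reference unknown samples: {list(missing)[:5]}"
                )

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def tissue_of(self, sample: str) -> str:
        if self.annotations is None or "tissue" not in self.annotations:
            raise ParainflamError("matrix has no tissue annotations")
        return self.annotations.loc[sample, "tissue"]

    def subset_samples(self, samples: Iterable[str]) -> "ExpressionMatrix":
        samples = list(samples)
        ann = None
        if self.annotations is not None:
            ann = self.annotations.loc[
                self.annotations.index.intersection(samples)
            ].reindex(samples)
        return ExpressionMatrix(self.values[samples], ann)

    def subset_class(self, sample_class: str) -> "ExpressionMatrix":
        if self.annotations is None or "sample_class" not in self.annotations:
            raise ParainflamError("matrix has no sample_class annotations")
        keep = self.annotations.index[
            self.annotations["sample_class"] == sample_class
        ]
        return self.subset_samples(keep)


@dataclass
class CountMatrix:
    """Raw RNA-seq counts (genes × samples) with a condition label per sample."""

    counts: pd.DataFrame
    conditions: pd.Series

    def __post_init__(self) -> None:
        self.conditions = self.conditions.reindex(self.counts.columns)
        if self.conditions.isna().any():
            raise ParainflamError("every sample needs a condition label")
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ParainflamError("counts must be non-negative")
        if not np.allclose(vals, np.round(vals)):
            raise ParainflamError("counts must be integers")

    def samples_in(self, condition: str) -> pd.Index:
        return self.conditions.index[self.conditions == condition]


@dataclass
class GeneList:
    """An ordered, unique list of gene symbols with provenance.

    ``annotations`` optionally carries a per-gene number (e.g. the
    correlation that admitted each gene into an expanded signature).
    """

    name: str
    genes: list[str]
    source: str = ""
    annotations: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ParainflamError("gene list needs a non-empty name")
        seen: dict[str, None] = {}
        for g in self.genes:
            if g not in seen:
                seen[g] = None
        self.genes = list(seen)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)

    def upper_set(self) -> set[str]:
        return {g.upper() for g in self.genes}


@dataclass
class PISignature:
    """The parainflammation gene sets: up, down and correlation-expanded."""

    up: GeneList
    down: Optional[GeneList] = None
    expanded: Optional[GeneList] = None
    species: str = "mouse"

    def __post_init__(self) -> None:
        if self.down is not None:
            overlap = set(self.up.genes) & set(self.down.genes)
            if overlap:
                raise ParainflamError(
                    f"up and down signatures overlap: {sorted(overlap)[:5]}"
                )


@dataclass
class Threshold:
    """A calibrated PI+ cut-point, tagged with the scoring universe.

    Scores are rank statistics over a gene universe; thresholds are only
    meaningful within the platform/universe they were calibrated on, so
    classification refuses a threshold from a different universe.
    """

    value: float
    calibration_fraction: float
    universe_size: Optional[int] = None
    n_genes_used: Optional[int] = None


@dataclass
class PIScoreTable:
    """Per-sample PI scores and (after classification) PI+/PI− calls.

    ``table`` columns: raw_score, shifted_score, call.
    """

    table: pd.DataFrame
    n_signature_genes_used: int
    universe_size: int
    signature_name: str = "PI"
    threshold: Optional[float] = None
    calibration_fraction: Optional[float] = None

    @property
    def raw(self) -> pd.Series:
        return self.table["raw_score"]

    @property
    def calls(self) -> pd.Series:
        return self.table["call"]

    def classified(self) -> bool:
        return self.threshold is not None


@dataclass
class AssociationResult:
    """One downstream statistic: its effect size, p value and context."""

    statistic: str
    effect: float
    p: float
    n: Mapping[str, int] = field(default_factory=dict)
    method: str = ""
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.isfinite(self.p) and not (0.0 <= self.p <= 1.0):
            raise ParainflamError(f"p value out of [0,1]: {self.p}")


def normalize_symbol(symbol: str) -> str:
    """Case-fold a gene symbol for voting/intersection comparisons."""
    return symbol.strip().upper()


__all__ = [
    "CD45",
    "ANNOTATION_COLUMNS",
    "ParainflamError",
    "ExpressionMatrix",
    "CountMatrix",
    "GeneList",
    "PISignature",
    "Threshold",
    "PIScoreTable",
    "AssociationResult",
    "normalize_symbol",
    "replace",
]
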