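"""Removing immune-infiltration signal from tumor expression.

Bulk tumor profiles mix tumor cells with infiltrating leukocytes, which
inflates inflammatory gene expression. The correction learns, from
reference normal tissue, how each gene's log2 expression depends linearly
on the pan-hematopoietic marker CD45 (PTPRC) within each tissue, then
subtracts ``slope × CD45`` from every cohort sample of the matching
tissue and shifts each gene so its cohort minimum is zero. Only the slope
is applied; intercepts are stored for diagnostics.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .datatypes import CD45, ExpressionMatrix, ParainflamError

#: Minimum training samples per tissue before slopes are trusted.
MIN_TRAIN_SAMPLES = 20


@dataclass
class InfiltrationModel:
    """Per-(tissue, gene) linear dependence of expression on CD45."""

    reference_gene: str
    slopes: pd.DataFrame       # tissue × gene, log2 per log2
    intercepts: pd.DataFrame   # stored for diagnostics, never applied
    n_train: dict = field(default_factory=dict)

    def tissues(self) -> list[str]:
        return list(self.slopes.index)

    def to_json(self, path) -> None:
        payload = {
            "reference_gene": self.reference_gene,
            "slopes": self.slopes.to_dict(orient="index"),
            "intercepts": self.intercepts.to_dict(orient="index"),
            "n_train": self.n_train,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path) -> "InfiltrationModel":
        d = json.loads(Path(path).read_text())
        return cls(
            reference_gene=d["reference_gene"],
            slopes=pd.DataFrame.from_dict(d["slopes"], orient="index"),
            intercepts=pd.DataFrame.from_dict(d["intercepts"], orient="index"),
            n_train=d.get("n_train", {}),
        )


@dataclass
class AdjustedExpression:
    """Infiltration-adjusted matrix plus the per-gene shift applied."""

    matrix: ExpressionMatrix
    shifts: pd.Series
    reference_gene: str = CD45


def fit_infiltration_slopes(
    normals: ExpressionMatrix,
    reference_gene: str = CD45,
    min_train: int = MIN_TRAIN_SAMPLES,
) -> InfiltrationModel:
    """Per-gene, per-tissue OLS of expression against the reference gene.

    Tissues with fewer than ``min_train`` samples are skipped with a
    warning. Genes with zero variance get slope 0.
    """
    if normals.annotations is None or "tissue" not in normals.annotations:
        raise ParainflamError("reference normals must carry tissue annotations")
    if reference_gene not in normals.genes:
        raise ParainflamError(f"reference gene {reference_gene!r} absent")

    slope_rows, icept_rows, n_train = {}, {}, {}
    for tissue, ann in normals.annotations.groupby("tissue"):
        cols = list(ann.index)
        if len(cols) < min_train:
            warnings.warn(
                f"tissue {tissue!r} has {len(cols)} < {min_train} training "
                "samples; skipped"
            )
            continue
        x = normals.values[cols]
        c = x.loc[reference_gene].to_numpy(float)
        c_center = c - c.mean()
        denom = (c_center**2).sum()
        if denom == 0:
            slopes = pd.Series(0.0, index=x.index)
        else:
            centered = x.sub(x.mean(axis=1), axis=0)
            slopes = (centered.to_numpy() @ c_center) / denom
            slopes = pd.Series(slopes, index=x.index)
        gene_var = x.var(axis=1, ddof=0)
        slopes[gene_var == 0] = 0.0
        icepts = x.mean(axis=1) - slopes * c.mean()
        slope_rows[tissue] = slopes
        icept_rows[tissue] = icepts
        n_train[tissue] = len(cols)
    if not slope_rows:
        raise ParainflamError("no tissue had enough training samples")
    return InfiltrationModel(
        reference_gene=reference_gene,
        slopes=pd.DataFrame(slope_rows).T,
        intercepts=pd.DataFrame(icept_rows).T,
        n_train=n_train,
    )


def adjust_expression(
    cohort: ExpressionMatrix,
    model: InfiltrationModel,
    on_missing: str = "error",
) -> AdjustedExpression:
    """Subtract tissue slopes × CD45, then shift each gene's minimum to 0.

    The reference gene itself is not slope-adjusted (its slope with itself
    is identically 1 and removing it would erase the infiltration readout)
    but participates in the min-shift. ``on_missing`` controls tissues
    absent from the model: ``"error"`` raises, ``"passthrough"`` leaves
    those samples slope-unadjusted.
    """
    if model.reference_gene not in cohort.genes:
        raise ParainflamError(
            f"reference gene {model.reference_gene!r} absent from cohort; "
            "refusing to adjust with a proxy"
        )
    if cohort.annotations is None or "tissue" not in cohort.annotations:
        raise ParainflamError("cohort must carry tissue annotations")
    if on_missing not in ("error", "passthrough"):
        raise ParainflamError("on_missing must be 'error' or 'passthrough'")

    adjusted = cohort.values.copy()
    c = cohort.values.loc[model.reference_gene]
    common_genes = cohort.genes.intersection(model.slopes.columns)
    apply_genes = common_genes.drop(model.reference_gene, errors="ignore")
    for tissue, ann in cohort.annotations.groupby("tissue"):
        cols = list(ann.index)
        if tissue not in model.slopes.index:
            if on_missing == "error":
                raise ParainflamError(
                    f"tissue {tissue!r} absent from infiltration model"
                )
            warnings.warn(f"tissue {tissue!r} not in model; passed through")
            continue
        beta = model.slopes.loc[tissue, apply_genes].to_numpy()
        adjusted.loc[apply_genes, cols] -= np.outer(
            beta, c[cols].to_numpy(float)
        )
    shifts = adjusted.min(axis=1)
    adjusted = adjusted.sub(shifts, axis=0)
    out = ExpressionMatrix(adjusted, cohort.annotations)
    return AdjustedExpression(out, shifts, model.reference_gene)


__all__ = [
    "MIN_TRAIN_SAMPLES",
    "InfiltrationModel",
    "AdjustedExpression",
    "fit_infiltration_slopes",
    "adjust_expression",
]
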