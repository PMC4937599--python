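"""Per-sample PI scores: single-sample GSEA, calibration and calls.

The PI score of a sample is a single-sample gene-set enrichment statistic
(ssGSEA): genes are ranked by decreasing expression and the score
integrates, over the ranked list, the difference between the
rank-weighted in-set empirical CDF and the uniform out-of-set ECDF. The
statistic is purely rank-based, so any per-sample monotone transform of
expression leaves it unchanged.

Classification calibrates a threshold on adjacent-normal samples — the
(1 − f) empirical quantile of their scores, f = 5% by default — and calls
a sample PI+ when its score is strictly above it. Scores live on a
platform/universe-specific scale, so a threshold carries the size of the
gene universe it was calibrated on and refuses to classify scores
computed over a different universe.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Optional, Union

import numpy as np
import pandas as pd

from .datatypes import (
    ExpressionMatrix,
    GeneList,
    ParainflamError,
    PIScoreTable,
    Threshold,
)

#: Default weight exponent on ranks (the de-facto ssGSEA default).
DEFAULT_ALPHA = 0.25

#: Default fraction of calibration normals allowed above the threshold.
DEFAULT_CALIBRATION_FRACTION = 0.05

#: Minimum fraction of signature genes that must exist in the matrix.
MIN_SIGNATURE_PRESENT = 0.5


def _as_genes(signature: Union[GeneList, Iterable[str]]) -> list[str]:
    return list(signature.genes) if isinstance(signature, GeneList) else list(signature)


def ssgsea_score(
    sample_expr: pd.Series,
    signature: Union[GeneList, Iterable[str]],
    alpha: float = DEFAULT_ALPHA,
) -> float:
    """Enrichment score of one sample for one gene set.

    Genes are ordered by decreasing expression (ties broken by gene
    symbol); walking down the list, the in-set ECDF weighted by
    rank^alpha (rank N at the top) accumulates against the uniform
    out-of-set ECDF, and the score is the sum of the difference over all
    positions.
    """
    genes = _as_genes(signature)
    in_set = sample_expr.index.isin(genes)
    n = len(sample_expr)
    n_in = int(in_set.sum())
    if n_in == 0:
        raise ParainflamError("no signature gene present in the sample")
    if n_in >= n:
        raise ParainflamError("signature must be smaller than the gene universe")
    values = sample_expr.to_numpy(float)
    if np.all(values == values[0]):
        raise ParainflamError("all-constant sample has no ranking")

    # lexical gene order first, then stable sort by decreasing expression
    lex = np.argsort(sample_expr.index.to_numpy())
    order = lex[np.argsort(-values[lex], kind="stable")]
    member = in_set[order]
    ranks = np.arange(n, 0, -1, dtype=float)  # N at the top position
    w = ranks**alpha
    w_in = np.where(member, w, 0.0)
    p_in = np.cumsum(w_in) / w_in.sum()
    p_out = np.cumsum(~member) / (n - n_in)
    return float(np.sum(p_in - p_out))


def _score_matrix(
    values: pd.DataFrame, sig_genes: list[str], alpha: float
) -> pd.Series:
    """Vectorized ssGSEA over all columns; matches :func:`ssgsea_score`."""
    values = values.sort_index()  # lexical order makes the tie-break stable
    x = values.to_numpy(float)
    n, m = x.shape
    in_set = values.index.isin(sig_genes)
    n_in = int(in_set.sum())
    const = np.ptp(x, axis=0) == 0
    if const.any():
        bad = list(values.columns[const])[:5]
        raise ParainflamError(f"all-constant samples cannot be ranked: {bad}")
    order = np.argsort(-x, kind="stable", axis=0)
    member = in_set[order]  # n × m membership in ranked order
    ranks = np.arange(n, 0, -1, dtype=float)[:, None]
    w_in = np.where(member, ranks**alpha, 0.0)
    p_in = np.cumsum(w_in, axis=0) / w_in.sum(axis=0)
    p_out = np.cumsum(~member, axis=0) / (n - n_in)
    return pd.Series((p_in - p_out).sum(axis=0), index=values.columns)


def score_cohort(
    expr: ExpressionMatrix,
    signature: Union[GeneList, Iterable[str]],
    normalize: str = "range",
    alpha: float = DEFAULT_ALPHA,
    min_present: float = MIN_SIGNATURE_PRESENT,
    signature_name: str = "PI",
) -> PIScoreTable:
    """Raw PI scores for every sample of a cohort.

    Signature genes absent from the matrix are dropped (reported via
    warning); below ``min_present`` coverage the call refuses. With
    ``normalize="range"`` raw scores are divided by (max − min) over the
    cohort, giving the sub-unit scale on which thresholds are quoted;
    ``normalize="none"`` keeps raw enrichment sums.
    """
    genes = _as_genes(signature)
    if not genes:
        raise ParainflamError("empty signature")
    present = [g for g in genes if g in expr.genes]
    if len(present) < max(1, int(np.ceil(min_present * len(genes)))):
        raise ParainflamError(
            f"only {len(present)}/{len(genes)} signature genes present "
            f"(floor {min_present:.0%})"
        )
    if len(present) < len(genes):
        missing = sorted(set(genes) - set(present))
        warnings.warn(
            f"{len(missing)} signature genes absent from matrix: "
            f"{missing[:5]}..."
        )
    raw = _score_matrix(expr.values, present, alpha)
    if normalize == "range":
        span = raw.max() - raw.min()
        if span > 0:
            raw = raw / span
    elif normalize != "none":
        raise ParainflamError("normalize must be 'range' or 'none'")
    table = pd.DataFrame(
        {"raw_score": raw, "shifted_score": np.nan, "call": pd.NA},
        index=raw.index,
    )
    return PIScoreTable(
        table=table,
        n_signature_genes_used=len(present),
        universe_size=len(expr.genes),
        signature_name=signature_name,
    )


def down_score(
    expr: ExpressionMatrix,
    down_signature: Union[GeneList, Iterable[str]],
    **kwargs,
) -> PIScoreTable:
    """Score the downregulated gene set with the same mechanics."""
    kwargs.setdefault("signature_name", "PI_down")
    return score_cohort(expr, down_signature, **kwargs)


def calibrate_threshold(
    normal_scores: Union[PIScoreTable, pd.Series, np.ndarray],
    calibration_fraction: float = DEFAULT_CALIBRATION_FRACTION,
) -> Threshold:
    """PI+ cut-point: the (1 − f) linear-interpolation quantile of normals.

    Guarantees that the fraction of calibration scores strictly above the
    threshold is at most ``calibration_fraction``.
    """
    if not 0.0 <= calibration_fraction <= 1.0:
        raise ParainflamError("calibration fraction must lie in [0,1]")
    universe = n_used = None
    if isinstance(normal_scores, PIScoreTable):
        universe = normal_scores.universe_size
        n_used = normal_scores.n_signature_genes_used
        values = normal_scores.raw.to_numpy(float)
    else:
        values = np.asarray(normal_scores, float)
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise ParainflamError("no calibration scores provided")
    if values.size < 20:
        warnings.warn(
            f"only {values.size} calibration scores; threshold is unstable"
        )
    value = float(np.quantile(values, 1.0 - calibration_fraction,
                              method="linear"))
    # the interpolated quantile can leave marginally more than the allowed
    # fraction strictly above for some n; enforce the guarantee by moving
    # to the smallest order statistic that satisfies it
    k_max = int(np.floor(calibration_fraction * values.size))
    if (values > value).sum() > k_max:
        value = float(np.sort(values)[::-1][k_max])
    return Threshold(
        value=value,
        calibration_fraction=calibration_fraction,
        universe_size=universe,
        n_genes_used=n_used,
    )


def classify_samples(
    scores: PIScoreTable, threshold: Union[Threshold, float]
) -> PIScoreTable:
    """Call PI+ when the raw score is strictly over the threshold.

    A :class:`Threshold` carrying a universe size different from the one
    the scores were computed on is rejected — enrichment scores are not
    comparable across platforms/universes.
    """
    if isinstance(threshold, Threshold):
        if (
            threshold.universe_size is not None
            and threshold.universe_size != scores.universe_size
        ):
            raise ParainflamError(
                f"threshold calibrated on a {threshold.universe_size}-gene "
                f"universe cannot classify scores over "
                f"{scores.universe_size} genes"
            )
        t, frac = threshold.value, threshold.calibration_fraction
    else:
        t, frac = float(threshold), None
    if not np.isfinite(t):
        raise ParainflamError("threshold must be finite")
    table = scores.table.copy()
    table["shifted_score"] = table["raw_score"] - t
    table["call"] = np.where(table["raw_score"] > t, "PI+", "PI-")
    return PIScoreTable(
        table=table,
        n_signature_genes_used=scores.n_signature_genes_used,
        universe_size=scores.universe_size,
        signature_name=scores.signature_name,
        threshold=t,
        calibration_fraction=frac,
    )


__all__ = [
    "DEFAULT_ALPHA",
    "DEFAULT_CALIBRATION_FRACTION",
    "MIN_SIGNATURE_PRESENT",
    "ssgsea_score",
    "score_cohort",
    "down_score",
    "calibrate_threshold",
    "classify_samples",
]
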