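"""Deriving the parainflammation signature from counts and curated lists.

The signature is the intersection of genes upregulated (fold > 2,
BH-adjusted p < 0.01) in each of two knockout models versus wild type,
restricted to an inflammatory gene universe assembled by majority vote
over curated databases. The differential-expression engine follows the
standard bulk RNA-seq recipe: median-of-ratios size factors, per-gene
negative-binomial dispersions moderated toward a fitted mean–dispersion
trend, and a Wald test on the log2 fold change with Benjamini–Hochberg
correction.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import (
    CountMatrix,
    ExpressionMatrix,
    GeneList,
    ParainflamError,
    PIScoreTable,
    PISignature,
    normalize_symbol,
)

#: Pseudo-count added to normalized group means before the fold ratio.
FOLD_PSEUDOCOUNT = 0.5

#: Prior degrees of freedom pulling per-gene dispersions toward the trend.
DISPERSION_PRIOR_DF = 4.0


# -------------------------------------------------------- inflammatory union

def assemble_inflammatory_genes(
    lists: Sequence[GeneList], min_votes: int = 2, name: str = "inflammatory"
) -> GeneList:
    """Union of curated lists restricted to symbols in ≥ ``min_votes`` lists.

    Voting is case-insensitive; the output keeps the casing of the first
    list that contributed each symbol, sorted by normalized symbol.
    """
    if len(lists) < min_votes:
        raise ParainflamError(
            f"need at least {min_votes} lists, got {len(lists)}"
        )
    votes: dict[str, int] = {}
    first_seen: dict[str, str] = {}
    for gl in lists:
        for sym in gl.upper_set():
            votes[sym] = votes.get(sym, 0) + 1
        for g in gl.genes:
            first_seen.setdefault(normalize_symbol(g), g)
    kept = sorted(s for s, v in votes.items() if v >= min_votes)
    return GeneList(
        name,
        [first_seen[s] for s in kept],
        source=f"vote>={min_votes} over {[gl.name for gl in lists]}",
    )


# ------------------------------------------------------------------ DE stage

def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalization over genes expressed in every sample."""
    log_counts = np.log(counts.where(counts > 0))
    log_geo = log_counts.mean(axis=1)
    usable = np.isfinite(log_geo) & counts.gt(0).all(axis=1)
    if not usable.any():
        raise ParainflamError("no gene is expressed in every sample")
    log_ratios = log_counts.loc[usable].sub(log_geo[usable], axis=0)
    return np.exp(log_ratios.median(axis=0)).rename("size_factor")


def _fit_dispersion_trend(mean: np.ndarray, disp: np.ndarray) -> np.ndarray:
    """Fit α(μ) = a₀ + a₁/μ by least squares on genes with positive MoM α."""
    ok = (disp > 0) & (mean > 0)
    if ok.sum() < 10:
        # too few informative genes: flat trend at the median (or a floor)
        level = float(np.median(disp[ok])) if ok.any() else 0.01
        return np.full_like(mean, max(level, 1e-6))
    X = np.column_stack([np.ones(ok.sum()), 1.0 / mean[ok]])
    coef, *_ = np.linalg.lstsq(X, disp[ok], rcond=None)
    a0, a1 = max(coef[0], 1e-6), max(coef[1], 0.0)
    return a0 + a1 / np.maximum(mean, 1e-8)


def differential_expression(
    counts: CountMatrix, condition: str, reference: str
) -> pd.DataFrame:
    """Two-group NB Wald test of ``condition`` against ``reference``.

    Returns a per-gene table with ``base_mean`` (mean normalized count over
    both groups), ``log2_fold`` (condition vs reference, pseudo-counted),
    ``p`` and BH-adjusted ``adj_p``. Genes with zero counts everywhere are
    excluded from testing.
    """
    for label in (condition, reference):
        if label not in set(counts.conditions):
            raise ParainflamError(f"unknown condition {label!r}")
        if len(counts.samples_in(label)) < 2:
            raise ParainflamError(
                f"condition {label!r} needs ≥2 replicates for a dispersion "
                "estimate"
            )
    cols = list(counts.samples_in(condition)) + list(counts.samples_in(reference))
    sub = counts.counts[cols]
    sub = sub.loc[sub.sum(axis=1) > 0]
    sf = size_factors(sub)
    norm = sub / sf

    a = norm[list(counts.samples_in(condition))].to_numpy(float)
    b = norm[list(counts.samples_in(reference))].to_numpy(float)
    sf_a = sf[list(counts.samples_in(condition))].to_numpy()
    sf_b = sf[list(counts.samples_in(reference))].to_numpy()
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    base_mean = norm.to_numpy().mean(axis=1)

    # method-of-moments NB dispersion from pooled within-group variability
    var_a, var_b = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    n_a, n_b = a.shape[1], b.shape[1]
    pooled_var = ((n_a - 1) * var_a + (n_b - 1) * var_b) / (n_a + n_b - 2)
    pooled_mean = (n_a * mean_a + n_b * mean_b) / (n_a + n_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp_mom = (pooled_var - pooled_mean) / pooled_mean**2
    disp_mom = np.where(np.isfinite(disp_mom), disp_mom, 0.0)
    trend = _fit_dispersion_trend(pooled_mean, disp_mom)
    resid_df = n_a + n_b - 2
    w = resid_df / (resid_df + DISPERSION_PRIOR_DF)
    log_mom = np.log(np.clip(disp_mom, 1e-8, None))
    disp = np.exp(w * log_mom + (1 - w) * np.log(np.clip(trend, 1e-8, None)))
    disp = np.clip(disp, 1e-8, 10.0)

    mu_a = mean_a + FOLD_PSEUDOCOUNT
    mu_b = mean_b + FOLD_PSEUDOCOUNT
    log2_fold = np.log2(mu_a / mu_b)

    # delta-method variance of log2 of a group's normalized-count mean:
    # Var(K_i/sf_i) = μ/sf_i + α μ² for a sample with size factor sf_i
    def _var_log2_mean(mu: np.ndarray, sfs: np.ndarray) -> np.ndarray:
        var_sum = mu * (1.0 / sfs).sum() + len(sfs) * disp * mu**2
        var_mean = var_sum / len(sfs) ** 2
        return var_mean / (mu**2 * np.log(2.0) ** 2)

    se = np.sqrt(_var_log2_mean(mu_a, sf_a) + _var_log2_mean(mu_b, sf_b))
    wald = log2_fold / np.maximum(se, 1e-12)
    p = 2.0 * stats.norm.sf(np.abs(wald))
    adj_p = multipletests(p, method="fdr_bh")[1]

    return pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2_fold": log2_fold,
            "p": p,
            "adj_p": adj_p,
        },
        index=sub.index,
    )


def select_up(
    de: pd.DataFrame, min_fold: float = 2.0, max_adj_p: float = 0.01,
    name: str = "up",
) -> GeneList:
    """Genes with fold ratio strictly > ``min_fold`` and adj_p < ``max_adj_p``."""
    if min_fold <= 0 or max_adj_p <= 0:
        raise ParainflamError("thresholds must be positive")
    keep = (2.0 ** de["log2_fold"] > min_fold) & (de["adj_p"] < max_adj_p)
    return GeneList(name, sorted(de.index[keep]), source="differential_expression")


def select_down(
    de: pd.DataFrame, min_fold: float = 2.0, max_adj_p: float = 0.01,
    name: str = "down",
) -> GeneList:
    """Genes more than ``min_fold``-fold lower with adj_p < ``max_adj_p``."""
    if min_fold <= 0 or max_adj_p <= 0:
        raise ParainflamError("thresholds must be positive")
    keep = (2.0 ** de["log2_fold"] < 1.0 / min_fold) & (de["adj_p"] < max_adj_p)
    return GeneList(name, sorted(de.index[keep]), source="differential_expression")


# ------------------------------------------------------------- intersection

def _intersect(lists: Sequence[GeneList], name: str) -> list[str]:
    common = None
    casing: dict[str, str] = {}
    for gl in lists:
        s = gl.upper_set()
        common = s if common is None else (common & s)
        for g in gl.genes:
            casing.setdefault(normalize_symbol(g), g)
    return [casing[s] for s in sorted(common or set())]


def derive_signature(
    up_model1: GeneList, up_model2: GeneList, inflammatory: GeneList,
    name: str = "PI_up",
) -> GeneList:
    """(up in model 1) ∩ (up in model 2) ∩ inflammatory universe, sorted."""
    if len(inflammatory) == 0:
        raise ParainflamError("inflammatory universe is empty")
    genes = _intersect([up_model1, up_model2, inflammatory], name)
    return GeneList(name, genes, source="derive_signature")


def derive_down(
    down_model1: GeneList, down_model2: GeneList, inflammatory: GeneList,
    name: str = "PI_down",
) -> GeneList:
    """Downregulated analogue of :func:`derive_signature`."""
    if len(inflammatory) == 0:
        raise ParainflamError("inflammatory universe is empty")
    genes = _intersect([down_model1, down_model2, inflammatory], name)
    return GeneList(name, genes, source="derive_down")


# ----------------------------------------------------------------- orthologs

def map_orthologs(
    genes: GeneList, mapping: Mapping[str, str], target_species: str = "human"
) -> GeneList:
    """Translate symbols through an ortholog table; misses are recorded.

    Lookup is case-insensitive on the source symbol. Unmapped genes are
    dropped and listed in the returned list's ``source`` provenance.
    """
    table = {normalize_symbol(k): v for k, v in mapping.items()}
    mapped, missed = [], []
    for g in genes:
        tgt = table.get(normalize_symbol(g))
        (mapped if tgt is not None else missed).append(tgt if tgt else g)
    source = f"orthologs->{target_species}"
    if missed:
        source += f"; unmapped: {','.join(missed)}"
    return GeneList(genes.name, mapped, source=source)


def map_signature_orthologs(
    sig: PISignature, mapping: Mapping[str, str], target_species: str = "human"
) -> PISignature:
    return PISignature(
        up=map_orthologs(sig.up, mapping, target_species),
        down=map_orthologs(sig.down, mapping, target_species) if sig.down else None,
        expanded=sig.expanded,
        species=target_species,
    )


# ----------------------------------------------------------------- expansion

def expand_signature(
    expr: ExpressionMatrix,
    scores: "PIScoreTable",
    min_corr: float = 0.5,
    method: str = "spearman",
    name: str = "PI_expanded",
) -> GeneList:
    """Genes whose expression correlates with the PI score above ``min_corr``.

    Constant genes (undefined correlation) are treated as correlation 0 and
    excluded. The admitting correlation is stored per gene.
    """
    raw = scores.raw.reindex(expr.samples)
    if raw.isna().any():
        raise ParainflamError("scores do not cover the matrix's samples")
    if expr.n_samples < 3:
        raise ParainflamError("need at least 3 samples for correlation")
    if method == "spearman":
        target = raw.rank()
        gene_data = expr.values.rank(axis=1)
    elif method == "pearson":
        target = raw
        gene_data = expr.values
    else:
        raise ParainflamError(f"unknown correlation method {method!r}")
    centered = gene_data.sub(gene_data.mean(axis=1), axis=0)
    tc = target - target.mean()
    denom = np.sqrt((centered**2).sum(axis=1) * (tc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = (centered @ tc) / denom
    corr = corr.fillna(0.0)
    keep = corr[corr > min_corr].sort_values(ascending=False)
    return GeneList(
        name, list(keep.index), source=f"{method} corr > {min_corr}",
        annotations=keep,
    )


__all__ = [
    "assemble_inflammatory_genes",
    "size_factors",
    "differential_expression",
    "select_up",
    "select_down",
    "derive_signature",
    "derive_down",
    "map_orthologs",
    "map_signature_orthologs",
    "expand_signature",
    "FOLD_PSEUDOCOUNT",
]
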