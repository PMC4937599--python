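"""Downstream associations of the PI score.

Correlations with other gene-set programs (scored with the same ssGSEA
engine), the two-gene cytolytic-activity metric, p53-mutation enrichment,
survival models (Cox proportional hazards, Kaplan–Meier with log-rank)
and the NSAID-response rank test. Every operation returns an
:class:`~parainflam.datatypes.AssociationResult` (or a table of them)
carrying effect size, p value and group sizes. A ``by=`` grouping layer
stratifies any of them per cancer type.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

from .datatypes import (
    AssociationResult,
    ExpressionMatrix,
    GeneList,
    ParainflamError,
    PIScoreTable,
)
from .pi_scoring import score_cohort


def _raw(scores: Union[PIScoreTable, pd.Series]) -> pd.Series:
    return scores.raw if isinstance(scores, PIScoreTable) else scores


# ------------------------------------------------------- gene-set correlation

def correlate_with_genesets(
    pi_scores: Union[PIScoreTable, pd.Series],
    expr: ExpressionMatrix,
    genesets: Mapping[str, Union[GeneList, Sequence[str]]],
    by: Optional[pd.Series] = None,
    **score_kwargs,
) -> pd.DataFrame:
    """Spearman rho between the PI score and each gene set's ssGSEA score.

    ``by`` (sample → group, e.g. cancer type) adds one column per group
    next to the pooled column. Gene sets fully absent from the matrix
    yield NaN with a warning.
    """
    pi = _raw(pi_scores).reindex(expr.samples)
    if expr.n_samples < 3:
        raise ParainflamError("need at least 3 samples")
    groups = {"pooled": list(expr.samples)}
    if by is not None:
        for g, idx in by.groupby(by).groups.items():
            groups[str(g)] = list(idx)
    out = pd.DataFrame(index=list(genesets), columns=list(groups), dtype=float)
    for name, gs in genesets.items():
        genes = list(gs.genes) if isinstance(gs, GeneList) else list(gs)
        present = [g for g in genes if g in expr.genes]
        if not present:
            warnings.warn(f"gene set {name!r} fully absent; rho set to NaN")
            continue
        gs_scores = score_cohort(
            expr, present, min_present=0.0, signature_name=name, **score_kwargs
        ).raw
        for gname, samples in groups.items():
            if len(samples) < 3:
                continue
            rho, _ = stats.spearmanr(pi[samples], gs_scores[samples])
            out.loc[name, gname] = rho
    return out


def cytolytic_activity(
    expr: ExpressionMatrix,
    genes: tuple = ("GZMA", "PRF1"),
    log_input: bool = True,
    pseudocount: float = 0.0,
) -> pd.Series:
    """Immune cytolytic activity: geometric mean of GZMA and PRF1.

    Input is log2 by convention; values are exponentiated to the linear
    scale before the geometric mean. A pseudo-count guards genes measured
    at zero.
    """
    for g in genes:
        if g not in expr.genes:
            raise ParainflamError(f"cytolytic marker {g!r} absent")
    sub = expr.values.loc[list(genes)]
    linear = np.power(2.0, sub) if log_input else sub
    linear = linear + pseudocount
    return pd.Series(
        stats.gmean(linear.to_numpy(float), axis=0),
        index=expr.samples,
        name="cytolytic_activity",
    )


# ------------------------------------------------------------ p53 association

def p53_association(
    scores: Union[PIScoreTable, pd.Series],
    p53_status: pd.Series,
    calls: Optional[pd.Series] = None,
    by: Optional[pd.Series] = None,
) -> dict:
    """PI vs TP53 mutation status.

    Returns a dict with (i) a two-sided rank-sum of scores mutant vs
    wild type, (ii) if calls are available, PI+ proportions per status
    with a chi-square test, and (iii) if ``by`` groups are given, the
    Spearman correlation across groups between the p53-mutation rate and
    the PI+ rate.
    """
    raw = _raw(scores)
    if calls is None and isinstance(scores, PIScoreTable) and scores.classified():
        calls = scores.calls
    status = p53_status.dropna()
    common = raw.index.intersection(status.index)
    status = status[common]
    mut = raw[common][status == "mut"]
    wt = raw[common][status == "WT"]
    if len(mut) == 0 or len(wt) == 0:
        raise ParainflamError("both p53 statuses must be represented")
    u = stats.mannwhitneyu(mut, wt, alternative="two-sided")
    results = {
        "score_ranksum": AssociationResult(
            statistic="PI score, p53 mut vs WT",
            effect=float(mut.median() - wt.median()),
            p=float(u.pvalue),
            n={"mut": len(mut), "WT": len(wt)},
            method="two-sided Mann-Whitney U",
        )
    }
    if calls is not None:
        c = calls[common].dropna()
        tab = pd.crosstab(status[c.index], c == "PI+")
        prop = {
            s: float((c[status == s] == "PI+").mean()) for s in ("mut", "WT")
        }
        if tab.shape == (2, 2) and (tab.to_numpy() > 0).all(axis=0).any():
            chi_p = float(stats.chi2_contingency(tab, correction=False)[1])
        else:
            chi_p = np.nan
        results["pi_rate_chi2"] = AssociationResult(
            statistic="PI+ rate by p53 status",
            effect=prop["mut"] - prop["WT"],
            p=chi_p,
            n={"mut": len(mut), "WT": len(wt)},
            method="chi-square on 2x2",
            extras={"prop_mut": prop["mut"], "prop_WT": prop["WT"]},
        )
    if by is not None and calls is not None:
        rates = []
        for g, idx in by.groupby(by).groups.items():
            idx = pd.Index(idx).intersection(common)
            s, c = status[idx], calls[idx]
            if len(s) < 5:
                continue
            rates.append(((s == "mut").mean(), (c == "PI+").mean()))
        if len(rates) >= 3:
            mut_rate, pi_rate = zip(*rates)
            rho, p = stats.spearmanr(mut_rate, pi_rate)
            results["per_type_rate_corr"] = AssociationResult(
                statistic="p53 mutation rate vs PI+ rate across types",
                effect=float(rho),
                p=float(p),
                n={"types": len(rates)},
                method="Spearman",
            )
    return results


# ------------------------------------------------------------------ survival

def _check_records(records: pd.DataFrame) -> None:
    if (records["time"] <= 0).any():
        raise ParainflamError("survival times must be positive")
    if not records["event"].isin((0, 1)).all():
        raise ParainflamError("event must be 0 (censored) or 1 (death)")


def cox_survival(
    records: pd.DataFrame,
    covariate: str = "score",
    controls: Iterable[str] = (),
    strata: Optional[str] = None,
) -> AssociationResult:
    """Cox proportional-hazards regression of survival on a score.

    ``records`` needs ``time`` and ``event`` columns plus the covariate
    (and optional control) columns. Efron handling of tied event times.
    Returns the log hazard ratio per unit covariate with its Wald p.
    """
    records = records.dropna(subset=["time", "event", covariate])
    _check_records(records)
    if records["event"].sum() < 10:
        raise ParainflamError("need at least 10 events for a stable fit")
    cols = ["time", "event", covariate, *controls]
    if strata:
        cols.append(strata)
    if records[covariate].nunique() == 1:
        return AssociationResult(
            statistic=f"Cox log-HR per unit {covariate}",
            effect=0.0,
            p=1.0,
            n={"samples": len(records), "events": int(records["event"].sum())},
            method="Cox PH (degenerate: constant covariate)",
        )
    cph = CoxPHFitter()
    cph.fit(
        records[cols],
        duration_col="time",
        event_col="event",
        strata=strata,
    )
    coef = float(cph.params_[covariate])
    p = float(cph.summary.loc[covariate, "p"])
    flagged = bool(abs(coef) > 20)  # likely separation
    return AssociationResult(
        statistic=f"Cox log-HR per unit {covariate}",
        effect=coef,
        p=p,
        n={"samples": len(records), "events": int(records["event"].sum())},
        method="Cox PH, Efron ties" + (", stratified" if strata else ""),
        extras={"hazard_ratio": float(np.exp(coef)), "separation_flag": flagged,
                "controls": list(controls)},
    )


def km_logrank(
    records: pd.DataFrame, group: str = "call"
) -> AssociationResult:
    """Kaplan–Meier curves per group with a two-sided log-rank test.

    Returns the log-rank result; ``extras`` carries per-group KM curve
    tables, median survival times, and the median-survival ratio
    (reference/alternative) when both medians are reached.
    """
    records = records.dropna(subset=["time", "event", group])
    _check_records(records)
    levels = sorted(records[group].unique())
    if len(levels) != 2:
        raise ParainflamError(f"need exactly two groups, got {levels}")
    if set(levels) == {"PI+", "PI-"}:
        levels = ["PI-", "PI+"]  # ratio reported as PI− median / PI+ median
    g0 = records[records[group] == levels[0]]
    g1 = records[records[group] == levels[1]]
    lr = logrank_test(
        g0["time"], g1["time"], event_observed_A=g0["event"],
        event_observed_B=g1["event"],
    )
    curves, medians = {}, {}
    for lvl, sub in ((levels[0], g0), (levels[1], g1)):
        km = KaplanMeierFitter()
        km.fit(sub["time"], sub["event"], label=str(lvl))
        curves[lvl] = km.survival_function_.reset_index().rename(
            columns={"timeline": "time", str(lvl): "survival"}
        )
        med = km.median_survival_time_
        medians[lvl] = float(med) if np.isfinite(med) else None
    if medians[levels[0]] and medians[levels[1]]:
        ratio = medians[levels[0]] / medians[levels[1]]
    else:
        ratio = None  # a group never reached 50% mortality
    return AssociationResult(
        statistic=f"log-rank {levels[0]} vs {levels[1]}",
        effect=np.nan if ratio is None else float(ratio),
        p=float(lr.p_value),
        n={str(levels[0]): len(g0), str(levels[1]): len(g1)},
        method="two-sided log-rank; effect = median-survival ratio",
        extras={"curves": curves, "medians": medians},
    )


def plot_km_curves(result: AssociationResult, path) -> None:
    """Write the Kaplan–Meier curves from :func:`km_logrank` to a file."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for label, curve in result.extras["curves"].items():
        ax.step(curve["time"], curve["survival"], where="post", label=label)
    ax.set_xlabel("time (days)")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend()
    ax.set_title(f"{result.statistic} (log-rank p = {result.p:.2g})")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


# ------------------------------------------------------------- NSAID response

def nsaid_response_test(
    logfc: pd.Series, signature: Union[GeneList, Sequence[str]]
) -> AssociationResult:
    """Are signature genes preferentially downregulated under treatment?

    Two-sided rank-sum of the signature genes' treated-vs-control log2
    fold changes against all remaining genes; also reports the fraction
    of signature genes with negative fold change.
    """
    genes = list(signature.genes) if isinstance(signature, GeneList) else list(signature)
    logfc = logfc.dropna()
    in_sig = logfc.index.isin(genes)
    covered = int(in_sig.sum())
    if covered < max(1, int(np.ceil(0.5 * len(genes)))):
        raise ParainflamError(
            f"fold changes cover only {covered}/{len(genes)} signature genes"
        )
    sig_fc = logfc[in_sig]
    bg_fc = logfc[~in_sig]
    if bg_fc.empty:
        raise ParainflamError("no background genes")
    if logfc.nunique() == 1:
        p = 1.0  # all genes tied: no evidence either way
    else:
        p = float(
            stats.mannwhitneyu(sig_fc, bg_fc, alternative="two-sided").pvalue
        )
    return AssociationResult(
        statistic="signature logFC vs background",
        effect=float(sig_fc.median() - bg_fc.median()),
        p=p,
        n={"signature": len(sig_fc), "background": len(bg_fc)},
        method="two-sided Mann-Whitney U",
        extras={"fraction_signature_down": float((sig_fc < 0).mean())},
    )


__all__ = [
    "correlate_with_genesets",
    "cytolytic_activity",
    "p53_association",
    "cox_survival",
    "km_logrank",
    "plot_km_curves",
    "nsaid_response_test",
]
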