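"""Synthetic cohorts with the statistical structure the pipeline assumes.

Four generators mirror the four kinds of real input the analysis consumes:

* reference normals whose per-gene expression depends linearly on the CD45
  (PTPRC) immune-infiltration marker, with gene- and tissue-specific slopes
  — the training data for the infiltration model;
* a tumor cohort (tumors + adjacent normals) sharing that infiltration
  structure, in which a parainflammation (PI) program is switched on in a
  subset of tumors over a random subset of the signature genes, with p53
  status and exponential survival linked to the program;
* a cell-line panel where signature genes are bimodal across lines
  (a high-expressing subpopulation) while background genes are unimodal;
* an RNA-seq count experiment (wild type vs knockout conditions, few
  replicates) with negative-binomial counts and embedded fold changes,
  for the differential-expression stage.

Every generator returns the matrix plus a :class:`SimTruth` recording the
ground truth (slopes, PI status, activated genes, embedded fold changes,
hazard coefficient), sufficient for parameter-recovery tests downstream.
A fixed ``seed`` makes every generator bit-reproducible; each generator
draws from its own deterministic substream of the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .datatypes import (
    CD45,
    CountMatrix,
    ExpressionMatrix,
    GeneList,
    ParainflamError,
    PISignature,
)

_MARKERS = (CD45, "GZMA", "PRF1")


@dataclass
class SimConfig:
    """Parameters of the synthetic cohorts.

    Expression values are log2 throughout; survival times are days.
    Defaults reproduce the structure reported for the real cohorts: a
    40-gene signature, roughly a quarter of tumors PI+, a median of ~17
    of the 40 signature genes activated per PI+ sample, and a 5%-quantile
    threshold calibration on adjacent normals downstream.
    """

    n_genes: int = 1000
    n_tissues: int = 2
    n_normals_per_tissue: int = 50
    n_tumors_per_tissue: int = 100
    n_cell_lines: int = 600

    signature_size: int = 40
    down_signature_size: int = 75
    coactivated_genes: int = 0

    pi_positive_fraction: float = 0.259
    mean_genes_activated: float = 17.0
    activation_effect_mean: float = 2.0
    activation_effect_sd: float = 0.5
    down_effect: float = 1.0

    infiltration_mean: float = 4.0
    infiltration_sd: float = 1.0
    slope_zero_fraction: float = 0.5
    slope_mean: float = 0.6
    slope_sd: float = 0.4
    baseline_mean: float = 5.0
    baseline_sd: float = 1.5
    noise_sd: float = 0.5

    bimodal_weight: float = 0.2
    bimodal_separation: float = 3.0
    bimodal_sd: float = 0.3

    conditions: tuple = ("WT", "KO1", "KO2")
    reference_condition: str = "WT"
    n_replicates: int = 2
    library_size: float = 5e5
    nb_dispersion: float = 0.05
    n_de_genes: int = 100
    de_log2fc: float = 2.5
    shared_de_fraction: float = 0.6
    n_inflammatory_genes: int = 300
    inflammatory_de_fraction: float = 0.4

    p53_intercept: float = -0.85
    p53_coef: float = 1.2
    hazard_base: float = 1.0 / 1500.0
    hazard_coef: float = 0.8
    censor_rate: float = 0.3

    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_genes", "n_tissues", "n_normals_per_tissue",
            "n_tumors_per_tissue", "n_cell_lines", "signature_size",
            "down_signature_size", "n_replicates",
        ):
            if getattr(self, name) <= 0:
                raise ParainflamError(f"{name} must be positive")
        for name in (
            "pi_positive_fraction", "censor_rate", "slope_zero_fraction",
            "bimodal_weight", "shared_de_fraction", "inflammatory_de_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParainflamError(f"{name} must lie in [0,1], got {v}")
        reserved = (
            len(_MARKERS) + self.signature_size + self.down_signature_size
            + self.coactivated_genes
        )
        if self.n_genes < reserved + 10:
            raise ParainflamError(
                f"n_genes={self.n_genes} too small for signature sets "
                f"plus markers ({reserved})"
            )
        if len(self.conditions) < 2:
            raise ParainflamError("need at least two count conditions")
        if self.n_inflammatory_genes >= self.n_genes:
            raise ParainflamError(
                "n_inflammatory_genes must be smaller than n_genes "
                "(the inflammatory list is a strict subset of the universe)"
            )
        if self.reference_condition not in self.conditions:
            raise ParainflamError("reference_condition must be a condition")

    def tissues(self) -> list[str]:
        return [f"tissue{i + 1}" for i in range(self.n_tissues)]


@dataclass
class SimTruth:
    """Ground truth recorded alongside each generated dataset."""

    signature: Optional[PISignature] = None
    true_slopes: Optional[pd.DataFrame] = None        # tissue × gene
    baselines: Optional[pd.Series] = None             # gene → log2 baseline
    pi_status: Optional[pd.Series] = None             # sample → bool
    activated_genes: dict = field(default_factory=dict)
    latent_intensity: Optional[pd.Series] = None      # hazard covariate
    p53_status: Optional[pd.Series] = None
    true_hazard_coef: Optional[float] = None
    de_genes: dict = field(default_factory=dict)      # condition → {gene: lfc}
    inflammatory: Optional[GeneList] = None
    expected_signature: Optional[list] = None         # shared DE ∩ inflammatory
    high_lines: dict = field(default_factory=dict)    # gene → list of samples


# --------------------------------------------------------------- scaffolding

def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(stream,))
    )


def _shared_params(
    config: SimConfig, genes: list[str]
) -> tuple[pd.DataFrame, pd.Series]:
    """Slopes and baselines drawn from a dedicated stream (stream 0).

    Shared by the reference-normal and tumor-cohort generators so that,
    for one seed, the infiltration model learned on reference normals
    transfers to the cohort — the same assumption the real analysis makes
    when applying healthy-tissue slopes to tumors.
    """
    rng = _rng(config, 0)
    slopes = _draw_slopes(config, genes, rng)
    baselines = _draw_baselines(config, genes, rng)
    return slopes, baselines


def _gene_names(config: SimConfig) -> tuple[list[str], PISignature]:
    up = [f"PI{i + 1:03d}" for i in range(config.signature_size)]
    down = [f"DN{i + 1:03d}" for i in range(config.down_signature_size)]
    coact = [f"CO{i + 1:03d}" for i in range(config.coactivated_genes)]
    n_bg = config.n_genes - len(_MARKERS) - len(up) - len(down) - len(coact)
    background = [f"G{i + 1:04d}" for i in range(n_bg)]
    genes = list(_MARKERS) + up + down + coact + background
    sig = PISignature(
        up=GeneList("PI_up", up, source="synthetic"),
        down=GeneList("PI_down", down, source="synthetic"),
        species="human",
    )
    return genes, sig


def _draw_slopes(
    config: SimConfig, genes: list[str], rng: np.random.Generator
) -> pd.DataFrame:
    """Per-(tissue, gene) CD45 slope: a zero-inflated Gaussian mix."""
    tissues = config.tissues()
    zero = rng.random((len(tissues), len(genes))) < config.slope_zero_fraction
    slopes = rng.normal(config.slope_mean, config.slope_sd, zero.shape)
    slopes[zero] = 0.0
    df = pd.DataFrame(slopes, index=tissues, columns=genes)
    df[CD45] = 1.0  # CD45 tracks itself exactly
    return df


def _draw_baselines(
    config: SimConfig, genes: list[str], rng: np.random.Generator
) -> pd.Series:
    base = pd.Series(
        rng.normal(config.baseline_mean, config.baseline_sd, len(genes)),
        index=genes,
    )
    base[CD45] = 0.0  # CD45 row equals the infiltration level itself
    return base


def _express(
    config: SimConfig,
    genes: list[str],
    sample_ids: list[str],
    tissue_of: pd.Series,
    infiltration: pd.Series,
    slopes: pd.DataFrame,
    baselines: pd.Series,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """baseline + tissue slope × CD45 + Gaussian noise; CD45 row exact."""
    x = np.empty((len(genes), len(sample_ids)))
    slope_arr = slopes[genes].to_numpy()
    base_arr = baselines[genes].to_numpy()
    tissue_idx = {t: i for i, t in enumerate(slopes.index)}
    for j, s in enumerate(sample_ids):
        beta = slope_arr[tissue_idx[tissue_of[s]]]
        x[:, j] = base_arr + beta * infiltration[s]
    if config.noise_sd > 0:
        x += rng.normal(0.0, config.noise_sd, x.shape)
    df = pd.DataFrame(x, index=genes, columns=sample_ids)
    df.loc[CD45] = infiltration[sample_ids].to_numpy()
    return df


# ----------------------------------------------------------------- normals

def simulate_reference_normals(
    config: SimConfig,
) -> tuple[ExpressionMatrix, SimTruth]:
    """Healthy-tissue panel for training the infiltration model.

    Expression of gene *g* in sample *s* of tissue *t* is
    ``baseline_g + slope_{g,t} · c_s + N(0, noise_sd)`` with ``c_s`` the
    sample's CD45 log2 level; the CD45 row equals ``c_s`` exactly.
    """
    rng = _rng(config, 1)
    genes, sig = _gene_names(config)
    slopes, baselines = _shared_params(config, genes)

    sample_ids, tissue_of = [], {}
    for t in config.tissues():
        for i in range(config.n_normals_per_tissue):
            sid = f"{t}_ref{i + 1:03d}"
            sample_ids.append(sid)
            tissue_of[sid] = t
    tissue_of = pd.Series(tissue_of)
    infiltration = pd.Series(
        rng.normal(config.infiltration_mean, config.infiltration_sd,
                   len(sample_ids)),
        index=sample_ids,
    )
    values = _express(config, genes, sample_ids, tissue_of, infiltration,
                      slopes, baselines, rng)
    ann = pd.DataFrame(
        {"tissue": tissue_of, "sample_class": "normal"}, index=sample_ids
    )
    truth = SimTruth(signature=sig, true_slopes=slopes, baselines=baselines)
    return ExpressionMatrix(values, ann), truth


# ------------------------------------------------------------- tumor cohort

def _censor_bound(config: SimConfig) -> float:
    """Upper end of the Uniform(0, m) censor-time window.

    m solves (1 − e^{−λ₀m})/(λ₀m) = censor_rate at the baseline hazard λ₀,
    so the expected censored fraction at baseline matches ``censor_rate``.
    """
    lam = config.hazard_base
    target = config.censor_rate

    def f(m: float) -> float:
        return (1.0 - np.exp(-lam * m)) / (lam * m) - target

    return brentq(f, 1e-9 / lam, 1e6 / lam)


def simulate_tumor_cohort(
    config: SimConfig, signature: Optional[PISignature] = None
) -> tuple[ExpressionMatrix, pd.DataFrame, SimTruth]:
    """Tumors plus adjacent normals sharing one infiltration model.

    A fraction ``pi_positive_fraction`` of tumors activates the PI program:
    each PI+ tumor adds a log2 shift (``activation_effect``) to a binomial
    subset of the up-signature genes (mean ``mean_genes_activated``) and a
    coupled shift to the down-set. p53 mutation probability follows a
    logistic model in PI status; survival is exponential with hazard
    ``hazard_base · exp(hazard_coef · latent intensity)`` and independent
    Uniform(0, m) censoring.

    Returns ``(expression, annotations, truth)``.
    """
    rng = _rng(config, 2)
    genes, generated_sig = _gene_names(config)
    sig = signature or generated_sig
    if len(sig.up) != config.signature_size:
        raise ParainflamError("signature size disagrees with config")
    slopes, baselines = _shared_params(config, genes)

    sample_ids, tissue_of, classes = [], {}, {}
    for t in config.tissues():
        for i in range(config.n_tumors_per_tissue):
            sid = f"{t}_tum{i + 1:04d}"
            sample_ids.append(sid)
            tissue_of[sid], classes[sid] = t, "tumor"
        for i in range(config.n_normals_per_tissue):
            sid = f"{t}_adj{i + 1:04d}"
            sample_ids.append(sid)
            tissue_of[sid], classes[sid] = t, "normal"
    tissue_of = pd.Series(tissue_of)
    classes = pd.Series(classes)

    infiltration = pd.Series(
        rng.normal(config.infiltration_mean, config.infiltration_sd,
                   len(sample_ids)),
        index=sample_ids,
    )
    values = _express(config, genes, sample_ids, tissue_of, infiltration,
                      slopes, baselines, rng)

    tumors = [s for s in sample_ids if classes[s] == "tumor"]
    pi_status = pd.Series(False, index=sample_ids)
    pi_status[tumors] = rng.random(len(tumors)) < config.pi_positive_fraction

    p_act = min(1.0, config.mean_genes_activated / config.signature_size)
    activated: dict[str, list[str]] = {}
    intensity = pd.Series(0.0, index=sample_ids)
    up_genes = np.asarray(sig.up.genes)
    down_genes = np.asarray(sig.down.genes) if sig.down else np.empty(0, str)
    coact = [g for g in genes if g.startswith("CO")]
    for s in tumors:
        if not pi_status[s]:
            continue
        k = max(1, rng.binomial(config.signature_size, p_act))
        chosen = rng.choice(up_genes, size=k, replace=False)
        effects = np.maximum(
            rng.normal(config.activation_effect_mean,
                       config.activation_effect_sd, k),
            0.25,
        )
        values.loc[chosen, s] += effects
        activated[s] = sorted(chosen)
        intensity[s] = effects.sum() / config.signature_size
        if len(down_genes) and config.down_effect != 0.0:
            # down-program amplitude follows the same latent intensity, so
            # up- and down-derived scores are positively coupled across
            # samples (the empirically observed behaviour of the two sets)
            kd = max(1, rng.binomial(len(down_genes), p_act))
            chosen_d = rng.choice(down_genes, size=kd, replace=False)
            values.loc[chosen_d, s] += config.down_effect * intensity[s]
        if coact:
            # co-activated genes track the program's latent intensity, so
            # their expression is maximally coupled to the PI score
            values.loc[coact, s] += intensity[s]

    # p53 status (tumors only): logistic in PI status
    logit = config.p53_intercept + config.p53_coef * pi_status[tumors].astype(float)
    p_mut = 1.0 / (1.0 + np.exp(-logit))
    p53 = pd.Series(pd.NA, index=sample_ids, dtype="object")
    p53[tumors] = np.where(rng.random(len(tumors)) < p_mut, "mut", "WT")

    # exponential survival with uniform censoring (tumors only)
    lam = config.hazard_base * np.exp(
        config.hazard_coef * intensity[tumors].to_numpy()
    )
    t_event = rng.exponential(1.0 / lam)
    time = pd.Series(np.nan, index=sample_ids)
    event = pd.Series(np.nan, index=sample_ids)
    if config.censor_rate > 0:
        c = rng.uniform(0.0, _censor_bound(config), len(tumors))
        time[tumors] = np.minimum(t_event, c)
        event[tumors] = (t_event <= c).astype(float)
    else:
        time[tumors] = t_event
        event[tumors] = 1.0

    ann = pd.DataFrame(
        {
            "tissue": tissue_of,
            "sample_class": classes,
            "p53_status": p53,
            "time": time,
            "event": event,
        },
        index=sample_ids,
    )
    truth = SimTruth(
        signature=sig,
        true_slopes=slopes,
        baselines=baselines,
        pi_status=pi_status,
        activated_genes=activated,
        latent_intensity=intensity,
        p53_status=p53,
        true_hazard_coef=config.hazard_coef,
    )
    return ExpressionMatrix(values, ann), ann, truth


# ------------------------------------------------------------ cell-line panel

def simulate_cell_line_panel(
    config: SimConfig,
) -> tuple[ExpressionMatrix, SimTruth]:
    """CCLE-like panel: signature genes bimodal across lines.

    Each signature gene draws from a two-component Gaussian mixture — a
    low mode at the gene's baseline and a high component shifted by
    ``bimodal_separation`` log2, membership Bernoulli(``bimodal_weight``)
    per (gene, line). Background genes are single Gaussians. Truth records
    the high-component lines per gene.
    """
    rng = _rng(config, 3)
    genes, sig = _gene_names(config)
    baselines = _draw_baselines(config, genes, rng)
    baselines[CD45] = 1.0  # cell lines carry no immune infiltrate

    samples = [f"line{i + 1:04d}" for i in range(config.n_cell_lines)]
    x = baselines.to_numpy()[:, None] + rng.normal(
        0.0, config.bimodal_sd, (len(genes), len(samples))
    )
    values = pd.DataFrame(x, index=genes, columns=samples)

    truth = SimTruth(signature=sig, baselines=baselines)
    for g in sig.up.genes:
        high = rng.random(len(samples)) < config.bimodal_weight
        values.loc[g, high] += config.bimodal_separation
        truth.high_lines[g] = [s for s, h in zip(samples, high) if h]

    ann = pd.DataFrame(
        {"tissue": "panel", "sample_class": "cell_line"}, index=samples
    )
    return ExpressionMatrix(values, ann), truth


# ------------------------------------------------------------------- counts

def simulate_counts(config: SimConfig) -> tuple[CountMatrix, SimTruth]:
    """NB-distributed RNA-seq counts with embedded fold changes.

    Emulates a wild-type vs knockout design with few replicates. A shared
    core of differentially expressed genes (fraction ``shared_de_fraction``)
    is embedded in every non-reference condition, the rest are
    condition-specific; a configurable fraction of the shared core is drawn
    from a designated inflammatory gene list, so the expected signature
    (shared DE ∩ inflammatory) is known by construction.
    """
    rng = _rng(config, 4)
    genes, _ = _gene_names(config)
    inflam = GeneList(
        "inflammatory",
        sorted(rng.choice(genes, size=min(config.n_inflammatory_genes,
                                          len(genes)), replace=False)),
        source="synthetic",
    )

    n_shared = int(round(config.n_de_genes * config.shared_de_fraction))
    n_inf_shared = int(round(n_shared * config.inflammatory_de_fraction))
    inf_pool = list(inflam.genes)
    rng.shuffle(inf_pool)
    shared = inf_pool[:n_inf_shared]
    other_pool = [g for g in genes if g not in set(shared)]
    rng.shuffle(other_pool)
    non_inf = [g for g in other_pool if g not in inflam][: n_shared - len(shared)]
    shared = shared + non_inf

    de_genes: dict[str, dict[str, float]] = {}
    used = set(shared)
    remaining = [g for g in genes if g not in used]
    rng.shuffle(remaining)
    n_specific = config.n_de_genes - n_shared
    for cond in config.conditions:
        if cond == config.reference_condition:
            continue
        specific = remaining[:n_specific]
        remaining = remaining[n_specific:]
        de_genes[cond] = {g: config.de_log2fc for g in shared + specific}

    # relative abundances and library sizes
    q = rng.lognormal(0.0, 1.0, len(genes))
    q /= q.sum()
    base_mu = config.library_size * q

    cols, cond_labels = [], []
    counts = {}
    for cond in config.conditions:
        lfc = de_genes.get(cond, {})
        fold = np.array([2.0 ** lfc.get(g, 0.0) for g in genes])
        for r in range(config.n_replicates):
            sid = f"{cond}_rep{r + 1}"
            libfac = rng.uniform(0.8, 1.2)
            mu = base_mu * fold * libfac
            if config.nb_dispersion > 0:
                n_param = 1.0 / config.nb_dispersion
                counts[sid] = rng.negative_binomial(
                    n_param, n_param / (n_param + mu)
                )
            else:
                counts[sid] = rng.poisson(mu)
            cols.append(sid)
            cond_labels.append(cond)

    cm = CountMatrix(
        pd.DataFrame(counts, index=genes),
        pd.Series(cond_labels, index=cols, name="condition"),
    )
    expected = sorted(set(shared) & set(inflam.genes)) if de_genes else []
    truth = SimTruth(
        de_genes=de_genes, inflammatory=inflam, expected_signature=expected
    )
    return cm, truth


__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_reference_normals",
    "simulate_tumor_cohort",
    "simulate_cell_line_panel",
    "simulate_counts",
]
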