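"""Differential-expression stand-in: CPM normalization, Welch's t, BH.

This caller exists so the pipeline is exercisable end to end on synthetic
counts; for real data an externally computed DEG table (e.g. from a
negative-binomial GLM framework) can be injected verbatim via
:func:`stressnet.core_io.read_deg_table` and the ``--deg-table`` pipeline
flag, bypassing this module entirely.

The DEG rule is |log2FC| >= 1 and BH-adjusted p <= 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .core_io import Category, DEGTable, ExpressionMatrix

__all__ = ["DEContrast", "normalize_cpm", "call_degs", "call_all_degs", "bh_adjust"]

#: pseudocount, in CPM units, for fold changes and the log transform
PSEUDOCOUNT = 1.0
#: genes below this mean CPM in both groups are not tested
MIN_MEAN_CPM = 1.0


@dataclass
class DEContrast:
    """Full per-gene test results for one stress-vs-control contrast.

    ``table`` has one row per gene with mean CPM of each group, log2FC and,
    for genes passing the expression filter, raw and BH-adjusted p-values
    (untested genes carry NaN).
    """

    table: pd.DataFrame
    species: str
    experiment: str
    level: str
    control_level: str


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (NaNs pass through untouched)."""
    p = np.asarray(pvals, dtype=float)
    out = np.full_like(p, np.nan)
    mask = ~np.isnan(p)
    pv = p[mask]
    n = pv.size
    if n == 0:
        return out
    out[mask] = multipletests(pv, method="fdr_bh")[1]
    return out


def normalize_cpm(counts: ExpressionMatrix) -> ExpressionMatrix:
    """Scale each sample to counts-per-million (column sums of 1e6)."""
    values = counts.values
    libsize = values.sum(axis=0)
    zero = libsize[libsize == 0]
    if len(zero):
        raise ValueError(f"all-zero sample(s): {list(zero.index)}")
    cpm = values / libsize * 1e6
    return ExpressionMatrix(values=cpm, design=counts.design.copy(), unit="CPM")


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration (Smyth's fitFDist step)."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = float(special.polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(special.polygamma(2, y))
        y += dif
        if abs(dif) < 1e-8 * y:
            break
    return y


def _fit_variance_prior(
    s2: np.ndarray, df: float, abundance: np.ndarray
) -> tuple[np.ndarray, float]:
    """Moment-fit a scaled inverse-chi-square prior with an abundance trend.

    Follows the classic empirical-Bayes recipe on log sample variances,
    with the prior location a lowess trend in mean log-abundance (counts
    noise makes weakly expressed genes intrinsically noisier): the excess
    spread of log(s^2) around the trend beyond the chi-square sampling
    spread determines the prior df d0; no excess means an effectively
    infinite d0 (the trend is the variance).
    """
    ok = np.isfinite(s2) & (s2 > 0)
    if ok.sum() < 10:
        val = float(np.median(s2[ok])) if ok.any() else 1.0
        return np.full(s2.shape, val), 1e6
    e = np.log(s2[ok]) - float(special.digamma(df / 2)) + np.log(df / 2)
    fit = lowess(e, abundance[ok], frac=0.5, return_sorted=True)
    trend = np.interp(abundance, fit[:, 0], fit[:, 1])
    evar = float((e - trend[ok]).var(ddof=1)) - float(special.polygamma(1, df / 2))
    if evar <= 0:
        d0 = 1e6
        offset = 0.0
    else:
        d0 = 2.0 * _trigamma_inverse(evar)
        offset = float(special.digamma(d0 / 2) - np.log(d0 / 2))
    return np.exp(trend - offset), d0


def _moderated_welch(log_stress: np.ndarray, log_control: np.ndarray) -> np.ndarray:
    """Welch's t with empirical-Bayes variance moderation, two-sided p.

    Per-gene group variances are squeezed toward an abundance-trended prior
    fitted to the pooled variances across genes, and the prior df augments
    each group's df in the Welch–Satterthwaite formula — the moderation
    that makes a 3-vs-3 design usable after BH correction. Genes with zero
    variance in both groups get p = 1 with a warning.
    """
    n1, n2 = log_stress.shape[1], log_control.shape[1]
    v1 = log_stress.var(axis=1, ddof=1)
    v2 = log_control.var(axis=1, ddof=1)
    flat = (v1 == 0) & (v2 == 0)
    pooled = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    abundance = np.hstack([log_stress, log_control]).mean(axis=1)
    s0, d0 = _fit_variance_prior(pooled, float(n1 + n2 - 2), abundance)
    d1, d2 = n1 - 1.0, n2 - 1.0
    v1m = (d0 * s0 + d1 * v1) / (d0 + d1)
    v2m = (d0 * s0 + d2 * v2) / (d0 + d2)
    se2 = v1m / n1 + v2m / n2
    diff = log_stress.mean(axis=1) - log_control.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = diff / np.sqrt(se2)
        df = se2**2 / (
            (v1m / n1) ** 2 / (d1 + d0) + (v2m / n2) ** 2 / (d2 + d0)
        )
        p = 2 * stats.t.sf(np.abs(t), df)
    if flat.any():
        warnings.warn(f"{int(flat.sum())} zero-variance gene(s): p set to 1")
        p[flat] = 1.0
    p[np.isnan(p)] = 1.0
    return p


def _median_of_ratios(matrix: np.ndarray) -> np.ndarray:
    """Per-sample size factors: median ratio to the geometric-mean profile.

    Corrects the composition bias of total-count scaling (a handful of
    strongly induced abundant genes deflates every other gene's CPM);
    computed over genes expressed in all samples of the contrast. Returns
    all-ones when fewer than 10 such genes exist.
    """
    positive = (matrix > 0).all(axis=1)
    if positive.sum() < 10:
        return np.ones(matrix.shape[1])
    logs = np.log(matrix[positive])
    ref = logs.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logs - ref, axis=0))
    return factors / np.exp(np.mean(np.log(factors)))


def call_degs(
    counts: ExpressionMatrix,
    experiment: str,
    level: str,
    fc_threshold: float = 1.0,
    p_threshold: float = 0.05,
    min_mean_cpm: float = MIN_MEAN_CPM,
) -> tuple[DEGTable, DEContrast]:
    """Call DEGs for one condition against its experiment control.

    CPM columns of the contrast are first rescaled by median-of-ratios
    size factors (composition correction); then
    log2FC = log2((mean CPM stress + c) / (mean CPM control + c)) with
    c = 1 CPM; p from moderated Welch's t on log2(CPM + c); BH across
    tested genes; the DEG table keeps rows with |log2FC| >= fc_threshold
    and p_adj <= p_threshold.
    """
    control_level = counts.control_level(experiment)
    if control_level is None:
        raise ValueError(f"experiment {experiment!r} has no control condition")
    stress_samples = counts.samples_of(experiment, level)
    control_samples = counts.samples_of(experiment, control_level)
    if len(stress_samples) < 2 or len(control_samples) < 2:
        raise ValueError(
            f"need >= 2 replicates per group for {experiment}:{level} "
            f"(got {len(stress_samples)} vs {len(control_samples)})"
        )
    cpm = normalize_cpm(counts) if counts.unit == "counts" else counts
    both = stress_samples + control_samples
    factors = _median_of_ratios(cpm.values[both].to_numpy(dtype=float))
    corrected = cpm.values[both] / factors
    stress = corrected[stress_samples].to_numpy(dtype=float)
    control = corrected[control_samples].to_numpy(dtype=float)
    mean_s = stress.mean(axis=1)
    mean_c = control.mean(axis=1)
    log2fc = np.log2((mean_s + PSEUDOCOUNT) / (mean_c + PSEUDOCOUNT))
    tested = (mean_s >= min_mean_cpm) | (mean_c >= min_mean_cpm)
    p_raw = np.full(len(log2fc), np.nan)
    if tested.any():
        p_raw[tested] = _moderated_welch(
            np.log2(stress[tested] + PSEUDOCOUNT),
            np.log2(control[tested] + PSEUDOCOUNT),
        )
    p_adj = bh_adjust(p_raw)
    full = pd.DataFrame(
        {
            "gene": cpm.gene_ids,
            "mean_cpm_stress": mean_s,
            "mean_cpm_control": mean_c,
            "log2FC": log2fc,
            "p_raw": p_raw,
            "p_adj": p_adj,
        }
    )
    contrast = DEContrast(
        table=full,
        species=counts.species,
        experiment=experiment,
        level=level,
        control_level=control_level,
    )
    keep = full[
        (full["log2FC"].abs() >= fc_threshold) & (full["p_adj"] <= p_threshold)
    ].copy()
    keep["direction"] = np.where(keep["log2FC"] > 0, "up", "down")
    deg = DEGTable(
        table=keep[["gene", "log2FC", "p_adj", "direction"]].reset_index(drop=True),
        species=counts.species,
        experiment=experiment,
        level=level,
        fc_threshold=fc_threshold,
        p_threshold=p_threshold,
    )
    return deg, contrast


def call_all_degs(
    counts: ExpressionMatrix,
    fc_threshold: float = 1.0,
    p_threshold: float = 0.05,
) -> dict[tuple[str, str], DEGTable]:
    """DEG tables for every non-control condition of one species.

    Keys are (experiment, level). Conditions of category ``other`` (e.g.
    light-quality ratios) are still contrasted against their experiment's
    designated control.
    """
    out: dict[tuple[str, str], DEGTable] = {}
    design = counts.design
    for (exp, level), grp in design.groupby(["experiment", "level"], sort=False):
        if (grp["category"] == Category.CONTROL.value).any():
            continue
        deg, _ = call_degs(counts, str(exp), str(level), fc_threshold, p_threshold)
        out[(str(exp), str(level))] = deg
    return out
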