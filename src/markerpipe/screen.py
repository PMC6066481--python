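"""Genome-wide screen for bimodal prognostic expression markers.

For every gene the screen

1. splits samples at the 75th percentile of expression and log-rank-tests
   overall survival between the resulting groups,
2. measures dynamic range (p99 / (p1 + pseudo-value)),
3. assesses bimodality with a two-component Gaussian mixture on log10
   values selected against the one-component fit by a BIC margin,
4. applies the marker-selection filters: bimodal shape, mode separation of
   at least ``fold_threshold`` (default 10-fold), and high-mode median
   expression above ``peak_threshold`` (default 1 RPKM),

then ranks genes by log-rank p-value, passing genes first.  The screen
uses overall survival only; the other endpoints belong to the validation
stage.  No multiple-testing correction enters the primary ranking; a
Benjamini–Hochberg column is reported for reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import report as _report
from ._gmm import fit_gmm1d, fit_gmm1d_batch
from .cohort import ExpressionMatrix
from .errors import (
    AlignmentError,
    DegenerateGroupsError,
    InsufficientDataError,
    InvalidInputError,
)
from .survival import logrank_test

__all__ = [
    "ScreenConfig",
    "BimodalityResult",
    "percentile_split",
    "assess_bimodality",
    "screen_genes",
    "annotate_enrichment",
]


@dataclass(frozen=True)
class ScreenConfig:
    percentile: float = 0.75
    fold_threshold: float = 10.0
    peak_threshold: float = 1.0          # RPKM; high-mode median must exceed
    dynamic_range_threshold: float | None = None   # reported; filter off
    bic_margin: float = 2.0
    min_component_weight: float = 0.05   # a mode must hold >= 5% of samples
    pseudo_rpkm: float = 0.01
    min_values_for_bimodality: int = 20


@dataclass(frozen=True)
class BimodalityResult:
    n_components_selected: int
    component_medians: tuple[float, float]  # original scale, ascending
    fold_separation_est: float
    model_selection_score_gap: float        # BIC(1) - BIC(2); > 0 favors 2


def percentile_split(values, q: float) -> np.ndarray:
    """Label samples 'high' iff value >= the q-th percentile.

    The percentile uses linear interpolation between order statistics;
    ties at the threshold go to 'high' (the >= convention used for the
    assay cutoff).
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise InvalidInputError("empty input")
    if not 0 < q < 1:
        raise InvalidInputError("q must be in (0, 1)")
    thr = np.quantile(values, q)
    return values >= thr


def assess_bimodality(
    values,
    bic_margin: float = 2.0,
    min_n: int = 20,
    min_component_weight: float = 0.05,
) -> BimodalityResult:
    """Two- vs one-component Gaussian mixture on log10 values.

    Zeros are replaced by half the smallest positive value before the log
    transform.  Two components are selected when BIC improves by more than
    ``bic_margin`` and both mixture weights reach ``min_component_weight``
    (two distinct *subgroups*, not a spike on a few outliers); component
    medians are back-transformed to the original scale and their ratio is
    the estimated fold separation.
    """
    values = np.asarray(values, dtype=float)
    if values.size < min_n:
        raise InsufficientDataError(f"need >= {min_n} values, got {values.size}")
    if np.any(values < 0) or not np.all(np.isfinite(values)):
        raise InvalidInputError("values must be finite and >= 0")
    pos = values[values > 0]
    if pos.size == 0:
        med = 0.0
        return BimodalityResult(1, (med, med), 1.0, -np.inf)
    x = np.where(values > 0, values, pos.min() / 2.0)
    logx = np.log10(x)
    if np.ptp(logx) == 0.0:
        med = float(10 ** logx[0])
        return BimodalityResult(1, (med, med), 1.0, -np.inf)

    fit1 = fit_gmm1d(logx, 1)
    fit2 = fit_gmm1d(logx, 2)
    gap = fit1.bic - fit2.bic
    if (
        fit2.n_components == 2
        and gap > bic_margin
        and fit2.weights.min() >= min_component_weight
    ):
        med_lo, med_hi = (float(10 ** m) for m in fit2.means)
        return BimodalityResult(2, (med_lo, med_hi), med_hi / med_lo, float(gap))
    med = float(10 ** fit1.means[0])
    return BimodalityResult(1, (med, med), 1.0, float(gap))


def _align_outcomes(expr: ExpressionMatrix, times, events):
    if isinstance(times, pd.Series) or isinstance(events, pd.Series):
        times = pd.Series(times)
        events = pd.Series(events)
        missing = [s for s in expr.sample_ids if s not in times.index]
        extra = [s for s in times.index if s not in expr.sample_ids]
        if missing or extra:
            raise AlignmentError(
                f"sample ids misaligned ({len(missing)} missing, {len(extra)} extra)",
                offenders=missing + extra,
            )
        times = times.reindex(expr.sample_ids).to_numpy(dtype=float)
        events = events.reindex(expr.sample_ids).to_numpy()
    else:
        times = np.asarray(times, dtype=float)
        events = np.asarray(events)
        if times.size != expr.n_samples or events.size != expr.n_samples:
            raise AlignmentError(
                "outcome vectors do not match the number of samples",
                offenders=[],
            )
    return times, np.asarray(events).astype(int)


def screen_genes(
    expr: ExpressionMatrix,
    times,
    events,
    config: ScreenConfig | None = None,
) -> pd.DataFrame:
    """Run the full marker screen; returns one row per gene.

    ``times``/``events`` are overall-survival follow-up and death
    indicators, either arrays aligned with ``expr.sample_ids`` or pandas
    Series indexed by sample id.
    """
    config = config or ScreenConfig()
    times, events = _align_outcomes(expr, times, events)
    if np.any(times < 0):
        raise InvalidInputError("times must be >= 0")

    if expr.n_samples < config.min_values_for_bimodality:
        raise InsufficientDataError(
            f"screen needs >= {config.min_values_for_bimodality} samples"
        )

    vals_all = expr.values
    q = np.quantile(vals_all, [0.01, config.percentile, 0.99], axis=1)
    dyn_all = q[2] / (q[0] + config.pseudo_rpkm)

    # log10 transform with per-gene half-minimum pseudo-value for zeros
    logx = np.empty_like(vals_all)
    spread = np.empty(expr.n_genes, dtype=bool)
    for gi in range(expr.n_genes):
        v = vals_all[gi]
        pos = v[v > 0]
        x = np.where(v > 0, v, pos.min() / 2.0) if pos.size else np.ones_like(v)
        logx[gi] = np.log10(x)
        spread[gi] = np.ptp(logx[gi]) > 0
    gmm = fit_gmm1d_batch(logx[spread])
    gap = np.full(expr.n_genes, -np.inf)
    med_lo = 10 ** np.where(spread, 0.0, logx[:, 0])
    med_hi = med_lo.copy()
    gap[spread] = gmm["bic1"] - gmm["bic2"]
    bimodal = gap > config.bic_margin
    bimodal[spread] &= gmm["weights"].min(axis=1) >= config.min_component_weight
    med_lo[spread] = np.where(bimodal[spread], 10 ** gmm["means"][:, 0], 10 ** logx[spread].mean(axis=1))
    med_hi[spread] = np.where(bimodal[spread], 10 ** gmm["means"][:, 1], med_lo[spread])
    fold = med_hi / med_lo

    records = []
    for gi, gene in enumerate(expr.gene_ids):
        vals = vals_all[gi]
        high = vals >= q[1, gi]
        try:
            lr = logrank_test(times, events, high.astype(int))
            p, chisq = lr.p_value, lr.statistic
        except DegenerateGroupsError:
            p, chisq = np.nan, np.nan
        peak = med_hi[gi]
        passes = (
            bool(bimodal[gi])
            and fold[gi] >= config.fold_threshold
            and peak > config.peak_threshold
        )
        if config.dynamic_range_threshold is not None:
            passes = passes and dyn_all[gi] >= config.dynamic_range_threshold
        records.append(
            {
                "gene_id": gene,
                "logrank_p": p,
                "logrank_chisq": chisq,
                "dynamic_range": dyn_all[gi],
                "bimodal": bool(bimodal[gi]),
                "fold_separation_est": fold[gi],
                "peak_high_rpkm": peak,
                "passes_all_filters": bool(passes),
            }
        )
    out = pd.DataFrame.from_records(records)
    # passing genes first, each block ordered by log-rank p (NaN last)
    order = out.sort_values(
        ["passes_all_filters", "logrank_p"],
        ascending=[False, True],
        na_position="last",
        kind="mergesort",
    ).index
    ranks = pd.Series(np.arange(1, len(out) + 1), index=order)
    out["rank"] = ranks.reindex(out.index).astype(int)
    # reference BH-adjusted p over all evaluated genes
    out["logrank_p_bh"] = _bh_adjust(out["logrank_p"].to_numpy())
    return out


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    out = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    m = ok.sum()
    if m == 0:
        return out
    idx = np.argsort(p[ok])
    adj = p[ok][idx] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    vals = np.empty(m)
    vals[idx] = np.minimum(adj, 1.0)
    out[ok] = vals
    return out


def annotate_enrichment(candidate_labels, feature_flags) -> dict:
    """2x2 association between marker-high status and a binary feature.

    Returns the contingency table (rows: high/low, columns: feature
    present/absent), the odds ratio (inf when a margin cell is empty) and
    Fisher's exact two-sided p.
    """
    high = np.asarray(candidate_labels).astype(bool)
    feat = np.asarray(feature_flags).astype(bool)
    if high.shape != feat.shape:
        raise AlignmentError("labels and flags must be aligned")
    a = int((high & feat).sum())
    b = int((high & ~feat).sum())
    c = int((~high & feat).sum())
    d = int((~high & ~feat).sum())
    table = np.array([[a, b], [c, d]])
    if b * c == 0:
        odds = np.inf if a * d > 0 else np.nan
    else:
        odds = (a * d) / (b * c)
    p = _report.fisher_exact(table)
    return {"table": table, "odds_ratio": odds, "fisher_p": p}
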