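"""Post-processing of niche-model suitability ensembles.

Operations on stacks of (algorithm x AOGCM x period) suitability maps:
TSS-weighted consensus, thresholded range sizes and their classification
into range dynamics (Stability / Retraction / Expansion with a +-199-cell
band), refugium mapping (suitable in every period), a hierarchical ANOVA
partition of predictive uncertainty (algorithm and AOGCM nested in time),
contingency association tests on classification tables, and range
centroids.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .grids import Grid, SuitabilityStack

RANGE_STABILITY = "Range Stability"
RANGE_RETRACTION = "Range Retraction"
RANGE_EXPANSION = "Range Expansion"

#: (older period, more recent period) pairs classified by default, matching
#: a 21 ka / 6 ka / 0 ka stack ordering from oldest to youngest.
DEFAULT_PERIOD_PAIRS = ((0, 1), (1, 2), (0, 2))


def compute_tss(tp: int, fn: int, tn: int, fp: int) -> float:
    """True Skill Statistic from a confusion table.

    ``TSS = sensitivity + specificity - 1``; 1 for perfect prediction, 0
    for no skill.
    """
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("confusion table must contain both presences and absences")
    return tp / (tp + fn) + tn / (tn + fp) - 1.0


def consensus_map(stack: SuitabilityStack, period, floor_negative: bool = True) -> Grid:
    """TSS-weighted mean suitability over all (algorithm, AOGCM) layers.

    Negative-skill weights are floored at zero by default so that models
    worse than chance cannot invert the ensemble.
    """
    ip = stack.periods.index(period) if isinstance(period, str) else int(period)
    weights = stack.tss.astype(float).copy()
    if floor_negative:
        weights = np.maximum(weights, 0.0)
    total = weights.sum()
    if total == 0:
        raise ValueError("all TSS weights are zero; consensus undefined")
    layers = stack.values[:, :, ip]  # (n_alg, n_gcm, rows, cols)
    data = np.tensordot(weights, layers, axes=([0, 1], [0, 1])) / total
    return stack._grid(data)


def range_size(grid: Grid, threshold: float = 0.3) -> int:
    """Number of cells with suitability >= threshold (inclusive rule)."""
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must lie in [0, 1]")
    return int(np.nansum(grid.data >= threshold))


def classify_dynamics(cells_old: int, cells_recent: int, cutoff: int = 199) -> str:
    """Label a range-size change between two periods.

    ``diff = cells_old - cells_recent``; within ``[-cutoff, cutoff]`` the
    range is stable, above it the range shrank toward the present
    (Retraction), below it the range grew (Expansion).
    """
    if cells_old < 0 or cells_recent < 0:
        raise ValueError("cell counts must be >= 0")
    diff = cells_old - cells_recent
    if diff > cutoff:
        return RANGE_RETRACTION
    if diff < -cutoff:
        return RANGE_EXPANSION
    return RANGE_STABILITY


def classify_stack_dynamics(
    stack: SuitabilityStack,
    threshold: float = 0.3,
    cutoff: int = 199,
    period_pairs=DEFAULT_PERIOD_PAIRS,
) -> pd.DataFrame:
    """Per-model range-dynamics classification.

    For every (algorithm, AOGCM) combination and every (older, recent)
    period pair, counts suitable cells in each period's layer and applies
    :func:`classify_dynamics`.  Returns a tidy DataFrame.
    """
    rows = []
    for ia, ig in product(range(len(stack.algorithms)), range(len(stack.aogcms))):
        sizes = [range_size(stack.layer(ia, ig, ip), threshold) for ip in range(len(stack.periods))]
        for old, recent in period_pairs:
            rows.append(
                {
                    "algorithm": stack.algorithms[ia],
                    "aogcm": stack.aogcms[ig],
                    "pair": f"{stack.periods[old]}-{stack.periods[recent]}",
                    "cells_old": sizes[old],
                    "cells_recent": sizes[recent],
                    "difference": sizes[old] - sizes[recent],
                    "label": classify_dynamics(sizes[old], sizes[recent], cutoff),
                }
            )
    return pd.DataFrame(rows)


def refugium_map(maps_by_period, threshold: float = 0.3) -> Grid:
    """Binary map of cells suitable in every period (historical refugium)."""
    maps_by_period = list(maps_by_period)
    if len(maps_by_period) < 2:
        raise ValueError("need at least two period maps")
    first = maps_by_period[0]
    for g in maps_by_period[1:]:
        if not first.same_geometry(g):
            raise ValueError("refugium_map requires aligned grids")
    stable = np.ones(first.shape, dtype=bool)
    for g in maps_by_period:
        stable &= g.data >= threshold
    return Grid(stable.astype(float), first.xll, first.yll, first.cellsize)


@dataclass
class VariancePartition:
    """Hierarchical ANOVA decomposition of a suitability stack.

    ``proportions`` maps component name (time, aogcm, algorithm, residual)
    to its overall proportional sum of squares; ``maps`` holds the per-cell
    proportion rasters (uncertainty maps).
    """

    proportions: dict[str, float]
    maps: dict[str, Grid]
    ss: dict[str, float]


def variance_partition(stack: SuitabilityStack) -> VariancePartition:
    """Partition per-cell variance across modelling components.

    Hierarchical design: time is the top factor; AOGCM and algorithm are
    nested within time and crossed with each other inside each period, so

    ``SS_total = SS_time + SS_aogcm(time) + SS_algorithm(time) + SS_residual``

    on the balanced full factorial (type-I sums of squares are unambiguous
    here).  Overall proportions are component sums over cells divided by
    the total sum over cells.
    """
    if np.isnan(stack.values).any():
        missing = np.argwhere(np.isnan(stack.values).any(axis=(3, 4)))
        raise ValueError(f"stack has missing layers at (algorithm, aogcm, period) {missing.tolist()}")
    y = stack.values  # (A, G, T, rows, cols)
    n_alg, n_gcm, n_per = y.shape[:3]
    grand = y.mean(axis=(0, 1, 2))
    m_t = y.mean(axis=(0, 1))  # (T, rows, cols)
    m_gt = y.mean(axis=0)  # (G, T, rows, cols)
    m_at = y.mean(axis=1)  # (A, T, rows, cols)

    ss_time = n_alg * n_gcm * ((m_t - grand) ** 2).sum(axis=0)
    ss_gcm = n_alg * ((m_gt - m_t[None]) ** 2).sum(axis=(0, 1))
    ss_alg = n_gcm * ((m_at - m_t[None]) ** 2).sum(axis=(0, 1))
    ss_total = ((y - grand) ** 2).sum(axis=(0, 1, 2))
    ss_res = ss_total - ss_time - ss_gcm - ss_alg

    comps = {"time": ss_time, "aogcm": ss_gcm, "algorithm": ss_alg, "residual": ss_res}
    totals = {k: float(v.sum()) for k, v in comps.items()}
    grand_total = float(ss_total.sum())
    proportions = {k: (v / grand_total if grand_total > 0 else float("nan")) for k, v in totals.items()}
    with np.errstate(invalid="ignore", divide="ignore"):
        maps = {k: stack._grid(np.where(ss_total > 0, v / ss_total, np.nan)) for k, v in comps.items()}
    return VariancePartition(proportions=proportions, maps=maps, ss=totals)


def classification_association(table) -> dict:
    """Pearson chi-square and likelihood-ratio G2 tests of independence.

    ``table`` is a 2-D contingency table of classification counts (e.g.
    labels by algorithm x AOGCM combination, or by period pair).  Rows or
    columns with zero marginals are dropped with a warning.  Returns a dict
    with chi2, G2, df and both p-values.
    """
    table = np.asarray(table, dtype=float)
    if (table < 0).any():
        raise ValueError("counts must be nonnegative")
    keep_rows = table.sum(axis=1) > 0
    keep_cols = table.sum(axis=0) > 0
    if not keep_rows.all() or not keep_cols.all():
        import warnings

        warnings.warn("dropping zero-marginal rows/columns from the contingency table")
        table = table[keep_rows][:, keep_cols]
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("contingency table needs at least two rows and two columns")
    chi2, p_chi2, df, _ = chi2_contingency(table, correction=False)
    g2, p_g2, _, _ = chi2_contingency(table, correction=False, lambda_="log-likelihood")
    return {"chi2": float(chi2), "p_chi2": float(p_chi2), "G2": float(g2), "p_G2": float(p_g2), "df": int(df)}


def map_centroid(grid: Grid, threshold: float = 0.3, weighted: bool = False) -> tuple[float, float]:
    """(lon, lat) centroid of the suitable area.

    Unweighted mean of suitable-cell centres by default; ``weighted``
    weights cells by their suitability value instead.  Returns NaNs when no
    cell is suitable.
    """
    lon, lat = grid.cell_centers()
    mask = grid.data >= threshold
    if not mask.any():
        return float("nan"), float("nan")
    if weighted:
        w = np.where(mask, grid.data, 0.0)
        return float((lon * w).sum() / w.sum()), float((lat * w).sum() / w.sum())
    return float(lon[mask].mean()), float(lat[mask].mean())
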