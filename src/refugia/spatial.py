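"""Spatial patterns in genetic diversity.

Links per-population genetic summaries to geography and to the climate
history encoded in consensus suitability maps: Mantel correlation between
genetic and geographic distance matrices (isolation by distance on
linearised FST vs log distance), and quantile regressions of diversity
(He, Ar*) against suitability, suitability change ("stability") and
distances to range centroids, including a triangular-envelope flag.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .grids import Grid

EARTH_RADIUS_KM = 6371.0088

DEFAULT_TAUS = (0.10, 0.50, 0.90)


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in kilometres (vectorised)."""
    lon1, lat1, lon2, lat2 = map(np.radians, (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return EARTH_RADIUS_KM * 2.0 * np.arcsin(np.sqrt(a))


def geographic_distance_matrix(lons, lats) -> np.ndarray:
    """Symmetric matrix of great-circle distances among populations (km)."""
    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    return haversine_km(lons[:, None], lats[:, None], lons[None, :], lats[None, :])


def extract_at_points(grid: Grid, lons, lats) -> np.ndarray:
    """Raster value of the cell containing each point.

    Points outside the grid extent yield NaN with a warning.
    """
    lons = np.atleast_1d(np.asarray(lons, dtype=float))
    lats = np.atleast_1d(np.asarray(lats, dtype=float))
    out = np.empty(lons.shape)
    for i, (lon, lat) in enumerate(zip(lons, lats)):
        try:
            row, col = grid.cell_index(lon, lat)
            out[i] = grid.data[row, col]
        except ValueError:
            warnings.warn(f"point ({lon}, {lat}) outside grid extent; value set to NaN")
            out[i] = np.nan
    return out


# --------------------------------------------------------------------------- #
# Mantel test


def _upper(mat: np.ndarray) -> np.ndarray:
    return mat[np.triu_indices_from(mat, k=1)]


def mantel_test(mat_a, mat_b, n_perm: int = 10_000, seed: int = 0):
    """Mantel correlation between two distance matrices.

    ``r`` is the Pearson correlation of the off-diagonal upper triangles;
    significance comes from simultaneous row/column permutations of the
    second matrix, two-sided on ``|r|``:
    ``p = (1 + #{|r_perm| >= |r_obs|}) / (n_perm + 1)``.

    Returns ``(r, r_squared, p)``; ``r`` is NaN for constant matrices.
    """
    a = np.asarray(mat_a, dtype=float)
    b = np.asarray(mat_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("matrices must be square and of equal size")
    if a.shape[0] < 3:
        raise ValueError("Mantel test needs at least three populations")
    if not (np.allclose(a, a.T) and np.allclose(b, b.T)):
        raise ValueError("matrices must be symmetric")
    va, vb = _upper(a), _upper(b)
    if np.ptp(va) == 0 or np.ptp(vb) == 0:
        return float("nan"), float("nan"), float("nan")
    r_obs = float(np.corrcoef(va, vb)[0, 1])
    rng = np.random.default_rng(seed)
    n = a.shape[0]
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r_perm = np.corrcoef(va, _upper(b[np.ix_(perm, perm)]))[0, 1]
        if abs(r_perm) >= abs(r_obs):
            exceed += 1
    p = (1.0 + exceed) / (n_perm + 1.0)
    return r_obs, r_obs**2, p


# --------------------------------------------------------------------------- #
# quantile regression


def quantile_fit(x, y, taus=DEFAULT_TAUS) -> pd.DataFrame:
    """Linear quantile regressions of ``y`` on ``x``.

    Minimises the check loss at each quantile level tau; slope p-values
    come from the asymptotic covariance of the quantile-regression
    estimator.  Returns a DataFrame (tau, slope, intercept, p_slope).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 5:
        raise ValueError("quantile regression needs at least five points")
    if np.ptp(x) == 0:
        raise ValueError("predictor is degenerate (constant)")
    exog = sm.add_constant(x)
    rows = []
    for tau in taus:
        if not (0.0 < tau < 1.0):
            raise ValueError("taus must lie in (0, 1)")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.QuantReg(y, exog).fit(q=tau)
        rows.append(
            {
                "tau": tau,
                "slope": float(res.params[1]),
                "intercept": float(res.params[0]),
                "p_slope": float(res.pvalues[1]),
            }
        )
    return pd.DataFrame(rows)


def envelope_report(
    populations: pd.DataFrame,
    responses=("He", "Ar_star"),
    predictors=None,
    taus=DEFAULT_TAUS,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Quantile-regression summary of diversity against climate predictors.

    ``populations`` holds one row per population with response columns
    (``He``, ``Ar_star``; NaN rows are dropped per response, so populations
    excluded from Ar* simply carry NaN there) and predictor columns.  Every
    (response, predictor) combination is fitted at all ``taus``; a
    "triangular envelope" is flagged when the upper-tau slope is
    significant while the lower-tau slope is not (or has opposite sign) —
    the signature of a constraint on maximum diversity rather than a mean
    shift.
    """
    if predictors is None:
        predictors = [
            c for c in populations.columns if c not in responses and np.issubdtype(populations[c].dtype, np.number)
        ]
    taus = sorted(taus)
    lo_tau, hi_tau = taus[0], taus[-1]
    rows = []
    for resp in responses:
        for pred in predictors:
            sub = populations[[pred, resp]].dropna()
            try:
                fits = quantile_fit(sub[pred], sub[resp], taus=taus)
            except ValueError:
                continue
            fits = fits.set_index("tau")
            lo, hi = fits.loc[lo_tau], fits.loc[hi_tau]
            envelope = bool(
                hi["p_slope"] < alpha
                and (lo["p_slope"] >= alpha or np.sign(lo["slope"]) != np.sign(hi["slope"]))
            )
            for tau, fit in fits.iterrows():
                rows.append(
                    {
                        "response": resp,
                        "predictor": pred,
                        "tau": tau,
                        "slope": fit["slope"],
                        "intercept": fit["intercept"],
                        "p_slope": fit["p_slope"],
                        "n": len(sub),
                        "envelope": envelope,
                    }
                )
    return pd.DataFrame(rows)
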