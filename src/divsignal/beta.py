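"""β-diversity distance decay: Sørensen turnover and regression on distance
matrices (MRM) with permutation inference.

For each family, pairwise Sørensen dissimilarities among its presence-only
sites are regressed on geographic distance, elevational distance and habitat
dissimilarity (Euclidean on arcsine-square-root transformed cover).  Slopes
come from one joint three-predictor MRM; per-gradient R² values come from
three single-predictor MRMs, set to 0 when not significant.  Significance is
assessed by jointly permuting rows and columns of the response matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .data_model import OccurrenceMatrix, SiteMetadata

__all__ = [
    "MrmResult",
    "sorensen_matrix",
    "site_distance_matrices",
    "mrm",
    "turnover_responses",
]


@dataclass
class MrmResult:
    slopes: np.ndarray  # intercept first
    ses: np.ndarray
    tvals: np.ndarray
    r2: float
    p_slopes: np.ndarray  # permutation p per coefficient (two-sided on |t|)
    p_r2: float  # permutation p of the overall fit
    n_perm: int
    names: list[str]

    def slope(self, name: str) -> float:
        return float(self.slopes[self.names.index(name)])

    def se(self, name: str) -> float:
        return float(self.ses[self.names.index(name)])

    def p(self, name: str) -> float:
        return float(self.p_slopes[self.names.index(name)])


def sorensen_matrix(submatrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Sørensen dissimilarity (b+c)/(2a+b+c) among sites.

    ``submatrix`` is the binary site × species incidence of one family,
    already restricted to its presence-only sites.
    """
    X = submatrix.to_numpy(dtype=bool)
    if X.shape[0] < 2:
        raise ValueError("need >= 2 sites")
    if (X.sum(axis=1) == 0).any():
        raise ValueError("empty site rows; restrict to presence-only sites first")
    d = pdist(X, metric="dice")  # Dice dissimilarity == Sørensen on binary data
    return pd.DataFrame(squareform(d), index=submatrix.index, columns=submatrix.index)


def site_distance_matrices(meta: SiteMetadata, sites: list) -> dict[str, pd.DataFrame]:
    """Geographic (Euclidean on x, y), elevational (|Δz|) and habitat
    (Euclidean on arcsin √cover) distance matrices for a site subset."""
    t = meta.table.loc[list(sites)]
    geo = squareform(pdist(t[["x", "y"]].to_numpy(dtype=float)))
    elev = np.abs(np.subtract.outer(t["elevation"].to_numpy(float), t["elevation"].to_numpy(float)))
    out = {
        "geographic": pd.DataFrame(geo, index=sites, columns=sites),
        "elevational": pd.DataFrame(elev, index=sites, columns=sites),
    }
    if meta.habitat_columns:
        hv = t[meta.habitat_columns].to_numpy(dtype=float)
        if ((hv < 0) | (hv > 1)).any():
            raise ValueError("habitat cover proportions outside [0, 1]")
        hab = squareform(pdist(np.arcsin(np.sqrt(hv))))
        out["habitat"] = pd.DataFrame(hab, index=sites, columns=sites)
    return out


def _lower(m: np.ndarray) -> np.ndarray:
    i, j = np.tril_indices(m.shape[0], k=-1)
    return m[i, j]


def _ols_stats(X: np.ndarray, y: np.ndarray, XtXi: np.ndarray):
    beta = XtXi @ (X.T @ y)
    r = y - X @ beta
    rss = float(r @ r)
    df = X.shape[0] - X.shape[1]
    s2 = rss / df if df > 0 else np.nan
    se = np.sqrt(np.maximum(np.diag(XtXi) * s2, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    return beta, se, t, r2


def mrm(
    response: pd.DataFrame,
    predictors: dict[str, pd.DataFrame],
    n_perm: int = 999,
    seed: int | np.random.Generator | None = None,
    exhaustive_max: int = 5,
) -> MrmResult:
    """Multiple regression on distance matrices.

    OLS on vectorized lower triangles; the permutation null jointly permutes
    rows and columns of the *response* matrix, refits, and compares |t| per
    slope and R² for the overall fit: p = (1 + #{perm ≥ obs}) / (n_perm + 1).
    With ≤ ``exhaustive_max`` objects all permutations are enumerated.
    """
    names = list(predictors)
    R = response.to_numpy(dtype=float)
    n = R.shape[0]
    if n < 4:
        raise ValueError("need >= 4 sites for MRM")
    cols = []
    for nm in names:
        v = _lower(predictors[nm].to_numpy(dtype=float))
        if np.ptp(v) == 0:
            raise ValueError(f"constant predictor {nm!r}: slope undefined")
        cols.append(v)
    X = np.c_[np.ones(len(cols[0])), np.column_stack(cols)]
    XtXi = np.linalg.inv(X.T @ X)
    y = _lower(R)
    beta, se, tobs, r2_obs = _ols_stats(X, y, XtXi)

    il, jl = np.tril_indices(n, k=-1)
    if n <= exhaustive_max:
        perms = list(permutations(range(n)))[1:]
        n_eff = len(perms)
    else:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        perms = [rng.permutation(n) for _ in range(n_perm)]
        n_eff = n_perm
    ge_t = np.zeros(X.shape[1])
    ge_r2 = 0
    for p in perms:
        p = np.asarray(p)
        yp = R[np.ix_(p, p)][il, jl]
        _, _, tp, r2p = _ols_stats(X, yp, XtXi)
        ge_t += np.abs(tp) >= np.abs(tobs) - 1e-12
        ge_r2 += r2p >= r2_obs - 1e-12
    p_slopes = (1.0 + ge_t) / (n_eff + 1.0)
    p_r2 = (1.0 + ge_r2) / (n_eff + 1.0)
    return MrmResult(beta, se, tobs, r2_obs, p_slopes, p_r2, n_eff, ["intercept"] + names)


def turnover_responses(
    occ: OccurrenceMatrix,
    meta: SiteMetadata,
    family: str,
    n_perm: int = 999,
    seed: int | None = None,
    alpha: float = 0.05,
) -> dict:
    """The six per-family turnover responses.

    Slope_xy / Slope_z / Slope_hab and their SEs come from one multiple MRM
    of Sørensen dissimilarity on all three predictors; R²_xy / R²_z / R²_hab
    come from three separate single-predictor MRMs, reported as 0 when the
    fit is not significant (permutation p ≥ ``alpha``).
    """
    sub = occ.family_submatrix(family)
    present = sub.sum(axis=1) > 0
    sub = sub.loc[present]
    beta_mat = sorensen_matrix(sub)
    dists = site_distance_matrices(meta, list(sub.index))
    key = {"geographic": "xy", "elevational": "z", "habitat": "hab"}
    rng = np.random.default_rng(seed)
    joint = mrm(beta_mat, dists, n_perm=n_perm, seed=rng)
    out = {"family": family, "n_sites": int(present.sum())}
    for nm, short in key.items():
        if nm not in dists:
            continue
        out[f"slope_{short}"] = joint.slope(nm)
        out[f"se_{short}"] = joint.se(nm)
        out[f"p_slope_{short}"] = joint.p(nm)
        single = mrm(beta_mat, {nm: dists[nm]}, n_perm=n_perm, seed=rng)
        out[f"r2_{short}"] = single.r2 if single.p_r2 < alpha else 0.0
        out[f"p_r2_{short}"] = single.p_r2
    return out
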