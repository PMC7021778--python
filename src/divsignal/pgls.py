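"""Generalized least squares with optional BM correlation and variance
weights, plus AICc-based model selection.

Regressions of diversity responses on family traits can absorb phylogenetic
dependence through a Brownian-motion correlation structure (the BM
covariance scaled to unit diagonal) and down-weight imprecise response
estimates through relative variance weights.  The residual covariance is

    Σ = σ² · W^{1/2} V W^{1/2}

with V the BM correlation (or identity) and W the normalized variance
weights.  Fits are by maximum likelihood so AICc comparisons across
fixed-effect structures remain valid; candidate models (all predictor
subsets × {no correlation, BM}) are ranked by AICc with Akaike weights, and
models within 3 AICc of the best are flagged as equally supported.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

from .phylo import bm_covariance

__all__ = ["GlsFit", "gls_fit", "model_selection"]


@dataclass
class GlsFit:
    params: pd.Series
    ses: pd.Series
    pvalues: pd.Series
    lnl: float
    k: int  # parameters counted for AICc (coefficients + sigma2)
    n: int
    aicc: float
    correlation: str  # "none" or "BM"
    weighted: bool
    sigma2: float


def _bm_correlation(tree, labels) -> np.ndarray:
    C = bm_covariance(tree, labels).to_numpy() if isinstance(tree, dendropy.Tree) else np.asarray(tree, float)
    d = np.sqrt(np.diag(C))
    return C / np.outer(d, d)


def gls_fit(
    y: pd.Series,
    X: pd.DataFrame,
    tree=None,
    weights: pd.Series | None = None,
    correlation: str = "none",
) -> GlsFit:
    """ML generalized least squares on family-level data.

    ``weights`` are relative residual variances (e.g. squared SEs of the
    response), normalized internally to mean 1; zeros are floored.  With
    ``correlation="BM"`` the residual correlation follows the tree.
    """
    labels = list(y.index)
    yv = y.to_numpy(dtype=float)
    Xm = X.loc[labels].to_numpy(dtype=float)
    names = list(X.columns)
    n, p = Xm.shape
    if np.linalg.matrix_rank(Xm) < p:
        raise ValueError("singular design matrix")
    if correlation == "BM":
        if tree is None:
            raise ValueError("BM correlation requires a tree")
        V = _bm_correlation(tree, labels)
    elif correlation == "none":
        V = np.eye(n)
    else:
        raise ValueError(f"unknown correlation {correlation!r}")
    if weights is not None:
        w = weights.loc[labels].to_numpy(dtype=float).copy()
        floor = 1e-8 * max(w.mean(), 1e-300)
        if (w <= 0).any():
            import warnings

            warnings.warn("zero variance weights floored", stacklevel=2)
            w = np.maximum(w, floor)
        w = w / w.mean()
        sw = np.sqrt(w)
        Sigma0 = V * np.outer(sw, sw)
    else:
        Sigma0 = V

    Si = np.linalg.inv(Sigma0)
    XtSi = Xm.T @ Si
    A = XtSi @ Xm
    beta = np.linalg.solve(A, XtSi @ yv)
    r = yv - Xm @ beta
    q = float(r @ Si @ r)
    sigma2 = q / n
    if sigma2 <= 0:
        raise ValueError("zero residual variance")
    sign, logdet = np.linalg.slogdet(Sigma0)
    lnl = -0.5 * (n * np.log(2 * np.pi * sigma2) + n + logdet)
    covb = sigma2 * np.linalg.inv(A)
    ses = np.sqrt(np.diag(covb))
    df = max(n - p, 1)
    tvals = beta / ses
    pvals = 2 * stats.t.sf(np.abs(tvals), df)
    k = p + 1
    if n - k - 1 > 0:
        aicc = -2 * lnl + 2 * k + 2 * k * (k + 1) / (n - k - 1)
    else:
        aicc = np.inf
    return GlsFit(
        params=pd.Series(beta, index=names),
        ses=pd.Series(ses, index=names),
        pvalues=pd.Series(pvals, index=names),
        lnl=float(lnl),
        k=k,
        n=n,
        aicc=float(aicc),
        correlation=correlation,
        weighted=weights is not None,
        sigma2=float(sigma2),
    )


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    if p < 0.10:
        return "."
    return ""


def model_selection(
    y: pd.Series,
    candidates: pd.DataFrame,
    tree=None,
    weights: pd.Series | None = None,
    delta_support: float = 3.0,
) -> pd.DataFrame:
    """Rank all predictor subsets × correlation structures by AICc.

    Enumerates the intercept-only model and every subset of the candidate
    predictors, each with and without the BM correlation (when a tree is
    supplied).  Returns a table with lnL, AICc, ΔAICc, Akaike weights, the
    equally-supported flag (ΔAICc < ``delta_support``) and annotated
    significant coefficients.
    """
    preds = list(candidates.columns)
    structures = ["none", "BM"] if tree is not None else ["none"]
    rows = []
    for r in range(len(preds) + 1):
        for subset in combinations(preds, r):
            X = pd.DataFrame({"intercept": np.ones(len(y))}, index=y.index)
            for pname in subset:
                X[pname] = candidates.loc[y.index, pname]
            for corr in structures:
                if len(y) - (X.shape[1] + 1) - 1 <= 0:
                    continue  # AICc undefined for this size
                try:
                    fit = gls_fit(y, X, tree=tree, weights=weights, correlation=corr)
                except (ValueError, np.linalg.LinAlgError):
                    continue
                coef_txt = " + ".join(
                    f"{nm} ({fit.params[nm]:.3g}{_stars(fit.pvalues[nm])})"
                    for nm in subset
                ) or "(intercept only)"
                if corr == "BM":
                    coef_txt += "; BM"
                rows.append(
                    dict(
                        predictors=",".join(subset),
                        correlation=corr,
                        label=coef_txt,
                        k=fit.k,
                        lnl=fit.lnl,
                        aicc=fit.aicc,
                    )
                )
    tab = pd.DataFrame(rows)
    tab["delta_aicc"] = tab["aicc"] - tab["aicc"].min()
    rel = np.exp(-0.5 * tab["delta_aicc"])
    tab["akaike_weight"] = rel / rel.sum()
    tab["supported"] = tab["delta_aicc"] < delta_support
    return tab.sort_values("aicc").reset_index(drop=True)
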