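"""Phylogenetic-signal statistics for family-level variables.

Two complementary routes detect whether families with similar diversity
responses are also close on the phylogeny:

* **Blomberg's K** — the ratio of the tip variance around the phylogenetic
  mean to the BM-expected error variance, normalized so E[K] = 1 under
  Brownian motion and K ≈ 0 under phylogenetic independence.  Significance
  by tip shuffling.  Known measurement error (SEs) can be absorbed by first
  estimating the BM rate under BM + error and inflating the covariance.
* **Fritz–Purvis D** — signal in a binary trait (here widespread vs rare
  families), scaling the observed sum of sister-clade differences between
  the expectation under random shuffling (D = 1) and under thresholded
  Brownian motion (D = 0).
* **Distance regression** — pairwise response dissimilarities (Cohen's d
  when SEs exist, raw absolute differences otherwise) regressed on patristic
  distances, with label-permutation inference.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import dendropy
import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .phylo import bm_covariance, tip_labels

__all__ = [
    "KResult",
    "DResult",
    "DistRegResult",
    "blomberg_k",
    "d_statistic",
    "effect_size_matrix",
    "signal_distance_regression",
]


@dataclass
class KResult:
    k: float
    p: float
    n_perm: int
    used_se: bool
    sigma2: float | None = None  # BM rate estimated when SEs supplied


@dataclass
class DResult:
    d: float
    p_random: float  # P(shuffled sum <= observed): departure from random
    p_brownian: float  # P(BM sum >= observed): departure from BM
    n_perm: int


@dataclass
class DistRegResult:
    slope: float
    intercept: float
    r2: float
    p: float
    kind: str
    n_perm: int


# ---------------------------------------------------------------------------
# Blomberg's K


def _k_ratio(y: np.ndarray, Ci: np.ndarray, denom_expect: float, one_Ci_one: float) -> float:
    n = len(y)
    onei = Ci.sum(axis=0)
    mu = float(onei @ y / one_Ci_one)
    r = y - mu
    mse0 = float(r @ r) / (n - 1)
    mse = float(r @ Ci @ r) / (n - 1)
    return (mse0 / mse) / denom_expect


def blomberg_k(
    values,
    tree: dendropy.Tree,
    se=None,
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = None,
    labels: list[str] | None = None,
) -> KResult:
    """Blomberg's K with optional measurement error, permutation p-value.

    K = (MSE0/MSE) / E[MSE0/MSE] with MSE0 the mean squared deviation of
    tip values from the phylogenetic (GLS) mean, MSE the BM-standardized
    error variance, and E[·] = (tr C − n/(1ᵀC⁻¹1))/(n − 1).  With SEs, the
    BM rate σ² is first estimated by ML under σ²C + diag(se²) and K is
    computed on the error-inflated covariance C + diag(se²)/σ².  p is the
    proportion of tip-shuffled datasets whose variance ratio is at least
    the observed one.
    """
    if labels is None:
        if hasattr(values, "keys"):
            labels = list(values.keys())
        elif isinstance(tree, dendropy.Tree):
            labels = tip_labels(tree)
        else:
            labels = list(range(len(values)))
    y = (
        np.array([values[l] for l in labels], dtype=float)
        if hasattr(values, "keys")
        else np.asarray(values, dtype=float)
    )
    n = len(y)
    if n < 4:
        raise ValueError("need >= 4 tips")
    if np.ptp(y) == 0:
        raise ValueError("constant values: K undefined")
    if n_perm < 99:
        import warnings

        warnings.warn("fewer than 99 permutations: p-value is coarse", stacklevel=2)
    C = bm_covariance(tree, labels).to_numpy() if isinstance(tree, dendropy.Tree) else np.asarray(tree, float)

    se_arr = None
    sigma2 = None
    if se is not None:
        se_arr = (
            np.array([se[l] for l in labels], dtype=float)
            if hasattr(se, "keys")
            else np.asarray(se, dtype=float)
        )
        if np.any(se_arr > 0):
            sigma2 = _ml_bm_rate(y, C, se_arr**2)
            C = C + np.diag(se_arr**2) / sigma2

    Ci = np.linalg.inv(C)
    one_Ci_one = float(Ci.sum())
    denom = (np.trace(C) - n / one_Ci_one) / (n - 1)
    k_obs = _k_ratio(y, Ci, denom, one_Ci_one)

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ge = 0
    for _ in range(n_perm):
        ge += _k_ratio(rng.permutation(y), Ci, denom, one_Ci_one) >= k_obs - 1e-12
    p = (1.0 + ge) / (n_perm + 1.0)
    return KResult(float(k_obs), float(p), n_perm, se_arr is not None, sigma2)


def _ml_bm_rate(y: np.ndarray, C: np.ndarray, se2: np.ndarray) -> float:
    n = len(y)
    one = np.ones(n)

    def neg(logs2):
        s2 = np.exp(logs2)
        V = s2 * C + np.diag(se2)
        sign, logdet = np.linalg.slogdet(V)
        if sign <= 0:
            return np.inf
        Vi = np.linalg.inv(V)
        mu = float(one @ Vi @ y / (one @ Vi @ one))
        r = y - mu
        return 0.5 * (n * np.log(2 * np.pi) + logdet + float(r @ Vi @ r))

    ref = np.log(max(np.var(y), 1e-12) / np.mean(np.diag(C)))
    res = minimize_scalar(neg, bounds=(ref - 20, ref + 6), method="bounded",
                          options={"xatol": 1e-10})
    return float(np.exp(res.x))


# ---------------------------------------------------------------------------
# Fritz–Purvis D


class _SisterSum:
    """Sum over internal nodes of |differences| between child values, with
    each node valued at the mean of its children (downpass averaging).

    The postorder structure is compiled once so repeated evaluation over
    shuffled/simulated tip values stays cheap.
    """

    def __init__(self, tree: dendropy.Tree, labels: list[str]):
        order: list[tuple[int, tuple[int, ...]]] = []
        index = {l: i for i, l in enumerate(labels)}
        slot = {}
        nxt = len(labels)
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                slot[node] = index[node.taxon.label]
            else:
                kids = tuple(slot[c] for c in node.child_nodes())
                slot[node] = nxt
                order.append((nxt, kids))
                nxt += 1
        self.order = order
        self.size = nxt

    def __call__(self, tips: np.ndarray) -> float:
        vals = np.empty(self.size)
        vals[: len(tips)] = tips
        total = 0.0
        for dst, kids in self.order:
            ch = [vals[k] for k in kids]
            for a in range(len(ch)):
                for b in range(a + 1, len(ch)):
                    total += abs(ch[a] - ch[b])
            vals[dst] = sum(ch) / len(ch)
        return total


def _sister_sum(tree: dendropy.Tree, tip_values: dict) -> float:
    labels = list(tip_values)
    f = _SisterSum(tree, labels)
    return f(np.array([tip_values[l] for l in labels], dtype=float))


def d_statistic(
    values,
    tree: dendropy.Tree,
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> DResult:
    """Fritz–Purvis D for a binary trait on the tree.

    D = (d_obs − mean d_B) / (mean d_R − mean d_B), where d_R comes from tip
    shuffles and d_B from Brownian simulations thresholded to the observed
    prevalence.  D ≈ 1 for phylogenetically random traits, ≈ 0 for traits as
    clumped as thresholded BM, < 0 for extreme clumping.
    """
    labels = list(values.keys()) if hasattr(values, "keys") else tip_labels(tree)
    y = np.array(
        [values[l] for l in labels] if hasattr(values, "keys") else values, dtype=float
    )
    k1 = int(y.sum())
    n = len(y)
    if k1 == 0 or k1 == n:
        raise ValueError("D undefined: trait has a single state")
    ssum = _SisterSum(tree, labels)
    d_obs = ssum(y)

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    d_r = np.empty(n_perm)
    for i in range(n_perm):
        d_r[i] = ssum(rng.permutation(y))

    C = bm_covariance(tree, labels).to_numpy()
    L = np.linalg.cholesky(C + 1e-12 * np.trace(C) / n * np.eye(n))
    d_b = np.empty(n_perm)
    for i in range(n_perm):
        z = L @ rng.standard_normal(n)
        thr = np.sort(z)[n - k1]  # top-k1 tips become state 1
        d_b[i] = ssum((z >= thr).astype(float))

    mean_r, mean_b = float(d_r.mean()), float(d_b.mean())
    d_stat = (d_obs - mean_b) / (mean_r - mean_b)
    p_random = float((1 + np.sum(d_r <= d_obs + 1e-12)) / (n_perm + 1))
    p_brownian = float((1 + np.sum(d_b >= d_obs - 1e-12)) / (n_perm + 1))
    return DResult(float(d_stat), p_random, p_brownian, n_perm)


# ---------------------------------------------------------------------------
# effect sizes and distance regression


def effect_size_matrix(
    values, se=None, kind: str = "cohens_d", labels: list[str] | None = None
) -> pd.DataFrame:
    """Pairwise family dissimilarities in a response variable.

    ``cohens_d``: |x_i − x_j| / sqrt((se_i² + se_j²)/2) — a standardized
    effect size usable when each family estimate carries an SE.
    ``raw_difference``: |x_i − x_j| for error-free variables (Edf, R²).
    """
    if hasattr(values, "keys"):
        labels = list(values.keys()) if labels is None else labels
        x = np.array([values[l] for l in labels], dtype=float)
    else:
        x = np.asarray(values, dtype=float)
        labels = list(range(len(x))) if labels is None else labels
    diff = np.abs(np.subtract.outer(x, x))
    if kind == "raw_difference":
        out = diff
    elif kind == "cohens_d":
        if se is None:
            raise ValueError("cohens_d requires SEs")
        s = (
            np.array([se[l] for l in labels], dtype=float)
            if hasattr(se, "keys")
            else np.asarray(se, dtype=float)
        )
        pooled = np.sqrt((np.add.outer(s**2, s**2)) / 2.0)
        if np.any(pooled[~np.eye(len(x), dtype=bool)] == 0):
            raise ValueError("both SEs zero for some pair: Cohen's d undefined")
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(pooled > 0, diff / pooled, 0.0)
    else:
        raise ValueError(f"unknown kind {kind!r}")
    np.fill_diagonal(out, 0.0)
    return pd.DataFrame(out, index=labels, columns=labels)


def signal_distance_regression(
    dissimilarity: pd.DataFrame,
    patristic: pd.DataFrame,
    n_perm: int = 999,
    seed: int | np.random.Generator | None = None,
    kind: str = "cohens_d",
    exhaustive_max: int = 5,
) -> DistRegResult:
    """OLS of pairwise dissimilarities on patristic distances, with a
    permutation null that relabels families on the dissimilarity matrix.

    Two-sided p on the slope; with ≤ ``exhaustive_max`` families the
    permutation null is enumerated exactly.
    """
    labels = list(dissimilarity.index)
    D = dissimilarity.loc[labels, labels].to_numpy(dtype=float)
    P = patristic.loc[labels, labels].to_numpy(dtype=float)
    n = len(labels)
    if n < 4:
        raise ValueError("need >= 4 families")
    il, jl = np.tril_indices(n, k=-1)
    xv = P[il, jl]
    if np.ptp(xv) == 0:
        raise ValueError("constant patristic distances")
    yv = D[il, jl]
    X = np.c_[np.ones(len(xv)), xv]
    XtXi = np.linalg.inv(X.T @ X)
    beta = XtXi @ (X.T @ yv)
    r = yv - X @ beta
    tss = float(((yv - yv.mean()) ** 2).sum())
    r2 = 1.0 - float(r @ r) / tss if tss > 0 else 0.0
    slope_obs = beta[1]

    if n <= exhaustive_max:
        perms = list(permutations(range(n)))[1:]
    else:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        perms = [rng.permutation(n) for _ in range(n_perm)]
    ge = 0
    for p in perms:
        p = np.asarray(p)
        yp = D[np.ix_(p, p)][il, jl]
        b = XtXi @ (X.T @ yp)
        ge += abs(b[1]) >= abs(slope_obs) - 1e-12
    pval = (1.0 + ge) / (len(perms) + 1.0)
    return DistRegResult(
        float(slope_obs), float(beta[0]), float(r2), float(pval), kind, len(perms)
    )
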