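import math
from itertools import permutations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from divsignal import beta
from divsignal.data_model import SiteMetadata


def _sym(df_vals, labels):
    m = np.asarray(df_vals, dtype=float)
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0)
    return pd.DataFrame(np.abs(m), index=labels, columns=labels)


class TestSorensen:
    def test_half_shared_formula(self):
        sub = pd.DataFrame(
            {"s1": [1, 0], "s2": [1, 1], "s3": [0, 1]}, index=["A", "B"]
        )
        d = beta.sorensen_matrix(sub)
        # one shared, one unique each: (1+1)/(2*1+1+1)
        assert d.loc["A", "B"] == pytest.approx(0.5)

    def test_identical_and_disjoint_endpoints(self):
        same = pd.DataFrame({"s1": [1, 1], "s2": [1, 1]}, index=["A", "B"])
        assert beta.sorensen_matrix(same).loc["A", "B"] == 0.0
        disj = pd.DataFrame({"s1": [1, 0], "s2": [0, 1]}, index=["A", "B"])
        assert beta.sorensen_matrix(disj).loc["A", "B"] == 1.0

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**30))
    def test_invariant_under_species_permutation(self, seed):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(rng.integers(0, 2, (5, 8)))
        X = X.loc[:, X.sum() >= 0]
        X = X[(X.sum(axis=1) > 0)]
        if X.shape[0] < 2:
            return
        d1 = beta.sorensen_matrix(X)
        d2 = beta.sorensen_matrix(X.sample(frac=1, axis=1, random_state=0))
        assert np.allclose(d1.to_numpy(), d2.to_numpy())


class TestSiteDistances:
    def test_elevational_is_absolute_difference(self, toy_metadata):
        d = beta.site_distance_matrices(toy_metadata, ["s1", "s2"])
        assert d["elevational"].loc["s1", "s2"] == pytest.approx(300.0)

    def test_arcsine_habitat_closed_form(self):
        tab = pd.DataFrame(
            {"x": [0.0, 0], "y": [0.0, 0], "elevation": [0.0, 0],
             "habitat_h": [0.25, 1.0]},
            index=["a", "b"],
        )
        d = beta.site_distance_matrices(SiteMetadata(tab), ["a", "b"])
        assert d["habitat"].loc["a", "b"] == pytest.approx(math.pi / 3)

    def test_identical_habitat_vectors_distance_zero(self, toy_metadata):
        tab = toy_metadata.table.copy()
        tab.loc[:, ["habitat_forest", "habitat_grass"]] = 0.5
        d = beta.site_distance_matrices(SiteMetadata(tab), list(tab.index))
        assert np.allclose(d["habitat"].to_numpy(), 0)


class TestMrm:
    def test_exact_linear_relation_recovered(self):
        labels = list("abcdef")
        rng = np.random.default_rng(0)
        P = _sym(rng.uniform(0, 5, (6, 6)), labels)
        R = 2.0 * P
        res = beta.mrm(R, {"p": P}, n_perm=99, seed=1)
        assert res.slope("p") == pytest.approx(2.0)
        assert res.r2 == pytest.approx(1.0)
        assert res.p("p") == min(res.p_slopes[1:])  # minimum attainable

    def test_coefficients_match_vectorized_ols(self):
        labels = [f"s{i}" for i in range(8)]
        rng = np.random.default_rng(2)
        P1 = _sym(rng.uniform(0, 5, (8, 8)), labels)
        P2 = _sym(rng.uniform(0, 5, (8, 8)), labels)
        R = _sym(rng.uniform(0, 2, (8, 8)), labels)
        res = beta.mrm(R, {"p1": P1, "p2": P2}, n_perm=49, seed=3)
        i, j = np.tril_indices(8, k=-1)
        X = np.c_[np.ones(len(i)), P1.to_numpy()[i, j], P2.to_numpy()[i, j]]
        b, *_ = np.linalg.lstsq(X, R.to_numpy()[i, j], rcond=None)
        assert np.allclose(res.slopes, b)

    def test_permutation_p_matches_full_enumeration(self):
        labels = list("wxyz")
        rng = np.random.default_rng(4)
        P = _sym(rng.uniform(0, 5, (4, 4)), labels)
        R = _sym(P.to_numpy() + rng.normal(0, 1, (4, 4)), labels)
        res = beta.mrm(R, {"p": P}, seed=0)
        # independent enumeration of all 4! row/column permutations
        i, j = np.tril_indices(4, k=-1)
        X = np.c_[np.ones(len(i)), P.to_numpy()[i, j]]
        XtXi = np.linalg.inv(X.T @ X)

        def tstat(yv):
            bhat = XtXi @ (X.T @ yv)
            r = yv - X @ bhat
            s2 = (r @ r) / (len(yv) - 2)
            return bhat[1] / np.sqrt(s2 * XtXi[1, 1])

        t_obs = tstat(R.to_numpy()[i, j])
        Rm = R.to_numpy()
        count = sum(
            abs(tstat(Rm[np.ix_(p, p)][i, j])) >= abs(t_obs) - 1e-12
            for p in permutations(range(4))
            if p != tuple(range(4))
        )
        assert res.p_slopes[1] == pytest.approx((1 + count) / 24)

    def test_constant_predictor_flagged(self):
        labels = list("abcd")
        R = _sym(np.random.default_rng(0).uniform(0, 1, (4, 4)), labels)
        flat = pd.DataFrame(1.0 - np.eye(4), index=labels, columns=labels)
        with pytest.raises(ValueError, match="constant predictor"):
            beta.mrm(R, {"flat": flat * 0}, n_perm=9, seed=0)


class TestTurnoverResponses:
    def test_elevation_only_decay_detected(self, study):
        occ, meta = study["occ"], study["meta"]
        fam = occ.families[0]
        out = beta.turnover_responses(occ, meta, fam, n_perm=199, seed=5)
        assert out["slope_z"] > 0
        assert out["p_slope_z"] < 0.05
        assert set(out) >= {"slope_xy", "slope_z", "slope_hab", "r2_xy", "r2_z", "r2_hab"}

    def test_null_r2_zeroed(self):
        # response unrelated to all predictors -> R2 reported as 0 usually
        rng = np.random.default_rng(6)
        hits = 0
        n = 15
        labels = [f"s{i}" for i in range(n)]
        for rep in range(20):
            R = _sym(rng.uniform(0, 1, (n, n)), labels)
            P = _sym(rng.uniform(0, 1, (n, n)), labels)
            res = beta.mrm(R, {"p": P}, n_perm=99, seed=rng)
            if res.p_r2 >= 0.05:
                hits += 1
        assert hits >= 16  # >= ~90% of null replicates give a non-significant fit
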