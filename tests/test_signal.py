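import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from divsignal import phylo, signal, synthetic
from divsignal.phylo import bm_covariance, tip_labels


class TestBlombergK:
    def test_four_tip_linear_algebra_oracle(self):
        tree = synthetic.simulate_tree(4, 100.0, seed=1)
        labels = tip_labels(tree)
        rng = np.random.default_rng(2)
        y = rng.normal(0, 1, 4)
        res = signal.blomberg_k(dict(zip(labels, y)), tree, n_perm=99, seed=3)
        C = bm_covariance(tree, labels).to_numpy()
        Ci = np.linalg.inv(C)
        one = np.ones(4)
        mu = one @ Ci @ y / (one @ Ci @ one)
        mse0 = (y - mu) @ (y - mu) / 3
        mse = (y - mu) @ Ci @ (y - mu) / 3
        expected = (np.trace(C) - 4 / (one @ Ci @ one)) / 3
        assert res.k == pytest.approx((mse0 / mse) / expected, abs=1e-12)

    def test_affine_invariance(self, tree10):
        labels = tip_labels(tree10)
        rng = np.random.default_rng(4)
        y = rng.normal(5, 2, 10)
        k1 = signal.blomberg_k(dict(zip(labels, y)), tree10, n_perm=99, seed=0)
        k2 = signal.blomberg_k(dict(zip(labels, 3 * y - 7)), tree10, n_perm=99, seed=0)
        assert k2.k == pytest.approx(k1.k, rel=1e-10)

    def test_matches_phytools_oracle(self, tree10, tmp_path):
        """Independent cross-check against R phytools::phylosig."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript unavailable")
        labels = tip_labels(tree10)
        rng = np.random.default_rng(5)
        y = synthetic.simulate_bm_traits(tree10, 2.0, 1.0, 1, seed=6).iloc[0]
        se = rng.uniform(0.3, 0.8, 10)
        res = signal.blomberg_k(y.to_dict(), tree10, n_perm=99, seed=7)
        res_se = signal.blomberg_k(
            y.to_dict(), tree10, se=dict(zip(labels, se)), n_perm=99, seed=7
        )
        (tmp_path / "t.nwk").write_text(phylo.write_newick(tree10))
        pd.DataFrame({"y": y[labels], "se": se}, index=labels).to_csv(tmp_path / "v.csv")
        script = (
            'suppressMessages(library(phytools));'
            'tr <- read.tree("t.nwk"); d <- read.csv("v.csv", row.names=1);'
            'y <- setNames(d$y, rownames(d)); se <- setNames(d$se, rownames(d));'
            'cat(phylosig(tr, y, method="K"), phylosig(tr, y, method="K", se=se)$K, "\\n")'
        )
        out = subprocess.run(
            ["Rscript", "-e", script], cwd=tmp_path, capture_output=True, text=True,
            timeout=120,
        )
        k_plain, k_se = map(float, out.stdout.split())
        assert res.k == pytest.approx(k_plain, abs=1e-6)
        assert res_se.k == pytest.approx(k_se, abs=0.01)

    def test_null_p_roughly_uniform(self, tree10):
        labels = tip_labels(tree10)
        rng = np.random.default_rng(8)
        ps = [
            signal.blomberg_k(
                dict(zip(labels, rng.normal(0, 1, 10))), tree10, n_perm=99, seed=rng
            ).p
            for _ in range(100)
        ]
        # under the null, p < 0.25 should occur about a quarter of the time
        frac = np.mean(np.array(ps) < 0.25)
        assert 0.10 < frac < 0.45

    def test_constant_values_rejected(self, tree10):
        with pytest.raises(ValueError):
            signal.blomberg_k(np.ones(10), tree10, n_perm=99, seed=0)


class TestDStatistic:
    def test_scaling_endpoints(self, tree20):
        labels = tip_labels(tree20)
        C = bm_covariance(tree20, labels).to_numpy()
        L = np.linalg.cholesky(C + 1e-9 * np.eye(20))
        rng = np.random.default_rng(9)
        d_bm, d_sh = [], []
        for _ in range(60):
            z = L @ rng.standard_normal(20)
            b = (z >= np.sort(z)[20 - 7]).astype(float)
            d_bm.append(signal.d_statistic(dict(zip(labels, b)), tree20,
                                           n_perm=150, seed=rng).d)
            d_sh.append(signal.d_statistic(dict(zip(labels, rng.permutation(b))),
                                           tree20, n_perm=150, seed=rng).d)
        assert np.mean(d_bm) == pytest.approx(0.0, abs=0.15)
        assert np.mean(d_sh) == pytest.approx(1.0, abs=0.15)

    def test_extreme_clumping_negative(self):
        # perfectly clade-restricted trait on a balanced two-clade tree
        t = phylo.read_newick("((a:1,b:1):3,(c:1,d:1):3);")
        d = signal.d_statistic({"a": 1, "b": 1, "c": 0, "d": 0}, t,
                               n_perm=300, seed=10)
        assert d.d < 0

    def test_single_state_rejected(self, tree10):
        labels = tip_labels(tree10)
        with pytest.raises(ValueError, match="undefined"):
            signal.d_statistic(dict.fromkeys(labels, 1), tree10, n_perm=9, seed=0)


class TestEffectSizes:
    def test_cohens_d_printed_formula(self):
        m = signal.effect_size_matrix([10.0, 20.0], se=[2.0, 2.0])
        assert m.iloc[0, 1] == pytest.approx(5.0)

    def test_raw_difference_and_zero_diagonal(self):
        m = signal.effect_size_matrix([1.0, 4.0, 4.0], kind="raw_difference")
        assert m.iloc[0, 1] == pytest.approx(3.0)
        assert m.iloc[1, 2] == 0.0
        assert (np.diag(m) == 0).all()

    def test_cohens_d_scale_free(self):
        x = np.array([1.0, 2.0, 5.0])
        se = np.array([0.5, 0.8, 0.3])
        m1 = signal.effect_size_matrix(x, se)
        m2 = signal.effect_size_matrix(10 * x, 10 * se)
        assert np.allclose(m1.to_numpy(), m2.to_numpy())

    def test_zero_ses_rejected(self):
        with pytest.raises(ValueError):
            signal.effect_size_matrix([1.0, 2.0], se=[0.0, 0.0])


class TestDistanceRegression:
    def test_exact_proportionality(self):
        labels = list("abcde")
        rng = np.random.default_rng(11)
        m = rng.uniform(10, 100, (5, 5))
        pat = pd.DataFrame((m + m.T) / 2, index=labels, columns=labels)
        np.fill_diagonal(pat.values, 0)
        dis = 0.01 * pat
        res = signal.signal_distance_regression(dis, pat, seed=0)
        assert res.slope == pytest.approx(0.01)
        assert res.r2 == pytest.approx(1.0)
        assert res.p == pytest.approx(1 / 120, abs=1e-9)  # only identity-like perms tie

    def test_matches_vector_ols_oracle(self):
        labels = [f"f{i}" for i in range(7)]
        rng = np.random.default_rng(12)
        m1, m2 = rng.uniform(0, 50, (7, 7)), rng.uniform(0, 2, (7, 7))
        pat = pd.DataFrame((m1 + m1.T) / 2, index=labels, columns=labels)
        dis = pd.DataFrame((m2 + m2.T) / 2, index=labels, columns=labels)
        for m in (pat, dis):
            np.fill_diagonal(m.values, 0)
        res = signal.signal_distance_regression(dis, pat, n_perm=49, seed=13)
        i, j = np.tril_indices(7, k=-1)
        b, *_ = np.linalg.lstsq(
            np.c_[np.ones(len(i)), pat.to_numpy()[i, j]], dis.to_numpy()[i, j], rcond=None
        )
        assert res.intercept == pytest.approx(b[0])
        assert res.slope == pytest.approx(b[1])
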