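import numpy as np
import pandas as pd
import pytest

from divsignal import data_model
from divsignal.data_model import OccurrenceMatrix, read_occurrence


def _write_inputs(tmp_path, matrix_df, tax_rows, meta_df):
    mp = tmp_path / "m.csv"
    tp = tmp_path / "t.csv"
    sp = tmp_path / "s.csv"
    matrix_df.rename_axis("site").to_csv(mp)
    pd.DataFrame(tax_rows, columns=["species", "family"]).to_csv(tp, index=False)
    meta_df.rename_axis("site").to_csv(sp)
    return str(mp), str(tp), str(sp)


@pytest.fixture()
def toy_files(tmp_path):
    inc = pd.DataFrame(
        {"sp1": [0, 1, 1], "sp2": [1, 0, 0], "sp3": [1, 1, 0], "sp4": [0, 0, 1]},
        index=["a", "b", "c"],
    )
    meta = pd.DataFrame(
        {"x": [0.0, 1, 2], "y": [0.0, 1, 2], "elevation": [10.0, 20, 30],
         "habitat_h1": [0.5, 0.5, 0.5]},
        index=["a", "b", "c"],
    )
    tax = [("sp1", "f1"), ("sp2", "f1"), ("sp3", "f2"), ("sp4", "f2")]
    return inc, tax, meta


class TestReadOccurrence:
    def test_identity_read(self, tmp_path, toy_files):
        inc, tax, meta = toy_files
        occ, md = read_occurrence(*_write_inputs(tmp_path, inc, tax, meta))
        assert occ.incidence.shape == (3, 4)
        assert (occ.incidence.to_numpy() == inc.to_numpy()).all()
        assert md.sites == ["a", "b", "c"]

    def test_site_missing_from_metadata_is_named(self, tmp_path, toy_files):
        inc, tax, meta = toy_files
        paths = _write_inputs(tmp_path, inc, tax, meta.drop(index="b"))
        with pytest.raises(ValueError, match="b"):
            read_occurrence(*paths)

    def test_abundance_coerced_to_presence_with_warning(self, tmp_path, toy_files):
        inc, tax, meta = toy_files
        inc = inc.copy()
        inc.loc["a", "sp2"] = 2
        paths = _write_inputs(tmp_path, inc, tax, meta)
        with pytest.warns(UserWarning, match="coerced"):
            occ, _ = read_occurrence(*paths)
        assert occ.incidence.loc["a", "sp2"] == 1

    def test_species_without_taxonomy_is_hard_error(self, tmp_path, toy_files):
        inc, tax, meta = toy_files
        paths = _write_inputs(tmp_path, inc, tax[:-1], meta)
        with pytest.raises(ValueError, match="sp4"):
            read_occurrence(*paths)


class TestFilterFamilies:
    def make(self, occupancies, species_counts, n_sites=60):
        rng = np.random.default_rng(1)
        cols, tax = {}, {}
        for f, (occ_n, nsp) in enumerate(zip(occupancies, species_counts)):
            fam = f"fam{f}"
            sites_occ = rng.choice(n_sites, size=occ_n, replace=False)
            for s in range(nsp):
                v = np.zeros(n_sites, dtype=int)
                # ensure the union of member species covers exactly occ_n sites
                mine = sites_occ[s::nsp]
                if len(mine) == 0:
                    mine = sites_occ[:1]
                v[mine] = 1
                cols[f"{fam}_s{s}"] = v
                tax[f"{fam}_s{s}"] = fam
        inc = pd.DataFrame(cols, index=[f"p{i}" for i in range(n_sites)])
        return OccurrenceMatrix(inc, pd.Series(tax))

    def test_thresholds_are_inclusive(self):
        occ = self.make([50, 49], [5, 6])
        retained, flags = data_model.filter_families(occ, min_plots=50, min_species=5)
        assert retained == ["fam0"]  # 50 plots / 5 species kept
        assert not flags.loc["fam1", "retained"]  # 49 plots excluded

    def test_flags_match_brute_force_counts(self, study):
        occ = study["occ"]
        _, flags = data_model.filter_families(occ, min_plots=10, min_species=2)
        for fam in occ.families:
            sub = occ.incidence[[s for s in occ.species if occ.taxonomy[s] == fam]]
            assert flags.loc[fam, "occupancy"] == int((sub.sum(axis=1) > 0).sum())
            assert flags.loc[fam, "n_species"] == sub.shape[1]

    def test_idempotent_and_monotone_in_thresholds(self, study):
        occ = study["occ"]
        r1, _ = data_model.filter_families(occ, 20, 3)
        r2, _ = data_model.filter_families(occ, 40, 3)
        r3, _ = data_model.filter_families(occ, 20, 8)
        assert set(r2) <= set(r1) and set(r3) <= set(r1)

    def test_empty_matrix_errors(self):
        occ = OccurrenceMatrix(pd.DataFrame(), pd.Series(dtype=object))
        with pytest.raises(ValueError):
            data_model.filter_families(occ)


class TestTraitAggregation:
    def test_body_size_averaged_on_log_scale(self):
        traits = pd.DataFrame({"body_size": [10.0, 100.0]}, index=["a", "b"])
        tax = pd.Series({"a": "f", "b": "f"})
        out = data_model.aggregate_family_traits(traits, tax, ["f"])
        assert out.loc["f", "body_size_mean"] == pytest.approx(
            (np.log(10) + np.log(100)) / 2
        )

    def test_binary_feature_incidence_is_fraction(self):
        traits = pd.DataFrame(
            {"plant_interaction": [1, 1, 1, 0]}, index=list("abcd")
        )
        tax = pd.Series(dict.fromkeys("abcd", "f"))
        out = data_model.aggregate_family_traits(
            traits, tax, ["f"], continuous=[], binary=["plant_interaction"]
        )
        assert out.loc["f", "plant_interaction_incidence"] == pytest.approx(0.75)

    def test_matches_groupby_oracle(self):
        rng = np.random.default_rng(3)
        sp = [f"s{i}" for i in range(30)]
        fams = [f"f{i % 4}" for i in range(30)]
        traits = pd.DataFrame({"wing": rng.normal(10, 2, 30)}, index=sp)
        tax = pd.Series(fams, index=sp)
        out = data_model.aggregate_family_traits(
            traits, tax, sorted(set(fams)), continuous=["wing"], binary=[]
        )
        g = traits.assign(fam=fams).groupby("fam")["wing"]
        exp_mean = g.mean()
        exp_se = g.std(ddof=1) / np.sqrt(g.count())
        assert np.allclose(out["wing_mean"], exp_mean[out.index])
        assert np.allclose(out["wing_se"], exp_se[out.index])

    def test_single_species_family_se_zero_with_warning(self):
        traits = pd.DataFrame({"wing": [5.0]}, index=["a"])
        tax = pd.Series({"a": "f"})
        with pytest.warns(UserWarning, match="single species"):
            out = data_model.aggregate_family_traits(
                traits, tax, ["f"], continuous=["wing"], binary=[]
            )
        assert out.loc["f", "wing_se"] == 0.0


class TestHigherLevelFeatures:
    def test_richness_occupancy_and_flag(self, toy_occurrence):
        feats = data_model.higher_level_features(toy_occurrence, ["famA"])
        assert feats.loc["famA", "richness"] == 2
        # famB members occupy the union of sites s4, s5, s6
        assert feats.loc["famB", "occupancy"] == 3
        assert feats.loc["famA", "widespread"] == 1
        assert feats.loc["famB", "widespread"] == 0

    def test_occupancy_equals_or_of_member_columns(self, study):
        occ = study["occ"]
        feats = data_model.higher_level_features(occ, [])
        for fam in occ.families:
            cols = [s for s in occ.species if occ.taxonomy[s] == fam]
            expected = int(occ.incidence[cols].any(axis=1).sum())
            assert feats.loc[fam, "occupancy"] == expected
        assert feats["richness"].sum() <= len(occ.species)
        assert (feats["occupancy"] <= len(occ.sites)).all()
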