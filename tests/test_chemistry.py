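"""Tests of the blood-chemistry panel: derived quantities and structure."""

import numpy as np
import pandas as pd
import pytest

from dropsig.chemistry import (
    CONDITION_STATS,
    chemistry_pca_centroids,
    condition_correlation_matrices,
    delta_blood_volume,
    hydrogen_ion,
    sample_panel,
    strong_ion_difference,
)


class TestStrongIonDifference:
    def test_resting_means_give_published_value(self):
        row = {"Na": 141.0, "K": 4.0, "Ca": 1.23, "Cl": 105.0, "La": 1.1}
        sid = strong_ion_difference(row)
        assert sid == pytest.approx(40.13)
        assert round(sid) == 40  # the tabulated resting value

    @pytest.mark.parametrize(
        "row,expected",
        [
            ({"Na": 0, "K": 0, "Ca": 0, "Cl": 0, "La": 0}, 0.0),
            ({"Na": 140, "K": 4, "Ca": 1, "Cl": 100, "La": 5}, 40.0),
        ],
    )
    def test_hand_arithmetic(self, row, expected):
        assert strong_ion_difference(row) == pytest.approx(expected)

    def test_linearity(self, rng):
        row = {k: float(v) for k, v in zip("Na K Ca Cl La".split(), rng.random(5) * 100)}
        doubled = {k: 2 * v for k, v in row.items()}
        assert strong_ion_difference(doubled) == pytest.approx(
            2 * strong_ion_difference(row)
        )

    def test_missing_analyte_rejected(self):
        with pytest.raises(KeyError, match="Ca"):
            strong_ion_difference({"Na": 140, "K": 4, "Cl": 100, "La": 1})


class TestHydrogenIon:
    @pytest.mark.parametrize("ph,expected", [(7.0, 100.0), (7.4, 39.81), (6.0, 1000.0)])
    def test_examples(self, ph, expected):
        assert hydrogen_ion(ph) == pytest.approx(expected, rel=1e-3)

    def test_roundtrip_with_ph(self, rng):
        ph = 6.5 + rng.random(20) * 1.5
        h = hydrogen_ion(ph)
        assert np.allclose(9.0 - np.log10(h), ph, rtol=1e-9)


class TestDeltaBloodVolume:
    def test_no_change(self):
        assert delta_blood_volume(15.0, 15.0) == 0.0

    def test_table_means_haemoconcentration(self):
        assert delta_blood_volume(15.4, 16.7) == pytest.approx(-7.78, abs=0.01)

    def test_halved_hb_doubles_volume(self):
        assert delta_blood_volume(14.0, 7.0) == pytest.approx(100.0)

    def test_zero_hb_rejected(self):
        with pytest.raises(ValueError):
            delta_blood_volume(15.0, 0.0)


class TestSamplePanel:
    def test_resting_lactate_moments(self):
        panel = sample_panel(n_participants=10_000, conditions=("baseline",), seed=0)
        la = panel["La"]
        assert la.mean() == pytest.approx(1.1, abs=0.02)
        assert la.std() == pytest.approx(0.4, abs=0.02)

    def test_zero_sd_reproduces_condition_means(self):
        panel = sample_panel(n_participants=5, seed=1, sd_scale=0.0)
        for cond in ("baseline", "peak"):
            grp = panel[panel["condition"] == cond]
            for var in ("La", "Na", "K", "PCO2", "Hb"):
                assert np.allclose(grp[var], CONDITION_STATS[var][cond][0])

    def test_resting_sid_near_forty(self):
        panel = sample_panel(n_participants=2000, conditions=("baseline",), seed=2)
        assert panel["SID"].mean() == pytest.approx(40.13, abs=0.15)

    def test_rest_dbv_is_zero_and_exercise_negative(self):
        panel = sample_panel(n_participants=200, seed=3)
        assert np.allclose(panel[panel["condition"] == "baseline"]["dBV"], 0.0)
        # exercise haemoconcentrates on average (Hb rises)
        assert panel[panel["condition"] == "peak"]["dBV"].mean() < 0


class TestCorrelationMatrices:
    def test_built_in_ph_pco2_coupling_recovered(self):
        panel = sample_panel(n_participants=30, seed=4)
        mats = condition_correlation_matrices(panel)
        r = mats["baseline"].loc["pH", "PCO2"]
        assert r == pytest.approx(-0.8, abs=0.15)

    def test_duplicated_and_negated_columns(self):
        panel = sample_panel(n_participants=20, conditions=("baseline",), seed=5)
        panel["copy"] = panel["Na"]
        panel["neg"] = -panel["Na"]
        mats = condition_correlation_matrices(panel, variables=["Na", "copy", "neg"])
        m = mats["baseline"]
        assert m.loc["Na", "copy"] == pytest.approx(1.0)
        assert m.loc["Na", "neg"] == pytest.approx(-1.0)

    def test_symmetric_positive_semidefinite(self):
        panel = sample_panel(n_participants=30, seed=6)
        for cond, m in condition_correlation_matrices(panel).items():
            vals = m.dropna(axis=0, how="all").dropna(axis=1, how="all")
            arr = vals.to_numpy()
            assert np.allclose(arr, arr.T, atol=1e-12)
            assert np.linalg.eigvalsh(arr).min() >= -1e-10

    def test_too_few_participants_rejected(self):
        panel = sample_panel(n_participants=2, seed=7)
        with pytest.raises(ValueError, match="3 participants"):
            condition_correlation_matrices(panel)


class TestChemistryPCA:
    def test_baseline_and_peak_separate(self):
        from sklearn.metrics import silhouette_score

        panel = sample_panel(n_participants=30, seed=8)
        scores, centroids = chemistry_pca_centroids(panel)
        two = scores[scores["condition"].isin(["baseline", "peak"])]
        sil = silhouette_score(two[["PC1", "PC2"]], two["condition"])
        assert sil > 0
        assert list(centroids.index) == ["baseline", "peak", "rec2", "rec4", "rec6"]

    def test_identical_distributions_coincide(self):
        from dropsig.chemistry import PCA_VARIABLES

        panel = sample_panel(n_participants=400, conditions=("baseline",), seed=9)
        half = len(panel) // 2
        panel = panel.copy()
        panel.loc[panel.index[:half], "condition"] = "first"
        panel.loc[panel.index[half:], "condition"] = "second"
        # dBV is identically zero in a rest-only panel; drop it
        variables = [v for v in PCA_VARIABLES if v != "dBV"]
        _, centroids = chemistry_pca_centroids(panel, variables=variables)
        # same underlying distribution: centroids agree within sampling error
        assert np.linalg.norm(centroids.loc["first"] - centroids.loc["second"]) < 0.5

    def test_zero_variance_guard(self):
        panel = sample_panel(n_participants=1, conditions=("baseline",), seed=10)
        with pytest.raises(ValueError, match="zero-variance"):
            chemistry_pca_centroids(panel)

    def test_missing_variable_rejected(self):
        panel = sample_panel(n_participants=5, seed=11).drop(columns=["Hb"])
        with pytest.raises(KeyError, match="Hb"):
            chemistry_pca_centroids(panel)
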