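"""Barcode calling, metabolite annotation, differential stats and PCA."""

import numpy as np
import pandas as pd
import pytest

from ubibar import calling, deconv, design, spectra
from ubibar.chem import NA_ADDUCT_SHIFT


def dm(mass, intensity=100.0):
    return deconv.DeconvolvedMass(mass, intensity, frozenset({9}), 8)


@pytest.fixture
def lvfyha_library(lvfyha):
    return [design.BarcodeRecord("LVFYHA", lvfyha.full_mass,
                                 lvfyha.met_cleaved_mass, False, 0)]


class TestCallBarcode:
    def test_full_match_at_rank_one(self, lvfyha, lvfyha_library):
        call = calling.call_barcode([dm(lvfyha.full_mass)], lvfyha_library)
        assert call.status == "full_matched"
        assert call.best_barcode == 0
        assert call.matched_rank == 1
        assert call.mass_error == pytest.approx(0.0, abs=1e-9)
        assert call.na_count_used == 0

    def test_met_cleaved_match(self, lvfyha, lvfyha_library):
        call = calling.call_barcode([dm(lvfyha.met_cleaved_mass)], lvfyha_library)
        assert call.status == "met_cleaved_matched"
        assert call.best_barcode == 0

    def test_sodium_adduct_match_when_base_absent(self, lvfyha, lvfyha_library):
        call = calling.call_barcode(
            [dm(lvfyha.full_mass + NA_ADDUCT_SHIFT)], lvfyha_library
        )
        assert call.status == "full_matched"
        assert call.na_count_used == 1
        assert call.mass_error == pytest.approx(0.0, abs=1e-9)

    def test_no_form_within_tolerance(self, lvfyha, lvfyha_library):
        masses = [dm(lvfyha.full_mass + 1.0 + 0.5 * i) for i in range(5)]
        call = calling.call_barcode(masses, lvfyha_library)
        assert call.status == "not_matched"
        assert call.best_barcode is None

    def test_empty_top_masses(self, lvfyha_library):
        call = calling.call_barcode([], lvfyha_library)
        assert call.status == "not_matched"
        assert call.diagnostic

    def test_lower_rank_wins_over_smaller_error(self, lvfyha, small_library):
        lib = small_library
        # rank 1 matches entry A with small error; rank 2 would match entry B exactly
        masses = [dm(lib[3].full_mass + 0.02, 100.0), dm(lib[5].full_mass, 50.0)]
        call = calling.call_barcode(masses, lib)
        assert call.best_barcode == lib[3].library_index
        assert call.matched_rank == 1

    def test_full_preferred_over_met_at_equal_rank(self, small_library):
        lib = small_library
        # a mass matching one entry's full and another's met-cleaved form
        collision = [
            design.BarcodeRecord("XAAAAA".replace("X", "L"), 9000.0, 8868.96, False, 0),
            design.BarcodeRecord("GGGGGG", 9131.04, 9000.0, False, 1),
        ]
        call = calling.call_barcode([dm(9000.0)], collision)
        assert call.status == "full_matched"
        assert call.best_barcode == 0

    def test_order_independent_of_library_file_order(self, lvfyha, small_library):
        masses = [dm(small_library[4].full_mass)]
        fwd = calling.call_barcode(masses, small_library)
        rev = calling.call_barcode(masses, list(reversed(small_library)))
        assert fwd.best_barcode == rev.best_barcode
        assert fwd.status == rev.status

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError):
            calling.call_barcode([dm(9000.0)], [])


def make_peaks(mz_height: dict[float, float], polarity="negative"):
    mzs = np.array(sorted(mz_height))
    heights = np.array([mz_height[m] for m in mzs])
    return spectra.PeakList(mz=mzs, height=heights, prominence=heights,
                            polarity=polarity)


@pytest.fixture(scope="module")
def mass_table():
    return calling.load_bundled_metabolite_table()


class TestAnnotation:
    def test_glucose_negative_hit(self, mass_table):
        peaks = make_peaks({179.0561: 2e4})
        hits = calling.annotate_metabolites(None, peaks, mass_table)
        glc = hits[hits.metabolite_id == "glc__D"]
        assert len(glc) == 1
        assert glc.iloc[0]["mode"] == "negative"
        assert abs(glc.iloc[0]["mz_error"]) <= 0.003

    def test_negative_mode_preferred_on_dual_annotation(self, mass_table):
        pos = make_peaks({181.0706: 1e4}, polarity="positive")
        neg = make_peaks({179.0561: 2e4})
        hits = calling.annotate_metabolites(pos, neg, mass_table)
        glc = hits[hits.metabolite_id == "glc__D"]
        assert len(glc) == 1
        assert glc.iloc[0]["mode"] == "negative"
        assert glc.iloc[0]["height"] == pytest.approx(2e4)

    def test_out_of_tolerance_peak_not_annotated(self, mass_table):
        peaks = make_peaks({179.0561 + 0.005: 2e4})
        hits = calling.annotate_metabolites(None, peaks, mass_table)
        assert "glc__D" not in set(hits.metabolite_id)

    def test_isobaric_metabolites_all_retained(self, mass_table):
        # citrate and isocitrate share C6H8O7
        cit_mass = float(mass_table.loc[mass_table.metabolite_id == "cit",
                                        "monoisotopic_mass"].iloc[0])
        peaks = make_peaks({cit_mass - 1.00728: 5e4})
        hits = calling.annotate_metabolites(None, peaks, mass_table)
        assert {"cit", "icit"} <= set(hits.metabolite_id)

    def test_empty_table_warns(self):
        peaks = make_peaks({100.0: 1e4})
        with pytest.warns(UserWarning, match="empty"):
            hits = calling.annotate_metabolites(None, peaks, pd.DataFrame(
                columns=["metabolite_id", "monoisotopic_mass"]))
        assert len(hits) == 0


class TestDifferentialStats:
    def make_matrix(self, case, control, n_rep=3):
        rows = {}
        for i in range(n_rep):
            rows[f"case_{i}"] = case
            rows[f"ctrl_{i}"] = control
        matrix = pd.DataFrame(rows).T
        groups = pd.Series(
            ["case"] * 0 + [g.split("_")[0] for g in matrix.index], index=matrix.index
        )
        return matrix, groups

    def test_identical_groups_fold_change_one(self):
        matrix, groups = self.make_matrix({"m1": 100.0}, {"m1": 100.0})
        res = calling.differential_stats(matrix, groups, "ctrl")
        assert res.iloc[0]["fold_change"] == pytest.approx(1.0)
        assert not res.iloc[0]["significant"]

    def test_sixteen_fold_shift_detected(self):
        rng = np.random.default_rng(42)
        case = {f"m{j}": 1600.0 * (1 + 0.05 * rng.standard_normal()) for j in range(5)}
        rows = {}
        for i in range(3):
            rows[f"case_{i}"] = {k: v * (1 + 0.05 * rng.standard_normal())
                                 for k, v in case.items()}
            rows[f"ctrl_{i}"] = {k: 100.0 * (1 + 0.05 * rng.standard_normal())
                                 for k in case}
        matrix = pd.DataFrame(rows).T
        groups = pd.Series([g.split("_")[0] for g in matrix.index], index=matrix.index)
        res = calling.differential_stats(matrix, groups, "ctrl")
        assert res["significant"].all()
        assert (res["fold_change"] > 4).all()

    def test_decreases_also_significant(self):
        rng = np.random.default_rng(7)
        rows = {}
        for i in range(3):
            rows[f"case_{i}"] = {"m1": 10.0 * (1 + 0.03 * rng.standard_normal())}
            rows[f"ctrl_{i}"] = {"m1": 100.0 * (1 + 0.03 * rng.standard_normal())}
        matrix = pd.DataFrame(rows).T
        groups = pd.Series([g.split("_")[0] for g in matrix.index], index=matrix.index)
        res = calling.differential_stats(matrix, groups, "ctrl")
        assert res.iloc[0]["fold_change"] < 0.25
        assert res.iloc[0]["significant"]

    def test_single_replicate_reports_fc_without_p(self):
        matrix = pd.DataFrame({"case_0": {"m1": 400.0}, "ctrl_0": {"m1": 100.0}}).T
        groups = pd.Series(["case", "ctrl"], index=matrix.index)
        res = calling.differential_stats(matrix, groups, "ctrl")
        assert res.iloc[0]["fold_change"] == pytest.approx(4.0)
        assert np.isnan(res.iloc[0]["p_value"])
        assert not res.iloc[0]["significant"]

    def test_zero_control_mean_flagged(self):
        matrix, groups = self.make_matrix({"m1": 10.0}, {"m1": 0.0})
        res = calling.differential_stats(matrix, groups, "ctrl")
        assert res.iloc[0]["undefined_fc"]
        assert np.isnan(res.iloc[0]["fold_change"])

    def test_missing_values_excluded_pairwise(self):
        matrix = pd.DataFrame(
            {
                "case_0": {"m1": 400.0}, "case_1": {"m1": 400.0},
                "case_2": {"m1": np.nan},
                "ctrl_0": {"m1": 100.0}, "ctrl_1": {"m1": 100.0},
                "ctrl_2": {"m1": 100.0},
            }
        ).T
        groups = pd.Series([g.split("_")[0] for g in matrix.index], index=matrix.index)
        res = calling.differential_stats(matrix, groups, "ctrl")
        assert res.iloc[0]["fold_change"] == pytest.approx(4.0)

    def test_missing_control_group_rejected(self):
        matrix, groups = self.make_matrix({"m1": 1.0}, {"m1": 1.0})
        with pytest.raises(ValueError, match="control"):
            calling.differential_stats(matrix, groups, "nope")

    def test_fdr_adds_q_values(self):
        matrix, groups = self.make_matrix({"m1": 100.0, "m2": 90.0},
                                          {"m1": 100.0, "m2": 100.0})
        res = calling.differential_stats(matrix, groups, "ctrl", fdr=True)
        assert "q_value" in res.columns


class TestPCA:
    def test_duplicated_samples_identical_scores(self):
        rng = np.random.default_rng(3)
        base = rng.lognormal(10, 1, size=8)
        matrix = pd.DataFrame(
            [base, base, base * 4, base * 4],
            index=["a1", "a2", "b1", "b2"],
        )
        scores = calling.pca_scores(matrix)
        np.testing.assert_allclose(scores.loc["a1"], scores.loc["a2"], atol=1e-9)

    def test_shifted_clusters_separate_on_pc1(self):
        rng = np.random.default_rng(5)
        base = rng.lognormal(10, 0.5, size=20)
        rows, labels = [], []
        for i in range(4):
            noise = 1 + 0.02 * rng.standard_normal(20)
            shift = np.ones(20)
            if i >= 2:
                shift[:10] = 16.0  # first pathway strongly up in cluster B
            rows.append(base * shift * noise)
            labels.append("A" if i < 2 else "B")
        matrix = pd.DataFrame(rows, index=[f"s{i}" for i in range(4)])
        scores = calling.pca_scores(matrix)
        from sklearn.metrics import silhouette_score

        sil = silhouette_score(scores[["PC1"]], labels)
        assert sil > 0

    def test_constant_matrix_degenerate(self):
        matrix = pd.DataFrame(np.full((3, 5), 7.0))
        scores = calling.pca_scores(matrix)
        assert np.allclose(scores.attrs["explained_variance"], 0.0)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            calling.pca_scores(pd.DataFrame([[1.0, 2.0]]))
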