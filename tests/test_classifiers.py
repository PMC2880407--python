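import numpy as np
import pytest
from hypothesis import given, strategies as st
from sklearn.base import clone

from idcensus.classifiers import (
    CDFBoundary,
    CDFClassifier,
    CDFCurve,
    CHClassifier,
    DEFAULT_CDF_GRID,
    calibrate_cdf_boundary,
    cdf_curve,
    cdf_distance,
    ch_distance,
    ch_point,
    chcdf_summary,
    classify_ch_cdf,
    classify_proteins,
    load_boundary,
    save_boundary,
)
from idcensus.io import ProteinRecord
from idcensus.scoring import DisorderProfile, score_proteome
from idcensus.simulate import generate_proteome, make_archetype


def profile(scores, pid="p"):
    return DisorderProfile(pid, np.asarray(scores, dtype=float))


def flat_curve(value):
    return CDFCurve(DEFAULT_CDF_GRID.copy(), np.full(20, value))


class TestCdfCurve:
    def test_structured_signature_saturates_immediately(self):
        curve = cdf_curve(profile([0.0] * 50))
        assert np.allclose(curve.values, 1.0)

    def test_disordered_signature_stays_flat_until_one(self):
        curve = cdf_curve(profile([1.0] * 50))
        assert np.allclose(curve.values[:-1], 0.0)
        assert curve.values[-1] == 1.0

    def test_uniform_scores_approximate_identity_ramp(self):
        curve = cdf_curve(profile(np.linspace(0, 1, 2001)))
        assert np.allclose(curve.values, curve.thresholds, atol=0.002)

    @given(
        st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=200)
    )
    def test_monotone_and_terminates_at_one(self, scores):
        curve = cdf_curve(profile(scores))
        assert np.all(np.diff(curve.values) >= 0)
        assert curve.values[-1] == 1.0


class TestBoundary:
    def test_midpoint_of_flat_classes(self):
        boundary = calibrate_cdf_boundary([flat_curve(0.9)], [flat_curve(0.1)])
        assert np.allclose(boundary.boundary_values, 0.5)
        assert boundary.active_bins.all()
        assert boundary.training_accuracy == 1.0

    def test_coincident_classes_inseparable(self):
        with pytest.raises(ValueError, match="classes inseparable"):
            calibrate_cdf_boundary([flat_curve(0.5)], [flat_curve(0.5)])

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError, match="need both classes"):
            calibrate_cdf_boundary([], [flat_curve(0.1)])

    def test_json_round_trip(self, tmp_path):
        boundary = calibrate_cdf_boundary([flat_curve(0.9)], [flat_curve(0.1)])
        path = tmp_path / "boundary.json"
        save_boundary(boundary, path)
        back = load_boundary(path)
        assert np.allclose(back.boundary_values, boundary.boundary_values)
        assert np.array_equal(back.active_bins, boundary.active_bins)


class TestCdfDistance:
    def make_boundary(self):
        return calibrate_cdf_boundary([flat_curve(0.9)], [flat_curve(0.1)])

    def test_curve_on_boundary_is_zero(self):
        boundary = self.make_boundary()
        assert cdf_distance(flat_curve(0.5), boundary) == pytest.approx(0.0)

    def test_offset_curve(self):
        boundary = self.make_boundary()
        assert cdf_distance(flat_curve(0.6), boundary) == pytest.approx(0.1)

    def test_all_zero_protein_is_strictly_ordered(self):
        boundary = self.make_boundary()
        curve = cdf_curve(profile([0.0] * 30))
        assert cdf_distance(curve, boundary) > 0

    def test_grid_mismatch_rejected(self):
        boundary = self.make_boundary()
        other = CDFCurve(np.arange(1, 11) / 10.0, np.linspace(0.1, 1.0, 10))
        with pytest.raises(ValueError, match="incompatible grids"):
            cdf_distance(other, boundary)

    @given(
        st.floats(min_value=0, max_value=1), st.floats(min_value=0, max_value=1)
    )
    def test_antisymmetry(self, a, b):
        grid = DEFAULT_CDF_GRID.copy()
        active = np.ones(20, bool)
        b1 = CDFBoundary(grid, np.full(20, b), active)
        b2 = CDFBoundary(grid, np.full(20, a), active)
        assert cdf_distance(flat_curve(a), b1) == pytest.approx(
            -cdf_distance(flat_curve(b), b2)
        )


class TestChPoint:
    def test_charge_symmetry(self):
        assert ch_point(ProteinRecord("x", "DDKK")).mean_net_charge == 0.0

    def test_poly_glutamate(self):
        point = ch_point(ProteinRecord("x", "E" * 25))
        assert point.mean_net_charge == pytest.approx(1.0, abs=1e-12)
        assert point.mean_hydropathy == pytest.approx((-3.5 + 4.5) / 9, abs=1e-12)

    def test_poly_glycine(self):
        point = ch_point(ProteinRecord("x", "G" * 10))
        assert point.mean_net_charge == 0.0
        assert point.mean_hydropathy == pytest.approx((-0.4 + 4.5) / 9, abs=1e-12)

    def test_ambiguity_codes_excluded(self):
        with_x = ch_point(ProteinRecord("x", "EXE"))
        without = ch_point(ProteinRecord("x", "EE"))
        assert with_x == without

    def test_only_ambiguity_rejected(self):
        with pytest.raises(ValueError, match="no scorable residues"):
            ch_point(ProteinRecord("x", "XXX"))

    @given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=60))
    def test_composition_determined(self, seq):
        shuffled = "".join(sorted(seq))
        a = ch_point(ProteinRecord("a", seq))
        b = ch_point(ProteinRecord("b", shuffled))
        assert a.mean_hydropathy == pytest.approx(b.mean_hydropathy, abs=1e-12)
        assert a.mean_net_charge == pytest.approx(b.mean_net_charge, abs=1e-12)


class TestChDistance:
    def test_default_boundary_arithmetic(self):
        from idcensus.classifiers import CHPoint

        d = ch_distance(CHPoint(0.5, 0.5))
        assert d == pytest.approx(0.5 - (2.785 * 0.5 - 1.151), abs=1e-12)
        assert d == pytest.approx(0.2585, abs=1e-12)

    def test_point_on_line_is_zero(self):
        from idcensus.classifiers import CHPoint

        h = 0.45
        assert ch_distance(CHPoint(h, 2.785 * h - 1.151)) == pytest.approx(0.0)

    def test_poly_glycine_is_ordered_side(self):
        d = ch_distance(ch_point(ProteinRecord("x", "G" * 10)))
        assert d == pytest.approx(-(2.785 * (4.1 / 9) - 1.151), abs=1e-12)
        assert d < 0


class TestQuadrants:
    @pytest.mark.parametrize(
        "cdf_d, ch_d, expected",
        [
            (-0.1, -0.1, "molten_globule_like"),
            (-0.1, 0.1, "extended_disordered"),
            (0.2, -0.3, "ordered"),
            (0.2, 0.3, "ch_disordered_cdf_ordered"),
            (0.0, 0.0, "ch_disordered_cdf_ordered"),
        ],
    )
    def test_sign_semantics(self, cdf_d, ch_d, expected):
        assert classify_ch_cdf(cdf_d, ch_d) == expected


class TestSummary:
    def make_call(self, cdf_d, ch_d, pid="p"):
        from idcensus.classifiers import WholeProteinCall

        return WholeProteinCall(pid, 0.5, 0.2, cdf_d, ch_d, classify_ch_cdf(cdf_d, ch_d))

    def test_single_call(self):
        s = chcdf_summary([self.make_call(0.1, -0.2)])
        assert s["cdf_rmsd"] == 0.0 and s["counts"]["ordered"] == 1

    def test_symmetric_distances(self):
        s = chcdf_summary([self.make_call(0.3, 0.0, "a"), self.make_call(-0.3, 0.0, "b")])
        assert s["cdf_mean"] == pytest.approx(0.0)
        assert s["cdf_rmsd"] == pytest.approx(0.3)

    def test_counts_partition_input(self, rng):
        calls = [
            self.make_call(d, c, f"p{i}")
            for i, (d, c) in enumerate(rng.normal(size=(50, 2)))
        ]
        s = chcdf_summary(calls)
        assert sum(s["counts"].values()) == 50

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="no calls"):
            chcdf_summary([])


class TestEstimators:
    def test_cdf_classifier_separates_synthetic_references(self):
        ordered, _, _ = generate_proteome(
            make_archetype("fo", 0.0), 60, seed=3, species_id="fo"
        )
        disordered, _, _ = generate_proteome(
            make_archetype("fd", 1.0), 60, seed=4, species_id="fd"
        )
        X = list(score_proteome(ordered).values()) + list(
            score_proteome(disordered).values()
        )
        y = ["ordered"] * 60 + ["disordered"] * 60
        clf = clone(CDFClassifier()).fit(X, y)
        assert clf.training_accuracy_ >= 0.95
        assert (clf.decision_function(X[:60]) > 0).mean() >= 0.95

    def test_ch_classifier_on_contrasting_sequences(self):
        charged = ProteinRecord("c", "EEKEDEEKDEEE" * 5)  # net-charged, hydrophilic
        hydrophobic = ProteinRecord("h", "ILVAILVVLAIV" * 5)
        clf = CHClassifier().fit()
        assert clf.predict([charged])[0] == "disordered"
        assert clf.predict([hydrophobic])[0] == "ordered"

    def test_classify_proteins_consistency(self):
        proteome, _, _ = generate_proteome(
            make_archetype("mix", 0.5, 30.0), 20, seed=5, species_id="mix"
        )
        profiles = score_proteome(proteome)
        boundary = calibrate_cdf_boundary([flat_curve(0.9)], [flat_curve(0.1)])
        calls = classify_proteins(proteome, profiles, boundary)
        for call in calls:
            assert call.quadrant == classify_ch_cdf(call.cdf_distance, call.ch_distance)
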