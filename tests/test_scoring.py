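import numpy as np
import pytest
from hypothesis import given, strategies as st
from sklearn.base import clone

from idcensus.io import ProteinRecord, Proteome
from idcensus.scales import AMBIGUITY_CODES, STANDARD_AA, TOP_IDP
from idcensus.scoring import (
    DisorderProfile,
    DisorderScorer,
    PropensityScale,
    TOPIDP_SCALE,
    calibrate_threshold,
    load_scores,
    score_sequence,
    write_scores,
)

VMIN = min(TOP_IDP.values())
VMAX = max(TOP_IDP.values())
MOST_DISORDERED = max(TOP_IDP, key=TOP_IDP.get)  # P under TOP-IDP
MOST_ORDERED = min(TOP_IDP, key=TOP_IDP.get)  # W under TOP-IDP


def rescale(v):
    return (v - VMIN) / (VMAX - VMIN)


class TestScoreSequence:
    def test_max_propensity_homopolymer_scores_one(self):
        rec = ProteinRecord("hi", MOST_DISORDERED * 40)
        assert np.allclose(score_sequence(rec, window=21).scores, 1.0)

    def test_min_propensity_homopolymer_scores_zero(self):
        rec = ProteinRecord("lo", MOST_ORDERED * 40)
        assert np.allclose(score_sequence(rec, window=21).scores, 0.0)

    def test_window_one_equals_rescaled_propensity(self):
        seq = "MKP"
        prof = score_sequence(ProteinRecord("x", seq), window=1)
        expected = [rescale(TOP_IDP[aa]) for aa in seq]
        assert np.allclose(prof.scores, expected, atol=1e-12)

    def test_short_sequence_gets_whole_chain_mean(self):
        seq = "MKPW"
        prof = score_sequence(ProteinRecord("x", seq), window=21)
        mean = np.mean([TOP_IDP[aa] for aa in seq])
        assert np.allclose(prof.scores, rescale(mean))

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="window must be odd"):
            score_sequence(ProteinRecord("x", "MKV"), window=4)

    def test_ambiguity_positions_get_scale_mean(self):
        prof = score_sequence(ProteinRecord("x", "X"), window=1)
        assert np.allclose(prof.scores, rescale(TOPIDP_SCALE.vmean))

    @given(
        st.text(
            alphabet=STANDARD_AA + AMBIGUITY_CODES, min_size=1, max_size=120
        ),
        st.sampled_from([1, 3, 5, 21]),
    )
    def test_scores_in_unit_interval(self, seq, window):
        prof = score_sequence(ProteinRecord("x", seq), window=window)
        assert prof.scores.min() >= 0.0 and prof.scores.max() <= 1.0

    @given(st.text(alphabet=STANDARD_AA, min_size=1, max_size=120))
    def test_reversal_covariance(self, seq):
        fwd = score_sequence(ProteinRecord("x", seq), window=5).scores
        rev = score_sequence(ProteinRecord("x", seq[::-1]), window=5).scores
        assert np.allclose(fwd, rev[::-1])


class TestLoadScores:
    def make_proteome(self):
        return Proteome("sp", [ProteinRecord("A", "MKV")])

    def write(self, tmp_path, rows):
        path = tmp_path / "scores.tsv"
        lines = ["protein_id\tposition\tresidue\tscore"]
        lines += ["\t".join(str(v) for v in r) for r in rows]
        path.write_text("\n".join(lines) + "\n")
        return path

    def test_valid_file(self, tmp_path):
        path = self.write(
            tmp_path, [("A", 1, "M", 0.1), ("A", 2, "K", 0.6), ("A", 3, "V", 0.9)]
        )
        profiles = load_scores(path, self.make_proteome())
        assert np.allclose(profiles["A"].scores, [0.1, 0.6, 0.9])

    def test_residue_mismatch(self, tmp_path):
        path = self.write(
            tmp_path, [("A", 1, "M", 0.1), ("A", 2, "Q", 0.6), ("A", 3, "V", 0.9)]
        )
        with pytest.raises(ValueError, match="sequence/score mismatch for 'A' at position 2"):
            load_scores(path, self.make_proteome())

    def test_incomplete_profile(self, tmp_path):
        path = self.write(tmp_path, [("A", 1, "M", 0.1), ("A", 3, "V", 0.9)])
        with pytest.raises(ValueError, match="incomplete profile"):
            load_scores(path, self.make_proteome())

    def test_score_out_of_range(self, tmp_path):
        path = self.write(
            tmp_path, [("A", 1, "M", 0.1), ("A", 2, "K", 1.6), ("A", 3, "V", 0.9)]
        )
        with pytest.raises(ValueError, match="score out of range"):
            load_scores(path, self.make_proteome())

    def test_round_trip_with_writer(self, tmp_path):
        proteome = self.make_proteome()
        profiles = {"A": DisorderProfile("A", np.array([0.2, 0.5, 0.8]))}
        path = tmp_path / "out.tsv"
        write_scores(profiles, proteome, path)
        back = load_scores(path, proteome)
        assert np.allclose(back["A"].scores, [0.2, 0.5, 0.8])


def brute_force_best_threshold(scores, labels):
    """Exhaustive grid-search oracle for the balanced-accuracy calibration."""
    grid = np.arange(101) / 100.0
    best_ba, best_ts = -1.0, []
    for t in grid:
        pred = scores >= t
        tpr = pred[labels].mean()
        tnr = (~pred[~labels]).mean()
        ba = 0.5 * (tpr + tnr)
        if ba > best_ba + 1e-12:
            best_ba, best_ts = ba, [t]
        elif abs(ba - best_ba) <= 1e-12:
            best_ts.append(t)
    return best_ba, best_ts


class TestCalibrateThreshold:
    def test_no_data_returns_convention(self):
        assert calibrate_threshold([]) == 0.5

    def test_perfectly_separated_returns_grid_midpoint(self):
        ordered = DisorderProfile("o", np.array([0.1, 0.2, 0.3]))
        disordered = DisorderProfile("d", np.array([0.7, 0.8, 0.9]))
        labeled = [
            (ordered, np.zeros(3, bool)),
            (disordered, np.ones(3, bool)),
        ]
        t = calibrate_threshold(labeled)
        ba, ts = brute_force_best_threshold(
            np.array([0.1, 0.2, 0.3, 0.7, 0.8, 0.9]),
            np.array([False] * 3 + [True] * 3),
        )
        assert ba == 1.0
        assert t == 0.50
        assert min(ts) <= t <= max(ts)

    def test_single_class_rejected(self):
        prof = DisorderProfile("o", np.array([0.1, 0.2]))
        with pytest.raises(ValueError, match="cannot calibrate"):
            calibrate_threshold([(prof, np.zeros(2, bool))])

    def test_matches_bruteforce_on_random_data(self, rng):
        scores = rng.random(400)
        labels = rng.random(400) < np.clip(scores, 0.1, 0.9)
        prof = DisorderProfile("r", scores)
        t = calibrate_threshold([(prof, labels)])
        ba, ts = brute_force_best_threshold(scores, labels)
        pred = scores >= t
        achieved = 0.5 * (pred[labels].mean() + (~pred[~labels]).mean())
        assert abs(achieved - ba) < 1e-9


class TestDisorderScorer:
    def test_sklearn_clone_and_params(self):
        scorer = DisorderScorer(window=11, threshold=0.4)
        cloned = clone(scorer)
        assert cloned.get_params()["window"] == 11
        assert cloned.set_params(window=5).window == 5

    def test_fit_without_labels_uses_configured_threshold(self):
        scorer = DisorderScorer(threshold=0.6).fit([ProteinRecord("a", "MKV")])
        assert scorer.threshold_ == 0.6

    def test_fit_calibrates_on_labels(self):
        records = [
            ProteinRecord("o", MOST_ORDERED * 30),
            ProteinRecord("d", MOST_DISORDERED * 30),
        ]
        y = [np.zeros(30, bool), np.ones(30, bool)]
        scorer = DisorderScorer(window=5).fit(records, y)
        preds = scorer.predict(records)
        assert not preds[0].any() and preds[1].all()

    def test_balanced_accuracy_on_separated_two_state_proteins(self):
        """With strongly contrasted state compositions, per-residue balanced
        accuracy at the calibrated threshold beats 0.75."""
        from idcensus.scales import DISORDER_PROMOTING, ORDER_PROMOTING
        from idcensus.simulate import biased_composition, generate_proteome, make_archetype

        arch = make_archetype(
            "separated",
            0.3,
            ordered_composition=biased_composition(ORDER_PROMOTING, 4.0),
            disordered_composition=biased_composition(DISORDER_PROMOTING, 4.0),
        )
        proteome, truths, _ = generate_proteome(arch, 60, seed=7)
        scorer = DisorderScorer().fit(proteome, [t.labels for t in truths])
        preds = scorer.predict(proteome)
        pred = np.concatenate(preds)
        truth = np.concatenate([t.labels for t in truths])
        ba = 0.5 * (pred[truth].mean() + (~pred[~truth]).mean())
        assert ba > 0.75
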