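"""ParCrys: standardization, Scott bandwidth, kernel scoring, calibration."""

import math

import numpy as np
import pytest

from xtalselect import evaluation, parcrys, seqfeat, synth
from xtalselect.errors import EvaluationError, ModelError
from xtalselect.parcrys import (ParzenModel, calibrate_threshold, fit_parzen,
                                log_density, parcrys_score, score_records,
                                scott_bandwidth)
from xtalselect.seqfeat import FeatureVector, ProteinRecord


def _model_from_matrix(x):
    return fit_parzen(np.asarray(x, dtype=float))


class TestFit:
    def test_scott_bandwidth_closed_form(self):
        # d=8, n=100: (4/1000)^(1/12)
        assert scott_bandwidth(100, 8) == pytest.approx(
            (4.0 / 1000.0) ** (1.0 / 12.0), abs=1e-12)
        x = np.random.default_rng(1).normal(size=(100, 8))
        model = _model_from_matrix(x)
        assert np.allclose(model.bandwidths, (4.0 / 1000.0) ** (1.0 / 12.0))

    def test_standardized_reference(self, parzen_model):
        assert np.allclose(parzen_model.reference.mean(axis=0), 0.0,
                           atol=1e-9)
        assert np.allclose(parzen_model.reference.std(axis=0), 1.0,
                           atol=1e-9)

    def test_refit_bit_exact(self, labelled_features):
        _, feats, labels = labelled_features
        pos = [f for f, l in zip(feats, labels) if l == 1]
        a, b = fit_parzen(pos), fit_parzen(pos)
        assert np.array_equal(a.reference, b.reference)
        assert np.array_equal(a.means, b.means)
        assert np.array_equal(a.sds, b.sds)
        assert np.array_equal(a.bandwidths, b.bandwidths)

    def test_too_few_positives(self):
        with pytest.raises(ModelError):
            fit_parzen(np.ones((1, 8)))

    def test_zero_variance_dimension_warns(self):
        x = np.random.default_rng(0).normal(size=(20, 3))
        x[:, 1] = 2.5
        with pytest.warns(UserWarning, match="zero-variance"):
            model = _model_from_matrix(x)
        assert model.sds[1] == 1.0


class TestScore:
    def test_zero_distance_kernel_peak(self):
        # two identical reference points: every sd degenerates to 1 and the
        # query at the reference scores the kernel maximum
        with pytest.warns(UserWarning):
            model = _model_from_matrix(np.tile([1.0, 2.0], (2, 1)))
        expected = sum(-math.log(h * math.sqrt(2 * math.pi))
                       for h in model.bandwidths)
        assert log_density(np.array([1.0, 2.0]), model)[0] == \
            pytest.approx(expected, rel=1e-12)

    def test_against_direct_sum_oracle(self, rng):
        ref = rng.normal(size=(5, 8))
        model = _model_from_matrix(ref)
        queries = rng.normal(size=(20, 8)) * 2.0
        for q in queries:
            z = (q - model.means) / model.sds
            total = 0.0
            for r in model.reference:
                prod = 1.0
                for zd, rd, h in zip(z, r, model.bandwidths):
                    u = (zd - rd) / h
                    prod *= math.exp(-0.5 * u * u) / (h * math.sqrt(2 * math.pi))
                total += prod
            expected = math.log(total / model.n_ref)
            assert log_density(q, model)[0] == pytest.approx(expected,
                                                             rel=1e-9)

    def test_mirror_symmetry(self):
        model = _model_from_matrix([[-1.0, 0.0], [1.0, 0.0]])
        left = log_density(np.array([-2.0, 0.3]), model)[0]
        right = log_density(np.array([2.0, 0.3]), model)[0]
        assert left == pytest.approx(right, rel=1e-9)

    def test_one_dimensional_density_normalizes(self):
        model = _model_from_matrix([[0.0], [0.0001]])
        zgrid = np.linspace(-12, 12, 24001)
        x = model.means[0] + model.sds[0] * zgrid
        dens = np.exp(log_density(x[:, None], model))
        assert np.trapezoid(dens, zgrid) == pytest.approx(1.0, abs=1e-3)

    def test_monotone_away_from_centroid(self):
        model = _model_from_matrix([[-1.0, -1.0], [1.0, 1.0]])
        direction = np.array([1.0, -2.0])
        radii = np.linspace(0, 6, 30)
        scores = [log_density(r * direction, model)[0] for r in radii]
        assert np.all(np.diff(scores) <= 1e-12)

    def test_never_minus_infinity(self):
        model = _model_from_matrix([[0.0] * 8, [1.0] * 8])
        far = np.full(8, 1e6)
        assert np.isfinite(log_density(far, model)[0])


class TestCalibration:
    def test_separated_scores_threshold_in_gap(self, parzen_model,
                                               labelled_features):
        _, feats, labels = labelled_features
        labelled = list(zip(feats, labels))
        threshold = calibrate_threshold(parzen_model, labelled)
        scores = np.array([parcrys_score(f, parzen_model) for f in feats])
        _, best = evaluation.best_mcc(scores, labels)
        counts = evaluation.confusion_at_threshold(scores, labels, threshold)
        assert evaluation.mcc(counts) == pytest.approx(best)

    def test_perfect_separation_gap(self):
        # construct a model and a labelled set with disjoint score ranges
        model = _model_from_matrix(np.random.default_rng(0).normal(size=(10, 2)))

        def fv2(a, b):
            return np.array([a, b])

        near = [fv2(0.0, 0.0), fv2(0.1, 0.1)]
        far = [fv2(30.0, 30.0), fv2(40.0, 40.0)]
        scores = [log_density(x, model)[0] for x in near + far]
        labels = [1, 1, 0, 0]
        threshold, best = evaluation.best_mcc(scores, labels)
        assert best == 1.0
        assert max(scores[2:]) < threshold < min(scores[:2])

    def test_null_labels_give_low_mcc(self, parzen_model, labelled_features):
        _, feats, labels = labelled_features
        rng = np.random.default_rng(42)
        scores = np.array([parcrys_score(f, parzen_model) for f in feats])
        _, best = evaluation.best_mcc(scores, rng.permutation(labels))
        assert abs(best) < 0.2

    def test_order_invariance(self, parzen_model, labelled_features):
        _, feats, labels = labelled_features
        labelled = list(zip(feats, labels))
        reversed_ = list(reversed(labelled))
        assert calibrate_threshold(parzen_model, labelled) == \
            calibrate_threshold(parzen_model, reversed_)

    def test_single_class_errors(self, parzen_model, labelled_features):
        _, feats, _ = labelled_features
        with pytest.raises(EvaluationError):
            calibrate_threshold(parzen_model, [(f, 1) for f in feats[:10]])


class TestScoreTable:
    def test_class_column_iff_threshold(self, parzen_model, labelled_features):
        records, _, _ = labelled_features
        sample = records[:10]
        without = score_records(sample, parzen_model)
        with_thr = score_records(sample, parzen_model, threshold=0.0)
        assert "predicted" not in without.columns
        assert set(with_thr["predicted"]) <= {0, 1}

    def test_deterministic_ordering(self, parzen_model, labelled_features):
        records, _, _ = labelled_features
        a = score_records(records[:30], parzen_model)
        b = score_records(records[:30], parzen_model)
        assert a.equals(b)

    def test_reference_like_scores_above_distant(self, parzen_model):
        # a sequence with background-like composition vs an extreme homopolymer
        recs, _ = synth.generate_labelled_dataset(1, 1, seed=5)
        extreme = ProteinRecord(id="poly", sequence="K" * 120)
        table = score_records([*recs, extreme], parzen_model)
        assert table.iloc[-1]["id"] == "poly"


def test_synthetic_recovery_auc(parzen_model, labelled_features):
    """Composition-shifted positives are separable from background."""
    _, feats, labels = labelled_features
    scores = log_density(np.stack([f.as_array() for f in feats]),
                         parzen_model)
    assert evaluation.roc_auc(scores, labels).auc >= 0.80


def test_serialization_round_trip(tmp_path, parzen_model, labelled_features):
    _, feats, _ = labelled_features
    path = tmp_path / "parcrys.json"
    parcrys.save_model(parzen_model, path)
    back = parcrys.load_model(path)
    for f in feats[:5]:
        assert parcrys_score(f, back) == pytest.approx(
            parcrys_score(f, parzen_model), rel=1e-12)
    assert back.feature_names == parzen_model.feature_names
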