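import numpy as np
import pytest

from oracles import lexmin_assignment
from pulseicp.evaluate import annotate_corpus
from pulseicp.recognize.spectral import (SrModel, _graph_embedding,
                                         _knn_affinity, fit_ksr, fit_sr,
                                         greedy_match, recognize_sr,
                                         vectorize)
from pulseicp.simulate import make_corpus
from pulseicp.types import CandidateSet, PulseWaveform


def ramp_pulse(n=320, fs=400.0):
    return PulseWaveform(np.linspace(5.0, 9.0, n), fs=fs)


@pytest.fixture(scope="module")
def training_data():
    """Complete-triple training pulses from a deterministic easy corpus."""
    corpus = make_corpus(4, 2, 30, 0.0, 31)
    ann = [ap for ap in annotate_corpus(corpus) if ap.truth.n_missing == 0]
    pulses = [ap.pulse for ap in ann]
    Y = np.array([[v for v in ap.truth.latencies] for ap in ann])
    return pulses, Y


class TestVectorize:
    def test_ramp_maps_to_unit_ramp(self):
        v = vectorize(ramp_pulse(), channels=("raw",), s=500)
        assert v.shape == (500,)
        assert v[0] == 0.0 and abs(v[-1] - 1.0) < 1e-12
        assert np.all(np.diff(v) >= 0)

    def test_channel_concatenation_lengths(self):
        p = ramp_pulse()
        assert vectorize(p, channels=("raw",)).size == 500
        assert vectorize(p, channels=("raw", "Lx")).size == 1000
        assert vectorize(p, channels=("raw", "Lx", "K")).size == 1500

    def test_derivative_channel_is_elevation_invariant(self):
        p = ramp_pulse()
        shifted = PulseWaveform(p.samples + 25.0, fs=p.fs)
        a = vectorize(p, channels=("Lx",))
        b = vectorize(shifted, channels=("Lx",))
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_flat_pulse_rejected(self):
        with pytest.raises(ValueError):
            vectorize(PulseWaveform(np.full(320, 8.0), fs=400.0))


class TestGraphEmbedding:
    def test_bipartition_of_two_clusters(self, rng):
        X = np.vstack([rng.normal(0, 0.2, (15, 4)),
                       rng.normal(5, 0.2, (15, 4))])
        W = _knn_affinity(X, 5)
        E = _graph_embedding(W, d=1)
        signs = np.sign(E[:, 0])
        assert abs(signs[:15].sum()) == 15
        assert abs(signs[15:].sum()) == 15
        assert signs[0] != signs[-1]


class TestFitSr:
    def test_beats_mean_predictor_on_training_set(self, training_data):
        pulses, Y = training_data
        model = fit_sr(pulses, Y, d=5)
        preds = np.vstack([model.predict_latencies(p) for p in pulses])
        mae_model = np.abs(preds - Y).mean()
        mae_mean = np.abs(Y.mean(axis=0) - Y).mean()
        assert mae_model < mae_mean

    def test_duplication_invariance(self, training_data):
        # Duplicating every training point (with k scaled to 2k+1 so each
        # copy also links to its twin) must leave the fitted projection
        # essentially unchanged; the twin edges perturb the node degrees,
        # so the agreement is close but not bitwise.
        pulses, Y = training_data
        pulses, Y = pulses[:40], Y[:40]
        m1 = fit_sr(pulses, Y, d=2, graph_k=3, ridge=0.5)
        m2 = fit_sr(pulses * 2, np.vstack([Y, Y]), d=2, graph_k=7, ridge=1.0)
        scale = np.abs(m1.betas).max()
        np.testing.assert_allclose(np.abs(m1.betas) / scale,
                                   np.abs(m2.betas) / scale, atol=0.05)
        p1 = np.vstack([m1.predict_latencies(p) for p in pulses[:10]])
        p2 = np.vstack([m2.predict_latencies(p) for p in pulses[:10]])
        np.testing.assert_allclose(p1, p2, atol=1.0)  # ms

    def test_predictions_affine_in_input_vector(self, training_data):
        pulses, Y = training_data
        model = fit_sr(pulses, Y, d=4)
        rng = np.random.default_rng(0)
        u, v = rng.normal(0, 1, (2, 500))
        for lam in (0.25, 0.5, 0.9):
            mix = model.predict_from_vectors(lam * u + (1 - lam) * v)
            combo = (lam * model.predict_from_vectors(u)
                     + (1 - lam) * model.predict_from_vectors(v))
            np.testing.assert_allclose(mix, combo, rtol=1e-8, atol=1e-8)

    def test_too_few_training_pulses(self, training_data):
        pulses, Y = training_data
        with pytest.raises(ValueError):
            fit_sr(pulses[:3], Y[:3])


class TestFitKsr:
    def test_vanishing_gamma_degenerates_to_constant(self, training_data):
        # gamma = 0 collapses the kernel matrix to all-ones, so every input
        # maps to the same kernel row and the predictor becomes constant
        pulses, Y = training_data
        model = fit_ksr(pulses, Y, gamma=0.0)
        preds = np.vstack([model.predict_latencies(p) for p in pulses[:20]])
        assert np.max(np.std(preds, axis=0)) < 1e-6

    def test_kernel_training_error_not_worse_than_linear(self, training_data):
        pulses, Y = training_data
        sr = fit_sr(pulses, Y, d=5)
        ksr = fit_ksr(pulses, Y, d=5, gamma=3e-3)
        err_sr = np.abs(np.vstack([sr.predict_latencies(p) for p in pulses]) - Y).mean()
        err_ksr = np.abs(np.vstack([ksr.predict_latencies(p) for p in pulses]) - Y).mean()
        assert err_ksr <= err_sr + 1e-9

    def test_deterministic_fit(self, training_data):
        pulses, Y = training_data
        a = fit_ksr(pulses, Y, gamma=1e-3)
        b = fit_ksr(pulses, Y, gamma=1e-3)
        np.testing.assert_array_equal(a.betas, b.betas)
        assert a.X_train is not None  # kernel model keeps its training inputs

    def test_json_roundtrip_preserves_predictions(self, training_data):
        pulses, Y = training_data
        model = fit_ksr(pulses[:30], Y[:30], gamma=1e-3)
        model2 = SrModel.from_json(model.to_json())
        p = pulses[31]
        np.testing.assert_allclose(model.predict_latencies(p),
                                   model2.predict_latencies(p), rtol=1e-12)


class TestRecognizeSr:
    def _model_with_predictions(self, training_data, yhat):
        pulses, Y = training_data
        model = fit_sr(pulses[:20], Y[:20], d=2)
        model.readout_coef = np.zeros_like(model.readout_coef)
        model.readout_intercept = np.asarray(yhat, dtype=float)
        return model, pulses[0]

    def test_empty_candidates(self, training_data):
        model, pulse = self._model_with_predictions(training_data,
                                                    [100.0, 200.0, 300.0])
        out = recognize_sr(model, pulse,
                           CandidateSet(np.array([]), np.array([])))
        assert out.latencies == (None, None, None)

    def test_exact_candidates_snap_exactly(self, training_data):
        model, pulse = self._model_with_predictions(training_data,
                                                    [100.0, 200.0, 300.0])
        cands = CandidateSet(np.array([100.0, 200.0, 300.0]),
                             np.array([40, 80, 120]))
        assert recognize_sr(model, pulse, cands).latencies == (100.0, 200.0, 300.0)

    def test_far_candidates_stay_missing(self, training_data):
        model, pulse = self._model_with_predictions(training_data,
                                                    [100.0, 200.0, 300.0])
        model.assign_delta = 20.0
        cands = CandidateSet(np.array([98.0, 202.0, 500.0]),
                             np.array([39, 81, 200]))
        assert recognize_sr(model, pulse, cands).latencies == (98.0, 202.0, None)

    def test_greedy_matches_lexmin_bruteforce(self, rng):
        for _ in range(300):
            yhat = rng.uniform(0, 500, 3)
            lat = np.unique(np.round(rng.uniform(0, 500, rng.integers(3, 9)), 2))
            chosen, _, _ = greedy_match(yhat, lat, delta=np.inf)
            want = lexmin_assignment(yhat, list(lat), delta=np.inf)
            assert tuple(chosen) == want

    def test_snapped_output_is_always_a_candidate(self, training_data, rng):
        pulses, Y = training_data
        model = fit_sr(pulses[:30], Y[:30], d=3)
        for ap in range(20):
            lat = np.unique(np.round(rng.uniform(0, 700, rng.integers(0, 7)), 1))
            cands = CandidateSet(lat, np.round(lat * 0.4).astype(int))
            out = recognize_sr(model, pulses[ap], cands)
            for v in out.latencies:
                assert v is None or v in lat
            present = [v for v in out.latencies if v is not None]
            assert all(b > a for a, b in zip(present, present[1:]))

    def test_ordering_repair_drops_later_assigned_peak(self, training_data):
        # p2's prediction is much closer to the early candidate than p1's,
        # so p2 grabs it first and p1's later, out-of-order snap is dropped
        model, pulse = self._model_with_predictions(training_data,
                                                    [140.0, 101.0, 300.0])
        cands = CandidateSet(np.array([100.0, 150.0, 300.0]),
                             np.array([40, 60, 120]))
        out = recognize_sr(model, pulse, cands)
        assert out.latencies == (None, 100.0, 300.0) or out.p1 is None
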