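"""Sn dispersion, the seven biomarkers, and the correlation-weighted composite."""
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from vigilfield import biomarkers as bm
from vigilfield.io import assemble_session

from conftest import make_frame, make_trial, sn_brute_force


class TestSnDispersion:
    @pytest.mark.parametrize(
        "points, expected",
        [
            ([(1.0, 1.0), (1.0, 1.0), (1.0, 1.0)], 0.0),
            ([0.0, 1.0, 2.0], 1.5),  # inner medians 1.5, 1, 1.5 -> outer 1.5
            ([(0.0, 0.0), (3.0, 4.0)], 5.0),  # single 3-4-5 distance
        ],
    )
    def test_frozen_examples(self, points, expected):
        assert bm.sn_dispersion(points) == pytest.approx(expected, abs=1e-12)

    def test_insufficient_points_is_null(self):
        assert bm.sn_dispersion([(1.0, 2.0)]) is None
        assert bm.sn_dispersion([]) is None

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            bm.sn_dispersion([(0.0, 0.0), (np.nan, 1.0)])

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(99)
        for _ in range(50):
            n, d = int(rng.integers(2, 51)), int(rng.integers(1, 4))
            pts = rng.normal(size=(n, d)) * rng.uniform(0.1, 10)
            assert bm.sn_dispersion(pts) == pytest.approx(sn_brute_force(pts), abs=1e-9)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        pts=arrays(
            float,
            st.tuples(st.integers(2, 15), st.integers(1, 3)),
            elements=st.floats(-100, 100, allow_nan=False),
        ),
        a=st.floats(-5, 5, allow_nan=False).filter(lambda v: abs(v) > 1e-3),
        b=st.floats(-50, 50, allow_nan=False),
    )
    def test_translation_invariant_scale_equivariant(self, pts, a, b):
        base = bm.sn_dispersion(pts)
        shifted = bm.sn_dispersion(pts + b)
        scaled = bm.sn_dispersion(a * pts)
        assert shifted == pytest.approx(base, rel=1e-9, abs=1e-9)
        assert scaled == pytest.approx(abs(a) * base, rel=1e-9, abs=1e-9)

    def test_robust_to_relocated_outliers(self):
        # 10 of 100 points thrown to 100x distance: Sn moves < 50%,
        # while the RMS distance from the centroid explodes > 500%.
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(100, 2))
        contaminated = pts.copy()
        contaminated[:10] *= 100.0

        def rms(p):
            c = p.mean(axis=0)
            return np.sqrt(((p - c) ** 2).sum(axis=1).mean())

        sn0, sn1 = bm.sn_dispersion(pts), bm.sn_dispersion(contaminated)
        assert abs(sn1 - sn0) < 0.5 * sn0
        assert rms(contaminated) > 6.0 * rms(pts)


class TestSessionBiomarkers:
    def test_constant_session_gives_zero_dispersion(self, toy_session):
        vec = bm.session_biomarkers(toy_session)
        assert vec.gaze_variability == 0.0
        assert vec.head_location_variability == 0.0
        assert vec.head_rotation_variability == 0.0
        assert vec.mean_response_latency == pytest.approx(0.5)

    def test_gaze_reuses_sn_oracle_embedded_1d(self, flat_grid):
        frames = [make_frame(i, gaze=(g, 0.0)) for i, g in enumerate([0.0, 1.0, 2.0])]
        assert bm.gaze_variability(frames) == pytest.approx(1.5)

    def test_rotation_triples(self, flat_grid):
        frames = [make_frame(0, rot=(0, 0, 0)), make_frame(1, rot=(3, 0, 4))]
        assert bm.head_rotation_variability(frames) == pytest.approx(5.0)

    def test_invalid_frames_never_enter(self):
        frames = [make_frame(0, gaze=(0, 0)), make_frame(1, gaze=(500, 500), valid=False), make_frame(2, gaze=(0, 0))]
        assert bm.gaze_variability(frames) == 0.0

    def test_fewer_than_two_valid_frames_is_null(self):
        assert bm.gaze_variability([make_frame(0)]) is None

    @pytest.mark.parametrize(
        "labels, aus, expected",
        [
            (bm.SADNESS_AUS, [{"AU04": 0.5, "AU15": 0.5}, {"AU04": 1.5, "AU15": 0.5}], 1.5),
            (bm.BLINK_AUS, [{"AU45": 0.0}, {"AU45": 1.0}, {"AU45": 2.0}], 1.0),
            (bm.SURPRISE_AUS, [{}, {}], 0.0),
        ],
    )
    def test_mean_au_sum(self, labels, aus, expected):
        frames = [make_frame(i, au=a) for i, a in enumerate(aus)]
        assert bm.mean_au_sum(frames, labels) == pytest.approx(expected)

    def test_mean_au_sum_additive_over_disjoint_labels(self):
        rng = np.random.default_rng(3)
        frames = [
            make_frame(i, au={k: float(v) for k, v in zip(bm.SADNESS_AUS + bm.SURPRISE_AUS, rng.uniform(0, 2, 6))})
            for i in range(5)
        ]
        total = bm.mean_au_sum(frames, bm.SADNESS_AUS + bm.SURPRISE_AUS)
        assert total == pytest.approx(
            bm.mean_au_sum(frames, bm.SADNESS_AUS) + bm.mean_au_sum(frames, bm.SURPRISE_AUS)
        )

    def test_latency_excludes_missed_trials(self):
        trials = [make_trial(0, 1.0, True, 0.4), make_trial(1, 2.0, False, None), make_trial(2, 3.0, True, 0.6)]
        assert bm.mean_response_latency(trials) == pytest.approx(0.5)
        assert bm.mean_response_latency([make_trial(0, 1.0, False, None)]) is None

    def test_empty_frame_stream_gives_null_video_fields(self, flat_grid):
        session = assemble_session([], [], flat_grid)
        vec = bm.session_biomarkers(session)
        assert vec.gaze_variability is None
        assert vec.mean_sadness is None
        assert vec.mean_response_latency is None


class TestWindowedBiomarkers:
    def test_window_in_constant_segment_gives_zero(self, toy_session):
        vec = bm.windowed_biomarkers(toy_session, toy_session.trials[2])
        assert vec.gaze_variability == 0.0
        assert vec.mean_response_latency is None  # excluded at trial resolution

    def test_window_truncates_at_session_start(self, flat_grid):
        frames = [make_frame(i) for i in range(60)]
        trial = make_trial(0, 0.6, True, 0.2)  # 3 frames precede onset
        session = assemble_session(frames, [trial], flat_grid)
        vec = bm.windowed_biomarkers(session, trial, window_frames=20)
        assert vec.gaze_variability == 0.0  # still computable from the few frames

    def test_foreign_trial_rejected(self, toy_session):
        foreign = make_trial(99, 5.0)
        with pytest.raises(ValueError):
            bm.windowed_biomarkers(toy_session, foreign)

    def test_lapse_window_inflated_vs_attentive(self, flat_grid):
        # frames 0..39 quiet, 40..79 noisy; trials centred in each segment
        rng = np.random.default_rng(11)
        quiet = [make_frame(i, gaze=tuple(rng.normal(0, 0.3, 2))) for i in range(40)]
        noisy = [make_frame(40 + i, gaze=tuple(rng.normal(0, 3.0, 2))) for i in range(40)]
        trials = [make_trial(0, 7.0, True, 0.5), make_trial(1, 15.0, True, 0.5)]
        session = assemble_session(quiet + noisy, trials, flat_grid)
        v0 = bm.windowed_biomarkers(session, trials[0])
        v1 = bm.windowed_biomarkers(session, trials[1])
        assert v1.gaze_variability > 3 * v0.gaze_variability


class TestComposite:
    def _matrix(self, rng, n=10):
        return pd.DataFrame(
            {name: rng.uniform(0, 1, n) + np.arange(n) * 0.1 for name in bm.BIOMARKER_NAMES}
        )

    def test_equal_correlations_give_equal_weights(self):
        rng = np.random.default_rng(0)
        n = 12
        y = np.linspace(0, 1, n)
        X = pd.DataFrame({name: y * (i + 1) for i, name in enumerate(bm.BIOMARKER_NAMES)})
        model = bm.fit_composite_model(X, y)
        np.testing.assert_allclose(model.weights, [1 / 7] * 7, atol=1e-12)

    def test_weights_are_rho_over_rho_sum(self):
        rng = np.random.default_rng(1)
        X = self._matrix(rng)
        y = rng.uniform(0, 2, len(X)) + X["gaze_variability"]
        model = bm.fit_composite_model(X, y)
        np.testing.assert_allclose(
            np.asarray(model.weights), np.asarray(model.rho) / np.sum(model.rho), atol=1e-12
        )
        assert sum(model.weights) == pytest.approx(1.0, abs=1e-12)

    def test_informative_biomarker_gets_largest_weight(self):
        rng = np.random.default_rng(42)
        n = 60
        X = pd.DataFrame({name: rng.normal(0, 1, n) for name in bm.BIOMARKER_NAMES})
        y = 2.0 * X["blink_rate"].to_numpy() + rng.normal(0, 0.5, n)
        model = bm.fit_composite_model(X, y)
        weights = dict(zip(model.names, model.weights))
        assert weights["blink_rate"] == max(weights.values())

    def test_zero_variance_column_named(self):
        X = self._matrix(np.random.default_rng(2))
        X["blink_rate"] = 1.0
        with pytest.raises(ValueError, match="blink_rate"):
            bm.fit_composite_model(X, np.arange(len(X), dtype=float))

    def test_degenerate_weights_raise(self):
        rng = np.random.default_rng(3)
        n = 20
        X = pd.DataFrame({name: rng.normal(size=n) for name in bm.BIOMARKER_NAMES})
        y = -X.sum(axis=1).to_numpy()  # all correlations negative
        with pytest.raises(bm.DegenerateWeightsError):
            bm.fit_composite_model(X, y)

    def test_score_at_means_is_zero_and_shared_z_passes_through(self):
        rng = np.random.default_rng(4)
        X = self._matrix(rng)
        y = X.mean(axis=1).to_numpy() + rng.normal(0, 0.1, len(X))
        model = bm.fit_composite_model(X, y)
        at_means = dict(zip(model.names, model.means))
        assert bm.composite_score(model, at_means) == pytest.approx(0.0, abs=1e-12)
        z = 1.7  # every biomarker exactly z SDs above its mean
        shifted = {n_: m + z * s for n_, m, s in zip(model.names, model.means, model.sds)}
        assert bm.composite_score(model, shifted) == pytest.approx(z, rel=1e-9)

    def test_three_session_toy_matches_manual_arithmetic(self):
        # Hand computation: x1=(1,2,3), x2=(2,2,4) vs target y=(1,2,3).
        # rho1=1, rho2=pearson((2,2,4),(1,2,3))=0.866025..., weights
        # (0.535898..., 0.464101...); z-scores of row 2: (1, 1.154700...)
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [2.0, 2.0, 4.0]})
        y = [1.0, 2.0, 3.0]
        model = bm.fit_composite_model(X, y)
        rho2 = 3 / (2 * math.sqrt(3))
        w1 = 1 / (1 + rho2)
        assert model.weights[0] == pytest.approx(w1, rel=1e-12)
        score = bm.composite_score(model, {"a": 3.0, "b": 4.0})
        z_a = (3.0 - 2.0) / 1.0
        z_b = (4.0 - 8 / 3) / math.sqrt((2 * (2 / 3) ** 2 + (4 / 3) ** 2) / 2)
        assert score == pytest.approx(w1 * z_a + (1 - w1) * z_b, rel=1e-9)

    def test_composite_invariant_to_affine_rescaling_of_column(self):
        rng = np.random.default_rng(5)
        X = self._matrix(rng)
        y = X["gaze_variability"].to_numpy() + rng.normal(0, 0.2, len(X))
        model = bm.fit_composite_model(X, y)
        scores = bm.composite_scores(model, X)
        X2 = X.copy()
        X2["mean_sadness"] = X2["mean_sadness"] * 37.0 + 5.0
        model2 = bm.fit_composite_model(X2, y)
        scores2 = bm.composite_scores(model2, X2)
        np.testing.assert_allclose(scores, scores2, rtol=1e-9)

    def test_missing_weighted_field_raises(self):
        X = self._matrix(np.random.default_rng(6))
        y = X.sum(axis=1).to_numpy()
        model = bm.fit_composite_model(X, y)
        incomplete = {name: 1.0 for name in bm.BIOMARKER_NAMES[:-1]}
        with pytest.raises(ValueError, match="mean_response_latency"):
            bm.composite_score(model, incomplete)
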