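"""The three IMF features and assembly of per-segment feature vectors."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emdeeg.exceptions import (
    DegenerateSignalError,
    InvalidInputError,
    MissingChannelError,
)
from emdeeg.features import (
    FEATURE_NAMES,
    extract_features,
    first_difference,
    log_normalized_energy,
    normalized_energy,
    phase_first_difference,
)
from emdeeg.phase import analytic_signal

FS = 128.0


class TestFirstDifference:
    @pytest.mark.parametrize(
        "series, expected",
        [
            ([3.0, 3.0, 3.0, 3.0], 0.0),
            ([1, -1, 1, -1, 1], 2.0),
            ([0, 1, 3, 2], 4.0 / 3.0),
        ],
    )
    def test_examples(self, series, expected):
        assert first_difference(series) == pytest.approx(expected)

    def test_too_short(self):
        with pytest.raises(InvalidInputError):
            first_difference([1.0])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=50))
    def test_matches_definition(self, values):
        x = np.asarray(values)
        oracle = np.sum(np.abs(x[1:] - x[:-1])) / (len(x) - 1)
        assert first_difference(x) == pytest.approx(oracle, rel=1e-12, abs=1e-12)


class TestPhaseFirstDifference:
    def test_uniform_increments(self):
        phase = np.array([0, np.pi / 8, np.pi / 4, 3 * np.pi / 8])
        assert phase_first_difference(phase) == pytest.approx(np.pi / 8)

    def test_constant_phase(self):
        assert phase_first_difference(np.full(10, 1.3)) == 0.0

    def test_tone_phase_rate(self):
        t = np.arange(640) / FS
        phase = analytic_signal(np.cos(2 * np.pi * 8 * t)).phase
        interior = phase[64:576]
        assert phase_first_difference(interior) == pytest.approx(
            np.pi / 8, rel=0.05
        )


class TestNormalizedEnergy:
    def test_identity(self):
        x = np.arange(1.0, 9.0)
        assert normalized_energy(x, x) == pytest.approx(1.0)

    def test_quadratic_scaling(self):
        x = np.arange(1.0, 9.0)
        assert normalized_energy(x / 2, x) == pytest.approx(0.25)

    def test_zero_imf(self):
        x = np.arange(1.0, 9.0)
        assert normalized_energy(np.zeros_like(x), x) == 0.0

    def test_zero_energy_source(self):
        with pytest.raises(DegenerateSignalError):
            normalized_energy(np.ones(8), np.zeros(8))


class TestLogNormalizedEnergy:
    @pytest.mark.parametrize(
        "e, expected",
        [(1.0, 0.0), (np.e**2, 2.0), (0.25, np.log(0.25))],
    )
    def test_examples(self, e, expected):
        assert log_normalized_energy(e) == pytest.approx(expected)

    def test_nonpositive_clamped(self):
        assert log_normalized_energy(0.0) == pytest.approx(np.log(1e-12))


@pytest.fixture(scope="module")
def tone_segment():
    t = np.arange(640) / FS
    tone = np.sin(2 * np.pi * 8 * t)
    return np.tile(tone, (8, 1)), [f"ch{i}" for i in range(8)]


class TestExtractFeatures:
    def test_vector_length_8ch_1level(self, tone_segment):
        sig, labels = tone_segment
        fv = extract_features(sig, labels, imf_levels=(1,))
        assert len(fv) == 8 * 1 * 3

    def test_vector_length_and_ordering_5levels(self, tone_segment):
        sig, labels = tone_segment
        fv = extract_features(sig[:2], labels[:2], imf_levels=range(1, 6))
        assert len(fv) == 2 * 5 * 3
        # channel-major, then level, then fixed feature order
        assert fv.index[0] == ("ch0", 1, "D_t")
        assert fv.index[2] == ("ch0", 1, "log_E_norm")
        assert fv.index[3] == ("ch0", 2, "D_t")
        assert fv.index[15] == ("ch1", 1, "D_t")
        names = [f for (_, _, f) in fv.index[:3]]
        assert tuple(names) == FEATURE_NAMES

    def test_channel_symmetry(self, tone_segment):
        sig, labels = tone_segment
        fv = extract_features(sig, labels, imf_levels=(1,))
        triples = fv.values.reshape(8, 3)
        np.testing.assert_allclose(
            triples, np.tile(triples[0], (8, 1)), rtol=1e-9, atol=1e-9
        )

    def test_missing_channel(self, tone_segment):
        sig, labels = tone_segment
        with pytest.raises(MissingChannelError):
            extract_features(sig, labels, channels=["nope"], imf_levels=(1,))

    def test_missing_imf_level_filled(self, tone_segment):
        sig, labels = tone_segment
        # a pure tone decomposes into a single IMF: level 5 must be filled
        fv = extract_features(sig[:1], labels[:1], imf_levels=(1, 5))
        d_t5, d_p5, loge5 = fv.values[3:6]
        assert (d_t5, d_p5) == (0.0, 0.0)
        assert loge5 == pytest.approx(np.log(1e-12))

    def test_amplitude_invariance(self):
        rng = np.random.default_rng(5)
        sig = rng.standard_normal((1, 640))
        base = extract_features(sig, ["c"], imf_levels=(1, 2))
        scaled = extract_features(3.0 * sig, ["c"], imf_levels=(1, 2))
        for (val_b, val_s, (_, _, name)) in zip(
            base.values, scaled.values, base.index
        ):
            if name == "D_t":
                assert val_s == pytest.approx(3.0 * val_b, rel=1e-6)
            elif name == "D_p":
                assert val_s == pytest.approx(val_b, rel=1e-6, abs=1e-9)
            else:  # log_E_norm: energy ratio cancels the scale exactly
                assert val_s == pytest.approx(val_b, rel=1e-9, abs=1e-9)

    def test_dp_decreases_with_imf_level_on_noise(self):
        """Faster components advance phase faster: D_p(IMF1) > D_p(IMF2)."""
        wins = 0
        n_trials = 40
        for seed in range(n_trials):
            x = np.random.default_rng(seed).standard_normal((1, 640))
            fv = extract_features(x, ["c"], imf_levels=(1, 2))
            d_p1, d_p2 = fv.values[1], fv.values[4]
            wins += d_p1 > d_p2
        assert wins >= 0.95 * n_trials

    def test_deterministic_serialization(self):
        x = np.random.default_rng(9).standard_normal((2, 640))
        a = extract_features(x, ["a", "b"], imf_levels=(1, 2))
        b = extract_features(x, ["a", "b"], imf_levels=(1, 2))
        assert a.index == b.index
        assert a.values.tobytes() == b.values.tobytes()
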