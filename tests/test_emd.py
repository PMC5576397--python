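"""EMD core: extrema, envelopes, the IMF test and full decomposition."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emdeeg.emd import (
    Epoch,
    SiftConfig,
    count_zero_crossings,
    decompose,
    envelope_mean,
    find_extrema,
    is_imf,
    sift_once,
)
from emdeeg.exceptions import InvalidInputError, NotEnoughExtremaError

FS = 128.0


class TestFindExtrema:
    @pytest.mark.parametrize(
        "samples, exp_max, exp_min",
        [
            ([0, 1, 0, -1, 0], [1], [3]),
            ([0, 1, 2, 3], [], []),  # monotone ramp: no interior extrema
            ([0, 1, 1, 0], [1], []),  # plateau -> floor-midpoint index
            ([0, 1, 1, 1, 0], [2], []),
            ([3, 1, 1, 3], [], [1]),
            ([0, 2, 1, 3, 0], [1, 3], [2]),
        ],
    )
    def test_examples(self, samples, exp_max, exp_min):
        max_idx, max_val, min_idx, min_val = find_extrema(samples)
        assert list(max_idx) == exp_max
        assert list(min_idx) == exp_min
        np.testing.assert_array_equal(max_val, np.asarray(samples)[max_idx])

    def test_indices_strictly_increasing_on_noise(self):
        x = np.random.default_rng(0).standard_normal(500)
        max_idx, _, min_idx, _ = find_extrema(x)
        assert np.all(np.diff(max_idx) > 0) and np.all(np.diff(min_idx) > 0)
        # maxima and minima must alternate for a continuous-like signal
        merged = np.sort(np.concatenate([max_idx, min_idx]))
        assert merged.size == max_idx.size + min_idx.size

    def test_non_finite_rejected(self):
        with pytest.raises(InvalidInputError):
            find_extrema([0.0, np.nan, 1.0])


class TestZeroCrossings:
    @pytest.mark.parametrize(
        "samples, expected",
        [
            ([1, -1, 1, -1], 3),
            ([1, 0, -1], 1),  # exact zero skipped, one sign change
            ([1, 2, 3], 0),
            ([0, 0, 0], 0),
        ],
    )
    def test_counting(self, samples, expected):
        assert count_zero_crossings(samples) == expected


class TestEnvelopeMean:
    def test_sinusoid_mean_near_zero(self, tone_8hz):
        m = envelope_mean(tone_8hz)
        assert m.size == tone_8hz.size
        interior = slice(64, 576)  # central 80%
        assert np.max(np.abs(m[interior])) < 0.05

    def test_shift_equivariance(self, tone_8hz):
        m = envelope_mean(tone_8hz + 3.5)
        assert np.max(np.abs(m[64:576] - 3.5)) < 0.05

    def test_ramp_has_no_envelopes(self):
        with pytest.raises(NotEnoughExtremaError):
            envelope_mean(np.linspace(0, 1, 100))


class TestIsImf:
    def test_pure_tone_is_imf(self, tone_8hz):
        assert is_imf(tone_8hz)

    def test_offset_tone_fails_zero_mean_condition(self, tone_8hz):
        assert not is_imf(tone_8hz + 0.5)

    def test_ramp_is_not_imf(self):
        assert not is_imf(np.linspace(0, 1, 100))


class TestSiftOnce:
    def test_imf_is_near_fixed_point(self, tone_8hz):
        out = sift_once(tone_8hz)
        assert np.max(np.abs(out - tone_8hz)) <= 0.05 * np.max(np.abs(tone_8hz))

    def test_removes_constant_offset(self, tone_8hz):
        out = sift_once(tone_8hz + 2.0)
        assert np.max(np.abs(out[64:576] - tone_8hz[64:576])) < 0.05

    def test_second_sift_changes_less_than_first(self, tone_8hz):
        once = sift_once(tone_8hz)
        twice = sift_once(once)
        change_pure = np.linalg.norm(twice - once)
        change_offset = np.linalg.norm(sift_once(tone_8hz + 0.5) - (tone_8hz + 0.5))
        assert change_pure < change_offset


class TestDecompose:
    def test_mono_component_passes_through(self, tone_8hz):
        dec = decompose(tone_8hz)
        assert np.corrcoef(dec.imfs[0], tone_8hz)[0, 1] > 0.99
        assert np.max(np.abs(dec.residual)) < 0.05 * np.max(np.abs(tone_8hz))

    def test_two_tone_separation(self, two_tone):
        mix, hi, lo = two_tone
        dec = decompose(mix)
        interior = slice(64, 576)
        assert np.corrcoef(dec.imfs[0][interior], hi[interior])[0, 1] > 0.95
        assert np.corrcoef(dec.imfs[1][interior], lo[interior])[0, 1] > 0.95

    def test_reconstruction_identity_seeded(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            x = rng.standard_normal(rng.integers(64, 640))
            dec = decompose(x)
            err = np.linalg.norm(dec.reconstruct() - x) / np.linalg.norm(x)
            assert err < 1e-9

    def test_zero_crossing_rate_nonincreasing_on_noise(self):
        rates = np.zeros(5)
        counts = np.zeros(5)
        for seed in range(20):
            x = np.random.default_rng(seed).standard_normal(640)
            dec = decompose(x)
            for k, imf in enumerate(dec.imfs):
                rates[k] += count_zero_crossings(imf)
                counts[k] += 1
        mean_rates = rates[counts > 0] / counts[counts > 0]
        assert np.all(np.diff(mean_rates) <= 0)

    @pytest.mark.parametrize("c", [2.0, 10.0])
    def test_amplitude_equivariance(self, c):
        x = np.random.default_rng(7).standard_normal(640)
        base = decompose(x)
        scaled = decompose(c * x)
        assert scaled.n_imfs == base.n_imfs
        for a, b in zip(scaled.imfs, base.imfs):
            assert np.linalg.norm(a - c * b) <= 1e-6 * np.linalg.norm(c * b)

    def test_offset_migrates_to_slow_components(self, two_tone):
        mix, _, _ = two_tone
        base = decompose(mix)
        shifted = decompose(mix + 5.0)
        interior = slice(64, 576)
        dev = np.max(np.abs(shifted.imfs[0][interior] - base.imfs[0][interior]))
        assert dev <= 0.05 * np.max(np.abs(mix))

    def test_max_imfs_respected(self):
        x = np.random.default_rng(1).standard_normal(640)
        dec = decompose(x, SiftConfig(max_imfs=2))
        assert dec.n_imfs <= 2
        assert np.allclose(dec.reconstruct(), x)

    def test_short_epoch_rejected(self):
        with pytest.raises(InvalidInputError):
            decompose(np.zeros(5))
        with pytest.raises(InvalidInputError):
            Epoch(samples=np.zeros(5), sampling_rate=FS)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        seed=st.integers(0, 2**16),
        n=st.integers(32, 128),
    )
    def test_reconstruction_property(self, seed, n):
        """Telescoping identity holds for arbitrary finite inputs."""
        x = np.random.default_rng(seed).standard_normal(n)
        dec = decompose(x)
        assert np.linalg.norm(dec.reconstruct() - x) <= 1e-9 * np.linalg.norm(x)
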