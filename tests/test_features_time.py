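"""Time-domain feature tests: hand-computed examples, independent oracles and
invariance properties."""

import numpy as np
import pytest
from scipy.signal import lfilter

import swallowflow as sf
from swallowflow.core import DegenerateInputError, SwallowSegment
from swallowflow.features_time import (autocorrelation, cross_entropy_rate,
                                       crosscorr_zero_lag, duration,
                                       entropy_rate, lz76_block_count,
                                       lz_complexity, memory_1e, moments,
                                       pattern_distribution, quantize)

from conftest import FS


class TestMoments:
    def test_symmetric_triple(self):
        mu, var, skew, kurt = moments(np.array([1.0, 2.0, 3.0]))
        assert mu == pytest.approx(2.0)
        assert var == pytest.approx(1.0)
        assert skew == pytest.approx(0.0)

    def test_two_point_distribution_kurtosis_is_one(self):
        x = np.tile([-1.0, 1.0], 500)
        assert moments(x)[3] == pytest.approx(1.0)

    def test_hand_computed_skew(self):
        # x=[0,0,0,1]: m2=3/16, m3=3/32 -> skew = (3/32)/(3/16)^1.5
        x = np.array([0.0, 0.0, 0.0, 1.0])
        expected = (3 / 32) / (3 / 16) ** 1.5
        assert moments(x)[2] == pytest.approx(expected)
        assert expected == pytest.approx(1.1547, abs=1e-4)

    def test_constant_input_rejected(self):
        with pytest.raises(DegenerateInputError):
            moments(np.ones(10))

    def test_gaussian_kurtosis_near_three(self, rng):
        assert moments(rng.standard_normal(200_000))[3] == pytest.approx(3.0, abs=0.1)


class TestQuantize:
    def test_binning_rule_with_max_clipped(self):
        q = quantize(np.array([0.0, 5.0, 10.0]), Q=10, normalize=False)
        assert list(q.symbols) == [0, 5, 9]

    def test_single_level_collapses_everything(self, rng):
        q = quantize(rng.standard_normal(100), Q=1)
        assert set(q.symbols) == {0}

    def test_uniform_ramp_gives_uniform_occupancy(self):
        q = quantize(np.linspace(0, 1, 1000), Q=10, normalize=False)
        counts = np.bincount(q.symbols, minlength=10)
        assert set(counts) == {100}

    def test_constant_input_flagged(self):
        with pytest.raises(DegenerateInputError):
            quantize(np.full(50, 3.3), Q=10)


def _naive_pattern_counts(symbols, L):
    counts = {}
    for i in range(len(symbols) - L + 1):
        key = tuple(symbols[i:i + L])
        counts[key] = counts.get(key, 0) + 1
    return counts


class TestPatternDistribution:
    def test_hand_enumerated_alternating(self):
        pd = pattern_distribution(np.array([0, 1, 0, 1, 0], dtype=np.uint8), 2)
        assert sorted(pd.counts) == [2, 2]
        assert pd.SE == pytest.approx(np.log(2))
        assert pd.perc == 0.0

    def test_constant_sequence(self):
        pd = pattern_distribution(np.zeros(20, dtype=np.uint8), 3)
        assert pd.SE == 0.0 and pd.perc == 0.0

    def test_all_distinct_patterns(self):
        pd = pattern_distribution(np.array([0, 1, 2, 3, 3], dtype=np.uint8), 2)
        assert pd.perc == 1.0
        assert pd.SE == pytest.approx(np.log(4))

    @pytest.mark.parametrize("n, L, Q", [(200, 2, 3), (500, 5, 4), (2000, 30, 10)])
    def test_matches_naive_dictionary_count(self, n, L, Q, rng):
        sym = rng.integers(0, Q, size=n).astype(np.uint8)
        pd = pattern_distribution(sym, L)
        naive = _naive_pattern_counts(sym, L)
        assert sorted(pd.counts) == sorted(naive.values())
        singles = sum(1 for v in naive.values() if v == 1)
        assert pd.perc == pytest.approx(singles / (n - L + 1))


class TestEntropyRate:
    def test_constant_signal_maximally_regular(self):
        assert entropy_rate(np.full(100, 2.5)) == 1.0

    def test_iid_noise_is_irregular(self, rng):
        assert entropy_rate(rng.uniform(size=5000)) < 0.2

    def test_slow_sinusoid_is_regular_and_noise_reduces_it(self, rng):
        n = 5000
        t = np.arange(n)
        clean = np.sin(2 * np.pi * 20 * t / n)  # 20 periods
        rho_clean = entropy_rate(clean)
        noisy = clean + np.sqrt(0.5) * rng.standard_normal(n)  # SNR 0 dB
        assert rho_clean > 0.8
        assert rho_clean > entropy_rate(noisy)

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError):
            entropy_rate(np.sin(np.arange(25.0)))


class TestCrossEntropyRate:
    def test_identical_signals_synchronized(self):
        n = 2000
        x = np.sin(2 * np.pi * 10 * np.arange(n) / n)
        assert cross_entropy_rate(x, x) >= 0.9

    def test_independent_noise_uncoupled(self, rng):
        assert cross_entropy_rate(rng.standard_normal(5000),
                                  rng.standard_normal(5000)) < 0.2

    def test_self_coupling_beats_independent(self, rng):
        n = 1500
        for _ in range(10):
            x = np.sin(2 * np.pi * 8 * np.arange(n) / n + rng.uniform(0, 6))
            x = x + 0.2 * rng.standard_normal(n)
            y = rng.standard_normal(n)
            assert cross_entropy_rate(x, x) >= cross_entropy_rate(x, y)

    def test_constant_channel_rejected(self):
        with pytest.raises(DegenerateInputError):
            cross_entropy_rate(np.ones(100), np.sin(np.arange(100.0)))


class TestMemory:
    def test_alternating_signal_one_sample_memory(self):
        x = np.tile([1.0, -1.0], 50)
        assert memory_1e(x, FS) == pytest.approx(1.0 / FS)

    def test_white_noise_memory_is_one_sample(self):
        hits = 0
        for seed in range(100):
            x = np.random.default_rng(seed).standard_normal(100_000)
            hits += memory_1e(x, 1.0) == 1.0
        assert hits >= 95

    def test_ar1_analytic_decay(self):
        # AR(1) with phi = e^(-1/10): r(tau) = e^(-tau/10), crosses 1/e at 10
        phi = np.exp(-0.1)
        x = lfilter([1.0], [1.0, -phi],
                    np.random.default_rng(42).standard_normal(200_000))
        tau = memory_1e(x, 1.0)
        assert abs(tau - 10) <= 2

    def test_constant_signal_rejected(self):
        with pytest.raises(DegenerateInputError):
            memory_1e(np.zeros(100), FS)


def _lz76_oracle(seq):
    """Brute-force exhaustive-history parsing on tuples."""
    s = list(seq)
    n = len(s)
    k = 0
    i = 0
    while i < n:
        l = 1
        while i + l <= n and any(s[j:j + l] == s[i:i + l] for j in range(i)):
            l += 1
        k += 1
        i += l
    return k


class TestLempelZiv:
    def test_constant_sequence_two_blocks(self):
        assert lz76_block_count(np.zeros(100, dtype=np.uint8)) == 2
        c = lz_complexity(np.full(100, 7.7))
        assert c == pytest.approx(2 * np.log(100) / np.log(100) / 100)
        assert c == pytest.approx(0.02)

    def test_random_more_complex_than_constant(self):
        c_const = lz_complexity(np.full(100, 1.0))
        for seed in range(20):
            x = np.random.default_rng(seed).uniform(size=100)
            assert lz_complexity(x) > c_const

    def test_block_count_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            n = int(rng.integers(2, 65))
            q = int(rng.integers(2, 5))
            s = rng.integers(0, q, size=n)
            assert lz76_block_count(s.astype(np.uint8)) == _lz76_oracle(list(s))


class TestDurationAndCrossCorr:
    def test_two_samples_at_10khz(self):
        assert duration(2, 10_000) == pytest.approx(0.0001)

    def test_single_sample_zero_duration(self):
        assert duration(1, 10_000) == 0.0

    def test_published_water_mean_sample_count(self):
        # ~21k samples at 10 kHz corresponds to the ~2.097 s mean duration
        assert duration(20_971, 10_000) == pytest.approx(2.097)

    def test_crosscorr_limits(self, rng):
        x = rng.standard_normal(500)
        assert crosscorr_zero_lag(x, x) == pytest.approx(1.0)
        assert crosscorr_zero_lag(x, -x) == pytest.approx(-1.0)

    def test_orthogonal_phases_uncorrelated(self):
        x = np.tile([1.0, 0.0, -1.0, 0.0], 25)
        y = np.roll(x, 1)
        assert abs(crosscorr_zero_lag(x, y)) < 1e-12

    def test_constant_channel_rejected(self, rng):
        with pytest.raises(DegenerateInputError):
            crosscorr_zero_lag(np.ones(100), rng.standard_normal(100))


class TestInvarianceProperties:
    @pytest.mark.parametrize("a, b", [(2.5, 0.0), (0.3, -4.0), (1000.0, 7.0)])
    def test_affine_invariance(self, a, b, rng):
        x = np.sin(2 * np.pi * 10 * np.arange(1000) / 1000)
        x = x + 0.3 * rng.standard_normal(1000)
        y = a * x + b
        assert entropy_rate(y) == pytest.approx(entropy_rate(x), abs=1e-9)
        assert lz_complexity(y) == pytest.approx(lz_complexity(x), abs=1e-9)
        assert memory_1e(y, FS) == pytest.approx(memory_1e(x, FS))
        _, _, sk_x, ku_x = moments(x)
        _, _, sk_y, ku_y = moments(y)
        assert sk_y == pytest.approx(sk_x) and ku_y == pytest.approx(ku_x)
        z = rng.standard_normal(1000)
        assert crosscorr_zero_lag(y, z) == pytest.approx(crosscorr_zero_lag(x, z))

    def test_rho_and_lambda_stay_in_unit_interval(self, rng):
        for _ in range(5):
            x = rng.standard_normal(200)
            y = rng.standard_normal(200)
            assert 0.0 <= entropy_rate(x, l_min=3, l_max=6) <= 1.0
            assert 0.0 <= cross_entropy_rate(x, y, l_min=3, l_max=6) <= 1.0


class TestRegularityOrderingOnGenerator:
    def test_viscosity_orders_rho_and_lz(self, profiles):
        """Thicker stimuli give more regular signals: higher entropy rate,
        lower Lempel-Ziv complexity (the headline mechanism)."""
        rng = np.random.default_rng(2024)
        mean_rho, mean_lz = {}, {}
        for name in sf.STIMULI:
            rhos, lzs = [], []
            for _ in range(200):
                ap, _, _ = sf.generate_swallow(profiles[name], "discrete", rng,
                                               sampling_rate=FS)
                rhos.append(entropy_rate(ap))
                lzs.append(lz_complexity(ap))
            mean_rho[name] = np.mean(rhos)
            mean_lz[name] = np.mean(lzs)
        assert mean_rho["honey"] > mean_rho["water"]
        assert mean_lz["honey"] < mean_lz["water"]
        rho_seq = [mean_rho[s] for s in sf.STIMULI]
        lz_seq = [mean_lz[s] for s in sf.STIMULI]
        assert rho_seq == sorted(rho_seq)
        assert lz_seq == sorted(lz_seq, reverse=True)
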