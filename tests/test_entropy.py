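"""Permutation entropy: exact values, oracle equivalence, and invariances."""

from __future__ import annotations

import numpy as np
import pytest

from conftest import pe_bruteforce
from eegfuse.entropy import PEConfig, pe_per_band, permutation_entropy, time_varying_pe
from eegfuse.preprocess import BandDefinition, DEFAULT_BANDS, EpochSet

# Length-14 sequence whose 12 ordinal triplets visit all 6 patterns twice.
UNIFORM_PATTERN_SEQ = np.array([3, 2, 0, 5, 4, 7, 13, 10, 11, 6, 9, 12, 8, 1], dtype=float)


class TestPermutationEntropy:
    def test_monotone_sequence_has_zero_entropy(self):
        assert permutation_entropy(np.arange(1.0, 101.0), PEConfig(m=3)) == 0.0

    def test_uniform_pattern_sequence_reaches_log_m_factorial(self):
        h = permutation_entropy(UNIFORM_PATTERN_SEQ, PEConfig(m=3))
        assert h == pytest.approx(np.log(6), abs=1e-14)
        # cross-checked against the brute-force oracle
        assert h == pytest.approx(pe_bruteforce(UNIFORM_PATTERN_SEQ, 3), abs=1e-14)

    def test_worked_example_matches_bruteforce(self):
        x = np.array([4.0, 7.0, 9.0, 10.0, 6.0, 11.0, 3.0])
        got = permutation_entropy(x, PEConfig(m=3))
        assert got == pytest.approx(pe_bruteforce(x, 3), abs=1e-14)

    @pytest.mark.parametrize("m", [3, 4, 5])
    @pytest.mark.parametrize("tau", [1, 2, 3])
    def test_oracle_equivalence_on_random_vectors(self, m, tau, rng):
        for _ in range(20):
            n = int(rng.integers(50, 500))
            x = rng.standard_normal(n)
            assert permutation_entropy(x, PEConfig(m=m, tau=tau)) == pytest.approx(
                pe_bruteforce(x, m, tau), abs=1e-12
            )

    def test_bounds(self, rng):
        cfg = PEConfig(m=4)
        h = permutation_entropy(rng.standard_normal(300), cfg)
        assert 0.0 <= h <= cfg.max_entropy
        hn = permutation_entropy(rng.standard_normal(300), PEConfig(m=4, normalize=True))
        assert 0.0 <= hn <= 1.0

    def test_invariant_under_strictly_monotone_transforms(self, rng):
        x = rng.standard_normal(400)
        cfg = PEConfig(m=4)
        base = permutation_entropy(x, cfg)
        assert permutation_entropy(np.exp(x), cfg) == base
        assert permutation_entropy(3.0 * x + 1.0, cfg) == base

    def test_tie_handling_is_deterministic(self):
        # swapping the origin of equal values must not change the pattern
        cfg = PEConfig(m=3)
        a = np.array([1.0, 2.0, 2.0, 1.0, 3.0, 2.0, 2.0])
        b = a.copy()
        assert permutation_entropy(a, cfg) == permutation_entropy(b, cfg)
        assert permutation_entropy(a, cfg) == pytest.approx(pe_bruteforce(a, 3), abs=1e-14)

    def test_too_short_input_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            permutation_entropy(np.arange(3.0), PEConfig(m=4))

    def test_bad_order_rejected(self):
        with pytest.raises(ValueError, match="pattern length"):
            PEConfig(m=1)
        with pytest.raises(ValueError, match="pattern length"):
            PEConfig(m=11)

    def test_log_base_two(self):
        h_e = permutation_entropy(UNIFORM_PATTERN_SEQ, PEConfig(m=3))
        h_2 = permutation_entropy(UNIFORM_PATTERN_SEQ, PEConfig(m=3, log_base="2"))
        assert h_2 == pytest.approx(h_e / np.log(2), rel=1e-12)


class TestTimeVaryingPE:
    def test_single_window_degenerates_to_plain_pe(self, rng):
        x = rng.standard_normal(503)
        cfg = PEConfig(m=3)
        tv = time_varying_pe(x, cfg, n_windows=1)
        assert tv.shape == (1,)
        assert tv[0] == permutation_entropy(x[:503], cfg)

    def test_stationary_noise_windows_agree_with_global_value(self, rng):
        x = rng.standard_normal(12_000)
        cfg = PEConfig(m=3)
        tv = time_varying_pe(x, cfg, n_windows=10)
        # Monte-Carlo reference for windows of the same length; PE is
        # bounded above by log m! so its null distribution is left-skewed
        # and an empirical range beats a Gaussian band
        null = np.array(
            [
                permutation_entropy(np.random.default_rng(k).standard_normal(1200), cfg)
                for k in range(200)
            ]
        )
        lo = null.min() - 2 * null.std()
        assert np.all(tv >= lo) and np.all(tv <= cfg.max_entropy)

    def test_changepoint_raises_second_half(self, rng):
        t = np.arange(3_000)
        near_periodic = np.sin(2 * np.pi * t / 40) + 0.01 * rng.standard_normal(t.size)
        noise = rng.standard_normal(t.size)
        x = np.concatenate([near_periodic, noise])
        tv = time_varying_pe(x, PEConfig(m=4), n_windows=12)
        assert tv[6:].mean() > tv[:6].mean()

    def test_argument_validation(self, rng):
        x = rng.standard_normal(100)
        with pytest.raises(ValueError, match="exactly one"):
            time_varying_pe(x, PEConfig(), n_windows=2, window_samples=50)
        with pytest.raises(ValueError, match="too short"):
            time_varying_pe(x, PEConfig(m=5), window_samples=4)


class TestPePerBand:
    def test_allpass_band_matches_unfiltered(self, rng):
        fs = 250.0
        x = rng.standard_normal((1, 1, 2_500))
        eps = EpochSet(epochs=x, fs=fs, channel_labels=["c0"])
        cfg = PEConfig(m=3)
        allpass = BandDefinition("allpass", 0.5, fs / 2)
        table = pe_per_band(eps, [allpass], cfg)
        plain = permutation_entropy(x[0, 0], cfg)
        assert table["pe"].iloc[0] == pytest.approx(plain, abs=1e-3)

    def test_degenerate_band_power_is_safe(self, rng):
        # delta-limited noise examined in gamma2: near-zero power, still finite PE
        from eegfuse.preprocess import bandpass_array

        fs = 1000.0
        x = bandpass_array(rng.standard_normal(5_000), DEFAULT_BANDS["delta"], fs)
        eps = EpochSet(epochs=x[None, None, :], fs=fs, channel_labels=["c0"])
        table = pe_per_band(eps, [DEFAULT_BANDS["gamma2"]], PEConfig(m=3))
        assert np.isfinite(table["pe"].iloc[0])

    def test_table_shape(self, rng):
        eps = EpochSet(
            epochs=rng.standard_normal((2, 3, 1_000)), fs=250.0,
            channel_labels=["a", "b", "c"],
        )
        bands = [DEFAULT_BANDS["delta"], DEFAULT_BANDS["alpha"]]
        table = pe_per_band(eps, bands, PEConfig(m=3))
        assert len(table) == 2 * 2 * 3
        assert set(table["band"]) == {"delta", "alpha"}
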