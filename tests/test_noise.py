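"""Multi-coil magnitude noise statistics and the acquisition simulators."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import gammaln

from dvcqmri import (
    CoilNoiseModel,
    add_multicoil_magnitude_noise,
    build_lookup_table,
    invert_ratio_to_t1,
    mp2rage_combine,
    simulate_mp2rage_pair,
    simulate_msme_series,
    simulate_ute_volume,
    tissue_params_for,
)


def chi_mean(L):
    return np.sqrt(2.0) * np.exp(gammaln(L + 0.5) - gammaln(L))


class TestMagnitudeNoise:
    def test_noiseless_identity(self, rng):
        clean = rng.uniform(0, 10, (8, 8, 8))
        out = add_multicoil_magnitude_noise(clean, CoilNoiseModel(sigma=0.0))
        assert np.array_equal(out, clean)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            CoilNoiseModel(sigma=-1.0)

    def test_negative_amplitude_rejected(self):
        with pytest.raises(ValueError):
            add_multicoil_magnitude_noise(np.array([-1.0]), CoilNoiseModel(sigma=1.0))

    @pytest.mark.parametrize("L", [1, 2, 4, 8])
    def test_noise_only_mean_matches_chi(self, L):
        """Empirical noise-only magnitude mean = sqrt(2)*gamma(L+1/2)/gamma(L)*sigma."""
        n = 200_000
        out = add_multicoil_magnitude_noise(
            np.zeros(n), CoilNoiseModel(sigma=1.0, n_channels=L, seed=L))
        se = out.std() / np.sqrt(n)
        assert abs(out.mean() - chi_mean(L)) < 3 * se

    @pytest.mark.parametrize("a_over_sigma", [0.0, 5.0, 20.0])
    @pytest.mark.parametrize("L", [1, 2, 4])
    def test_second_moment_conservation(self, a_over_sigma, L):
        """E[M^2] = A^2 + 2*L*sigma^2 for the sum-of-squares magnitude."""
        sigma, n = 1.5, 200_000
        A = a_over_sigma * sigma
        out = add_multicoil_magnitude_noise(
            np.full(n, A), CoilNoiseModel(sigma=sigma, n_channels=L, seed=7))
        m2 = out**2
        se = m2.std() / np.sqrt(n)
        assert abs(m2.mean() - (A**2 + 2 * L * sigma**2)) < 3 * se

    def test_seeded_reproducibility(self):
        clean = np.linspace(0, 5, 1000)
        a = add_multicoil_magnitude_noise(clean, CoilNoiseModel(sigma=1.0, seed=3))
        b = add_multicoil_magnitude_noise(clean, CoilNoiseModel(sigma=1.0, seed=3))
        c = add_multicoil_magnitude_noise(clean, CoilNoiseModel(sigma=1.0, seed=4))
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)


class TestMSMESimulation:
    def test_noiseless_decay_closed_form(self, small_label, healthy_table):
        series = simulate_msme_series(small_label, healthy_table)
        np_voxel = np.argwhere(small_label.labels == 1)[0]
        sig = series.data[tuple(np_voxel)]
        t = series.echo_times_ms
        # ratio of signals isolates the exponential decay
        expected = np.exp(-(105.0 - t[0]) / 105.0)
        idx = np.argmin(np.abs(t - 105.0))
        assert sig[idx] / sig[0] == pytest.approx(np.exp(-(t[idx] - t[0]) / 105.0), rel=1e-12)
        assert sig[0] == pytest.approx(100.0 * np.exp(-t[0] / 105.0), rel=1e-12)
        del expected

    def test_background_noise_stationary_chi(self, small_label, healthy_table):
        sigma = 0.7
        series = simulate_msme_series(
            small_label, healthy_table,
            noise=CoilNoiseModel(sigma=sigma, n_channels=4, seed=11))
        bg = series.data[small_label.labels == 0, :]
        mean_per_echo = bg.mean(axis=0)
        expect = chi_mean(4) * sigma
        se = bg.std() / np.sqrt(bg.shape[0])
        assert np.all(np.abs(mean_per_echo - expect) < 4 * se)

    def test_bad_echo_grid_rejected(self, small_label, healthy_table):
        with pytest.raises(ValueError):
            simulate_msme_series(small_label, healthy_table, np.array([5.0, 4.0, 6.0]))

    def test_unknown_label_rejected(self, small_label, healthy_table):
        table = tissue_params_for("mature", "healthy", "D0")
        frame = table.frame.drop(index=4)  # remove GP entry
        from dvcqmri.tissues import TissueParamTable
        broken = TissueParamTable("mature", "healthy", "D0", frame)
        with pytest.raises(ValueError, match="labels without tissue parameters"):
            simulate_msme_series(small_label, broken)


class TestUTESimulation:
    def test_noiseless_amplitude_map(self, small_label, healthy_table):
        vol = simulate_ute_volume(small_label, healthy_table, CoilNoiseModel(sigma=0.0))
        amp = healthy_table.ute_amplitude(1.0)
        assert np.array_equal(vol, amp[small_label.labels])

    def test_amplitude_tracks_sigma(self, small_label, healthy_table):
        vol = simulate_ute_volume(small_label, healthy_table,
                                  CoilNoiseModel(sigma=2.0, seed=5))
        af = vol[small_label.labels == 2]
        assert af.mean() == pytest.approx(16.8 * 2.0, rel=0.05)

    def test_af_brighter_than_np(self, small_label, healthy_table):
        vol = simulate_ute_volume(small_label, healthy_table, CoilNoiseModel(sigma=0.0))
        assert vol[small_label.labels == 2].mean() > vol[small_label.labels == 1].mean()


class TestMP2RAGESimulation:
    def test_noiseless_roundtrip_recovers_t1(self, small_label, healthy_table):
        gre1, gre2 = simulate_mp2rage_pair(small_label, healthy_table,
                                           noise=CoilNoiseModel(sigma=0.0))
        ratio, degenerate = mp2rage_combine(gre1, gre2)
        t1map = invert_ratio_to_t1(ratio, build_lookup_table(), extra_invalid=degenerate)
        for structure, truth in (("NP", 1810.0), ("AF", 803.0), ("SB", 568.0)):
            sel = small_label.mask(structure) & t1map.valid
            assert np.nanmean(t1map.values_ms[sel]) == pytest.approx(truth, abs=0.5)

    def test_seeding_contract(self, small_label, healthy_table):
        clean = simulate_mp2rage_pair(small_label, healthy_table,
                                      noise=CoilNoiseModel(sigma=0.0))
        a = simulate_mp2rage_pair(small_label, healthy_table,
                                  noise=CoilNoiseModel(sigma=0.5, seed=1))
        b = simulate_mp2rage_pair(small_label, healthy_table,
                                  noise=CoilNoiseModel(sigma=0.5, seed=2))
        assert not np.array_equal(a[0], b[0])
        # noise is zero-mean around the same clean signal
        assert np.mean(a[0] - clean[0]) == pytest.approx(0.0, abs=0.01)
        assert np.mean(b[0] - clean[0]) == pytest.approx(0.0, abs=0.01)


@settings(deadline=None, derandomize=True, max_examples=50)
@given(st.floats(0.0, 50.0), st.integers(1, 8), st.integers(0, 2**31 - 1))
def test_magnitude_nonnegative_and_deterministic(amplitude, L, seed):
    model = CoilNoiseModel(sigma=1.0, n_channels=L, seed=seed)
    clean = np.full(16, amplitude)
    out = add_multicoil_magnitude_noise(clean, model)
    assert np.all(out >= 0)
    assert np.array_equal(out, add_multicoil_magnitude_noise(clean, model))
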