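"""Decay model, fraction algebra and Monte-Carlo simulator."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

import flimmix as fm
from flimmix.decay import _background_level

from conftest import moment_lifetime


class TestFractionAlgebra:
    @pytest.mark.parametrize(
        "amplitudes, lifetimes, expected",
        [
            ([1.0], [5.0], [1.0]),
            ([2.0, 1.0], [5.0, 10.0], [0.5, 0.5]),
            ([2.0, 1.0], [10.6, 5.6], [21.2 / 26.8, 5.6 / 26.8]),
        ],
    )
    def test_fractional_contributions(self, amplitudes, lifetimes, expected):
        np.testing.assert_allclose(
            fm.fractional_contributions(amplitudes, lifetimes), expected, atol=1e-12
        )

    @pytest.mark.parametrize(
        "volumes, intensities, expected",
        [
            ([100.0], [7.3], [1.0]),
            ([100.0, 100.0], [2.7, 2.7], [0.5, 0.5]),
            ([100.0, 25.0], [1.0, 1.0], [0.8, 0.2]),
        ],
    )
    def test_reference_fractions(self, volumes, intensities, expected):
        np.testing.assert_allclose(
            fm.reference_fractions(volumes, intensities), expected, atol=1e-12
        )

    def test_degenerate_and_mismatched_inputs_raise(self):
        with pytest.raises(fm.DegenerateMixtureError):
            fm.fractional_contributions([0.0, 0.0], [5.0, 10.0])
        with pytest.raises(fm.FlimmixError):
            fm.fractional_contributions([1.0], [5.0, 10.0])
        with pytest.raises(fm.DegenerateMixtureError):
            fm.reference_fractions([0.0], [3.0])

    def test_amplitude_normalization(self):
        np.testing.assert_allclose(
            fm.amplitudes_from_fractions([1.0], [5.0]), [0.2], atol=1e-15
        )
        alpha = fm.amplitudes_from_fractions([0.5, 0.5], [5.0, 10.0])
        assert alpha[0] * 5.0 == pytest.approx(alpha[1] * 10.0, abs=1e-15)

    @given(
        st.lists(st.floats(0.01, 100.0), min_size=1, max_size=6),
        st.randoms(use_true_random=False),
    )
    def test_fraction_amplitude_round_trip(self, lifetimes, random):
        """fractional_contributions and amplitudes_from_fractions invert
        each other over random simplex points."""
        raw = np.array([random.random() + 1e-3 for _ in lifetimes])
        fractions = raw / raw.sum()
        alpha = fm.amplitudes_from_fractions(fractions, lifetimes)
        back = fm.fractional_contributions(alpha, lifetimes)
        np.testing.assert_allclose(back, fractions, atol=1e-12)
        assert np.all(back >= 0) and back.sum() == pytest.approx(1.0, abs=1e-9)


class TestExpectedHistogram:
    def test_pure_exponential_bin_integrals(self, bare_instrument):
        """Without laser pulse and jitter the signal expectation per bin is
        the exact integral of the exponential density."""
        tau = 10.0
        mix = fm.MixtureSample.from_fractions([tau], [1.0])
        expected = fm.expected_histogram(mix, bare_instrument)
        edges = np.arange(bare_instrument.n_bins + 1) * bare_instrument.bin_width_ns
        exact = bare_instrument.n_photons * (
            np.exp(-edges[:-1] / tau) - np.exp(-edges[1:] / tau)
        )
        np.testing.assert_allclose(expected, exact, rtol=1e-9, atol=1e-9)

    def test_signal_conservation(self, bare_instrument):
        tau = 15.0
        mix = fm.MixtureSample.from_fractions([tau], [1.0])
        total = fm.expected_histogram(mix, bare_instrument).sum()
        in_window = 1.0 - np.exp(-bare_instrument.window_ns / tau)
        assert total == pytest.approx(bare_instrument.n_photons * in_window, rel=1e-9)

    def test_snr_sets_peak_to_background_ratio(self):
        inst = fm.InstrumentConfig(snr=100.0)
        mix = fm.MixtureSample.from_fractions([4.0, 9.0], [0.3, 0.7])
        with_bg = fm.expected_histogram(mix, inst)
        no_bg = fm.expected_histogram(
            mix, fm.InstrumentConfig(snr=None)
        )
        background = with_bg - no_bg
        assert np.ptp(background) == pytest.approx(0.0, abs=1e-9)
        assert no_bg.max() / background[0] == pytest.approx(100.0, rel=1e-9)


class TestSimulateDecay:
    def test_no_photons_no_background_is_empty(self, tiny_instrument):
        inst = fm.InstrumentConfig(window_ns=80.0, n_photons=0, snr=None)
        mix = fm.MixtureSample.from_fractions([4.0], [1.0])
        curve = fm.simulate_decay(mix, inst, seed=0)
        assert curve.counts.sum() == 0

    def test_photon_conservation_without_background(self, bare_instrument):
        mix = fm.MixtureSample.from_fractions([5.0], [1.0])
        curve = fm.simulate_decay(mix, bare_instrument, seed=1)
        # window (1.28 us) >> tau, so virtually every photon lands in-window
        assert curve.counts.sum() <= bare_instrument.n_photons
        assert curve.counts.sum() == bare_instrument.n_photons

    def test_seed_is_mandatory(self, tiny_instrument):
        mix = fm.MixtureSample.from_fractions([4.0, 9.0], [0.5, 0.5])
        with pytest.raises(fm.ReproducibilityError):
            fm.simulate_decay(mix, tiny_instrument, seed=None)

    def test_same_seed_identical_curves(self, tiny_instrument):
        mix = fm.MixtureSample.from_fractions([4.0, 9.0], [0.2, 0.8])
        a = fm.simulate_decay(mix, tiny_instrument, seed=7)
        b = fm.simulate_decay(mix, tiny_instrument, seed=7)
        np.testing.assert_array_equal(a.counts, b.counts)

    def test_mean_arrival_time_matches_lifetime(self, bare_instrument):
        """With instrument effects off, arrivals are Exponential(tau)."""
        tau = 10.0
        inst = fm.InstrumentConfig(
            laser_fwhm_ns=0, laser_turnoff_ns=0, jitter_sigma_ns=0, snr=None,
            n_photons=100_000,
        )
        curve = fm.simulate_decay(fm.MixtureSample.from_fractions([tau], [1.0]), inst, seed=3)
        se = tau / np.sqrt(inst.n_photons)
        assert moment_lifetime(curve) == pytest.approx(tau, abs=3 * se)

    @pytest.mark.parametrize("tau", [1.0, 5.0, 20.0])
    def test_lifetime_recovery(self, tau):
        """The lifetime recovered from a simulated mono-exponential curve
        equals the configured tau within 3 standard errors."""
        inst = fm.InstrumentConfig(
            laser_fwhm_ns=0, laser_turnoff_ns=0, jitter_sigma_ns=0, snr=None
        )
        curve = fm.simulate_decay(
            fm.MixtureSample.from_fractions([tau], [1.0]), inst, seed=11
        )
        se = tau / np.sqrt(inst.n_photons)
        assert moment_lifetime(curve) == pytest.approx(tau, abs=3 * se)

    def test_monte_carlo_matches_expected_histogram(self):
        """Chi-square agreement between the empirical histogram and the
        analytic expectation, with all instrument effects on."""
        inst = fm.InstrumentConfig(n_photons=1_000_000)
        mix = fm.MixtureSample.from_fractions([4.0, 9.0], [0.35, 0.65])
        curve = fm.simulate_decay(mix, inst, seed=5)
        expected = fm.expected_histogram(mix, inst)
        keep = expected > 20
        x2 = float(np.sum((curve.counts[keep] - expected[keep]) ** 2 / expected[keep]))
        dof = int(keep.sum())
        p = stats.chi2.sf(x2, dof)
        assert p > 0.001

    def test_poisson_error_scaling(self):
        """Doubling the photon budget shrinks the relative bin-count error
        by sqrt(2)."""
        mix = fm.MixtureSample.from_fractions([5.0], [1.0])
        rel = {}
        for n in (2_000, 4_000):
            inst = fm.InstrumentConfig(window_ns=80.0, n_photons=n, snr=None)
            peak = np.array(
                [fm.simulate_decay(mix, inst, seed=100 + k).counts[0] for k in range(150)]
            )
            rel[n] = peak.std() / peak.mean()
        assert rel[2_000] / rel[4_000] == pytest.approx(np.sqrt(2.0), rel=0.25)


class TestGenerateDataset:
    def test_shapes_labels_and_determinism(self, tiny_instrument):
        ds = fm.generate_dataset(10, [4.0, 9.0], tiny_instrument, seed=21)
        assert len(ds) == 10 and ds.labels.shape == (10, 2)
        np.testing.assert_allclose(ds.labels.sum(axis=1), 1.0, atol=1e-9)
        ds2 = fm.generate_dataset(10, [4.0, 9.0], tiny_instrument, seed=21)
        np.testing.assert_array_equal(ds.count_matrix(), ds2.count_matrix())
        np.testing.assert_array_equal(ds.labels, ds2.labels)

    def test_flat_prior_marginal_mean(self):
        inst = fm.InstrumentConfig(window_ns=5.0, n_photons=10, snr=None)
        ds = fm.generate_dataset(4_000, [4.0, 9.0], inst, prior="flat", seed=8)
        se = (1.0 / np.sqrt(12)) / np.sqrt(len(ds))
        assert ds.labels[:, 0].mean() == pytest.approx(0.5, abs=3 * se)

    def test_invalid_prior_rejected(self, tiny_instrument):
        with pytest.raises(fm.FlimmixError):
            fm.generate_dataset(5, [4.0, 9.0], tiny_instrument, prior=[1.0], seed=0)

    def test_background_level_follows_configured_snr(self):
        """The estimator max(counts)/tail-mean recovers the configured SNR."""
        inst = fm.InstrumentConfig(snr=100.0)
        mix = fm.MixtureSample.from_fractions([10.0], [1.0])
        estimates = [
            fm.snr_of(fm.simulate_decay(mix, inst, seed=s)) for s in range(50)
        ]
        assert np.mean(estimates) == pytest.approx(100.0, rel=0.2)


class TestSnrOf:
    def test_reference_values(self):
        time_ns = np.arange(100) * 0.3125
        counts = np.full(100, 10)
        counts[0] = 1000
        curve = fm.DecayCurve(counts=counts, time_ns=time_ns)
        assert fm.snr_of(curve) == pytest.approx(100.0)
        flat = fm.DecayCurve(counts=np.full(100, 7), time_ns=time_ns)
        assert fm.snr_of(flat) == pytest.approx(1.0)

    def test_zero_tail_unbounded(self):
        time_ns = np.arange(10) * 1.0
        counts = np.array([5, 4, 3, 2, 1, 0, 0, 0, 0, 0])
        curve = fm.DecayCurve(counts=counts, time_ns=time_ns)
        assert fm.snr_of(curve, tail_fraction=0.2) == np.inf


def test_background_level_matches_expected_peak():
    inst = fm.InstrumentConfig(snr=50.0)
    mix = fm.MixtureSample.from_fractions([4.0, 9.0], [0.5, 0.5])
    no_bg = fm.expected_histogram(mix, fm.InstrumentConfig(snr=None))
    assert _background_level(mix, inst) == pytest.approx(no_bg.max() / 50.0, rel=1e-12)
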