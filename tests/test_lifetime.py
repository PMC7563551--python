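"""TCSPC decay fitting and average-lifetime arithmetic."""

import numpy as np
import pytest

from quenchbind import (
    DecayHistogram,
    GroundTruth,
    ValidationError,
    average_lifetime,
    fit_decay,
    lifetime_ratio_series,
    simulate_decay,
)


class TestAverageLifetime:
    def test_hand_evaluation(self):
        assert average_lifetime([0.5, 0.5], [2.0, 4.0]) == pytest.approx(10.0 / 3.0)

    def test_single_component_identity(self):
        assert average_lifetime([1.0], [4.8]) == pytest.approx(4.8)

    def test_permutation_symmetry(self):
        assert average_lifetime([0.3, 0.7], [1.5, 5.0]) == pytest.approx(
            average_lifetime([0.7, 0.3], [5.0, 1.5])
        )

    def test_bounded_by_extremes(self):
        avg = average_lifetime([0.2, 0.8], [1.0, 6.0])
        assert 1.0 <= avg <= 6.0

    def test_zero_amplitudes_rejected(self):
        with pytest.raises(ValidationError):
            average_lifetime([0.0, 0.0], [1.0, 2.0])


class TestFitDecay:
    def test_noiseless_single_exponential_exact(self):
        t = np.linspace(0.0, 50.0, 1024)
        counts = 1e4 * np.exp(-t / 4.8)
        fit = fit_decay(DecayHistogram(times=t, counts=counts), 1)
        assert fit.taus[0] == pytest.approx(4.8, rel=1e-6)
        assert fit.tau_avg == pytest.approx(4.8, rel=1e-6)

    def test_poisson_biexponential_recovery(self):
        # per-histogram, the major component and <tau> are the statistically
        # stable quantities at 1e5 counts; the minor component's per-seed
        # scatter (~4-5% s.d.) is covered by the replicate-median test below
        gt = GroundTruth(tau0=4.8, seed=11, decay_alphas=(0.3, 0.7),
                         decay_taus=(1.5, 5.0))
        hist = simulate_decay(gt, 0.0, total_counts=1e5)
        fit = fit_decay(hist, 2)
        assert fit.taus[1] == pytest.approx(5.0, rel=0.05)
        true_avg = (0.3 * 1.5**2 + 0.7 * 5.0**2) / (0.3 * 1.5 + 0.7 * 5.0)
        assert fit.tau_avg == pytest.approx(true_avg, rel=0.02)

    def test_overfit_single_exponential_robust(self):
        # two-component fit of a pure single exponential still recovers <tau>
        gt = GroundTruth(tau0=4.8, seed=12)
        hist = simulate_decay(gt, 0.0, total_counts=1e5)
        fit = fit_decay(hist, 2)
        assert fit.tau_avg == pytest.approx(4.8, rel=0.01)

    def test_alphas_normalised(self):
        gt = GroundTruth(tau0=4.8, seed=13, decay_alphas=(0.3, 0.7),
                         decay_taus=(1.5, 5.0))
        fit = fit_decay(simulate_decay(gt, 0.0), 2)
        assert sum(fit.alphas) == pytest.approx(1.0, rel=1e-9)
        assert fit.taus == tuple(sorted(fit.taus))

    def test_component_recovery_over_replicates(self):
        """Median relative error of fitted components < 5% at 1e5 counts."""
        errs = []
        for seed in range(20):
            gt = GroundTruth(tau0=4.8, seed=100 + seed, decay_alphas=(0.3, 0.7),
                             decay_taus=(1.5, 5.0))
            fit = fit_decay(simulate_decay(gt, 0.0, total_counts=1e5), 2)
            errs.append(abs(fit.taus[0] / 1.5 - 1.0))
            errs.append(abs(fit.taus[1] / 5.0 - 1.0))
        assert np.median(errs) < 0.05

    def test_insufficient_counts(self):
        t = np.linspace(0.0, 50.0, 64)
        with pytest.raises(ValidationError):
            fit_decay(DecayHistogram(times=t, counts=np.ones(64)), 1)


class TestRatioSeries:
    def test_static_series_flat(self):
        gt = GroundTruth(ka=2.41e4, tau0=4.8, mechanism="static", seed=21)
        fits = [
            fit_decay(simulate_decay(gt, lc, seed_offset=i), 1)
            for i, lc in enumerate(np.linspace(0.0, 4.9e-5, 8))
        ]
        ratios = lifetime_ratio_series(fits)
        assert all(0.98 <= r <= 1.02 for _, r in ratios)

    def test_identical_histograms_give_unit_ratios(self):
        gt = GroundTruth(tau0=4.8, seed=22)
        fit0 = fit_decay(simulate_decay(gt, 0.0), 1)
        fits = [fit0] + [
            type(fit0)(
                taus=fit0.taus, alphas=fit0.alphas, tau_avg=fit0.tau_avg,
                chi2_reduced=fit0.chi2_reduced, ligand_conc=lc,
            )
            for lc in (1e-6, 2e-6)
        ]
        assert all(r == pytest.approx(1.0) for _, r in lifetime_ratio_series(fits))

    def test_dynamic_series_rises(self):
        gt = GroundTruth(ka=1e5, tau0=10.0, mechanism="dynamic", seed=23)
        fits = [
            fit_decay(simulate_decay(gt, lc, window_ns=100.0, seed_offset=i,
                                     p_tot=4e-6), 1)
            for i, lc in enumerate([0.0, 1.6e-5, 3.2e-5, 4.8e-5])
        ]
        ratios = [r for _, r in lifetime_ratio_series(fits)]
        assert ratios == sorted(ratios)
        assert ratios[-1] > 1.5

    def test_missing_zero_point(self):
        gt = GroundTruth(tau0=4.8, seed=24)
        fit = fit_decay(simulate_decay(gt, 1e-6), 1)
        fit = type(fit)(taus=fit.taus, alphas=fit.alphas, tau_avg=fit.tau_avg,
                        chi2_reduced=fit.chi2_reduced, ligand_conc=1e-6)
        with pytest.raises(ValidationError):
            lifetime_ratio_series([fit])
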