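"""Interaction density function and Scatchard regression."""

import numpy as np
import pytest

from quenchbind import (
    GroundTruth,
    IDFLevel,
    IntensityPoint,
    QuenchCurveModel,
    ValidationError,
    fit_quench_curve,
    idf_campaign,
    idf_levels,
    quench_percentage,
    scatchard_fit,
    simulate_titration,
    solve_binding,
)


class TestQuenchPercentage:
    @pytest.mark.parametrize(
        "f,f0,expected", [(100.0, 100.0, 0.0), (60.0, 100.0, 40.0), (50.0, 100.0, 50.0)]
    )
    def test_values(self, f, f0, expected):
        assert quench_percentage(f, f0) == pytest.approx(expected)

    def test_bad_f0(self):
        with pytest.raises(ValidationError):
            quench_percentage(1.0, 0.0)


def dark_points(ka, p_tot, ligand_concs, f0=1000.0):
    pts = [IntensityPoint(ligand_conc=0.0, f=f0, f0=f0)]
    for lc in ligand_concs:
        frac = solve_binding(p_tot, lc, ka).frac_protein_free
        pts.append(IntensityPoint(ligand_conc=lc, f=f0 * frac, f0=f0))
    return pts


class TestQuenchCurve:
    def test_noiseless_curve_reproduces_points(self):
        concs = np.arange(1, 61) * 1e-6
        curve = QuenchCurveModel(dark_points(1.43e5, 4e-6, concs), 4e-6).fit()
        for lc, df in curve.points:
            assert curve.predict(np.log10(lc)) == pytest.approx(df, abs=0.5)

    def test_inversion_is_exact_inverse(self):
        concs = np.arange(1, 61) * 1e-6
        curve = QuenchCurveModel(dark_points(1.43e5, 4e-6, concs), 4e-6).fit()
        lo, hi = curve.fitted_range
        for lev in np.linspace(lo + 1.0, hi - 1.0, 5):
            lt = curve.invert(lev)
            assert float(curve.predict(np.log10(lt))) == pytest.approx(lev, rel=1e-9)

    def test_monotone_prediction(self):
        concs = np.arange(1, 31) * 1e-6
        curve = QuenchCurveModel(dark_points(1e5, 4e-6, concs), 4e-6).fit()
        xs = np.linspace(-6.5, -4.0, 50)
        vals = curve.predict(xs)
        assert np.all(np.diff(vals) >= 0)

    def test_flat_curve_flagged(self):
        pts = [IntensityPoint(ligand_conc=lc, f=1000.0, f0=1000.0)
               for lc in np.arange(0, 8) * 1e-6]
        with pytest.raises(ValidationError):
            QuenchCurveModel(pts, 4e-6).fit()

    def test_too_few_points(self):
        with pytest.raises(ValidationError):
            QuenchCurveModel(dark_points(1e5, 4e-6, np.arange(1, 4) * 1e-6), 4e-6)


class TestIDFLevels:
    @pytest.fixture
    def noiseless_curves(self):
        concs = np.arange(1, 61) * 1e-6
        return [
            QuenchCurveModel(dark_points(1.43e5, p, concs), p).fit()
            for p in (4e-6, 8e-6)
        ]

    def test_levels_recover_binding_density(self, noiseless_curves):
        """At every level the line slope matches nu(l_free) of the generator
        and the intercept matches l_free, within 2%."""
        levels = idf_levels(noiseless_curves)
        ka = 1.43e5
        for lv in levels:
            # ground truth: theta at this quenching level
            theta = lv.delta_f_level / 100.0
            l_free_true = theta / (ka * (1.0 - theta))
            assert lv.sum_nu == pytest.approx(theta, rel=0.02)
            assert lv.l_free == pytest.approx(l_free_true, rel=0.02)

    def test_nu_nondecreasing_with_level(self, noiseless_curves):
        levels = idf_levels(noiseless_curves)
        nus = [lv.sum_nu for lv in levels]
        assert nus == sorted(nus)

    def test_duplicate_protein_concs_rejected(self, noiseless_curves):
        with pytest.raises(ValidationError):
            idf_levels([noiseless_curves[0], noiseless_curves[0]])

    def test_zero_protein_extrapolation_identity(self, noiseless_curves):
        # intercept at P=0 is the free-ligand concentration by construction
        levels = idf_levels(noiseless_curves)
        for lv in levels:
            (p1, l1), (p2, l2) = lv.ligand_totals
            slope = (l2 - l1) / (p2 - p1)
            assert lv.l_free == pytest.approx(l1 - slope * p1, rel=1e-9)


class TestScatchard:
    def test_exact_line_recovery(self):
        kb, n = 1.43e5, 1.0
        levels = [
            IDFLevel(delta_f_level=100 * nu, ligand_totals=(),
                     sum_nu=nu, l_free=nu / (kb * (n - nu)), fit_se=(0, 0))
            for nu in (0.2, 0.4, 0.6)
        ]
        fit = scatchard_fit(levels)
        assert fit.kb == pytest.approx(kb, rel=1e-9)
        assert fit.n_sites == pytest.approx(n, rel=1e-9)

    def test_two_site_line(self):
        kb, n = 1e5, 2.0
        levels = [
            IDFLevel(delta_f_level=50 * nu, ligand_totals=(),
                     sum_nu=nu, l_free=nu / (kb * (n - nu)), fit_se=(0, 0))
            for nu in (0.4, 0.8, 1.2, 1.6)
        ]
        fit = scatchard_fit(levels)
        assert fit.kb == pytest.approx(kb, rel=1e-9)
        assert fit.n_sites == pytest.approx(2.0, rel=1e-9)

    def test_positive_slope_rejected(self):
        levels = [
            IDFLevel(delta_f_level=10 * i, ligand_totals=(),
                     sum_nu=0.1 * i, l_free=1e-6 / i, fit_se=(0, 0))
            for i in (1, 2, 3)
        ]
        with pytest.raises(ValidationError):
            scatchard_fit(levels)


class TestEndToEnd:
    def test_noiseless_pipeline_recovery(self):
        gt = GroundTruth(ka=1.43e5, mechanism="static", noise_rel=0.0, seed=0)
        fit, levels = idf_campaign(gt)
        assert fit.kb == pytest.approx(1.43e5, rel=0.02)
        assert fit.n_sites == pytest.approx(1.0, abs=0.05)
        assert fit.r_squared > 0.99

    def test_noisy_pipeline_median_error(self):
        errs, nerrs = [], []
        for seed in range(20):
            gt = GroundTruth(ka=1.43e5, mechanism="static", noise_rel=0.01,
                             seed=400 + seed)
            fit, _ = idf_campaign(gt)
            errs.append(abs(fit.kb / 1.43e5 - 1.0))
            nerrs.append(abs(fit.n_sites - 1.0))
        assert np.median(errs) < 0.10
        assert np.median(nerrs) < 0.15

    def test_consistency_with_double_log(self):
        """On the same noiseless model, IDF Kb and double-log Ka agree."""
        from quenchbind import binding_recovery_campaign

        gt = GroundTruth(ka=1.43e5, mechanism="static", noise_rel=0.0, seed=0)
        kb = idf_campaign(gt)[0].kb
        ligand = np.concatenate([[0.0], np.arange(1, 61) * 1e-6])
        ka = binding_recovery_campaign(gt, ligand_concs=ligand).ka
        assert kb == pytest.approx(ka, rel=0.05)
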