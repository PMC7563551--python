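"""Binding solver and simulators: oracles, conservation, determinism."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import quadratic_l_free
from quenchbind import (
    GroundTruth,
    ValidationError,
    simulate_decay,
    simulate_titration,
    solve_binding,
)


class TestSolveBinding:
    def test_no_ligand(self):
        state = solve_binding(4e-6, 0.0, 1e5)
        assert state.l_free == 0.0 and state.nu == 0.0
        assert state.frac_protein_free == 1.0

    def test_agrees_with_quadratic_oracle(self):
        state = solve_binding(4e-6, 4e-6, 1e5, 1.0)
        expected = quadratic_l_free(4e-6, 4e-6, 1e5)
        assert state.l_free == pytest.approx(expected, rel=1e-10)

    @pytest.mark.parametrize("ka", [1e3, 1e4, 1e5, 1e6])
    def test_quadratic_oracle_grid(self, ka):
        """Bisection matches the 1:1 closed form on a 10x10 concentration grid."""
        for p_tot in np.linspace(1e-6, 2e-5, 10):
            for l_tot in np.linspace(1e-6, 8e-5, 10):
                state = solve_binding(p_tot, l_tot, ka, 1.0)
                expected = quadratic_l_free(p_tot, l_tot, ka)
                assert state.l_free == pytest.approx(expected, rel=1e-10)

    def test_weak_binding_limit(self):
        state = solve_binding(4e-6, 1e-5, 1e-6)
        assert state.l_free == pytest.approx(1e-5, rel=1e-6)

    def test_negative_input_rejected(self):
        with pytest.raises(ValidationError):
            solve_binding(-1e-6, 1e-6, 1e4)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        p_tot=st.floats(1e-8, 1e-3),
        l_tot=st.floats(0, 1e-3),
        ka=st.floats(1.0, 1e8),
        n_sites=st.floats(0.5, 4.0),
    )
    def test_mass_conservation(self, p_tot, l_tot, ka, n_sites):
        state = solve_binding(p_tot, l_tot, ka, n_sites)
        recon = state.l_free + state.nu * p_tot
        assert abs(recon - l_tot) < 1e-12 * max(l_tot, 1e-12)
        assert 0.0 <= state.nu <= n_sites


class TestSimulateTitration:
    def test_static_ratio_equals_free_fraction(self, static_gt, ligand_grid):
        # single-band condition: the ligand band's far tail would otherwise
        # perturb the 340 nm ratio at the 1e-6 level
        from dataclasses import replace

        gt = replace(static_gt, ligand_band_gain=0.0)
        series = simulate_titration(gt, 4e-6, ligand_grid,
                                    apply_inner_filter=False)
        for lc, spec in zip(series.ligand_concs, series.spectra):
            state = solve_binding(4e-6, float(lc), gt.ka)
            ratio = spec.intensity_at(340.0) / series.spectra[0].intensity_at(340.0)
            assert ratio == pytest.approx(state.frac_protein_free, rel=1e-12)

    def test_static_quenching_monotone(self, static_series):
        f340 = [s.intensity_at(340.0) for s in static_series.spectra]
        assert all(a > b for a, b in zip(f340, f340[1:]))

    def test_seeded_determinism(self, ligand_grid):
        gt = GroundTruth(ka=1e5, noise_rel=0.02, seed=42)
        s1 = simulate_titration(gt, 4e-6, ligand_grid)
        s2 = simulate_titration(gt, 4e-6, ligand_grid)
        for a, b in zip(s1.spectra, s2.spectra):
            np.testing.assert_array_equal(a.intensities, b.intensities)

    def test_requires_zero_start(self, static_gt):
        with pytest.raises(ValidationError):
            simulate_titration(static_gt, 4e-6, [4e-6, 8e-6])

    def test_absorbances_follow_extinction(self, static_series, static_gt):
        for lc, pair in zip(static_series.ligand_concs, static_series.absorbances):
            assert pair.a_ex == pytest.approx(static_gt.epsilon_ex * lc)


class TestSimulateDecay:
    def test_seeded_determinism(self, static_gt):
        h1 = simulate_decay(static_gt, 1e-5)
        h2 = simulate_decay(static_gt, 1e-5)
        np.testing.assert_array_equal(h1.counts, h2.counts)

    def test_static_decay_ligand_independent_expectation(self, static_gt):
        # same seed, different ligand: static decays share the expectation
        h0 = simulate_decay(static_gt, 0.0, total_counts=1e6)
        h1 = simulate_decay(static_gt, 4.8e-5, total_counts=1e6)
        # identical seeds and expectations give identical Poisson draws
        np.testing.assert_array_equal(h0.counts, h1.counts)

    def test_dynamic_decay_shortens(self):
        gt = GroundTruth(ka=1e5, tau0=10.0, mechanism="dynamic", seed=3)
        h0 = simulate_decay(gt, 0.0, total_counts=1e6)
        h1 = simulate_decay(gt, 4.8e-5, total_counts=1e6, p_tot=4e-6)
        # quenched decay concentrates counts at early times
        mid = len(h0.times) // 4
        assert h1.counts[:mid].sum() > h0.counts[:mid].sum()

    def test_bad_window_rejected(self, static_gt):
        with pytest.raises(ValidationError):
            simulate_decay(static_gt, 0.0, window_ns=-1.0)
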