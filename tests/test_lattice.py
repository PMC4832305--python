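"""Lattice growth, geometry, taper and thermal-bending tests."""

import numpy as np
import pytest

from mttrack.lattice import (
    GrowthParams,
    LatticeParams,
    apply_thermal_deflection,
    beam_shape,
    new_lattice,
    place_subunits,
    sigma_pf,
    step_growth,
    tip_coords_local,
    true_end,
)

LP = LatticeParams()


def grow(lp=LP, gp=None, seed=0, n_steps=1, seed_nm=500.0, init_nm=1000.0):
    gp = gp or GrowthParams(frame_interval=1.0, exposure=1.0)
    rng = np.random.default_rng(seed)
    state = new_lattice(lp, gp, seed_nm, init_nm, rng=rng)
    for _ in range(n_steps):
        state = step_growth(state, gp, lp, rng)
    return state


class TestStepGrowth:
    def test_zero_variance_growth_is_deterministic(self):
        # v_g = 50 nm/s over 1 s adds exactly round(50 * 13 / 8) = 81 subunits
        gp = GrowthParams(v_g=50, D_p=0, sigma_LD=0, taper_length=0,
                          frame_interval=1.0, exposure=1.0)
        rng = np.random.default_rng(0)
        state = new_lattice(LP, gp, 500, 1000, rng=rng)
        before = state.n_subunits
        state = step_growth(state, gp, LP, rng)
        assert state.n_subunits - before == 81

    def test_growth_law_moments_match_monte_carlo(self):
        # mean v_g*dt*n/d, variance 2*D_p*dt*(n/d)^2 for the subunit count
        gp = GrowthParams(v_g=11, D_p=271, sigma_LD=0, taper_length=0,
                          frame_interval=1.0, exposure=1.0)
        rng = np.random.default_rng(42)
        state = new_lattice(LP, gp, 500, 20000, rng=rng)
        deltas = []
        for _ in range(4000):
            new = step_growth(state, gp, LP, rng)
            deltas.append(new.n_subunits - state.n_subunits)
            state = new
        deltas = np.asarray(deltas, dtype=float)
        assert deltas.mean() == pytest.approx(11 * 13 / 8, abs=1.0)
        assert deltas.var() == pytest.approx(2 * 271 * (13 / 8) ** 2, rel=0.1)

    def test_blunt_end_tip_spread_stays_below_one_subunit(self):
        gp = GrowthParams(v_g=30, D_p=100, sigma_LD=0, taper_length=0,
                          frame_interval=1.0, exposure=1.0)
        state = grow(gp=gp, n_steps=20, seed=5)
        tips = tip_coords_local(state, LP)[:, 0]
        assert tips.max() - tips.min() <= LP.subunit_length

    def test_shrinkage_clamps_at_seed(self):
        gp = GrowthParams(v_g=-500, D_p=0, sigma_LD=0, taper_length=0,
                          frame_interval=1.0, exposure=1.0)
        rng = np.random.default_rng(0)
        state = new_lattice(LP, gp, 500, 600, rng=rng)
        state = step_growth(state, gp, LP, rng)
        assert state.hit_seed
        assert np.all(state.pf_lengths >= state.seed_lengths)

    def test_labels_immutable_across_steps(self):
        gp = GrowthParams(v_g=40, D_p=0, sigma_LD=0, taper_length=0,
                          frame_interval=1.0, exposure=1.0)
        rng = np.random.default_rng(3)
        lp = LatticeParams(labelling_ratio=0.5)
        state = new_lattice(lp, gp, 500, 1000, rng=rng)
        snapshot = [lab.copy() for lab in state.labels]
        state2 = step_growth(state, gp, lp, rng)
        for old, new in zip(snapshot, state2.labels):
            assert np.array_equal(old, new[: len(old)])


class TestGeometry:
    def test_single_protofilament_axial_spacing(self):
        lp = LatticeParams(n_protofilaments=1, labelling_ratio=1.0)
        gp = GrowthParams(taper_length=0, frame_interval=1.0, exposure=1.0)
        rng = np.random.default_rng(0)
        state = new_lattice(lp, gp, 16, 24, rng=rng)
        coords, _ = place_subunits(state, lp)
        assert np.allclose(np.sort(coords[:, 0]), [0.0, 8.0, 16.0])

    def test_terminal_ring_spans_helical_pitch(self):
        # equal subunit counts: terminal emitters span (n-1)/n of one
        # helical turn = 3 subunits rise
        lp = LatticeParams(labelling_ratio=1.0)
        state = new_lattice(lp, GrowthParams(taper_length=0, frame_interval=1, exposure=1),
                            500, 500, rng=np.random.default_rng(0))
        tips = tip_coords_local(state, lp)[:, 0]
        expected_span = (lp.n_protofilaments - 1) * lp.helix_rise
        assert tips.max() - tips.min() == pytest.approx(expected_span, abs=1e-9)

    def test_zero_labelling_gives_empty_coordinates(self):
        lp = LatticeParams(labelling_ratio=0.0)
        state = new_lattice(lp, GrowthParams(frame_interval=1, exposure=1),
                            500, 2000, rng=np.random.default_rng(0))
        coords, ids = place_subunits(state, lp)
        assert coords.shape == (0, 2) and ids == []

    def test_true_end_of_linear_taper_is_mean_of_ramp(self):
        gp = GrowthParams(v_g=0, D_p=0, taper_length=96, frame_interval=1, exposure=1)
        state = new_lattice(LP, gp, 500, 3000, rng=np.random.default_rng(1))
        tips = tip_coords_local(state, LP)[:, 0]
        assert true_end(state, LP)[0] == pytest.approx(tips.mean())
        # ramp extent ~TL; tips span within a subunit of the target
        assert tips.max() - tips.min() == pytest.approx(96, abs=LP.subunit_length)

    def test_sigma_pf_matches_brute_force_sd(self):
        gp = GrowthParams(v_g=0, D_p=0, taper_length=200, frame_interval=1, exposure=1)
        state = new_lattice(LP, gp, 500, 3000, rng=np.random.default_rng(1))
        tips = tip_coords_local(state, LP)[:, 0]
        assert sigma_pf(state, LP) == pytest.approx(float(np.std(tips)))
        assert sigma_pf(state, LP) == pytest.approx(np.std(np.linspace(0, 200, 13)), rel=0.1)


class TestThermalDeflection:
    def test_beam_shape_endpoints_and_monotonicity(self):
        u = np.linspace(0, 1, 101)
        w = beam_shape(u)
        assert w[0] == 0.0 and w[-1] == pytest.approx(1.0)
        assert np.all(np.diff(w) > 0)

    def test_zero_sigma_leaves_coordinates_unchanged(self, rng):
        gp = GrowthParams(sigma_LD=0.0, frame_interval=1, exposure=1)
        coords = rng.uniform(0, 3000, size=(50, 2))
        out, d = apply_thermal_deflection(coords, gp, clamp_length=500, rng=rng)
        assert d == 0.0
        assert np.array_equal(out, coords)

    def test_tip_deflection_sd_matches_sigma_ld(self):
        # Fig 7 baseline sigma_LD = 150 nm: Monte-Carlo SD of the tip
        gp = GrowthParams(sigma_LD=150.0, frame_interval=1, exposure=1)
        rng = np.random.default_rng(11)
        tip = np.array([[3000.0, 0.0]])
        defl = [
            apply_thermal_deflection(tip, gp, 500, rng, free_length=2500.0)[0][0, 1]
            for _ in range(4000)
        ]
        assert np.std(defl) == pytest.approx(150.0, rel=0.05)

    def test_axial_positions_unmodified(self, rng):
        gp = GrowthParams(sigma_LD=150.0, frame_interval=1, exposure=1)
        coords = rng.uniform(0, 3000, size=(50, 2))
        out, _ = apply_thermal_deflection(coords, gp, clamp_length=500, rng=rng)
        assert np.array_equal(out[:, 0], coords[:, 0])
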