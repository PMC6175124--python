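"""ACFs, biexponential fits, order parameters, splittings, structure tools."""

import numpy as np
import pytest

from spinline import (
    SpinParameters,
    compute_acf,
    detect_flip_flop,
    fit_biexponential,
    hm_order_parameter,
    hubbell_mcconnell,
    order_parameter_direct,
    rdf_projected,
    scd_profile,
)
from spinline.spectral_analysis import AcfResult, SplittingError, biexponential


def acf_from_curve(t_ns, y):
    return AcfResult(lag=np.asarray(t_ns) * 1000.0, C=np.asarray(y),
                     n_samples=np.ones(len(y), dtype=int))


class TestComputeAcf:
    def test_constant_vector_gives_unity(self):
        v = np.tile([0.0, 0.0, 1.0], (200, 1))
        acf = compute_acf(v, dt=20.0)
        assert np.allclose(acf.C, 1.0, atol=1e-12)
        assert acf.C[0] == pytest.approx(1.0, abs=1e-9)

    def test_sign_flips_invisible_to_p2(self):
        v = np.tile([0.0, 0.0, 1.0], (200, 1))
        v[1::2] *= -1.0
        acf = compute_acf(v, dt=20.0)
        assert np.allclose(acf.C, 1.0, atol=1e-12)

    def test_scalar_series_accepted(self):
        s = np.ones(100)
        acf = compute_acf(s, dt=20.0)
        assert np.allclose(acf.C, 1.0)

    def test_bounded_by_one(self, isotropic_traj):
        acf = compute_acf(isotropic_traj.axis_vectors("x"), dt=isotropic_traj.dt,
                          boundaries=isotropic_traj.boundaries)
        assert np.all(np.abs(acf.C) <= 1.0 + 1e-12)

    def test_lag_cap_enforced(self):
        v = np.tile([0.0, 0.0, 1.0], (50, 1))
        with pytest.raises(ValueError, match="max_lag"):
            compute_acf(v, dt=20.0, max_lag=60)

    def test_windows_never_span_boundaries(self):
        # two blocks pointing along different axes: any cross-boundary pair
        # would contribute P2(0) = -0.5 and pull C below 1
        up = np.tile([0.0, 0.0, 1.0], (60, 1))
        side = np.tile([1.0, 0.0, 0.0], (60, 1))
        acf = compute_acf(np.vstack([up, side]), dt=20.0, boundaries=[0, 60, 120])
        assert np.allclose(acf.C, 1.0, atol=1e-12)


class TestBiexponentialFit:
    def test_noiseless_round_trip_to_one_percent(self):
        t = np.concatenate([[0.0], np.geomspace(0.005, 40.0, 180)])
        y = biexponential(t, 0.25, 0.6, 0.2, 5.0)
        fit = fit_biexponential(acf_from_curve(t, y), sign_source=1.0)
        assert fit.converged
        assert fit.S0_sq == pytest.approx(0.25, rel=0.01)
        assert fit.w1 == pytest.approx(0.6, rel=0.01)
        assert fit.tau1 == pytest.approx(0.2, rel=0.01)
        assert fit.tau2 == pytest.approx(5.0, rel=0.01)
        assert fit.tau_eff == pytest.approx(0.6 * 0.2 + 0.4 * 5.0, rel=0.01)

    def test_tau_eff_identity_exact(self):
        t = np.concatenate([[0.0], np.geomspace(0.01, 20.0, 60)])
        y = biexponential(t, 0.1, 0.3, 0.5, 3.0)
        fit = fit_biexponential(acf_from_curve(t, y))
        assert fit.tau_eff == fit.w1 * fit.tau1 + fit.w2 * fit.tau2

    def test_static_plateau_flagged_unidentifiable(self):
        t = np.linspace(0, 10, 50)
        fit = fit_biexponential(acf_from_curve(t, np.full(50, 0.36)))
        assert fit.S0_sq == pytest.approx(0.36, abs=1e-9)
        assert "tau_unidentifiable" in fit.flags
        assert np.isnan(fit.tau1)

    def test_single_exponential_limit_tau_eff(self):
        # w1 = 1 fixture: tau_eff must equal tau1
        t = np.concatenate([[0.0], np.geomspace(0.01, 10.0, 80)])
        y = biexponential(t, 0.0, 1.0, 0.7, 50.0)  # second mode has zero weight
        fit = fit_biexponential(acf_from_curve(t, y))
        dominant = fit.tau1 if fit.w1 > 0.5 else fit.tau2
        assert dominant == pytest.approx(0.7, rel=0.01)
        assert fit.tau_eff == pytest.approx(0.7, rel=0.02)

    def test_canonical_ordering(self):
        t = np.concatenate([[0.0], np.geomspace(0.01, 30.0, 100)])
        y = biexponential(t, 0.2, 0.35, 6.0, 0.3)  # given in reversed order
        fit = fit_biexponential(acf_from_curve(t, y))
        assert fit.tau1 <= fit.tau2
        assert fit.w1 + fit.w2 == pytest.approx(1.0)

    def test_sign_taken_from_direct_estimate(self):
        t = np.concatenate([[0.0], np.geomspace(0.01, 10.0, 50)])
        y = biexponential(t, 0.25, 0.5, 0.5, 2.0)
        fit = fit_biexponential(acf_from_curve(t, y), sign_source=-0.4)
        assert fit.S0 == pytest.approx(-0.5, rel=0.02)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="20 lag points"):
            fit_biexponential(acf_from_curve(np.linspace(0, 1, 10), np.ones(10)))


class TestOrderParameters:
    @pytest.mark.parametrize(
        "theta_deg,expected",
        [(0.0, 1.0), (90.0, -0.5), (54.7356103, 0.0)],
    )
    def test_exact_angles(self, theta_deg, expected):
        c = np.full(100, np.cos(np.deg2rad(theta_deg)))
        assert order_parameter_direct(c) == pytest.approx(expected, abs=1e-6)

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            order_parameter_direct(np.array([]))


class TestHubbellMcConnell:
    def test_rigid_aligned_limit_is_one(self, default_spin):
        Axx, Ayy, Azz = default_spin.A_principal
        assert hm_order_parameter(Azz, 0.5 * (Axx + Ayy), default_spin) == pytest.approx(1.0)

    def test_isotropic_limit_is_zero(self, default_spin):
        a = default_spin.a_iso
        assert hm_order_parameter(a, a, default_spin) == pytest.approx(0.0)

    def test_hand_computed_example(self, default_spin):
        # (25.0 - 10.0) / (33.5 - 6.0), evaluated by hand before the build
        assert hm_order_parameter(25.0, 10.0, default_spin) == pytest.approx(
            0.5454545454545454
        )

    def test_spectrum_measurement_recovers_imposed_order(
        self, ordered_fast_traj, default_spin
    ):
        from spinline import powder_average, trajectory_order_parameter

        s0 = trajectory_order_parameter(ordered_fast_traj, "z")
        spec = powder_average(ordered_fast_traj, default_spin, n_tilts=8,
                              window=200.0, stride=200)
        m = hubbell_mcconnell(spec, default_spin, refine=True)
        assert m.A_par_eff >= m.A_perp_eff
        assert -0.5 <= m.S0_hm <= 1.0
        assert m.S0_hm == pytest.approx(s0, abs=0.05)

    def test_featureless_spectrum_raises(self, default_spin):
        from spinline import Spectrum

        spec = Spectrum(field=default_spin.field_grid(),
                        intensity=np.zeros(default_spin.n_field_points))
        with pytest.raises(SplittingError, match="outer peaks"):
            hubbell_mcconnell(spec, default_spin)


class TestScdProfile:
    def test_all_trans_chain_parallel_to_normal(self):
        # C-H bonds perpendicular to the normal: S_CD = -1/2 for every carbon
        coords = np.zeros((6, 3))
        coords[0] = [0, 0, 0.0]
        coords[1] = [1, 0, 0.0]  # H on carbon 0
        coords[2] = [-1, 0, 0.0]
        coords[3] = [0, 0, 1.27]
        coords[4] = [0, 1, 1.27]
        coords[5] = [0, -1, 1.27]
        chain_map = [{2: (0, [1, 2]), 3: (3, [4, 5])}]
        df = scd_profile([coords], chain_map)
        assert np.allclose(df["S_CD"], -0.5, atol=1e-12)

    def test_isotropic_ch_vectors_average_to_zero(self):
        rng = np.random.default_rng(6)
        frames = []
        for _ in range(400):
            coords = np.zeros((2, 3))
            v = rng.normal(size=3)
            coords[1] = v / np.linalg.norm(v)
            frames.append(coords)
        df = scd_profile(frames, [{1: (0, [1])}])
        assert abs(df["S_CD"][0]) < 0.05

    def test_tilted_chain_with_free_axial_rotation(self):
        # closed-form azimuthal average: S_CD = -1/2 * P2(cos 30 deg) = -0.3125
        beta = np.deg2rad(30.0)
        axis = np.array([np.sin(beta), 0.0, np.cos(beta)])
        perp = np.cross(axis, [0.0, 0.0, 1.0])
        perp /= np.linalg.norm(perp)
        perp2 = np.cross(axis, perp)
        frames = []
        for phi in np.linspace(0, 2 * np.pi, 720, endpoint=False):
            coords = np.zeros((2, 3))
            coords[1] = np.cos(phi) * perp + np.sin(phi) * perp2
            frames.append(coords)
        df = scd_profile(frames, [{1: (0, [1])}])
        assert df["S_CD"][0] == pytest.approx(-0.3125, abs=1e-6)

    def test_missing_hydrogens_raise(self):
        with pytest.raises(ValueError, match="no hydrogens"):
            scd_profile([np.zeros((2, 3))], [{1: (0, [])}])


class TestRdfProjected:
    def test_uniform_2d_points_flat(self):
        rng = np.random.default_rng(11)
        box = [50.0, 50.0, 10.0]
        pts = rng.uniform(0, 50, size=(20, 800, 3))
        pts[..., 2] = 5.0
        r, g = rdf_projected(pts, pts, box, mode="2d", n_bins=40)
        tail = g[r > 5.0]
        assert np.allclose(tail, 1.0, atol=0.05)

    def test_fixed_pair_single_bin_peak(self):
        box = [20.0, 20.0, 20.0]
        a = np.array([[1.0, 1.0, 1.0]])
        b = np.array([[4.0, 5.0, 1.0]])  # in-plane distance 5
        r, g = rdf_projected(a, b, box, mode="2d", r_max=8.0, n_bins=16)
        assert np.count_nonzero(g) == 1
        assert abs(r[np.argmax(g)] - 5.0) < 0.5

    def test_poisson_3d_within_bootstrap_envelope(self):
        rng = np.random.default_rng(12)
        box = [30.0, 30.0, 30.0]

        def one(seed):
            r = np.random.default_rng(seed)
            pts = r.uniform(0, 30, size=(600, 3))
            return rdf_projected(pts, pts, box, mode="3d", r_max=12.0, n_bins=24)[1]

        obs = one(999)
        boot = np.array([one(s) for s in range(200)])
        lo, hi = np.percentile(boot, [0.5, 99.5], axis=0)
        violations = np.count_nonzero((obs < lo) | (obs > hi))
        assert violations <= 2

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            rdf_projected(np.empty((0, 3)), np.ones((3, 3)), [10, 10, 10])


class TestFlipFlop:
    def test_constant_series_no_events(self):
        assert detect_flip_flop(np.ones(100)) == []

    def test_telegraph_three_switches(self):
        s = np.concatenate([np.ones(50), -np.ones(50), np.ones(50), -np.ones(50)])
        events = detect_flip_flop(s, threshold=0.5, dwell=5)
        assert len(events) == 3
        assert events == [50, 100, 150]

    def test_brief_excursions_debounced(self):
        s = np.ones(100)
        s[40:42] = -1.0  # shorter than the dwell requirement
        assert detect_flip_flop(s, threshold=0.5, dwell=5) == []

    def test_matches_brute_force_recount(self, isotropic_traj):
        from spinline import angle_to_director

        def recount(s, threshold, dwell):
            # independent re-implementation: run-length encode the band signal
            bands = np.where(s > threshold, 1, np.where(s < -threshold, -1, 0))
            state, count = 0, 0
            i = 0
            while i < len(bands):
                j = i
                while j < len(bands) and bands[j] == bands[i]:
                    j += 1
                if bands[i] != 0 and (j - i) >= dwell and bands[i] != state:
                    if state != 0:
                        count += 1
                    state = bands[i]
                i = j
            return count

        for series in angle_to_director(isotropic_traj, "z")[:3]:
            got = len(detect_flip_flop(series, threshold=0.6, dwell=10))
            assert got == recount(series, 0.6, 10)
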