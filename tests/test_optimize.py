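import numpy as np
import pytest
from scipy import sparse

import imctplan as ip
from imctplan.influence import DoseEngine
from imctplan.optimize import (NominalObjectiveConfig, WCConfig, f_dnom,
                               f_grad, f_hetero, f_oar_sparing, f_wc,
                               _ratio_penalty, build_gradient_pairs,
                               density_index, risk_indices, solve, solve_wc)
from conftest import fd_gradient, random_influence


def toy_config(infl, n_target=12, e_presc=1.5, e_max=0.5, w_oar=0.7):
    n = len(infl.voxel_idx)
    return NominalObjectiveConfig(
        e_presc=e_presc, target_rows=np.arange(n_target),
        oar_rows=np.arange(n_target, n), e_max=e_max, w_oar=w_oar,
    )


class TestFDnom:
    def test_zero_at_prescription(self, rng):
        D = np.array([[1.0], [1.0]])
        alpha, beta = 0.5, 0.05
        infl = ip.InfluenceSet.from_matrices(D, alpha * D, beta * D)
        x = np.array([2.0])
        e = alpha * 2.0 + beta * 4.0
        cfg = NominalObjectiveConfig(
            e_presc=e, target_rows=np.array([0, 1]),
            oar_rows=np.array([], dtype=int), e_max=0.0,
        )
        val, grad = f_dnom(x, infl, cfg)
        assert val == pytest.approx(0.0, abs=1e-24)
        np.testing.assert_allclose(grad, 0.0, atol=1e-12)

    def test_single_voxel_closed_form_minimizer(self):
        """One voxel, one spot: optimum solves alpha D x + beta D^2 x^2 = e."""
        D = np.array([[2.0]])
        alpha, beta = 0.4, 0.03
        infl = ip.InfluenceSet.from_matrices(D, alpha * D, beta * D)
        e_presc = 1.9
        cfg = NominalObjectiveConfig(
            e_presc=e_presc, target_rows=np.array([0]),
            oar_rows=np.array([], dtype=int),
        )
        res = solve(lambda x: f_dnom(x, infl, cfg), np.array([0.5]))
        aa, bb = alpha * 2.0, beta * 4.0
        x_star = (-aa + np.sqrt(aa**2 + 4 * bb * e_presc)) / (2 * bb)
        assert res.x[0] == pytest.approx(x_star, rel=1e-4)

    def test_gradient_matches_finite_differences(self, rng):
        infl = random_influence(rng, n_vox=20, n_spots=10, n_fields=2)
        cfg = toy_config(infl)
        x = rng.uniform(0.5, 2.0, 10)
        _, g = f_dnom(x, infl, cfg)
        g_fd = fd_gradient(lambda xx: f_dnom(xx, infl, cfg)[0], x)
        np.testing.assert_allclose(g, g_fd, rtol=1e-5, atol=1e-10)


class TestRatioTerms:
    def test_hetero_zero_for_homogeneous_water(self, machine):
        ph = ip.build_water_box(side_mm=80.0, spacing=2.0)
        eng = DoseEngine(ph, [ip.FieldGeometry(port_deg=0.0)], machine)
        spots = [ip.Spot(0, 50.0, 0.0, 0.0, 1.0), ip.Spot(0, 60.0, 4.0, 0.0, 1.0)]
        m = density_index(spots, eng)
        np.testing.assert_allclose(m, 0.0, atol=1e-6)
        val, _ = f_hetero(np.ones(2), m, k0=0.5)
        assert val == pytest.approx(0.0, abs=1e-7)

    def test_hetero_positive_near_insert_boundary(self, rtog_het_coarse,
                                                  machine):
        eng = DoseEngine(rtog_het_coarse, ip.rtog_fields(), machine,
                         voxel_idx=rtog_het_coarse.roi_indices("CTV"))
        # field 1 enters from +x through the air insert; a spot whose area
        # straddles the insert edge sees unequal lateral WEPLs
        spot = ip.Spot(1, 100.0, 0.0, 20.0, 1.0)
        m = density_index([spot], eng)
        assert m[0] > 1.0

    def test_scale_invariance(self, rng):
        m = rng.uniform(0, 5, 8)
        x = rng.uniform(0.1, 2, 8)
        v1, _ = f_hetero(x, m, 0.5)
        v2, _ = f_hetero(2 * x, m, 0.5)
        assert v1 == pytest.approx(v2, rel=1e-12)

    def test_ratio_gradient_matches_fd(self, rng):
        c = rng.uniform(0, 3, 9)
        x = rng.uniform(0.2, 2, 9)
        _, g = _ratio_penalty(x, c)
        g_fd = fd_gradient(lambda xx: _ratio_penalty(xx, c)[0], x)
        np.testing.assert_allclose(g, g_fd, rtol=1e-5, atol=1e-10)

    def test_oar_sparing_examples(self):
        val, _ = f_oar_sparing(np.ones(3), np.zeros(3), np.zeros(3), 10, 5)
        assert val == 0.0
        for w in (0.5, 4.0):
            val, _ = f_oar_sparing(np.array([w]), np.array([1.0]),
                                   np.array([0.0]), 10.0, 5.0)
            assert val == pytest.approx(10.0)

    def test_moving_weight_to_safe_spot_decreases_term(self):
        p_r = np.array([1.0, 0.0])
        x_risky = np.array([2.0, 1.0])
        x_safe = np.array([1.0, 2.0])
        v1, _ = f_oar_sparing(x_risky, p_r, np.zeros(2), 10, 5)
        v2, _ = f_oar_sparing(x_safe, p_r, np.zeros(2), 10, 5)
        assert v2 < v1


class TestGradTerm:
    def _pairs(self, pts, delta_r=6.0, cap=0, seed=0):
        return build_gradient_pairs(pts, delta_r, cap, seed)

    def test_uniform_effect_gives_zero(self, rng):
        D = np.ones((4, 3)) * 0.5
        infl = ip.InfluenceSet.from_matrices(D, 0.5 * D, 0.05 * D)
        pts = np.array([[0, 0, 0], [2, 0, 0], [0, 2, 0], [2, 2, 0.]])
        pairs = self._pairs(pts)
        val, g = f_grad(np.ones(3), infl, np.arange(4), pairs, g0=1.0)
        assert val == pytest.approx(0.0, abs=1e-20)

    def test_two_voxel_hand_value(self):
        # single field, per-field effects 0.5 and 0.6, r = 2 mm, G0 = 1:
        # ordered pairs count both directions -> 2 * (0.1/2)^2 = 0.005
        D = np.diag([1.0, 1.0])
        A = np.diag([0.5, 0.6])   # alpha_ij * d_ij chosen to give e = (0.5, 0.6)
        B = np.zeros((2, 2))
        infl = ip.InfluenceSet.from_matrices(D, A, B)
        pts = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        pairs = self._pairs(pts)
        val, _ = f_grad(np.ones(2), infl, np.arange(2), pairs, g0=1.0)
        assert val == pytest.approx(0.005, rel=1e-12)

    def test_gradient_matches_fd(self, rng):
        infl = random_influence(rng, n_vox=20, n_spots=10, n_fields=2)
        pts = rng.uniform(0, 10, size=(12, 3))
        pairs = self._pairs(pts)
        x = rng.uniform(0.5, 1.5, 10)
        _, g = f_grad(x, infl, np.arange(12), pairs, g0=0.7)
        g_fd = fd_gradient(
            lambda xx: f_grad(xx, infl, np.arange(12), pairs, 0.7)[0], x
        )
        np.testing.assert_allclose(g, g_fd, rtol=1e-5, atol=1e-9)

    def test_projected_gradient_step_descends(self, rng):
        infl = random_influence(rng, n_vox=15, n_spots=8)
        pts = rng.uniform(0, 8, size=(15, 3))
        pairs = self._pairs(pts)
        x = rng.uniform(0.5, 1.5, 8)
        v0, g = f_grad(x, infl, np.arange(15), pairs, g0=1.0)
        x1 = np.maximum(x - 1e-3 * g / max(np.linalg.norm(g), 1e-12), 0)
        v1, _ = f_grad(x1, infl, np.arange(15), pairs, g0=1.0)
        assert v1 < v0

    def test_pair_subsampling_is_seeded_and_scaled(self, rng):
        pts = rng.uniform(0, 20, size=(60, 3))
        full = build_gradient_pairs(pts, 8.0, cap=0)
        sub1 = build_gradient_pairs(pts, 8.0, cap=40, seed=7)
        sub2 = build_gradient_pairs(pts, 8.0, cap=40, seed=7)
        np.testing.assert_array_equal(sub1[0], sub2[0])
        assert len(sub1[0]) == 40
        assert sub1[3] == pytest.approx(len(full[0]) / 40)


@pytest.fixture(scope="module")
def rtog_engine(rtog_coarse, machine):
    return DoseEngine(rtog_coarse, ip.rtog_fields(), machine,
                      voxel_idx=rtog_coarse.roi_indices("CTV"))


class TestRiskIndices:

    def test_far_spot_has_negligible_risk(self, rtog_engine, rtog_coarse):
        # peak 60 mm short of the OAR, axis 40 mm off: > 5 lambda away
        spot = ip.Spot(0, 56.0, 40.0, 0.0, 1.0)
        p_r, p_s = risk_indices([spot], rtog_engine, rtog_coarse)
        assert p_r[0] < 0.01
        assert p_s[0] < 0.01

    def test_peak_inside_oar_gives_unit_range_risk(self, rtog_engine,
                                                   rtog_coarse):
        # central axis, range = cylinder radius: Bragg peak at the isocenter
        spot = ip.Spot(0, 116.0, 0.0, 0.0, 1.0)
        p_r, p_s = risk_indices([spot], rtog_engine, rtog_coarse)
        assert p_r[0] == pytest.approx(1.0)
        assert p_s[0] == pytest.approx(1.0)

    def test_range_risk_monotone_in_peak_distance(self, rtog_engine,
                                                  rtog_coarse):
        ranges = [116.0, 100.0, 90.0, 80.0, 70.0]  # receding from the OAR
        p_r, _ = risk_indices(
            [ip.Spot(0, R, 0.0, 18.0, 1.0) for R in ranges],
            rtog_engine, rtog_coarse,
        )
        assert np.all(np.diff(p_r) <= 1e-12)


class TestWorstCase:
    def test_nominal_only_scenario_at_prescription_gives_fdnom(self, rng):
        infl = random_influence(rng, n_vox=10, n_spots=6)
        cfg = toy_config(infl, n_target=6, e_presc=1.0, e_max=50.0)
        wc = WCConfig(p_w=2.0, scenarios=[ip.nominal_scenario()])
        x = rng.uniform(0.5, 1.5, 6)
        v_wc, _ = f_wc(x, [infl], infl, cfg, wc)
        v_nom, _ = f_dnom(x, infl, cfg)
        # OAR is far below its ceiling; only target min/max terms remain and
        # both equal the nominal deviation
        d, a, b = infl.dab(x)
        e = (a + b * d)[cfg.target_rows]
        expected = v_nom + 2.0 * 2.0 * float(((e - 1.0) ** 2).sum())
        assert v_wc == pytest.approx(expected, rel=1e-12)

    def test_oar_below_ceiling_contributes_zero(self, rng):
        infl = random_influence(rng, n_vox=8, n_spots=5)
        cfg = toy_config(infl, n_target=4, e_presc=1.0, e_max=1e6)
        wc = WCConfig(p_w=1.0, scenarios=[ip.nominal_scenario()])
        x = rng.uniform(0.5, 1.5, 5)
        v_with, _ = f_wc(x, [infl], infl, cfg, wc)
        cfg2 = toy_config(infl, n_target=4, e_presc=1.0, e_max=1e6, w_oar=0.0)
        v_without, _ = f_wc(x, [infl], infl, cfg2, wc)
        assert v_with == pytest.approx(v_without, rel=1e-12)

    def test_two_voxel_two_scenario_exhaustive_oracle(self):
        D1 = np.array([[1.0, 0.0], [0.0, 1.0]])
        D2 = np.array([[0.8, 0.1], [0.2, 1.1]])
        mk = lambda D: ip.InfluenceSet.from_matrices(D, 0.5 * D, 0.0 * D)
        s1, s2 = mk(D1), mk(D2)
        cfg = NominalObjectiveConfig(
            e_presc=0.6, target_rows=np.array([0]), oar_rows=np.array([1]),
            e_max=0.3, w_target=1.0, w_oar=1.0,
        )
        wc = WCConfig(p_w=1.5, scenarios=[ip.nominal_scenario()] * 2)
        x = np.array([1.0, 0.5])

        # oracle: enumerate scenario effects by hand (beta = 0 -> e = 0.5 d)
        def effects(D):
            d = D @ x
            return 0.5 * d
        e1, e2 = effects(D1), effects(D2)
        emin_t = min(e1[0], e2[0])
        emax_t = max(e1[0], e2[0])
        emax_o = max(e1[1], e2[1])
        fdw = (emin_t - 0.6) ** 2 + (emax_t - 0.6) ** 2
        fdw += (emax_o - 0.3) ** 2 if emax_o > 0.3 else 0.0
        v_nom, _ = f_dnom(x, s1, cfg)
        v, _ = f_wc(x, [s1, s2], s1, cfg, wc)
        assert v == pytest.approx(v_nom + 1.5 * fdw, rel=1e-12)

    @pytest.mark.parametrize("reference", ["prescription", "nominal"])
    def test_gradient_matches_fd(self, rng, reference):
        infls = [random_influence(np.random.default_rng(s), n_vox=20,
                                  n_spots=10, n_fields=2) for s in (1, 2, 3)]
        nom = random_influence(np.random.default_rng(9), n_vox=20, n_spots=10,
                               n_fields=2)
        cfg = toy_config(infls[0], e_presc=1.2, e_max=0.4)
        wc = WCConfig(p_w=1.3, scenarios=[ip.nominal_scenario()] * 3,
                      reference=reference)
        x = np.random.default_rng(5).uniform(0.5, 1.5, 10)
        # freeze the selection so the finite-difference probe stays on one
        # smooth branch of the minimax objective
        e_stack = np.stack([(lambda t: t[1] + t[2] * t[0])(i.dab(x))
                            for i in infls])
        from imctplan.optimize import _wc_selection
        frozen = _wc_selection(e_stack, cfg.target_rows, cfg.oar_rows)
        _, g = f_wc(x, infls, nom, cfg, wc, frozen=frozen)
        g_fd = fd_gradient(
            lambda xx: f_wc(xx, infls, nom, cfg, wc, frozen=frozen)[0], x
        )
        np.testing.assert_allclose(g, g_fd, rtol=1e-4, atol=1e-9)

    def test_empty_scenario_list_rejected(self, rng):
        infl = random_influence(rng)
        cfg = toy_config(infl)
        with pytest.raises(ValueError):
            f_wc(np.ones(10), [], infl, cfg, WCConfig(p_w=1.0, scenarios=[]))


class TestSolve:
    def test_convex_beta_zero_recovers_normal_equations(self, rng):
        """With beta = 0 the target term is linear least squares in x."""
        n_vox, n_spots = 12, 6
        # each spot mostly covers its own two voxels, so the least-squares
        # solution of a uniform prescription is strictly positive (interior)
        alpha = 0.5
        D = np.kron(np.eye(n_spots), np.ones((2, 1)))
        D = D * rng.uniform(0.8, 1.2, size=D.shape) \
            + 0.05 * rng.uniform(size=(n_vox, n_spots))
        infl = ip.InfluenceSet.from_matrices(D, alpha * D, 0.0 * D)
        e_presc = 1.0
        cfg = NominalObjectiveConfig(
            e_presc=e_presc, target_rows=np.arange(n_vox),
            oar_rows=np.array([], dtype=int),
        )
        res = solve(lambda x: f_dnom(x, infl, cfg), np.full(n_spots, 1.5),
                    max_iter=500, ftol=1e-14)
        A = alpha * D
        x_ne, *_ = np.linalg.lstsq(A, np.full(n_vox, e_presc), rcond=None)
        assert np.all(x_ne > 0), "toy must have an interior solution"
        np.testing.assert_allclose(res.x, x_ne, rtol=1e-4, atol=1e-6)

    def test_trace_nonincreasing(self, rng):
        infl = random_influence(rng, n_vox=20, n_spots=10)
        cfg = toy_config(infl)
        res = solve(lambda x: f_dnom(x, infl, cfg), np.ones(10))
        assert np.all(np.diff(res.trace) <= 1e-9)

    def test_nonnegative_solution(self, rng):
        infl = random_influence(rng, n_vox=20, n_spots=10)
        cfg = toy_config(infl)
        res = solve(lambda x: f_dnom(x, infl, cfg), np.ones(10))
        assert np.all(res.x >= 0)

    def test_wc_with_zero_importance_equals_conventional(self, rng):
        infl = random_influence(rng, n_vox=20, n_spots=10)
        scen = [random_influence(np.random.default_rng(3), n_vox=20,
                                 n_spots=10)]
        cfg = toy_config(infl)
        x0 = np.ones(10)
        res_conv = solve(
            ip.Objective({"f_dnom": lambda x: f_dnom(x, infl, cfg)}), x0
        )
        res_wc = solve_wc(scen, infl, cfg, WCConfig(p_w=0.0, scenarios=scen),
                          x0, max_iter=300, ftol=1e-6)
        np.testing.assert_array_equal(res_conv.x, res_wc.x)

    def test_nonfinite_objective_aborts(self):
        def bad(x):
            return np.inf, np.zeros_like(x)
        with pytest.raises(FloatingPointError):
            solve(bad, np.ones(3))
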