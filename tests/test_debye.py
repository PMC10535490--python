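import numpy as np
import pytest

from icmsas import (AtomicModel, SimulationConfig, SolventSpec,
                    add_hydration_shell, debye_curve, effective_lengths,
                    pair_distance_histogram)
from icmsas.debye import shell_volume
from conftest import make_ball, make_point_model


def vacuum_cfg(q):
    return SimulationConfig(q_grid=np.asarray(q, float), in_vacuum=True)


class TestEffectiveLengths:
    def test_carbon_in_vacuum_is_tabulated_length(self):
        m = AtomicModel(np.array(["C"], dtype=object), [[0, 0, 0]], [0])
        b = effective_lengths(m, vacuum_cfg([0.1]))
        assert b[0] == pytest.approx(6.646, abs=1e-3)

    def test_amide_nitrogen_fully_exchanged(self):
        m = AtomicModel(np.array(["N"], dtype=object), [[0, 0, 0]], [1])
        cfg = SimulationConfig(solvent=SolventSpec(1.0),
                               exchange_efficiency=1.0, in_vacuum=True,
                               q_grid=np.array([0.1]))
        assert effective_lengths(m, cfg)[0] == pytest.approx(16.031, abs=1e-3)

    def test_linear_in_solvent_d_fraction(self):
        m = AtomicModel(np.array(["O"], dtype=object), [[0, 0, 0]], [2])
        cfgs = [SimulationConfig(solvent=SolventSpec(x),
                                 exchange_efficiency=1.0, in_vacuum=True,
                                 q_grid=np.array([0.1])) for x in (0.0, 1.0)]
        b0, b1 = (effective_lengths(m, c)[0] for c in cfgs)
        assert b1 - b0 == pytest.approx(2 * (6.671 + 3.739), abs=1e-6)

    def test_excluded_volume_lowers_length_in_solvent(self):
        m = AtomicModel(np.array(["C"], dtype=object), [[0, 0, 0]], [0])
        cfg = SimulationConfig(solvent=SolventSpec(1.0),
                               q_grid=np.array([0.1]))
        assert effective_lengths(m, cfg)[0] < 6.646


class TestDebyeCurve:
    def test_single_atom_flat_b_squared(self):
        m = make_point_model([[0, 0, 0]], b=2.5)
        c = debye_curve(m, vacuum_cfg(np.linspace(0.01, 1, 20)))
        np.testing.assert_allclose(c.intensity, 6.25)

    def test_two_point_closed_form(self):
        d = 10.0
        m = make_point_model([[0, 0, 0], [0, 0, d]])
        q = np.linspace(0.01, 2.0, 100)
        c = debye_curve(m, vacuum_cfg(q))
        np.testing.assert_allclose(
            c.intensity, 2 * (1 + np.sin(q * d) / (q * d)), rtol=1e-12)

    def test_forward_limit_is_total_length_squared(self):
        m = make_ball(30.0, 200, seed=4)
        c = debye_curve(m, vacuum_cfg([1e-6]))
        assert c.intensity[0] == pytest.approx(200.0 ** 2, rel=1e-8)

    def test_sphere_form_factor_oracle(self):
        # Monte-Carlo ball vs analytic sphere form factor
        # [3 (sin qR - qR cos qR)/(qR)^3]^2; the N-point self term is the
        # known sampling floor and is removed before comparison.
        R, n = 50.0, 5000
        m = make_ball(R, n, seed=1)
        q = np.geomspace(0.005, 8.0 / R, 60)
        c = debye_curve(m, SimulationConfig(q_grid=q, histogram_bin=0.5,
                                            in_vacuum=True), exact=False)
        est = (c.intensity - n) / (n * (n - 1))
        qR = q * R
        ff = (3 * (np.sin(qR) - qR * np.cos(qR)) / qR ** 3) ** 2
        rms = np.sqrt(np.mean((est - ff) ** 2))
        assert rms < 0.02

    def test_rigid_motion_invariance(self):
        m = make_ball(20.0, 150, seed=2)
        q = np.geomspace(0.01, 0.5, 30)
        c0 = debye_curve(m, vacuum_cfg(q))
        from scipy.spatial.transform import Rotation
        rot = Rotation.from_rotvec([0.3, -1.2, 0.7])
        m2 = m.copy()
        m2.coords = rot.apply(m2.coords) + np.array([100.0, -50.0, 3.0])
        c1 = debye_curve(m2, vacuum_cfg(q))
        np.testing.assert_allclose(c1.intensity, c0.intensity, rtol=1e-9)

    def test_contrast_parabola_around_match_point(self):
        # a protonated model's I(0) falls to the match point then rises
        m = AtomicModel(np.array(["C"] * 50, dtype=object),
                        make_ball(15.0, 50, seed=3).coords,
                        np.ones(50))
        i0 = []
        fracs = np.linspace(0.0, 1.0, 21)
        for f in fracs:
            cfg = SimulationConfig(solvent=SolventSpec(f),
                                   q_grid=np.array([1e-6]))
            i0.append(debye_curve(m, cfg).intensity[0])
        i0 = np.array(i0)
        k = int(np.argmin(i0))
        assert 0 < k < len(i0) - 1
        assert np.all(np.diff(i0[:k + 1]) < 0) and np.all(np.diff(i0[k:]) > 0)


class TestPairDistanceHistogram:
    def test_two_atoms_single_bin(self):
        m = make_point_model([[0, 0, 0], [0, 0, 10]])
        centers, hist = pair_distance_histogram(m, 0.5)
        occupied = np.flatnonzero(hist)
        assert len(occupied) == 1
        assert abs(centers[occupied[0]] - 10.0) <= 0.25

    def test_total_weight_counting_identity(self):
        m = make_ball(25.0, 300, seed=5)
        b = np.linspace(0.5, 2.0, 300)
        _, hist = pair_distance_histogram(m, 0.5, weights=b)
        assert 2 * hist.sum() == pytest.approx(b.sum() ** 2 - (b ** 2).sum(),
                                               rel=1e-12)

    def test_histogram_sum_matches_exact_debye(self):
        m = make_ball(30.0, 500, seed=6)
        q = np.array([0.3])
        cfg = SimulationConfig(q_grid=q, histogram_bin=0.5, in_vacuum=True)
        exact = debye_curve(m, cfg, exact=True).intensity[0]
        hist = debye_curve(m, cfg, exact=False).intensity[0]
        assert abs(hist - exact) / exact < 0.005


class TestHydrationShell:
    def test_null_shell_leaves_curve_unchanged(self):
        m = make_ball(15.0, 100, seed=7)
        q = np.geomspace(0.01, 0.5, 20)
        cfg = SimulationConfig(q_grid=q, hydration_contrast_factor=1.0)
        c0 = debye_curve(m, cfg)
        c1 = debye_curve(m, cfg, hydration_shell=True)
        np.testing.assert_allclose(c1.intensity, c0.intensity)

    def test_forward_scattering_sum_rule(self):
        m = AtomicModel(np.array(["C"] * 60, dtype=object),
                        make_ball(10.0, 60, seed=8).coords, np.zeros(60))
        cfg = SimulationConfig(q_grid=np.array([1e-6]))
        dec = add_hydration_shell(m, cfg)
        b_core = effective_lengths(m, cfg).sum()
        b_all = effective_lengths(dec, cfg).sum()
        i0_core = debye_curve(m, cfg).intensity[0]
        i0_shell = debye_curve(dec, cfg, exact=False).intensity[0]
        assert i0_shell / i0_core == pytest.approx((b_all / b_core) ** 2,
                                                   rel=1e-6)

    def test_shell_volume_matches_analytic_spherical_shell(self):
        # grid-packed ball whose van der Waals envelope sits at R = 20
        g = np.arange(-19, 19.01, 2.0)
        pts = np.array(np.meshgrid(g, g, g)).reshape(3, -1).T
        pts = pts[np.linalg.norm(pts, axis=1) <= 20 - 1.7]
        ball = AtomicModel(np.array(["C"] * len(pts), dtype=object), pts,
                           np.zeros(len(pts)))
        v = shell_volume(ball)
        analytic = 4 / 3 * np.pi * (23.0 ** 3 - 20.0 ** 3)
        assert v == pytest.approx(analytic, rel=0.10)

    def test_collinear_geometry_skips_shell_with_warning(self):
        m = make_point_model([[0, 0, z] for z in range(5)])
        with pytest.warns(UserWarning, match="degenerate"):
            out = add_hydration_shell(m, SimulationConfig())
        assert len(out) == len(m)
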