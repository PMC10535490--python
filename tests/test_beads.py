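import numpy as np
import pytest
from scipy.spatial.distance import cdist

from icmsas import (AnnealConfig, BeadModel, ScatteringCurve, SimulationConfig,
                    bead_fit, debye_curve, ensemble_filter, hcp_lattice, nsd)


def sphere_model(sites, radius_occ, bead_radius=25.5, center=(0, 0, 0)):
    mask = np.linalg.norm(sites - np.asarray(center, float), axis=1) <= radius_occ
    return BeadModel(sites, bead_radius, mask)


def target_from(model, q, noise_sigma_frac=0.01):
    c = debye_curve(model.to_atomic_model(),
                    SimulationConfig(q_grid=q, histogram_bin=2.0,
                                     in_vacuum=True), exact=True)
    return ScatteringCurve(q, c.intensity, noise_sigma_frac * c.intensity)


class TestLattice:
    def test_minimum_spacing_is_bead_diameter(self):
        sites = hcp_lattice(200.0, 20.0)
        d = cdist(sites, sites)
        np.fill_diagonal(d, np.inf)
        assert d.min() == pytest.approx(40.0, rel=1e-6)

    def test_sites_inside_search_sphere(self):
        sites = hcp_lattice(300.0, 25.5)
        assert np.all(np.linalg.norm(sites, axis=1) <= 150.0 + 1e-9)


class TestNsd:
    def test_identity_is_zero(self):
        sites = hcp_lattice(200.0, 20.0)
        m = sphere_model(sites, 80.0, 20.0)
        assert nsd(m, m) == pytest.approx(0.0, abs=1e-12)

    def test_translation_invariance(self):
        sites = hcp_lattice(200.0, 20.0)
        m = sphere_model(sites, 80.0, 20.0)
        shifted = BeadModel(sites + np.array([31.0, -17.0, 5.0]), 20.0,
                            m.occupied)
        assert nsd(m, shifted) == pytest.approx(0.0, abs=1e-9)

    def test_interpenetrating_lattices_match_brute_force(self):
        # cubic lattice vs its half-cell-offset interpenetrating partner,
        # clipped to the same box so the offset is not a pure translation
        g = np.arange(0, 31, 10.0)
        a = np.array(np.meshgrid(g, g, g)).reshape(3, -1).T
        b = a[:, :] + 5.0
        b = b[np.all(b <= 30.0, axis=1)]

        # independent full-matrix oracle implementing the same definition
        from itertools import permutations, product
        def mean_nn(p):
            d = cdist(p, p)
            np.fill_diagonal(d, np.inf)
            return d.min(axis=1).mean()
        pa = a - a.mean(axis=0)
        pb = b - b.mean(axis=0)
        da, db = mean_nn(pa), mean_nn(pb)
        best = np.inf
        for perm in permutations(range(3)):
            for signs in product((1, -1), repeat=3):
                m = np.zeros((3, 3))
                for row, (col, s) in enumerate(zip(perm, signs)):
                    m[row, col] = s
                pr = pa @ m.T
                d_ab = cdist(pr, pb).min(axis=1)
                d_ba = cdist(pb, pr).min(axis=1)
                val = np.sqrt(0.5 * ((d_ab ** 2).mean() / db ** 2
                                     + (d_ba ** 2).mean() / da ** 2))
                best = min(best, val)
        assert best > 0.1  # genuinely distinct sets
        assert nsd(a, b) == pytest.approx(best, rel=1e-9)

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        a, b = rng.random((30, 3)) * 50, rng.random((25, 3)) * 50
        assert nsd(a, b) == pytest.approx(nsd(b, a), rel=1e-9)


class TestEnsembleFilter:
    def test_identical_models_all_accepted(self):
        sites = hcp_lattice(200.0, 20.0)
        models = [sphere_model(sites, 80.0, 20.0) for _ in range(4)]
        assert len(ensemble_filter(models)) == 4

    def test_gross_outlier_rejected(self):
        sites = hcp_lattice(300.0, 20.0)
        similar = [sphere_model(sites, 80.0, 20.0,
                                center=(dx, 0, 0))
                   for dx in (0.0, 5.0, -5.0, 10.0)]
        # outlier: a long thin line of beads instead of a ball
        line = np.column_stack([np.arange(-500, 501, 40.0),
                                np.zeros(26), np.zeros(26)])
        stick = BeadModel(line, 20.0, np.ones(26, dtype=bool))
        assert nsd(stick, similar[0]) > 1.7
        kept = ensemble_filter(similar + [stick], threshold=1.7)
        assert len(kept) == 4
        assert all(k is not stick for k in kept)


class TestBeadFit:
    def test_sphere_recovery(self):
        sites = hcp_lattice(400.0, 25.5)
        truth = sphere_model(sites, 150.0)
        q = np.geomspace(0.004, 0.08, 40)
        cfg = AnnealConfig(target_from(truth, q), bead_radius=25.5,
                           search_diameter=400.0, seed=1)
        model, rep = bead_fit(cfg)
        assert rep["chi2"] < rep["chi2_initial"] / 10
        assert nsd(model, truth) < 1.0

    def test_looseness_dominated_limit_is_compact(self):
        sites = hcp_lattice(300.0, 25.5)
        truth = sphere_model(sites, 100.0)
        q = np.geomspace(0.005, 0.08, 30)
        cfg = AnnealConfig(target_from(truth, q), bead_radius=25.5,
                           search_diameter=300.0, looseness_weight=1e6,
                           seed=2)
        model, _ = bead_fit(cfg)
        pts = model.occupied_centers
        if len(pts) > 4:
            d = cdist(pts, pts)
            neigh = (d > 1e-9) & (d <= 2 * 25.5 * 1.1)
            assert (neigh.sum(axis=1) >= 3).mean() > 0.7

    def test_annealing_reduces_energy_on_every_seed(self):
        sites = hcp_lattice(300.0, 25.5)
        truth = sphere_model(sites, 100.0)
        q = np.geomspace(0.005, 0.08, 30)
        for seed in range(3):
            cfg = AnnealConfig(target_from(truth, q), bead_radius=25.5,
                               search_diameter=300.0, seed=seed,
                               max_steps=20000)
            _, rep = bead_fit(cfg)
            assert rep["energy_final"] <= rep["energy_initial"]

    def test_short_target_curve_rejected(self):
        q = np.geomspace(0.01, 0.05, 5)
        t = ScatteringCurve(q, np.ones(5), np.ones(5))
        with pytest.raises(ValueError):
            AnnealConfig(t)
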