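"""Canned numerical experiments at the scale of the study's simulations.

Each function runs one self-contained measurement the pipeline is built
around — fractal slope of simulated debris aggregates, the thin-rod
signature of elongated fibrils, interference peaks of laterally paired
fibrils, match-point recovery from a contrast series — and returns plain
numbers.  They are the substance behind ``scripts/acceptance.py`` and the
integration tests.
"""

from __future__ import annotations

import numpy as np

from .analysis import fit_match_point, porod_slope
from .assembly import lateral_pair
from .debye import SimulationConfig, debye_curve
from .io import AtomicModel
from .synth import gen_contrast_series, gen_dla_cluster


def dla_porod_slope(n_monomers: int = 3000, monomer_radius: float = 1.0,
                    seeds=(0, 1, 2)) -> dict:
    """Log-log Porod slope of simulated DLA clusters, averaged over seeds.

    The fit window spans the Guinier-to-monomer fractal regime,
    1/Rg < q < 0.5/monomer_radius; for diffusion-limited aggregates the
    slope approaches -D with D ~ 2.5.
    """
    slopes = []
    for seed in seeds:
        cluster = gen_dla_cluster(n_monomers, monomer_radius, seed=seed)
        pts = cluster.coords - cluster.coords.mean(axis=0)
        rg = float(np.sqrt((pts ** 2).sum(axis=1).mean()))
        q = np.geomspace(1.0 / rg, 0.5 / monomer_radius, 40)
        cfg = SimulationConfig(q_grid=q, histogram_bin=0.1 * monomer_radius,
                               in_vacuum=True)
        curve = debye_curve(cluster, cfg, exact=False)
        slopes.append(porod_slope(curve, (q[0], q[-1])).slope)
    return {"slope_mean": float(np.mean(slopes)),
            "slopes": [float(s) for s in slopes],
            "n_monomers": n_monomers}


def make_rod_model(length: float, radius: float, n_points: int,
                   seed: int = 0) -> AtomicModel:
    """Uniform random point scatterers filling a cylinder along z."""
    rng = np.random.default_rng(seed)
    z = rng.uniform(-length / 2, length / 2, n_points)
    phi = rng.uniform(0, 2 * np.pi, n_points)
    r = radius * np.sqrt(rng.random(n_points))
    pts = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    return AtomicModel(np.array(["X"] * n_points, dtype=object), pts,
                       np.zeros(n_points), b_explicit=np.ones(n_points),
                       axis=np.array([0.0, 0.0, 1.0]))


def rod_porod_slope(length: float = 1000.0, radius: float = 20.0,
                    n_points: int = 4000, seed: int = 0,
                    q_window=None) -> dict:
    """Intermediate-regime log-log slope of a long thin rod's curve.

    The window defaults to the full thin-rod regime 2 pi / length < q <
    1 / radius, where the slope approaches the rod value -1 (the
    cross-section form factor steepens the curve beyond q ~ 1/radius).
    """
    if q_window is None:
        q_window = (2 * np.pi / length, 1.0 / radius)
    rod = make_rod_model(length, radius, n_points, seed)
    q = np.geomspace(q_window[0], q_window[1], 30)
    cfg = SimulationConfig(q_grid=q, histogram_bin=0.5, in_vacuum=True)
    curve = debye_curve(rod, cfg, exact=False)
    fit = porod_slope(curve, q_window)
    return {"slope": fit.slope, "stderr": fit.stderr, "n_points": n_points}


def pair_interference_positions(separations=(225.0, 250.0, 275.0),
                                length: float = 525.0, radius: float = 20.0,
                                n_points: int = 1500, seed: int = 0) -> dict:
    """First interference maximum of I_pair/I_mono for lateral fibril pairs.

    Returns the peak position (A^-1) per separation; positions shift to
    smaller q as the separation grows.
    """
    from scipy.signal import find_peaks

    rod = make_rod_model(length, radius, n_points, seed)
    q = np.geomspace(0.008, 0.1, 150)
    cfg = SimulationConfig(q_grid=q, histogram_bin=0.5, in_vacuum=True)
    i_mono = debye_curve(rod, cfg, exact=False).intensity
    out = {}
    for sep in separations:
        pair = lateral_pair(rod, float(sep))
        ratio = debye_curve(pair, cfg, exact=False).intensity / i_mono
        idx, _ = find_peaks(ratio)
        idx = [k for k in idx if q[k] > 0.012]
        out[float(sep)] = float(q[idx[0]]) if idx else float("nan")
    return out


def match_point_recovery(true_match: float = 96.7, noise_frac: float = 0.02,
                         n_seeds: int = 100, seed0: int = 0) -> dict:
    """Recover a known match point from noisy synthetic contrast series."""
    recovered = []
    for s in range(seed0, seed0 + n_seeds):
        series = gen_contrast_series(match_point_pct=true_match,
                                     noise_frac=noise_frac, seed=s)
        recovered.append(fit_match_point(series).match_point)
    recovered = np.asarray(recovered)
    return {"mean": float(recovered.mean()),
            "max_abs_error": float(np.abs(recovered - true_match).max()),
            "true": true_match, "n_seeds": n_seeds}
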