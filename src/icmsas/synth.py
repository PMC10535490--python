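"""Synthetic instrument-free inputs with known ground truth.

Emulates the statistical structure of the measurement campaign the
pipeline analyses — polydisperse mass-fractal cell-debris scattering with
an H-content-driven incoherent floor, a 0-100% D2O contrast series
crossing a configurable match point, off-lattice diffusion-limited
aggregates (DLA, fractal dimension ~2.5 in 3D), and a fibrillization
time course where first/second-order interference peaks (default
periodicity 251 A) grow on a steepening power-law background with a
broad inter-sheet hump at 0.4 A^-1.

Every generator is deterministic under its seed and stamps its
ground-truth parameters into the curve metadata, so each analysis stage
has a closed-loop parameter-recovery test.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .io import AtomicModel, ScatteringCurve


def gen_debris_curve(q_grid, fractal_dim: float = 2.4, rg: float = 300.0,
                     scale: float = 1.0, incoherent_level: float = 0.01,
                     noise_frac: float = 0.0, seed: int = 0) -> ScatteringCurve:
    """Featureless mass-fractal debris curve.

    I(q) = scale / (1 + (2/(3 D)) q^2 Rg^2)^(D/2) + incoherent_level,
    a Fisher-Burford-type fractal profile whose Porod slope tends to -D
    for q Rg >> 1, with multiplicative Gaussian noise of fractional width
    ``noise_frac``.
    """
    if not 1.0 < fractal_dim < 3.0:
        raise ValueError("fractal_dim must be in (1, 3)")
    q = np.asarray(q_grid, dtype=float)
    rng = np.random.default_rng(seed)
    d = fractal_dim
    coh = scale / (1.0 + (2.0 / (3.0 * d)) * (q * rg) ** 2) ** (d / 2.0)
    ideal = coh + incoherent_level
    noisy = ideal * (1.0 + noise_frac * rng.standard_normal(len(q)))
    sigma = np.abs(ideal) * noise_frac if noise_frac > 0 else np.sqrt(np.abs(ideal))
    meta = {"true_fractal_dim": d, "true_rg": rg, "true_scale": scale,
            "true_incoherent": incoherent_level, "noise_frac": noise_frac,
            "seed": seed}
    return ScatteringCurve(q, noisy, sigma, label="synthetic_debris", meta=meta)


def gen_dla_cluster(n_monomers: int, monomer_radius: float = 1.0,
                    seed: int = 0) -> AtomicModel:
    """Off-lattice 3D diffusion-limited aggregate.

    Monomers are launched from a sphere enclosing the cluster and random
    walk (sticking probability 1) until they touch it; far from the
    cluster the walker jumps by its distance to the nearest monomer minus
    the contact distance, which leaves the hit distribution unchanged.
    Returns monomer centres as unit point scatterers.
    """
    if n_monomers < 10:
        raise ValueError("need n_monomers >= 10")
    rng = np.random.default_rng(seed)
    contact = 2.0 * monomer_radius
    # near-field walker step; small enough that cluster density is
    # converged (coarser steps measurably densify the aggregate)
    step_min = 0.3 * monomer_radius
    pts = np.zeros((n_monomers, 3))
    npts = 1
    r_cluster = 0.0
    kill_margin = 30.0 * contact

    def rand_dir(n=1):
        v = rng.standard_normal((n, 3))
        return v / np.linalg.norm(v, axis=1, keepdims=True)

    tree = cKDTree(pts[:1])
    rebuild_at = 2
    while npts < n_monomers:
        r_launch = r_cluster + 5.0 * contact
        pos = r_launch * rand_dir()[0]
        while True:
            d_tree, _ = tree.query(pos)
            if npts > tree.n:
                d_extra = np.linalg.norm(pts[tree.n:npts] - pos,
                                         axis=1).min()
                d_near = min(d_tree, d_extra)
            else:
                d_near = d_tree
            if d_near <= contact + 0.5 * step_min:
                # stick: place at contact distance from the nearest monomer
                all_d = np.linalg.norm(pts[:npts] - pos, axis=1)
                j = int(np.argmin(all_d))
                u = pos - pts[j]
                norm = np.linalg.norm(u)
                u = rand_dir()[0] if norm < 1e-12 else u / norm
                pts[npts] = pts[j] + contact * u
                npts += 1
                r_cluster = max(r_cluster, np.linalg.norm(pts[npts - 1]))
                if npts >= rebuild_at:
                    tree = cKDTree(pts[:npts])
                    rebuild_at = npts + max(8, npts // 50)
                break
            step = max(d_near - contact, step_min)
            pos = pos + step * rand_dir()[0]
            r_pos = np.linalg.norm(pos)
            if r_pos > r_launch + kill_margin:
                # re-launch on the sphere (walker escaped)
                pos = r_launch * rand_dir()[0]
    n = n_monomers
    return AtomicModel(np.array(["X"] * n, dtype=object), pts, np.zeros(n),
                       b_explicit=np.ones(n), label=f"dla_{n}_seed{seed}")


def gen_contrast_series(match_point_pct: float = 96.7,
                        fractions=(0, 20, 40, 60, 80, 100),
                        q_grid=None, scale: float = 1.0,
                        noise_frac: float = 0.0, seed: int = 0,
                        fractal_dim: float = 2.4, rg: float = 300.0,
                        incoherent_level: float = 0.01):
    """Contrast-variation series of debris curves.

    Each curve is the mass-fractal debris profile scaled by the squared
    contrast (f - match_point)^2 (in percent units), plus an incoherent
    floor that decreases linearly with the D2O fraction, mimicking the
    H-content trend of real solvent series.
    """
    fractions = list(fractions)
    if any(not 0 <= f <= 100 for f in fractions):
        raise ValueError("fractions must lie in [0, 100] % D2O")
    if q_grid is None:
        q_grid = np.geomspace(0.005, 0.5, 200)
    out = []
    for k, f in enumerate(fractions):
        contrast2 = (f - match_point_pct) ** 2
        inc = incoherent_level * (1.0 - 0.9 * f / 100.0)
        c = gen_debris_curve(q_grid, fractal_dim=fractal_dim, rg=rg,
                             scale=scale * contrast2, incoherent_level=inc,
                             noise_frac=noise_frac, seed=seed + 1000 * k)
        c.label = f"debris_{f:g}pctD2O"
        c.meta.update({"d2o_percent": float(f),
                       "true_match_point": match_point_pct})
        out.append((float(f), c))
    return out


def gen_fibrillization_timecourse(times, q_grid=None,
                                  periodicity: float = 251.0,
                                  onset_h: float = 5.0,
                                  growth_rate: float = 0.1,
                                  peak_fwhm: float = 0.004,
                                  noise_frac: float = 0.0, seed: int = 0):
    """Time series of fibrillization curves with growing interference peaks.

    Background: power law A q^p with p drifting -2.4 -> -2.5 across the
    series (aggregate coarsening) plus a flat floor.  After ``onset_h``,
    Gaussian peaks at q0 = 2 pi / periodicity and 2 q0 grow with
    saturating amplitude 1 - exp(-growth_rate (t - onset)), the second
    order at half the first-order amplitude, together with a broad
    beta-sheet hump fixed at 0.4 A^-1.
    """
    times = list(times)
    if any(b <= a for a, b in zip(times, times[1:])) or (times and times[0] < 0):
        raise ValueError("times must be non-negative and increasing")
    if q_grid is None:
        q_grid = np.geomspace(0.008, 0.8, 400)
    q = np.asarray(q_grid, dtype=float)
    rng = np.random.default_rng(seed)
    q0 = 2.0 * np.pi / periodicity
    sig_pk = peak_fwhm / 2.3548
    t_span = max(times[-1] - times[0], 1e-9)
    out = []
    for t in times:
        p = -2.4 - 0.1 * (t - times[0]) / t_span
        bg = 1e-4 * q ** p + 0.01
        amp = 0.0 if t <= onset_h else 1.0 - np.exp(-growth_rate * (t - onset_h))
        peak_scale = amp * 1e-4 * q0 ** (-2.4) * 0.5
        i = bg.copy()
        i += peak_scale * np.exp(-0.5 * ((q - q0) / sig_pk) ** 2)
        i += 0.5 * peak_scale * np.exp(-0.5 * ((q - 2 * q0) / sig_pk) ** 2)
        hump_scale = amp * 0.05
        i += hump_scale * np.exp(-0.5 * ((q - 0.4) / 0.06) ** 2)
        noisy = i * (1.0 + noise_frac * rng.standard_normal(len(q)))
        sigma = i * noise_frac if noise_frac > 0 else np.sqrt(i)
        meta = {"time_h": float(t), "true_periodicity": periodicity,
                "true_q0": q0, "onset_h": onset_h,
                "true_slope": p, "peak_amplitude": float(amp), "seed": seed}
        out.append((float(t), ScatteringCurve(q, noisy, sigma,
                                              label=f"fibril_t{t:g}h",
                                              meta=meta)))
    return out
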