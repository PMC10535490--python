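"""Orientationally averaged neutron scattering curves via the Debye formula.

    I(q) = sum_i sum_j b_i b_j sin(q r_ij) / (q r_ij)

with per-atom *effective* lengths b_i that account for (i) the element's
coherent length, (ii) exchangeable hydrogens at the solvent's D occupancy,
and (iii) the solvent-displaced volume (excluded-volume term), so that a
particle at its contrast-match point scatters nothing at q -> 0.  A
hydration shell of configurable excess SLD (default +10% of solvent) can
be added as surface pseudo-atoms, following the convention of
solution-scattering simulators for proteins in D2O solvents.

The double sum is evaluated exactly for small models and through a
b-weighted pair-distance histogram above a size threshold; the histogram
bin width (default 0.5 A) keeps the approximation below 0.5% for
q < pi / (2 bin).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .constants import (COHERENT_B_FM, DISPLACED_VOLUME_A3,
                        FM_PER_A3_TO_SLD, VDW_RADIUS_A)
from .contrast import SolventSpec, solvent_sld
from .io import AtomicModel, ScatteringCurve, concat_models

#: models up to this size use the exact double sum
EXACT_ATOM_LIMIT = 2000


def default_q_grid(q_min: float = 0.005, q_max: float = 2.0,
                   n: int = 400, log: bool = True) -> np.ndarray:
    if log:
        return np.geomspace(q_min, q_max, n)
    return np.linspace(q_min, q_max, n)


@dataclass
class SimulationConfig:
    """Debye-engine settings.

    Defaults mirror the inverse contrast-matching measurement conditions:
    96.7% D2O solvent, hydration shell 10% above the solvent SLD and 3 A
    thick, 90% labile-H exchange.
    """

    solvent: SolventSpec = field(
        default_factory=lambda: SolventSpec(0.967))
    hydration_contrast_factor: float = 1.10
    shell_thickness: float = 3.0
    exchange_efficiency: float = 0.9
    q_grid: np.ndarray = field(default_factory=default_q_grid)
    histogram_bin: float = 0.5
    shell_mesh_spacing: float = 1.5
    in_vacuum: bool = False   # drop the excluded-volume term (rho_solvent = 0)

    def __post_init__(self):
        self.q_grid = np.asarray(self.q_grid, dtype=float)
        if self.hydration_contrast_factor <= 0:
            raise ValueError("hydration_contrast_factor must be positive")
        if self.histogram_bin <= 0:
            raise ValueError("histogram_bin must be positive")
        if np.any(self.q_grid <= 0) or np.any(np.diff(self.q_grid) <= 0):
            raise ValueError("q_grid must be positive and increasing")

    @property
    def solvent_rho_fm_a3(self) -> float:
        """Solvent SLD in fm/A^3 (0 when in_vacuum)."""
        if self.in_vacuum:
            return 0.0
        return solvent_sld(self.solvent) / FM_PER_A3_TO_SLD


def effective_lengths(model: AtomicModel,
                      config: SimulationConfig | None = None) -> np.ndarray:
    """Per-atom effective scattering lengths, fm.

    b_eff = b_el + n_exch [(1-x) b_H + x b_D] - rho_solv (V_el + n_exch V_H)

    with x = d2o_fraction x exchange_efficiency.  Pseudo-atoms (element
    "X") pass their explicit length through unchanged.
    """
    config = config or SimulationConfig()
    x = config.solvent.d2o_volume_fraction * config.exchange_efficiency
    rho = config.solvent_rho_fm_a3
    b = np.empty(len(model))
    for i, el in enumerate(model.elements):
        if el == "X":
            b[i] = model.b_explicit[i]
            continue
        nex = model.n_exchangeable_h[i]
        b[i] = (COHERENT_B_FM[el]
                + nex * ((1 - x) * COHERENT_B_FM["H"] + x * COHERENT_B_FM["D"])
                - rho * (DISPLACED_VOLUME_A3[el] + nex * DISPLACED_VOLUME_A3["H"]))
    return b * model.occupancy


def pair_distance_histogram(model: AtomicModel, bin_width: float,
                            weights: np.ndarray | None = None):
    """b-weighted histogram of pair distances (i < j counted once).

    Returns (r_k, w_k): per-bin weighted mean distances and summed
    weights b_i b_j.  Using the weighted mean distance instead of the
    geometric bin centre keeps the histogram-accelerated Debye sum well
    inside 0.5% of the exact double sum for q < pi / (2 bin_width).
    The total weight equals ((sum b)^2 - sum b^2) / 2.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    xyz = model.coords
    b = weights if weights is not None else np.ones(len(model))
    n = len(xyz)
    # bounding-box diagonal bounds the largest pair distance
    span = np.linalg.norm(xyz.max(axis=0) - xyz.min(axis=0)) if n > 1 else 0.0
    nbins = max(int(np.ceil(span / bin_width)) + 1, 1)
    hist = np.zeros(nbins)
    wr = np.zeros(nbins)  # weighted sum of distances per bin
    block = max(1, int(4e6 // max(n, 1)))
    cols = np.arange(n)
    for start in range(0, n, block):
        stop = min(start + block, n)
        d = np.linalg.norm(xyz[start:stop, None, :] - xyz[None, :, :], axis=2)
        w = b[start:stop, None] * b[None, :]
        mask = cols[None, :] > np.arange(start, stop)[:, None]
        dv, wv = d[mask], w[mask]
        if not len(dv):
            continue
        idx = np.minimum((dv / bin_width).astype(np.int64), nbins - 1)
        hist += np.bincount(idx, weights=wv, minlength=nbins)
        wr += np.bincount(idx, weights=wv * dv, minlength=nbins)
    edges = np.arange(nbins) * bin_width
    centers = edges + 0.5 * bin_width
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_r = wr / np.where(hist != 0, hist, 1.0)
    # mixed-sign weights can push the ratio outside the bin; clamp
    mean_r = np.clip(mean_r, edges, edges + bin_width)
    centers = np.where(hist != 0, mean_r, centers)
    return centers, hist


def _debye_exact(xyz, b, q):
    n = len(xyz)
    iq = np.full(len(q), float(np.sum(b ** 2)))
    block = max(1, int(4e6 // max(n, 1)))
    for start in range(0, n, block):
        stop = min(start + block, n)
        d = np.linalg.norm(xyz[start:stop, None, :] - xyz[None, :, :], axis=2)
        w = b[start:stop, None] * b[None, :]
        rows = np.arange(start, stop)
        mask = np.arange(n)[None, :] > rows[:, None]
        dv, wv = d[mask], w[mask]
        if not len(dv):
            continue
        qr = np.outer(q, dv)
        with np.errstate(invalid="ignore", divide="ignore"):
            sinc = np.where(qr == 0, 1.0, np.sin(qr) / qr)
        iq += 2.0 * sinc @ wv
    return iq


def _debye_histogram(xyz, b, q, bin_width):
    centers, hist = pair_distance_histogram(
        AtomicModel(np.array(["X"] * len(xyz), dtype=object), xyz,
                    np.zeros(len(xyz)), b_explicit=np.ones(len(xyz))),
        bin_width, weights=b)
    qr = np.outer(q, centers)
    with np.errstate(invalid="ignore", divide="ignore"):
        sinc = np.where(qr == 0, 1.0, np.sin(qr) / qr)
    return np.sum(b ** 2) + 2.0 * sinc @ hist


def debye_curve(model: AtomicModel,
                config: SimulationConfig | None = None,
                hydration_shell: bool = False,
                exact: bool | None = None) -> ScatteringCurve:
    """Orientationally averaged I(q) of a model in the configured solvent.

    ``hydration_shell=True`` decorates the model with surface pseudo-atoms
    (see :func:`add_hydration_shell`) before the sum.  ``exact`` forces
    the exact double sum or the histogram path; by default models up to
    2000 atoms are summed exactly.
    """
    config = config or SimulationConfig()
    if len(model) < 1:
        raise ValueError("model must contain at least one atom")
    if hydration_shell:
        model = add_hydration_shell(model, config)
    b = effective_lengths(model, config)
    q = config.q_grid
    use_exact = exact if exact is not None else len(model) <= EXACT_ATOM_LIMIT
    if use_exact:
        iq = _debye_exact(model.coords, b, q)
    else:
        iq = _debye_histogram(model.coords, b, q, config.histogram_bin)
    meta = {"d2o_percent": 100 * config.solvent.d2o_volume_fraction,
            "n_atoms": len(model), "i0": float(np.sum(b) ** 2)}
    return ScatteringCurve(q, iq, np.zeros_like(iq),
                           label=f"{model.label}_debye", meta=meta)


def _shell_voxels(model: AtomicModel, thickness: float,
                  spacing: float) -> np.ndarray:
    """Centres of cubic voxels whose distance to the van der Waals
    surface lies in [0, thickness)."""
    from scipy.spatial import cKDTree

    xyz = model.coords
    radii = np.array([VDW_RADIUS_A.get(el, 1.7) for el in model.elements])
    pad = radii.max() + thickness + spacing
    lo = xyz.min(axis=0) - pad
    hi = xyz.max(axis=0) + pad
    axes = [np.arange(lo[k] + spacing / 2, hi[k], spacing) for k in range(3)]
    tree = cKDTree(xyz)
    out = []
    # slab-wise to bound memory on elongated models
    yz = np.array(np.meshgrid(axes[1], axes[2], indexing="ij")
                  ).reshape(2, -1).T
    for x in axes[0]:
        pts = np.column_stack([np.full(len(yz), x), yz])
        d, j = tree.query(pts)
        dsurf = d - radii[j]
        keep = (dsurf >= 0.0) & (dsurf < thickness)
        if keep.any():
            out.append(pts[keep])
    return np.vstack(out) if out else np.empty((0, 3))


def add_hydration_shell(model: AtomicModel,
                        config: SimulationConfig | None = None) -> AtomicModel:
    """Decorate a model with hydration-shell pseudo-atoms.

    The shell is the layer of solvent within ``shell_thickness`` of the
    model's van der Waals surface, discretised on a cubic mesh of
    ``shell_mesh_spacing``; each mesh cell becomes a pseudo-atom of
    length (factor - 1) rho_solvent V_cell, so the shell's total excess
    scattering equals the excess SLD times the shell volume (+10% of the
    solvent SLD over the hydration layer by default).
    """
    config = config or SimulationConfig()
    if len(model) < 1:
        raise ValueError("model must not be empty")
    if config.hydration_contrast_factor == 1.0:
        return model.copy()  # null shell: no excess SLD
    xyz = model.coords
    if len(model) >= 3:
        centered = xyz - xyz.mean(axis=0)
        svals = np.linalg.svd(centered, compute_uv=False)
        if svals[1] < 1e-6 * max(svals[0], 1.0):
            warnings.warn("degenerate (collinear) geometry; shell skipped")
            return model.copy()

    pts = _shell_voxels(model, config.shell_thickness,
                        config.shell_mesh_spacing)
    if not len(pts):
        warnings.warn("no shell voxels found; shell skipped")
        return model.copy()
    rho = config.solvent_rho_fm_a3
    v_cell = config.shell_mesh_spacing ** 3
    b_dot = np.full(len(pts),
                    (config.hydration_contrast_factor - 1.0) * rho * v_cell)
    shell = AtomicModel(np.array(["X"] * len(pts), dtype=object), pts,
                        np.zeros(len(pts)), b_explicit=b_dot,
                        label="hydration_shell")
    out = concat_models([model, shell])
    out.label = model.label
    out.axis = None if model.axis is None else model.axis.copy()
    return out


def shell_volume(model: AtomicModel,
                 config: SimulationConfig | None = None) -> float:
    """Total hydration-shell volume (A^3) of the voxel construction."""
    config = config or SimulationConfig()
    pts = _shell_voxels(model, config.shell_thickness,
                        config.shell_mesh_spacing)
    return float(len(pts) * config.shell_mesh_spacing ** 3)
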