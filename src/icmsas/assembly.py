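"""Build higher-order amyloid fibril models from a repeating unit.

Three constructions cover the super-assembly hypotheses explored for the
interference peaks near 0.025 / 0.05 A^-1: axial elongation of a
protofibril unit with an optional per-repeat twist (pseudo-helical
stacking), lateral dimers at a fixed centre-to-centre separation, and an
idealized cross-beta unit (paired beta-sheets, 4.7 A strand spacing) so
the engine can be exercised without downloading PDB entries.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

from .io import AtomicModel, concat_models


def principal_axis(model: AtomicModel) -> np.ndarray:
    """Unit vector along the principal axis of inertia (largest extent)."""
    c = model.coords - model.coords.mean(axis=0)
    _, _, vt = np.linalg.svd(c, full_matrices=False)
    v = vt[0]
    return v / np.linalg.norm(v)


def _require_axis(model: AtomicModel) -> np.ndarray:
    return model.axis if model.axis is not None else principal_axis(model)


def elongate(unit: AtomicModel, n_repeats: int, rise: float,
             twist_deg: float = 0.0) -> AtomicModel:
    """Stack ``n_repeats`` rigid copies of a unit along its fibril axis.

    Copy k is translated k*rise along the axis and rotated k*twist about
    it; twist defaults to 0 (untwisted stack) since the per-repeat twist
    of real fibrils is a free parameter here.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    if rise <= 0:
        raise ValueError("rise must be positive")
    axis = _require_axis(unit)
    com = unit.coords.mean(axis=0)
    copies = []
    for k in range(n_repeats):
        m = unit.copy()
        rot = Rotation.from_rotvec(np.radians(k * twist_deg) * axis)
        m.coords = rot.apply(m.coords - com) + com + k * rise * axis
        copies.append(m)
    out = concat_models(copies)
    out.axis = axis
    out.label = f"{unit.label}_x{n_repeats}"
    return out


def lateral_pair(model: AtomicModel, separation: float,
                 direction=None) -> AtomicModel:
    """Union of a model and a copy shifted by ``separation`` perpendicular
    to the fibril axis (centre-of-mass to centre-of-mass distance)."""
    axis = _require_axis(model)
    if direction is None:
        # any unit vector perpendicular to the axis
        trial = np.array([1.0, 0.0, 0.0])
        if abs(trial @ axis) > 0.9:
            trial = np.array([0.0, 1.0, 0.0])
        direction = trial - (trial @ axis) * axis
        direction = direction / np.linalg.norm(direction)
    direction = np.asarray(direction, dtype=float)
    if abs(np.linalg.norm(direction) - 1.0) > 1e-6:
        raise ValueError("direction must be a unit vector")
    if abs(direction @ axis) > 1e-6:
        raise ValueError("direction must be orthogonal to the fibril axis")
    out = concat_models([model, model.translated(separation * direction)])
    out.axis = axis
    out.label = f"{model.label}_pair{separation:g}"
    return out


def make_cross_beta_unit(n_strands: int, strand_spacing: float = 4.7,
                         sheet_separation: float = 10.0,
                         strand_length: float = 30.0,
                         scatterers_per_strand: int = 7) -> AtomicModel:
    """Idealized paired-beta-sheet unit of point scatterers.

    Two flat parallel sheets of ``n_strands`` strands each; strands are
    lines of scatterers spaced along y, strands stack along the fibril
    (z) axis at 4.7 A, and the sheets sit ``sheet_separation`` apart in x.
    Deterministic geometry; axis set to z.
    """
    if n_strands < 1:
        raise ValueError("n_strands must be >= 1")
    ys = np.linspace(-strand_length / 2, strand_length / 2,
                     scatterers_per_strand)
    pts = []
    for sheet in (0.0, sheet_separation):
        for k in range(n_strands):
            z = k * strand_spacing
            for y in ys:
                pts.append((sheet, y, z))
    pts = np.asarray(pts)
    n = len(pts)
    return AtomicModel(np.array(["X"] * n, dtype=object), pts, np.zeros(n),
                       b_explicit=np.ones(n), axis=np.array([0.0, 0.0, 1.0]),
                       label=f"cross_beta_{n_strands}")
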