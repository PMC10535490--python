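"""Solute-intensity reduction for solution SANS.

Turns solution / solvent / empty-cell measurements into the
background-subtracted solute curve

    I_solute(q) = [I_soln/(B_soln T_soln) - I_cell/(B_cell T_cell)]
                  - (1 - c v_a) [I_solv/(B_solv T_solv) - I_cell/(B_cell T_cell)]

where B are beam-monitor counts, T transmissions, c the solute
concentration (g/cm^3) and v_a its partial specific volume (cm^3/g); the
(1 - c v_a) factor removes the solvent volume displaced by the solute.
Uncertainties propagate in quadrature with the same coefficients.
Absolute calibration (against a water standard) is an external
multiplicative factor and is not performed here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import ScatteringCurve

#: default partial specific volumes, cm^3/g
VA_DEBRIS = 0.74
VA_PROTEIN = 0.73


@dataclass
class ReductionInputs:
    solution: ScatteringCurve
    solvent: ScatteringCurve
    cell: ScatteringCurve
    concentration: float           # g/cm^3
    partial_specific_volume: float = VA_DEBRIS
    interpolate: bool = False      # resample solvent/cell onto solution grid

    def __post_init__(self):
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")
        cva = self.concentration * self.partial_specific_volume
        if cva >= 1:
            raise ValueError(f"c*v_a = {cva:.3f} >= 1 is nonphysical")


def _monitor_transmission(curve: ScatteringCurve) -> tuple[float, float]:
    b = float(curve.meta.get("beam_monitor", 1.0))
    t = float(curve.meta.get("transmission", 1.0))
    if b <= 0:
        raise ValueError(f"beam monitor must be positive, got {b}")
    if not 0 < t <= 1:
        raise ValueError(f"transmission must be in (0, 1], got {t}")
    return b, t


def interpolate_to_grid(curve: ScatteringCurve, q_target) -> ScatteringCurve:
    """Linearly resample I and sigma onto ``q_target`` (no extrapolation)."""
    q_target = np.asarray(q_target, dtype=float)
    if q_target.min() < curve.q[0] or q_target.max() > curve.q[-1]:
        raise ValueError("q_target extends outside the curve's q-range")
    return ScatteringCurve(
        q_target,
        np.interp(q_target, curve.q, curve.intensity),
        np.interp(q_target, curve.q, curve.sigma),
        curve.label, dict(curve.meta),
    )


def reduce_solute(inputs: ReductionInputs,
                  constant_background: float = 0.0) -> ScatteringCurve:
    """Apply the solute reduction equation; see module docstring.

    ``constant_background``, off by default, subtracts a residual flat
    (incoherent) term after the solvent subtraction.
    """
    soln, solv, cell = inputs.solution, inputs.solvent, inputs.cell
    if inputs.interpolate:
        solv = interpolate_to_grid(solv, soln.q)
        cell = interpolate_to_grid(cell, soln.q)
    elif not (np.array_equal(soln.q, solv.q) and np.array_equal(soln.q, cell.q)):
        raise ValueError("curves are on different q-grids; set interpolate=True")

    b1, t1 = _monitor_transmission(soln)
    b2, t2 = _monitor_transmission(solv)
    b3, t3 = _monitor_transmission(cell)
    disp = 1.0 - inputs.concentration * inputs.partial_specific_volume

    cell_norm = cell.intensity / (b3 * t3)
    i_out = ((soln.intensity / (b1 * t1) - cell_norm)
             - disp * (solv.intensity / (b2 * t2) - cell_norm)
             - constant_background)
    # quadrature propagation; the cell term enters with coefficient (1 - disp)
    var = ((soln.sigma / (b1 * t1)) ** 2
           + (disp * solv.sigma / (b2 * t2)) ** 2
           + ((1.0 - disp) * cell.sigma / (b3 * t3)) ** 2)
    meta = {"concentration": inputs.concentration,
            "partial_specific_volume": inputs.partial_specific_volume}
    return ScatteringCurve(soln.q, i_out, np.sqrt(var),
                           label=f"{soln.label}_solute", meta=meta)
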