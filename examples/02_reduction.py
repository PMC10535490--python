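"""Reduce solution / solvent / empty-cell measurements to the solute
curve, with monitor and transmission normalisation and the solvent
displacement correction (1 - c v_a)."""

import numpy as np

from icmsas import (ReductionInputs, ScatteringCurve, gen_debris_curve,
                    reduce_solute)

q = np.geomspace(0.006, 0.5, 150)
rng = np.random.default_rng(0)

# ground truth: debris signal and solvent/cell backgrounds (per-monitor
# normalised units)
debris_true = gen_debris_curve(q, fractal_dim=2.4, rg=300.0, noise_frac=0.0)
solvent_level = np.full_like(q, 0.08)
cell_level = np.full_like(q, 0.01)

def frame(signal, monitor, transmission):
    """Detector counts for a measurement: monitor x transmission x signal."""
    counts = monitor * transmission * signal
    return ScatteringCurve(q, counts, np.sqrt(np.abs(counts)),
                           meta={"beam_monitor": monitor,
                                 "transmission": transmission})

c, va = 0.02, 0.74  # 2% w/v debris, v_a = 0.74 cm^3/g
solution = frame(debris_true.intensity + (1 - c * va) * solvent_level
                 + cell_level, 1.2e7, 0.90)
solvent = frame(solvent_level + cell_level, 1.1e7, 0.93)
cell = frame(cell_level, 1.0e7, 0.97)

out = reduce_solute(ReductionInputs(solution, solvent, cell,
                                    concentration=c,
                                    partial_specific_volume=va))
err = np.max(np.abs(out.intensity - debris_true.intensity))
print(f"reduced solute curve: {len(out)} points, "
      f"I({out.q[0]:.4f}) = {out.intensity[0]:.4f}")
print(f"max |reduced - true debris signal| = {err:.2e}")
print("The reduction normalises each frame by its monitor x transmission, "
      "subtracts the empty cell from both brackets, and removes the "
      f"solvent with weight (1 - c v_a) = {1 - c * va:.4f} to account for "
      "the solvent volume the solute displaces.")
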