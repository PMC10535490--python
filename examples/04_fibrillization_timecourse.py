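"""Analyse a fibrillization time course: detect interference peaks over
a power-law background, assign harmonic orders, and convert the
fundamental to a real-space periodicity."""

from icmsas import (assign_harmonics, bragg_spacing, detect_peaks,
                    gen_fibrillization_timecourse, porod_slope)

times = [0, 2, 5, 10, 20, 37]  # hours
series = gen_fibrillization_timecourse(times, periodicity=251.0,
                                       onset_h=5.0, noise_frac=0.0, seed=0)
print(" t/h   peaks (A^-1)          orders   periodicity   Porod slope")
for t, c in series:
    rep = assign_harmonics(detect_peaks(c, 0.05))
    slope = porod_slope(c, (c.q[0], 0.02)).slope
    qs = ", ".join(f"{p.q:.3f}" for p in rep.peaks) or "-"
    orders = [p.order for p in rep.peaks] or "-"
    period = f"{rep.periodicity:.0f} A" if rep.periodicity else "-"
    print(f"{t:5.1f}  {qs:<22}{str(orders):<9}{period:<13}{slope:+.2f}")

print("\nAfter the onset, first/second-order peaks appear near 0.025 and "
      "0.050 A^-1 (plus the broad inter-sheet hump at 0.4 A^-1); the "
      f"fundamental maps to d = 2 pi / q = {bragg_spacing(0.025):.0f} A — "
      "a periodic super-assembly of fibrils, not amorphous aggregation.")
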