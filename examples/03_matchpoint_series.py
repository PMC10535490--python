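"""Determine a crowder's contrast-match point from a D2O contrast series:
sqrt of the integrated small-q intensity is proportional to |contrast|,
so |a f + b| regression against the D2O percentage locates the zero."""

from icmsas import fit_match_point, gen_contrast_series

series = gen_contrast_series(match_point_pct=96.7,
                             fractions=(0, 20, 40, 60, 80, 100),
                             noise_frac=0.02, seed=11)
fit = fit_match_point(series)  # default band 0.0065-0.009 A^-1
print(f"measured fractions : {[f for f, _ in series]} % D2O")
print(f"fitted match point : {fit.match_point:.2f} +/- {fit.std_error:.2f} "
      "% D2O")
print("At this D2O fraction the deuterated debris scatters nothing at "
      "small q; solvent mixed to this point hides the crowder while a "
      "protonated protein keeps ~full contrast (inverse contrast "
      "matching).")
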