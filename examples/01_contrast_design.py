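"""Design the deuteration of a cell-debris crowder for inverse contrast
matching: compute SLDs, match points, and the growth-medium mix that
parks the debris near a 100% D2O solvent."""

from icmsas import (ComponentComposition, SolventSpec, component_sld,
                    dilution, match_point, mixture_match_point, solvent_sld)

print("Solvent SLDs (A^-2):")
print(f"  H2O : {solvent_sld(SolventSpec(0.0)):+.3e}")
print(f"  D2O : {solvent_sld(SolventSpec(1.0)):+.3e}")

protein = ComponentComposition({"protein": 1.0})
print(f"\nNon-deuterated protein SLD in H2O: "
      f"{component_sld(protein, SolventSpec(0.0)):+.3e} A^-2")
print(f"Non-deuterated protein match point: {match_point(protein):.1f}% D2O "
      "(the classic ~40-45% value; the target protein stays visible in "
      "high-D2O solvent)")

debris_full_d = ComponentComposition.ecoli_debris(deuteration_fraction=1.0)
debris_h = ComponentComposition.ecoli_debris(deuteration_fraction=0.0)
mp_d = match_point(debris_full_d)
mp_h = match_point(debris_h)
print(f"\nE. coli debris match points: fully deuterated {mp_d:.0f}% D2O "
      f"(beyond pure D2O), protonated {mp_h:.0f}% D2O")

mix = mixture_match_point(110.0, 33.0, 0.87)
print(f"Growth media mixed 87/13 deuterated/protonated (debris equivalents "
      f"110% / 33% D2O) -> crowder match point {mix:.1f}% D2O,\n"
      "  i.e. the debris becomes invisible in a ~100% D2O solvent while "
      "the protonated target keeps full contrast.")

print(f"\nSample mixing at 1:7 (v/v): 15% w/v debris stock -> "
      f"{dilution(15, 7, 1):.1f}% w/v final; 4% w/v protein stock -> "
      f"{dilution(4, 1, 7):.1f}% w/v final.")
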