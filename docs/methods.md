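# Methods

## Contrast arithmetic

Scattering-length densities are computed as Σb/V from a shipped table of
bound-atom coherent lengths (fm): b_H = −3.739, b_D = 6.671, b_C = 6.646,
b_N = 9.36, b_O = 5.803, b_S = 2.847, b_P = 5.13. Water is fixed at
30.0 Å³/molecule, giving ρ(H₂O) = −0.558×10⁻⁶ Å⁻² and ρ(D₂O) =
+6.38×10⁻⁶ Å⁻²; solvent SLD is affine in the D₂O volume fraction, and
dilute buffer solutes (mM EDTA/HEPES) are carried as metadata but ignored
in the SLD.

Composite particles (cell debris) are described by mass fractions over
six classes, each with a fixed reference monomer: the average amino-acid
residue (133 Å³), an average ribonucleotide (310 Å³), a POPC-like lipid
(1265 Å³), an anhydroglucose unit (164 Å³), protein-like "other
organics", and a phosphate-like inorganic unit. The default composition
is the *E. coli* dry matter split 15/7/2/3/1/1 (% w/w of whole cell),
renormalised over dry mass. Non-labile hydrogens are deuterated at the
growth `deuteration_fraction`; labile (N/O/S-bound) hydrogens follow the
solvent at an exchange efficiency of 0.9 by default — complete exchange
is rarely achieved in practice, and the value is configurable. Match
points are the crossing of component and solvent SLD lines, solved on
[−50, 200]% D₂O: values above 100% are legitimate extrapolated crossings
for heavily deuterated material (the package's fully deuterated debris
composition matches near 119% D₂O; the measured crowder grown in mixed
media is designed to sit near 100%). Because match point is linear in
SLD and SLD is linear in volume fraction, a mixture's match point is the
volume-weighted mean of its parts — this is the arithmetic behind mixing
deuterated and protonated growth media.

## Reduction

The solute curve is
I_solute = [I_soln/(B·T) − I_cell/(B·T)] − (1 − c·v_a)·[I_solv/(B·T) −
I_cell/(B·T)], with per-measurement monitor B and transmission T
(transmissions are scalars; no wavelength-resolved T is modelled) and the
(1 − c·v_a) factor accounting for solvent displaced by the solute
(defaults v_a = 0.74 cm³/g for debris, 0.73 for protein). Uncertainties
propagate in quadrature with the same coefficients; the empty-cell term
enters with net coefficient (1 − disp). Absolute calibration against a
water standard is represented as an external multiplicative factor and
not implemented. An optional constant-background subtraction (off by
default) handles residual flat incoherent scattering.

## Curve statistics

* **Match-point regression.** v_i = √(∫I dq) over a small-q band
  (default 0.0065–0.009 Å⁻¹) is proportional to |Δρ|, i.e. |a·f + b| in
  the D₂O percentage. Because the absolute-value model is non-smooth,
  joint gradient fits stall on the crease; the fit instead profiles the
  match point (for fixed −b/a the amplitude has a closed form) over a
  dense grid with bounded refinement. The standard error comes from the
  Jacobian of the two-parameter model at the solution. A warning is
  attached when the match point extrapolates far beyond the measured
  range.
* **Porod slopes** are OLS on log₁₀I vs log₁₀q; the mass-fractal
  dimension D = −slope is reported only for slopes in (−3, −1).
* **Peak detection** fits a robust power-law + constant baseline
  (soft-L1 on log residuals), then finds maxima of the lightly smoothed
  (Savitzky–Golay, window 7) excess. A peak must clear
  max(min_prominence, 4×noise)·baseline where the point-noise scale
  comes from the second difference of the curve (trend-free), must span
  ≥2.5 samples, and must have FWHM < q/2 — a correlation peak needs at
  least ~2 repeat distances of coherence; broader bumps are
  baseline-model mismatch (e.g. a Guinier knee), not interference peaks.
  Positions are refined by 3-point parabolic interpolation.
* **Harmonic assignment** searches fundamentals q_i/n (orders 1–4),
  scores candidates by peaks assigned within a relative tolerance, then
  refines q₀ by least squares over the assigned orders; periodicity is
  2π/q₀. Bragg spacing is d = 2π/q.

## Debye engine

Per-atom effective lengths are b_eff = b_el + n_exch·[(1−x)b_H + x·b_D] −
ρ_solv·(V_el + n_exch·V_H) with x = (D₂O fraction)×(exchange
efficiency) and displaced volumes per heavy-atom group
(Fraser–MacRae–Suzuki style: H 5.15, C 16.44, N 2.49, O 9.13, S 19.86,
P 5.73 Å³) — a fixed table rather than an adjustable envelope, adequate
for the qualitative model comparisons this pipeline performs. Models up
to 2000 atoms use the exact double sum; larger models use a b-weighted
pair-distance histogram whose bins store the weighted *mean* distance
(not the geometric centre), keeping the accelerated sum within ~0.1% of
the exact sum for q < π/(2·bin); the default 0.5 Å bin caps the usable
range near 3 Å⁻¹, beyond the 2 Å⁻¹ of interest. I(0) equals (Σb_eff)²
exactly.

The hydration shell is the solvent layer within `shell_thickness`
(default 3 Å — the shell contrast of +10% over solvent SLD is the
conventional default, its thickness is this package's assumption) of the
model's van der Waals surface, discretised into cubic voxels (1.5 Å
mesh) that become pseudo-atoms of length (factor−1)·ρ_solv·V_cell. The
voxel construction reproduces the analytic shell volume of a sphere to
~2% and keeps one scattering engine for atoms, shell voxels and beads.
Degenerate (collinear) geometries skip the shell with a warning. The
default solvent everywhere is 96.7% D₂O, the match point of the
deuterated crowder.

PDB models are read via Biopython (first model of multi-model NMR
entries; the figures of record show single conformers). Files without
explicit hydrogens get labile-H counts from a per-residue lookup
(backbone amide N–H except proline, plus side-chain OH/NH/SH of Ser,
Thr, Tyr, Lys, Arg, Asn, Gln, His, Trp, Cys); explicit hydrogens are
instead classified by bonding (H within 1.25 Å of N/O/S is labile and
folded into that heavy atom, others remain atoms), so both
hydrogen-bearing and stripped structures are usable.

## Assemblies

Elongation stacks rigid copies along the fibril axis (given, or the
principal inertia axis) at a fixed rise with an optional per-repeat
twist; the twist defaults to 0° because the pseudo-helical twist of the
modelled fibrils is not quantified anywhere authoritative — it is left a
free parameter. Lateral pairs translate a copy centre-to-centre along a
direction orthogonal to the axis. The idealized cross-β unit is two
parallel point-scatterer sheets (4.7 Å strand stacking, 10 Å sheet
separation) so the engine can be exercised without any PDB download. No
sterics or energetics are modelled.

## Bead modeling

The search volume is a sphere filled with an HCP lattice of beads
(spacing = bead diameter; densest equal-sphere packing). Annealing flips
single beads, with energy χ²(optimal scale) + w·f_loose, where f_loose
is the fraction of occupied beads with fewer than three occupied
neighbours — a neighbour-count compactness penalty standing in for the
unpublished interconnectivity term of classic dummy-atom annealers, with
the coefficient exposed. The forward model is an incrementally updated
pair-distance histogram over lattice sites with fine bins
(search_diameter/400), keeping it within ~0.1% of the exact Debye sum so
the annealer's χ² is trustworthy. The schedule is geometric (T₀ adaptive
at half the initial energy, cooling 0.9, one sweep per temperature);
after annealing the largest connected component is kept and polished at
T = 0, and the reported χ² is recomputed with the exact sum. NSD between
models is the symmetric nearest-neighbour metric normalized by each
set's mean NN distance, minimised over centroid superposition and the 48
axis-aligned orthogonal transforms — a full rotational search is out of
scope and is the metric's documented limitation. Ensembles are filtered
at mean pairwise NSD ≤ 1.7, the conventional acceptance bound.

## Synthetic data

The generators emulate the statistical structure of the measurement
campaign; each stamps its ground truth into curve metadata so every
analysis stage has a closed-loop recovery test.

* **Debris curves**: Fisher–Burford mass-fractal profile
  scale/(1 + (2/3D)q²R_g²)^{D/2} plus a flat incoherent level, with
  multiplicative Gaussian noise; featureless by construction. Defaults
  D = 2.4, R_g = 300 Å.
* **Contrast series**: the debris profile scaled by the squared contrast
  (f − f*)² across 0–100% D₂O (default f* = 96.7), with an incoherent
  floor decreasing linearly in f, mimicking the H-content trend of real
  solvent series; the floor is small in the integration band so the
  noiseless match-point round trip closes to <0.01% D₂O.
* **DLA clusters**: off-lattice 3D diffusion-limited aggregation,
  sticking probability 1, walk-on-spheres far-field jumps and 0.3-radius
  near-field steps (coarser steps measurably densify the aggregate).
  Growth scaling N ∝ R_g^D gives D = 2.45 ± 0.05.
* **Time courses**: power-law background with slope drifting −2.4 → −2.5
  across the series, Gaussian interference peaks at q₀ = 2π/251 Å⁻¹ and
  2q₀ (second order at half amplitude, 0.004 Å⁻¹ FWHM — a finite-domain
  width chosen to resemble the measured curves) growing with saturating
  kinetics after a 5 h onset, plus a broad inter-sheet hump at 0.4 Å⁻¹.

What the generators deliberately do not model: instrument resolution
smearing, time-of-flight wavelength frames, detector geometry, count-rate
statistics, and inter-particle structure factors of the crowded debris.
Passing the closed-loop tests therefore demonstrates the correctness of
the analysis chain under the stated statistical model, not performance on
raw instrument frames.

## Problem sizes and numerical checks

The standard verification experiments use 3000-monomer DLA clusters
(three seeds) with the Porod fit over the Guinier-to-monomer fractal
window 1/R_g < q < 0.5/r_monomer — below that window the Guinier knee
flattens the curve, above it the monomer self and bonded-pair terms
floor it; a 4000-point 1000 Å × 20 Å rod fitted over the thin-rod regime
2π/L < q < 1/R (an independent analytic finite-cylinder oracle gives
−1.05 for this window; the cross-section form factor steepens any window
pushed towards qR ≈ 1); a 5000-point Monte-Carlo ball against the
analytic sphere form factor with the known N-point sampling floor
removed; and bead recovery of a 150 Å sphere at 25.5 Å bead radius in a
400 Å search volume. Sizes were chosen so the full suite and the
acceptance script each complete in minutes on one CPU while keeping
every estimate's sampling error well inside its test tolerance.
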