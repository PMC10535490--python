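"""Neutron scattering-length-density (SLD) arithmetic.

Covers H2O/D2O solvent SLDs, SLDs of deuterated biomolecular composites,
contrast-match points (the solvent D2O fraction at which a component's
excess SLD vanishes — possibly above 100% for heavily deuterated
material), deuteration design for mixed growth media, and the dilution
bookkeeping of sample mixing.

Units: SLD in A^-2; D2O content as volume fraction (0-1) in `SolventSpec`
and as percent in match-point interfaces, mirroring how practitioners
quote them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from scipy.optimize import brentq

from .constants import (CLASS_FORMULAS, COHERENT_B_FM, ECOLI_MASS_PERCENT,
                        FM_PER_A3_TO_SLD, WATER_VOLUME_A3)

COMPONENT_CLASSES = tuple(CLASS_FORMULAS)

_B = COHERENT_B_FM

#: SLD of pure H2O / D2O from Sears lengths and 30.0 A^3 per molecule
SLD_H2O = (2 * _B["H"] + _B["O"]) / WATER_VOLUME_A3 * FM_PER_A3_TO_SLD
SLD_D2O = (2 * _B["D"] + _B["O"]) / WATER_VOLUME_A3 * FM_PER_A3_TO_SLD


@dataclass
class SolventSpec:
    """An H2O/D2O mixture; dilute buffer solutes are metadata only."""

    d2o_volume_fraction: float = 0.0
    solutes: dict = field(default_factory=dict)  # name -> molarity, ignored in SLD

    def __post_init__(self):
        if not 0.0 <= self.d2o_volume_fraction <= 1.0:
            raise ValueError("d2o_volume_fraction must be in [0, 1]")


@dataclass
class ComponentComposition:
    """Mass-fraction recipe of a biomolecular component (e.g. cell debris).

    ``deuteration_fraction`` is the fraction of *non-labile* hydrogens
    replaced by deuterium (set by the growth medium); labile hydrogens
    follow the solvent at ``exchange_efficiency``.
    """

    mass_fractions: dict
    deuteration_fraction: float = 0.0
    partial_specific_volume: float = 0.74  # cm^3/g
    exchange_efficiency: float = 0.9

    def __post_init__(self):
        unknown = set(self.mass_fractions) - set(COMPONENT_CLASSES)
        if unknown:
            raise ValueError(f"unknown component class(es): {sorted(unknown)}")
        if any(v < 0 for v in self.mass_fractions.values()):
            raise ValueError("mass fractions must be >= 0")
        if sum(self.mass_fractions.values()) <= 0:
            raise ValueError("mass fractions must not all be zero")
        if not 0.0 <= self.deuteration_fraction <= 1.0:
            raise ValueError("deuteration_fraction must be in [0, 1]")
        if not 0.4 < self.partial_specific_volume < 1.2:
            raise ValueError("partial_specific_volume outside (0.4, 1.2) cm^3/g")

    @classmethod
    def ecoli_debris(cls, deuteration_fraction: float = 0.0,
                     **kwargs) -> "ComponentComposition":
        """The default E. coli dry-matter composition (protein 15, nucleic
        acid 7, lipid 2, carbohydrate 3, other organic 1, inorganic 1,
        % w/w of whole cell), renormalised over dry matter."""
        total = sum(ECOLI_MASS_PERCENT.values())
        fr = {k: v / total for k, v in ECOLI_MASS_PERCENT.items()}
        return cls(fr, deuteration_fraction=deuteration_fraction, **kwargs)


@dataclass
class MatchPointFit:
    """Result of a contrast-match-point regression (see curve analysis)."""

    match_point: float        # % D2O
    std_error: float          # % D2O
    slope: float
    intercept: float
    q_window: tuple
    warning: str | None = None

    def __post_init__(self):
        if self.std_error < 0:
            raise ValueError("std_error must be >= 0")


def solvent_sld(spec: SolventSpec | float) -> float:
    """SLD of an H2O/D2O mixture, A^-2 (linear in D2O volume fraction)."""
    f = spec.d2o_volume_fraction if isinstance(spec, SolventSpec) else float(spec)
    return (1.0 - f) * SLD_H2O + f * SLD_D2O


def _class_sld(name: str, deuteration: float, x_solvent_d: float) -> float:
    """SLD of one reference monomer class, A^-2.

    ``x_solvent_d`` is the effective D occupancy of labile sites
    (solvent D2O fraction x exchange efficiency).
    """
    f = CLASS_FORMULAS[name]
    b = sum(n * _B[el] for el, n in f["heavy"].items())
    b += f["h_nonlabile"] * ((1 - deuteration) * _B["H"] + deuteration * _B["D"])
    b += f["h_labile"] * ((1 - x_solvent_d) * _B["H"] + x_solvent_d * _B["D"])
    return b / f["volume_a3"] * FM_PER_A3_TO_SLD


def component_sld(comp: ComponentComposition,
                  solvent: SolventSpec | float) -> float:
    """Mass-fraction-weighted SLD of a composite particle in a solvent.

    Each class contributes with volume weight (mass fraction x specific
    volume of the class monomer); labile H exchange with solvent D at
    ``comp.exchange_efficiency``.
    """
    f_d2o = (solvent.d2o_volume_fraction if isinstance(solvent, SolventSpec)
             else float(solvent))
    x = f_d2o * comp.exchange_efficiency
    num = den = 0.0
    for name, w in comp.mass_fractions.items():
        if w == 0:
            continue
        frm = CLASS_FORMULAS[name]
        mass = _class_mass(frm)
        vol = w / mass * frm["volume_a3"]  # per-class volume weight
        num += vol * _class_sld(name, comp.deuteration_fraction, x)
        den += vol
    return num / den


def _class_mass(frm: dict) -> float:
    masses = {"H": 1.008, "D": 2.014, "C": 12.011, "N": 14.007, "O": 15.999,
              "S": 32.06, "P": 30.974}
    m = sum(n * masses[el] for el, n in frm["heavy"].items())
    m += (frm["h_nonlabile"] + frm["h_labile"]) * masses["H"]
    return m


def match_point(comp: ComponentComposition) -> float:
    """Contrast-match point of a component, in % D2O.

    Solves component_sld(comp, f) = solvent_sld(f) for the D2O fraction f.
    Values above 100% are legal extrapolated crossings (heavily deuterated
    material); the search spans -50% to 200% D2O.
    """

    def g(f):
        return component_sld(comp, f) - solvent_sld(f)

    lo, hi = -0.5, 2.0
    if g(lo) * g(hi) > 0:
        raise ValueError(
            "component SLD does not cross the solvent line in [-50, 200]% D2O")
    return 100.0 * brentq(g, lo, hi, xtol=1e-12)


def match_point_of_sld(sld_const: float) -> float:
    """Match point (% D2O) of a particle with composition-independent SLD."""
    return 100.0 * (sld_const - SLD_H2O) / (SLD_D2O - SLD_H2O)


def mixture_match_point(mp_a: float, mp_b: float, vol_ratio_a: float) -> float:
    """Match point of a volume mixture of two materials, % D2O.

    The match point is linear in SLD, and SLD is linear in volume
    fraction, so the mixture's match point is the volume-weighted mean.
    Used to design growth-medium mixes (e.g. 87/13 deuterated/protonated
    medium moving debris from 110% to ~100% D2O equivalent).
    """
    if not 0.0 <= vol_ratio_a <= 1.0:
        raise ValueError("vol_ratio_a must be in [0, 1]")
    return vol_ratio_a * mp_a + (1.0 - vol_ratio_a) * mp_b


def dilution(c_stock: float, vol_parts_stock: float,
             vol_parts_other: float) -> float:
    """Final concentration after volumetric mixing of a stock with diluent.

    E.g. a 15% w/v debris stock mixed 7:1 with protein solution gives
    15 x 7/8 = 13.125 ~ 13.1% w/v.
    """
    if vol_parts_stock <= 0 or vol_parts_other < 0:
        raise ValueError("volume parts must be positive")
    return c_stock * vol_parts_stock / (vol_parts_stock + vol_parts_other)
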