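"""Domain containers and file I/O for SAS curves and structural models.

Scattering curves travel as 3-column ASCII (q, I, sigma) with an optional
``# key: value`` header; atomic models are read from PDB files via
Biopython.  All lengths are in Angstroms, q in inverse Angstroms.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .constants import SIDECHAIN_LABILE_H, STANDARD_RESIDUES

logger = logging.getLogger(__name__)

KNOWN_ELEMENTS = {"H", "D", "C", "N", "O", "S", "P"}


@dataclass
class ScatteringCurve:
    """A 1-D scattering curve I(q) with uncertainties and acquisition metadata.

    Parameters
    ----------
    q : array
        Momentum transfer grid in A^-1, strictly increasing and positive.
    intensity : array
        Scattered intensity per q point (arbitrary units unless calibrated).
    sigma : array, optional
        1-sigma uncertainty per point; defaults to sqrt-counting
        ``sqrt(|I|)``.
    label : str
        Free-text identifier.
    meta : dict
        Acquisition metadata.  Recognised keys include ``beam_monitor``
        (incident counts), ``transmission`` (0-1), ``concentration``
        (g/cm^3), ``temperature`` (deg C) and ``exposure_h``.
    """

    q: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray | None = None
    label: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.sigma is None:
            self.sigma = np.sqrt(np.abs(self.intensity))
        self.sigma = np.asarray(self.sigma, dtype=float)
        if not (len(self.q) == len(self.intensity) == len(self.sigma)):
            raise ValueError("q, intensity and sigma must have equal length")
        if np.any(self.q <= 0):
            raise ValueError("q must be strictly positive")
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be strictly increasing")
        if np.any(self.sigma < 0):
            raise ValueError("sigma must be non-negative")
        t = self.meta.get("transmission")
        if t is not None and not (0 < float(t) <= 1):
            raise ValueError(f"transmission must be in (0, 1], got {t}")

    def __len__(self) -> int:
        return len(self.q)

    def copy(self) -> "ScatteringCurve":
        return ScatteringCurve(
            self.q.copy(), self.intensity.copy(), self.sigma.copy(),
            self.label, dict(self.meta),
        )


@dataclass
class AtomicModel:
    """Element-typed point model with per-heavy-atom exchangeable-H counts.

    ``elements`` may contain the placeholder ``"X"`` for pseudo-atoms whose
    scattering length is given explicitly in ``b_explicit`` (fm); regular
    atoms carry ``nan`` there and obtain their length from the element
    tables.  ``axis``, when set, is a unit vector marking the fibril axis.
    """

    elements: np.ndarray          # dtype object / str
    coords: np.ndarray            # (N, 3) in A
    n_exchangeable_h: np.ndarray  # int per atom
    occupancy: np.ndarray | None = None
    b_explicit: np.ndarray | None = None  # fm, nan = use element table
    axis: np.ndarray | None = None
    label: str = ""

    def __post_init__(self):
        self.elements = np.asarray(self.elements, dtype=object)
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        self.n_exchangeable_h = np.asarray(self.n_exchangeable_h, dtype=float)
        n = len(self.elements)
        if self.coords.shape[0] != n or len(self.n_exchangeable_h) != n:
            raise ValueError("inconsistent atom array lengths")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if np.any(self.n_exchangeable_h < 0):
            raise ValueError("exchangeable-H counts must be >= 0")
        bad = [e for e in set(self.elements) if e not in KNOWN_ELEMENTS | {"X"}]
        if bad:
            raise ValueError(f"unknown element(s): {sorted(bad)}")
        if self.occupancy is None:
            self.occupancy = np.ones(n)
        self.occupancy = np.asarray(self.occupancy, dtype=float)
        if self.b_explicit is None:
            self.b_explicit = np.full(n, np.nan)
        self.b_explicit = np.asarray(self.b_explicit, dtype=float)
        if self.axis is not None:
            self.axis = np.asarray(self.axis, dtype=float)
            if abs(np.linalg.norm(self.axis) - 1.0) > 1e-9:
                raise ValueError("axis must be a unit vector")

    def __len__(self) -> int:
        return len(self.elements)

    def translated(self, shift) -> "AtomicModel":
        m = self.copy()
        m.coords = m.coords + np.asarray(shift, dtype=float)
        return m

    def copy(self) -> "AtomicModel":
        return AtomicModel(
            self.elements.copy(), self.coords.copy(),
            self.n_exchangeable_h.copy(), self.occupancy.copy(),
            self.b_explicit.copy(),
            None if self.axis is None else self.axis.copy(), self.label,
        )


def concat_models(models: Iterable[AtomicModel]) -> AtomicModel:
    """Union of several atomic models; axis/label taken from the first."""
    models = list(models)
    first = models[0]
    return AtomicModel(
        np.concatenate([m.elements for m in models]),
        np.vstack([m.coords for m in models]),
        np.concatenate([m.n_exchangeable_h for m in models]),
        np.concatenate([m.occupancy for m in models]),
        np.concatenate([m.b_explicit for m in models]),
        None if first.axis is None else first.axis.copy(),
        first.label,
    )


@dataclass
class BeadModel:
    """Fixed-radius dummy-atom model on a lattice (ab initio shape)."""

    centers: np.ndarray        # (N, 3) all lattice positions, A
    bead_radius: float
    occupied: np.ndarray       # bool mask over centers

    def __post_init__(self):
        self.centers = np.asarray(self.centers, dtype=float).reshape(-1, 3)
        self.occupied = np.asarray(self.occupied, dtype=bool)
        if self.bead_radius <= 0:
            raise ValueError("bead_radius must be positive")
        if len(self.occupied) != len(self.centers):
            raise ValueError("occupied mask length mismatch")
        if self.occupied.sum() < 1:
            raise ValueError("at least one bead must be occupied")

    @property
    def occupied_centers(self) -> np.ndarray:
        return self.centers[self.occupied]

    def to_atomic_model(self) -> AtomicModel:
        pts = self.occupied_centers
        n = len(pts)
        return AtomicModel(
            np.array(["X"] * n, dtype=object), pts, np.zeros(n),
            b_explicit=np.ones(n),
        )


# ---------------------------------------------------------------------------
# curve I/O
# ---------------------------------------------------------------------------

_FLOAT_META = {
    "beam_monitor", "transmission", "concentration", "temperature",
    "exposure_h", "d2o_percent", "scale",
}


def read_curve(path, dialect: str = "header+3col") -> ScatteringCurve:
    """Read a 3-column ASCII curve (q, I, sigma).

    Lines starting with ``#`` before the data may carry ``key: value``
    metadata.  Rows with q <= 0 are dropped (with a logged count); a row
    that fails to parse as numbers raises with its line number.
    """
    path = Path(path)
    meta: dict = {}
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            s = line.strip()
            if not s:
                continue
            if s.startswith("#"):
                body = s.lstrip("#").strip()
                if ":" in body:
                    key, _, val = body.partition(":")
                    key, val = key.strip(), val.strip()
                    try:
                        meta[key] = float(val)
                    except ValueError:
                        meta[key] = val
                continue
            parts = s.split()
            if len(parts) < 3:
                raise ValueError(
                    f"{path}:{lineno}: expected >= 3 columns, got {len(parts)}")
            try:
                rows.append([float(x) for x in parts[:3]])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed numeric row") from exc
    if not rows:
        raise ValueError(f"{path}: no data rows")
    arr = np.asarray(rows)
    keep = arr[:, 0] > 0
    ndrop = int((~keep).sum())
    if ndrop:
        logger.info("%s: dropped %d rows with q <= 0", path, ndrop)
    arr = arr[keep]
    return ScatteringCurve(arr[:, 0], arr[:, 1], arr[:, 2],
                           label=str(meta.get("label", path.stem)), meta=meta)


def write_curve(curve: ScatteringCurve, path) -> None:
    """Write a curve as '# key: value' header plus q/I/sigma columns.

    Numbers are emitted with 10 significant digits so a read/write
    round-trip is lossless to better than 1e-9 relative.
    """
    path = Path(path)
    with open(path, "w") as fh:
        if curve.label:
            fh.write(f"# label: {curve.label}\n")
        for key in sorted(curve.meta):
            if key == "label":
                continue
            val = curve.meta[key]
            fh.write(f"# {key}: {val}\n" if isinstance(val, str)
                     else f"# {key}: {val:.10g}\n")
        fh.write("# columns: q_invA intensity sigma\n")
        for q, i, s in zip(curve.q, curve.intensity, curve.sigma):
            fh.write(f"{q:.10g} {i:.10g} {s:.10g}\n")


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

_LABILE_PARTNERS = {"N", "O", "S"}


def read_pdb(path) -> AtomicModel:
    """Read the first model of a PDB file into an :class:`AtomicModel`.

    Exchangeable-hydrogen bookkeeping: when the file carries no explicit
    hydrogens (the common case for fibril entries), labile H are assigned
    to heavy atoms from a per-residue lookup (backbone amide N-H plus the
    side-chain OH/NH/SH hydrogens of Ser, Thr, Tyr, Lys, Arg, Asn, Gln,
    His, Trp, Cys).  Explicit hydrogens, when present, are classified by a
    bonding heuristic instead: an H within 1.25 A of an N/O/S is labile
    and folded into that heavy atom's count, non-labile H are kept as
    atoms in their own right.
    """
    from Bio.PDB import PDBParser

    path = Path(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = PDBParser(QUIET=True).get_structure(path.stem, str(path))
    try:
        model = next(structure.get_models())
    except StopIteration:
        raise ValueError(f"{path}: no models found")

    elements, coords, occ = [], [], []
    res_keys, atom_names = [], []
    for chain in model:
        for residue in chain:
            for atom in residue:
                el = (atom.element or "").strip().upper()
                if not el:
                    el = atom.get_name().strip()[0].upper()
                elements.append(el)
                coords.append(atom.coord)
                occ.append(atom.get_occupancy() or 1.0)
                res_keys.append((chain.id, residue.id, residue.get_resname()))
                atom_names.append(atom.get_name().strip().upper())
    if not elements:
        raise ValueError(f"{path}: no ATOM/HETATM records in first model")

    elements = np.asarray(elements, dtype=object)
    coords = np.asarray(coords, dtype=float)
    occ = np.asarray(occ, dtype=float)
    n_exch = np.zeros(len(elements))

    has_h = np.isin(elements, ("H", "D"))
    if has_h.any():
        # explicit hydrogens: bonding heuristic
        keep = np.ones(len(elements), dtype=bool)
        heavy_idx = np.flatnonzero(~has_h)
        heavy_xyz = coords[heavy_idx]
        for i in np.flatnonzero(has_h):
            d = np.linalg.norm(heavy_xyz - coords[i], axis=1)
            j = int(np.argmin(d))
            if d[j] < 1.25 and elements[heavy_idx[j]] in _LABILE_PARTNERS:
                n_exch[heavy_idx[j]] += 1
                keep[i] = False
        elements, coords, occ = elements[keep], coords[keep], occ[keep]
        n_exch = n_exch[keep]
    else:
        # lookup table per residue
        unknown = set()
        for i, (key, name, el) in enumerate(zip(res_keys, atom_names, elements)):
            resname = key[2].upper()
            if resname in ("HOH", "DOD", "WAT"):
                n_exch[i] = 2.0 if name.startswith("O") else 0.0
                continue
            if resname not in STANDARD_RESIDUES:
                unknown.add(resname)
                continue
            if name == "N" and el == "N" and resname != "PRO":
                n_exch[i] = 1.0
            side = SIDECHAIN_LABILE_H.get(resname, {})
            if name in side:
                n_exch[i] = n_exch[i] + side[name]
        if unknown:
            warnings.warn(
                f"{path}: unknown residue(s) {sorted(unknown)}; "
                "exchangeable H set to 0 for their atoms")

    bad = {e for e in set(elements) if e not in KNOWN_ELEMENTS}
    if bad:
        raise ValueError(f"{path}: unsupported element(s) {sorted(bad)}")
    return AtomicModel(elements, coords, n_exch, occupancy=occ,
                       label=path.stem)


def write_pdb(model: AtomicModel, path, record: str = "ATOM") -> None:
    """Write a point model as a minimal single-model PDB file.

    Pseudo-atoms (element ``"X"``) are written as carbon dummy atoms with
    record type HETATM, the convention for bead models.
    """
    path = Path(path)
    with open(path, "w") as fh:
        for i, (el, xyz) in enumerate(zip(model.elements, model.coords), 1):
            rec = "HETATM" if el == "X" else record
            name = " CA " if el == "X" else f" {el:<3s}"[:4]
            sym = "C" if el == "X" else el
            fh.write(
                f"{rec:<6s}{i % 100000:5d} {name}{'':1s}DUM A{(i % 10000):4d}"
                f"    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                f"{1.0:6.2f}{0.0:6.2f}          {sym:>2s}\n")
        fh.write("END\n")


def write_bead_pdb(model: BeadModel, path) -> None:
    write_pdb(model.to_atomic_model(), path)
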