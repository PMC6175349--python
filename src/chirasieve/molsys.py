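"""Core molecular data model.

A :class:`Structure` is the universal container of the toolkit: element
symbols plus Cartesian coordinates in Å, with optional per-atom partial
charges (elementary charge units) and nonbonded atom-type labels.  All
geometry in the package is finite and non-periodic; atom order is
significant and preserved by every operation.

Besides XYZ I/O the module provides the rigid-body primitives that the
rest of the toolkit is built on: proper rigid transforms, mirror
reflection (which turns one enantiomer into the other), optimal
superposition (Kabsch), the complex-size metric ``max_extent`` -- the
distance between the two most distant atoms of a structure, used as the
descriptor for propagation-barrier height -- and the center of mass.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.spatial.transform import Rotation


class MolsysError(ValueError):
    """Base error for molecular-system operations."""


class XYZParseError(MolsysError):
    """Malformed XYZ input; message names the offending line."""


@dataclass(frozen=True)
class ElementData:
    vdw_radius: float       # Å
    covalent_radius: float  # Å
    mass: float             # amu


#: Supported elements.  vdW radii: Bondi; covalent radii: Cordero; masses: IUPAC.
ELEMENTS: dict[str, ElementData] = {
    "H": ElementData(1.20, 0.31, 1.008),
    "C": ElementData(1.70, 0.76, 12.011),
    "N": ElementData(1.55, 0.71, 14.007),
    "O": ElementData(1.52, 0.66, 15.999),
    "F": ElementData(1.47, 0.57, 18.998),
    "S": ElementData(1.80, 1.05, 32.06),
    "Cl": ElementData(1.75, 1.02, 35.45),
    "Br": ElementData(1.85, 1.20, 79.904),
}


def normalize_element(symbol: str) -> str:
    """Case-normalize an element symbol and check it is supported."""
    sym = symbol.strip().capitalize()
    if sym not in ELEMENTS:
        raise MolsysError(f"unknown element symbol: {symbol!r}")
    return sym


@dataclass
class Structure:
    """Elements + Cartesian coordinates (Å) with optional charges/types.

    Invariants (checked on construction): N >= 1, all coordinates finite,
    every element supported, optional arrays have length N.
    """

    elements: list[str]
    coords: np.ndarray
    charges: np.ndarray | None = None
    atom_types: list[str] | None = None
    metadata: str = ""

    def __post_init__(self) -> None:
        self.elements = [normalize_element(e) for e in self.elements]
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        n = len(self.elements)
        if n < 1:
            raise MolsysError("Structure needs at least one atom")
        if self.coords.shape != (n, 3):
            raise MolsysError(
                f"coords shape {self.coords.shape} does not match {n} elements"
            )
        if not np.all(np.isfinite(self.coords)):
            raise MolsysError("non-finite coordinate")
        if self.charges is not None:
            self.charges = np.asarray(self.charges, dtype=float).reshape(-1)
            if self.charges.shape != (n,):
                raise MolsysError("charges length does not match atom count")
        if self.atom_types is not None:
            if len(self.atom_types) != n:
                raise MolsysError("atom_types length does not match atom count")
            self.atom_types = list(self.atom_types)

    def __len__(self) -> int:
        return len(self.elements)

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def types_or_elements(self) -> list[str]:
        """Nonbonded type labels, falling back to element symbols."""
        return self.atom_types if self.atom_types is not None else list(self.elements)

    def copy(self) -> "Structure":
        return Structure(
            list(self.elements),
            self.coords.copy(),
            None if self.charges is None else self.charges.copy(),
            None if self.atom_types is None else list(self.atom_types),
            self.metadata,
        )

    def with_coords(self, coords: np.ndarray) -> "Structure":
        out = self.copy()
        out.coords = np.asarray(coords, dtype=float).reshape(-1, 3)
        if out.coords.shape != self.coords.shape:
            raise MolsysError("replacement coordinates have wrong shape")
        return out


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion x -> R @ x + t (rotation then translation)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if abs(np.linalg.det(R) - 1.0) > 1e-8:
            raise MolsysError("rotation matrix must be proper (det = +1)")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise MolsysError("rotation matrix must be orthogonal")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_rotvec(cls, rotvec, translation=(0.0, 0.0, 0.0)) -> "RigidTransform":
        return cls(Rotation.from_rotvec(np.asarray(rotvec, float)).as_matrix(),
                   np.asarray(translation, float))

    @classmethod
    def translation_by(cls, t) -> "RigidTransform":
        return cls(np.eye(3), np.asarray(t, float))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, float) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply ``other`` first, then ``self``."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)


# ---------------------------------------------------------------------------
# XYZ I/O
# ---------------------------------------------------------------------------

def read_xyz(path) -> Structure:
    """Read a standard XYZ file (count line, comment line, atom records)."""
    with open(path, "r") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise XYZParseError(f"{path}: empty file")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise XYZParseError(f"{path}: line 1: malformed atom-count line "
                            f"{lines[0]!r}") from None
    if n < 1:
        raise XYZParseError(f"{path}: line 1: atom count must be >= 1")
    comment = lines[1] if len(lines) > 1 else ""
    if len(lines) < 2 + n:
        raise XYZParseError(f"{path}: expected {n} atom records, "
                            f"found {max(0, len(lines) - 2)}")
    elements: list[str] = []
    coords = np.empty((n, 3))
    for i in range(n):
        lineno = 3 + i
        parts = lines[2 + i].split()
        if len(parts) < 4:
            raise XYZParseError(f"{path}: line {lineno}: expected "
                                f"'element x y z', got {lines[2 + i]!r}")
        try:
            sym = normalize_element(parts[0])
        except MolsysError as exc:
            raise XYZParseError(f"{path}: line {lineno}: {exc}") from None
        try:
            coords[i] = [float(p) for p in parts[1:4]]
        except ValueError:
            raise XYZParseError(f"{path}: line {lineno}: non-numeric "
                                f"coordinate in {lines[2 + i]!r}") from None
        elements.append(sym)
    return Structure(elements, coords, metadata=comment)


def write_xyz(structure: Structure, path, comment: str | None = None) -> None:
    """Write a standard XYZ file with 8-decimal coordinates."""
    if comment is None:
        comment = structure.metadata.replace("\n", " ")
    with open(path, "w") as fh:
        fh.write(f"{structure.n_atoms}\n{comment}\n")
        for el, (x, y, z) in zip(structure.elements, structure.coords):
            fh.write(f"{el:<2s} {x:18.8f} {y:18.8f} {z:18.8f}\n")


# ---------------------------------------------------------------------------
# Rigid-body geometry
# ---------------------------------------------------------------------------

def apply_transform(structure: Structure, transform: RigidTransform) -> Structure:
    """Apply a proper rigid motion; all interatomic distances are preserved."""
    return structure.with_coords(transform.apply(structure.coords))


def mirror(structure: Structure, point=(0.0, 0.0, 0.0),
           normal=(1.0, 0.0, 0.0)) -> Structure:
    """Reflect through the plane defined by ``point`` and ``normal``.

    For a chiral structure this produces the opposite enantiomer; applying
    the same mirror twice is the identity.
    """
    p = np.asarray(point, float).reshape(3)
    n = np.asarray(normal, float).reshape(3)
    nn = np.linalg.norm(n)
    if nn < 1e-12:
        raise MolsysError("mirror plane normal has zero length")
    n = n / nn
    x = structure.coords
    return structure.with_coords(x - 2.0 * np.outer((x - p) @ n, n))


def distance_matrix(structure: Structure) -> np.ndarray:
    return squareform(pdist(structure.coords))


def kabsch_align(A: Structure, B: Structure) -> tuple[float, RigidTransform]:
    """Optimal proper-rotation superposition of B onto A.

    Returns ``(rmsd, transform)`` where ``transform`` maps B's coordinates
    onto A with the minimum root-mean-square deviation over all proper
    rotations and translations (atom correspondence is by index).
    """
    if A.n_atoms != B.n_atoms:
        raise MolsysError("kabsch_align: atom-count mismatch")
    if A.elements != B.elements:
        raise MolsysError("kabsch_align: element sequences differ")
    ca = A.coords.mean(axis=0)
    cb = B.coords.mean(axis=0)
    import warnings
    with warnings.catch_warnings():
        # linear/planar point sets give a degenerate but still optimal fit
        warnings.simplefilter("ignore", UserWarning)
        rot, rssd = Rotation.align_vectors(A.coords - ca, B.coords - cb)
    rmsd = float(rssd) / math.sqrt(A.n_atoms)
    R = rot.as_matrix()
    t = ca - R @ cb
    return rmsd, RigidTransform(R, t)


def max_extent(structure: Structure) -> float:
    """Size of a complex: distance between its two most distant atoms."""
    if structure.n_atoms < 2:
        raise MolsysError("max_extent needs at least 2 atoms")
    return float(pdist(structure.coords).max())


def center_of_mass(structure: Structure) -> np.ndarray:
    masses = np.array([ELEMENTS[e].mass for e in structure.elements])
    return masses @ structure.coords / masses.sum()


#: RMSD below which a structure superposable on its mirror image counts as
#: achiral (separates numerical noise from genuine chirality on fixture scales).
ACHIRAL_RMSD_TOL = 1e-3


def is_achiral(structure: Structure, tol: float = ACHIRAL_RMSD_TOL) -> bool:
    """Chirality witness: can the mirror image be rigidly superposed?

    Atom correspondence is by index, so the witness detects configurational
    chirality of structures whose sites are distinct; topologically
    equivalent atoms are not permuted.
    """
    if structure.n_atoms < 4:
        return True  # <=3 atoms are always coplanar, hence achiral
    rmsd, _ = kabsch_align(structure, mirror(structure))
    return rmsd < tol


def merge(fragA: Structure, fragB: Structure, metadata: str = "") -> Structure:
    """Concatenate two fragments into one structure (A first, then B)."""
    charges = None
    if fragA.charges is not None or fragB.charges is not None:
        qa = fragA.charges if fragA.charges is not None else np.zeros(fragA.n_atoms)
        qb = fragB.charges if fragB.charges is not None else np.zeros(fragB.n_atoms)
        charges = np.concatenate([qa, qb])
    types = None
    if fragA.atom_types is not None or fragB.atom_types is not None:
        types = fragA.types_or_elements() + fragB.types_or_elements()
    return Structure(
        fragA.elements + fragB.elements,
        np.vstack([fragA.coords, fragB.coords]),
        charges,
        types,
        metadata,
    )
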