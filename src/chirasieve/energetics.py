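"""Internal nonbonded energy model and the energy-engine contract.

The toolkit's conclusions are engine-agnostic: every search and scan only
requires a callable that returns the interaction energy (kcal/mol) of two
rigid fragments.  The internal engine is a plain Lennard-Jones 12-6 plus
Coulomb model over per-type parameters,

    E = sum_ij 4 eps_ij [ (sig_ij/r_ij)^12 - (sig_ij/r_ij)^6 ]
               + k_e q_i q_j / r_ij,

with Lorentz-Berthelot or geometric combination rules, hard truncation at
a 12 Å cutoff by default (energies reported unshifted), and only
*inter*-fragment terms -- monomers are rigid, so intramolecular energy is
a constant and omitted.  The shipped per-element sigma/epsilon table is a
UFF-style stand-in, not a re-parameterized force field; partial charges
come from the structures themselves (fixture charges) or from the
parameter table.

Units: kcal/mol, Å, elementary charge; k_e = 332.0636 kcal·Å/(mol·e²).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Protocol, runtime_checkable

import numpy as np

from .molsys import Structure, mirror

__all__ = [
    "COULOMB_CONSTANT", "KB_KCAL_PER_MOL_K", "NonbondedParams",
    "EnergyEngine", "LJCoulombEngine", "OverlapError", "EngineError",
    "pair_energy", "interaction_energy", "combine",
    "mirror_invariance_check", "default_params", "load_params", "save_params",
    "ExternalXYZEngine",
]

COULOMB_CONSTANT = 332.0636          # kcal·Å/(mol·e²)
KB_KCAL_PER_MOL_K = 0.0019872041     # Boltzmann constant, kcal/(mol·K)

#: Per-element LJ well depths (kcal/mol) and zero-crossing distances (Å),
#: UFF-style (sigma = x_vdw / 2^(1/6)).  A stand-in parameter set for the
#: toolkit's synthetic fixtures.
_UFF_STYLE = {
    "H": (0.044, 2.886), "C": (0.105, 3.851), "N": (0.069, 3.660),
    "O": (0.060, 3.500), "F": (0.050, 3.364), "S": (0.274, 4.035),
    "Cl": (0.227, 3.947), "Br": (0.251, 4.389),
}
_SIXTH_ROOT_2 = 2.0 ** (1.0 / 6.0)


class EngineError(RuntimeError):
    """An energy engine failed to produce an energy."""


class OverlapError(EngineError):
    """Fragments overlap (interatomic distance below 0.1 Å)."""


COMBINATION_RULES = ("lorentz_berthelot", "geometric")


def combine(eps_i: float, sig_i: float, eps_j: float, sig_j: float,
            rule: str = "lorentz_berthelot") -> tuple[float, float]:
    """Cross-interaction parameters under the named combination rule."""
    if rule == "lorentz_berthelot":
        return float(np.sqrt(eps_i * eps_j)), 0.5 * (sig_i + sig_j)
    if rule == "geometric":
        return float(np.sqrt(eps_i * eps_j)), float(np.sqrt(sig_i * sig_j))
    raise ValueError(f"unknown combination rule: {rule!r}")


@dataclass
class NonbondedParams:
    """Per-type epsilon (kcal/mol) / sigma (Å) / charge (e) table.

    ``cutoff`` is in Å or ``None`` for no truncation.  Structures carrying
    their own per-atom charges override the table charge.
    """

    table: dict[str, tuple[float, float, float]]
    combination_rule: str = "lorentz_berthelot"
    cutoff: float | None = 12.0
    coulomb_constant: float = COULOMB_CONSTANT

    def __post_init__(self):
        if self.combination_rule not in COMBINATION_RULES:
            raise ValueError(
                f"unknown combination rule: {self.combination_rule!r}")
        if self.cutoff is not None and self.cutoff <= 6.0:
            raise ValueError("finite cutoff must exceed 6 Å")
        for t, (eps, sig, _q) in self.table.items():
            if eps < 0:
                raise ValueError(f"type {t}: epsilon must be >= 0")
            if sig <= 0:
                raise ValueError(f"type {t}: sigma must be > 0")

    def lookup(self, atom_type: str) -> tuple[float, float, float]:
        try:
            return self.table[atom_type]
        except KeyError:
            raise EngineError(f"no nonbonded parameters for type "
                              f"{atom_type!r}") from None

    def resolve(self, st: Structure):
        """(epsilon, sigma, charge) arrays for a structure; structure
        charges take precedence over table charges."""
        rows = [self.lookup(t) for t in st.types_or_elements()]
        eps = np.array([r[0] for r in rows])
        sig = np.array([r[1] for r in rows])
        q = (st.charges if st.charges is not None
             else np.array([r[2] for r in rows]))
        return eps, sig, q


def default_params(cutoff: float | None = 12.0,
                   rule: str = "lorentz_berthelot") -> NonbondedParams:
    """UFF-style per-element stand-in table with zero table charges."""
    table = {el: (eps, x / _SIXTH_ROOT_2, 0.0)
             for el, (eps, x) in _UFF_STYLE.items()}
    return NonbondedParams(table, combination_rule=rule, cutoff=cutoff)


def pair_energy(r: float, type_i: str, type_j: str,
                params: NonbondedParams) -> float:
    """LJ 12-6 + Coulomb energy of one atom pair at separation r (Å)."""
    if r <= 0:
        raise ValueError("pair separation must be positive")
    if params.cutoff is not None and r > params.cutoff:
        return 0.0
    ei, si, qi = params.lookup(type_i)
    ej, sj, qj = params.lookup(type_j)
    eps, sig = combine(ei, si, ej, sj, params.combination_rule)
    sr6 = (sig / r) ** 6
    return 4.0 * eps * (sr6 * sr6 - sr6) + params.coulomb_constant * qi * qj / r


def _pairwise(params: NonbondedParams, fragA: Structure, fragB: Structure):
    """Precomputed cross tables for a fragment pair."""
    epsA, sigA, qA = params.resolve(fragA)
    epsB, sigB, qB = params.resolve(fragB)
    if params.combination_rule == "lorentz_berthelot":
        sig = 0.5 * (sigA[:, None] + sigB[None, :])
    else:
        sig = np.sqrt(sigA[:, None] * sigB[None, :])
    eps = np.sqrt(epsA[:, None] * epsB[None, :])
    kqq = params.coulomb_constant * qA[:, None] * qB[None, :]
    return eps, sig, kqq


def _energy_from_tables(coordsA, coordsB, eps, sig, kqq, cutoff,
                        min_dist: float = 0.1) -> float:
    diff = coordsA[:, None, :] - coordsB[None, :, :]
    r = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    if r.min() < min_dist:
        raise OverlapError(f"atom pair at r = {r.min():.3f} Å")
    if cutoff is not None:
        mask = r <= cutoff
        if not mask.any():
            return 0.0
        r = np.where(mask, r, 1.0)
        sr6 = np.where(mask, (sig / r) ** 6, 0.0)
        coul = np.where(mask, kqq / r, 0.0)
    else:
        sr6 = (sig / r) ** 6
        coul = kqq / r
    return float(np.sum(4.0 * eps * (sr6 * sr6 - sr6)) + np.sum(coul))


def interaction_energy(fragA: Structure, fragB: Structure,
                       params: NonbondedParams) -> float:
    """Total inter-fragment nonbonded energy (kcal/mol).

    Sums pair energies over all cross pairs within the cutoff;
    intra-fragment terms are excluded (rigid-fragment assumption).
    Raises :class:`OverlapError` when any pair is closer than 0.1 Å.
    """
    eps, sig, kqq = _pairwise(params, fragA, fragB)
    return _energy_from_tables(fragA.coords, fragB.coords, eps, sig, kqq,
                               params.cutoff)


@runtime_checkable
class EnergyEngine(Protocol):
    """Contract every energy backend must satisfy.

    A physically meaningful engine is invariant under global rotations,
    translations and reflections of the whole system, and its interaction
    energy vanishes at infinite fragment separation.
    """

    has_gradients: bool

    def interaction_energy(self, fragA: Structure, fragB: Structure) -> float:
        ...


@dataclass
class LJCoulombEngine:
    """The internal engine: rigid-fragment LJ 12-6 + Coulomb."""

    params: NonbondedParams = field(default_factory=default_params)
    has_gradients: bool = False

    def interaction_energy(self, fragA: Structure, fragB: Structure) -> float:
        return interaction_energy(fragA, fragB, self.params)

    def bind(self, fragA: Structure, fragB: Structure
             ) -> Callable[[np.ndarray, np.ndarray], float]:
        """Fast path: precompute cross tables once, then evaluate on bare
        coordinate arrays.  Same result as :meth:`interaction_energy`."""
        eps, sig, kqq = _pairwise(self.params, fragA, fragB)
        cutoff = self.params.cutoff

        def energy(coordsA: np.ndarray, coordsB: np.ndarray) -> float:
            return _energy_from_tables(coordsA, coordsB, eps, sig, kqq, cutoff)

        return energy


def bind_engine(engine, fragA: Structure, fragB: Structure):
    """Coordinate-level evaluator for any engine (fast path if offered)."""
    if hasattr(engine, "bind"):
        return engine.bind(fragA, fragB)

    def energy(coordsA, coordsB):
        return engine.interaction_energy(fragA.with_coords(coordsA),
                                         fragB.with_coords(coordsB))

    return energy


def mirror_invariance_check(engine: EnergyEngine, fragA: Structure,
                            fragB: Structure, tol: float = 1e-8) -> bool:
    """True iff reflecting the whole system leaves the energy unchanged.

    This is the property that makes E(RR) = E(SS) for enantiomeric
    complexes testable with a given engine.
    """
    e0 = engine.interaction_energy(fragA, fragB)
    e1 = engine.interaction_energy(mirror(fragA), mirror(fragB))
    return abs(e0 - e1) < tol


# ---------------------------------------------------------------------------
# parameter-file I/O:  "type  epsilon  sigma  charge" with # comments
# ---------------------------------------------------------------------------

def load_params(path, combination_rule: str = "lorentz_berthelot",
                cutoff: float | None = 12.0) -> NonbondedParams:
    table: dict[str, tuple[float, float, float]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(f"{path}: line {lineno}: expected "
                                 f"'type epsilon sigma charge'")
            t, e, s, q = parts[0], *[float(x) for x in parts[1:]]
            table[t] = (e, s, q)
    if not table:
        raise ValueError(f"{path}: empty parameter table")
    return NonbondedParams(table, combination_rule, cutoff)


def save_params(params: NonbondedParams, path) -> None:
    with open(path, "w") as fh:
        fh.write("# type  epsilon(kcal/mol)  sigma(A)  charge(e)\n")
        for t, (e, s, q) in sorted(params.table.items()):
            fh.write(f"{t:<6s} {e:12.6f} {s:12.6f} {q:12.6f}\n")


@dataclass
class ExternalXYZEngine:
    """Adapter for an external XYZ-in / energy-out backend.

    ``command`` is run with the path of a two-fragment XYZ file appended;
    it must print a single energy in kcal/mol on stdout.  Any nonzero
    exit status or unparsable output raises :class:`EngineError` (the
    declared failure mode).  No external engine is required by the
    toolkit's own tests.
    """

    command: list[str]
    has_gradients: bool = False

    def interaction_energy(self, fragA: Structure, fragB: Structure) -> float:
        import subprocess
        import tempfile

        from .molsys import merge, write_xyz
        with tempfile.NamedTemporaryFile("w", suffix=".xyz",
                                         delete=False) as fh:
            path = fh.name
        write_xyz(merge(fragA, fragB,
                        metadata=f"fragments {fragA.n_atoms}+{fragB.n_atoms}"),
                  path)
        try:
            out = subprocess.run(self.command + [path], capture_output=True,
                                 text=True, check=True, timeout=600)
            return float(out.stdout.strip().split()[-1])
        except Exception as exc:
            raise EngineError(f"external engine failed: {exc}") from exc
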