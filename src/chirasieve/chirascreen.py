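"""Enantioselectivity screening via bimolecular complex sizes.

For a chiral target molecule paired with a chiral partner, the lowest
energy complex geometry generally differs between the same-chirality
(SS) and opposite-chirality (RS) pairings.  The screening descriptors
are

    delta_E = E_RS - E_SS        (kcal/mol)
    delta_R = R_RS - R_SS        (Å),

where E is the interaction energy of the best complex found and R is the
complex size -- the distance between its two most distant atoms.  A large
|delta_R| is the signature of a pair that a size-selective pore can
separate, because the complex size translates directly into a
propagation-barrier difference.

Monomers are kept rigid: the search runs over the six pose degrees of
freedom of the second monomer (rotation + translation) from a seeded,
quasi-uniform set of starting poses (a low-discrepancy sequence of
approach directions times a fixed orientation set), each relaxed by a
derivative-free coordinate pattern search.  Candidates are deduplicated by RMSD and the best few are
re-converged at tight tolerance.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .energetics import EngineError, bind_engine
from .molsys import (RigidTransform, Structure, is_achiral, kabsch_align,
                     max_extent, merge, mirror)

__all__ = ["SearchConfig", "ComplexCandidate", "PairingResult",
           "find_complex_minima", "best_complex", "pairing_deltas",
           "screen_matrix"]


@dataclass(frozen=True)
class SearchConfig:
    """Settings of the rigid 6-DOF complex search."""

    n_starts: int = 64
    seed: int = 7
    dedup_rmsd: float = 0.25     # Å; candidates closer than this merge
    refine_top: int = 10         # how many best candidates get tight reopt
    coarse_tol: float = 2e-2     # pattern-search step tolerance, stage 1
    fine_tol: float = 1e-4       # pattern-search step tolerance, stage 2
    max_poll_rounds: int = 4000


@dataclass
class ComplexCandidate:
    """One locally optimal rigid bimolecular complex."""

    structure: Structure         # monomer A atoms first, then monomer B
    energy: float                # kcal/mol at the local minimum
    size_R: float                # Å, max_extent of the complex
    start_id: int                # provenance: index of the initial pose
    n_monomer_A: int = 0

    @property
    def monomer_slices(self):
        return slice(0, self.n_monomer_A), slice(self.n_monomer_A, None)


@dataclass
class PairingResult:
    """The delta_E / delta_R screening record of one combination."""

    combo_label: str
    E_RS: float
    E_SS: float
    R_RS: float
    R_SS: float
    flag: str = ""

    @property
    def delta_E(self) -> float:
        return self.E_RS - self.E_SS

    @property
    def delta_R(self) -> float:
        return self.R_RS - self.R_SS


# ---------------------------------------------------------------------------
# start-pose generation
# ---------------------------------------------------------------------------

def _halton(index: int, base: int) -> float:
    f, r = 1.0, 0.0
    i = index
    while i > 0:
        f /= base
        r += f * (i % base)
        i //= base
    return r


def _sphere_direction(k: int) -> np.ndarray:
    """k-th direction of a low-discrepancy sequence on the unit sphere.

    Prefix-stable: the first n directions are the same for every n, so
    enlarging ``n_starts`` only *adds* starting poses (which makes the
    best energy found monotonically non-increasing in ``n_starts``).
    """
    u, v = _halton(k + 1, 2), _halton(k + 1, 3)
    z = 1.0 - 2.0 * u
    r = math.sqrt(max(0.0, 1.0 - z * z))
    phi = 2.0 * math.pi * v
    return np.array([r * math.cos(phi), r * math.sin(phi), z])


#: Fixed orientation set cycled over the approach directions.
_ORIENTATIONS = [
    np.zeros(3),
    np.array([math.pi, 0, 0]), np.array([0, math.pi, 0]),
    np.array([0, 0, math.pi]),
    np.array([math.pi / 2, 0, 0]), np.array([0, math.pi / 2, 0]),
    np.array([0, 0, math.pi / 2]),
    np.array([math.pi / 2, math.pi / 2, 0]),
]


def _pose_coords(coordsB0: np.ndarray, comB: np.ndarray,
                 pose: np.ndarray) -> np.ndarray:
    """Apply a 6-DOF pose (rotvec, translation of the centroid)."""
    from scipy.spatial.transform import Rotation
    R = Rotation.from_rotvec(pose[:3]).as_matrix()
    return (coordsB0 - comB) @ R.T + comB + pose[3:]


def _pattern_search(f, x0: np.ndarray, steps: np.ndarray, tol: float,
                    max_rounds: int) -> tuple[np.ndarray, float]:
    """Derivative-free coordinate pattern search (poll ±step per axis,
    halve steps when no poll improves)."""
    x = x0.copy()
    fx = f(x)
    steps = steps.copy()
    for _ in range(max_rounds):
        improved = False
        for i in range(len(x)):
            for sgn in (1.0, -1.0):
                trial = x.copy()
                trial[i] += sgn * steps[i]
                ft = f(trial)
                if ft < fx - 1e-13:
                    x, fx = trial, ft
                    improved = True
                    break
        if not improved:
            steps *= 0.5
            if steps.max() < tol:
                break
    return x, fx


# ---------------------------------------------------------------------------
# complex search
# ---------------------------------------------------------------------------

def find_complex_minima(molA: Structure, molB: Structure, engine,
                        config: SearchConfig | None = None,
                        ) -> list[ComplexCandidate]:
    """Rigid 6-DOF local optimizations from seeded multi-starts.

    Monomer A stays fixed; monomer B's pose (rotation about its centroid
    + translation) is optimized from ``n_starts`` initial poses placed on
    a sphere of approach directions.  Returns deduplicated candidates
    sorted by ascending energy.
    """
    cfg = config or SearchConfig()
    if cfg.n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    rng = np.random.default_rng(cfg.seed)
    energy_fn = bind_engine(engine, molA, molB)
    coordsA = molA.coords
    comB = molB.coords.mean(axis=0)
    coordsB0 = molB.coords

    def objective(pose):
        try:
            return energy_fn(coordsA, _pose_coords(coordsB0, comB, pose))
        except EngineError:
            return 1.0e6

    comA = coordsA.mean(axis=0)
    # outer radius beyond any contact
    try:
        extA = max_extent(molA) if molA.n_atoms > 1 else 0.0
        extB = max_extent(molB) if molB.n_atoms > 1 else 0.0
    except Exception:
        extA = extB = 0.0
    r_far = 0.5 * (extA + extB) + 8.0

    raw: list[tuple[np.ndarray, float, int]] = []
    n_failed = 0
    for k in range(cfg.n_starts):
        d = _sphere_direction(k // len(_ORIENTATIONS))
        rv = _ORIENTATIONS[k % len(_ORIENTATIONS)] + rng.normal(0.0, 0.05, 3)
        # radial pre-scan along the approach direction; every local
        # minimum of the radial profile seeds a search, so basins hidden
        # behind a repulsive wall at shorter range are not skipped
        radii = np.arange(1.0, r_far, 0.25)
        prof = np.array([objective(np.concatenate([rv, comA + s * d - comB]))
                         for s in radii])
        seeds_s = [radii[i] for i in range(len(radii))
                   if prof[i] < 1.0e5
                   and (i == 0 or prof[i] <= prof[i - 1])
                   and (i == len(radii) - 1 or prof[i] < prof[i + 1])]
        seeds_s.sort(key=lambda s: prof[int(round((s - 1.0) / 0.25))])
        if not seeds_s:
            n_failed += 1
            continue
        ok = False
        for s in seeds_s[:2]:
            pose0 = np.concatenate([rv, comA + s * d - comB])
            try:
                steps = np.array([0.4, 0.4, 0.4, 0.5, 0.5, 0.5])
                pose, e = _pattern_search(objective, pose0, steps,
                                          cfg.coarse_tol, cfg.max_poll_rounds)
            except EngineError:
                continue
            raw.append((pose, e, k))
            ok = True
        if not ok:
            warnings.warn(f"engine failed on start {k}; discarded")
            n_failed += 1
    if not raw:
        raise EngineError("all starting poses failed")
    if n_failed:
        warnings.warn(f"{n_failed}/{cfg.n_starts} starting poses discarded")

    raw.sort(key=lambda t: t[1])
    # tight re-optimization of the best distinct poses
    kept: list[tuple[np.ndarray, float, int]] = []
    for pose, e, k in raw:
        if len(kept) >= cfg.refine_top:
            break
        if any(np.linalg.norm(pose[3:] - p[3:]) < 0.3
               and np.linalg.norm(pose[:3] - p[:3]) < 0.3
               for p, _, _ in kept):
            continue
        steps = np.array([0.05, 0.05, 0.05, 0.06, 0.06, 0.06])
        pose2, e2 = _pattern_search(objective, pose, steps, cfg.fine_tol,
                                    cfg.max_poll_rounds)
        kept.append((pose2, e2, k))

    candidates: list[ComplexCandidate] = []
    for pose, e, k in sorted(kept, key=lambda t: t[1]):
        geom = merge(molA, molB.with_coords(_pose_coords(coordsB0, comB, pose)),
                     metadata=f"complex start={k}")
        cand = ComplexCandidate(geom, e, max_extent(geom), k, molA.n_atoms)
        if any(_same_complex(cand, other, cfg.dedup_rmsd)
               for other in candidates):
            continue
        candidates.append(cand)
    return candidates


def _same_complex(a: ComplexCandidate, b: ComplexCandidate,
                  rmsd_tol: float) -> bool:
    try:
        rmsd, _ = kabsch_align(a.structure, b.structure)
    except Exception:
        return False
    return rmsd < rmsd_tol


def best_complex(candidates: list[ComplexCandidate]) -> ComplexCandidate:
    """Minimum-energy candidate; energy ties (within 1e-9 kcal/mol) break
    toward smaller complex size, then smaller start id."""
    if not candidates:
        raise ValueError("best_complex: empty candidate list")
    e_min = min(c.energy for c in candidates)
    tied = [c for c in candidates if c.energy <= e_min + 1e-9]
    return min(tied, key=lambda c: (c.size_R, c.start_id))


# ---------------------------------------------------------------------------
# pairings and the screening matrix
# ---------------------------------------------------------------------------

def pairing_deltas(molA_R: Structure, molA_S: Structure, molB_S: Structure,
                   engine, config: SearchConfig | None = None,
                   combo_label: str = "pair") -> PairingResult:
    """delta_E / delta_R for one bimolecular combination.

    ``molA_R`` must be the mirror image of ``molA_S`` (checked by rigid
    superposition).  The RS record pairs the R target with the S partner;
    the SS record pairs the two S forms.
    """
    rmsd, _ = kabsch_align(molA_R, mirror(molA_S))
    if rmsd > 1e-6:
        raise ValueError("molA_R is not the mirror image of molA_S "
                         f"(superposition rmsd {rmsd:.2e} Å)")
    cfg = config or SearchConfig()
    best_rs = best_complex(find_complex_minima(molA_R, molB_S, engine, cfg))
    best_ss = best_complex(find_complex_minima(molA_S, molB_S, engine, cfg))
    return PairingResult(combo_label,
                         E_RS=best_rs.energy, E_SS=best_ss.energy,
                         R_RS=best_rs.size_R, R_SS=best_ss.size_R)


def screen_matrix(library: list[tuple[str, Structure, Structure]], engine,
                  config: SearchConfig | None = None) -> pd.DataFrame:
    """Screen all unordered combinations (with self-pairings) of a
    library of chiral monomers given as (label, R, S) triples.

    Returns one row per combination with columns combo_label, E_RS,
    E_SS, R_RS, R_SS, delta_E, delta_R and a flag column that marks
    monomers failing the chirality witness.
    """
    if len(library) < 2:
        raise ValueError("library must contain at least 2 monomers")
    cfg = config or SearchConfig()
    rows = []
    idx = 0
    for i in range(len(library)):
        for j in range(i, len(library)):
            la, ra, sa = library[i]
            lb, rb, sb = library[j]
            label = f"{la}-{lb}"
            flags = []
            for lab, st in ((la, sa), (lb, sb)):
                if is_achiral(st):
                    flags.append(f"achiral:{lab}")
                    warnings.warn(f"monomer {lab!r} fails the chirality "
                                  "witness; deltas are expected to vanish")
            pair_seed = (cfg.seed + 7919 * idx) % (2 ** 31)
            pair_cfg = SearchConfig(cfg.n_starts, pair_seed, cfg.dedup_rmsd,
                                    cfg.refine_top, cfg.coarse_tol,
                                    cfg.fine_tol, cfg.max_poll_rounds)
            res = pairing_deltas(ra, sa, sb, engine, pair_cfg, label)
            res.flag = ";".join(flags)
            rows.append({
                "combo_label": res.combo_label,
                "E_RS": res.E_RS, "E_SS": res.E_SS,
                "R_RS": res.R_RS, "R_SS": res.R_SS,
                "delta_E": res.delta_E, "delta_R": res.delta_R,
                "flag": res.flag,
            })
            idx += 1
    return pd.DataFrame(rows)
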