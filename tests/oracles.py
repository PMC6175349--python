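"""Independent reference implementations used to cross-check the package.

Everything here is deliberately brute force -- explicit double loops,
dense grids, union-find flooding -- and shares no search/optimization
code with the implementation under test.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from chirasieve.energetics import NonbondedParams, combine, pair_energy
from chirasieve.molsys import Structure


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def brute_force_max_extent(coords: np.ndarray) -> float:
    best = 0.0
    n = len(coords)
    for i in range(n):
        for j in range(i + 1, n):
            best = max(best, float(np.linalg.norm(coords[i] - coords[j])))
    return best


def brute_force_min_mirror_rmsd(A: np.ndarray, B: np.ndarray,
                                levels: int = 8) -> float:
    """Minimum RMSD of B onto A over proper rotations, by nested dense
    Euler-angle grid refinement (translation removed by centering)."""
    from scipy.spatial.transform import Rotation
    A = A - A.mean(axis=0)
    B = B - B.mean(axis=0)

    def rmsd_of(euler):
        R = Rotation.from_euler("zyz", euler).as_matrix()
        return float(np.sqrt(np.mean(np.sum((A - B @ R.T) ** 2, axis=1))))

    center = np.zeros(3)
    widths = np.array([2 * math.pi, math.pi, 2 * math.pi])
    best = (np.inf, center)
    for _ in range(levels):
        grid = [np.linspace(c - w / 2, c + w / 2, 9)
                for c, w in zip(best[1] if best[0] < np.inf else center,
                                widths)]
        for euler in itertools.product(*grid):
            r = rmsd_of(euler)
            if r < best[0]:
                best = (r, np.array(euler))
        widths = widths / 4.0
    return best[0]


# ---------------------------------------------------------------------------
# energies
# ---------------------------------------------------------------------------

def double_loop_energy(fragA: Structure, fragB: Structure,
                       params: NonbondedParams) -> float:
    """Explicit double loop over cross pairs with no cutoff tricks:
    each term evaluated scalar-by-scalar from the closed form."""
    typesA = fragA.types_or_elements()
    typesB = fragB.types_or_elements()
    qA = (fragA.charges if fragA.charges is not None
          else np.array([params.lookup(t)[2] for t in typesA]))
    qB = (fragB.charges if fragB.charges is not None
          else np.array([params.lookup(t)[2] for t in typesB]))
    total = 0.0
    for i, ti in enumerate(typesA):
        for j, tj in enumerate(typesB):
            r = float(np.linalg.norm(fragA.coords[i] - fragB.coords[j]))
            if params.cutoff is not None and r > params.cutoff:
                continue
            ei, si, _ = params.lookup(ti)
            ej, sj, _ = params.lookup(tj)
            eps, sig = combine(ei, si, ej, sj, params.combination_rule)
            sr6 = (sig / r) ** 6
            total += 4.0 * eps * (sr6 ** 2 - sr6)
            total += params.coulomb_constant * qA[i] * qB[j] / r
    return total


# ---------------------------------------------------------------------------
# dense 6-DOF dimer grid search
# ---------------------------------------------------------------------------

def _euler_rotations(n: int) -> np.ndarray:
    """Dense proper-rotation set from an n x n x n zyz Euler grid."""
    from scipy.spatial.transform import Rotation
    a = np.linspace(0.0, 2 * math.pi, n, endpoint=False)
    b = np.linspace(0.0, math.pi, n)
    angles = np.array(list(itertools.product(a, b, a)))
    return Rotation.from_euler("zyz", angles).as_matrix()


def grid_search_dimer_energy(molA: Structure, molB: Structure, engine,
                             n_euler: int = 8, n_dir: int = 72,
                             r_max: float = 12.0, r_step: float = 0.1,
                             refine_levels: int = 40) -> tuple[float, np.ndarray]:
    """Dense 6-DOF grid search for the lowest dimer interaction energy.

    Independent of the package's pattern search: pure enumeration plus
    nested grid refinement around the best cell.
    """
    from scipy.spatial.transform import Rotation
    from chirasieve.energetics import EngineError, bind_engine

    energy_fn = bind_engine(engine, molA, molB)
    cA = molA.coords
    comB = molB.coords.mean(axis=0)
    relB = molB.coords - comB
    comA = cA.mean(axis=0)

    def eval_pose(pose):
        R = Rotation.from_rotvec(pose[:3]).as_matrix()
        try:
            return energy_fn(cA, relB @ R.T + comB + pose[3:])
        except EngineError:
            return 1.0e6

    # stage 1: orientation x direction x radius enumeration
    rots = _euler_rotations(n_euler)
    rotvecs = Rotation.from_matrix(rots).as_rotvec()
    i_dir = np.arange(n_dir) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i_dir
    z = 1.0 - 2.0 * i_dir / n_dir
    rr = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    dirs = np.stack([rr * np.cos(phi), rr * np.sin(phi), z], axis=1)
    radii = np.arange(1.0, r_max, r_step)
    offsets = (dirs[:, None, :] * radii[None, :, None]).reshape(-1, 3)

    cells: list[tuple[float, np.ndarray]] = []
    for rv, R in zip(rotvecs, rots):
        rotated = relB @ R.T                       # (nB, 3)
        # all offsets at once: (n_off, nB, 3) vs (nA, 3)
        posed = rotated[None, :, :] + comA[None, None, :] + offsets[:, None, :]
        diff = cA[None, :, None, :] - posed[:, None, :, :]
        r = np.sqrt(np.einsum("oabk,oabk->oab", diff, diff))
        r = np.maximum(r, 1e-3)
        e = _vector_energy(r, molA, molB, engine)
        k = int(np.argmin(e))
        cells.append((float(e[k]),
                      np.concatenate([rv, comA + offsets[k] - comB])))

    # stage 2: nested local refinement (3^6 per level) of the best cells
    # from well-separated stage-1 basins
    cells.sort(key=lambda t: t[0])
    seeds: list[tuple[float, np.ndarray]] = []
    for e, pose in cells:
        if len(seeds) >= 16:
            break
        if any(np.linalg.norm(pose[3:] - p[3:]) < 0.5
               and np.linalg.norm(pose[:3] - p[:3]) < 0.5 for _, p in seeds):
            continue
        seeds.append((e, pose))

    best_e, best_pose = np.inf, None
    for e0, pose0 in seeds:
        e_cur, pose = e0, pose0.copy()
        widths = np.array([0.9, 0.9, 0.9, 0.4, 0.4, 0.4])
        for _ in range(refine_levels):
            axes = [np.array([-1.0, 0.0, 1.0]) * w / 2 + c
                    for c, w in zip(pose, widths)]
            improved = False
            for combo in itertools.product(*axes):
                cand = np.array(combo)
                e = eval_pose(cand)
                if e < e_cur - 1e-15:
                    e_cur, pose = e, cand
                    improved = True
            # shrink only when the level brought no progress, so the
            # grid can track curved valleys at constant resolution
            if not improved:
                widths *= 0.5
                if widths.max() < 1e-7:
                    break
        if e_cur < best_e:
            best_e, best_pose = e_cur, pose
    return best_e, best_pose


def _vector_energy(r: np.ndarray, molA: Structure, molB: Structure, engine):
    """Vectorized LJ+Coulomb over a batch of cross-distance tensors,
    recomputed from the engine's parameter table (no shared code with
    the implementation's masked evaluation)."""
    params = engine.params
    typesA = molA.types_or_elements()
    typesB = molB.types_or_elements()
    rowsA = [params.lookup(t) for t in typesA]
    rowsB = [params.lookup(t) for t in typesB]
    qA = (molA.charges if molA.charges is not None
          else np.array([row[2] for row in rowsA]))
    qB = (molB.charges if molB.charges is not None
          else np.array([row[2] for row in rowsB]))
    eps = np.empty((len(typesA), len(typesB)))
    sig = np.empty_like(eps)
    for i, (ei, si, _) in enumerate(rowsA):
        for j, (ej, sj, _) in enumerate(rowsB):
            eps[i, j], sig[i, j] = combine(ei, si, ej, sj,
                                           params.combination_rule)
    kqq = params.coulomb_constant * np.outer(qA, qB)
    sr6 = (sig[None] / r) ** 6
    e = 4.0 * eps[None] * (sr6 ** 2 - sr6) + kqq[None] / r
    if params.cutoff is not None:
        e = np.where(r <= params.cutoff, e, 0.0)
    return e.sum(axis=(1, 2))


# ---------------------------------------------------------------------------
# minimax barrier by union-find flooding
# ---------------------------------------------------------------------------

def minimax_barrier_2d(f, start, end, lo=(-2.0, -2.0), hi=(2.0, 2.0),
                       n: int = 201) -> float:
    """Lowest possible maximum energy along any grid path from start to
    end: cells are merged in order of increasing energy (union-find)
    until the two endpoint cells connect."""
    xs = np.linspace(lo[0], hi[0], n)
    ys = np.linspace(lo[1], hi[1], n)
    E = np.array([[f(np.array([x, y])) for y in ys] for x in xs])
    start_idx = (int(np.argmin(np.abs(xs - start[0]))),
                 int(np.argmin(np.abs(ys - start[1]))))
    end_idx = (int(np.argmin(np.abs(xs - end[0]))),
               int(np.argmin(np.abs(ys - end[1]))))
    parent = {}

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    order = np.dstack(np.unravel_index(np.argsort(E, axis=None),
                                       E.shape))[0]
    active = set()
    for i, j in order:
        cell = (int(i), int(j))
        parent[cell] = cell
        active.add(cell)
        for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            nb = (cell[0] + di, cell[1] + dj)
            if nb in active:
                union(cell, nb)
        if (start_idx in active and end_idx in active
                and find(start_idx) == find(end_idx)):
            return float(E[cell])
    raise RuntimeError("endpoints never connected")


# ---------------------------------------------------------------------------
# dense-grid extrema of a 1D function
# ---------------------------------------------------------------------------

def grid_extrema_1d(f, lo: float, hi: float, n: int = 200001):
    """Interior extrema of f by dense sampling and neighbor comparison;
    returns a list of (x, f(x), 'minimum'|'maximum')."""
    x = np.linspace(lo, hi, n)
    y = f(x)
    out = []
    for i in range(1, n - 1):
        if y[i] < y[i - 1] and y[i] < y[i + 1]:
            out.append((float(x[i]), float(y[i]), "minimum"))
        elif y[i] > y[i - 1] and y[i] > y[i + 1]:
            out.append((float(x[i]), float(y[i]), "maximum"))
    return out
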