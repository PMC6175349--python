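"""Membrane-propagation machinery.

A propagation event through a single-atom-thick membrane is treated as a
one-dimensional reaction: the target molecule, held rigid in a fixed
orientation, is translated along the membrane normal through the pore
center in steps of 0.25 Å.  The interaction energy at each step, with
the zero of energy at infinite pore--molecule separation, is
interpolated with a cubic spline, and the interior extrema are
classified onto a five-slot pathway schema (left minimum, 1st transition
state, intermediate, 2nd transition state, right minimum).  The highest
transition state is the rate-determining step.

Beyond the constrained scan, a nudged-elastic-band optimizer relaxes a
chain of rigid-body poses (6 degrees of freedom per image) between two
end minima, providing an unconstrained estimate of the minimum-energy
pathway and its saddle.  Barrier differences map to selectivity ratios
via a Boltzmann factor, and absolute barriers to a permeance indicator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .energetics import KB_KCAL_PER_MOL_K, EngineError, bind_engine
from .molsys import RigidTransform, Structure, center_of_mass, max_extent
from .porelib import PoreModel

__all__ = [
    "ScanProtocol", "EnergyProfile", "PathwayExtrema", "SelectivityEstimate",
    "rigid_scan", "interpolate_profile", "find_extrema", "neb",
    "neb_path", "NEBResult", "selectivity_estimate", "permeance_indicator",
    "double_well_2d", "ENERGY_CAP",
]

#: Energies above this value (kcal/mol) are capped and flagged, keeping
#: splines finite near hard-core overlap while preserving ordering.
ENERGY_CAP = 1.0e4


@dataclass(frozen=True)
class ScanProtocol:
    """Settings of the rigid constrained z-scan.

    ``orientation`` is applied to the molecule once before scanning (the
    scan itself never rotates anything); ``z_range`` endpoints should be
    far enough out that the profile has decayed to zero.
    """

    step: float = 0.25
    z_range: tuple[float, float] = (-8.0, 8.0)
    orientation: RigidTransform | None = None
    cap: float = ENERGY_CAP

    def __post_init__(self):
        if self.step <= 0:
            raise ValueError("scan step must be positive")
        if self.z_range[0] >= self.z_range[1]:
            raise ValueError("z_range must satisfy z_min < z_max")

    def grid(self) -> np.ndarray:
        z0, z1 = self.z_range
        n = int(round((z1 - z0) / self.step))
        return z0 + self.step * np.arange(n + 1)


@dataclass
class EnergyProfile:
    """Sampled scan energies with spline interpolant and extrema."""

    z_values: np.ndarray
    energies: np.ndarray
    spline: CubicSpline
    capped: np.ndarray            # bool mask of overlap-capped samples
    extrema: list[tuple[float, float, str]] = field(default_factory=list)

    def __call__(self, z):
        return self.spline(z)


@dataclass
class PathwayExtrema:
    """The five-slot pathway schema, in order of the reaction coordinate.

    Slots that the profile does not realize are ``None``; the
    rate-determining entry is the highest transition state present.
    """

    left_minimum: tuple[float, float] | None = None
    ts1: tuple[float, float] | None = None
    intermediate: tuple[float, float] | None = None
    ts2: tuple[float, float] | None = None
    right_minimum: tuple[float, float] | None = None
    rate_determining: tuple[float, float] | None = None

    def slots(self):
        return {"left_minimum": self.left_minimum, "ts1": self.ts1,
                "intermediate": self.intermediate, "ts2": self.ts2,
                "right_minimum": self.right_minimum}


# ---------------------------------------------------------------------------
# constrained scan
# ---------------------------------------------------------------------------

def rigid_scan(pore: PoreModel, molecule: Structure,
               protocol: ScanProtocol | None = None,
               engine=None) -> EnergyProfile:
    """Frozen-geometry translation of a molecule through a pore.

    At each grid point the molecule's center of mass sits at
    ``pore.center + z * pore.normal``; pore and molecule are rigid and
    never rotate.  Energies are referenced to infinite separation
    (realized deterministically far along the normal) and capped at
    ``protocol.cap`` where fragments overlap.
    """
    proto = protocol or ScanProtocol()
    if engine is None:
        from .energetics import LJCoulombEngine
        engine = LJCoulombEngine()
    mol = molecule
    if proto.orientation is not None:
        from .molsys import apply_transform
        mol = apply_transform(mol, proto.orientation)
    energy_fn = bind_engine(engine, pore.structure, mol)
    com = center_of_mass(mol)
    rel = mol.coords - com
    pc = pore.structure.coords

    # infinite-separation reference: 3 x (cutoff + extents) along the normal
    cutoff = getattr(getattr(engine, "params", None), "cutoff", None) or 12.0
    ext_m = max_extent(mol) if mol.n_atoms > 1 else 0.0
    ext_p = max_extent(pore.structure) if pore.structure.n_atoms > 1 else 0.0
    z_far = 3.0 * (cutoff + ext_m + ext_p)
    try:
        e_ref = energy_fn(pc, rel + pore.center + z_far * pore.normal)
    except EngineError:
        raise EngineError("engine failed at the infinite-separation reference")

    grid = proto.grid()
    energies = np.empty_like(grid)
    capped = np.zeros(len(grid), dtype=bool)
    for i, z in enumerate(grid):
        pos = rel + pore.center + z * pore.normal
        try:
            e = energy_fn(pc, pos) - e_ref
        except EngineError:
            e = proto.cap
            capped[i] = True
        if e > proto.cap:
            e = proto.cap
            capped[i] = True
        energies[i] = e
    spline = interpolate_profile(grid, energies)
    profile = EnergyProfile(grid, energies, spline, capped)
    find_extrema(profile)
    return profile


def interpolate_profile(z_values, energies) -> CubicSpline:
    """Cubic spline through the sampled profile.

    Not-a-knot boundary conditions: unlike natural boundaries they do
    not force zero curvature at the scan ends, so a profile that is
    locally cubic is reproduced exactly everywhere.
    """
    z = np.asarray(z_values, float)
    e = np.asarray(energies, float)
    if len(z) < 4:
        raise ValueError("need at least 4 samples for a cubic spline")
    if np.any(np.diff(z) <= 0):
        raise ValueError("z values must be strictly increasing")
    return CubicSpline(z, e, bc_type="not-a-knot")


def find_extrema(profile: EnergyProfile,
                 curvature_tol: float = 1e-10) -> PathwayExtrema:
    """Locate and classify interior extrema of the spline.

    Roots of the spline derivative are classified by the sign of the
    second derivative, near-duplicates merged, and the alternating
    min/max sequence mapped in z-order onto the five-slot schema.
    Updates ``profile.extrema`` in place and returns the schema.
    """
    dspl = profile.spline.derivative()
    roots = dspl.roots(extrapolate=False)
    roots = np.real(roots[np.isreal(roots)])
    z0, z1 = profile.z_values[0], profile.z_values[-1]
    roots = np.sort(roots[(roots > z0 + 1e-9) & (roots < z1 - 1e-9)])
    d2 = profile.spline.derivative(2)
    found: list[tuple[float, float, str]] = []
    for z in roots:
        c = float(d2(z))
        if abs(c) < curvature_tol:
            continue
        kind = "minimum" if c > 0 else "maximum"
        if found and abs(z - found[-1][0]) < 1e-6 and found[-1][2] == kind:
            continue
        found.append((float(z), float(profile.spline(z)), kind))
    # enforce alternation: merge runs of equal kind, keeping the extreme one
    cleaned: list[tuple[float, float, str]] = []
    for ext in found:
        if cleaned and cleaned[-1][2] == ext[2]:
            keep_new = (ext[1] < cleaned[-1][1] if ext[2] == "minimum"
                        else ext[1] > cleaned[-1][1])
            if keep_new:
                cleaned[-1] = ext
        else:
            cleaned.append(ext)
    profile.extrema = cleaned
    return classify_extrema(cleaned)


def classify_extrema(extrema: list[tuple[float, float, str]]
                     ) -> PathwayExtrema:
    """Map an alternating extrema sequence onto the pathway schema."""
    out = PathwayExtrema()
    minima = [(z, e) for z, e, k in extrema if k == "minimum"]
    maxima = [(z, e) for z, e, k in extrema if k == "maximum"]
    if maxima:
        out.ts1 = maxima[0]
        if len(maxima) > 1:
            out.ts2 = maxima[-1]
        out.rate_determining = max(maxima, key=lambda t: t[1])
    if minima:
        out.left_minimum = minima[0]
        if len(minima) > 1:
            out.right_minimum = minima[-1]
        if len(minima) > 2:
            # interior minimum between the two transition states
            out.intermediate = min(minima[1:-1], key=lambda t: t[1])
    return out


# ---------------------------------------------------------------------------
# nudged elastic band
# ---------------------------------------------------------------------------

@dataclass
class NEBResult:
    images: np.ndarray            # (n_images, dof) coordinates
    energies: np.ndarray
    saddle_energy: float
    saddle_coords: np.ndarray
    converged: bool
    n_iterations: int
    extrema: PathwayExtrema | None = None


def _finite_diff_grad(f, x: np.ndarray, h: float) -> np.ndarray:
    g = np.empty_like(x)
    for i in range(len(x)):
        xp = x.copy(); xp[i] += h
        xm = x.copy(); xm[i] -= h
        g[i] = (f(xp) - f(xm)) / (2.0 * h)
    return g


def neb(f, x_initial, x_final, n_images: int = 11, k_spring: float = 1.0,
        fmax: float = 1e-3, max_iterations: int = 2000,
        step_size: float = 0.05, climbing: bool = False,
        grad=None, fd_step: float = 1e-5) -> NEBResult:
    """Improved-tangent nudged elastic band on a generic energy function.

    ``f`` maps a coordinate vector to an energy; endpoints are fixed.
    The band is converged when the maximum projected-force norm drops
    below ``fmax``.  With ``climbing`` the highest image feels the
    inverted parallel force and converges onto the saddle itself;
    otherwise the saddle is estimated from a spline through the image
    energies.  Gradients are taken by central finite differences unless
    an analytic ``grad`` is supplied.
    """
    x0 = np.asarray(x_initial, float)
    x1 = np.asarray(x_final, float)
    if n_images < 3:
        raise ValueError("n_images must be >= 3")
    if grad is None:
        grad = lambda x: _finite_diff_grad(f, x, fd_step)
    t = np.linspace(0.0, 1.0, n_images)[:, None]
    images = (1 - t) * x0[None, :] + t * x1[None, :]
    if np.linalg.norm(x1 - x0) < 1e-12:
        e = np.array([f(x) for x in images])
        return NEBResult(images, e, float(e.max()), images[int(e.argmax())],
                         True, 0)

    n_inner = n_images - 2
    velocity = np.zeros((n_inner, images.shape[1]))
    converged = False
    it = 0
    for it in range(1, max_iterations + 1):
        energies = np.array([f(x) for x in images])
        grads = np.array([grad(images[i]) for i in range(1, n_images - 1)])
        climb_idx = int(np.argmax(energies[1:-1])) if climbing else -1
        forces = np.empty_like(grads)
        for j in range(n_inner):
            i = j + 1
            # improved tangent: toward the higher-energy neighbor
            dplus = images[i + 1] - images[i]
            dminus = images[i] - images[i - 1]
            e_prev, e_i, e_next = energies[i - 1], energies[i], energies[i + 1]
            if e_next > e_i and e_i > e_prev:
                tau = dplus
            elif e_next < e_i and e_i < e_prev:
                tau = dminus
            else:
                dmax = max(abs(e_next - e_i), abs(e_prev - e_i))
                dmin = min(abs(e_next - e_i), abs(e_prev - e_i))
                if e_next > e_prev:
                    tau = dplus * dmax + dminus * dmin
                else:
                    tau = dplus * dmin + dminus * dmax
            tn = np.linalg.norm(tau)
            tau = tau / tn if tn > 1e-14 else tau
            g = grads[j]
            if j == climb_idx:
                forces[j] = -g + 2.0 * (g @ tau) * tau
            else:
                f_spring = k_spring * (np.linalg.norm(dplus)
                                       - np.linalg.norm(dminus))
                forces[j] = -(g - (g @ tau) * tau) + f_spring * tau
        fnorm = float(np.max(np.linalg.norm(forces, axis=1)))
        if fnorm < fmax:
            converged = True
            break
        # damped velocity step (simple FIRE-like projection)
        dot = np.sum(velocity * forces)
        velocity = forces * max(0.0, dot) / (np.sum(forces * forces) + 1e-300) \
            if dot > 0 else np.zeros_like(velocity)
        velocity += step_size * forces
        move = step_size * velocity
        norm = np.linalg.norm(move, axis=1, keepdims=True)
        move = np.where(norm > 0.2, move * 0.2 / np.maximum(norm, 1e-300),
                        move)
        images[1:-1] += move

    energies = np.array([f(x) for x in images])
    # saddle estimate: spline through image energies along arc length
    s = np.concatenate([[0.0], np.cumsum(
        np.linalg.norm(np.diff(images, axis=0), axis=1))])
    if s[-1] > 1e-12 and len(images) >= 4:
        spl = CubicSpline(s, energies)
        ss = np.linspace(s[0], s[-1], 2001)
        vals = spl(ss)
        i_best = int(np.argmax(vals))
        saddle_e = float(vals[i_best])
        i_img = int(np.argmax(energies))
        saddle_x = images[i_img]
        if climbing:
            saddle_e = float(energies[1:-1].max())
            saddle_x = images[1 + int(np.argmax(energies[1:-1]))]
        ext = _band_extrema(s, energies)
    else:
        saddle_e = float(energies.max())
        saddle_x = images[int(energies.argmax())]
        ext = None
    return NEBResult(images, energies, saddle_e, saddle_x, converged, it, ext)


def _band_extrema(s, energies) -> PathwayExtrema:
    spl = CubicSpline(s, energies, bc_type="not-a-knot")
    prof = EnergyProfile(np.asarray(s, float), np.asarray(energies, float),
                         spl, np.zeros(len(s), bool))
    return find_extrema(prof)


def neb_path(pore: PoreModel, molecule: Structure, pose_initial, pose_final,
             engine=None, n_images: int = 11, k_spring: float = 1.0,
             fmax: float = 1e-3, max_iterations: int = 1000,
             climbing: bool = False, cap: float = ENERGY_CAP) -> NEBResult:
    """NEB over the rigid molecule's 6-DOF pose through a frozen pore.

    Poses are (rotation-vector, centroid-translation) 6-vectors; the
    pore never moves.  Endpoints should be locally minimized poses (for
    example the minima of a rigid scan).  Energies are referenced to
    infinite separation, as in :func:`rigid_scan`.
    """
    if engine is None:
        from .energetics import LJCoulombEngine
        engine = LJCoulombEngine()
    energy_fn = bind_engine(engine, pore.structure, molecule)
    com = molecule.coords.mean(axis=0)
    rel = molecule.coords - com
    pc = pore.structure.coords
    from scipy.spatial.transform import Rotation

    cutoff = getattr(getattr(engine, "params", None), "cutoff", None) or 12.0
    ext = (max_extent(molecule) if molecule.n_atoms > 1 else 0.0) + \
        (max_extent(pore.structure) if pore.structure.n_atoms > 1 else 0.0)
    far = pore.center + 3.0 * (cutoff + ext) * pore.normal
    e_ref = energy_fn(pc, rel + far)

    def f(pose):
        R = Rotation.from_rotvec(pose[:3]).as_matrix()
        try:
            e = energy_fn(pc, rel @ R.T + pose[3:]) - e_ref
        except EngineError:
            return cap
        return min(e, cap)

    return neb(f, np.asarray(pose_initial, float),
               np.asarray(pose_final, float), n_images=n_images,
               k_spring=k_spring, fmax=fmax, max_iterations=max_iterations,
               climbing=climbing)


# ---------------------------------------------------------------------------
# selectivity and permeance
# ---------------------------------------------------------------------------

@dataclass
class SelectivityEstimate:
    """Boltzmann mapping of a rate-determining barrier difference."""

    barrier_A: float
    barrier_B: float
    temperature: float
    barrier_A_from_minimum: float | None = None
    barrier_B_from_minimum: float | None = None

    @property
    def ddE(self) -> float:
        return self.barrier_A - self.barrier_B

    @property
    def ratio(self) -> float:
        return math.exp(-self.ddE / (KB_KCAL_PER_MOL_K * self.temperature))


def _rate_determining(pathway: PathwayExtrema):
    if pathway.rate_determining is None:
        raise ValueError("pathway has no rate-determining barrier")
    return pathway.rate_determining


def _barrier_from_preceding_minimum(pathway: PathwayExtrema) -> float | None:
    rd = pathway.rate_determining
    if rd is None:
        return None
    z_rd, e_rd = rd
    minima = [m for m in (pathway.left_minimum, pathway.intermediate,
                          pathway.right_minimum)
              if m is not None and m[0] < z_rd]
    if not minima:
        return None
    z_prev, e_prev = max(minima, key=lambda m: m[0])
    return e_rd - e_prev


def selectivity_estimate(pathway_A: PathwayExtrema, pathway_B: PathwayExtrema,
                         temperature: float = 298.15) -> SelectivityEstimate:
    """Selectivity ratio exp(-(Ea_A - Ea_B) / kT) of two pathways.

    Barriers are the rate-determining transition-state energies measured
    from the shared infinite-separation zero; the barriers measured from
    each pathway's preceding minimum are reported alongside.
    """
    eA = _rate_determining(pathway_A)[1]
    eB = _rate_determining(pathway_B)[1]
    return SelectivityEstimate(
        eA, eB, temperature,
        _barrier_from_preceding_minimum(pathway_A),
        _barrier_from_preceding_minimum(pathway_B))


def permeance_indicator(pathway: PathwayExtrema,
                        temperature: float = 298.15) -> float:
    """Boltzmann passage indicator exp(-max(0, barrier)/kT) in (0, 1];
    monotone decreasing in the rate-determining barrier height."""
    barrier = _rate_determining(pathway)[1]
    return math.exp(-max(0.0, barrier) / (KB_KCAL_PER_MOL_K * temperature))


# ---------------------------------------------------------------------------
# shipped analytic test surface
# ---------------------------------------------------------------------------

def double_well_2d(x: np.ndarray) -> float:
    """Two-dimensional double well E(x, y) = (x^2 - 1)^2 + 2 (y - x/2)^2.

    Minima at (±1, ±1/2) with E = 0; one first-order saddle at the
    origin with E = 1.  Shipped as the analytic validation surface for
    the band optimizer.
    """
    x = np.asarray(x, float)
    return float((x[0] ** 2 - 1.0) ** 2 + 2.0 * (x[1] - 0.5 * x[0]) ** 2)
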