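"""Finite nanoporous membrane models.

Builds idealized, planar, hydrogen-passivated flakes of graphene with a
pore cut out, and a single triangular graphdiyne pore unit.  The models
are finite molecular clusters (not periodic slabs): only the benzene
rings needed to define the pore shape are kept, and every dangling bond
is saturated with hydrogen.  Geometries are unrelaxed by construction --
aromatic C-C bonds are exactly ``cc_bond`` -- which keeps atom counts,
symmetries and pore diameters exactly reproducible.

Pore diameter conventions
-------------------------
``geometric``
    Twice the radius of the largest circle that fits in the membrane
    plane without touching any rim-atom nucleus.
``vdw``
    The geometric value reduced by the van der Waals radii of the two
    limiting rim atoms.

The *calibrated* default is ``geometric``: with standard bond lengths it
reproduces the reference openings of 6.0 Å (4-ring graphene pore),
5.6 Å (3-ring graphene pore) and 5.6 Å (graphdiyne) to within 0.1 Å.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.optimize import minimize

from .molsys import ELEMENTS, MolsysError, RigidTransform, Structure

__all__ = [
    "LatticeSpec", "GrapheneFlake", "PoreModel", "PoreError",
    "build_graphene_flake", "cut_pore", "build_graphdiyne_pore",
    "substitute_nitrogen", "detect_rim", "pore_diameter",
    "build_preset", "PRESET_RING_LAYOUTS", "bond_graph",
    "write_pore", "read_pore", "attach_group",
]


class PoreError(MolsysError):
    pass


@dataclass(frozen=True)
class LatticeSpec:
    """Idealized bond lengths (Å) used by the builders."""

    cc_bond: float = 1.42        # aromatic C-C in graphene
    ch_bond: float = 1.09        # C-H
    gdy_aromatic: float = 1.43   # aromatic C-C in graphdiyne corner rings
    gdy_single: float = 1.40     # C(aromatic)-C(sp) single bond
    gdy_triple: float = 1.22     # C#C
    gdy_inter: float = 1.34      # C(sp)-C(sp) bond between the two triples

    def __post_init__(self):
        for name in ("cc_bond", "ch_bond", "gdy_aromatic", "gdy_single",
                     "gdy_triple", "gdy_inter"):
            v = getattr(self, name)
            if not (0.5 < v < 3.0):
                raise PoreError(f"{name}={v} outside sane range (0.5, 3.0) Å")


@dataclass
class GrapheneFlake:
    """A planar all-sp2 flake: Structure plus the hexagon-ring layout.

    Rings are addressed by axial indices (q, r) on the triangular lattice
    of hexagon centers.
    """

    structure: Structure
    rings: list[tuple[int, int]]
    lattice: LatticeSpec


@dataclass
class PoreModel:
    """A membrane structure plus pore geometry metadata."""

    structure: Structure
    center: np.ndarray
    normal: np.ndarray
    rim_indices: list[int]
    diameter: float | None = None
    convention: str | None = None
    preset: str | None = None
    porous: bool = True

    def __post_init__(self):
        self.center = np.asarray(self.center, float).reshape(3)
        self.normal = np.asarray(self.normal, float).reshape(3)
        n = np.linalg.norm(self.normal)
        if abs(n - 1.0) > 1e-10:
            if n < 1e-12:
                raise PoreError("membrane normal has zero length")
            self.normal = self.normal / n
        if self.porous:
            if not self.rim_indices:
                raise PoreError("porous model must have rim atoms")
            if max(self.rim_indices) >= self.structure.n_atoms:
                raise PoreError("rim index out of range")
            # rim atoms must lie in the membrane plane
            d = (self.structure.coords[self.rim_indices] - self.center) @ self.normal
            if np.max(np.abs(d)) > 1.0:
                raise PoreError("rim atom further than 1 Å from membrane plane")


# ---------------------------------------------------------------------------
# hexagonal-lattice helpers
# ---------------------------------------------------------------------------

_AXIAL_NEIGHBORS = [(1, 0), (-1, 0), (0, 1), (0, -1), (1, -1), (-1, 1)]


def _lattice_vectors(cc: float):
    a = cc * math.sqrt(3.0)
    return (np.array([a, 0.0]), np.array([a / 2.0, a * math.sqrt(3.0) / 2.0]))


def _ring_center(q: int, r: int, cc: float) -> np.ndarray:
    a1, a2 = _lattice_vectors(cc)
    return q * a1 + r * a2


def _ring_vertices(center2d: np.ndarray, cc: float) -> np.ndarray:
    ang = np.deg2rad(30.0 + 60.0 * np.arange(6))
    return center2d + cc * np.stack([np.cos(ang), np.sin(ang)], axis=1)


def _dedupe(points: np.ndarray, tol: float = 1e-6) -> np.ndarray:
    key = np.round(points / tol).astype(np.int64)
    _, idx = np.unique(key, axis=0, return_index=True)
    return points[np.sort(idx)]


def ring_neighbors(rings) -> list[tuple[int, int]]:
    """All lattice rings edge-adjacent to (but not in) the given set."""
    rings = set(map(tuple, rings))
    out = set()
    for (q, r) in rings:
        for dq, dr in _AXIAL_NEIGHBORS:
            out.add((q + dq, r + dr))
    return sorted(out - rings)


def _rings_connected(rings) -> bool:
    rings = list(map(tuple, rings))
    if len(rings) <= 1:
        return True
    g = nx.Graph()
    g.add_nodes_from(rings)
    rs = set(rings)
    for (q, r) in rings:
        for dq, dr in _AXIAL_NEIGHBORS:
            if (q + dq, r + dr) in rs:
                g.add_edge((q, r), (q + dq, r + dr))
    return nx.is_connected(g)


def _passivate(carbons2d: np.ndarray, cc: float, ch: float) -> np.ndarray:
    """Place one H per missing sp2 neighbor, in-plane along the ideal
    bond direction (the three honeycomb neighbor directions are 120°
    apart, so missing directions follow from the present ones)."""
    n = len(carbons2d)
    if n == 0:
        return np.zeros((0, 2))
    diff = carbons2d[:, None, :] - carbons2d[None, :, :]
    dist = np.linalg.norm(diff, axis=-1)
    hydrogens = []
    for i in range(n):
        nb = np.where((dist[i] > 0.1) & (dist[i] < cc * 1.05))[0]
        dirs = [(carbons2d[j] - carbons2d[i]) / dist[i, j] for j in nb]
        if len(dirs) >= 3:
            continue
        if len(dirs) == 2:
            m = -(dirs[0] + dirs[1])
            m /= np.linalg.norm(m)
            hydrogens.append(carbons2d[i] + ch * m)
        elif len(dirs) == 1:
            for sign in (1.0, -1.0):
                th = sign * 2.0 * math.pi / 3.0
                R = np.array([[math.cos(th), -math.sin(th)],
                              [math.sin(th), math.cos(th)]])
                hydrogens.append(carbons2d[i] + ch * (R @ dirs[0]))
        else:
            raise PoreError("isolated carbon cannot be passivated")
    return np.array(hydrogens) if hydrogens else np.zeros((0, 2))


def _to_structure(carbons2d, hydrogens2d, extra=(), metadata="") -> Structure:
    els = ["C"] * len(carbons2d) + ["H"] * len(hydrogens2d)
    pts = [np.hstack([carbons2d, np.zeros((len(carbons2d), 1))]),
           np.hstack([hydrogens2d, np.zeros((len(hydrogens2d), 1))])]
    coords = np.vstack([p for p in pts if len(p)])
    st = Structure(els, coords, charges=np.zeros(len(els)), metadata=metadata)
    return st


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------

def build_graphene_flake(rings, lattice: LatticeSpec | None = None) -> GrapheneFlake:
    """Build a planar H-terminated graphene flake from hexagon indices.

    ``rings`` are axial (q, r) indices of the hexagons to include; they
    must form a connected layout.
    """
    lattice = lattice or LatticeSpec()
    rings = [tuple(r) for r in rings]
    if not rings:
        raise PoreError("empty ring layout")
    if not _rings_connected(rings):
        raise PoreError("disconnected ring layout")
    pts = np.vstack([_ring_vertices(_ring_center(q, r, lattice.cc_bond),
                                    lattice.cc_bond) for q, r in rings])
    carbons = _dedupe(pts)
    hydrogens = _passivate(carbons, lattice.cc_bond, lattice.ch_bond)
    st = _to_structure(carbons, hydrogens,
                       metadata=f"graphene flake, {len(rings)} rings")
    return GrapheneFlake(st, rings, lattice)


def cut_pore(flake: GrapheneFlake, rings_to_remove,
             convention: str = "geometric") -> PoreModel:
    """Remove whole rings from a flake and re-passivate the cut edge.

    Every carbon that is a vertex of a removed ring is deleted (shared
    vertices included); carbons left with fewer than three neighbors get
    in-plane hydrogens along the former bond directions.  The pore center
    is the centroid of the removed-ring centers.
    """
    rings_to_remove = [tuple(r) for r in rings_to_remove]
    lattice = flake.lattice
    if not rings_to_remove:
        st = flake.structure.copy()
        centroid = st.coords.mean(axis=0)
        return PoreModel(st, centroid, np.array([0.0, 0.0, 1.0]), [],
                         diameter=None, convention=None, porous=False)
    unknown = set(rings_to_remove) - set(flake.rings)
    if unknown:
        raise PoreError(f"rings not in flake: {sorted(unknown)}")
    if not _rings_connected(rings_to_remove):
        raise PoreError("rings_to_remove must form a connected set")
    cc, ch = lattice.cc_bond, lattice.ch_bond
    keep2d = np.vstack([_ring_vertices(_ring_center(q, r, cc), cc)
                        for q, r in flake.rings])
    keep2d = _dedupe(keep2d)
    rem2d = np.vstack([_ring_vertices(_ring_center(q, r, cc), cc)
                       for q, r in rings_to_remove])
    remkeys = {tuple(k) for k in np.round(rem2d / 1e-6).astype(np.int64)}
    mask = np.array([tuple(k) not in remkeys
                     for k in np.round(keep2d / 1e-6).astype(np.int64)])
    carbons = keep2d[mask]
    if len(carbons) == 0:
        raise PoreError("removal deletes the whole flake")
    hydrogens = _passivate(carbons, cc, ch)
    st = _to_structure(carbons, hydrogens,
                       metadata=f"graphene pore, {len(rings_to_remove)} rings removed")
    if not _carbons_connected(st):
        raise PoreError("removing these rings disconnects the flake")
    c2d = np.mean([_ring_center(q, r, cc) for q, r in rings_to_remove], axis=0)
    center = np.array([c2d[0], c2d[1], 0.0])
    normal = np.array([0.0, 0.0, 1.0])
    pore = PoreModel(st, center, normal, rim_indices=[0], porous=True)
    pore.rim_indices = detect_rim(pore)
    pore.diameter = pore_diameter(pore, convention)
    pore.convention = convention
    return pore


def _carbons_connected(st: Structure) -> bool:
    g = bond_graph(st)
    heavy = [i for i, e in enumerate(st.elements) if e != "H"]
    return nx.is_connected(g.subgraph(heavy))


def build_graphdiyne_pore(lattice: LatticeSpec | None = None,
                          convention: str = "geometric") -> PoreModel:
    """Single triangular graphdiyne pore unit.

    Three benzene rings sit at the corners of an equilateral triangle and
    are joined pairwise by diacetylene (-C#C-C#C-) links; the remaining
    ring positions are H-terminated.  The model is threefold symmetric
    about the pore center by construction.
    """
    lat = lattice or LatticeSpec()
    ar, sb, tb, cb, ch = (lat.gdy_aromatic, lat.gdy_single, lat.gdy_triple,
                          lat.gdy_inter, lat.ch_bond)
    L = 2 * ar + 2 * sb + 2 * tb + cb          # ring-center to ring-center
    Rc = L / math.sqrt(3.0)                    # centroid to ring center
    corners = [Rc * np.array([math.cos(a), math.sin(a)])
               for a in (math.pi / 2,
                         math.pi / 2 + 2 * math.pi / 3,
                         math.pi / 2 + 4 * math.pi / 3)]
    els: list[str] = []
    pts: list[np.ndarray] = []
    for ci, c in enumerate(corners):
        towards = [corners[(ci + 1) % 3] - c, corners[(ci + 2) % 3] - c]
        angs = [math.atan2(t[1], t[0]) for t in towards]
        for k in range(6):
            a = angs[0] + k * math.pi / 3.0
            d = np.array([math.cos(a), math.sin(a)])
            els.append("C")
            pts.append(c + ar * d)
            # substituent: chain toward another corner, else H
            is_link = any(abs((a - a0 + math.pi) % (2 * math.pi) - math.pi) < 1e-9
                          for a0 in angs)
            if not is_link:
                els.append("H")
                pts.append(c + (ar + ch) * d)
    for i in range(3):
        c1, c2 = corners[i], corners[(i + 1) % 3]
        d = (c2 - c1) / np.linalg.norm(c2 - c1)
        s = ar
        for bond in (sb, tb, cb, tb):
            s += bond
            els.append("C")
            pts.append(c1 + s * d)
    pts2d = np.array(pts)
    key = np.round(pts2d / 1e-6).astype(np.int64)
    _, idx = np.unique(key, axis=0, return_index=True)
    order = np.sort(idx)
    els = [els[i] for i in order]
    coords = np.hstack([pts2d[order], np.zeros((len(order), 1))])
    st = Structure(els, coords, charges=np.zeros(len(els)),
                   metadata="graphdiyne triangular pore unit")
    pore = PoreModel(st, np.zeros(3), np.array([0.0, 0.0, 1.0]),
                     rim_indices=[0], porous=True)
    pore.rim_indices = detect_rim(pore)
    pore.diameter = pore_diameter(pore, convention)
    pore.convention = convention
    return pore


# ---------------------------------------------------------------------------
# bond graph and rim detection
# ---------------------------------------------------------------------------

def bond_graph(st: Structure, scale: float = 1.25) -> nx.Graph:
    """Covalent bond graph: atoms bonded when closer than
    ``scale * (r_cov_i + r_cov_j)``."""
    g = nx.Graph()
    g.add_nodes_from(range(st.n_atoms))
    rc = np.array([ELEMENTS[e].covalent_radius for e in st.elements])
    diff = st.coords[:, None, :] - st.coords[None, :, :]
    dist = np.linalg.norm(diff, axis=-1)
    cut = scale * (rc[:, None] + rc[None, :])
    ii, jj = np.where((dist < cut) & (dist > 0.1))
    g.add_edges_from((int(i), int(j)) for i, j in zip(ii, jj) if i < j)
    return g


def _plane_basis(normal: np.ndarray):
    n = normal / np.linalg.norm(normal)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(n @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(n, ref)
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    return u, v


def _hole_face_cycle(st: Structure, center: np.ndarray,
                     normal: np.ndarray) -> list[int]:
    """Walk the face of the planar heavy-atom bond graph that contains
    the pore center, via clockwise-next half-edge traversal."""
    g = bond_graph(st)
    heavy = [i for i, e in enumerate(st.elements) if e != "H"]
    sub = g.subgraph(heavy)
    u_ax, v_ax = _plane_basis(normal)
    p2 = {i: np.array([(st.coords[i] - center) @ u_ax,
                       (st.coords[i] - center) @ v_ax]) for i in heavy}

    def face_from(u, v):
        """Traverse the face lying to the left of directed edge u->v."""
        cyc = [u]
        first = (u, v)
        for _ in range(4 * st.n_atoms):
            cyc.append(v)
            nbrs = [w for w in sub.neighbors(v) if w != u]
            if not nbrs:
                back = u  # dead end: bounce back
                u, v = v, back
            else:
                a_in = math.atan2(*(p2[u] - p2[v])[::-1])
                # most clockwise neighbor from the incoming edge
                best = min(
                    nbrs,
                    key=lambda w: (math.atan2(*(p2[w] - p2[v])[::-1]) - a_in)
                    % (2 * math.pi),
                )
                u, v = v, best
            if (u, v) == first:
                return cyc[:-1] if cyc[-1] == first[0] else cyc
        return None

    def contains_center(cycle) -> bool:
        poly = np.array([p2[i] for i in cycle])
        # winding number of origin
        x, y = poly[:, 0], poly[:, 1]
        x2, y2 = np.roll(x, -1), np.roll(y, -1)
        ang = np.arctan2(x * y2 - y * x2, x * x2 + y * y2)
        return abs(ang.sum()) > math.pi

    # start from edges incident to atoms nearest the center
    order = sorted(heavy, key=lambda i: float(np.linalg.norm(p2[i])))
    seen = set()
    for u in order[:8]:
        for v in sub.neighbors(u):
            for a, b in ((u, v), (v, u)):
                if (a, b) in seen:
                    continue
                cyc = face_from(a, b)
                if cyc is None:
                    continue
                seen.update(zip(cyc, cyc[1:] + cyc[:1]))
                if len(cyc) >= 3 and contains_center(cyc):
                    return cyc
    raise PoreError("no hole found")


def detect_rim(pore: PoreModel, window: float = 1.5) -> list[int]:
    """Atoms bordering the pore opening.

    The enclosing cycle of the heavy-atom bond graph around the pore
    center is located by planar face traversal; the rim is that cycle
    plus attached hydrogens, filtered to atoms within ``window`` Å of the
    closest approach to the center (so outward-pointing edge atoms are
    excluded).
    """
    if not pore.porous:
        raise PoreError("no hole found")
    st = pore.structure
    cyc = _hole_face_cycle(st, pore.center, pore.normal)
    g = bond_graph(st)
    cand = set(cyc)
    for i in cyc:
        for j in g.neighbors(i):
            if st.elements[j] == "H":
                cand.add(j)
    d = {i: float(np.linalg.norm(st.coords[i] - pore.center)) for i in cand}
    dmin = min(d.values())
    return sorted(i for i in cand if d[i] < dmin + window)


# ---------------------------------------------------------------------------
# diameter
# ---------------------------------------------------------------------------

DIAMETER_CONVENTIONS = ("geometric", "vdw")
#: Convention calibrated against the reference 6.0 / 5.6 / 5.6 Å openings.
CALIBRATED_CONVENTION = "geometric"


def pore_diameter(pore: PoreModel, convention: str = CALIBRATED_CONVENTION) -> float:
    """Pore diameter: twice the largest in-plane inscribed-circle radius.

    ``geometric`` measures to rim-atom nuclei; ``vdw`` subtracts each rim
    atom's van der Waals radius (the limiting atoms' radii end up
    subtracted from the diameter).  Deterministic: the maximization over
    circle centers uses a fixed grid of Nelder-Mead starts.
    """
    if convention not in DIAMETER_CONVENTIONS:
        raise PoreError(f"unknown diameter convention: {convention!r}")
    if not pore.porous:
        raise PoreError("non-porous model has no diameter")
    st = pore.structure
    rim = pore.rim_indices
    u_ax, v_ax = _plane_basis(pore.normal)
    rel = st.coords[rim] - pore.center
    pts = np.stack([rel @ u_ax, rel @ v_ax], axis=1)
    if convention == "vdw":
        corr = np.array([ELEMENTS[st.elements[i]].vdw_radius for i in rim])
    else:
        corr = np.zeros(len(rim))

    def neg_clearance(p):
        return -(np.min(np.linalg.norm(pts - p, axis=1) - corr))

    best = None
    for dx in np.linspace(-1.0, 1.0, 7):
        for dy in np.linspace(-1.0, 1.0, 7):
            res = minimize(neg_clearance, np.array([dx, dy]),
                           method="Nelder-Mead",
                           options={"xatol": 1e-8, "fatol": 1e-10,
                                    "maxiter": 400})
            if best is None or res.fun < best:
                best = float(res.fun)
    return -2.0 * best


# ---------------------------------------------------------------------------
# modifications
# ---------------------------------------------------------------------------

def substitute_nitrogen(pore: PoreModel, carbon_indices) -> PoreModel:
    """Replace rim C-H units by N (pyridinic substitution).

    Each listed carbon must be a rim carbon bonded to exactly one
    hydrogen; the carbon becomes nitrogen and its hydrogen is deleted,
    shrinking the atom count by one per substitution and slightly
    enlarging the geometric opening.
    """
    carbon_indices = list(carbon_indices)
    if not carbon_indices:
        return pore
    st = pore.structure
    g = bond_graph(st)
    rim = set(pore.rim_indices)
    to_delete = []
    elements = list(st.elements)
    for ci in carbon_indices:
        if ci not in rim or st.elements[ci] != "C":
            raise PoreError(f"atom {ci} is not a rim carbon")
        hs = [j for j in g.neighbors(ci) if st.elements[j] == "H"]
        if len(hs) != 1:
            raise PoreError(f"rim carbon {ci} must carry exactly one H "
                            f"(found {len(hs)})")
        elements[ci] = "N"
        to_delete.append(hs[0])
    keep = [i for i in range(st.n_atoms) if i not in set(to_delete)]
    new = Structure(
        [elements[i] for i in keep],
        st.coords[keep],
        None if st.charges is None else st.charges[keep],
        None if st.atom_types is None else [st.atom_types[i] for i in keep],
        st.metadata + f" | N-substituted at {sorted(carbon_indices)}",
    )
    out = PoreModel(new, pore.center.copy(), pore.normal.copy(),
                    rim_indices=[0], preset=pore.preset, porous=True)
    out.rim_indices = detect_rim(out)
    conv = pore.convention or CALIBRATED_CONVENTION
    out.diameter = pore_diameter(out, conv)
    out.convention = conv
    return out


def attach_group(pore: PoreModel, group: Structure, anchor: int,
                 rim_carbon: int | None = None,
                 bond_length: float = 1.47) -> PoreModel:
    """Attach a rigid side group at a rim carbon, replacing its hydrogen.

    The group's ``anchor`` atom is bonded to the chosen rim carbon along
    the former C-H direction; the group is rotated so its principal
    extension leans away from the membrane plane.
    """
    st = pore.structure
    g = bond_graph(st)
    candidates = ([rim_carbon] if rim_carbon is not None else
                  [i for i in pore.rim_indices if st.elements[i] == "C"])
    site = None
    for ci in candidates:
        hs = [j for j in g.neighbors(ci) if st.elements[j] == "H"]
        if len(hs) == 1:
            site, hyd = ci, hs[0]
            break
    if site is None:
        raise PoreError("no rim carbon with a single H available")
    direction = st.coords[hyd] - st.coords[site]
    direction /= np.linalg.norm(direction)
    # orient group: anchor at origin, mean heavy-atom direction along +x
    gc = group.coords - group.coords[anchor]
    heavy = [i for i, e in enumerate(group.elements) if e != "H" and i != anchor]
    axis = gc[heavy].mean(axis=0) if heavy else np.array([1.0, 0.0, 0.0])
    axis = axis / (np.linalg.norm(axis) + 1e-12)
    # tilt the attachment direction 35 deg out of plane to avoid rim clash
    tilt = 0.6 * pore.normal + direction
    tilt /= np.linalg.norm(tilt)
    rot, _ = _rotation_between(axis, tilt)
    placed = gc @ rot.T + (st.coords[site] + bond_length * tilt)
    keep = [i for i in range(st.n_atoms) if i != hyd]
    base = Structure([st.elements[i] for i in keep], st.coords[keep],
                     None if st.charges is None else st.charges[keep],
                     None, st.metadata + " | gatekeeper attached")
    merged = Structure(
        base.elements + list(group.elements),
        np.vstack([base.coords, placed]),
        np.concatenate([base.charges if base.charges is not None
                        else np.zeros(base.n_atoms),
                        group.charges if group.charges is not None
                        else np.zeros(group.n_atoms)]),
        None, base.metadata)
    out = PoreModel(merged, pore.center.copy(), pore.normal.copy(),
                    rim_indices=[0], preset=(pore.preset or "") + "-gatekeeper",
                    porous=True)
    out.rim_indices = detect_rim(out)
    return out


def _rotation_between(a: np.ndarray, b: np.ndarray):
    """Proper rotation taking unit vector a to unit vector b."""
    v = np.cross(a, b)
    c = float(a @ b)
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3), 0.0
        # antiparallel: rotate pi about any perpendicular axis
        perp = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(a, [0.0, 1.0, 0.0])
        perp /= np.linalg.norm(perp)
        K = np.array([[0, -perp[2], perp[1]],
                      [perp[2], 0, -perp[0]],
                      [-perp[1], perp[0], 0]])
        return np.eye(3) + 2.0 * K @ K, math.pi
    K = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    R = np.eye(3) + K + K @ K * (1.0 / (1.0 + c))
    return R, math.acos(max(-1.0, min(1.0, c)))


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

#: Ring layouts (axial hexagon indices) of the shipped pore presets.
#: graphene4: C3-symmetric hole of a central ring plus three alternating
#: edge-neighbours (a triphenylene-shaped opening); graphene3: compact
#: triangle; graphene5: the graphene4 hole plus one ring filling a notch,
#: used as the gatekeeper host.
PRESET_RING_LAYOUTS: dict[str, list[tuple[int, int]]] = {
    "graphene4": [(0, 0), (1, 0), (-1, 1), (0, -1)],
    "graphene3": [(0, 0), (1, 0), (0, 1)],
    "graphene5": [(0, 0), (1, 0), (-1, 1), (0, -1), (1, -1)],
}


def build_preset(name: str, lattice: LatticeSpec | None = None,
                 convention: str = CALIBRATED_CONVENTION,
                 nsub: str | None = None) -> PoreModel:
    """Build a named pore preset.

    ``name``: graphene4 | graphene3 | graphene5 | graphdiyne |
    graphene5-gatekeeper.  ``nsub`` ('opposite' or 'adjacent') applies
    the two-nitrogen rim substitution relative to the gatekeeper site.
    """
    lattice = lattice or LatticeSpec()
    gatekeeper = name == "graphene5-gatekeeper"
    base_name = "graphene5" if gatekeeper else name
    if base_name == "graphdiyne":
        pore = build_graphdiyne_pore(lattice, convention)
    elif base_name in PRESET_RING_LAYOUTS:
        removed = PRESET_RING_LAYOUTS[base_name]
        flake_rings = removed + ring_neighbors(removed)
        flake = build_graphene_flake(flake_rings, lattice)
        pore = cut_pore(flake, removed, convention)
    else:
        raise PoreError(f"unknown preset: {name!r}")
    pore.preset = base_name
    if nsub is not None:
        pore = _apply_nsub(pore, nsub)
    if gatekeeper:
        from .fixtures import generate_fixture  # local import: layering
        amine = generate_fixture("aminoethanol")
        pore = attach_group(pore, amine, anchor=_amine_nitrogen(amine))
    return pore


def _amine_nitrogen(st: Structure) -> int:
    for i, e in enumerate(st.elements):
        if e == "N":
            return i
    raise PoreError("group has no nitrogen anchor")


def _gatekeeper_site(pore: PoreModel) -> int:
    """Deterministic gatekeeper attachment site: the rim C-H carbon with
    the smallest azimuth about the pore center."""
    st = pore.structure
    g = bond_graph(st)
    best, best_ang = None, None
    for i in pore.rim_indices:
        if st.elements[i] != "C":
            continue
        hs = [j for j in g.neighbors(i) if st.elements[j] == "H"]
        if len(hs) != 1:
            continue
        rel = st.coords[i] - pore.center
        ang = math.atan2(rel[1], rel[0])
        if best is None or ang < best_ang:
            best, best_ang = i, ang
    if best is None:
        raise PoreError("no suitable gatekeeper site on rim")
    return best


def _apply_nsub(pore: PoreModel, mode: str) -> PoreModel:
    """Two-nitrogen rim substitution 'opposite' or 'adjacent' to the
    gatekeeper attachment site."""
    if mode not in ("opposite", "adjacent"):
        raise PoreError(f"nsub must be 'opposite' or 'adjacent', got {mode!r}")
    st = pore.structure
    g = bond_graph(st)
    site = _gatekeeper_site(pore)
    ref = st.coords[site] - pore.center
    ref /= np.linalg.norm(ref)
    scored = []
    for i in pore.rim_indices:
        if i == site or st.elements[i] != "C":
            continue
        hs = [j for j in g.neighbors(i) if st.elements[j] == "H"]
        if len(hs) != 1:
            continue
        rel = st.coords[i] - pore.center
        cosang = float(rel @ ref / np.linalg.norm(rel))
        scored.append((cosang, i))
    scored.sort()
    if len(scored) < 2:
        raise PoreError("not enough substitutable rim carbons")
    if mode == "opposite":
        chosen = [i for _, i in scored[:2]]        # most anti-aligned
    else:
        chosen = [i for _, i in sorted(scored, reverse=True)[:2]]
    return substitute_nitrogen(pore, chosen)


# ---------------------------------------------------------------------------
# sidecar I/O
# ---------------------------------------------------------------------------

def write_pore(pore: PoreModel, xyz_path) -> None:
    """Write XYZ plus a plain-text key=value sidecar (<xyz>.meta)."""
    from .molsys import write_xyz
    write_xyz(pore.structure, xyz_path)
    meta = str(xyz_path) + ".meta"
    with open(meta, "w") as fh:
        fh.write(f"preset = {pore.preset or ''}\n")
        fh.write(f"porous = {int(pore.porous)}\n")
        fh.write("center = " + " ".join(f"{v:.8f}" for v in pore.center) + "\n")
        fh.write("normal = " + " ".join(f"{v:.8f}" for v in pore.normal) + "\n")
        fh.write("rim_indices = " + ",".join(map(str, pore.rim_indices)) + "\n")
        if pore.diameter is not None:
            fh.write(f"diameter = {pore.diameter:.6f}\n")
            fh.write(f"convention = {pore.convention}\n")


def read_pore(xyz_path) -> PoreModel:
    from .molsys import read_xyz
    st = read_xyz(xyz_path)
    meta: dict[str, str] = {}
    with open(str(xyz_path) + ".meta") as fh:
        for line in fh:
            if "=" in line:
                k, v = line.split("=", 1)
                meta[k.strip()] = v.strip()
    porous = bool(int(meta.get("porous", "1")))
    rim = ([int(x) for x in meta["rim_indices"].split(",") if x]
           if meta.get("rim_indices") else [])
    pore = PoreModel(
        st,
        np.array([float(x) for x in meta["center"].split()]),
        np.array([float(x) for x in meta["normal"].split()]),
        rim_indices=rim,
        diameter=float(meta["diameter"]) if "diameter" in meta else None,
        convention=meta.get("convention") or None,
        preset=meta.get("preset") or None,
        porous=porous,
    )
    return pore
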