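"""Deterministic molecular fixtures.

Every probe and template molecule used by the toolkit is generated here
from idealized internal coordinates (literature bond lengths and angles,
no optimization), so the whole test matrix is reproducible bit-for-bit
with no external data.  Partial charges are small, hand-assigned values
chosen to give each functional group a sensible dipole; they are
synthetic fixture charges for the internal LJ+Coulomb engine, not fitted
force-field charges.

Fixture ids
-----------
``co2_like``     linear O=C=O, r(C-O) = 1.16 Å (cigar-shaped probe)
``ch4_like``     tetrahedral CH4, r(C-H) = 1.09 Å (near-spherical probe)
``ethane_like``  staggered C2H6, r(C-C) = 1.54 Å (corrugated probe)
``chiral_probe`` CHFClBr: one carbon with four distinct halide/H sites
``aminoethanol`` 1-aminoethanol CH3-CH(OH)-NH2, a chiral gatekeeper
``template_library``  five chiral organic templates (acid, aldehyde,
                 alcohol, olefinic alcohol, ether), both enantiomers
"""

from __future__ import annotations

import math

import numpy as np

from .molsys import Structure, mirror

__all__ = ["generate_fixture", "generate_template_library", "enantiomer_pair",
           "FIXTURE_IDS", "TEMPLATE_LABELS"]

TETRA = math.degrees(math.acos(-1.0 / 3.0))  # 109.4712... tetrahedral angle

# tetrahedral unit directions around a stereocenter
_T = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]]) / math.sqrt(3)


def _frame(d: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Right-handed orthonormal frame with first axis along d."""
    d = d / np.linalg.norm(d)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(d @ ref) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    u = np.cross(d, ref)
    u /= np.linalg.norm(u)
    v = np.cross(d, u)
    return d, u, v


def _cone(d, u, v, angle_deg: float, azimuth_deg: float) -> np.ndarray:
    """Unit vector at ``angle`` from d, at the given azimuth about d."""
    a = math.radians(angle_deg)
    b = math.radians(azimuth_deg)
    return (math.cos(a) * d
            + math.sin(a) * (math.cos(b) * u + math.sin(b) * v))


class _Builder:
    def __init__(self):
        self.elements: list[str] = []
        self.coords: list[np.ndarray] = []
        self.charges: list[float] = []

    def add(self, el: str, pos, q: float = 0.0) -> int:
        self.elements.append(el)
        self.coords.append(np.asarray(pos, float))
        self.charges.append(q)
        return len(self.elements) - 1

    def structure(self, metadata: str) -> Structure:
        return Structure(self.elements, np.array(self.coords),
                         charges=np.array(self.charges), metadata=metadata)


# --- substituent groups -----------------------------------------------------
# Each group is attached at point ``p`` (the stereocenter) along unit
# direction ``d``; bond lengths in Å, angles idealized.

def _grp_h(b: _Builder, p, d, q=0.06):
    b.add("H", p + 1.09 * d, q)


def _grp_methyl(b: _Builder, p, d, qc=-0.18, qh=0.06):
    c = p + 1.54 * d
    b.add("C", c, qc)
    dd, u, v = _frame(d)
    for az in (0.0, 120.0, 240.0):
        b.add("H", c + 1.09 * _cone(dd, u, v, 180.0 - TETRA, az), qh)


def _grp_ethyl(b: _Builder, p, d):
    c1 = p + 1.54 * d
    b.add("C", c1, -0.12)
    dd, u, v = _frame(d)
    for az in (120.0, 240.0):
        b.add("H", c1 + 1.09 * _cone(dd, u, v, 180.0 - TETRA, az), 0.06)
    d2 = _cone(dd, u, v, 180.0 - TETRA, 0.0)
    _grp_methyl(b, c1, d2)


def _grp_hydroxyl(b: _Builder, p, d, phase=0.0):
    o = p + 1.43 * d
    b.add("O", o, -0.40)
    dd, u, v = _frame(d)
    b.add("H", o + 0.96 * _cone(dd, u, v, 180.0 - 104.5, phase), 0.35)


def _grp_amino(b: _Builder, p, d):
    n = p + 1.47 * d
    b.add("N", n, -0.50)
    dd, u, v = _frame(d)
    for az in (60.0, 300.0):
        b.add("H", n + 1.01 * _cone(dd, u, v, 180.0 - 107.0, az), 0.28)


def _grp_aldehyde(b: _Builder, p, d):
    c = p + 1.50 * d
    b.add("C", c, 0.30)
    dd, u, v = _frame(d)
    b.add("O", c + 1.21 * _cone(dd, u, v, 60.0, 0.0), -0.38)
    b.add("H", c + 1.10 * _cone(dd, u, v, 60.0, 180.0), 0.05)


def _grp_carboxyl(b: _Builder, p, d):
    c = p + 1.52 * d
    b.add("C", c, 0.52)
    dd, u, v = _frame(d)
    b.add("O", c + 1.21 * _cone(dd, u, v, 59.0, 0.0), -0.44)
    o2 = c + 1.34 * _cone(dd, u, v, 69.0, 180.0)
    b.add("O", o2, -0.45)
    doh = (o2 - c) / np.linalg.norm(o2 - c)
    d2, u2, v2 = _frame(doh)
    b.add("H", o2 + 0.96 * _cone(d2, u2, v2, 180.0 - 106.0, 0.0), 0.37)


def _grp_methoxy(b: _Builder, p, d):
    o = p + 1.43 * d
    b.add("O", o, -0.36)
    dd, u, v = _frame(d)
    d2 = _cone(dd, u, v, 180.0 - 111.0, 0.0)
    c = o + 1.43 * d2
    b.add("C", c, 0.05)
    d3, u3, v3 = _frame(d2)
    for az in (0.0, 120.0, 240.0):
        b.add("H", c + 1.09 * _cone(d3, u3, v3, 180.0 - TETRA, az), 0.05)


def _grp_vinyl(b: _Builder, p, d):
    c1 = p + 1.50 * d
    b.add("C", c1, -0.10)
    dd, u, v = _frame(d)
    b.add("H", c1 + 1.09 * _cone(dd, u, v, 60.0, 180.0), 0.08)
    c2 = c1 + 1.33 * _cone(dd, u, v, 58.0, 0.0)
    b.add("C", c2, -0.18)
    d2 = (c2 - c1) / np.linalg.norm(c2 - c1)
    e2, u2, v2 = _frame(d2)
    b.add("H", c2 + 1.09 * _cone(e2, u2, v2, 60.0, 0.0), 0.08)
    b.add("H", c2 + 1.09 * _cone(e2, u2, v2, 60.0, 180.0), 0.08)


_GROUPS = {
    "H": _grp_h, "methyl": _grp_methyl, "ethyl": _grp_ethyl,
    "hydroxyl": _grp_hydroxyl, "amino": _grp_amino,
    "aldehyde": _grp_aldehyde, "carboxyl": _grp_carboxyl,
    "methoxy": _grp_methoxy, "vinyl": _grp_vinyl,
}


def _stereocenter(groups: tuple[str, str, str, str], metadata: str,
                  qc: float = 0.15) -> Structure:
    """Carbon stereocenter with four substituents on tetrahedral axes.

    With four distinct groups the result is chiral; the mirror image is
    the opposite enantiomer.
    """
    b = _Builder()
    b.add("C", np.zeros(3), qc)
    for grp, d in zip(groups, _T):
        _GROUPS[grp](b, np.zeros(3), d)
    st = b.structure(metadata)
    q = st.charges
    q -= q.sum() / len(q)  # enforce strict neutrality
    return st


# --- probes -----------------------------------------------------------------

def _co2_like() -> Structure:
    b = _Builder()
    b.add("C", [0.0, 0.0, 0.0], 0.6512)
    b.add("O", [0.0, 0.0, 1.16], -0.3256)
    b.add("O", [0.0, 0.0, -1.16], -0.3256)
    return b.structure("co2_like: linear O=C=O, r(CO)=1.16")


def _ch4_like() -> Structure:
    """Tetrahedral CH4 oriented for membrane scans: one C-H axis along
    the scan axis with the tip hydrogen pointing to +z.  Scanning from
    negative z the tip then reaches (and threads) the pore first, which
    puts the adsorption global minimum on the negative-z side."""
    b = _Builder()
    b.add("C", np.zeros(3), -0.24)
    b.add("H", 1.09 * np.array([0.0, 0.0, 1.0]), 0.06)
    for az in (0.0, 120.0, 240.0):
        a = math.radians(TETRA)   # polar angle from +z
        d = np.array([math.sin(a) * math.cos(math.radians(az)),
                      math.sin(a) * math.sin(math.radians(az)),
                      math.cos(a)])
        b.add("H", 1.09 * d, 0.06)
    return b.structure("ch4_like: tetrahedral, r(CH)=1.09, tip along +z")


def _ethane_like() -> Structure:
    b = _Builder()
    z = np.array([0.0, 0.0, 1.0])
    c1 = b.add("C", -0.77 * z, -0.18)
    c2 = b.add("C", 0.77 * z, -0.18)
    d1, u, v = _frame(-z)
    for az in (0.0, 120.0, 240.0):
        b.add("H", b.coords[c1] + 1.09 * _cone(d1, u, v, 180.0 - TETRA, az),
              0.06)
    d2, u2, v2 = _frame(z)
    # same azimuth set on both carbons: the mirrored local frames of the
    # +z / -z cones then put the methyls exactly 60 deg apart (staggered)
    for az in (0.0, 120.0, 240.0):
        b.add("H", b.coords[c2] + 1.09 * _cone(d2, u2, v2, 180.0 - TETRA, az),
              0.06)
    return b.structure("ethane_like: staggered, r(CC)=1.54, r(CH)=1.09")


def _chiral_probe() -> Structure:
    """CHFClBr: the minimal chiral tetrahedral probe.

    The four sites are deliberately size-mismatched (H vs Br) and the
    charges set up one strong directional H···F contact, so the
    lowest-energy dimer geometry -- and with it the complex size --
    depends visibly on the relative chirality of the two monomers."""
    b = _Builder()
    b.add("C", np.zeros(3), 0.0)
    b.add("H", 1.09 * _T[0], 0.30)
    b.add("F", 1.35 * _T[1], -0.40)
    b.add("Cl", 1.77 * _T[2], 0.10)
    b.add("Br", 1.94 * _T[3], 0.0)
    return b.structure("chiral_probe: CHFClBr tetrahedral stereocenter")


def _aminoethanol() -> Structure:
    return _stereocenter(("H", "methyl", "hydroxyl", "amino"),
                         "aminoethanol: CH3-CH(OH)-NH2 gatekeeper template")


TEMPLATE_LABELS = ("acid", "aldehyde", "alcohol", "olef_alcohol", "ether")

_TEMPLATE_GROUPS: dict[str, tuple[str, str, str, str]] = {
    "acid": ("H", "methyl", "ethyl", "carboxyl"),
    "aldehyde": ("H", "methyl", "ethyl", "aldehyde"),
    "alcohol": ("H", "methyl", "ethyl", "hydroxyl"),
    "olef_alcohol": ("H", "methyl", "vinyl", "hydroxyl"),
    "ether": ("H", "methyl", "ethyl", "methoxy"),
}

FIXTURE_IDS = ("chiral_probe", "co2_like", "ch4_like", "ethane_like",
               "aminoethanol") + TEMPLATE_LABELS


def generate_fixture(fixture_id: str) -> Structure:
    """Deterministic idealized geometry for a named fixture id."""
    if fixture_id == "co2_like":
        return _co2_like()
    if fixture_id == "ch4_like":
        return _ch4_like()
    if fixture_id == "ethane_like":
        return _ethane_like()
    if fixture_id == "chiral_probe":
        return _chiral_probe()
    if fixture_id == "aminoethanol":
        return _aminoethanol()
    if fixture_id in _TEMPLATE_GROUPS:
        return _stereocenter(_TEMPLATE_GROUPS[fixture_id],
                             f"{fixture_id} template")
    raise ValueError(f"unknown fixture id: {fixture_id!r}")


def enantiomer_pair(fixture_id: str) -> tuple[Structure, Structure]:
    """(R-like, S-like) pair: the built geometry and its mirror image.

    The R/S labels are bookkeeping labels of the toolkit, not CIP
    assignments; what matters downstream is that the two are exact
    mirror images.
    """
    s = generate_fixture(fixture_id)
    r = mirror(s)
    r.metadata = s.metadata + " (mirrored enantiomer)"
    return r, s


def generate_template_library() -> list[tuple[str, Structure, Structure]]:
    """The five chiral template molecules as (label, R, S) triples."""
    out = []
    for label in TEMPLATE_LABELS:
        r, s = enantiomer_pair(label)
        out.append((label, r, s))
    return out
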