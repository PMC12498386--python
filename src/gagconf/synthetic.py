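"""Synthetic conformer and ensemble generation for heparin-like chains.

Everything the analysis pipeline consumes can be generated here without any
external data: idealized pyranose rings at canonical Cremer–Pople
coordinates, dodecamer chains with prescribed glycosidic torsions and ring
puckers, and stochastic ensembles with known state populations.

The ring model is deliberately reduced: the six ring atoms (O5, C1–C5) are
placed exactly on the Cremer–Pople displacement pattern, the glycosidic
oxygen O4 is explicit, and sulfate / N-sulfo / carboxylate / hydroxyl
substituents are single united pseudo-atoms carrying the mass of the whole
group. Mass-weighted descriptors and all torsion definitions only involve
these sites, so full substituent geometry is unnecessary for testing the
pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .geometry import torsion_angle, wrap_angle
from .structure import (
    PSEUDO_ATOM_MASSES,
    Ensemble,
    Structure,
    TopologyError,
    mass_of,
)

# Ring atoms in Cremer-Pople order (j = 1..6). O5 first is the carbohydrate
# convention; the ring is traversed O5 -> C1 -> ... -> C5.
RING_ATOM_ORDER = ("O5", "C1", "C2", "C3", "C4", "C5")

#: canonical puckering amplitude for pyranoses, Å
DEFAULT_Q = 0.57

#: target ring bond length used when realizing CP coordinates, Å
_RING_BOND_LENGTH = 1.49

#: realistic pyranose ring bond targets, Å: bond j connects ring atoms j and
#: j+1 in CP order (O5-C1, C1-C2, C2-C3, C3-C4, C4-C5, C5-O5)
_PYRANOSE_BONDS = (1.43, 1.52, 1.52, 1.52, 1.52, 1.43)
#: ring valence angle targets, degrees, per atom in CP order (112° at O5)
_PYRANOSE_ANGLES = (112.0, 110.0, 110.0, 110.0, 110.0, 110.0)

GLCNS = "GlcNS(6S)"
IDOA = "IdoA(2S)"


class ChainBuildError(ValueError):
    """Raised when chain assembly produces a steric clash."""


@dataclass(frozen=True)
class CPParameters:
    """Cremer–Pople puckering coordinates of a six-membered ring.

    Q is the total puckering amplitude in Å (Q = 0 is the planar ring),
    theta the polar angle in degrees (0 and 180 are the two chairs, 90 the
    boat/twist-boat equator), phi2 the pseudorotation phase in degrees.
    """

    Q: float
    theta: float
    phi2: float = 0.0

    def __post_init__(self) -> None:
        if self.Q < 0:
            raise ValueError("puckering amplitude Q must be >= 0")
        if self.Q > 1.0:
            raise ValueError(f"non-physical puckering amplitude Q = {self.Q} Å")
        if not 0.0 <= self.theta <= 180.0:
            raise ValueError("theta must lie in [0, 180] degrees")


def _cp_z_displacements(cp: CPParameters) -> np.ndarray:
    """Out-of-plane displacement z_j for j = 1..6 (CP convention, N = 6)."""
    j = np.arange(6)
    q2 = cp.Q * np.sin(np.radians(cp.theta))
    q3 = cp.Q * np.cos(np.radians(cp.theta))
    phi2 = np.radians(cp.phi2)
    z = np.sqrt(1.0 / 3.0) * q2 * np.cos(phi2 + 2.0 * np.pi * 2.0 * j / 6.0)
    z += np.sqrt(1.0 / 6.0) * q3 * ((-1.0) ** j)
    return z


def _uniform_ring_xy(z: np.ndarray, bond: float) -> np.ndarray:
    """Regular-hexagon projection with adjacent-atom distance near ``bond``."""
    dz2 = (np.roll(z, -1) - z) ** 2
    r2 = bond**2 - dz2.mean()
    if r2 <= 0:
        raise ValueError("puckering amplitude too large to close the ring")
    # for a regular hexagon the side equals the circumradius
    radius = np.sqrt(r2)
    ang = -2.0 * np.pi * np.arange(6) / 6.0
    return np.column_stack([radius * np.cos(ang), radius * np.sin(ang)])


def _pyranose_ring_xy(z: np.ndarray) -> np.ndarray:
    """In-plane coordinates fitted to realistic pyranose bonds and angles.

    Only x/y are optimized; the CP out-of-plane pattern ``z`` is held fixed,
    so the Cremer–Pople parameters of the result are exactly those of the
    input (the CP mean plane stays the xy-plane because the displacement
    pattern has no first-order Fourier component).
    """
    from scipy.optimize import least_squares

    x0 = _uniform_ring_xy(z, _RING_BOND_LENGTH).ravel()

    def residuals(x: np.ndarray) -> list[float]:
        pos = np.column_stack([x.reshape(6, 2), z])
        out = []
        for j in range(6):
            d = np.linalg.norm(pos[(j + 1) % 6] - pos[j])
            out.append(200.0 * (d - _PYRANOSE_BONDS[j]))
        for j in range(6):
            u = pos[(j - 1) % 6] - pos[j]
            v = pos[(j + 1) % 6] - pos[j]
            cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
            ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
            out.append(0.05 * (ang - _PYRANOSE_ANGLES[j]))
        return out

    sol = least_squares(residuals, x0, method="lm", max_nfev=10000)
    return sol.x.reshape(6, 2)


def build_pyranose_ring(cp: CPParameters, bond_profile: str = "pyranose") -> Structure:
    """Realize CP coordinates as a six-atom ring Structure (O5, C1..C5).

    Atoms are placed around a hexagonal projection (clockwise seen from +z,
    which makes +z the side from which the ring numbering runs clockwise —
    the reference side for conformer designations) with the exact CP
    out-of-plane pattern.

    ``bond_profile`` selects the in-plane geometry: "pyranose" (default)
    fits realistic alternating C-O/C-C bond lengths and valence angles;
    "uniform" uses a regular hexagonal projection with all bonds equal
    (convenient for symmetry arguments — an ideal chair then has six ring
    torsions of exactly equal magnitude).
    """
    z = _cp_z_displacements(cp)
    if bond_profile == "uniform":
        xy = _uniform_ring_xy(z, _RING_BOND_LENGTH)
    elif bond_profile == "pyranose":
        xy = _pyranose_ring_xy(z)
    else:
        raise ValueError(f"unknown bond_profile {bond_profile!r}")
    pos = np.column_stack([xy, z])
    names = list(RING_ATOM_ORDER)
    elements = [n[0] for n in names]  # "O" or "C"
    masses = np.array([mass_of(n, e) for n, e in zip(names, elements)])
    return Structure(
        atom_names=names,
        elements=elements,
        masses=masses,
        residue_indices=np.ones(6, dtype=int),
        residue_types=["pyranose"] * 6,
        positions=pos,
    )


# ---------------------------------------------------------------------------
# Conformer designation (4C1 / 1C4 / twist-boats) from geometry
# ---------------------------------------------------------------------------

# Out-of-plane atom pairs admissible for twist-boat (skew) designations, in
# IUPAC preference order: the pair containing the lowest-numbered exoplanar
# carbon is used. Each pair is (superscript-candidate, subscript-candidate)
# as 0-based indices into RING_ATOM_ORDER.
_SKEW_PAIRS = (
    (1, 3),  # C1 / C3
    (1, 5),  # C1 / C5
    (2, 0),  # C2 / O5
)

_SKEW_LABELS = {
    (1, 3): ("1S3", "3S1"),
    (1, 5): ("1S5", "5S1"),
    (2, 0): ("2SO", "OS2"),
}


def _ring_up_direction(pos: np.ndarray) -> np.ndarray:
    """Unit vector to the reference side of the ring.

    Conformer designations place the superscript atom on the side from
    which the ring numbering (O5 -> C1 -> C2 ...) appears clockwise.
    """
    c = pos.mean(axis=0)
    n = np.zeros(3)
    for j in range(6):
        n += np.cross(pos[j] - c, pos[(j + 1) % 6] - c)
    # traversal appears counterclockwise from +n, clockwise from -n
    u = -n
    return u / np.linalg.norm(u)


def _plane_displacements(pos: np.ndarray, plane_idx: Sequence[int], u: np.ndarray):
    """Signed distances along u from the best-fit plane of ``plane_idx``."""
    pts = pos[list(plane_idx)]
    centroid = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - centroid)
    normal = vt[2]
    if np.dot(normal, u) < 0:
        normal = -normal
    disp = (pos - centroid) @ normal
    plane_rms = float(np.sqrt((disp[list(plane_idx)] ** 2).mean()))
    return disp, plane_rms


def designate_ring(ring: Structure) -> str:
    """Name the conformer of an idealized six-membered ring.

    Recognizes the two chairs and the six twist-boats; anything else (boats,
    envelopes, strongly distorted rings, the planar ring) returns "other".
    The chair reference plane is O5-C2-C3-C5 with C1/C4 exoplanar; a
    twist-boat plane is four ring atoms with a meta pair exoplanar on
    opposite sides, preferring the pair containing the lowest-numbered
    carbon.
    """
    pos = ring.positions[[ring.atom_index(1, n) for n in RING_ATOM_ORDER]]
    u = _ring_up_direction(pos)
    scale = float(np.abs(pos[:, :] - pos.mean(axis=0)).max())

    # chair test: plane O5, C2, C3, C5 (0-based 0, 2, 3, 5); C1/C4 out
    disp, plane_rms = _plane_displacements(pos, (0, 2, 3, 5), u)
    amp = max(abs(disp[1]), abs(disp[4]))
    if amp > 0.05 and plane_rms < 0.25 * amp and disp[1] * disp[4] < 0:
        return "4C1" if disp[4] > 0 else "1C4"

    for a, b in _SKEW_PAIRS:
        plane = tuple(k for k in range(6) if k not in (a, b))
        disp, plane_rms = _plane_displacements(pos, plane, u)
        amp = max(abs(disp[a]), abs(disp[b]))
        if amp < 0.05 or plane_rms > 0.15 * amp:
            continue
        if disp[a] * disp[b] >= 0:
            continue
        if abs(abs(disp[a]) - abs(disp[b])) > 0.3 * amp:
            continue
        up_label, down_label = _SKEW_LABELS[(a, b)]
        return up_label if disp[a] > 0 else down_label
    return "other"


from functools import lru_cache


@lru_cache(maxsize=None)
def canonical_cp(state: str, Q: float = DEFAULT_Q) -> CPParameters:
    """CP coordinates of a named canonical conformer, located by search.

    Chairs live at theta = 0/180; twist-boats on the theta = 90 equator at
    odd multiples of 30 degrees in phi2. Instead of transcribing a phase
    convention, every candidate position is built and geometrically
    designated; the match is returned. Deterministic (no randomness).
    """
    candidates = [CPParameters(Q, 0.0, 0.0), CPParameters(Q, 180.0, 0.0)]
    candidates += [
        CPParameters(Q, 90.0, phi2) for phi2 in range(30, 360, 60)
    ]
    for cp in candidates:
        if designate_ring(build_pyranose_ring(cp)) == state:
            return cp
    raise ValueError(f"no canonical CP position found for state {state!r}")


def ring_gamma_delta(ring: Structure) -> tuple[float, float]:
    """(γ, δ) ring dihedrals: γ = C1-C2-C3-C4, δ = C1-O5-C5-C4, degrees."""
    p = {n: ring.atom_position(1, n) for n in RING_ATOM_ORDER}
    gamma = torsion_angle(p["C1"], p["C2"], p["C3"], p["C4"])
    delta = torsion_angle(p["C1"], p["O5"], p["C5"], p["C4"])
    return gamma, delta


def derive_pucker_references(
    Q: float = DEFAULT_Q, half_width: float = 23.0
):
    """Derive the classifier's reference (γ, δ) from canonical conformers.

    Builds ideal 4C1, 1C4, 2SO and 1S3 rings at amplitude Q, measures their
    γ/δ dihedrals, and returns PuckerReference objects; the PuckerReferenceSet
    constructor asserts the ±half_width windows are pairwise disjoint, which
    would otherwise invalidate the classifier.
    """
    from .pucker import PuckerReference, PuckerReferenceSet

    refs = []
    for state in ("4C1", "1C4", "2SO", "1S3"):
        ring = build_pyranose_ring(canonical_cp(state, Q))
        gamma, delta = ring_gamma_delta(ring)
        refs.append(
            PuckerReference(
                state=state,
                gamma_ref=gamma,
                delta_ref=delta,
                half_width=half_width,
            )
        )
    return PuckerReferenceSet(refs)


# ---------------------------------------------------------------------------
# Residue templates and chain assembly
# ---------------------------------------------------------------------------

_TETRAHEDRAL = np.degrees(np.arccos(-1.0 / 3.0))  # 109.47°


def _exocyclic_directions(
    center: np.ndarray, nb1: np.ndarray, nb2: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """The two unit vectors making ~tetrahedral angles with both ring bonds."""
    u1 = (nb1 - center) / np.linalg.norm(nb1 - center)
    u2 = (nb2 - center) / np.linalg.norm(nb2 - center)
    c12 = float(np.dot(u1, u2))
    s = u1 + u2
    n = np.cross(u1, u2)
    ct = np.cos(np.radians(_TETRAHEDRAL))
    a = ct / (1.0 + c12)
    rad2 = 1.0 - a * a * float(np.dot(s, s))
    rad2 = max(rad2, 0.0)
    b = np.sqrt(rad2 / float(np.dot(n, n)))
    return a * s + b * n, a * s - b * n


def _axial_equatorial(
    ring_pos: np.ndarray, center: np.ndarray, d1: np.ndarray, d2: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Split the two exocyclic directions into (axial, equatorial)."""
    u = _ring_up_direction(ring_pos)
    if abs(np.dot(d1, u)) >= abs(np.dot(d2, u)):
        return d1, d2
    return d2, d1


# substituent pseudo-atoms per residue class: atom name -> (ring carbon,
# bond length Å). Masses come from PSEUDO_ATOM_MASSES.
_SUBSTITUENTS = {
    GLCNS: {"SN": ("C2", 1.45), "O3": ("C3", 1.43), "S6": ("C5", 1.52)},
    IDOA: {"S2": ("C2", 1.43), "O3": ("C3", 1.43), "CX": ("C5", 1.52)},
}

_GLYCOSIDIC_BOND = 1.41  # C1-O4, Å
_C4_O4_BOND = 1.43


@dataclass
class _ResidueTemplate:
    names: list[str]
    elements: list[str]
    positions: np.ndarray  # (n, 3)
    link_direction: np.ndarray  # unit vector C1 -> glycosidic oxygen


_template_cache: dict = {}


def _residue_template(residue_type: str, pucker_state: str) -> _ResidueTemplate:
    key = (residue_type, pucker_state)
    if key in _template_cache:
        return _template_cache[key]
    ring = build_pyranose_ring(canonical_cp(pucker_state))
    ring_pos = ring.positions
    by_name = {n: ring_pos[i] for i, n in enumerate(ring.atom_names)}

    names = list(ring.atom_names)
    elements = list(ring.elements)
    positions = [ring_pos[i] for i in range(6)]

    ring_order = {n: i for i, n in enumerate(RING_ATOM_ORDER)}

    def neighbors(atom: str) -> tuple[str, str]:
        i = ring_order[atom]
        return RING_ATOM_ORDER[(i - 1) % 6], RING_ATOM_ORDER[(i + 1) % 6]

    # glycosidic acceptor oxygen O4, equatorial at C4
    nb1, nb2 = neighbors("C4")
    d1, d2 = _exocyclic_directions(by_name["C4"], by_name[nb1], by_name[nb2])
    _, eq = _axial_equatorial(ring_pos, by_name["C4"], d1, d2)
    names.append("O4")
    elements.append("O")
    positions.append(by_name["C4"] + _C4_O4_BOND * eq)

    for sub_name, (carbon, bond) in _SUBSTITUENTS[residue_type].items():
        nb1, nb2 = neighbors(carbon)
        d1, d2 = _exocyclic_directions(by_name[carbon], by_name[nb1], by_name[nb2])
        _, eq = _axial_equatorial(ring_pos, by_name[carbon], d1, d2)
        names.append(sub_name)
        elements.append("X")
        positions.append(by_name[carbon] + bond * eq)

    # anomeric (donor) link direction at C1: the axial exocyclic direction,
    # mimicking the alpha configuration of heparin's 1->4 linkages
    nb1, nb2 = neighbors("C1")
    d1, d2 = _exocyclic_directions(by_name["C1"], by_name[nb1], by_name[nb2])
    ax, _ = _axial_equatorial(ring_pos, by_name["C1"], d1, d2)

    tpl = _ResidueTemplate(
        names=names,
        elements=elements,
        positions=np.array(positions),
        link_direction=ax / np.linalg.norm(ax),
    )
    _template_cache[key] = tpl
    return tpl


def _rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    t = np.radians(angle_deg)
    k = np.array(
        [
            [0, -axis[2], axis[1]],
            [axis[2], 0, -axis[0]],
            [-axis[1], axis[0], 0],
        ]
    )
    return np.eye(3) + np.sin(t) * k + (1 - np.cos(t)) * (k @ k)


def _rotation_aligning(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Proper rotation mapping unit vector a onto unit vector b."""
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate 180° about any perpendicular axis
        perp = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(a, [0.0, 1.0, 0.0])
        return _rotation_about_axis(perp, 180.0)
    k = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + k + k @ k * ((1 - c) / float(np.dot(v, v)))


def _nerf_place(
    a: np.ndarray, b: np.ndarray, c: np.ndarray, bond: float, angle_deg: float, torsion_deg: float
) -> np.ndarray:
    """Place atom d with |cd| = bond, angle(b,c,d), torsion(a,b,c,d)."""
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    ang = np.radians(180.0 - angle_deg)
    tor = np.radians(torsion_deg)
    d_local = bond * np.array(
        [
            np.cos(ang),
            np.sin(ang) * np.cos(tor),
            np.sin(ang) * np.sin(tor),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_chain(
    n_residues: int,
    residue_types: Optional[Sequence[str]] = None,
    linkage_torsions: Optional[Sequence[tuple[float, float]]] = None,
    pucker_states: Optional[Sequence[str]] = None,
    clash_tolerance: float = 1.5,
) -> Structure:
    """Assemble a 1->4 linked chain with prescribed torsions and puckers.

    Residue 1 is the reducing end; residue n+1 is glycosidically bonded as
    donor onto residue n's O4. ``linkage_torsions[k]`` is the (φ, ψ) pair of
    the linkage between residues k+1 (acceptor) and k+2 (donor), with
    φ = O5(n+1)-C1(n+1)-O4(n)-C4(n) and ψ = C1(n+1)-O4(n)-C4(n)-C3(n).

    Raises ChainBuildError if any non-bonded inter-residue atom pair ends up
    closer than ``clash_tolerance`` Å, which usually means the requested
    torsions need revision.
    """
    if n_residues < 2:
        raise ValueError("a chain needs at least 2 residues")
    if residue_types is None:
        residue_types = [GLCNS if i % 2 == 0 else IDOA for i in range(n_residues)]
    if len(residue_types) != n_residues:
        raise ValueError("residue_types length mismatch")
    if linkage_torsions is None:
        # donor residue is k+2 (0-based k+1): GlcNS donors sit at the
        # (φ,ψ)≈(−70°,120°) minimum, IdoA donors near (60°,60°)
        linkage_torsions = [
            (-70.0, 120.0) if residue_types[k + 1] == GLCNS else (60.0, 60.0)
            for k in range(n_residues - 1)
        ]
    if len(linkage_torsions) != n_residues - 1:
        raise ValueError("need n_residues - 1 (φ, ψ) pairs")
    if pucker_states is None:
        pucker_states = [
            "4C1" if t == GLCNS else "2SO" for t in residue_types
        ]
    if len(pucker_states) != n_residues:
        raise ValueError("pucker_states length mismatch")

    all_names: list[str] = []
    all_elements: list[str] = []
    all_res_idx: list[int] = []
    all_res_type: list[str] = []
    placed: list[np.ndarray] = []

    # residue 1 template at the origin, plus an anomeric hydroxyl for mass
    tpl = _residue_template(residue_types[0], pucker_states[0])
    coords = tpl.positions.copy()
    c1 = coords[tpl.names.index("C1")]
    o1 = c1 + 1.43 * tpl.link_direction
    res_coords = np.vstack([coords, o1])
    res_names = tpl.names + ["O1"]
    res_elements = tpl.elements + ["O"]

    def commit(res_i: int, names, elements, xyz) -> None:
        all_names.extend(names)
        all_elements.extend(elements)
        all_res_idx.extend([res_i] * len(names))
        all_res_type.extend([residue_types[res_i - 1]] * len(names))
        placed.append(np.asarray(xyz))

    commit(1, res_names, res_elements, res_coords)

    for k in range(n_residues - 1):
        acc_i = k + 1
        phi, psi = linkage_torsions[k]
        acc_xyz = placed[k]
        # acceptor atom positions by name within residue acc_i
        start = sum(p.shape[0] for p in placed[:k])
        names_k = all_names[start : start + placed[k].shape[0]]
        by = {n: acc_xyz[i] for i, n in enumerate(names_k)}
        c3, c4, o4 = by["C3"], by["C4"], by["O4"]

        # NeRF: torsion(C3, C4, O4, C1') = ψ (reversal-invariant definition)
        c1_new = _nerf_place(c3, c4, o4, _GLYCOSIDIC_BOND, 116.0, psi)

        tpl = _residue_template(residue_types[k + 1], pucker_states[k + 1])
        t_c1 = tpl.positions[tpl.names.index("C1")]
        # align template link direction with C1' -> O4
        b = (o4 - c1_new) / np.linalg.norm(o4 - c1_new)
        r1 = _rotation_aligning(tpl.link_direction, b)
        xyz = (tpl.positions - t_c1) @ r1.T + c1_new
        o5_new = xyz[tpl.names.index("O5")]
        tau0 = torsion_angle(o5_new, c1_new, o4, c4)
        # rotation about the C1'-O4 axis adjusts φ; sense fixed empirically
        for sense in (1.0, -1.0):
            rot = _rotation_about_axis(b, sense * (phi - tau0))
            cand = (xyz - c1_new) @ rot.T + c1_new
            tau = torsion_angle(cand[tpl.names.index("O5")], c1_new, o4, c4)
            if abs(wrap_angle(tau - phi)) < 1e-6:
                xyz = cand
                break
        else:  # pragma: no cover - one sense always matches
            raise RuntimeError("failed to set glycosidic φ")
        commit(k + 2, tpl.names, tpl.elements, xyz)

    positions = np.vstack(placed)
    masses = np.array(
        [mass_of(n, e) for n, e in zip(all_names, all_elements)]
    )
    chain = Structure(
        atom_names=all_names,
        elements=all_elements,
        masses=masses,
        residue_indices=np.array(all_res_idx),
        residue_types=all_res_type,
        positions=positions,
    )
    _check_clashes(chain, clash_tolerance)
    return chain


def _check_clashes(chain: Structure, tolerance: float) -> None:
    """Error on inter-residue contacts closer than ``tolerance`` Å.

    Pairs bonded through the glycosidic bond (and their 1-3 neighbours) are
    exempt: donor {C1, O5, C2} against acceptor {O4, C4, C3} for adjacent
    residues.
    """
    if tolerance <= 0:
        return
    tree = cKDTree(chain.positions)
    donor_exempt = {"C1", "O5", "C2"}
    acceptor_exempt = {"O4", "C4", "C3"}
    for i, j in tree.query_pairs(tolerance):
        ri, rj = int(chain.residue_indices[i]), int(chain.residue_indices[j])
        if ri == rj:
            continue
        lo, hi = (i, j) if ri < rj else (j, i)
        if abs(ri - rj) == 1:
            if (
                chain.atom_names[hi] in donor_exempt
                and chain.atom_names[lo] in acceptor_exempt
            ):
                continue
        d = float(np.linalg.norm(chain.positions[i] - chain.positions[j]))
        raise ChainBuildError(
            f"steric clash: residue {ri} atom {chain.atom_names[i]} vs "
            f"residue {rj} atom {chain.atom_names[j]} at {d:.2f} Å — "
            "revise the requested linkage torsions"
        )


# ---------------------------------------------------------------------------
# Stochastic ensembles
# ---------------------------------------------------------------------------


@dataclass
class EnsembleRecipe:
    """Specification of a synthetic conformational ensemble.

    Per-residue pucker states are drawn iid from ``pucker_probabilities``
    (residue type -> {state: probability}, overridable per residue index via
    ``pucker_overrides``), per-linkage (φ, ψ) from wrapped normal
    distributions around class-specific means, and iid Gaussian Cartesian
    noise of width ``noise_sigma`` Å is added last.
    """

    n_frames: int
    seed: int
    n_residues: int = 12
    residue_types: Optional[Sequence[str]] = None
    pucker_probabilities: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            GLCNS: {"4C1": 1.0},
            IDOA: {"2SO": 0.65, "1S3": 0.35},
        }
    )
    pucker_overrides: Mapping[int, Mapping[str, float]] = field(default_factory=dict)
    linkage_means: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            f"{GLCNS}-{IDOA}": (-70.0, 120.0),
            f"{IDOA}-{GLCNS}": (60.0, 60.0),
        }
    )
    linkage_sigma: float = 12.0
    noise_sigma: float = 0.05
    frame_spacing_ps: float = 100.0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.linkage_sigma < 0:
            raise ValueError("linkage_sigma must be >= 0")
        for tag, probs in list(self.pucker_probabilities.items()) + list(
            self.pucker_overrides.items()
        ):
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"pucker probabilities for {tag!r} sum to {total}, not 1"
                )

    def resolved_residue_types(self) -> list[str]:
        if self.residue_types is not None:
            if len(self.residue_types) != self.n_residues:
                raise ValueError("residue_types length mismatch")
            return list(self.residue_types)
        return [GLCNS if i % 2 == 0 else IDOA for i in range(self.n_residues)]


def generate_ensemble(recipe: EnsembleRecipe) -> Ensemble:
    """Draw a reproducible synthetic ensemble from a recipe.

    The same seed yields a bit-identical ensemble; with zero noise, zero
    torsion spread and deterministic (single-state) pucker probabilities
    every frame equals the template chain.
    """
    rng = np.random.default_rng(recipe.seed)
    types = recipe.resolved_residue_types()
    n = recipe.n_residues

    state_choices: list[tuple[list[str], np.ndarray]] = []
    for i in range(1, n + 1):
        probs = recipe.pucker_overrides.get(
            i, recipe.pucker_probabilities[types[i - 1]]
        )
        labels = sorted(probs)
        state_choices.append((labels, np.array([probs[k] for k in labels])))

    frames = []
    for _ in range(recipe.n_frames):
        states = [
            labels[rng.choice(len(labels), p=p)] for labels, p in state_choices
        ]
        torsions = []
        for k in range(n - 1):
            cls = f"{types[k + 1]}-{types[k]}"
            mu_phi, mu_psi = recipe.linkage_means[cls]
            phi = wrap_angle(rng.normal(mu_phi, recipe.linkage_sigma))
            psi = wrap_angle(rng.normal(mu_psi, recipe.linkage_sigma))
            torsions.append((phi, psi))
        chain = build_chain(
            n, types, torsions, states, clash_tolerance=0.0
        )
        pos = chain.positions
        if recipe.noise_sigma > 0:
            pos = pos + rng.normal(0.0, recipe.noise_sigma, pos.shape)
        frames.append(chain.with_positions(pos))
    return Ensemble.from_structures(frames, recipe.frame_spacing_ps)
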