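"""Exact geometric primitives: torsions, centers of mass, superposition, Rg.

Everything downstream (pucker classification, glycosidic torsions, shape
descriptors) reduces to these operations, so they are deliberately small,
fully vectorised where it matters, and strict about degenerate input.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .structure import AtomSelection, SelectionError, Structure


class DegenerateGeometryError(ValueError):
    """Raised for torsions over collinear points or unusable superpositions.

    Raising (rather than returning NaN or 0) keeps classification code from
    silently mislabelling conformers.
    """


def torsion_angle(
    p1: np.ndarray, p2: np.ndarray, p3: np.ndarray, p4: np.ndarray
) -> float:
    """Dihedral angle p1-p2-p3-p4 in degrees on (−180, 180].

    Sign follows the IUPAC convention: looking from p2 towards p3, a
    clockwise rotation from the p2→p1 projection to the p3→p4 projection is
    positive; the eclipsed (cis) arrangement is 0°.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p1 - p2
    b2 = p3 - p2
    b3 = p4 - p3
    nb2 = np.linalg.norm(b2)
    if nb2 < 1e-10:
        raise DegenerateGeometryError("central atoms p2 and p3 coincide")
    # components of the outer bonds orthogonal to the central bond
    b2u = b2 / nb2
    v = b1 - np.dot(b1, b2u) * b2u
    w = b3 - np.dot(b3, b2u) * b2u
    nv = np.linalg.norm(v)
    nw = np.linalg.norm(w)
    if nv < 1e-8 * max(np.linalg.norm(b1), 1.0) or nv == 0.0:
        raise DegenerateGeometryError("p1, p2, p3 are collinear")
    if nw < 1e-8 * max(np.linalg.norm(b3), 1.0) or nw == 0.0:
        raise DegenerateGeometryError("p2, p3, p4 are collinear")
    x = np.dot(v, w)
    y = np.dot(np.cross(b2u, v), w)
    ang = np.degrees(np.arctan2(y, x))
    # map onto (−180, 180]
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def wrap_angle(angle_deg: np.ndarray | float):
    """Wrap angle(s) onto (−180, 180] degrees."""
    a = np.asarray(angle_deg, dtype=float)
    wrapped = -((-a + 180.0) % 360.0 - 180.0)
    out = np.where(wrapped == -180.0, 180.0, wrapped)
    if np.isscalar(angle_deg) or out.ndim == 0:
        return float(out)
    return out


def circular_difference(a_deg, b_deg):
    """Smallest absolute angular separation |a − b| on the circle, degrees."""
    d = (np.asarray(a_deg, dtype=float) - np.asarray(b_deg, dtype=float) + 180.0) % 360.0 - 180.0
    out = np.abs(d)
    if out.ndim == 0:
        return float(out)
    return out


def center_of_mass(
    structure: Structure, selection: Optional[AtomSelection] = None
) -> np.ndarray:
    """Mass-weighted mean position (Å) of the selected atoms."""
    sel = selection if selection is not None else AtomSelection.all()
    idx = sel.resolve_nonempty(structure)
    m = structure.masses[idx]
    return (m[:, None] * structure.positions[idx]).sum(axis=0) / m.sum()


def radius_of_gyration(
    structure: Structure, selection: Optional[AtomSelection] = None
) -> float:
    """Mass-weighted RMS distance from the center of mass, Å.

    Rg = sqrt( Σ mᵢ |rᵢ − r_COM|² / Σ mᵢ ).
    """
    sel = selection if selection is not None else AtomSelection.all()
    idx = sel.resolve_nonempty(structure)
    m = structure.masses[idx]
    r = structure.positions[idx]
    com = (m[:, None] * r).sum(axis=0) / m.sum()
    d2 = ((r - com) ** 2).sum(axis=1)
    return float(np.sqrt((m * d2).sum() / m.sum()))


def _plain_rmsd(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    d2 = ((x - y) ** 2).sum(axis=1)
    return float(np.sqrt((w * d2).sum() / w.sum()))


def optimal_superposition(
    mobile: Structure,
    reference: Structure,
    selection: Optional[AtomSelection] = None,
    mass_weighted: bool = True,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Best rigid-body fit of ``mobile`` onto ``reference`` (Kabsch).

    Returns ``(rotation, translation, rmsd)`` with the proper rotation
    (det = +1, reflections rejected) and translation minimising the
    (optionally mass-weighted) RMSD over the selected atoms:
    applying ``x -> R x + t`` to the mobile coordinates attains ``rmsd``.
    """
    sel = selection if selection is not None else AtomSelection.all()
    idx_m = sel.resolve_nonempty(mobile)
    idx_r = sel.resolve_nonempty(reference)
    if idx_m.size != idx_r.size:
        raise SelectionError(
            f"selection sizes differ: {idx_m.size} vs {idx_r.size}"
        )
    if idx_m.size < 3:
        raise DegenerateGeometryError("superposition needs at least 3 atoms")
    x = mobile.positions[idx_m]
    y = reference.positions[idx_r]
    w = mobile.masses[idx_m] if mass_weighted else np.ones(idx_m.size)
    wsum = w.sum()
    xc = (w[:, None] * x).sum(axis=0) / wsum
    yc = (w[:, None] * y).sum(axis=0) / wsum
    x0 = x - xc
    y0 = y - yc
    # collinearity guard: rank of the weighted coordinate cloud
    if np.linalg.matrix_rank(x0, tol=1e-8) < 2 or np.linalg.matrix_rank(y0, tol=1e-8) < 2:
        raise DegenerateGeometryError("selected atoms are collinear")
    h = (w[:, None] * x0).T @ y0
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    trans = yc - rot @ xc
    rmsd = _plain_rmsd(x0 @ rot.T, y0, w)
    return rot, trans, rmsd


def rmsd_after_superposition(
    mobile: Structure,
    reference: Structure,
    selection: Optional[AtomSelection] = None,
    mass_weighted: bool = True,
) -> float:
    """Convenience wrapper returning only the fitted RMSD in Å."""
    return optimal_superposition(mobile, reference, selection, mass_weighted)[2]
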