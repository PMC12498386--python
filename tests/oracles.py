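"""Independent brute-force oracles used to validate the package's geometry.

Each function here is deliberately implemented from a different formula (or
by direct summation / eigendecomposition) than the library code it checks.
"""

from __future__ import annotations

import numpy as np


def dihedral_cross_oracle(p1, p2, p3, p4) -> float:
    """Dihedral via atan2 of cross products of the two bond-plane normals."""
    p1, p2, p3, p4 = (np.asarray(p) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    x = np.dot(n1, n2)
    y = np.dot(np.cross(n1, n2), b2 / np.linalg.norm(b2))
    ang = np.degrees(np.arctan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def com_oracle(masses, positions) -> np.ndarray:
    """Center of mass by explicit elementwise summation."""
    m = np.asarray(masses, float)
    r = np.asarray(positions, float)
    acc = np.zeros(3)
    for mi, ri in zip(m, r):
        acc += mi * ri
    return acc / m.sum()


def rg_oracle(masses, positions) -> float:
    """Radius of gyration by the direct two-pass formula."""
    com = com_oracle(masses, positions)
    m = np.asarray(masses, float)
    s = 0.0
    for mi, ri in zip(m, np.asarray(positions, float)):
        s += mi * float(((ri - com) ** 2).sum())
    return float(np.sqrt(s / m.sum()))


def quaternion_superposition_rmsd(x, y, weights=None) -> float:
    """Minimum weighted RMSD over rigid transforms, by Horn's quaternion method.

    Builds the 4×4 key matrix from the weighted correlation of the centered
    clouds and takes the largest eigenvalue; fully independent of the
    SVD-based Kabsch algorithm.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    w = np.ones(len(x)) if weights is None else np.asarray(weights, float)
    wsum = w.sum()
    xc = x - (w[:, None] * x).sum(0) / wsum
    yc = y - (w[:, None] * y).sum(0) / wsum
    m = (w[:, None] * xc).T @ yc
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    k = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    lam = np.linalg.eigvalsh(k)[-1]
    g = float((w[:, None] * (xc**2 + yc**2)).sum())
    e2 = max(g - 2.0 * lam, 0.0) / wsum
    return float(np.sqrt(e2))


def cp_analysis_oracle(ring_positions) -> tuple[float, float, float]:
    """Cremer–Pople (Q, θ, φ2) of a six-membered ring.

    ``ring_positions`` must be in CP atom order (O5, C1..C5). Returns θ in
    [0, 180] and φ2 in [0, 360) degrees. Standard mean-plane construction
    from the two in-plane Fourier sums.
    """
    r = np.asarray(ring_positions, float)
    r = r - r.mean(axis=0)
    j = np.arange(6)
    rp = (r * np.sin(2 * np.pi * j / 6)[:, None]).sum(axis=0)
    rpp = (r * np.cos(2 * np.pi * j / 6)[:, None]).sum(axis=0)
    n = np.cross(rp, rpp)
    n /= np.linalg.norm(n)
    z = r @ n
    q2cos = np.sqrt(2.0 / 6.0) * (z * np.cos(4 * np.pi * j / 6)).sum()
    q2sin = -np.sqrt(2.0 / 6.0) * (z * np.sin(4 * np.pi * j / 6)).sum()
    q3 = np.sqrt(1.0 / 6.0) * (z * (-1.0) ** j).sum()
    q2 = np.hypot(q2cos, q2sin)
    big_q = np.hypot(q2, q3)
    theta = np.degrees(np.arctan2(q2, q3))
    phi2 = np.degrees(np.arctan2(q2sin, q2cos)) % 360.0
    return float(big_q), float(theta), float(phi2)


def water_dimer_energy_oracle(model, pos_a, pos_b, k=332.0636) -> float:
    """Pair energy by an explicit double loop over interaction sites."""
    e = 0.0
    q = model.site_charges
    for i in range(len(q)):
        for jdx in range(len(q)):
            if q[i] == 0.0 or q[jdx] == 0.0:
                continue
            rij = float(np.linalg.norm(pos_a[i] - pos_b[jdx]))
            e += k * q[i] * q[jdx] / rij
    o = model.oxygen_index
    r_oo = float(np.linalg.norm(pos_a[o] - pos_b[o]))
    sr6 = (model.lj_sigma / r_oo) ** 6
    return e + 4.0 * model.lj_epsilon * (sr6 * sr6 - sr6)
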