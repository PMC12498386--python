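"""Glycosidic linkage analysis: φ/ψ torsions, 2D histograms, mode finding.

For a 1→4 linkage between donor residue n+1 and acceptor residue n the
torsions are defined over the atom chains

    φ = O5(n+1) - C1(n+1) - O4(n) - C4(n)
    ψ = C1(n+1) - O4(n)  - C4(n) - C3(n)

with residue 1 at the reducing end. Populations are binned periodically on
(−180°, 180°]² and conformational modes (maxima of population = minima of
the free-energy surface) are located as local maxima on the torus.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .geometry import torsion_angle
from .structure import Ensemble, Structure, TopologyError


class LinkageError(ValueError):
    """Raised for a missing or geometrically broken glycosidic linkage."""


#: maximum C1(donor)-O4(acceptor) distance accepted as a covalent bond, Å
GLYCOSIDIC_BOND_CUTOFF = 1.8


@dataclass(frozen=True)
class LinkageSpec:
    """One glycosidic linkage: donor residue n+1 bonded onto acceptor n."""

    donor_residue: int
    acceptor_residue: int
    linkage_class: str

    def __post_init__(self) -> None:
        if self.donor_residue != self.acceptor_residue + 1:
            raise LinkageError(
                "donor must be the residue immediately after the acceptor "
                f"(got donor {self.donor_residue}, acceptor {self.acceptor_residue})"
            )


def detect_linkages(structure: Structure) -> list[LinkageSpec]:
    """Enumerate the chain's 1→4 linkages from residue adjacency.

    The linkage class is named donor-first (e.g. ``GlcNS(6S)-IdoA(2S)``),
    matching glycan notation for a (1→4) bond.
    """
    links = []
    for ri in structure.residue_ids[:-1]:
        donor = ri + 1
        cls = (
            f"{structure.residue_type_of(donor)}-{structure.residue_type_of(ri)}"
        )
        links.append(LinkageSpec(donor, ri, cls))
    return links


def _linkage_atoms(structure: Structure, link: LinkageSpec) -> dict[str, np.ndarray]:
    try:
        return {
            "O5d": structure.atom_position(link.donor_residue, "O5"),
            "C1d": structure.atom_position(link.donor_residue, "C1"),
            "O4a": structure.atom_position(link.acceptor_residue, "O4"),
            "C4a": structure.atom_position(link.acceptor_residue, "C4"),
            "C3a": structure.atom_position(link.acceptor_residue, "C3"),
        }
    except TopologyError as exc:
        raise LinkageError(
            f"linkage {link.donor_residue}->{link.acceptor_residue}: {exc}"
        ) from exc


def compute_phi_psi(structure: Structure, link: LinkageSpec) -> tuple[float, float]:
    """(φ, ψ) of one linkage in degrees on (−180, 180].

    Verifies the glycosidic bond geometrically (C1-O4 distance below
    :data:`GLYCOSIDIC_BOND_CUTOFF`) before measuring.
    """
    p = _linkage_atoms(structure, link)
    d = float(np.linalg.norm(p["C1d"] - p["O4a"]))
    if d > GLYCOSIDIC_BOND_CUTOFF:
        raise LinkageError(
            f"residues {link.donor_residue} and {link.acceptor_residue} are "
            f"not glycosidically bonded (C1-O4 distance {d:.2f} Å)"
        )
    phi = torsion_angle(p["O5d"], p["C1d"], p["O4a"], p["C4a"])
    psi = torsion_angle(p["C1d"], p["O4a"], p["C4a"], p["C3a"])
    return phi, psi


def linkage_series(
    ensemble: Ensemble,
    links: Optional[Sequence[LinkageSpec]] = None,
    aggregate_by_class: bool = True,
) -> dict[str, pd.DataFrame]:
    """Per-frame φ/ψ series, pooled by linkage class.

    Returns a mapping from series key to a DataFrame with columns
    (frame, donor_residue, phi, psi). With ``aggregate_by_class`` all
    same-class linkages are pooled into one series of length
    frames × pooled linkages; otherwise each linkage keeps its own series
    keyed ``"<class>[donor->acceptor]"``.
    """
    if links is None:
        links = detect_linkages(ensemble.topology)
    out: dict[str, list] = {}
    for f in range(ensemble.n_frames):
        frame = ensemble.frame(f)
        for link in links:
            try:
                phi, psi = compute_phi_psi(frame, link)
            except (LinkageError, ValueError) as exc:
                raise LinkageError(
                    f"frame {f}, linkage {link.donor_residue}->"
                    f"{link.acceptor_residue}: {exc}"
                ) from exc
            key = (
                link.linkage_class
                if aggregate_by_class
                else f"{link.linkage_class}[{link.donor_residue}->{link.acceptor_residue}]"
            )
            out.setdefault(key, []).append((f, link.donor_residue, phi, psi))
    return {
        key: pd.DataFrame(rows, columns=["frame", "donor_residue", "phi", "psi"])
        for key, rows in out.items()
    }


@dataclass
class TorsionHeatmap:
    """Periodic 2D histogram of (φ, ψ) with counts and fractions."""

    bin_edges_phi: np.ndarray
    bin_edges_psi: np.ndarray
    counts: np.ndarray  # (n_phi, n_psi) integers

    @property
    def n_samples(self) -> int:
        return int(self.counts.sum())

    @property
    def fractions(self) -> np.ndarray:
        return self.counts / self.counts.sum()

    @property
    def bin_centers_phi(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_phi[:-1] + self.bin_edges_phi[1:])

    @property
    def bin_centers_psi(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_psi[:-1] + self.bin_edges_psi[1:])

    def to_frame(self) -> pd.DataFrame:
        """Fractions as a DataFrame with bin-center index/columns (φ rows)."""
        return pd.DataFrame(
            self.fractions,
            index=pd.Index(self.bin_centers_phi, name="phi"),
            columns=pd.Index(self.bin_centers_psi, name="psi"),
        )


def torsion_heatmap(
    series_phi: np.ndarray,
    series_psi: np.ndarray,
    bin_width: float = 5.0,
) -> TorsionHeatmap:
    """Bin paired angle series periodically on (−180, 180]².

    ``bin_width`` (degrees) must divide 360 exactly; the total count equals
    the series length, and shifting any angle by a multiple of 360° leaves
    the histogram unchanged.
    """
    phi = np.asarray(series_phi, dtype=float)
    psi = np.asarray(series_psi, dtype=float)
    if phi.shape != psi.shape or phi.ndim != 1:
        raise ValueError("phi and psi series must be 1-D and equally long")
    if phi.size == 0:
        raise ValueError("empty torsion series")
    n_bins = 360.0 / bin_width
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError(f"bin width {bin_width}° does not divide 360°")
    n_bins = int(round(n_bins))
    edges = np.linspace(-180.0, 180.0, n_bins + 1)
    # wrap onto [-180, 180): equivalent to (−180, 180] on the circle and
    # keeps every sample strictly inside the edge range
    phi_w = (phi + 180.0) % 360.0 - 180.0
    psi_w = (psi + 180.0) % 360.0 - 180.0
    counts, _, _ = np.histogram2d(phi_w, psi_w, bins=[edges, edges])
    return TorsionHeatmap(edges.copy(), edges.copy(), counts.astype(int))


def smooth_heatmap(h: TorsionHeatmap) -> TorsionHeatmap:
    """Optional 3×3 periodic mean filter (returns scaled float counts)."""
    c = h.counts.astype(float)
    acc = np.zeros_like(c)
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            acc += np.roll(np.roll(c, di, axis=0), dj, axis=1)
    return TorsionHeatmap(h.bin_edges_phi, h.bin_edges_psi, acc / 9.0)


def find_modes(
    h: TorsionHeatmap, min_fraction: float = 0.0
) -> list[tuple[float, float, float]]:
    """Local population maxima on the torus, as (φ, ψ, fraction) tuples.

    A bin is a mode when its count is ≥ all eight periodic neighbours and
    positive; plateaus of equal-valued adjacent candidates are collapsed to
    a single representative, so a peak straddling the ±180° seam is
    reported exactly once. Modes below ``min_fraction`` are dropped; the
    result is sorted by descending fraction.
    """
    c = h.counts.astype(float)
    if c.sum() <= 0:
        raise ValueError("empty heatmap")
    frac = c / c.sum()
    is_peak = np.ones_like(c, dtype=bool)
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if di == 0 and dj == 0:
                continue
            is_peak &= c >= np.roll(np.roll(c, di, axis=0), dj, axis=1)
    is_peak &= c > 0
    cand = list(zip(*np.nonzero(is_peak)))

    # collapse plateaus: equal-valued candidates adjacent on the torus
    n_phi, n_psi = c.shape
    parent = {p: p for p in cand}

    def find(p):
        while parent[p] != p:
            parent[p] = parent[parent[p]]
            p = parent[p]
        return p

    cand_set = set(cand)
    for i, j in cand:
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                q = ((i + di) % n_phi, (j + dj) % n_psi)
                if q in cand_set and c[q] == c[i, j]:
                    parent[find((i, j))] = find(q)
    reps = sorted(set(find(p) for p in cand))

    centers_phi = h.bin_centers_phi
    centers_psi = h.bin_centers_psi
    modes = [
        (float(centers_phi[i]), float(centers_psi[j]), float(frac[i, j]))
        for i, j in reps
        if frac[i, j] >= min_fraction
    ]
    modes.sort(key=lambda m: (-m[2], m[0], m[1]))
    return modes


def heatmap_to_long(h: TorsionHeatmap) -> pd.DataFrame:
    """Flat long-format view: one row per bin (phi, psi, count, fraction)."""
    pp, ss = np.meshgrid(h.bin_centers_phi, h.bin_centers_psi, indexing="ij")
    return pd.DataFrame(
        {
            "phi": pp.ravel(),
            "psi": ss.ravel(),
            "count": h.counts.ravel(),
            "fraction": h.fractions.ravel(),
        }
    )
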