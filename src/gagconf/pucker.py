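"""Pyranose ring puckering classification from the γ/δ ring dihedrals.

A conformer is assigned to one of the four principal puckering states —
the chairs ⁴C₁ and ¹C₄ and the skew-boats ²S_O and ¹S₃ — when both of its
ring dihedrals γ (C1-C2-C3-C4) and δ (C1-O5-C5-C4) fall within a circular
window of ±23° around the state's reference values; anything else is
labelled "other" (noncanonical). The reference values are derived
geometrically from idealized Cremer–Pople conformers (see
:mod:`gagconf.synthetic` and ``scripts/derive_pucker_references.py``) and
frozen in :mod:`gagconf._pucker_refs`.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from . import _pucker_refs
from .geometry import circular_difference, torsion_angle
from .structure import Ensemble, Structure, TopologyError

STATES = ("4C1", "1C4", "2SO", "1S3")
OTHER = "other"

DEFAULT_HALF_WIDTH = 23.0  # degrees, the ±23° assignment window


class OverlappingWindowsError(ValueError):
    """Reference windows overlap, making classification ambiguous."""


@dataclass(frozen=True)
class PuckerReference:
    """One puckering state: reference (γ, δ) and its assignment window."""

    state: str
    gamma_ref: float
    delta_ref: float
    half_width: float = DEFAULT_HALF_WIDTH

    def contains(self, gamma: float, delta: float) -> bool:
        """Window membership: circular distance per coordinate, boundary inclusive."""
        return (
            circular_difference(gamma, self.gamma_ref) <= self.half_width
            and circular_difference(delta, self.delta_ref) <= self.half_width
        )


class PuckerReferenceSet:
    """A validated set of puckering references.

    Construction rejects reference sets in which one state's (γ, δ) center
    lies inside another state's window — classification would then be
    genuinely ambiguous. Mere corner overlap of two windows is tolerated:
    ²S_O and ¹S₃ are adjacent stations on the pseudorotation equator
    (Δφ₂ = 60°) and their ideal (γ, δ) differ by only ~25°, so ±23° boxes
    intersect for purely geometric reasons; a point falling in such an
    intersection is assigned to the circularly nearest reference.
    """

    def __init__(self, references: Sequence[PuckerReference]):
        refs = list(references)
        self.overlapping_pairs: list[tuple[str, str]] = []
        for i in range(len(refs)):
            for j in range(i + 1, len(refs)):
                a, b = refs[i], refs[j]
                dg = circular_difference(a.gamma_ref, b.gamma_ref)
                dd = circular_difference(a.delta_ref, b.delta_ref)
                if dg <= max(a.half_width, b.half_width) and dd <= max(
                    a.half_width, b.half_width
                ):
                    raise OverlappingWindowsError(
                        f"reference of {a.state} lies inside the window of "
                        f"{b.state} (Δγ={dg:.1f}°, Δδ={dd:.1f}°)"
                    )
                if dg <= a.half_width + b.half_width and dd <= a.half_width + b.half_width:
                    self.overlapping_pairs.append((a.state, b.state))
        self._refs = refs

    def __iter__(self):
        return iter(self._refs)

    def __len__(self) -> int:
        return len(self._refs)

    def __getitem__(self, state: str) -> PuckerReference:
        for r in self._refs:
            if r.state == state:
                return r
        raise KeyError(state)

    @property
    def states(self) -> list[str]:
        return [r.state for r in self._refs]


def default_references(half_width: float = DEFAULT_HALF_WIDTH) -> PuckerReferenceSet:
    """The frozen, geometrically derived reference set."""
    return PuckerReferenceSet(
        [
            PuckerReference(state, g, d, half_width)
            for state, (g, d) in _pucker_refs.REFERENCE_GAMMA_DELTA.items()
        ]
    )


def compute_gamma_delta(
    structure: Structure, residue_index: int
) -> tuple[float, float]:
    """(γ, δ) = (C1-C2-C3-C4, C1-O5-C5-C4) dihedrals of one residue, degrees."""
    try:
        p = {
            name: structure.atom_position(residue_index, name)
            for name in ("C1", "C2", "C3", "C4", "C5", "O5")
        }
    except TopologyError as exc:
        raise TopologyError(
            f"cannot compute ring dihedrals for residue {residue_index}: {exc}"
        ) from exc
    gamma = torsion_angle(p["C1"], p["C2"], p["C3"], p["C4"])
    delta = torsion_angle(p["C1"], p["O5"], p["C5"], p["C4"])
    return gamma, delta


def classify_pucker(
    gamma: float,
    delta: float,
    references: Optional[PuckerReferenceSet] = None,
) -> str:
    """Assign (γ, δ) to a puckering state, or "other" outside every window.

    Membership is circular distance per coordinate, boundary inclusive. In
    the rare corner region where two windows intersect, the circularly
    nearest reference (Chebyshev metric over γ, δ) wins.
    """
    refs = references if references is not None else default_references()
    hits = [ref for ref in refs if ref.contains(gamma, delta)]
    if not hits:
        return OTHER
    if len(hits) == 1:
        return hits[0].state
    return min(
        hits,
        key=lambda r: (
            max(
                circular_difference(gamma, r.gamma_ref),
                circular_difference(delta, r.delta_ref),
            ),
            r.state,
        ),
    ).state


def assignment_series(
    ensemble: Ensemble,
    residue_index: int,
    references: Optional[PuckerReferenceSet] = None,
) -> list[str]:
    """Per-frame state labels for one residue (length = frame count)."""
    refs = references if references is not None else default_references()
    labels = []
    for f in range(ensemble.n_frames):
        try:
            gamma, delta = compute_gamma_delta(ensemble.frame(f), residue_index)
        except (TopologyError, ValueError) as exc:
            raise type(exc)(f"frame {f}: {exc}") from exc
        labels.append(classify_pucker(gamma, delta, refs))
    return labels


def pucker_populations(
    ensemble: Ensemble,
    residues: Optional[Iterable[int]] = None,
    references: Optional[PuckerReferenceSet] = None,
) -> pd.DataFrame:
    """Per-residue state fractions over an ensemble.

    Returns a DataFrame with one row per residue (columns: residue_index,
    residue_type, one fraction column per state plus "other"). Fractions
    are exact ratios of counts, so each row sums to 1.
    """
    refs = references if references is not None else default_references()
    if residues is None:
        residues = ensemble.topology.residue_ids
    residues = list(residues)
    states = refs.states + [OTHER]
    rows = []
    n = ensemble.n_frames
    for ri in residues:
        labels = assignment_series(ensemble, ri, refs)
        counts = {s: labels.count(s) for s in states}
        fractions = {s: Fraction(counts[s], n) for s in states}
        assert sum(fractions.values()) == 1
        row = {
            "residue_index": ri,
            "residue_type": ensemble.topology.residue_type_of(ri),
        }
        row.update({s: float(fractions[s]) for s in states})
        rows.append(row)
    return pd.DataFrame(rows)
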