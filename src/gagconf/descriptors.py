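"""Global shape descriptors of a conformational ensemble.

RMSD relative to the first frame, pairwise RMSD matrices over (strided)
frames, radius-of-gyration and end-to-end-distance series, mean
inter-residue distance maps, summary statistics and Pearson correlations
between descriptors. All RMSDs are computed after optimal rigid-body
superposition (mass-weighted by default, mirroring the common MD-analysis
convention).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .geometry import center_of_mass, optimal_superposition, radius_of_gyration
from .structure import AtomSelection, Ensemble


def rmsd_timeseries(
    ensemble: Ensemble,
    selection: Optional[AtomSelection] = None,
    mass_weighted: bool = True,
) -> np.ndarray:
    """Superposed RMSD of every frame against frame 0, Å.

    Element 0 is exactly zero by construction.
    """
    if ensemble.n_frames < 2:
        raise ValueError("RMSD time series needs at least 2 frames")
    ref = ensemble.frame(0)
    out = np.empty(ensemble.n_frames)
    out[0] = 0.0
    for f in range(1, ensemble.n_frames):
        out[f] = optimal_superposition(
            ensemble.frame(f), ref, selection, mass_weighted
        )[2]
    return out


@dataclass
class RmsdMatrix:
    """Pairwise superposed RMSD over strided frames.

    Symmetric with a zero diagonal by computation of one triangle. The
    triangle inequality is *not* guaranteed: each entry comes from an
    independent superposition.
    """

    values: np.ndarray
    frame_indices: np.ndarray
    stride: int

    def to_long_frame(self) -> pd.DataFrame:
        i, j = np.meshgrid(self.frame_indices, self.frame_indices, indexing="ij")
        return pd.DataFrame(
            {"i": i.ravel(), "j": j.ravel(), "rmsd": self.values.ravel()}
        )


def rmsd_matrix(
    ensemble: Ensemble,
    selection: Optional[AtomSelection] = None,
    stride: int = 1,
    mass_weighted: bool = True,
    max_dim: int = 2000,
) -> RmsdMatrix:
    """All-vs-all superposed RMSD between strided frames, Å.

    ``stride`` keeps every stride-th frame; if the strided frame count
    still exceeds ``max_dim`` the stride is increased automatically so the
    matrix stays desk-scale.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if stride > ensemble.n_frames:
        raise ValueError(
            f"stride {stride} exceeds frame count {ensemble.n_frames}"
        )
    idx = np.arange(0, ensemble.n_frames, stride)
    if idx.size > max_dim:
        stride = int(np.ceil(ensemble.n_frames / max_dim))
        idx = np.arange(0, ensemble.n_frames, stride)
    frames = [ensemble.frame(int(i)) for i in idx]
    n = len(frames)
    m = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            r = optimal_superposition(
                frames[b], frames[a], selection, mass_weighted
            )[2]
            m[a, b] = m[b, a] = r
    return RmsdMatrix(m, idx, stride)


def eed_series(
    ensemble: Ensemble, terminal_a: int, terminal_b: int
) -> np.ndarray:
    """Distance between the COMs of two (terminal) residues per frame, Å."""
    sel_a = AtomSelection.residues([terminal_a])
    sel_b = AtomSelection.residues([terminal_b])
    out = np.empty(ensemble.n_frames)
    for f in range(ensemble.n_frames):
        frame = ensemble.frame(f)
        ca = center_of_mass(frame, sel_a)
        cb = center_of_mass(frame, sel_b)
        out[f] = np.linalg.norm(ca - cb)
    return out


def rg_series(
    ensemble: Ensemble, selection: Optional[AtomSelection] = None
) -> np.ndarray:
    """Radius of gyration per frame, Å."""
    return np.array(
        [radius_of_gyration(ensemble.frame(f), selection) for f in range(ensemble.n_frames)]
    )


def residue_distance_map(ensemble: Ensemble) -> pd.DataFrame:
    """Mean inter-residue COM distance matrix over the ensemble, Å.

    Symmetric with a zero diagonal; rows/columns are residue indices.
    """
    residues = ensemble.topology.residue_ids
    sels = {ri: AtomSelection.residues([ri]) for ri in residues}
    n = len(residues)
    acc = np.zeros((n, n))
    for f in range(ensemble.n_frames):
        frame = ensemble.frame(f)
        coms = np.array([center_of_mass(frame, sels[ri]) for ri in residues])
        diff = coms[:, None, :] - coms[None, :, :]
        acc += np.sqrt((diff**2).sum(axis=-1))
    acc /= ensemble.n_frames
    return pd.DataFrame(acc, index=residues, columns=residues)


def summary_stats(series: np.ndarray, ddof: int = 1) -> tuple[float, float]:
    """(mean, standard deviation) of a series.

    The SD is the sample convention (n−1) by default; pass ``ddof=0`` for
    the population convention. The distinction is negligible for long
    trajectories but must be pinned for reproducibility.
    """
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("empty series")
    if x.size == 1 and ddof == 1:
        return float(x[0]), 0.0
    return float(x.mean()), float(x.std(ddof=ddof))


def descriptor_table(
    ensemble: Ensemble,
    selection: Optional[AtomSelection] = None,
    terminal_a: Optional[int] = None,
    terminal_b: Optional[int] = None,
    mass_weighted: bool = True,
) -> pd.DataFrame:
    """Per-frame RMSD (vs frame 0), Rg and EED, aligned on frame index.

    Terminal residues default to the first and last residue of the chain,
    matching the end-to-end-distance definition over the terminal
    monosaccharide units.
    """
    residues = ensemble.topology.residue_ids
    if terminal_a is None:
        terminal_a = residues[0]
    if terminal_b is None:
        terminal_b = residues[-1]
    table = pd.DataFrame(
        {
            "frame": np.arange(ensemble.n_frames),
            "rmsd": rmsd_timeseries(ensemble, selection, mass_weighted),
            "rg": rg_series(ensemble, selection),
            "eed": eed_series(ensemble, terminal_a, terminal_b),
        }
    )
    if not np.all(np.isfinite(table[["rmsd", "rg", "eed"]].to_numpy())):
        raise ValueError("non-finite descriptor value")
    return table


def descriptor_correlations(table: pd.DataFrame) -> pd.DataFrame:
    """3×3 Pearson correlation matrix of the rmsd/rg/eed columns.

    Raises on constant columns (the correlation would be undefined) rather
    than propagating NaN.
    """
    cols = ["rmsd", "rg", "eed"]
    if len(table) < 3:
        raise ValueError("need at least 3 frames for correlations")
    data = table[cols].to_numpy(dtype=float)
    stds = data.std(axis=0)
    for name, s in zip(cols, stds):
        if s == 0:
            raise ValueError(f"descriptor column {name!r} is constant; "
                             "Pearson correlation is undefined")
    corr = np.corrcoef(data, rowvar=False)
    return pd.DataFrame(corr, index=cols, columns=cols)
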