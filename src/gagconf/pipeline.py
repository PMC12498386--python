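"""End-to-end analysis pipeline: configuration, staging, CSV outputs.

One call runs every stage of the trajectory analysis on an ensemble —
shape descriptors, per-residue pucker populations, glycosidic linkage
heatmaps and modes, the pairwise RMSD matrix and descriptor correlations —
and writes plain CSV tables plus a manifest (inputs hashed, configuration
echoed, package version logged). Outputs are byte-identical across reruns
of the same configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import __version__
from .descriptors import (
    descriptor_correlations,
    descriptor_table,
    residue_distance_map,
    rmsd_matrix,
    summary_stats,
)
from .linkage import find_modes, linkage_series, torsion_heatmap
from .pucker import DEFAULT_HALF_WIDTH, default_references, pucker_populations
from .structure import AtomSelection, Ensemble

logger = logging.getLogger("gagconf")

_SELECTIONS = {
    "all": AtomSelection.all,
    "heavy": AtomSelection.heavy,
    "ring": AtomSelection.ring_atoms,
}


@dataclass
class RunConfig:
    """Pipeline configuration; defaults follow the analysis conventions
    documented in docs/methods.md (±23° pucker windows, 5° torsion bins,
    sample SD, mass-weighted RMSD fits)."""

    input_path: str
    output_dir: str
    input_format: Optional[str] = None
    selection: str = "all"
    pucker_half_width: float = DEFAULT_HALF_WIDTH
    heatmap_bin_width: float = 5.0
    matrix_stride: int = 1
    matrix_max_dim: int = 2000
    sd_ddof: int = 1
    mass_weighted: bool = True
    aggregate_linkages: bool = True
    mode_min_fraction: float = 0.002
    terminal_a: Optional[int] = None
    terminal_b: Optional[int] = None
    frame_spacing_ps: float = 100.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.selection not in _SELECTIONS:
            raise ValueError(
                f"unknown selection {self.selection!r}; one of {sorted(_SELECTIONS)}"
            )
        if self.pucker_half_width <= 0 or self.pucker_half_width >= 90:
            raise ValueError("pucker_half_width must be in (0, 90) degrees")
        if self.sd_ddof not in (0, 1):
            raise ValueError("sd_ddof must be 0 (population) or 1 (sample)")
        if self.matrix_stride < 1:
            raise ValueError("matrix_stride must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def to_dict(self) -> dict:
        return {
            k: getattr(self, k)
            for k in self.__dataclass_fields__  # noqa: SLF001 - dataclass API
        }


def _sanitize(name: str) -> str:
    return (
        name.replace("(", "").replace(")", "").replace("/", "-").replace(" ", "_")
    )


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(cfg: RunConfig, ensemble: Optional[Ensemble] = None) -> dict:
    """Run every analysis stage and write CSV outputs plus manifest.json.

    ``ensemble`` may be passed directly (skipping the file read); otherwise
    ``cfg.input_path`` is loaded. Returns a small summary dict with output
    paths and headline statistics.
    """
    from .io import read_ensemble

    out_dir = Path(cfg.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sel = _SELECTIONS[cfg.selection]()

    def stage(name):
        t0 = time.perf_counter()

        def done(extra=""):
            logger.info(
                "stage %-12s %.2f s %s", name, time.perf_counter() - t0, extra
            )

        return done

    if ensemble is None:
        done = stage("read")
        ensemble = read_ensemble(
            cfg.input_path, cfg.input_format, cfg.frame_spacing_ps
        )
        done(f"({ensemble.n_frames} frames, {ensemble.topology.n_atoms} atoms)")

    outputs: dict[str, str] = {}

    def save(df, name, **kw):
        path = out_dir / name
        df.to_csv(path, **kw)
        outputs[name] = str(path)

    done = stage("descriptors")
    table = descriptor_table(
        ensemble, sel, cfg.terminal_a, cfg.terminal_b, cfg.mass_weighted
    )
    save(table, "descriptors.csv", index=False)
    import pandas as pd

    stats = pd.DataFrame(
        [
            (col, *summary_stats(table[col].to_numpy(), cfg.sd_ddof))
            for col in ("rmsd", "rg", "eed")
        ],
        columns=["descriptor", "mean", "sd"],
    )
    save(stats, "descriptor_stats.csv", index=False)
    corr = descriptor_correlations(table)
    save(corr, "correlations.csv")
    done(f"({ensemble.n_frames} frames)")

    done = stage("pucker")
    refs = default_references(cfg.pucker_half_width)
    pops = pucker_populations(ensemble, references=refs)
    save(pops, "pucker_populations.csv", index=False)
    done(f"({len(pops)} residues)")

    done = stage("linkage")
    series = linkage_series(ensemble, aggregate_by_class=cfg.aggregate_linkages)
    all_modes = []
    for cls, df in series.items():
        h = torsion_heatmap(
            df["phi"].to_numpy(), df["psi"].to_numpy(), cfg.heatmap_bin_width
        )
        save(h.to_frame(), f"linkage_heatmap_{_sanitize(cls)}.csv")
        for phi, psi, fracn in find_modes(h, cfg.mode_min_fraction):
            all_modes.append((cls, phi, psi, fracn))
    modes_df = pd.DataFrame(
        all_modes, columns=["linkage_class", "phi_mode", "psi_mode", "fraction"]
    )
    save(modes_df, "linkage_modes.csv", index=False)
    done(f"({len(series)} classes)")

    done = stage("matrix")
    mat = rmsd_matrix(
        ensemble, sel, cfg.matrix_stride, cfg.mass_weighted, cfg.matrix_max_dim
    )
    save(
        pd.DataFrame(mat.values, index=mat.frame_indices, columns=mat.frame_indices),
        "rmsd_matrix.csv",
    )
    save(mat.to_long_frame(), "rmsd_matrix_long.csv", index=False)
    done(f"({mat.values.shape[0]}x{mat.values.shape[0]}, stride {mat.stride})")

    done = stage("distances")
    dmap = residue_distance_map(ensemble)
    save(dmap, "residue_distance_map.csv")
    done()

    manifest = {
        "package": "gagconf",
        "version": __version__,
        "config": cfg.to_dict(),
        "input_sha256": (
            _sha256(cfg.input_path) if Path(cfg.input_path).exists() else None
        ),
        "n_frames": ensemble.n_frames,
        "n_atoms": ensemble.topology.n_atoms,
        "outputs": sorted(outputs),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")

    return {
        "outputs": outputs,
        "n_frames": ensemble.n_frames,
        "descriptor_stats": stats,
        "manifest": manifest,
    }
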