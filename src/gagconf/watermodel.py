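"""Pairwise water–water energetics for rigid explicit solvent models.

The interaction energy between two rigid water molecules a and b is the
Coulomb sum over all charged interaction sites plus a single oxygen–oxygen
Lennard–Jones term:

    E_ab = Σ_ij k q_i q_j / r_ij + 4 ε0 [ (σ0/r_OO)^12 − (σ0/r_OO)^6 ]

with k the Coulomb constant in kcal Å mol⁻¹ e⁻². The registry ships the
five models analysed here (TIP3P, TIP4P, TIP5P, SPC/E, OPC) as a
human-readable YAML file; for TIP5P the oxygen carries no charge and
σ0 = 3.12 Å, ε0 = 0.16 kcal mol⁻¹.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import yaml

#: Coulomb constant, kcal Å mol⁻¹ e⁻²
COULOMB_CONSTANT = 332.0636

#: 1 e·Å in Debye
EA_TO_DEBYE = 1.0 / 0.20819434


@dataclass(frozen=True)
class WaterModelSpec:
    """A rigid water model: labelled charge sites in the molecular frame.

    Site positions are Å with the oxygen at the origin and the H-O-H
    bisector along +z; charges in e; the Lennard-Jones site sits on the
    oxygen.
    """

    name: str
    site_labels: tuple[str, ...]
    site_positions: np.ndarray  # (n_sites, 3)
    site_charges: np.ndarray  # (n_sites,)
    lj_sigma: float
    lj_epsilon: float
    dipole_reference: float

    def __post_init__(self) -> None:
        if self.lj_sigma <= 0:
            raise ValueError("lj_sigma must be positive")
        if self.lj_epsilon < 0:
            raise ValueError("lj_epsilon must be non-negative")
        if abs(float(self.site_charges.sum())) > 1e-9:
            raise ValueError(
                f"model {self.name}: net charge "
                f"{float(self.site_charges.sum()):+.4f} e is not zero"
            )

    @property
    def oxygen_index(self) -> int:
        return self.site_labels.index("O")

    def place(
        self,
        translation=(0.0, 0.0, 0.0),
        rotation: np.ndarray | None = None,
    ) -> "PlacedWater":
        """Rigidly place the molecule in the lab frame."""
        rot = np.eye(3) if rotation is None else np.asarray(rotation, float)
        pos = self.site_positions @ rot.T + np.asarray(translation, float)
        return PlacedWater(self, pos)


@dataclass
class PlacedWater:
    """A water molecule with lab-frame site coordinates."""

    model: WaterModelSpec
    positions: np.ndarray

    @property
    def oxygen_position(self) -> np.ndarray:
        return self.positions[self.model.oxygen_index]


def _build_sites(name: str, entry: dict) -> WaterModelSpec:
    r_oh = float(entry["r_oh"])
    half = np.radians(float(entry["hoh_angle"])) / 2.0
    charges = entry["charges"]
    labels = ["O", "H1", "H2"]
    positions = [
        [0.0, 0.0, 0.0],
        [r_oh * np.sin(half), 0.0, r_oh * np.cos(half)],
        [-r_oh * np.sin(half), 0.0, r_oh * np.cos(half)],
    ]
    q = [float(charges["O"]), float(charges["H"]), float(charges["H"])]
    if "m_site" in entry:
        labels.append("M")
        positions.append([0.0, 0.0, float(entry["m_site"])])
        q.append(float(charges["M"]))
    if "lone_pairs" in entry:
        lp = entry["lone_pairs"]
        r_ol = float(lp["r_ol"])
        lhalf = np.radians(float(lp["lol_angle"])) / 2.0
        # lone pairs sit in the yz plane on the far side of the oxygen
        for sign in (1.0, -1.0):
            labels.append("L1" if sign > 0 else "L2")
            positions.append(
                [0.0, sign * r_ol * np.sin(lhalf), -r_ol * np.cos(lhalf)]
            )
            q.append(float(charges["L"]))
    return WaterModelSpec(
        name=name,
        site_labels=tuple(labels),
        site_positions=np.array(positions, dtype=float),
        site_charges=np.array(q, dtype=float),
        lj_sigma=float(entry["lj_sigma"]),
        lj_epsilon=float(entry["lj_epsilon"]),
        dipole_reference=float(entry["dipole_reference"]),
    )


@lru_cache(maxsize=1)
def load_registry() -> dict[str, WaterModelSpec]:
    """The shipped five-model registry, keyed by lowercase model name."""
    text = (
        importlib.resources.files("gagconf") / "data" / "water_models.yaml"
    ).read_text()
    raw = yaml.safe_load(text)
    return {name: _build_sites(name, entry) for name, entry in raw.items()}


def get_model(name: str) -> WaterModelSpec:
    registry = load_registry()
    key = name.lower().replace("/", "")
    if key not in registry:
        raise KeyError(
            f"unknown water model {name!r}; available: {sorted(registry)}"
        )
    return registry[key]


def water_pair_energy(
    a: PlacedWater,
    b: PlacedWater,
    coulomb_constant: float = COULOMB_CONSTANT,
) -> float:
    """Interaction energy of two placed waters of the same model, kcal/mol."""
    if a.model.name != b.model.name:
        raise ValueError(
            f"molecules use different models: {a.model.name} vs {b.model.name}"
        )
    qa = a.model.site_charges
    qb = b.model.site_charges
    diff = a.positions[:, None, :] - b.positions[None, :, :]
    r = np.sqrt((diff**2).sum(axis=-1))
    charged = np.outer(qa != 0, qb != 0)
    if np.any(r[charged] == 0) or np.linalg.norm(a.oxygen_position - b.oxygen_position) == 0:
        raise ValueError("overlapping interaction sites (r = 0)")
    coulomb = float(
        (coulomb_constant * np.outer(qa, qb)[charged] / r[charged]).sum()
    )
    r_oo = float(np.linalg.norm(a.oxygen_position - b.oxygen_position))
    sr6 = (a.model.lj_sigma / r_oo) ** 6
    lj = 4.0 * a.model.lj_epsilon * (sr6**2 - sr6)
    return coulomb + lj


def model_dipole(model: WaterModelSpec) -> float:
    """Dipole moment |Σ qᵢ rᵢ| of the fixed charge distribution, Debye.

    Only defined for a neutral site set (the dipole of a charged system
    depends on the origin); the registry constructor already guarantees
    neutrality, so the check here guards hand-built models.
    """
    if abs(float(model.site_charges.sum())) > 1e-9:
        raise ValueError("dipole of a net-charged model is origin-dependent")
    mu = (model.site_charges[:, None] * model.site_positions).sum(axis=0)
    return float(np.linalg.norm(mu)) * EA_TO_DEBYE
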