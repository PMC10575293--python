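"""Simulation configuration: material tables, cell kinetics, loads, run setup.

All defaults are the study conditions of the rat femoral 5 mm segmental-defect
model: linear-elastic material properties per tissue/implant phase, daily cell
kinetic rates with a 7-day latency period, the gait-derived load case
(17.7 N compression, 5.7 N shear), and a 112-day (16-week) healing horizon.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from enum import IntEnum
from pathlib import Path

import yaml


class Phase(IntEnum):
    """Voxel phase labels of the domain model."""

    OUTSIDE = 0
    CORTICAL_BONE = 1
    BONE_MARROW = 2
    FIXATION = 3
    SCREW = 4
    SCAFFOLD = 5
    CALLUS = 6


class Tissue(IntEnum):
    """Per-site tissue labels on the healing lattice."""

    GRANULATION = 0
    FIBROUS = 1
    CARTILAGE = 2
    BONE = 3


class Cell(IntEnum):
    """Cell occupancy codes (osteoblast fixed at 2 by convention)."""

    EMPTY = 0
    MSC = 1
    OSTEOBLAST = 2
    CHONDROCYTE = 3
    FIBROBLAST = 4


#: (Young's modulus MPa, Poisson ratio) by implant/tissue phase.
#: Callus starts as granulation tissue; screws share the PEEK fixation
#: properties.  The scaffold modulus depends on the design (HA-PELGA 350 MPa
#: for the validation implant, 1000 MPa polymer-ceramic composite for the
#: case-study designs) and is set per run, see ``scaffold_material``.
PHASE_MATERIALS: dict[int, tuple[float, float]] = {
    Phase.CORTICAL_BONE: (8000.0, 0.3),
    Phase.BONE_MARROW: (2.0, 0.167),
    Phase.FIXATION: (3800.0, 0.36),
    Phase.SCREW: (3800.0, 0.36),
    Phase.CALLUS: (0.2, 0.167),
}

#: (E MPa, nu) by tissue type for the mechanoregulated material update.
#: Newly formed (woven) bone uses ``RegulationParams.new_bone_modulus``,
#: not the 8000 MPa of intact cortical bone.
TISSUE_MATERIALS: dict[int, tuple[float, float]] = {
    Tissue.GRANULATION: (0.2, 0.167),
    Tissue.FIBROUS: (2.0, 0.167),
    Tissue.CARTILAGE: (10.0, 0.3),
}

#: Scaffold (E MPa, nu) by design id string.
SCAFFOLD_MATERIALS: dict[str, tuple[float, float]] = {
    "VALIDATION": (350.0, 0.3),  # HA-PELGA composite
    "REG": (1000.0, 0.3),
    "IREG1": (1000.0, 0.3),
    "IREG2": (1000.0, 0.3),
}


@dataclass
class RegulationParams:
    """Mechanoregulation constants and tissue-outcome thresholds.

    The stimulus is S = |gamma|/a + |p|/b with gamma the minimal principal
    strain (dimensionless) and p the hydrostatic stress (MPa, compression
    positive).  The constant ``b`` is printed with units of mm/s in the source
    stimulus theory (which was formulated for fluid velocity); here p is a
    stress in MPa and b is applied literally — see docs/methods.md.

    Thresholds map S intervals to outcomes: S < resorption_max -> resorption,
    S <= bone_max -> bone, S <= cartilage_max -> cartilage, else fibrous.
    The interval breakpoints follow the mechanoregulation literature defaults
    and are fully configurable.
    """

    a: float = 0.0375
    b: float = 0.003
    resorption_max: float = 0.011
    bone_max: float = 1.0
    cartilage_max: float = 3.0
    update_period: int = 3  # FE material update every N daily iterations
    new_bone_modulus: float = 1000.0  # MPa, woven-bone range
    new_bone_poisson: float = 0.3

    def validate(self) -> None:
        if not (self.a > 0 and self.b > 0):
            raise ValueError("stimulus constants a, b must be positive")
        if not (0 < self.resorption_max < self.bone_max < self.cartilage_max):
            raise ValueError("thresholds must be strictly increasing")
        if self.update_period < 1:
            raise ValueError("update_period must be >= 1")


@dataclass
class CellKinetics:
    """Daily event probabilities for one cell phenotype."""

    proliferation_baseline: float
    proliferation_after: float
    apoptosis: float
    differentiation_baseline: float = 0.0
    differentiation_after: float = 0.0


@dataclass
class KineticsTable:
    """Cell kinetic rates (events/day) with the 7-day latency switch.

    Baseline rates apply on days 1..latency_days; reduced after-latency rates
    from day latency_days+1 onward.  MSC migration is realized as
    ``jumps_per_day`` single-site jumps on the 50 um lattice per daily
    iteration (the nominal migration speed is 30 um/h).
    """

    msc: CellKinetics = field(
        default_factory=lambda: CellKinetics(0.3, 0.12, 0.05, 0.3, 0.06)
    )
    fibroblast: CellKinetics = field(
        default_factory=lambda: CellKinetics(0.275, 0.11, 0.05)
    )
    chondrocyte: CellKinetics = field(
        default_factory=lambda: CellKinetics(0.1, 0.04, 0.1)
    )
    osteoblast: CellKinetics = field(
        default_factory=lambda: CellKinetics(0.15, 0.06, 0.16)
    )
    msc_migration_speed_um_h: float = 30.0
    jumps_per_day: int = 7
    latency_days: int = 7

    def by_cell(self, cell_code: int) -> CellKinetics:
        return {
            Cell.MSC: self.msc,
            Cell.FIBROBLAST: self.fibroblast,
            Cell.CHONDROCYTE: self.chondrocyte,
            Cell.OSTEOBLAST: self.osteoblast,
        }[cell_code]

    def proliferation_rate(self, cell_code: int, day: int) -> float:
        k = self.by_cell(cell_code)
        return k.proliferation_baseline if day <= self.latency_days else k.proliferation_after

    def differentiation_rate(self, cell_code: int, day: int) -> float:
        k = self.by_cell(cell_code)
        return k.differentiation_baseline if day <= self.latency_days else k.differentiation_after


@dataclass
class LoadCase:
    """External loads on the fixed femur model.

    The proximal end (cortical bone and marrow) is fully constrained; the
    axial compression acts on the cortical face at the opposite (distal) end
    and the transverse shear on the distal end cross-section.
    """

    compression_load: float = 17.7  # N, axial, compressive
    shear_load: float = 5.7  # N, transverse (+x), distal end
    fix_proximal: bool = True


def _to_plain(obj):
    if hasattr(obj, "__dataclass_fields__"):
        return {k: _to_plain(v) for k, v in asdict(obj).items()}
    return obj


def _kinetics_from_dict(d: dict) -> KineticsTable:
    kw = dict(d)
    for name in ("msc", "fibroblast", "chondrocyte", "osteoblast"):
        if name in kw and isinstance(kw[name], dict):
            kw[name] = CellKinetics(**kw[name])
    return KineticsTable(**kw)


@dataclass
class SimConfig:
    """Full configuration of one healing simulation."""

    design_id: str = "VALIDATION"
    spacing: float = 0.05  # mm, shared FE-voxel / cell-lattice pitch
    fe_coarsening: int = 4  # FE element = k^3 voxels
    total_days: int = 112  # 16 weeks, one iteration per healing day
    seed: int = 0
    seeding_fraction: float = 0.3  # MSC share of the marrow+periosteum masks
    miniature: bool = False  # scaled-down domain for fast studies
    load_case: LoadCase = field(default_factory=LoadCase)
    regulation: RegulationParams = field(default_factory=RegulationParams)
    kinetics: KineticsTable = field(default_factory=KineticsTable)
    scaffold_length: float | None = None  # mm; None -> design default
    output_dir: str | None = None  # write per-day CSV snapshots if set
    checkpoint_every: int = 0  # days; 0 disables periodic checkpoints
    solver_tol: float = 1e-8
    memory_budget_voxels: int = 300_000_000

    def validate(self) -> None:
        if self.total_days < 1:
            raise ValueError("total_days must be >= 1")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if not 0.0 <= self.seeding_fraction <= 1.0:
            raise ValueError("seeding_fraction must lie in [0, 1]")
        if self.fe_coarsening < 1:
            raise ValueError("fe_coarsening must be >= 1")
        self.regulation.validate()

    # ---- YAML round trip -------------------------------------------------
    def to_dict(self) -> dict:
        return _to_plain(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        kw = dict(d)
        if "load_case" in kw and isinstance(kw["load_case"], dict):
            kw["load_case"] = LoadCase(**kw["load_case"])
        if "regulation" in kw and isinstance(kw["regulation"], dict):
            kw["regulation"] = RegulationParams(**kw["regulation"])
        if "kinetics" in kw and isinstance(kw["kinetics"], dict):
            kw["kinetics"] = _kinetics_from_dict(kw["kinetics"])
        valid = {f.name for f in fields(cls)}
        unknown = set(kw) - valid
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**kw)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "SimConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
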