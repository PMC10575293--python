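"""Voxelized domain construction: bone, marrow, fixation, screws, scaffold, callus.

The simulated anatomy is a rat femoral segmental defect: two intact cortical
bone segments (tubes enclosing marrow) separated by a 5 mm gap, bridged by a
3D-printed scaffold and surrounded by a pre-defined callus cylinder that
overlaps the cortical ends.  A PEEK plate with four screws fixes the bone.
Everything is rasterized onto one cubic voxel grid (default pitch 0.05 mm)
shared by the finite-element model and the cell lattice.

Scaffolds are orthogonal filament lattices: layers of parallel rectangular
filaments stacked along the bone axis (z), alternating filament orientation
between x and y, with longitudinal pores (gaps) between layers.  The
case-study designs vary the longitudinal filament/pore sizes along z —
uniform (REG), growing from the defect edges to the center (IREG1), or
shrinking from the edges to the center (IREG2) — while keeping the in-plane
(radial) filament width and pore size fixed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path

import numpy as np
from scipy import ndimage

from ossify.config import Phase


class DesignId(str, Enum):
    VALIDATION = "VALIDATION"
    REG = "REG"
    IREG1 = "IREG1"
    IREG2 = "IREG2"


# in-plane (radial) dimensions, mm
_CASE_RADIAL_FILAMENT = 0.2
_CASE_RADIAL_PORE = 0.25
_VALIDATION_FILAMENT = 0.4
_VALIDATION_PORE = 0.8


@dataclass
class ScaffoldSpec:
    """Parametric description of one scaffold lattice.

    ``layout`` is the full longitudinal sequence of ('filament', size) /
    ('pore', size) segments from the proximal to the distal scaffold face; it
    tiles ``length`` exactly and is mirror-symmetric about the mid-plane.
    """

    design_id: str
    outer_diameter: float  # mm
    length: float  # mm
    radial_pore: float  # mm, in-plane gap between filaments
    radial_filament: float  # mm, in-plane filament width
    longitudinal_filament_sizes: list[float]
    longitudinal_pore_sizes: list[float]
    layout: list[tuple[str, float]] = field(default_factory=list)

    def validate(self) -> None:
        dims = [self.outer_diameter, self.length, self.radial_pore, self.radial_filament]
        if any(d <= 0 for d in dims):
            raise ValueError("all scaffold dimensions must be positive")
        if any(s <= 0 for s in self.longitudinal_filament_sizes):
            raise ValueError("longitudinal filament sizes must be positive")
        total = sum(size for _, size in self.layout)
        if abs(total - self.length) > 0.05 + 1e-9:
            raise ValueError(
                f"longitudinal layout ({total:.3f} mm) does not tile the "
                f"scaffold length ({self.length:.3f} mm) to within one voxel"
            )

    @property
    def radius(self) -> float:
        return self.outer_diameter / 2.0


def _symmetric_layout(
    half_filaments: list[float], half_pores: list[float]
) -> list[tuple[str, float]]:
    """Mirror-symmetric layout half + reversed(half), half = f1 p1 f2 p2 ..."""
    half: list[tuple[str, float]] = []
    for f, p in zip(half_filaments, half_pores):
        half.append(("filament", f))
        half.append(("pore", p))
    return half + half[::-1]


def make_scaffold_spec(
    design_id: str | DesignId,
    length: float | None = None,
    outer_diameter: float | None = None,
) -> ScaffoldSpec:
    """Build the scaffold specification for one of the four supported designs.

    VALIDATION is the 3 mm diameter x 3 mm long HA-PELGA implant with 0.4 mm
    filaments and 0.8 mm pores.  REG/IREG1/IREG2 are the case-study designs:
    3 mm diameter, spanning the full 5 mm defect, radial pore 0.25 mm and
    filament 0.2 mm, with longitudinal sizes uniform 0.2/0.3 mm (REG) or
    graded linearly within [0.1, 0.4] mm (IREG1 edges->center increasing,
    IREG2 decreasing).  ``length``/``outer_diameter`` override the defaults
    (the longitudinal grading is rescaled to tile the new length).
    """
    try:
        design = DesignId(design_id)
    except ValueError:
        valid = ", ".join(d.value for d in DesignId)
        raise ValueError(f"unknown design_id {design_id!r}; valid options: {valid}") from None

    if design is DesignId.VALIDATION:
        L = 3.0 if length is None else length
        d = 3.0 if outer_diameter is None else outer_diameter
        f, p = _VALIDATION_FILAMENT, _VALIDATION_PORE
        # 0.4/0.8 does not tile 3 mm (2.5 periods): three filaments with two
        # interior 0.8 mm pores plus 0.1 mm end clearances absorbed into the
        # edge pores.
        n = max(1, int(np.floor((L + p) / (f + p))))
        clear = (L - (n * f + (n - 1) * p)) / 2.0
        layout: list[tuple[str, float]] = []
        if clear > 1e-12:
            layout.append(("pore", clear))
        for k in range(n):
            layout.append(("filament", f))
            if k < n - 1:
                layout.append(("pore", p))
        if clear > 1e-12:
            layout.append(("pore", clear))
        return ScaffoldSpec(
            design_id=design.value,
            outer_diameter=d,
            length=L,
            radial_pore=p,
            radial_filament=f,
            longitudinal_filament_sizes=[f] * n,
            longitudinal_pore_sizes=[s for kind, s in layout if kind == "pore"],
            layout=layout,
        )

    # case-study designs span the defect
    L = 5.0 if length is None else length
    d = 3.0 if outer_diameter is None else outer_diameter
    n_pairs = 5  # filament/pore pairs per half
    if design is DesignId.REG:
        half_f = [0.2] * n_pairs
        half_p = [0.3] * n_pairs
    else:
        sizes = np.linspace(0.1, 0.4, n_pairs)
        if design is DesignId.IREG2:
            sizes = sizes[::-1]  # larger at the edges, smallest at the center
        half_f = list(sizes)
        half_p = list(sizes)
    scale = (L / 2.0) / (sum(half_f) + sum(half_p))
    half_f = [s * scale for s in half_f]
    half_p = [s * scale for s in half_p]
    layout = _symmetric_layout(half_f, half_p)
    return ScaffoldSpec(
        design_id=design.value,
        outer_diameter=d,
        length=L,
        radial_pore=_CASE_RADIAL_PORE,
        radial_filament=_CASE_RADIAL_FILAMENT,
        longitudinal_filament_sizes=half_f + half_f[::-1],
        longitudinal_pore_sizes=half_p + half_p[::-1],
        layout=layout,
    )


def make_miniature_scaffold_spec(
    style: str, length: float = 1.5, diameter: float = 1.5
) -> ScaffoldSpec:
    """Scaled-down scaffold for miniature (fast) case studies.

    A 0.5x scale model of the case-study designs on a 1.5 mm defect, keeping
    their relative geometry: radial filament 0.1 mm / pore 0.125 mm; three
    longitudinal filament/pore pairs per half with sizes 0.1/0.15 mm uniform
    (REG style, 40% longitudinal fill) or graded linearly between 0.05 and
    0.2 mm with equal filament and pore sizes (IREG1 increasing towards the
    center, IREG2 decreasing; 4:1 edge-to-center contrast, 50% fill), as in
    the full-size designs.
    """
    style = str(style).upper().replace("MINI_", "")
    n_pairs = 3
    if style == "REG":
        half_f = [0.1] * n_pairs
        half_p = [0.15] * n_pairs
    elif style in ("IREG1", "IREG2"):
        sizes = np.linspace(0.05, 0.2, n_pairs)
        if style == "IREG2":
            sizes = sizes[::-1]
        half_f = list(sizes)
        half_p = list(sizes)
    else:
        raise ValueError(f"unknown miniature style {style!r}; use REG, IREG1 or IREG2")
    scale = (length / 2.0) / (sum(half_f) + sum(half_p))
    half_f = [s * scale for s in half_f]
    half_p = [s * scale for s in half_p]
    layout = _symmetric_layout(half_f, half_p)
    return ScaffoldSpec(
        design_id=f"MINI_{style}",
        outer_diameter=diameter,
        length=length,
        radial_pore=0.125,
        radial_filament=0.1,
        longitudinal_filament_sizes=half_f + half_f[::-1],
        longitudinal_pore_sizes=half_p + half_p[::-1],
        layout=layout,
    )


@dataclass
class GeometryParams:
    """Anatomical dimensions of the defect model (mm)."""

    defect_length: float = 5.0
    callus_length: float = 9.0
    callus_diameter: float = 5.0
    marrow_diameter: float = 2.0
    bone_segment_length: float = 3.0  # marrow length per side
    cortical_thickness: float = 0.5
    fixation_length: float = 9.0
    fixation_width: float = 2.0
    fixation_thickness: float = 0.5
    screw_diameter: float = 0.5
    screw_length: float = 3.5
    include_fixation: bool = True

    @property
    def marrow_radius(self) -> float:
        return self.marrow_diameter / 2.0

    @property
    def bone_outer_radius(self) -> float:
        return self.marrow_radius + self.cortical_thickness

    @property
    def total_length(self) -> float:
        return 2 * self.bone_segment_length + self.defect_length


def miniature_geometry_params() -> GeometryParams:
    """Geometry of the miniature study domain (1.5 mm defect, no fixation)."""
    return GeometryParams(
        defect_length=1.5,
        callus_length=2.5,
        callus_diameter=2.0,
        marrow_diameter=0.8,
        bone_segment_length=1.0,
        cortical_thickness=0.25,
        include_fixation=False,
    )


@dataclass
class DomainModel:
    """Voxel phase map plus named region masks.

    Voxel ``(i, j, k)`` has its center at ``origin + (i+0.5, j+0.5, k+0.5) *
    spacing`` (mm); the bone axis is z.  ``region_masks`` holds boolean arrays
    for 'periosteum', 'marrow_seed', 'defect_gap' and 'healing' (the callus +
    scaffold-pore + marrow-seed region simulated by the cell lattice).
    """

    spacing: float
    dims: tuple[int, int, int]
    origin: tuple[float, float, float]
    phase: np.ndarray  # uint8, shape dims
    region_masks: dict[str, np.ndarray]
    spec: ScaffoldSpec
    params: GeometryParams

    @property
    def voxel_volume(self) -> float:
        return self.spacing**3

    def phase_counts(self) -> dict[str, int]:
        return {p.name: int(np.sum(self.phase == p)) for p in Phase}

    def voxel_centers_1d(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        h = self.spacing
        return tuple(
            self.origin[a] + (np.arange(self.dims[a]) + 0.5) * h for a in range(3)
        )

    # ---- persistence -----------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Dense label array + JSON header in one .npz container."""
        header = {
            "spacing": self.spacing,
            "dims": list(self.dims),
            "origin": list(self.origin),
            "labels": {p.name: int(p) for p in Phase},
            "design_id": self.spec.design_id,
        }
        np.savez_compressed(
            path,
            header=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8),
            phase=self.phase,
            **{f"mask_{k}": v for k, v in self.region_masks.items()},
        )

    @staticmethod
    def load_arrays(path: str | Path) -> tuple[dict, np.ndarray, dict[str, np.ndarray]]:
        with np.load(path) as z:
            header = json.loads(bytes(z["header"]).decode())
            phase = z["phase"]
            masks = {k[5:]: z[k] for k in z.files if k.startswith("mask_")}
        return header, phase, masks

    def export_vtk(self, path: str | Path, fields: dict[str, np.ndarray] | None = None) -> None:
        """Legacy ASCII VTK structured-points export for external viewers."""
        nx, ny, nz = self.dims
        h = self.spacing
        lines = [
            "# vtk DataFile Version 3.0",
            "ossify domain",
            "ASCII",
            "DATASET STRUCTURED_POINTS",
            f"DIMENSIONS {nx} {ny} {nz}",
            f"ORIGIN {self.origin[0] + h / 2} {self.origin[1] + h / 2} {self.origin[2] + h / 2}",
            f"SPACING {h} {h} {h}",
            f"POINT_DATA {nx * ny * nz}",
        ]
        data = {"phase": self.phase}
        if fields:
            data.update(fields)
        for name, arr in data.items():
            flat = np.asarray(arr).reshape(self.dims).transpose(2, 1, 0).ravel()
            lines.append(f"SCALARS {name} float 1")
            lines.append("LOOKUP_TABLE default")
            lines.extend(" ".join(f"{v:g}" for v in flat[i : i + 9]) for i in range(0, flat.size, 9))
        Path(path).write_text("\n".join(lines) + "\n")


def _in_band(coord: np.ndarray, width: float, period: float) -> np.ndarray:
    """True where a coordinate falls inside a filament band.

    Bands of the given width repeat with the given period and one band is
    centered on coordinate 0, so the pattern is even in the coordinate.
    """
    frac = np.mod(coord + period / 2.0, period) - period / 2.0
    return np.abs(frac) <= width / 2.0 + 1e-12


def voxelize_scaffold(
    spec: ScaffoldSpec,
    xc: np.ndarray,
    yc: np.ndarray,
    zc: np.ndarray,
    z_center: float,
) -> np.ndarray:
    """Rasterize the scaffold lattice onto voxel-center coordinate vectors.

    Filament layers alternate orientation (x/y) indexed from the nearest
    scaffold end so the voxelization is mirror-symmetric about the mid-plane.
    """
    X = xc[:, None, None]
    Y = yc[None, :, None]
    envelope = (X**2 + Y**2) <= spec.radius**2 + 1e-12
    period = spec.radial_filament + spec.radial_pore
    n_fil = sum(1 for kind, _ in spec.layout if kind == "filament")
    h = zc[1] - zc[0] if zc.size > 1 else spec.length

    mask = np.zeros((xc.size, yc.size, zc.size), dtype=bool)
    z0 = z_center - spec.length / 2.0
    fil_idx = 0
    pos = z0
    for kind, size in spec.layout:
        if kind == "filament":
            # majority-overlap membership per z layer keeps the rasterization
            # mirror-symmetric when segment boundaries land on voxel centers
            overlap = np.minimum(pos + size, zc + h / 2) - np.maximum(pos, zc - h / 2)
            layer = (overlap > h / 2 - 1e-9)[None, None, :]
            orient_idx = min(fil_idx, n_fil - 1 - fil_idx)
            if orient_idx % 2 == 0:  # filaments run along x -> bands in y
                bands = _in_band(Y, spec.radial_filament, period)
            else:  # filaments run along y -> bands in x
                bands = _in_band(X, spec.radial_filament, period)
            mask |= layer & bands
            fil_idx += 1
        pos += size
    return mask & envelope


def build_domain(
    spec: ScaffoldSpec,
    spacing: float = 0.05,
    params: GeometryParams | None = None,
    memory_budget_voxels: int = 300_000_000,
) -> DomainModel:
    """Rasterize the seven-component defect model onto a voxel grid.

    The callus cylinder is generated first and the scaffold, marrow, cortical
    bone, plate and screws are carved out of / laid over it in priority order
    (Boolean subtraction), so scaffold pores remain callus phase and form part
    of the healing region.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    g = params or GeometryParams()
    spec.validate()

    # key dimensions should sit on (half-)voxel boundaries
    for name, dim in [
        ("defect_length", g.defect_length),
        ("callus_diameter", g.callus_diameter),
        ("total_length", g.total_length),
    ]:
        ratio = dim / spacing
        if abs(ratio - round(ratio)) > 0.5 + 1e-9:
            raise ValueError(f"spacing {spacing} does not divide {name}={dim}")

    callus_r = g.callus_diameter / 2.0
    x_max = max(callus_r, g.bone_outer_radius + g.fixation_thickness if g.include_fixation else 0.0)
    half_x = spacing * np.ceil(x_max / spacing - 1e-9)
    half_y = spacing * np.ceil(callus_r / spacing - 1e-9)
    nx = int(round(2 * half_x / spacing))
    ny = int(round(2 * half_y / spacing))
    nz = int(round(g.total_length / spacing))
    if nx * ny * nz > memory_budget_voxels:
        raise MemoryError(
            f"grid {nx}x{ny}x{nz} exceeds the memory budget of "
            f"{memory_budget_voxels} voxels"
        )
    origin = (-half_x, -half_y, 0.0)
    xc = origin[0] + (np.arange(nx) + 0.5) * spacing
    yc = origin[1] + (np.arange(ny) + 0.5) * spacing
    zc = origin[2] + (np.arange(nz) + 0.5) * spacing
    X = xc[:, None, None]
    Y = yc[None, :, None]
    Z = zc[None, None, :]
    r2 = X**2 + Y**2

    z_cut_p = g.bone_segment_length
    z_cut_d = g.bone_segment_length + g.defect_length
    z_mid = g.total_length / 2.0

    phase = np.zeros((nx, ny, nz), dtype=np.uint8)

    callus = (r2 <= callus_r**2) & (np.abs(Z - z_mid) <= g.callus_length / 2.0)
    phase[callus] = Phase.CALLUS

    scaffold = voxelize_scaffold(spec, xc, yc, zc, z_mid)
    phase[scaffold] = Phase.SCAFFOLD

    bone_z = (Z < z_cut_p) | (Z > z_cut_d)
    marrow = bone_z & (r2 <= g.marrow_radius**2)
    cortical = bone_z & (r2 > g.marrow_radius**2) & (r2 <= g.bone_outer_radius**2)
    phase[np.broadcast_to(marrow, phase.shape)] = Phase.BONE_MARROW
    phase[np.broadcast_to(cortical, phase.shape)] = Phase.CORTICAL_BONE

    if g.include_fixation:
        plate = (
            (X >= g.bone_outer_radius)
            & (X <= g.bone_outer_radius + g.fixation_thickness)
            & (np.abs(Y) <= g.fixation_width / 2.0)
            & (np.abs(Z - z_mid) <= g.fixation_length / 2.0)
        )
        phase[np.broadcast_to(plate, phase.shape)] = Phase.FIXATION
        screw_r = g.screw_diameter / 2.0
        x_outer = g.bone_outer_radius + g.fixation_thickness
        screw_z = [
            z_mid - g.fixation_length / 2.0 + screw_r,
            z_cut_p - screw_r,
            z_cut_d + screw_r,
            z_mid + g.fixation_length / 2.0 - screw_r,
        ]
        for zs in screw_z:
            screw = (
                (Y**2 + (Z - zs) ** 2 <= screw_r**2)
                & (X >= x_outer - g.screw_length)
                & (X <= x_outer)
            )
            phase[np.broadcast_to(screw, phase.shape)] = Phase.SCREW

    # ---- region masks ----------------------------------------------------
    cort_mask = phase == Phase.CORTICAL_BONE
    callus_mask = phase == Phase.CALLUS
    struct = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
    near_cortical = ndimage.binary_dilation(cort_mask, structure=struct)
    outer_shell = np.broadcast_to(r2 >= (g.bone_outer_radius - spacing) ** 2, phase.shape)
    periosteum = near_cortical & callus_mask & outer_shell

    marrow_mask = phase == Phase.BONE_MARROW
    near_cut = (np.abs(Z - z_cut_p) < spacing) | (np.abs(Z - z_cut_d) < spacing)
    marrow_seed = marrow_mask & np.broadcast_to(near_cut, phase.shape)

    defect_gap = np.broadcast_to(
        (Z > z_cut_p) & (Z < z_cut_d) & (r2 <= callus_r**2), phase.shape
    ).copy()
    healing = callus_mask | marrow_seed

    if not periosteum.any() or not marrow_seed.any():
        raise ValueError("empty periosteum or marrow seeding mask; check geometry")

    return DomainModel(
        spacing=spacing,
        dims=(nx, ny, nz),
        origin=origin,
        phase=phase,
        region_masks={
            "periosteum": periosteum,
            "marrow_seed": marrow_seed,
            "defect_gap": defect_gap,
            "healing": healing,
        },
        spec=spec,
        params=g,
    )


def uniform_box_domain(
    dims: tuple[int, int, int], spacing: float = 0.05, phase: int = Phase.CALLUS
) -> DomainModel:
    """Homogeneous rectangular domain (single phase) for mechanics studies."""
    arr = np.full(dims, phase, dtype=np.uint8)
    masks = {
        "periosteum": np.zeros(dims, dtype=bool),
        "marrow_seed": np.zeros(dims, dtype=bool),
        "defect_gap": np.zeros(dims, dtype=bool),
        "healing": arr == Phase.CALLUS,
    }
    spec = make_scaffold_spec(DesignId.VALIDATION)
    return DomainModel(
        spacing=spacing,
        dims=tuple(dims),
        origin=(0.0, 0.0, 0.0),
        phase=arr,
        region_masks=masks,
        spec=spec,
        params=GeometryParams(),
    )


def build_miniature_domain(style: str, spacing: float = 0.05) -> DomainModel:
    """Miniature two-material gradient domain for fast directional studies."""
    spec = make_miniature_scaffold_spec(style)
    return build_domain(spec, spacing=spacing, params=miniature_geometry_params())
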