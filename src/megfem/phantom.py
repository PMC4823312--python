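"""Synthetic layered head phantom with conducting skull defects.

This module generates the ground-truth inputs of the skull-defect study: a
labeled voxel volume of a ~3 cm head with a three-layer skull
(compact--cancellous--compact), brain compartments, a thin conducting liquid
film on the outer surface, cylindrical skull defects filled with conducting
agar, a tangential source shift line under the defects, and a 16-channel
planar axial first-order gradiometer array.

Coordinate conventions: 0-based voxel indices; world coordinates in mm at
voxel centers; right-handed axes with +z toward the sensor array.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage


class Tissue(enum.IntEnum):
    """Integer tissue labels of the voxel phantom."""

    BACKGROUND = 0
    SCALP = 1            # scalp / body tissue
    COMPACT_BONE = 2
    CANCELLOUS_BONE = 3
    GRAY_MATTER = 4
    WHITE_MATTER = 5
    CSF = 6
    BLOOD_VESSEL = 7
    OCULAR_HUMOR = 8
    OCULAR_LENS = 9
    AGAR_DEFECT = 10     # conducting agar filling a skull defect
    LIQUID_LAYER = 11    # thin conducting liquid film on the head surface


#: labels belonging to the skull
BONE_LABELS = (Tissue.COMPACT_BONE, Tissue.CANCELLOUS_BONE)

#: labels a dipole source may legitimately occupy
BRAIN_LABELS = (Tissue.GRAY_MATTER, Tissue.WHITE_MATTER)

#: equivalent homogeneous conductivities in S/m
DEFAULT_CONDUCTIVITIES: dict[Tissue, float] = {
    Tissue.SCALP: 0.33,
    Tissue.COMPACT_BONE: 0.004,
    Tissue.CANCELLOUS_BONE: 0.046,
    Tissue.GRAY_MATTER: 0.23,
    Tissue.WHITE_MATTER: 0.31,           # isotropic equivalent
    Tissue.CSF: 1.79,
    Tissue.BLOOD_VESSEL: 0.78,
    Tissue.OCULAR_HUMOR: 1.7,
    Tissue.OCULAR_LENS: 0.35,
    Tissue.AGAR_DEFECT: 1.0,             # agar at 30 degC
    Tissue.LIQUID_LAYER: 0.6,
}


@dataclass(frozen=True)
class TissueTable:
    """Mapping from tissue label to conductivity in S/m."""

    conductivity: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_CONDUCTIVITIES)
    )

    def __post_init__(self) -> None:
        for label, sigma in self.conductivity.items():
            if not sigma > 0:
                raise ValueError(
                    f"conductivity of label {Tissue(label).name} must be > 0, "
                    f"got {sigma}"
                )

    def __getitem__(self, label: int) -> float:
        try:
            return self.conductivity[label]
        except KeyError:
            try:
                name = Tissue(label).name
            except ValueError:
                name = "unknown"
            raise KeyError(
                f"label {int(label)} ({name}) missing from tissue table"
            ) from None

    def with_overrides(self, **overrides: float) -> "TissueTable":
        """Return a copy with conductivities overridden by ``Tissue`` name."""
        table = dict(self.conductivity)
        for name, sigma in overrides.items():
            table[Tissue[name.upper()]] = sigma
        return TissueTable(table)

    def perturbed(self, label: int, fraction: float) -> "TissueTable":
        """Return a copy with one tissue conductivity scaled by 1+fraction."""
        table = dict(self.conductivity)
        table[label] = table[label] * (1.0 + fraction)
        return TissueTable(table)


@dataclass(frozen=True)
class LayerRadii:
    """Nested shell radii of the layered head, in mm (outermost first)."""

    scalp: float = 15.0
    skull_outer: float = 14.0
    cancellous_outer: float = 13.2
    cancellous_inner: float = 12.8
    skull_inner: float = 12.0
    white: float = 10.0

    def as_tuple(self) -> tuple[float, ...]:
        return (
            self.scalp,
            self.skull_outer,
            self.cancellous_outer,
            self.cancellous_inner,
            self.skull_inner,
            self.white,
        )

    def __post_init__(self) -> None:
        r = self.as_tuple()
        if any(x <= 0 for x in r):
            raise ValueError("layer radii must be positive")
        if any(r[i] <= r[i + 1] for i in range(len(r) - 1)):
            raise ValueError(f"layer radii must be strictly nested, got {r}")


@dataclass(frozen=True)
class PhantomConfig:
    """Parameters of the synthetic layered head.

    ``shape`` is ``"sphere"`` (for analytic validation) or ``"ellipsoid"``
    (mildly anisotropic, rabbit-like topology).  For the ellipsoid the shell
    radii are scaled per axis by ``axis_scales``.
    """

    shape: str = "sphere"
    radii: LayerRadii = field(default_factory=LayerRadii)
    voxel_size: float = 0.4
    axis_scales: tuple[float, float, float] = (1.15, 1.0, 0.95)
    margin_voxels: int = 2
    include_liquid: bool = True

    def __post_init__(self) -> None:
        if self.shape not in ("sphere", "ellipsoid"):
            raise ValueError(f"unknown phantom shape {self.shape!r}")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")

    @property
    def scales(self) -> np.ndarray:
        if self.shape == "sphere":
            return np.ones(3)
        return np.asarray(self.axis_scales, dtype=float)


@dataclass
class LabeledVoxelGrid:
    """Integer tissue labels on a regular isotropic grid.

    ``origin`` is the world position (mm) of the center of voxel (0, 0, 0);
    ``labels`` has shape ``dims`` and is indexed ``[ix, iy, iz]``.
    """

    dims: tuple[int, int, int]
    voxel_size: float
    origin: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.labels.shape != tuple(self.dims):
            raise ValueError("labels shape does not match dims")

    def copy(self) -> "LabeledVoxelGrid":
        return LabeledVoxelGrid(
            self.dims, self.voxel_size, self.origin.copy(), self.labels.copy()
        )

    # -- coordinate transforms ------------------------------------------
    def index_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """World coordinates (mm) of voxel centers for index triples."""
        return self.origin + np.asarray(ijk, dtype=float) * self.voxel_size

    def world_to_index(self, xyz: np.ndarray) -> np.ndarray:
        """Nearest voxel index triples for world points (mm), unclipped."""
        return np.rint((np.asarray(xyz, dtype=float) - self.origin)
                       / self.voxel_size).astype(int)

    def label_at(self, xyz: np.ndarray) -> np.ndarray:
        """Tissue label at world points; BACKGROUND outside the grid."""
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        idx = self.world_to_index(xyz)
        out = np.full(len(idx), int(Tissue.BACKGROUND), dtype=int)
        inside = np.all((idx >= 0) & (idx < np.asarray(self.dims)), axis=1)
        ii = idx[inside]
        out[inside] = self.labels[ii[:, 0], ii[:, 1], ii[:, 2]]
        return out if out.size > 1 else out[0]

    def voxel_centers(self) -> np.ndarray:
        """(nx, ny, nz, 3) array of voxel-center world coordinates."""
        axes = [self.origin[d] + np.arange(self.dims[d]) * self.voxel_size
                for d in range(3)]
        return np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)

    def label_counts(self) -> dict[int, int]:
        values, counts = np.unique(self.labels, return_counts=True)
        return {int(v): int(c) for v, c in zip(values, counts)}


@dataclass(frozen=True)
class DefectSpec:
    """A cylindrical skull defect.

    The cylinder axis passes through ``center`` (a point on the outer skull
    surface, mm) along ``axis`` (outward surface normal); every bone voxel
    within ``radius`` of the axis is relabeled ``fill_label``.
    """

    center: tuple[float, float, float]
    radius: float = 2.5
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    fill_label: int = Tissue.AGAR_DEFECT

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("defect radius must be positive")
        a = np.linalg.norm(np.asarray(self.axis, dtype=float))
        if a == 0:
            raise ValueError("defect axis must be nonzero")

    @property
    def unit_axis(self) -> np.ndarray:
        a = np.asarray(self.axis, dtype=float)
        return a / np.linalg.norm(a)


@dataclass(frozen=True)
class ShiftLine:
    """Regularly spaced source positions along a tangential line.

    Positions are ``half_step`` apart; a *full step* (two half steps) is the
    physical 0.691 mm screw advance.  Index 0 is at ``origin``.
    """

    origin: tuple[float, float, float]
    direction: tuple[float, float, float]
    n_positions: int
    half_step: float = 0.3455

    def __post_init__(self) -> None:
        d = np.linalg.norm(np.asarray(self.direction, dtype=float))
        if not np.isclose(d, 1.0, atol=1e-9):
            raise ValueError("shift-line direction must be a unit vector")
        if self.half_step <= 0 or self.n_positions < 1:
            raise ValueError("half_step must be > 0 and n_positions >= 1")

    @property
    def full_step(self) -> float:
        return 2.0 * self.half_step

    @property
    def unit_direction(self) -> np.ndarray:
        return np.asarray(self.direction, dtype=float)

    def position(self, index: int) -> np.ndarray:
        return np.asarray(self.origin) + index * self.half_step * self.unit_direction

    def positions(self) -> np.ndarray:
        idx = np.arange(self.n_positions)[:, None]
        return np.asarray(self.origin) + idx * self.half_step * self.unit_direction

    def full_step_indices(self) -> np.ndarray:
        return np.arange(0, self.n_positions, 2)


@dataclass(frozen=True)
class SensorArrayConfig:
    """Geometry of the planar axial first-order gradiometer array."""

    n_channels: int = 16
    grid_shape: tuple[int, int] = (4, 4)
    spacing: float = 6.0              # mm between neighboring coil centers
    center: tuple[float, float] = (0.0, 0.0)
    plane_z: float = 18.0             # mm, bottom-coil plane
    base_length: float = 30.0         # mm between bottom and top coil
    base_lengths: tuple[float, ...] | None = None   # per-channel override
    coil_radius: float | None = None  # None -> point-coil evaluation
    allow_nonstandard: bool = False

    def __post_init__(self) -> None:
        if self.n_channels != 16 and not self.allow_nonstandard:
            raise ValueError(
                "the modeled array has 16 channels; pass allow_nonstandard=True "
                "to deviate"
            )
        if self.grid_shape[0] * self.grid_shape[1] != self.n_channels:
            raise ValueError("grid_shape inconsistent with n_channels")


@dataclass
class SensorArray:
    """Planar array of axial first-order gradiometers.

    ``positions`` are bottom-coil centers (mm); the top coil of channel *i*
    sits at ``positions[i] + base_lengths[i] * axes[i]``.  All bottom coils
    are coplanar with common plane normal ``plane_normal``.
    """

    positions: np.ndarray                   # (m, 3) mm
    axes: np.ndarray                        # (m, 3) unit vectors
    base_lengths: np.ndarray                # (m,) mm
    plane_normal: np.ndarray                # (3,)
    coil_radius: float | None = None

    @property
    def n_channels(self) -> int:
        return len(self.positions)

    @property
    def top_positions(self) -> np.ndarray:
        return self.positions + self.base_lengths[:, None] * self.axes

    def with_base_lengths(self, base_lengths: np.ndarray) -> "SensorArray":
        out = SensorArray(
            self.positions.copy(), self.axes.copy(),
            np.asarray(base_lengths, dtype=float).copy(),
            self.plane_normal.copy(), self.coil_radius,
        )
        if len(out.base_lengths) != self.n_channels:
            raise ValueError("base_lengths length mismatch")
        return out


# ---------------------------------------------------------------------------
# construction operations
# ---------------------------------------------------------------------------

def build_phantom(config: PhantomConfig) -> LabeledVoxelGrid:
    """Generate the layered head volume.

    The label shells are, from the outside in: scalp/body, compact bone,
    cancellous bone, compact bone, gray matter, white matter, with an optional
    1-voxel liquid film added on the outer surface.  Deterministic for a
    given config.
    """
    h = config.voxel_size
    scales = config.scales
    extent = config.radii.scalp * float(np.max(scales)) + config.margin_voxels * h
    n = int(np.ceil(2.0 * extent / h))
    dims = (n, n, n)
    origin = -(n - 1) / 2.0 * h * np.ones(3)

    grid = LabeledVoxelGrid(dims, h, origin,
                            np.zeros(dims, dtype=np.int16))
    centers = grid.voxel_centers()
    # effective radius: scaled so that each shell is an ellipsoid with
    # semi-axes radius * axis_scales
    r_eff = np.linalg.norm(centers / scales, axis=-1)

    r = config.radii
    shells = [
        (r.scalp, Tissue.SCALP),
        (r.skull_outer, Tissue.COMPACT_BONE),
        (r.cancellous_outer, Tissue.CANCELLOUS_BONE),
        (r.cancellous_inner, Tissue.COMPACT_BONE),
        (r.skull_inner, Tissue.GRAY_MATTER),
        (r.white, Tissue.WHITE_MATTER),
    ]
    for radius, label in shells:
        grid.labels[r_eff <= radius] = int(label)

    # enforce enclosure of the cancellous layer: any cancellous voxel with a
    # face neighbor outside the skull becomes compact bone, so the spongy
    # layer never touches scalp or brain even at coarse voxel sizes
    bone = np.isin(grid.labels, [int(l) for l in BONE_LABELS])
    structure = ndimage.generate_binary_structure(3, 1)
    interior = ndimage.binary_erosion(bone, structure=structure)
    exposed = (grid.labels == int(Tissue.CANCELLOUS_BONE)) & ~interior
    grid.labels[exposed] = int(Tissue.COMPACT_BONE)

    if config.include_liquid:
        grid = add_liquid_layer(grid)
    return grid


def carve_defects(grid: LabeledVoxelGrid,
                  defects: Sequence[DefectSpec]) -> LabeledVoxelGrid:
    """Carve cylindrical skull defects and fill them with the fill label.

    Only bone-label voxels inside a defect cylinder are relabeled; all other
    voxels are untouched.  Raises if a defect cylinder misses the skull
    entirely.
    """
    out = grid.copy()
    if not defects:
        return out
    centers = grid.voxel_centers()
    bone = np.isin(out.labels, [int(l) for l in BONE_LABELS])
    n_bone_total = int(bone.sum())
    for k, defect in enumerate(defects):
        axis = defect.unit_axis
        rel = centers - np.asarray(defect.center, dtype=float)
        along = rel @ axis
        radial = np.linalg.norm(rel - along[..., None] * axis, axis=-1)
        in_cyl = radial <= defect.radius
        carve = in_cyl & np.isin(out.labels, [int(l) for l in BONE_LABELS])
        n_carved = int(carve.sum())
        if n_carved == 0:
            raise ValueError(
                f"defect {k} at {defect.center} does not intersect the skull"
            )
        if n_carved > 0.25 * n_bone_total:
            warnings.warn(
                f"defect {k} removes {n_carved}/{n_bone_total} bone voxels "
                "(> 25% of the skull); geometry is likely degenerate",
                stacklevel=2,
            )
        out.labels[carve] = int(defect.fill_label)
    return out


def add_liquid_layer(grid: LabeledVoxelGrid) -> LabeledVoxelGrid:
    """Add the 1-voxel conducting liquid film on the outer head surface.

    Background voxels that share a face (6-connectivity) with any head tissue
    (everything except background and liquid itself) are labeled liquid.
    Idempotent: the film does not seed further dilation.
    """
    out = grid.copy()
    head = (out.labels != int(Tissue.BACKGROUND)) & \
           (out.labels != int(Tissue.LIQUID_LAYER))
    structure = ndimage.generate_binary_structure(3, 1)   # 6-neighborhood
    dilated = ndimage.binary_dilation(head, structure=structure)
    shell = dilated & ~head & (out.labels == int(Tissue.BACKGROUND))
    out.labels[shell] = int(Tissue.LIQUID_LAYER)
    return out


def make_sensor_array(config: SensorArrayConfig,
                      rng: np.random.Generator | None = None) -> SensorArray:
    """Build the planar 4x4 axial gradiometer array.

    Bottom coils lie on a regular grid in the plane ``z = plane_z`` with the
    coil axes along +z; the gradiometer signal convention is bottom-coil
    value minus top-coil value.  Per-channel base lengths may be overridden
    (for the base-length uniformization experiment) either explicitly via
    ``config.base_lengths`` or reproducibly drawn from [28.5, 31.5] mm when a
    seeded ``rng`` is supplied and ``base_lengths`` is the string draw range.
    """
    ny, nx = config.grid_shape
    ix = (np.arange(nx) - (nx - 1) / 2.0) * config.spacing + config.center[0]
    iy = (np.arange(ny) - (ny - 1) / 2.0) * config.spacing + config.center[1]
    gx, gy = np.meshgrid(ix, iy, indexing="xy")
    positions = np.column_stack([
        gx.ravel(), gy.ravel(), np.full(config.n_channels, config.plane_z)
    ])
    axes = np.tile(np.array([0.0, 0.0, 1.0]), (config.n_channels, 1))
    if config.base_lengths is not None:
        base = np.asarray(config.base_lengths, dtype=float)
        if base.shape != (config.n_channels,):
            raise ValueError("base_lengths must have one entry per channel")
    else:
        base = np.full(config.n_channels, config.base_length)
    return SensorArray(positions, axes, base,
                       plane_normal=np.array([0.0, 0.0, 1.0]),
                       coil_radius=config.coil_radius)


def draw_base_lengths(config: SensorArrayConfig, seed: int,
                      low: float = 28.5, high: float = 31.5) -> np.ndarray:
    """Reproducibly draw per-channel base lengths in [low, high] mm."""
    rng = np.random.default_rng(seed)
    return rng.uniform(low, high, size=config.n_channels)


def compute_shift_eccentricity(point: np.ndarray, defect: DefectSpec,
                               line: ShiftLine) -> float:
    """Normalized along-line coordinate of a source relative to a defect.

    0 at the normal projection of the defect center onto the shift line,
    +-1 at the projections of the outermost defect-edge points, affine in
    between and beyond.
    """
    point = np.asarray(point, dtype=float)
    d = line.unit_direction
    origin = np.asarray(line.origin, dtype=float)
    s_point = (point - origin) @ d
    s_center = (np.asarray(defect.center, dtype=float) - origin) @ d
    # the rim circle lies in the plane perpendicular to the defect axis;
    # its extent along the line direction:
    cos_axis = float(np.clip(d @ defect.unit_axis, -1.0, 1.0))
    extent = defect.radius * np.sqrt(max(0.0, 1.0 - cos_axis ** 2))
    if extent < 1e-12:
        raise ValueError(
            "defect has no extent along the shift line (axis parallel to line)"
        )
    return float((s_point - s_center) / extent)
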