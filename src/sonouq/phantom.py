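"""Synthetic multi-tissue head phantoms.

Generates segmented label volumes on a regular voxel grid: planar tissue
slabs stacked along the propagation axis (skin/skull/CSF/gray/white etc.),
an optional embedded ellipsoidal target (the amygdala analog), and spherical
shells (a curved-skull analog for refraction checks). Geometry is purely
deterministic; voxel centers sit at (index + 0.5) * spacing with the
propagation axis last.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigurationError, TissueLookupError
from .tissuedb import DEFAULT_LABELS, TissueTable

__all__ = [
    "LabelVolume",
    "PhantomSpec",
    "make_layered_phantom",
    "make_shell_phantom",
    "default_desk_phantom",
    "DESK_GRID_SHAPE",
    "DESK_SPACING_MM",
]

#: Default desk-scale phantom grid: 72 x 72 x 90 voxels at 1 mm. The
#: transverse size must exceed the 64 mm transducer aperture.
DESK_GRID_SHAPE: tuple[int, int, int] = (72, 72, 90)
DESK_SPACING_MM: float = 1.0


@dataclass
class LabelVolume:
    """Integer tissue labels on a regular voxel grid with mm spacing."""

    labels: np.ndarray  # integer array, propagation axis last
    spacing_mm: float
    names: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_LABELS))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ConfigurationError("labels must be an integer array")
        if self.spacing_mm <= 0:
            raise ConfigurationError("spacing must be positive")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.labels.shape

    @property
    def extent_mm(self) -> np.ndarray:
        return np.array(self.shape) * self.spacing_mm

    def voxel_centers_mm(self, axis: int) -> np.ndarray:
        return (np.arange(self.shape[axis]) + 0.5) * self.spacing_mm

    def count(self, name: str) -> int:
        return int(np.count_nonzero(self.labels == self.names[name]))


@dataclass
class PhantomSpec:
    """Layered phantom description.

    ``layers`` is an ordered list of (tissue_name, thickness_mm) slabs along
    the propagation (last) axis starting at the grid face; voxels beyond the
    stack carry ``background``. ``target`` optionally embeds an ellipsoid:
    (tissue_name, center_mm (3-vector), radii_mm (scalar or 3-vector)).
    """

    grid_shape: tuple[int, int, int]
    voxel_spacing_mm: float
    layers: Sequence[tuple[str, float]] = ()
    target: tuple[str, Sequence[float], float | Sequence[float]] | None = None
    background: str = "water"

    def validate(self, table: TissueTable | None = None) -> None:
        if len(self.grid_shape) != 3 or any(s <= 0 for s in self.grid_shape):
            raise ConfigurationError("grid_shape must be 3 positive integers")
        if self.voxel_spacing_mm <= 0:
            raise ConfigurationError("voxel spacing must be positive")
        if any(t < 0 for _, t in self.layers):
            raise ConfigurationError("layer thicknesses must be >= 0")
        depth = self.grid_shape[-1] * self.voxel_spacing_mm
        if sum(t for _, t in self.layers) > depth + 1e-9:
            raise ConfigurationError(
                f"layer stack ({sum(t for _, t in self.layers)} mm) exceeds "
                f"domain depth ({depth} mm)"
            )
        names = [self.background] + [n for n, _ in self.layers]
        if self.target is not None:
            tname, center, radii = self.target
            names.append(tname)
            center = np.asarray(center, dtype=float)
            r = np.broadcast_to(np.asarray(radii, dtype=float), (3,))
            if np.any(r <= 0):
                raise ConfigurationError("target radii must be positive")
            ext = np.array(self.grid_shape) * self.voxel_spacing_mm
            if np.any(center - r < 0) or np.any(center + r > ext):
                raise ConfigurationError("target ellipsoid extends outside grid")
        if table is not None:
            for n in names:
                if n not in table:
                    raise TissueLookupError(n)


def make_layered_phantom(
    spec: PhantomSpec, table: TissueTable | None = None
) -> LabelVolume:
    """Build a slab-stack phantom with an optional ellipsoidal target.

    Slabs are perpendicular to the propagation (last) axis; a voxel belongs
    to the slab containing its center. The target ellipsoid overwrites
    enclosed voxels (center strictly inside); everything else is background.
    """
    spec.validate(table)
    names = dict(DEFAULT_LABELS)
    if table is not None:
        names = dict(table.labels)
    vol = np.full(spec.grid_shape, names[spec.background], dtype=np.int16)

    dx = spec.voxel_spacing_mm
    zc = (np.arange(spec.grid_shape[-1]) + 0.5) * dx
    z0 = 0.0
    for name, thick in spec.layers:
        sel = (zc >= z0) & (zc < z0 + thick)
        vol[:, :, sel] = names[name]
        z0 += thick

    if spec.target is not None:
        tname, center, radii = spec.target
        center = np.asarray(center, dtype=float)
        r = np.broadcast_to(np.asarray(radii, dtype=float), (3,))
        axes = [
            (np.arange(n) + 0.5) * dx - c for n, c in zip(spec.grid_shape, center)
        ]
        gx, gy, gz = np.meshgrid(*axes, indexing="ij", sparse=True)
        inside = (gx / r[0]) ** 2 + (gy / r[1]) ** 2 + (gz / r[2]) ** 2 < 1.0
        vol[inside] = names[tname]

    return LabelVolume(vol, dx, names)


def make_shell_phantom(
    grid_shape: tuple[int, int, int],
    spacing_mm: float,
    shell_tissue: str,
    inner_tissue: str,
    center_mm: Sequence[float],
    inner_radius_mm: float,
    outer_radius_mm: float,
    background: str = "water",
    table: TissueTable | None = None,
) -> LabelVolume:
    """Concentric-sphere phantom: a curved shell around an inner sphere.

    Voxel centers with distance in [inner, outer) from ``center_mm`` get the
    shell tissue, distance < inner the inner tissue, the rest background.
    """
    if not 0 < inner_radius_mm < outer_radius_mm:
        raise ConfigurationError("need 0 < inner_radius < outer_radius")
    ext = np.array(grid_shape) * spacing_mm
    center = np.asarray(center_mm, dtype=float)
    if np.any(center - outer_radius_mm < 0) or np.any(center + outer_radius_mm > ext):
        raise ConfigurationError("shell extends outside grid")
    names = dict(DEFAULT_LABELS) if table is None else dict(table.labels)
    for n in (shell_tissue, inner_tissue, background):
        if n not in names:
            raise TissueLookupError(n)

    axes = [(np.arange(n) + 0.5) * spacing_mm - c for n, c in zip(grid_shape, center)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij", sparse=True)
    d = np.sqrt(gx**2 + gy**2 + gz**2)
    vol = np.full(grid_shape, names[background], dtype=np.int16)
    vol[(d >= inner_radius_mm) & (d < outer_radius_mm)] = names[shell_tissue]
    vol[d < inner_radius_mm] = names[inner_tissue]
    return LabelVolume(vol, spacing_mm, names)


def make_spherical_head_phantom(
    grid_shape: tuple[int, int, int],
    spacing_mm: float,
    center_mm: Sequence[float],
    shells: Sequence[tuple[str, float]],
    target: tuple[str, Sequence[float], float | Sequence[float]] | None = None,
    background: str = "water",
    table: TissueTable | None = None,
) -> LabelVolume:
    """Concentric-shell head analog: nested spheres around one center.

    ``shells`` lists (tissue, outer_radius_mm) from the outermost inward;
    a voxel gets the innermost shell containing it (distance < outer radius
    of that shell and >= the next one in). Curved tissue interfaces vary
    the path length through each layer across the beam aperture, washing
    out the flat-slab thickness resonance that planar stacks exhibit.
    """
    radii = [r for _, r in shells]
    if any(r2 >= r1 for r1, r2 in zip(radii, radii[1:])):
        raise ConfigurationError("shell radii must strictly decrease inward")
    names = dict(DEFAULT_LABELS) if table is None else dict(table.labels)
    for n, _ in list(shells) + [(background, 0)]:
        if n not in names:
            raise TissueLookupError(n)

    center = np.asarray(center_mm, dtype=float)
    axes = [(np.arange(n) + 0.5) * spacing_mm - c
            for n, c in zip(grid_shape, center)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij", sparse=True)
    d = np.sqrt(gx**2 + gy**2 + gz**2)
    vol = np.full(grid_shape, names[background], dtype=np.int16)
    for tissue, outer in shells:  # outermost first; inner shells overwrite
        vol[d < outer] = names[tissue]
    out = LabelVolume(vol, spacing_mm, names)

    if target is not None:
        tname, t_center, t_radii = target
        t_center = np.asarray(t_center, dtype=float)
        r = np.broadcast_to(np.asarray(t_radii, dtype=float), (3,))
        taxes = [(np.arange(n) + 0.5) * spacing_mm - c
                 for n, c in zip(grid_shape, t_center)]
        tx, ty, tz = np.meshgrid(*taxes, indexing="ij", sparse=True)
        inside = (tx / r[0]) ** 2 + (ty / r[1]) ** 2 + (tz / r[2]) ** 2 < 1.0
        vol[inside] = names[tname]
    return out


#: Head-curvature radius of the desk phantom's outer skin surface (mm).
DESK_HEAD_RADIUS_MM = 90.0
#: On-axis skull thickness (mm). The amygdala is insonified through the
#: temporal acoustic window, where the squamous temporal bone is thin
#: (about 2-4 mm), not through the much thicker calvarium.
DESK_SKULL_THICKNESS_MM = 3.0
#: Half-range (mm) of the per-column irregularity applied to every
#: inter-tissue boundary: one voxel. The phantom emulates MRI-segmented
#: anatomy, whose tissue surfaces are rough at the voxel scale; perfectly
#: smooth shells would act as idealized coherent thickness resonators,
#: which segmented heads are not — the irregularity scatters internal
#: layer echoes diffusely.
DESK_BOUNDARY_ROUGHNESS_MM = 1.0
#: Fixed seed of the roughness texture: the phantom is a deterministic
#: object; the jitter is part of its geometry, not a study random variable.
_DESK_ROUGHNESS_SEED = 12345


def default_desk_phantom(table: TissueTable | None = None) -> LabelVolume:
    """The default desk-scale multi-tissue head phantom.

    72 x 72 x 90 voxels at 1 mm: a spherically curved head analog (90 mm
    outer radius) whose skin surface crosses the beam axis 12 mm from the
    near face (water coupling gap holding the transducer bowl), modelling
    the temporal-window placement used for amygdala sonication. On-axis
    layer thicknesses: 3 mm skin, 3 mm temporal bone, 3 mm CSF, 4 mm gray
    matter, white matter inside, plus an 8 mm-radius amygdala-analog
    sphere centered 62 mm deep on the beam axis. Both skull surfaces carry
    a fixed millimetre-scale roughness texture (deterministic, seeded) so
    the bone scatters like segmented anatomy rather than a polished shell.
    """
    nx, ny, nz = DESK_GRID_SHAPE
    dx = DESK_SPACING_MM
    names = dict(DEFAULT_LABELS) if table is None else dict(table.labels)
    cx, cy = nx * dx / 2.0, ny * dx / 2.0
    r = DESK_HEAD_RADIUS_MM
    center = np.array([cx, cy, 12.0 + r])

    axes = [(np.arange(n) + 0.5) * dx for n in DESK_GRID_SHAPE]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij", sparse=True)
    d = np.sqrt((gx - center[0]) ** 2 + (gy - center[1]) ** 2
                + (gz - center[2]) ** 2)
    jit = DESK_BOUNDARY_ROUGHNESS_MM
    rng = np.random.default_rng(_DESK_ROUGHNESS_SEED)

    def jitter():
        return rng.uniform(-jit, jit, (nx, ny))[:, :, None]

    vol = np.full(DESK_GRID_SHAPE, names["water"], dtype=np.int16)
    vol[d < r + jitter()] = names["skin"]
    vol[d < r - 3.0 + jitter()] = names["skull"]
    inner = r - 3.0 - DESK_SKULL_THICKNESS_MM + jitter()
    vol[d < inner] = names["csf"]
    vol[d < inner - 3.0 + jitter()] = names["gray_matter"]
    vol[d < inner - 7.0 + jitter()] = names["white_matter"]
    tx, ty, tz = gx - cx, gy - cy, gz - 62.0
    vol[tx**2 + ty**2 + tz**2 < 8.0**2] = names["amygdala"]
    return LabelVolume(vol, dx, names)
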