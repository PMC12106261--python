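"""Digital phantoms and deterministic VOI construction.

Three phantoms back the analysis:

* ``nema_iq`` — torso-shaped image-quality phantom: six fillable coplanar
  spheres (inner diameters 10, 13, 17, 22, 28, 37 mm) on a 57.2 mm ring, a
  cold cylindrical lung insert on the central axis, and a fillable
  background compartment.  The torso interior is modelled as an elliptical
  cylinder (a simplification of the true NEMA outline, documented in the
  methods note).
* ``uniform_cylinder`` — 5650 ml uniform cylinder used for the camera
  calibration factor.
* ``body_countrate`` — body-shaped PMMA slab with a central activity vial,
  used only as a label map by the count-rate simulator.

VOIs mirror the published analysis scheme: one sphere VOI per hot sphere
(diameter = inner sphere diameter, concentric), 12 background spheres per
sphere diameter (72 total) placed by a deterministic ring search at least
15 mm clear of every hot-sphere surface, the lung insert and the phantom
wall, three background cylinders (45 mm diameter, 150 mm length) and one
lung VOI (30 mm diameter, 130 mm length).

Conventions: world coordinates in mm, sphere plane at z = 0, voxel centers
at ``origin + index * voxel_size``, voxel membership by center inclusion.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .physics import ConfigurationError, _defaults

__all__ = [
    "VoxelGrid",
    "PhantomSpec",
    "VOISet",
    "VoiStats",
    "rasterize_phantom",
    "compartment_labels",
    "build_voi_set",
    "build_cylinder_voi",
    "voi_stats",
    "total_activity_mbq",
]

SPHERE_RING_RADIUS_MM = 57.2
SPHERE_ANGLES_DEG = (0.0, 60.0, 120.0, 180.0, 240.0, 300.0)


@dataclass(frozen=True)
class VoxelGrid:
    """Isotropic voxel grid; voxel (i,j,k) center at origin + index*voxel."""

    shape: tuple[int, int, int]
    voxel_size_mm: float = 2.4
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if not self.voxel_size_mm > 0:
            raise ValueError("voxel size must be positive")
        if len(self.shape) != 3 or any(n < 1 for n in self.shape):
            raise ValueError(f"grid shape must be 3 positive integers, got {self.shape}")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "origin_mm", tuple(float(v) for v in self.origin_mm))

    @classmethod
    def centered(cls, half_extent_mm: tuple[float, float, float], voxel_size_mm: float = 2.4) -> "VoxelGrid":
        """Grid symmetric about the world origin covering ±half_extent."""
        shape = tuple(max(1, int(math.ceil(2 * h / voxel_size_mm))) for h in half_extent_mm)
        origin = tuple(-(n - 1) / 2.0 * voxel_size_mm for n in shape)
        return cls(shape, voxel_size_mm, origin)

    def axis_coords(self, axis: int) -> np.ndarray:
        return self.origin_mm[axis] + np.arange(self.shape[axis]) * self.voxel_size_mm

    def coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Broadcastable world coordinates of voxel centers (x, y, z)."""
        x = self.axis_coords(0)[:, None, None]
        y = self.axis_coords(1)[None, :, None]
        z = self.axis_coords(2)[None, None, :]
        return x, y, z

    @property
    def voxel_volume_ml(self) -> float:
        return self.voxel_size_mm**3 / 1000.0

    def extent_mm(self) -> tuple[tuple[float, float], ...]:
        """World-space bounding box covered by the voxels (face to face)."""
        h = self.voxel_size_mm / 2.0
        return tuple(
            (self.origin_mm[a] - h, self.origin_mm[a] + (self.shape[a] - 1) * self.voxel_size_mm + h)
            for a in range(3)
        )

    def affine(self) -> np.ndarray:
        aff = np.diag([self.voxel_size_mm] * 3 + [1.0])
        aff[:3, 3] = self.origin_mm
        return aff


@dataclass(frozen=True)
class PhantomSpec:
    """Phantom geometry plus per-compartment fill concentrations (kBq/ml).

    ``true_ratio`` carries the unrounded sphere-to-background concentration
    ratio when one is known; printed concentrations are rounded, so when
    provided it takes precedence over the quotient of the fills.
    """

    kind: str  # "nema_iq" | "uniform_cylinder" | "body_countrate"
    sphere_diameters_mm: tuple[float, ...] = (10.0, 13.0, 17.0, 22.0, 28.0, 37.0)
    sphere_kbq_ml: float = 0.0
    background_kbq_ml: float = 0.0
    true_ratio: float | None = None
    # NEMA IQ geometry
    sphere_ring_radius_mm: float = SPHERE_RING_RADIUS_MM
    torso_semiaxis_x_mm: float = 147.0
    torso_semiaxis_y_mm: float = 107.0
    interior_length_mm: float = 180.0
    lung_diameter_mm: float = 50.0
    # calibration cylinder geometry
    cylinder_volume_ml: float = 5650.0
    cylinder_radius_mm: float = 100.0
    # count-rate body phantom geometry
    body_diameter_mm: float = 300.0
    body_width_mm: float = 80.0
    vial_volume_ml: float = 20.0
    vial_activity_mbq: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("nema_iq", "uniform_cylinder", "body_countrate"):
            raise ConfigurationError(f"unknown phantom kind {self.kind!r}")
        diam = tuple(float(d) for d in self.sphere_diameters_mm)
        if list(diam) != sorted(diam):
            raise ValueError("sphere diameters must be sorted ascending")
        object.__setattr__(self, "sphere_diameters_mm", diam)
        if self.sphere_kbq_ml < 0 or self.background_kbq_ml < 0:
            raise ValueError("concentrations must be non-negative")

    # ---- constructors -------------------------------------------------
    @classmethod
    def nema_iq(
        cls,
        sphere_kbq_ml: float,
        background_kbq_ml: float = 0.0,
        true_ratio: float | None = None,
        **kwargs,
    ) -> "PhantomSpec":
        return cls(
            "nema_iq",
            sphere_kbq_ml=sphere_kbq_ml,
            background_kbq_ml=background_kbq_ml,
            true_ratio=true_ratio,
            **kwargs,
        )

    @classmethod
    def uniform_cylinder(cls, concentration_kbq_ml: float, **kwargs) -> "PhantomSpec":
        return cls("uniform_cylinder", background_kbq_ml=concentration_kbq_ml, **kwargs)

    @classmethod
    def body_countrate(cls, vial_activity_mbq: float, **kwargs) -> "PhantomSpec":
        return cls("body_countrate", vial_activity_mbq=vial_activity_mbq, **kwargs)

    @classmethod
    def preset(cls, nuclide: str, setup: str) -> "PhantomSpec":
        """NEMA IQ fill schemes of the measurement campaign.

        ``setup`` is one of ``spheres-only``, ``contrast-8to1``,
        ``contrast-4to1``.
        """
        presets = _defaults()["phantom_presets"]
        try:
            entry = presets[nuclide][setup]
        except KeyError as exc:
            raise ConfigurationError(f"unknown phantom preset {nuclide!r}/{setup!r}") from exc
        return cls.nema_iq(
            sphere_kbq_ml=entry["sphere_kbq_ml"],
            background_kbq_ml=entry["background_kbq_ml"],
            true_ratio=entry["true_ratio"],
        )

    # ---- derived geometry --------------------------------------------
    @property
    def sphere_centers_mm(self) -> tuple[tuple[float, float, float], ...]:
        """Hot-sphere centers: coplanar ring in the z = 0 plane."""
        out = []
        for d, ang in zip(self.sphere_diameters_mm, SPHERE_ANGLES_DEG):
            t = math.radians(ang)
            out.append(
                (self.sphere_ring_radius_mm * math.cos(t), self.sphere_ring_radius_mm * math.sin(t), 0.0)
            )
        return tuple(out)

    @property
    def cylinder_length_mm(self) -> float:
        return self.cylinder_volume_ml * 1000.0 / (math.pi * self.cylinder_radius_mm**2)

    @property
    def contrast_ratio(self) -> float | None:
        """True sphere-to-background ratio; None for background-free fills."""
        if self.true_ratio is not None:
            return self.true_ratio
        if self.background_kbq_ml > 0:
            return self.sphere_kbq_ml / self.background_kbq_ml
        return None

    def bounding_half_extent_mm(self) -> tuple[float, float, float]:
        if self.kind == "nema_iq":
            return (self.torso_semiaxis_x_mm, self.torso_semiaxis_y_mm, self.interior_length_mm / 2)
        if self.kind == "uniform_cylinder":
            return (self.cylinder_radius_mm, self.cylinder_radius_mm, self.cylinder_length_mm / 2)
        return (self.body_diameter_mm / 2, self.body_diameter_mm / 2, self.body_width_mm / 2)


# label codes in compartment maps
LABEL_OUTSIDE = 0
LABEL_BACKGROUND = 1
LABEL_LUNG = 2
LABEL_SPHERE_BASE = 3  # sphere i (ascending diameter) = 3 + i


def _check_fits(spec: PhantomSpec, grid: VoxelGrid) -> None:
    half = spec.bounding_half_extent_mm()
    for axis, h in enumerate(half):
        lo, hi = grid.extent_mm()[axis]
        if -h < lo - 1e-9 or h > hi + 1e-9:
            raise ValueError(
                f"phantom (±{h:.1f} mm on axis {axis}) exceeds grid extent [{lo:.1f}, {hi:.1f}]"
            )


def compartment_labels(spec: PhantomSpec, grid: VoxelGrid) -> np.ndarray:
    """Label volume: 0 outside, 1 background, 2 lung, 3.. spheres (ascending)."""
    _check_fits(spec, grid)
    x, y, z = grid.coords()
    labels = np.zeros(grid.shape, dtype=np.uint8)

    if spec.kind == "uniform_cylinder":
        half_l = spec.cylinder_length_mm / 2
        inside = (x**2 + y**2 <= spec.cylinder_radius_mm**2) & (np.abs(z) <= half_l)
        labels[np.broadcast_to(inside, grid.shape)] = LABEL_BACKGROUND
        return labels

    if spec.kind == "body_countrate":
        r = spec.body_diameter_mm / 2
        inside = (x**2 + y**2 <= r**2) & (np.abs(z) <= spec.body_width_mm / 2)
        labels[np.broadcast_to(inside, grid.shape)] = LABEL_BACKGROUND
        vial_r = (3 * spec.vial_volume_ml * 1000.0 / (4 * math.pi)) ** (1 / 3)
        vial = x**2 + y**2 + z**2 <= vial_r**2
        labels[np.broadcast_to(vial, grid.shape)] = LABEL_LUNG + 1  # vial reuses sphere slot 3
        return labels

    # nema_iq
    a, b = spec.torso_semiaxis_x_mm, spec.torso_semiaxis_y_mm
    torso = ((x / a) ** 2 + (y / b) ** 2 <= 1.0) & (np.abs(z) <= spec.interior_length_mm / 2)
    labels[np.broadcast_to(torso, grid.shape)] = LABEL_BACKGROUND
    lung_r = spec.lung_diameter_mm / 2
    lung = (x**2 + y**2 <= lung_r**2) & (np.abs(z) <= spec.interior_length_mm / 2)
    labels[np.broadcast_to(lung, grid.shape) & (labels == LABEL_BACKGROUND)] = LABEL_LUNG
    for i, (d, c) in enumerate(zip(spec.sphere_diameters_mm, spec.sphere_centers_mm)):
        rsq = (x - c[0]) ** 2 + (y - c[1]) ** 2 + (z - c[2]) ** 2
        labels[rsq <= (d / 2) ** 2] = LABEL_SPHERE_BASE + i
    return labels


def rasterize_phantom(spec: PhantomSpec, grid: VoxelGrid) -> np.ndarray:
    """Ground-truth activity-concentration volume in Bq/ml.

    Voxel value = concentration of the compartment containing the voxel
    center; the lung insert is cold (0).
    """
    labels = compartment_labels(spec, grid)
    out = np.zeros(grid.shape, dtype=float)
    if spec.kind == "body_countrate":
        vial_r = (3 * spec.vial_volume_ml * 1000.0 / (4 * math.pi)) ** (1 / 3)
        vial_mask = labels == LABEL_LUNG + 1
        n = int(vial_mask.sum())
        if n and spec.vial_activity_mbq > 0:
            out[vial_mask] = spec.vial_activity_mbq * 1e6 / (n * grid.voxel_volume_ml)
        return out
    out[labels == LABEL_BACKGROUND] = spec.background_kbq_ml * 1000.0
    for i in range(len(spec.sphere_diameters_mm)):
        out[labels == LABEL_SPHERE_BASE + i] = spec.sphere_kbq_ml * 1000.0
    return out


def total_activity_mbq(activity_bq_ml: np.ndarray, grid: VoxelGrid) -> float:
    """Total activity of a concentration volume (Bq/ml) on its grid, in MBq."""
    return float(activity_bq_ml.sum()) * grid.voxel_volume_ml / 1e6


@dataclass(frozen=True)
class VoiStats:
    mean: float
    sd: float
    total: float
    n_voxels: int


def voi_stats(volume: np.ndarray, mask: np.ndarray) -> VoiStats:
    """Mean/SD (ddof=1)/sum/count over voxels whose centers lie in the mask."""
    if volume.shape != mask.shape:
        raise ValueError(f"volume {volume.shape} and mask {mask.shape} grids differ")
    vals = np.asarray(volume)[np.asarray(mask, dtype=bool)]
    if vals.size == 0:
        raise ValueError("empty VOI mask")
    sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    return VoiStats(float(vals.mean()), sd, float(vals.sum()), int(vals.size))


@dataclass(frozen=True)
class VOISet:
    """All analysis VOIs of the NEMA IQ scheme, as boolean masks on one grid.

    ``background_spheres[d]`` holds the 12 background masks matched to the
    sphere of diameter ``d``; their centers are kept for provenance.
    """

    grid: VoxelGrid
    spheres: dict[float, np.ndarray]
    sphere_centers: dict[float, tuple[float, float, float]]
    background_spheres: dict[float, tuple[np.ndarray, ...]]
    background_centers: dict[float, tuple[tuple[float, float, float], ...]]
    background_cylinders: tuple[np.ndarray, ...]
    lung: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def n_masks(self) -> int:
        return (
            len(self.spheres)
            + sum(len(v) for v in self.background_spheres.values())
            + len(self.background_cylinders)
            + (1 if self.lung is not None else 0)
        )

    def to_table(self) -> pd.DataFrame:
        rows = []
        for d, m in self.spheres.items():
            c = self.sphere_centers[d]
            rows.append(("sphere", d, *c, int(m.sum())))
        for d, masks in self.background_spheres.items():
            for c, m in zip(self.background_centers[d], masks):
                rows.append(("background_sphere", d, *c, int(m.sum())))
        for i, m in enumerate(self.background_cylinders):
            rows.append((f"background_cylinder_{i}", 45.0, np.nan, np.nan, np.nan, int(m.sum())))
        if self.lung is not None:
            rows.append(("lung", 30.0, 0.0, 0.0, 0.0, int(self.lung.sum())))
        return pd.DataFrame(
            rows, columns=["label", "diameter_mm", "x_mm", "y_mm", "z_mm", "n_voxels"]
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_table().to_csv(path, index=False)

    def save_labels_nifti(self, path: str | Path) -> None:
        """Write all masks as one unsigned-integer label volume."""
        labels = np.zeros(self.grid.shape, dtype=np.uint16)
        code = 1
        for d in self.spheres:
            labels[self.spheres[d]] = code
            code += 1
        for d in self.background_spheres:
            for m in self.background_spheres[d]:
                labels[m & (labels == 0)] = code
                code += 1
        for m in self.background_cylinders:
            labels[m & (labels == 0)] = code
            code += 1
        if self.lung is not None:
            labels[self.lung & (labels == 0)] = code
        nib.save(nib.Nifti1Image(labels, self.grid.affine()), str(path))


def _sphere_mask(grid: VoxelGrid, center: tuple[float, float, float], radius: float) -> np.ndarray:
    x, y, z = grid.coords()
    return (x - center[0]) ** 2 + (y - center[1]) ** 2 + (z - center[2]) ** 2 <= radius**2


def _cylinder_mask(
    grid: VoxelGrid, axis_xy: tuple[float, float], radius: float, half_length: float, z0: float = 0.0
) -> np.ndarray:
    x, y, z = grid.coords()
    radial = (x - axis_xy[0]) ** 2 + (y - axis_xy[1]) ** 2 <= radius**2
    return radial & (np.abs(z - z0) <= half_length)


# deterministic candidate layout for the 72 background spheres
_BG_PLANES_MM = (0.0, 35.0, -35.0, 50.0, -50.0)
_BG_RINGS_MM = (50.0, 60.0, 70.0, 85.0, 95.0)
_BG_ANGLES_DEG = tuple(range(0, 360, 10))
_BG_CLEARANCE_MM = 15.0


def _background_sphere_centers(
    spec: PhantomSpec, diameter: float
) -> tuple[tuple[float, float, float], ...]:
    """First 12 candidate centers satisfying all clearance rules.

    Candidates are scanned plane-by-plane (sphere plane first, then ±35 and
    ±50 mm slices), ring-by-ring, angle-by-angle, so the layout is a pure
    function of the phantom geometry.
    """
    r = diameter / 2.0
    clear = _BG_CLEARANCE_MM
    a = spec.torso_semiaxis_x_mm - (r + clear)
    b = spec.torso_semiaxis_y_mm - (r + clear)
    z_max = spec.interior_length_mm / 2 - (r + clear)
    lung_min = spec.lung_diameter_mm / 2 + r + clear
    hot = list(zip(spec.sphere_diameters_mm, spec.sphere_centers_mm))
    accepted: list[tuple[float, float, float]] = []
    for z0 in _BG_PLANES_MM:
        if abs(z0) > z_max:
            continue
        for ring in _BG_RINGS_MM:
            if ring < lung_min:
                continue
            for ang in _BG_ANGLES_DEG:
                t = math.radians(ang)
                p = (ring * math.cos(t), ring * math.sin(t), z0)
                if (p[0] / a) ** 2 + (p[1] / b) ** 2 > 1.0:
                    continue
                ok = True
                for dh, ch in hot:
                    dist = math.dist(p, ch)
                    if dist < r + dh / 2 + clear:
                        ok = False
                        break
                if not ok:
                    continue
                if any(math.dist(p, q) < 2 * r for q in accepted):
                    continue
                accepted.append(p)
                if len(accepted) == 12:
                    return tuple(accepted)
    raise RuntimeError(
        f"could not place 12 background VOIs of diameter {diameter} mm "
        f"({len(accepted)} found); phantom geometry too tight"
    )


def build_voi_set(spec: PhantomSpec, grid: VoxelGrid) -> VOISet:
    """Construct the full NEMA IQ VOI scheme on ``grid`` (deterministic)."""
    if spec.kind != "nema_iq":
        raise ConfigurationError("VOI scheme is defined for the nema_iq phantom")
    _check_fits(spec, grid)
    if min(spec.sphere_diameters_mm) < 3 * grid.voxel_size_mm:
        warnings.warn(
            f"grid ({grid.voxel_size_mm} mm) is coarse for the smallest sphere "
            f"({min(spec.sphere_diameters_mm)} mm, < 3 voxels across)",
            stacklevel=2,
        )
    spheres: dict[float, np.ndarray] = {}
    centers: dict[float, tuple[float, float, float]] = {}
    for d, c in zip(spec.sphere_diameters_mm, spec.sphere_centers_mm):
        spheres[d] = _sphere_mask(grid, c, d / 2.0)
        centers[d] = c
    bg: dict[float, tuple[np.ndarray, ...]] = {}
    bg_centers: dict[float, tuple[tuple[float, float, float], ...]] = {}
    for d in spec.sphere_diameters_mm:
        pts = _background_sphere_centers(spec, d)
        bg[d] = tuple(_sphere_mask(grid, p, d / 2.0) for p in pts)
        bg_centers[d] = pts
    # three axial cylinders in the uniform background, between the hot spheres
    cyl_axes = [(80.0, 90.0), (80.0, 210.0), (80.0, 330.0)]
    cylinders = tuple(
        _cylinder_mask(
            grid,
            (rad * math.cos(math.radians(ang)), rad * math.sin(math.radians(ang))),
            45.0 / 2.0,
            150.0 / 2.0,
        )
        for rad, ang in cyl_axes
    )
    lung = _cylinder_mask(grid, (0.0, 0.0), 30.0 / 2.0, 130.0 / 2.0)
    return VOISet(
        grid=grid,
        spheres=spheres,
        sphere_centers=centers,
        background_spheres=bg,
        background_centers=bg_centers,
        background_cylinders=cylinders,
        lung=lung,
    )


def build_cylinder_voi(spec: PhantomSpec, grid: VoxelGrid, margin_mm: float = 20.0) -> np.ndarray:
    """Large central VOI in the calibration cylinder, eroded from all edges.

    The margin keeps the VOI clear of edge blur so the mean concentration in
    the VOI reflects the fill, not the partial-volume falloff at the wall.
    """
    if spec.kind != "uniform_cylinder":
        raise ConfigurationError("calibration VOI is defined for the uniform_cylinder phantom")
    _check_fits(spec, grid)
    return _cylinder_mask(
        grid,
        (0.0, 0.0),
        spec.cylinder_radius_mm - margin_mm,
        spec.cylinder_length_mm / 2 - margin_mm,
    )
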