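"""Synthetic voxel phantoms and regions of interest.

The planning geometry is a 3-D grid of relative stopping power (RSP; water
= 1.0, air ~ 0.001) plus named boolean ROI masks.  Three deterministic
scenario generators emulate common clinical situations at desk scale:

``prostate-like``
    Central spherical target in a water cylinder with two lateral-posterior
    organs at risk; planned over a full gantry arc.
``liver-like``
    Lateralized target (patient-right) with a surrounding normal-organ
    shell; planned over a partial arc that faces the target through tissue.
``brain-like``
    Central target flanked by four small organs at risk.

Coordinates: 0-based voxel indices; world positions (mm) at voxel centers;
the isocenter sits at the geometric center of the grid.  Gantry angles
follow IEC 61217 (0 deg enters anteriorly, increasing clockwise viewed
from the couch foot).  World axes: +x patient-left, +y anterior,
+z superior.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from ._errors import ConfigurationError, ContractViolation, GeometryError

AIR_RSP = 0.001
WATER_RSP = 1.0

#: scenario id -> geometry defaults (all lengths mm, doses Gy)
SCENARIO_DEFAULTS = {
    "prostate-like": dict(
        grid_shape=(44, 44, 12),
        spacing_mm=4.0,
        body_radius_mm=80.0,
        target_radius_mm=14.0,
        oar_radius_mm=10.0,
        oar_offset_mm=28.0,
        arc_start_deg=0.0,
        arc_stop_deg=0.0,  # start == stop -> full 360 arc
        prescription_gy=78.0,
        fractions=39,
    ),
    "liver-like": dict(
        grid_shape=(48, 48, 12),
        spacing_mm=4.0,
        body_radius_mm=88.0,
        target_radius_mm=16.0,
        gtv_radius_mm=10.0,
        liver_radius_mm=34.0,
        target_offset_mm=-40.0,  # patient-right lateralization
        arc_start_deg=160.0,
        arc_stop_deg=40.0,
        prescription_gy=75.0,
        fractions=25,
    ),
    "brain-like": dict(
        grid_shape=(40, 40, 12),
        spacing_mm=4.0,
        body_radius_mm=72.0,
        target_radius_mm=14.0,
        oar_radius_mm=6.0,
        oar_offset_mm=24.0,
        arc_start_deg=0.0,
        arc_stop_deg=0.0,
        prescription_gy=54.0,
        fractions=30,
    ),
}


@dataclass(frozen=True)
class VoxelPhantom:
    """3-D relative-stopping-power grid.

    Attributes
    ----------
    density : ndarray, shape (nx, ny, nz)
        Relative stopping power per voxel (water = 1.0).
    spacing : (float, float, float)
        Voxel size along each axis, mm; strictly positive.
    origin : (float, float, float)
        World position (mm) of the center of voxel (0, 0, 0).
    """

    density: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        d = np.asarray(self.density, dtype=float)
        if d.ndim != 3:
            raise GeometryError(f"density must be 3-D, got ndim={d.ndim}")
        if np.any(d < 0):
            raise GeometryError("densities must be >= 0")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise GeometryError(f"spacing must be 3 positive lengths, got {self.spacing}")
        object.__setattr__(self, "density", d)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.density.shape  # type: ignore[return-value]

    @property
    def voxel_volume_cc(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz / 1000.0

    def axes_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World coordinates of voxel centers along each axis."""
        return tuple(
            self.origin[k] + self.spacing[k] * np.arange(self.shape[k])
            for k in range(3)
        )  # type: ignore[return-value]

    @property
    def isocenter_mm(self) -> np.ndarray:
        """Geometric center of the grid (world mm); the machine isocenter."""
        return np.array(
            [self.origin[k] + self.spacing[k] * (self.shape[k] - 1) / 2.0 for k in range(3)]
        )

    def voxel_centers_mm(self) -> np.ndarray:
        """(N, 3) world coordinates of every voxel center, C-order flattened."""
        ax, ay, az = self.axes_mm()
        gx, gy, gz = np.meshgrid(ax, ay, az, indexing="ij")
        return np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)

    def body_mask(self, threshold: float = 0.5) -> np.ndarray:
        """Boolean mask of tissue voxels (RSP above *threshold*)."""
        return self.density > threshold


@dataclass(frozen=True)
class ROIMask:
    """Named boolean region of interest on a phantom grid."""

    name: str
    mask: np.ndarray
    kind: str = "oar"  # one of target / oar / external

    def __post_init__(self) -> None:
        if self.kind not in ("target", "oar", "external"):
            raise ConfigurationError(f"unknown ROI kind {self.kind!r}")
        m = np.asarray(self.mask, dtype=bool)
        if self.kind == "target" and not m.any():
            raise GeometryError(f"target ROI {self.name!r} is empty")
        object.__setattr__(self, "mask", m)

    def volume_cc(self, phantom: VoxelPhantom) -> float:
        if self.mask.shape != phantom.shape:
            raise GeometryError(
                f"ROI {self.name!r} shape {self.mask.shape} != phantom {phantom.shape}"
            )
        return float(self.mask.sum()) * phantom.voxel_volume_cc

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class ScenarioSpec:
    """Parameters of one planning scenario.

    ``arc_start_deg == arc_stop_deg`` denotes a full 360-degree arc.
    ``geometry`` overrides entries of :data:`SCENARIO_DEFAULTS` for the
    scenario (grid shape, radii, offsets).
    """

    scenario: str
    arc_start_deg: float
    arc_stop_deg: float
    prescription_gy: float
    fractions: int
    spacing_mm: float = 4.0
    geometry: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIO_DEFAULTS:
            raise ConfigurationError(
                f"unknown scenario {self.scenario!r}; known: {sorted(SCENARIO_DEFAULTS)}"
            )
        if not (0.0 <= self.arc_start_deg < 360.0 and 0.0 <= self.arc_stop_deg < 360.0):
            raise ConfigurationError("arc angles must lie in [0, 360)")
        if self.prescription_gy <= 0:
            raise ConfigurationError("prescription dose must be > 0")
        if not (1.0 <= self.spacing_mm <= 5.0):
            raise ConfigurationError("grid resolution must be 1-5 mm per axis")

    @property
    def arc_span_deg(self) -> float:
        span = (self.arc_stop_deg - self.arc_start_deg) % 360.0
        return 360.0 if span == 0.0 else span


def scenario_spec(scenario: str, **overrides) -> ScenarioSpec:
    """Build a :class:`ScenarioSpec` from the packaged defaults."""
    try:
        base = SCENARIO_DEFAULTS[scenario]
    except KeyError:
        raise ConfigurationError(
            f"unknown scenario {scenario!r}; known: {sorted(SCENARIO_DEFAULTS)}"
        ) from None
    geometry = {
        k: v
        for k, v in base.items()
        if k not in ("arc_start_deg", "arc_stop_deg", "prescription_gy", "fractions", "spacing_mm")
    }
    geometry.update(overrides.pop("geometry", {}))
    kwargs = dict(
        scenario=scenario,
        arc_start_deg=base["arc_start_deg"],
        arc_stop_deg=base["arc_stop_deg"],
        prescription_gy=base["prescription_gy"],
        fractions=base["fractions"],
        spacing_mm=base["spacing_mm"],
    )
    kwargs.update(overrides)
    kwargs["geometry"] = geometry
    return ScenarioSpec(**kwargs)


def _sphere(centers: np.ndarray, center_mm: Sequence[float], radius_mm: float) -> np.ndarray:
    delta = centers - np.asarray(center_mm, dtype=float)
    return (delta**2).sum(axis=1) <= radius_mm**2


def build_phantom(spec: ScenarioSpec) -> tuple[VoxelPhantom, list[ROIMask]]:
    """Construct the voxel phantom and ROI set for a scenario.

    The body is a water cylinder (axis superior-inferior) embedded in air;
    all ROIs are carved from body voxels, so no ROI overlaps air.  The
    construction is deterministic: identical specs give identical grids.
    """
    geo = dict(SCENARIO_DEFAULTS[spec.scenario])
    geo.update(spec.geometry)
    shape = tuple(int(n) for n in geo["grid_shape"])
    h = float(spec.spacing_mm)
    phantom_density = np.full(shape, AIR_RSP, dtype=float)
    phantom = VoxelPhantom(phantom_density, (h, h, h))
    centers = phantom.voxel_centers_mm()
    iso = phantom.isocenter_mm

    body_r = float(geo["body_radius_mm"])
    half_extent = min(shape[0], shape[1]) * h / 2.0
    if body_r > half_extent:
        raise GeometryError(
            f"body radius {body_r} mm exceeds grid half-extent {half_extent} mm"
        )
    radial = np.hypot(centers[:, 0] - iso[0], centers[:, 1] - iso[1])
    body = (radial <= body_r).reshape(shape)
    density = np.where(body, WATER_RSP, AIR_RSP)
    phantom = VoxelPhantom(density, (h, h, h))

    rois: list[ROIMask] = []
    t_r = float(geo["target_radius_mm"])

    if spec.scenario == "prostate-like":
        target = _sphere(centers, iso, t_r).reshape(shape) & body
        o_r = float(geo["oar_radius_mm"])
        off = float(geo["oar_offset_mm"])
        # two lateral-posterior organs at risk (anterior is +y)
        left = _sphere(centers, iso + np.array([off * 0.707, -off * 0.707, 0.0]), o_r)
        right = _sphere(centers, iso + np.array([-off * 0.707, -off * 0.707, 0.0]), o_r)
        rois.append(ROIMask("ctv", target, "target"))
        rois.append(ROIMask("oar_left", left.reshape(shape) & body & ~target, "oar"))
        rois.append(ROIMask("oar_right", right.reshape(shape) & body & ~target, "oar"))
    elif spec.scenario == "liver-like":
        t_center = iso + np.array([float(geo["target_offset_mm"]), 0.0, 0.0])
        ctv = _sphere(centers, t_center, t_r).reshape(shape) & body
        gtv = _sphere(centers, t_center, float(geo["gtv_radius_mm"])).reshape(shape) & body
        liver = _sphere(centers, t_center + np.array([4.0, 0.0, 0.0]),
                        float(geo["liver_radius_mm"])).reshape(shape) & body
        rois.append(ROIMask("ctv", ctv, "target"))
        rois.append(ROIMask("gtv", gtv, "target"))
        rois.append(ROIMask("normal_liver", liver & ~ctv, "oar"))
    elif spec.scenario == "brain-like":
        target = _sphere(centers, iso, t_r).reshape(shape) & body
        o_r = float(geo["oar_radius_mm"])
        off = float(geo["oar_offset_mm"])
        oar_offsets = {
            "brainstem": np.array([0.0, -off, 0.0]),
            "chiasm": np.array([0.0, off, 0.0]),
            "optic_nerve_left": np.array([off, 0.0, 0.0]),
            "optic_nerve_right": np.array([-off, 0.0, 0.0]),
        }
        rois.append(ROIMask("ctv", target, "target"))
        for name, offset in oar_offsets.items():
            m = _sphere(centers, iso + offset, o_r).reshape(shape) & body & ~target
            rois.append(ROIMask(name, m, "oar"))
    else:  # pragma: no cover - guarded by ScenarioSpec
        raise ConfigurationError(f"unknown scenario {spec.scenario!r}")

    rois.append(ROIMask("body", body, "external"))
    for roi in rois:
        if roi.mask.shape != shape:
            raise GeometryError(f"ROI {roi.name!r} shape mismatch")
        if np.any(roi.mask & ~body):
            raise GeometryError(f"ROI {roi.name!r} extends outside the body")
    return phantom, rois


def shrink_roi(roi: ROIMask, margin_mm: float, phantom: VoxelPhantom) -> ROIMask:
    """Erode an ROI by a metric margin (mm).

    Erosion works on the Euclidean distance transform computed with the
    physical voxel spacing, so anisotropic grids behave correctly.  The
    transform measures distance to the nearest exterior voxel *center*,
    which overestimates the distance to the ROI surface by between zero
    and half a voxel depending on direction; the threshold applies the
    quarter-voxel midpoint correction.  A zero margin returns the input
    unchanged; eroding to the empty set is legal (it ends a shrink
    series) and raises a warning.
    """
    if margin_mm < 0:
        raise ContractViolation(f"margin must be >= 0, got {margin_mm}")
    if margin_mm == 0:
        return roi
    dist = ndimage.distance_transform_edt(roi.mask, sampling=phantom.spacing)
    quarter_voxel = float(np.mean(phantom.spacing)) / 4.0
    eroded = dist > (margin_mm + quarter_voxel)
    if not eroded.any():
        warnings.warn(
            f"shrinking ROI {roi.name!r} by {margin_mm} mm leaves an empty mask",
            stacklevel=2,
        )
    # an emptied target would violate the non-empty target invariant; the
    # endpoint of a shrink series is returned as a plain region instead
    kind = roi.kind if eroded.any() else "oar"
    return ROIMask(f"{roi.name}_shrunk_{margin_mm:g}mm", eroded, kind)


def sib_series(
    target: ROIMask, phantom: VoxelPhantom, step_mm: float = 5.0, max_steps: int = 10
) -> list[ROIMask]:
    """Nested boost volumes obtained by shrinking a target in fixed steps.

    Returns the target itself followed by successively eroded copies
    (cumulative margins ``step_mm, 2*step_mm, ...``) until the erosion
    empties, mirroring how simultaneous-integrated-boost series are built
    by shrinking a clinical target volume.  Masks are strictly nested.
    """
    series = [ROIMask("sib_0", target.mask, "target")]
    for k in range(1, max_steps + 1):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            nxt = shrink_roi(target, k * step_mm, phantom)
        if not nxt.mask.any():
            break
        series.append(ROIMask(f"sib_{k}", nxt.mask, "target"))
    return series


def save_phantom(path, phantom: VoxelPhantom, rois: Sequence[ROIMask]) -> None:
    """Persist a phantom and its ROIs to a compressed ``.npz`` container.

    Array payloads go into the npz; a JSON metadata record (spacing,
    origin, ROI names/kinds) is stored alongside as a string array.
    """
    meta = {
        "spacing_mm": list(phantom.spacing),
        "origin_mm": list(phantom.origin),
        "rois": [{"name": r.name, "kind": r.kind} for r in rois],
    }
    arrays = {"density": phantom.density, "meta_json": np.array(json.dumps(meta))}
    for i, roi in enumerate(rois):
        arrays[f"roi_{i}"] = roi.mask
    np.savez_compressed(path, **arrays)


def load_phantom(path) -> tuple[VoxelPhantom, list[ROIMask]]:
    """Inverse of :func:`save_phantom`."""
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta_json"]))
        phantom = VoxelPhantom(
            data["density"], tuple(meta["spacing_mm"]), tuple(meta["origin_mm"])
        )
        rois = [
            ROIMask(rec["name"], data[f"roi_{i}"], rec["kind"])
            for i, rec in enumerate(meta["rois"])
        ]
    return phantom, rois
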