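"""Deterministic digital breast phantom with analytic ground truth.

The phantom emulates a bilateral breast DCE-MRI label map in the canonical
frame: a posterior chest-wall slab, hemispherical breasts attached to its
anterior face, a skin shell, a paraboloidal nipple bump at each apex, a
deep fibroglandular core with a retroareolar stalk converging behind the
nipple (the ductal tissue that makes the nipple the unique spot where
fibroglandular tissue approaches the skin), tubular vessels, and
axis-aligned ellipsoidal tumor foci.

Ground truth (volumes, extents, tumor-to-landmark distances, nipple
position, intended quadrant) is computed from the continuous geometry, not
from the voxel grid, so voxelisation error is a measurable quantity.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from ._geometry import ellipsoid_extremal_distance, point_segment_distance_grid
from .labelmap import LabelMap, TissueSchema

__all__ = [
    "TumorSpec",
    "VesselSpec",
    "AdiposeLobeSpec",
    "PhantomConfig",
    "TumorTruth",
    "SideTruth",
    "GroundTruth",
    "PhantomConfigError",
    "generate_phantom",
    "phantom_suite",
    "PRESET_NAMES",
]


class PhantomConfigError(ValueError):
    """The phantom configuration is geometrically inconsistent."""


@dataclass(frozen=True)
class TumorSpec:
    """Axis-aligned ellipsoidal tumor focus (mm, canonical frame)."""

    center_mm: tuple
    semi_axes_mm: tuple


@dataclass(frozen=True)
class VesselSpec:
    """Capsule (cylinder with hemispherical caps) blood vessel."""

    start_mm: tuple
    end_mm: tuple
    radius_mm: float


@dataclass(frozen=True)
class AdiposeLobeSpec:
    """Extra spherical adipose body fused to a breast (e.g. an inframammary
    bulge or a lateral lobe); carries its own skin shell."""

    center_mm: tuple
    radius_mm: float


@dataclass(frozen=True)
class PhantomConfig:
    shape: tuple = (160, 80, 96)
    spacing_mm: tuple = (1.0, 1.0, 1.0)
    chest_thickness_mm: float = 14.0
    breast_radius_mm: float = 35.0
    #: x positions of breast centers; one entry = unilateral, two = bilateral
    breast_centers_x_mm: tuple = (120.0, 40.0)
    breast_center_z_mm: float | None = None
    skin_thickness_mm: float = 2.0
    fibro_semi_axes_mm: tuple = (13.0, 12.0, 13.0)
    #: subcutaneous clearance between skin inner surface and core front
    fibro_anterior_gap_mm: float = 16.0
    fibro_stalk_radius_mm: float = 4.0
    #: depth of the stalk tip beneath the outer breast surface at the apex
    fibro_stalk_tip_depth_mm: float = 4.0
    nipple_radius_mm: float = 5.0
    nipple_height_mm: float = 2.0
    vessels: tuple = ()
    tumors: tuple = ()
    adipose_lobes: tuple = ()
    jitter_mm: float = 0.0
    seed: int = 0

    def field_of_view_mm(self) -> tuple:
        return tuple(n * s for n, s in zip(self.shape, self.spacing_mm))


@dataclass(frozen=True)
class TumorTruth:
    center_mm: tuple
    semi_axes_mm: tuple
    side: str
    volume_mm3: float
    extents_mm: tuple
    to_skin_mm: float
    to_chest_mm: float
    to_nipple_mm: float
    intended_quadrant: str


@dataclass(frozen=True)
class SideTruth:
    side: str
    breast_center_mm: tuple
    breast_radius_mm: float
    nipple_apex_mm: tuple
    #: apex offset 6 mm posteriorly -- the reference the detector aims for
    nipple_ref_mm: tuple
    analytic_breast_volume_mm3: float


@dataclass
class GroundTruth:
    sides: dict
    tumors: list
    voxel_counts: dict
    chest_plane_y_mm: float
    spacing_mm: tuple

    def tumors_on(self, side: str):
        return [t for t in self.tumors if t.side == side]

    def min_distances_on(self, side: str) -> dict:
        ts = self.tumors_on(side)
        if not ts:
            return {}
        return {
            "to_skin_mm": min(t.to_skin_mm for t in ts),
            "to_chest_mm": min(t.to_chest_mm for t in ts),
            "to_nipple_mm": min(t.to_nipple_mm for t in ts),
        }

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "chest_plane_y_mm": self.chest_plane_y_mm,
            "spacing_mm": list(self.spacing_mm),
            "sides": {k: asdict(v) for k, v in self.sides.items()},
            "tumors": [asdict(t) for t in self.tumors],
            "voxel_counts": {k: int(v) for k, v in self.voxel_counts.items()},
        }


def _ellipsoid_mask(X, Y, Z, center, semi) -> np.ndarray:
    return (
        ((X - center[0]) / semi[0]) ** 2
        + ((Y - center[1]) / semi[1]) ** 2
        + ((Z - center[2]) / semi[2]) ** 2
    ) <= 1.0


def _validate(config: PhantomConfig) -> None:
    for name in (
        "chest_thickness_mm",
        "breast_radius_mm",
        "skin_thickness_mm",
        "nipple_radius_mm",
        "nipple_height_mm",
    ):
        if getattr(config, name) <= 0:
            raise PhantomConfigError(f"{name} must be positive")
    if any(s <= 0 for s in config.spacing_mm):
        raise PhantomConfigError("spacing must be positive")
    if config.skin_thickness_mm >= config.breast_radius_mm:
        raise PhantomConfigError("skin thicker than the breast radius")
    if not config.breast_centers_x_mm:
        raise PhantomConfigError("at least one breast center required")

    fov = config.field_of_view_mm()
    y0 = fov[1] - config.chest_thickness_mm
    R, t = config.breast_radius_mm, config.skin_thickness_mm
    inner = R - t
    centers = _breast_centers(config)
    for spec in config.tumors:
        tc = np.asarray(spec.center_mm, dtype=float)
        semi = np.asarray(spec.semi_axes_mm, dtype=float)
        if np.any(semi <= 0):
            raise PhantomConfigError("tumor semi-axes must be positive")
        if tc[1] + semi[1] >= y0:
            raise PhantomConfigError(
                f"tumor at {spec.center_mm} overlaps the chest slab"
            )
        inside_any = any(
            np.linalg.norm(tc - np.asarray(cb)) + semi.max() <= inner
            for cb in centers
        )
        if not inside_any:
            raise PhantomConfigError(
                f"tumor at {spec.center_mm} is not strictly inside a breast"
            )


def _breast_centers(config: PhantomConfig):
    fov = config.field_of_view_mm()
    y0 = fov[1] - config.chest_thickness_mm
    cz = config.breast_center_z_mm if config.breast_center_z_mm is not None else fov[2] / 2.0
    return [(float(cx), float(y0), float(cz)) for cx in config.breast_centers_x_mm]


def _side_of_x(x: float, fov_x: float) -> str:
    return "left" if x >= fov_x / 2.0 else "right"


def generate_phantom(config: PhantomConfig):
    """Voxelise the phantom. Returns ``(LabelMap, GroundTruth)``.

    Deterministic for a fixed config (the seed only drives the optional
    boundary jitter field).
    """
    _validate(config)
    schema = TissueSchema.default()
    fov = config.field_of_view_mm()
    y0 = fov[1] - config.chest_thickness_mm
    R, t = config.breast_radius_mm, config.skin_thickness_mm
    centers = _breast_centers(config)

    lm = LabelMap(
        np.zeros(config.shape, dtype=np.int16), config.spacing_mm, schema
    )
    X, Y, Z = lm.center_grids_mm()
    labels = np.full(config.shape, schema["air"], dtype=np.int16)

    # posterior chest slab
    labels[np.broadcast_to(Y >= y0, config.shape)] = schema["chest"]

    if config.jitter_mm > 0:
        rng = np.random.default_rng(config.seed)
        noise = gaussian_filter(rng.standard_normal(config.shape), sigma=4.0)
        noise /= max(noise.std(), 1e-12)
        dR = config.jitter_mm * noise
    else:
        dR = 0.0

    anterior = Y < y0
    body = np.zeros(config.shape, dtype=bool)      # everything breast-shaped
    interior = np.zeros(config.shape, dtype=bool)  # body minus the skin shell
    bodies = [(cb, R) for cb in centers]
    bodies += [(tuple(map(float, l.center_mm)), float(l.radius_mm)) for l in config.adipose_lobes]
    for cb, rad in bodies:
        r = np.sqrt((X - cb[0]) ** 2 + (Y - cb[1]) ** 2 + (Z - cb[2]) ** 2)
        body |= (r <= rad + dR) & anterior
        interior |= (r <= rad - t + dR) & anterior

    labels[interior] = schema["adipose"]

    # fibroglandular core + retroareolar stalk, clipped to the interior
    fibro = np.zeros(config.shape, dtype=bool)
    for cb in centers:
        apex_y = cb[1] - R
        semi = np.asarray(config.fibro_semi_axes_mm, dtype=float)
        core_center = (
            cb[0],
            apex_y + t + config.fibro_anterior_gap_mm + semi[1],
            cb[2],
        )
        fibro |= _ellipsoid_mask(X, Y, Z, core_center, semi)
        if config.fibro_stalk_radius_mm > 0:
            tip = (cb[0], apex_y + config.fibro_stalk_tip_depth_mm, cb[2])
            fibro |= (
                point_segment_distance_grid(X, Y, Z, core_center, tip)
                <= config.fibro_stalk_radius_mm
            )
    labels[fibro & interior] = schema["fibroglandular"]

    for v in config.vessels:
        vmask = (
            point_segment_distance_grid(X, Y, Z, v.start_mm, v.end_mm) <= v.radius_mm
        )
        labels[vmask & interior] = schema["vessel"]

    # skin shell over every body, plus the nipple bumps
    labels[body & ~interior] = schema["skin"]
    for cb in centers:
        apex_y = cb[1] - R
        h, rn = config.nipple_height_mm, config.nipple_radius_mm
        rho2 = (X - cb[0]) ** 2 + (Z - cb[2]) ** 2
        bump = (Y < apex_y) & (Y >= apex_y - h) & (
            rho2 <= rn**2 * (1.0 - (apex_y - Y) / h)
        )
        labels[np.broadcast_to(bump, config.shape)] = schema["skin"]

    for spec in config.tumors:
        labels[_ellipsoid_mask(X, Y, Z, spec.center_mm, spec.semi_axes_mm)] = schema["tumor"]

    out = LabelMap(labels, config.spacing_mm, schema)
    truth = _ground_truth(config, out)
    return out, truth


def _ground_truth(config: PhantomConfig, labelmap: LabelMap) -> GroundTruth:
    fov = config.field_of_view_mm()
    y0 = fov[1] - config.chest_thickness_mm
    R, t = config.breast_radius_mm, config.skin_thickness_mm
    centers = _breast_centers(config)

    sides = {}
    for cb in centers:
        side = _side_of_x(cb[0], fov[0])
        apex = (cb[0], cb[1] - R - config.nipple_height_mm, cb[2])
        hemi = 2.0 / 3.0 * np.pi * R**3
        bump = 0.5 * np.pi * config.nipple_radius_mm**2 * config.nipple_height_mm
        sides[side] = SideTruth(
            side=side,
            breast_center_mm=cb,
            breast_radius_mm=R,
            nipple_apex_mm=apex,
            nipple_ref_mm=(apex[0], apex[1] + 6.0, apex[2]),
            analytic_breast_volume_mm3=hemi + bump,
        )

    tumors = []
    for spec in config.tumors:
        tc = np.asarray(spec.center_mm, dtype=float)
        semi = np.asarray(spec.semi_axes_mm, dtype=float)
        # tumor belongs to the nearest breast
        cb = min(centers, key=lambda c: np.linalg.norm(tc - np.asarray(c)))
        side = _side_of_x(cb[0], fov[0])
        st = sides[side]
        far = ellipsoid_extremal_distance(cb, tc, semi, mode="max")
        to_skin = (R - t) - far
        to_chest = y0 - (tc[1] + semi[1])
        to_nipple = ellipsoid_extremal_distance(st.nipple_ref_mm, tc, semi, mode="min")
        nref = np.asarray(st.nipple_ref_mm)
        lateral_sign = 1.0 if side == "left" else -1.0
        horiz = "outer" if (tc[0] - nref[0]) * lateral_sign > 0 else "inner"
        vert = "upper" if tc[2] >= nref[2] else "lower"
        tumors.append(
            TumorTruth(
                center_mm=tuple(tc),
                semi_axes_mm=tuple(semi),
                side=side,
                volume_mm3=float(4.0 / 3.0 * np.pi * np.prod(semi)),
                extents_mm=tuple(2.0 * semi),
                to_skin_mm=float(to_skin),
                to_chest_mm=float(to_chest),
                to_nipple_mm=float(to_nipple),
                intended_quadrant=f"{vert}-{horiz}",
            )
        )

    counts = {
        name: int(np.count_nonzero(labelmap.voxels == labelmap.schema[name]))
        for name in labelmap.schema.label_of
    }
    return GroundTruth(
        sides=sides,
        tumors=tumors,
        voxel_counts=counts,
        chest_plane_y_mm=float(y0),
        spacing_mm=config.spacing_mm,
    )


# ---------------------------------------------------------------------------
# presets

_BASE_VESSELS = (
    VesselSpec((106.0, 62.0, 34.0), (134.0, 62.0, 62.0), 1.5),
    VesselSpec((54.0, 62.0, 34.0), (26.0, 62.0, 62.0), 1.5),
)


def _base(**overrides) -> PhantomConfig:
    return replace(PhantomConfig(vessels=_BASE_VESSELS), **overrides)


def _presets() -> dict:
    return {
        # mirror-symmetric anatomy, spherical tumor in the left upper-outer
        "unifocal_small": _base(
            tumors=(TumorSpec((126.0, 50.0, 54.0), (10.0, 10.0, 10.0)),),
        ),
        "unifocal_large": _base(
            tumors=(TumorSpec((122.0, 50.0, 50.0), (14.0, 12.0, 10.0)),),
        ),
        # two foci with a 6 mm surface gap: a 5 mm margin forces a merge
        "multifocal_near": _base(
            tumors=(
                TumorSpec((110.0, 50.0, 52.0), (8.0, 8.0, 8.0)),
                TumorSpec((132.0, 50.0, 52.0), (8.0, 8.0, 8.0)),
            ),
        ),
        # two foci with a 42 mm surface gap (> 2 x the 20 mm max margin)
        "multifocal_far": _base(
            shape=(184, 84, 96),
            breast_radius_mm=42.0,
            breast_centers_x_mm=(138.0, 46.0),
            vessels=(),
            tumors=(
                TumorSpec((111.0, 62.0, 52.0), (6.0, 6.0, 6.0)),
                TumorSpec((165.0, 62.0, 52.0), (6.0, 6.0, 6.0)),
            ),
        ),
        # mirror-symmetric tumors, one per breast
        "bilateral": _base(
            tumors=(
                TumorSpec((126.0, 50.0, 54.0), (9.0, 9.0, 9.0)),
                TumorSpec((34.0, 50.0, 54.0), (9.0, 9.0, 9.0)),
            ),
        ),
        "dense_fibroglandular": _base(
            fibro_semi_axes_mm=(17.0, 14.0, 17.0),
            tumors=(TumorSpec((126.0, 50.0, 54.0), (10.0, 10.0, 10.0)),),
        ),
    }


PRESET_NAMES = tuple(_presets().keys())


def phantom_suite(name: str) -> PhantomConfig:
    """Return a frozen preset configuration by name."""
    presets = _presets()
    if name not in presets:
        raise KeyError(
            f"unknown preset {name!r}; choose from {sorted(presets)}"
        )
    return presets[name]
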