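"""Reformatting native-coordinate volumes into cardiac measurement planes.

Five planes are produced per case: two long-axis views (2-CH and PLAX,
planes containing the LV long axis at two azimuths) and three short-axis
(SAX) views perpendicular to the long axis at basal / middle / apical
positions, placed at configurable fractions of the apex-to-base length.

The long axis is estimated from the blood-pool segmentation (principal
second-moment eigenvector); the apex is the myocardial extreme opposite
the base, and the basal end is identified from the cavity cross-section
area profile (the cavity ends in a flat basal cut, the apex tapers to a
point).  ED-derived planes are reused for the ES phase so that strains
compare corresponding planes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

from .volumes import LabelVolume, ImageVolume, BLOOD_POOL, MYOCARDIUM, VALID_LABELS

VIEW_KEYS = ("2CH", "PLAX", "SAX_basal", "SAX_middle", "SAX_apical")

#: Minimum blood-pool elongation (principal / second moment eigenvalue ratio)
#: below which the long axis is considered undefined.
MIN_EIGENVALUE_RATIO = 1.2


class DegenerateAxisError(ValueError):
    """Blood pool too isotropic for a long axis to be defined."""


@dataclass(frozen=True)
class LVAxis:
    """Unit apex->base direction with apex/base landmarks (mm, world frame)."""

    direction: tuple[float, float, float]
    apex: tuple[float, float, float]
    base: tuple[float, float, float]
    length_mm: float

    def __post_init__(self):
        d = np.asarray(self.direction)
        if abs(np.linalg.norm(d) - 1.0) > 1e-6:
            raise ValueError("axis direction must be unit length")
        if not self.length_mm > 0:
            raise ValueError("axis length must be positive")


@dataclass(frozen=True)
class ViewConfig:
    sax_fractions: tuple = (("basal", 0.8), ("middle", 0.5), ("apical", 0.2))
    long_axis_azimuth_deg: tuple = (("2CH", 0.0), ("PLAX", 90.0))
    pixel_spacing_mm: float = 1.0
    extent_mm: float = 176.0
    #: reformat slab thickness: the float masks and image are averaged over
    #: this many evenly spaced sub-planes across the slab (labels stay
    #: single-plane nearest-neighbour).  A thin slab mimics clinical
    #: reformats and suppresses through-plane voxel-quantisation bias.
    slab_thickness_mm: float = 3.0
    slab_samples: int = 3

    def __post_init__(self):
        for name, f in self.sax_fractions:
            if not (0.0 < f < 1.0):
                raise ValueError(f"SAX fraction for {name!r} must lie in (0,1), got {f}")
        if self.pixel_spacing_mm <= 0 or self.extent_mm <= 0:
            raise ValueError("pixel spacing and extent must be positive")
        if self.slab_thickness_mm < 0 or self.slab_samples < 1:
            raise ValueError("slab thickness must be >= 0 and slab samples >= 1")

    @property
    def sax(self) -> dict:
        return dict(self.sax_fractions)

    @property
    def azimuths(self) -> dict:
        return dict(self.long_axis_azimuth_deg)


@dataclass
class PlanarView:
    """One resampled plane: nearest-neighbour labels plus per-class float
    masks (trilinear) for sub-pixel boundary measurement."""

    key: str
    center: np.ndarray          # (3,) mm
    axes: np.ndarray            # (2, 3) in-plane unit vectors
    normal: np.ndarray          # (3,)
    spacing: float              # mm / pixel, isotropic in-plane
    labels: np.ndarray          # (H, W) uint8
    masks: np.ndarray           # (n_classes, H, W) float32
    image: np.ndarray | None = None

    def plane_definition(self) -> dict:
        return {
            "key": self.key,
            "center_mm": [float(v) for v in self.center],
            "axes": [[float(v) for v in a] for a in self.axes],
            "normal": [float(v) for v in self.normal],
            "pixel_spacing_mm": self.spacing,
            "shape": list(self.labels.shape),
        }


@dataclass
class ViewSet:
    views: dict
    axis: LVAxis
    config: ViewConfig

    def __getitem__(self, key: str) -> PlanarView:
        return self.views[key]

    def __contains__(self, key):
        return key in self.views

    def keys(self):
        return self.views.keys()

    def plane_definitions(self) -> dict:
        return {k: v.plane_definition() for k, v in self.views.items()}


# --- long-axis estimation -------------------------------------------------

def _projected_voxel_step(grid, direction: np.ndarray) -> float:
    """Voxel footprint along a direction (for slab widths)."""
    return float(np.abs(np.asarray(grid.spacing) * direction).sum())


def estimate_long_axis(label_volume: LabelVolume) -> LVAxis:
    pool = label_volume.mask(BLOOD_POOL)
    if not pool.any():
        raise ValueError("cannot estimate long axis: no blood-pool voxels in volume")

    coords = label_volume.grid.world_coordinates()[pool]
    centroid = coords.mean(axis=0)
    centered = coords - centroid
    cov = centered.T @ centered / len(coords)
    evals, evecs = np.linalg.eigh(cov)      # ascending
    if evals[2] / max(evals[1], 1e-12) < MIN_EIGENVALUE_RATIO:
        raise DegenerateAxisError(
            f"blood pool is nearly isotropic (eigenvalue ratio "
            f"{evals[2]/max(evals[1],1e-12):.3f} < {MIN_EIGENVALUE_RATIO}); long axis undefined"
        )
    v = evecs[:, 2]

    t = centered @ v
    step = _projected_voxel_step(label_volume.grid, v)
    slab = 2.0 * step
    n_lo = int(np.count_nonzero(t <= t.min() + slab))
    n_hi = int(np.count_nonzero(t >= t.max() - slab))
    # the basal end is the flat cavity cut (large terminal cross-section);
    # the apex tapers to a point
    if n_lo > n_hi:
        v = -v
        t = -t

    t_base = float(t.max()) + 0.5 * step
    base_slab = coords[t >= t.max() - slab]
    base_point = base_slab.mean(axis=0)
    base_point = base_point + (t_base - (base_point - centroid) @ v) * v

    myo = label_volume.mask(MYOCARDIUM)
    if not myo.any():
        raise ValueError("cannot locate apex: no myocardium voxels in volume")
    mcoords = label_volume.grid.world_coordinates()[myo]
    tm = (mcoords - centroid) @ v
    t_apex = float(tm.min()) - 0.5 * step
    apex_slab = mcoords[tm <= tm.min() + slab]
    apex_point = apex_slab.mean(axis=0)
    apex_point = apex_point + (t_apex - (apex_point - centroid) @ v) * v

    length = t_base - t_apex
    return LVAxis(
        direction=tuple(float(x) for x in v),
        apex=tuple(float(x) for x in apex_point),
        base=tuple(float(x) for x in base_point),
        length_mm=float(length),
    )


# --- plane resampling -----------------------------------------------------

def _orthonormal_frame(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic in-plane frame perpendicular to u."""
    e = np.zeros(3)
    e[int(np.argmin(np.abs(u)))] = 1.0
    v = np.cross(u, e)
    v /= np.linalg.norm(v)
    w = np.cross(u, v)
    return v, w

def _sample_plane(label_volume, image_volume, key, center, ax0, ax1, normal, cfg):
    n = int(round(cfg.extent_mm / cfg.pixel_spacing_mm))
    offs = (np.arange(n) - (n - 1) / 2.0) * cfg.pixel_spacing_mm
    world = (center[None, None, :]
             + offs[:, None, None] * ax0[None, None, :]
             + offs[None, :, None] * ax1[None, None, :])

    if cfg.slab_samples > 1 and cfg.slab_thickness_mm > 0:
        depths = np.linspace(-cfg.slab_thickness_mm / 2.0, cfg.slab_thickness_mm / 2.0,
                             cfg.slab_samples)
    else:
        depths = np.array([0.0])

    idx_center = label_volume.grid.index_of(world.reshape(-1, 3)).T  # (3, N)
    lab = map_coordinates(label_volume.array, idx_center, order=0, mode="constant", cval=0)
    lab = lab.reshape(n, n).astype(np.uint8)

    class_fields = [(label_volume.array == c).astype(np.float32) for c in VALID_LABELS]
    masks = np.zeros((len(VALID_LABELS), n, n), dtype=np.float32)
    img = np.zeros((n, n), dtype=np.float32) if image_volume is not None else None
    for d in depths:
        idx = label_volume.grid.index_of((world + d * normal).reshape(-1, 3)).T
        for ci, f in enumerate(class_fields):
            masks[ci] += map_coordinates(f, idx, order=1, mode="constant",
                                         cval=0.0).reshape(n, n)
        if img is not None:
            img += map_coordinates(image_volume.array.astype(np.float32), idx, order=1,
                                   mode="constant",
                                   cval=float(image_volume.array.min())).reshape(n, n)
    masks /= len(depths)
    if img is not None:
        img /= len(depths)
    return PlanarView(key=key, center=center.copy(), axes=np.stack([ax0, ax1]),
                      normal=normal.copy(), spacing=cfg.pixel_spacing_mm,
                      labels=lab, masks=masks, image=img)


def resample_views(label_volume: LabelVolume, image_volume: ImageVolume | None,
                   lv_axis: LVAxis, view_config: ViewConfig | None = None) -> ViewSet:
    """Resample the five measurement planes.

    Labels use nearest-neighbour interpolation; images (and the auxiliary
    per-class masks) are interpolated trilinearly.  Long-axis views have
    their first in-plane axis aligned with the apex->base direction.
    """
    cfg = view_config or ViewConfig()
    u = np.asarray(lv_axis.direction)
    apex = np.asarray(lv_axis.apex)
    base = np.asarray(lv_axis.base)
    v0, w0 = _orthonormal_frame(u)

    views = {}
    for name, az in cfg.azimuths.items():
        a = np.deg2rad(az)
        m = np.cos(a) * v0 + np.sin(a) * w0
        center = (apex + base) / 2.0
        normal = np.cross(u, m)
        views[name] = _sample_plane(label_volume, image_volume, name, center, u, m, normal, cfg)
    for level, g in cfg.sax.items():
        center = apex + g * lv_axis.length_mm * u
        views[f"SAX_{level}"] = _sample_plane(
            label_volume, image_volume, f"SAX_{level}", center, v0, w0, u, cfg)
    return ViewSet(views=views, axis=lv_axis, config=cfg)


def save_views(view_set: ViewSet, out_dir: str, prefix: str = "view",
               write_images: bool = True) -> dict:
    """Export a view set as PNG per plane plus a JSON sidecar with the
    plane definitions (centre, in-plane axes, normal, spacing)."""
    import json
    import os

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    os.makedirs(out_dir, exist_ok=True)
    paths = {"planes": os.path.join(out_dir, f"{prefix}_planes.json")}
    for key, view in view_set.views.items():
        fig, axes = plt.subplots(1, 2 if view.image is not None else 1,
                                 figsize=(8, 4), squeeze=False)
        axes[0, 0].imshow(view.labels.T, origin="lower", cmap="viridis",
                          vmin=0, vmax=2, interpolation="nearest")
        axes[0, 0].set_title(f"{key} labels")
        if view.image is not None and write_images:
            axes[0, 1].imshow(view.image.T, origin="lower", cmap="gray")
            axes[0, 1].set_title(f"{key} image (HU)")
        for ax in axes.ravel():
            ax.set_xticks([]), ax.set_yticks([])
        p = os.path.join(out_dir, f"{prefix}_{key}.png")
        fig.savefig(p, dpi=110, bbox_inches="tight")
        plt.close(fig)
        paths[key] = p
    with open(paths["planes"], "w") as fh:
        json.dump(view_set.plane_definitions(), fh, indent=2)
    return paths
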