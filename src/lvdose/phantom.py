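"""Synthetic beating-LV phantom with closed-form ground-truth function.

The left ventricle is modelled as a truncated prolate-spheroid shell in a
canonical pose (long axis along +z, apex pointing to -z).  At end-diastole
(ED) the endocardial and epicardial surfaces are concentric spheroids
centred on the origin; the cavity is truncated by a basal plane at
``base_truncation_frac * endo_long_axis`` above the centre, and the
myocardial shell closes over the cavity with a basal lid one apical-wall
thickness deep, so the blood pool is always enclosed.

End-systole (ES) scales the endocardial semi-axes by ``es_radial_scale``
and ``es_long_scale`` *about the apex*: the apex stays fixed while the base
descends, emulating mitral-annular descent.  The epicardium follows either
a volume-preserving rule (shell volume conserved, giving nonzero wall
thickening) or a fixed-thickness rule.

Because every surface is an ellipsoid, cavity volumes, long-axis lengths,
endocardial radii and wall thicknesses have closed forms, which yields
exact ground truth for EF, GLS, per-level CS and per-level wall thickening.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.optimize import brentq

from .volumes import Grid, ImageVolume, LabelVolume, BACKGROUND, MYOCARDIUM, BLOOD_POOL

ED, ES = "ED", "ES"
PHASES = (ED, ES)

SAX_LEVELS = ("basal", "middle", "apical")
#: SAX plane positions as fractions of the apex->base axis length, from the apex.
DEFAULT_SAX_FRACTIONS = {"basal": 0.8, "middle": 0.5, "apical": 0.2}

DEFAULT_HU_MAP = {"background": 40.0, "myocardium": 100.0, "blood_pool": 350.0}

WALL_MODELS = ("volume-preserving", "fixed-thickness")

#: Default desk-scale voxel grid (96^3 at 1.5 mm isotropic, centred on origin).
DEFAULT_GRID = Grid.centered(96, 1.5)


class PhantomValidationError(ValueError):
    """Raised for geometrically invalid phantom parameters."""


class TargetEFError(ValueError):
    """Raised when a requested ejection fraction cannot be reached."""


def _truncated_spheroid_volume(a: float, c: float, f: float) -> float:
    """Volume of {x^2+y^2 <= a^2 (1 - z^2/c^2), z <= f*c} in mm^3."""
    return math.pi * a * a * c * (2.0 / 3.0 + f - f**3 / 3.0)


@dataclass(frozen=True)
class PhantomSpec:
    endo_long_axis_mm: float = 45.0
    endo_short_axis_mm: float = 28.0
    epi_long_axis_mm: float = 52.0
    epi_short_axis_mm: float = 36.0
    base_truncation_frac: float = 0.5
    es_radial_scale: float = 0.80
    es_long_scale: float = 0.85
    wall_model: str = "volume-preserving"
    orientation: tuple = (1, 0, 0, 0, 1, 0, 0, 0, 1)
    hu_map: tuple = tuple(sorted(DEFAULT_HU_MAP.items()))
    seed: int = 0

    def __post_init__(self):
        a_e, c_e = self.endo_short_axis_mm, self.endo_long_axis_mm
        a_p, c_p = self.epi_short_axis_mm, self.epi_long_axis_mm
        for name, v in (("endo_short", a_e), ("endo_long", c_e), ("epi_short", a_p), ("epi_long", c_p)):
            if not (v > 0):
                raise PhantomValidationError(f"{name} axis must be positive, got {v}")
        if c_e < a_e or c_p < a_p:
            raise PhantomValidationError("long semi-axes must be >= short semi-axes (prolate LV)")
        if a_p <= a_e or c_p <= c_e:
            raise PhantomValidationError(
                "epicardial semi-axes must strictly exceed endocardial semi-axes "
                f"(endo {a_e}x{c_e}, epi {a_p}x{c_p}): wall thickness would be <= 0"
            )
        if not (0.0 < self.base_truncation_frac < 1.0):
            raise PhantomValidationError("base_truncation_frac must lie in (0, 1)")
        for name, s in (("es_radial_scale", self.es_radial_scale), ("es_long_scale", self.es_long_scale)):
            if not (0.0 < s <= 1.0):
                raise PhantomValidationError(f"{name} must lie in (0, 1], got {s}")
        if self.wall_model not in WALL_MODELS:
            raise PhantomValidationError(f"wall_model must be one of {WALL_MODELS}")
        R = self.rotation_matrix
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-6) or abs(np.linalg.det(R) - 1.0) > 1e-6:
            raise PhantomValidationError("orientation must be a proper rotation (R R^T = I, det = +1)")

    # --- derived geometry -------------------------------------------------

    @property
    def rotation_matrix(self) -> np.ndarray:
        return np.asarray(self.orientation, dtype=float).reshape(3, 3)

    @property
    def hu(self) -> dict:
        return dict(self.hu_map)

    @property
    def lid_thickness_mm(self) -> float:
        """Depth of the basal myocardial lid (apical wall thickness at ED)."""
        return self.epi_long_axis_mm - self.endo_long_axis_mm

    def es_epi_axes(self) -> tuple[float, float]:
        """ES epicardial (short, long) semi-axes under the wall model."""
        a_e, c_e = self.endo_short_axis_mm, self.endo_long_axis_mm
        a_p, c_p = self.epi_short_axis_mm, self.epi_long_axis_mm
        s_r, s_l = self.es_radial_scale, self.es_long_scale
        if self.wall_model == "fixed-thickness":
            return s_r * a_e + (a_p - a_e), s_l * c_e + (c_p - c_e)
        # volume-preserving: long axis follows the endocardium, short axis
        # solved so the truncated-shell volume is conserved.
        c_p_es = s_l * c_p
        a_p_es_sq = (a_p * a_p * c_p - a_e * a_e * c_e * (1.0 - s_r * s_r * s_l)) / (s_l * c_p)
        return math.sqrt(a_p_es_sq), c_p_es

    def surfaces(self, phase: str) -> dict:
        """Ellipsoid parameters per phase in the canonical frame.

        Returns a dict with ``endo``/``epi`` entries ``(a, c, z_center)`` and
        the basal cut planes ``cavity_cut_z`` / ``myo_cut_z``.
        """
        if phase not in PHASES:
            raise ValueError(f"phase must be one of {PHASES}, got {phase!r}")
        a_e, c_e = self.endo_short_axis_mm, self.endo_long_axis_mm
        a_p, c_p = self.epi_short_axis_mm, self.epi_long_axis_mm
        f = self.base_truncation_frac
        if phase == ED:
            endo = (a_e, c_e, 0.0)
            epi = (a_p, c_p, 0.0)
            cavity_cut = f * c_e
        else:
            s_r, s_l = self.es_radial_scale, self.es_long_scale
            a_p_es, c_p_es = self.es_epi_axes()
            endo = (s_r * a_e, s_l * c_e, -c_e + s_l * c_e)  # apex fixed at -c_e
            epi = (a_p_es, c_p_es, -c_p + c_p_es)            # apex fixed at -c_p
            cavity_cut = endo[2] + f * endo[1]
        return {
            "endo": endo,
            "epi": epi,
            "cavity_cut_z": cavity_cut,
            "myo_cut_z": cavity_cut + self.lid_thickness_mm,
        }

    def cavity_volume_ml(self, phase: str) -> float:
        a, c, _ = self.surfaces(phase)["endo"]
        return _truncated_spheroid_volume(a, c, self.base_truncation_frac) / 1000.0

    def shell_volume_ml(self, phase: str) -> float:
        """Myocardial volume between epi and endo, below each surface's own cut."""
        s = self.surfaces(phase)
        f = self.base_truncation_frac
        v_epi = _truncated_spheroid_volume(s["epi"][0], s["epi"][1], f)
        v_endo = _truncated_spheroid_volume(s["endo"][0], s["endo"][1], f)
        return (v_epi - v_endo) / 1000.0

    def bounding_radius_mm(self) -> float:
        vals = [self.epi_long_axis_mm, self.epi_short_axis_mm]
        a_p_es, c_p_es = self.es_epi_axes()
        vals += [a_p_es, c_p_es]
        return float(max(vals))

    # --- (de)serialization ------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["orientation"] = [float(v) for v in self.orientation]
        d["hu_map"] = dict(self.hu_map)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        if "hu_map" in d and isinstance(d["hu_map"], dict):
            d["hu_map"] = tuple(sorted(d["hu_map"].items()))
        if "orientation" in d:
            d["orientation"] = tuple(float(v) for v in np.asarray(d["orientation"]).ravel())
        return cls(**d)


@dataclass(frozen=True)
class GroundTruthMetrics:
    """Closed-form functional metrics, all in percent, ED as reference."""

    ef_pct: float
    gls_pct: float
    cs_pct: dict
    wt_pct: dict

    def as_flat_dict(self) -> dict:
        out = {"ef": self.ef_pct, "gls": self.gls_pct}
        for lvl in SAX_LEVELS:
            out[f"cs_{lvl}"] = self.cs_pct[lvl]
            out[f"wt_{lvl}"] = self.wt_pct[lvl]
        return out


def _ellipse_radius(z: float, a: float, c: float, zc: float) -> float:
    u = 1.0 - ((z - zc) / c) ** 2
    return a * math.sqrt(u) if u > 0 else 0.0


def analytic_ground_truth(spec: PhantomSpec, sax_fractions: dict | None = None) -> GroundTruthMetrics:
    """Exact EF / GLS / CS / WT for a phantom spec.

    SAX planes are fixed in space at the ED positions (fractions of the
    apex->base axis measured from the epicardial apex), matching the view
    module's convention of reusing ED-derived planes for the ES phase.
    """
    sax_fractions = dict(DEFAULT_SAX_FRACTIONS if sax_fractions is None else sax_fractions)
    s_r, s_l = spec.es_radial_scale, spec.es_long_scale
    ef = 100.0 * (1.0 - s_r * s_r * s_l)
    gls = 100.0 * (s_l - 1.0)

    apex_z = -spec.epi_long_axis_mm
    base_z = spec.base_truncation_frac * spec.endo_long_axis_mm
    axis_len = base_z - apex_z

    ed, es = spec.surfaces(ED), spec.surfaces(ES)
    cs, wt = {}, {}
    for level, g in sax_fractions.items():
        z = apex_z + g * axis_len
        r_en_ed = _ellipse_radius(z, *ed["endo"])
        r_en_es = _ellipse_radius(z, *es["endo"])
        r_ep_ed = _ellipse_radius(z, *ed["epi"])
        r_ep_es = _ellipse_radius(z, *es["epi"])
        if r_en_ed <= 0:
            raise PhantomValidationError(f"SAX plane '{level}' misses the ED cavity (z={z:.1f} mm)")
        cs[level] = 100.0 * (r_en_es / r_en_ed - 1.0)
        t_ed = r_ep_ed - r_en_ed
        t_es = r_ep_es - r_en_es
        wt[level] = 100.0 * (t_es - t_ed) / t_ed
    return GroundTruthMetrics(ef_pct=ef, gls_pct=gls, cs_pct=cs, wt_pct=wt)


def build_phantom_spec(params: dict | None = None, target_ef_pct: float | None = None,
                       seed: int = 0) -> PhantomSpec:
    """Construct a validated spec, optionally solving for a target EF.

    When ``target_ef_pct`` is given, ``es_radial_scale`` is solved by 1-D
    root finding on the analytic cavity-volume formula with ``es_long_scale``
    held at its supplied value, so the analytic EF matches the target.
    """
    params = dict(params or {})
    params.setdefault("seed", seed)
    if target_ef_pct is not None:
        if not (5.0 < target_ef_pct < 90.0):
            raise TargetEFError(f"target EF must lie in (5, 90) %, got {target_ef_pct}")
        s_l = float(params.get("es_long_scale", PhantomSpec.es_long_scale))
        lo, hi = 0.05, 1.0

        def ef_err(s_r):
            return 100.0 * (1.0 - s_r * s_r * s_l) - target_ef_pct

        if ef_err(lo) < 0 or ef_err(hi) > 0:
            raise TargetEFError(
                f"target EF {target_ef_pct}% unattainable with es_long_scale={s_l} "
                f"(attainable range: {100*(1-s_l):.1f}% to {100*(1-lo*lo*s_l):.1f}%)"
            )
        params["es_radial_scale"] = float(brentq(ef_err, lo, hi, xtol=1e-10))
        params["es_long_scale"] = s_l
    return PhantomSpec(**params)


# --- voxelization ---------------------------------------------------------

def voxelize_phase(spec: PhantomSpec, phase: str, grid: Grid | None = None
                   ) -> tuple[LabelVolume, ImageVolume]:
    """Rasterize one phase onto a grid: analytic inside-tests on the rotated
    ellipsoids produce labels; the HU image is the label-wise HU map
    (noise-free; dose degradation is the scanner simulator's job)."""
    grid = DEFAULT_GRID if grid is None else grid
    r_b = spec.bounding_radius_mm()
    half = [e / 2.0 for e in grid.extent_mm]
    if any(r_b > h for h in half):
        need = 2.0 * r_b
        raise ValueError(
            f"grid extent {tuple(round(e,1) for e in grid.extent_mm)} mm too small: "
            f"the phantom (bounding sphere {r_b:.1f} mm radius, any orientation) "
            f"requires at least {need:.1f} mm per axis"
        )

    pts = grid.world_coordinates().reshape(-1, 3)
    canon = pts @ spec.rotation_matrix  # R^T applied row-wise: world -> canonical
    x, y, z = canon[:, 0], canon[:, 1], canon[:, 2]
    rho2 = x * x + y * y

    s = spec.surfaces(phase)

    def inside(surface):
        a, c, zc = surface
        return rho2 / (a * a) + ((z - zc) / c) ** 2 <= 1.0

    cavity = inside(s["endo"]) & (z <= s["cavity_cut_z"])
    myo = inside(s["epi"]) & (z <= s["myo_cut_z"]) & ~cavity

    labels = np.zeros(len(pts), dtype=np.uint8)
    labels[myo] = MYOCARDIUM
    labels[cavity] = BLOOD_POOL
    labels = labels.reshape(grid.shape)

    hu = spec.hu
    lut = np.array([hu["background"], hu["myocardium"], hu["blood_pool"]], dtype=np.float32)
    image = lut[labels]

    meta = {"phase": phase, "source": "phantom"}
    return (LabelVolume(array=labels, grid=grid, meta=dict(meta)),
            ImageVolume(array=image, grid=grid, meta=dict(meta)))


# --- cohort generation ----------------------------------------------------

DEFAULT_PARAM_RANGES = {
    "endo_short_axis_mm": (22.0, 30.0),
    "endo_long_axis_mm": (40.0, 50.0),
    "wall_radial_mm": (6.0, 10.0),
    "wall_long_mm": (5.0, 8.0),
    "es_long_scale": (0.84, 0.95),
    "target_ef_pct": (20.0, 70.0),
    "base_truncation_frac": (0.5, 0.5),
}


def _random_rotation(rng: np.random.Generator) -> tuple:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, xq, yq, zq = q
    R = np.array([
        [1 - 2 * (yq * yq + zq * zq), 2 * (xq * yq - w * zq), 2 * (xq * zq + w * yq)],
        [2 * (xq * yq + w * zq), 1 - 2 * (xq * xq + zq * zq), 2 * (yq * zq - w * xq)],
        [2 * (xq * zq - w * yq), 2 * (yq * zq + w * xq), 1 - 2 * (xq * xq + yq * yq)],
    ])
    return tuple(float(v) for v in R.ravel())


def generate_cohort(n: int, param_ranges: dict | None = None, seed: int = 0,
                    wall_model: str = "volume-preserving",
                    random_orientation: bool = True) -> list[PhantomSpec]:
    """Draw ``n`` phantom specs with parameters uniform over the given ranges,
    EF targets spanning normal and abnormal function, and random orientations.
    Bitwise reproducible from ``(param_ranges, seed)``."""
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    ranges = dict(DEFAULT_PARAM_RANGES)
    ranges.update(param_ranges or {})
    for k, (lo, hi) in ranges.items():
        if not (np.isfinite(lo) and np.isfinite(hi)) or lo > hi:
            raise ValueError(f"invalid range for {k!r}: ({lo}, {hi})")
    rng = np.random.default_rng(seed)
    cohort = []
    for i in range(n):
        draw = {k: float(rng.uniform(lo, hi)) for k, (lo, hi) in ranges.items()}
        s_l = draw["es_long_scale"]
        ef_lo, ef_hi = ranges["target_ef_pct"]
        # EF below 100*(1 - es_long_scale) would need radial dilation; clip.
        ef_lo = max(ef_lo, 100.0 * (1.0 - s_l) + 1.0)
        target_ef = float(rng.uniform(ef_lo, max(ef_lo, ef_hi)))
        orientation = _random_rotation(rng) if random_orientation else PhantomSpec.orientation
        params = {
            "endo_short_axis_mm": draw["endo_short_axis_mm"],
            "endo_long_axis_mm": draw["endo_long_axis_mm"],
            "epi_short_axis_mm": draw["endo_short_axis_mm"] + draw["wall_radial_mm"],
            "epi_long_axis_mm": draw["endo_long_axis_mm"] + draw["wall_long_mm"],
            "base_truncation_frac": draw["base_truncation_frac"],
            "es_long_scale": s_l,
            "wall_model": wall_model,
            "orientation": orientation,
            "seed": int(rng.integers(0, 2**31 - 1)),
        }
        cohort.append(build_phantom_spec(params, target_ef_pct=target_ef))
    return cohort


# --- on-disk case format --------------------------------------------------

def write_case(spec: PhantomSpec, out_dir: str, grid: Grid | None = None,
               case_id: str = "case") -> dict:
    """Write ED/ES image+label NIfTI pairs plus a JSON sidecar with the spec
    and its analytic ground truth.  Returns the manifest dict."""
    import os
    from . import io as _io

    os.makedirs(out_dir, exist_ok=True)
    paths = {}
    for phase in PHASES:
        labels, image = voxelize_phase(spec, phase, grid)
        for kind, vol in (("labels", labels), ("image", image)):
            p = os.path.join(out_dir, f"{case_id}_{phase}_{kind}.nii.gz")
            _io.write_volume(vol, p)
            paths[f"{phase}_{kind}"] = p
    gt = analytic_ground_truth(spec)
    manifest = {
        "case_id": case_id,
        "spec": spec.to_dict(),
        "ground_truth": {"ef_pct": gt.ef_pct, "gls_pct": gt.gls_pct,
                         "cs_pct": gt.cs_pct, "wt_pct": gt.wt_pct},
        "files": paths,
    }
    with open(os.path.join(out_dir, f"{case_id}.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
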