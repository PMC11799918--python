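"""Simulated CT acquisition, reconstruction and low-dose noise emulation.

A simplified parallel-beam, per-axial-slice scanner: HU volumes are
converted to linear attenuation, forward projected (Radon transform) into
per-slice sinograms of log-attenuation line integrals, corrupted with
Poisson quantum noise plus Gaussian electronic noise in the count domain,
and reconstructed with Hann-apodised filtered back-projection.

Reduced-dose scans are emulated the way clinical noise-insertion pipelines
do it: from the standard-dose sinogram, zero-mean Gaussian noise with the
per-ray *incremental* variance (low-dose minus standard-dose, predicted by
the counts model via the delta method) is added, so the emulated sinogram's
total noise matches a direct acquisition at the lower tube current.  Tube
current scales the photon flux linearly: I0(mA) = I0_ref * mA / 500.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import map_coordinates
from skimage.transform import radon, iradon

from .volumes import Grid, ImageVolume

#: Reference tube current (mA) at which I0_ref is specified.
REFERENCE_MA = 500.0

#: Count floor applied before the log (photon-starvation guard).
COUNT_FLOOR = 0.1


@dataclass(frozen=True)
class ScanGeometry:
    """Parallel-beam per-slice geometry (angles uniform over [0, 180))."""

    n_detectors: int = 192
    detector_pitch_mm: float = 1.0
    n_angles: int = 180
    mu_water_per_mm: float = 0.020

    def __post_init__(self):
        if self.n_detectors < 2 or self.detector_pitch_mm <= 0 or self.n_angles < 1:
            raise ValueError("invalid scan geometry")
        if self.mu_water_per_mm <= 0:
            raise ValueError("mu_water_per_mm must be positive")
        if self.n_angles < self.n_detectors * np.pi / 2.0:
            warnings.warn(
                f"n_angles={self.n_angles} is below the ~n_detectors*pi/2 "
                f"({self.n_detectors * np.pi / 2:.0f}) sampling rule of thumb",
                stacklevel=2,
            )

    @property
    def angles_deg(self) -> np.ndarray:
        return np.arange(self.n_angles) * (180.0 / self.n_angles)

    @property
    def span_mm(self) -> float:
        return self.n_detectors * self.detector_pitch_mm


@dataclass(frozen=True)
class AcquisitionSpec:
    """Flux/noise model: linear mA->flux scaling plus electronic noise."""

    tube_current_mA: float = 500.0
    # photons/ray at REFERENCE_MA, calibrated so the dose ladder spans
    # clinically plausible standard-dose noise (~16 HU SD) through clearly
    # degraded-but-analyzable 10 mA images (~90 HU SD)
    I0_ref: float = 1.0e5
    electronic_noise_sd: float = 10.0  # counts
    seed: int = 0

    def __post_init__(self):
        if self.tube_current_mA <= 0:
            raise ValueError("tube current must be positive")
        if self.I0_ref <= 0:
            raise ValueError("reference flux I0_ref must be positive")
        if self.electronic_noise_sd < 0:
            raise ValueError("electronic noise SD must be >= 0")

    @property
    def I0(self) -> float:
        return self.I0_ref * self.tube_current_mA / REFERENCE_MA

    def at_current(self, mA: float, seed: int | None = None) -> "AcquisitionSpec":
        return replace(self, tube_current_mA=mA, seed=self.seed if seed is None else seed)


def dose_reduction_factor(acq_standard: AcquisitionSpec, acq_low: AcquisitionSpec) -> float:
    """Dose (x-ray flux) reduction factor between two acquisitions; dose is
    proportional to tube current at fixed kVp and rotation time."""
    return acq_standard.I0 / acq_low.I0


@dataclass
class SinogramStack:
    """Per-slice log-attenuation line integrals, shape (n_slices, n_angles, n_detectors)."""

    data: np.ndarray
    geometry: ScanGeometry
    provenance: str = "ideal"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3 or self.data.shape[1] != self.geometry.n_angles \
                or self.data.shape[2] != self.geometry.n_detectors:
            raise ValueError(
                f"sinogram shape {self.data.shape} does not match geometry "
                f"(n_angles={self.geometry.n_angles}, n_detectors={self.geometry.n_detectors})"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("sinogram contains non-finite values")


def hu_to_mu(hu: np.ndarray, mu_water_per_mm: float) -> np.ndarray:
    """HU -> linear attenuation per mm, clamped at zero."""
    return np.clip(mu_water_per_mm * (1.0 + np.asarray(hu, dtype=np.float64) / 1000.0), 0.0, None)


def mu_to_hu(mu: np.ndarray, mu_water_per_mm: float) -> np.ndarray:
    return 1000.0 * (np.asarray(mu, dtype=np.float64) / mu_water_per_mm - 1.0)


def _detector_grid_slices(volume: ImageVolume, geometry: ScanGeometry) -> np.ndarray:
    """Resample each axial (z) slice of the mu volume onto the square
    detector-pitch grid centred on the world origin (linear interpolation)."""
    mu = hu_to_mu(volume.array, geometry.mu_water_per_mm)
    n = geometry.n_detectors
    pitch = geometry.detector_pitch_mm
    coords = (np.arange(n) - (n - 1) / 2.0) * pitch
    xx, yy = np.meshgrid(coords, coords, indexing="ij")
    grid = volume.grid
    ix = (xx - grid.origin[0]) / grid.spacing[0]
    iy = (yy - grid.origin[1]) / grid.spacing[1]
    flat = np.stack([ix.ravel(), iy.ravel()])
    # field of view = circle inscribed in the detector span; material outside
    # it is not measured (parallel-beam projections would otherwise be
    # inconsistent across angles)
    fov = (xx**2 + yy**2) <= (geometry.span_mm / 2.0 - pitch) ** 2
    out = np.empty((volume.array.shape[2], n, n))
    for k in range(volume.array.shape[2]):
        sl = map_coordinates(mu[:, :, k], flat, order=1, mode="constant",
                             cval=0.0).reshape(n, n)
        out[k] = np.where(fov, sl, 0.0)
    return out


def forward_project(volume: ImageVolume, geometry: ScanGeometry) -> SinogramStack:
    """Per-slice Radon transform of the attenuation volume.

    The field of view is the circle inscribed in the detector span; the
    volume's in-plane extent must fit inside the span.
    """
    ext = volume.grid.extent_mm
    if max(ext[0], ext[1]) > geometry.span_mm + 1e-6:
        raise ValueError(
            f"volume in-plane extent {ext[0]:.1f} x {ext[1]:.1f} mm exceeds the "
            f"detector span {geometry.span_mm:.1f} mm"
        )
    slices = _detector_grid_slices(volume, geometry)
    theta = geometry.angles_deg
    sino = np.empty((slices.shape[0], geometry.n_angles, geometry.n_detectors))
    for k, sl in enumerate(slices):
        # radon() integrates in pixel units; multiply by pitch for mm integrals
        sino[k] = radon(sl, theta=theta, circle=True).T * geometry.detector_pitch_mm
    return SinogramStack(data=sino, geometry=geometry, provenance="ideal")


def simulate_counts(sinogram: SinogramStack, acquisition: AcquisitionSpec) -> SinogramStack:
    """Poisson quantum + Gaussian electronic noise in the count domain.

    N = Poisson(I0 exp(-p)) + Normal(0, sd_e^2), floored at COUNT_FLOOR,
    then p_noisy = ln(I0 / N).
    """
    I0 = acquisition.I0
    rng = np.random.default_rng(acquisition.seed)
    expected = I0 * np.exp(-sinogram.data)
    counts = rng.poisson(expected).astype(np.float64)
    if acquisition.electronic_noise_sd > 0:
        counts += rng.normal(0.0, acquisition.electronic_noise_sd, size=counts.shape)
    counts = np.maximum(counts, COUNT_FLOOR)
    return SinogramStack(
        data=np.log(I0 / counts), geometry=sinogram.geometry,
        provenance=f"noisy@{acquisition.tube_current_mA:g}mA",
    )


def _log_domain_variance(p: np.ndarray, acquisition: AcquisitionSpec) -> np.ndarray:
    """Delta-method variance of the log-domain projection: (Nbar + sd_e^2)/Nbar^2."""
    nbar = np.maximum(acquisition.I0 * np.exp(-p), COUNT_FLOOR)
    return (nbar + acquisition.electronic_noise_sd**2) / nbar**2


def inject_incremental_noise(standard_sinogram: SinogramStack,
                             acq_standard: AcquisitionSpec,
                             acq_low: AcquisitionSpec,
                             seed: int) -> SinogramStack:
    """Emulate a low-dose sinogram from a measured standard-dose sinogram.

    Adds zero-mean Gaussian noise per ray with variance equal to the
    difference of the delta-method log-domain variances at the two doses,
    so the total noise matches a direct acquisition at ``acq_low``."""
    if acq_low.tube_current_mA > acq_standard.tube_current_mA:
        raise ValueError(
            f"emulation target ({acq_low.tube_current_mA} mA) must not exceed the "
            f"standard acquisition ({acq_standard.tube_current_mA} mA)"
        )
    p = standard_sinogram.data
    var_inc = np.clip(_log_domain_variance(p, acq_low) - _log_domain_variance(p, acq_standard),
                      0.0, None)
    rng = np.random.default_rng(seed)
    noisy = p + rng.normal(size=p.shape) * np.sqrt(var_inc)
    return SinogramStack(
        data=noisy, geometry=standard_sinogram.geometry,
        provenance=f"emulated@{acq_low.tube_current_mA:g}mA",
    )


def fbp_reconstruct(sinogram: SinogramStack, geometry: ScanGeometry,
                    grid: Grid) -> ImageVolume:
    """Hann-apodised ramp-filter FBP per slice, resampled onto ``grid`` in HU."""
    if sinogram.geometry != geometry:
        raise ValueError("sinogram geometry does not match the requested geometry")
    if sinogram.data.shape[0] != grid.shape[2]:
        raise ValueError(
            f"sinogram has {sinogram.data.shape[0]} slices but the output grid "
            f"expects {grid.shape[2]}"
        )
    n = geometry.n_detectors
    pitch = geometry.detector_pitch_mm
    theta = geometry.angles_deg

    coords = (np.arange(n) - (n - 1) / 2.0) * pitch
    gx = grid.origin[0] + grid.spacing[0] * np.arange(grid.shape[0])
    gy = grid.origin[1] + grid.spacing[1] * np.arange(grid.shape[1])
    xx, yy = np.meshgrid(gx, gy, indexing="ij")
    ix = (xx - coords[0]) / pitch
    iy = (yy - coords[0]) / pitch
    flat = np.stack([ix.ravel(), iy.ravel()])

    out = np.empty(grid.shape, dtype=np.float32)
    for k in range(grid.shape[2]):
        mu_det = iradon(sinogram.data[k].T / pitch, theta=theta, filter_name="hann",
                        circle=True, output_size=n)
        sl = map_coordinates(mu_det, flat, order=1, mode="constant",
                             cval=0.0).reshape(grid.shape[0], grid.shape[1])
        out[:, :, k] = mu_to_hu(sl, geometry.mu_water_per_mm)
    return ImageVolume(array=out, grid=grid,
                       meta={"provenance": sinogram.provenance, "recon": "fbp-hann"})


def emulate_dose_ladder(volume: ImageVolume, geometry: ScanGeometry,
                        acq_standard: AcquisitionSpec, dose_list_mA,
                        seed: int) -> dict:
    """Scan once at the standard dose, then emulate each lower dose from the
    standard-dose sinogram (paired design: same anatomy and same quantum
    noise realisation underlying every rung).  Returns {mA: ImageVolume}
    with all volumes reconstructed on the input grid."""
    dose_list_mA = list(dose_list_mA)
    if sorted(dose_list_mA, reverse=True) != dose_list_mA:
        raise ValueError("dose list must be sorted descending (standard dose first)")
    if abs(dose_list_mA[0] - acq_standard.tube_current_mA) > 1e-9:
        raise ValueError("first dose-list entry must equal the standard tube current")

    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(len(dose_list_mA))]

    ideal = forward_project(volume, geometry)
    sino_sd = simulate_counts(ideal, replace(acq_standard, seed=child_seeds[0]))
    out = {dose_list_mA[0]: fbp_reconstruct(sino_sd, geometry, volume.grid)}
    for mA, s in zip(dose_list_mA[1:], child_seeds[1:]):
        sino = inject_incremental_noise(sino_sd, acq_standard, acq_standard.at_current(mA), s)
        out[mA] = fbp_reconstruct(sino, geometry, volume.grid)
    return out


def save_sinograms(stack: SinogramStack, path_prefix: str) -> None:
    """Persist a sinogram stack as NPZ with a JSON geometry sidecar."""
    import json

    np.savez_compressed(path_prefix + ".npz", data=stack.data)
    sidecar = {
        "provenance": stack.provenance,
        "geometry": {
            "n_detectors": stack.geometry.n_detectors,
            "detector_pitch_mm": stack.geometry.detector_pitch_mm,
            "n_angles": stack.geometry.n_angles,
            "mu_water_per_mm": stack.geometry.mu_water_per_mm,
        },
    }
    with open(path_prefix + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=2)


def load_sinograms(path_prefix: str) -> SinogramStack:
    import json

    with open(path_prefix + ".json") as fh:
        sidecar = json.load(fh)
    data = np.load(path_prefix + ".npz")["data"]
    return SinogramStack(data=data, geometry=ScanGeometry(**sidecar["geometry"]),
                         provenance=sidecar["provenance"])
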