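"""Trainable and rule-based segmentation observers.

An *observer* turns an HU image volume into a three-class label volume.
Two kinds are provided:

* :class:`NetObserver` — the residual 3D U-Net trained with the generalized
  Dice loss and Adam on foreground-biased patches.  Two recipes mirror the
  study design: a *Standard* observer trained on standard-dose images only,
  and a *Noise-Robust* observer trained on the standard-dose images plus
  the emulated low-dose ladder of the same cases.
* :class:`RuleBasedObserver` — deterministic HU-threshold classification
  with connected-component and hole-filling cleanup, used where fully
  reproducible segmentations are needed without training.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.ndimage import binary_fill_holes, gaussian_filter

from ..volumes import ImageVolume, LabelVolume, BACKGROUND, MYOCARDIUM, BLOOD_POOL
from .loss import softmax_gdl_grad
from .nn import Adam, softmax
from .unet import NetConfig, ResUNet3D

#: Fixed affine HU normalisation applied to network inputs.
HU_CENTER, HU_SCALE = 150.0, 200.0


@dataclass(frozen=True)
class TrainRecipe:
    learning_rate: float = 5e-4
    batch_size: int = 32
    epochs: int = 200
    patches_per_case: int = 1
    #: fixed number of patch draws per epoch; None derives it from the
    #: dataset size (cases x patches_per_case).  Setting it explicitly keeps
    #: the optimisation budget identical across recipes whose datasets
    #: differ in size (e.g. standard vs noise-robust).
    draws_per_epoch: int | None = None
    foreground_patch_prob: float = 0.9
    #: dose levels (mA) admitted into the training set; None = all supplied.
    dose_levels: tuple | None = None
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0 or self.batch_size < 1 or self.epochs < 1 \
                or self.patches_per_case < 1:
            raise ValueError("learning rate, batch size, epochs and patches/case must be positive")
        if not (0.0 <= self.foreground_patch_prob <= 1.0):
            raise ValueError("foreground_patch_prob must lie in [0, 1]")


@dataclass
class TrainingCase:
    case_id: str
    dose_mA: float
    image: ImageVolume
    labels: LabelVolume


def standard_recipe(standard_dose_mA: float = 500.0, **overrides) -> TrainRecipe:
    """Recipe admitting only standard-dose volumes."""
    overrides.setdefault("dose_levels", (standard_dose_mA,))
    return TrainRecipe(**overrides)


def noise_robust_recipe(**overrides) -> TrainRecipe:
    """Recipe admitting every supplied dose level (standard + low-dose set)."""
    overrides.setdefault("dose_levels", None)
    return TrainRecipe(**overrides)


def _normalize(hu: np.ndarray) -> np.ndarray:
    """Fixed affine HU normalisation, clipped to +/-3 so far-out-of-range
    inputs (e.g. air outside the scanner's field-of-view circle) cannot
    drive the network outside its training distribution."""
    x = (hu - HU_CENTER) / HU_SCALE
    return np.clip(x, -3.0, 3.0).astype(np.float32)


def largest_component_cleanup(labels: np.ndarray) -> np.ndarray:
    """Keep only the largest connected component of each foreground class
    (standard cardiac-segmentation post-processing; removes stray islands)."""
    from skimage.measure import label as cc_label

    out = labels.copy()
    for class_id in (MYOCARDIUM, BLOOD_POOL):
        mask = labels == class_id
        if not mask.any():
            continue
        cc = cc_label(mask)
        sizes = np.bincount(cc.ravel())
        sizes[0] = 0
        out[mask & (cc != sizes.argmax())] = BACKGROUND
    return out


def _one_hot(labels: np.ndarray, n_classes: int = 3) -> np.ndarray:
    return np.eye(n_classes, dtype=np.float32)[labels].transpose(3, 0, 1, 2)


class NetObserver:
    def __init__(self, config: NetConfig, seed: int = 0, name: str = "net"):
        self.config = config
        self.net = ResUNet3D(config, seed=seed)
        self.name = name
        self.trained = False
        self.loss_history: list[float] = []
        self.dataset_audit: list[tuple[str, float]] = []

    # --- inference --------------------------------------------------------

    def segment(self, image_volume: ImageVolume, stride: tuple | None = None,
                postprocess: bool = True) -> LabelVolume:
        """Sliding-window inference; per-voxel argmax over averaged softmax
        probabilities (ties resolved toward the lower class index), followed
        by largest-connected-component cleanup per foreground class."""
        if not self.trained:
            raise RuntimeError("observer has not been trained")
        patch = self.config.patch_size
        arr = image_volume.array.astype(np.float32)
        orig_shape = arr.shape
        pad = [max(0, p - s) for p, s in zip(patch, orig_shape)]
        if any(pad):
            arr = np.pad(arr, [(0, p) for p in pad], mode="edge")
        x = _normalize(arr)

        stride = tuple(stride) if stride is not None else patch
        starts = [self._starts(x.shape[d], patch[d], stride[d]) for d in range(3)]
        probs = np.zeros((self.config.n_classes, *x.shape), dtype=np.float32)
        counts = np.zeros(x.shape, dtype=np.float32)
        for i in starts[0]:
            for j in starts[1]:
                for k in starts[2]:
                    sl = (slice(i, i + patch[0]), slice(j, j + patch[1]), slice(k, k + patch[2]))
                    logits = self.net.forward(x[sl][None])[0]
                    probs[(slice(None), *sl)] += softmax(logits, axis=0)
                    counts[sl] += 1.0
        probs /= counts
        labels = probs.argmax(axis=0).astype(np.uint8)
        labels = labels[: orig_shape[0], : orig_shape[1], : orig_shape[2]]
        if postprocess:
            labels = largest_component_cleanup(labels)
        return LabelVolume(array=labels, grid=image_volume.grid,
                           meta={"observer": self.name})

    @staticmethod
    def _starts(size: int, patch: int, stride: int) -> list[int]:
        out = list(range(0, max(size - patch, 0) + 1, stride))
        if out[-1] != size - patch:
            out.append(size - patch)
        return out

    # --- persistence ------------------------------------------------------

    def save(self, path_prefix: str) -> None:
        np.savez_compressed(path_prefix + ".npz", **self.net.state_dict())
        sidecar = {
            "config": asdict(self.config), "name": self.name, "trained": self.trained,
            "loss_history": self.loss_history, "dataset_audit": self.dataset_audit,
        }
        with open(path_prefix + ".json", "w") as fh:
            json.dump(sidecar, fh, indent=2)

    @classmethod
    def load(cls, path_prefix: str) -> "NetObserver":
        with open(path_prefix + ".json") as fh:
            sidecar = json.load(fh)
        cfg = dict(sidecar["config"])
        for key in ("deep_supervision_weights", "patch_size"):
            cfg[key] = tuple(cfg[key])
        obs = cls(NetConfig(**cfg), name=sidecar["name"])
        state = dict(np.load(path_prefix + ".npz"))
        obs.net.load_state_dict(state)
        obs.trained = sidecar["trained"]
        obs.loss_history = list(sidecar["loss_history"])
        obs.dataset_audit = [tuple(e) for e in sidecar["dataset_audit"]]
        return obs


def _sample_patch(case: TrainingCase, patch, fg_prob: float, rng: np.random.Generator):
    img, lab = case.image.array, case.labels.array
    shape = img.shape
    if any(s < p for s, p in zip(shape, patch)):
        raise ValueError(f"volume shape {shape} smaller than patch {tuple(patch)}")
    if rng.uniform() < fg_prob:
        fg = np.argwhere(lab > 0)
        center = fg[rng.integers(len(fg))]
        start = [int(np.clip(c - p // 2, 0, s - p)) for c, p, s in zip(center, patch, shape)]
    else:
        start = [int(rng.integers(0, s - p + 1)) for s, p in zip(shape, patch)]
    sl = tuple(slice(st, st + p) for st, p in zip(start, patch))
    return img[sl], lab[sl]


def train_observer(net_config: NetConfig, recipe: TrainRecipe,
                   training_cases: list[TrainingCase], name: str = "net",
                   init_from: "NetObserver | None" = None) -> NetObserver:
    """Train a U-Net observer; returns it with its per-epoch loss history.

    Patches are foreground-biased; deep-supervision targets are the labels
    subsampled to each auxiliary head's resolution; the per-head GDL terms
    are combined with the configured weights.  Fully reproducible for a
    fixed (config, recipe, data) triple.

    ``init_from`` warm-starts from an existing observer's weights — the
    continuous-learning workflow in which a network trained on standard-dose
    data is subsequently tuned with the low-dose set.
    """
    cases = list(training_cases)
    if recipe.dose_levels is not None:
        admitted = set(float(d) for d in recipe.dose_levels)
        cases = [c for c in cases if float(c.dose_mA) in admitted]
    if not cases:
        raise ValueError("no training cases remain after dose-level filtering")
    patch = net_config.patch_size
    for c in cases:
        if any(s < p for s, p in zip(c.image.array.shape, patch)):
            raise ValueError(
                f"case {c.case_id}: volume {c.image.array.shape} smaller than patch {patch}")

    observer = NetObserver(net_config, seed=recipe.seed, name=name)
    if init_from is not None:
        if init_from.config != net_config:
            raise ValueError("warm-start observer must share the network configuration")
        observer.net.load_state_dict(init_from.net.state_dict())
        observer.loss_history = list(init_from.loss_history)
    observer.dataset_audit = sorted({(c.case_id, float(c.dose_mA)) for c in cases})
    net = observer.net
    opt = Adam(net.params(), lr=recipe.learning_rate)
    rng = np.random.default_rng(recipe.seed + 1)
    w_heads = net_config.head_weights()

    n_draws = recipe.draws_per_epoch or len(cases) * recipe.patches_per_case
    for _epoch in range(recipe.epochs):
        epoch_losses = []
        drawn = 0
        while drawn < n_draws:
            batch = min(recipe.batch_size, n_draws - drawn)
            opt.zero_grad()
            for _ in range(batch):
                case = cases[rng.integers(len(cases))]
                img, lab = _sample_patch(case, patch, recipe.foreground_patch_prob, rng)
                x = _normalize(img)[None]
                logits = net.forward(x)
                g_logits, total = [], 0.0
                for lvl, (lg, w) in enumerate(zip(logits, w_heads)):
                    step = 2**lvl
                    ref = _one_hot(lab[::step, ::step, ::step], net_config.n_classes)
                    l, g = softmax_gdl_grad(lg, ref)
                    total += w * l
                    g_logits.append(np.float32(w / batch) * g)
                net.backward(g_logits)
                epoch_losses.append(total)
            opt.step()
            drawn += batch
        observer.loss_history.append(float(np.mean(epoch_losses)))
    observer.trained = True
    return observer


def segment_volume(observer, image_volume: ImageVolume) -> LabelVolume:
    """Uniform entry point for any observer object with ``.segment``."""
    return observer.segment(image_volume)


# --- rule-based observer --------------------------------------------------

DEFAULT_HU_THRESHOLDS = (70.0, 225.0)


def rule_based_segment(image_volume: ImageVolume,
                       hu_thresholds: tuple = DEFAULT_HU_THRESHOLDS,
                       smooth_sigma_vox: float = 1.0) -> LabelVolume:
    """Deterministic threshold observer.

    Gaussian pre-smoothing (in voxels), two ordered HU thresholds
    (background < myocardium < blood pool), then largest-connected-component
    selection and hole filling per foreground class."""
    from skimage.measure import label as cc_label

    t1, t2 = hu_thresholds
    if not t1 < t2:
        raise ValueError(f"hu_thresholds must be strictly increasing, got {hu_thresholds}")
    hu = image_volume.array.astype(np.float32)
    if smooth_sigma_vox > 0:
        hu = gaussian_filter(hu, smooth_sigma_vox)

    def largest_cc(mask):
        if not mask.any():
            return mask
        cc = cc_label(mask)
        sizes = np.bincount(cc.ravel())
        sizes[0] = 0
        return cc == sizes.argmax()

    pool = binary_fill_holes(largest_cc(hu >= t2))
    myo = largest_cc((hu >= t1) & ~pool)
    wall = binary_fill_holes(myo | pool)
    myo = wall & ~pool

    labels = np.zeros(hu.shape, dtype=np.uint8)
    labels[myo] = MYOCARDIUM
    labels[pool] = BLOOD_POOL
    return LabelVolume(array=labels, grid=image_volume.grid,
                       meta={"observer": "rule-based", "thresholds": list(hu_thresholds)})


class RuleBasedObserver:
    """Observer-protocol wrapper around :func:`rule_based_segment`."""

    def __init__(self, hu_thresholds: tuple = DEFAULT_HU_THRESHOLDS,
                 smooth_sigma_vox: float = 1.0, name: str = "rule-based"):
        t1, t2 = hu_thresholds
        if not t1 < t2:
            raise ValueError(f"hu_thresholds must be strictly increasing, got {hu_thresholds}")
        self.hu_thresholds = tuple(hu_thresholds)
        self.smooth_sigma_vox = smooth_sigma_vox
        self.name = name
        self.trained = True

    def segment(self, image_volume: ImageVolume) -> LabelVolume:
        return rule_based_segment(image_volume, self.hu_thresholds, self.smooth_sigma_vox)
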