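"""Synthetic low-contrast phantoms for segmentation experiments.

The generator produces small, irregularly shaped foreground blobs on a
noisy background with nearby distractor structures, so that desk-scale
experiments face the same statistical difficulties as small-organ CT
segmentation: low contrast, small foreground fraction and large
inter-case shape variation.

Everything is a pure function of ``PhantomConfig`` (including its seed):
case shapes derive from ``(seed, case_id)``, per-slice perturbations from
``(seed, case_id, slice_id)``, and fold assignment from an independent
stream so that re-splitting never changes the images.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

_CASE_STREAM = 101
_SLICE_STREAM = 202
_FOLD_STREAM = 777

N_FOLDS = 4


@dataclass(frozen=True)
class PhantomConfig:
    image_size: int = 208
    n_cases: int = 8
    slices_per_case: int = 4
    contrast: float = 0.6
    noise_sd: float = 0.03
    n_distractors: int = 2
    shape_irregularity: float = 0.3
    area_bounds: tuple[float, float] = (0.005, 0.08)
    seed: int = 0

    def __post_init__(self):
        if self.image_size < 16:
            raise ValueError("image_size must be at least 16")
        if self.contrast <= 0 or self.contrast > 1:
            raise ValueError("contrast must lie in (0, 1]; 0 makes the mask unlearnable")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.n_cases < 1 or self.slices_per_case < 1:
            raise ValueError("n_cases and slices_per_case must be positive")
        if self.n_distractors < 0:
            raise ValueError("n_distractors must be nonnegative")
        if self.shape_irregularity < 0:
            raise ValueError("shape_irregularity must be nonnegative")
        lo, hi = self.area_bounds
        if not (0 < lo < hi < 1):
            raise ValueError("area_bounds must satisfy 0 < lo < hi < 1")


@dataclass
class PhantomSlice:
    """One image/mask pair with provenance metadata."""

    image: np.ndarray
    mask: np.ndarray
    case_id: int
    slice_id: int

    def __post_init__(self):
        self.image = np.asarray(self.image, dtype=np.float32)
        self.mask = np.asarray(self.mask, dtype=np.uint8)
        if self.image.shape != self.mask.shape:
            raise ValueError(
                f"image shape {self.image.shape} != mask shape {self.mask.shape}"
            )
        if not np.isin(self.mask, (0, 1)).all():
            raise ValueError("mask values must be 0 or 1")


@dataclass(frozen=True)
class FoldAssignment:
    """Case-level mapping case_id -> fold index in {0..3}."""

    mapping: dict[int, int] = field(default_factory=dict)

    def fold_of(self, case_id: int) -> int:
        return self.mapping[case_id]

    def test_cases(self, fold: int) -> list[int]:
        return sorted(c for c, f in self.mapping.items() if f == fold)

    def train_cases(self, fold: int) -> list[int]:
        return sorted(c for c, f in self.mapping.items() if f != fold)

    @property
    def n_folds(self) -> int:
        return N_FOLDS


def _boundary_radius(theta, coeffs, phases, amplitude):
    f = np.ones_like(theta)
    for k, (a, phi) in enumerate(zip(coeffs, phases), start=2):
        f = f + amplitude * a * np.cos(k * theta + phi)
    return np.clip(f, 0.3, None)


def _render_blob(size, center, axes, angle, coeffs, phases, amplitude):
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    dy, dx = yy - center[0], xx - center[1]
    ca, sa = np.cos(angle), np.sin(angle)
    u = ca * dx + sa * dy
    v = -sa * dx + ca * dy
    rho = np.sqrt((u / axes[0]) ** 2 + (v / axes[1]) ** 2)
    theta = np.arctan2(v, u)
    return rho <= _boundary_radius(theta, coeffs, phases, amplitude)


def _case_params(config: PhantomConfig, case_seed: int):
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed & 0xFFFFFFFF, _CASE_STREAM, case_seed])
    )
    size = config.image_size
    lo, hi = config.area_bounds
    # base semi-axes target the middle of the area band; exact control is
    # applied per slice by rescaling
    target = np.sqrt(lo * hi)
    r = size * np.sqrt(target / np.pi)
    ecc = rng.uniform(0.6, 1.0)
    return {
        "center": rng.uniform(0.38 * size, 0.62 * size, size=2),
        "axes": np.array([r / np.sqrt(ecc), r * np.sqrt(ecc)]),
        "angle": rng.uniform(0, np.pi),
        "coeffs": rng.uniform(-1.0, 1.0, size=4),
        "phases": rng.uniform(0, 2 * np.pi, size=4),
    }


def generate_phantom(config: PhantomConfig, case_seed: int, slice_id: int = 0) -> PhantomSlice:
    """Render one slice: deformed elliptical foreground, distractors, noise.

    The foreground shape is the case's base blob with a per-slice
    perturbation; its area fraction is driven into ``config.area_bounds``
    by iterative axis rescaling. Distractor blobs are painted outside the
    mask at intensities offset from the background.
    """
    base = _case_params(config, case_seed)
    rng = np.random.default_rng(
        np.random.SeedSequence(
            [config.seed & 0xFFFFFFFF, _SLICE_STREAM, case_seed, slice_id]
        )
    )
    size = config.image_size
    lo, hi = config.area_bounds
    amp = 0.12 * config.shape_irregularity

    center = base["center"] + rng.normal(0, 0.015 * size, size=2)
    center = np.clip(center, 0.3 * size, 0.7 * size)
    axes = base["axes"] * rng.uniform(0.85, 1.15, size=2)
    angle = base["angle"] + rng.normal(0, 0.15)
    phases = base["phases"] + rng.normal(0, 0.25, size=4)
    target = rng.uniform(lo * 1.15, hi * 0.85)

    mask = None
    for _ in range(12):
        mask = _render_blob(size, center, axes, angle, base["coeffs"], phases, amp)
        frac = mask.mean()
        if frac == 0:
            axes = axes * 1.5
            continue
        if lo <= frac <= hi and abs(frac - target) / target < 0.25:
            break
        axes = axes * np.sqrt(target / frac)
    frac = mask.mean()
    if not (lo <= frac <= hi):  # pragma: no cover - defensive
        raise RuntimeError(f"phantom area control failed: fraction {frac:.4f}")

    bg = (1.0 - config.contrast) / 2.0
    fg = bg + config.contrast
    image = np.full((size, size), bg, dtype=np.float64)
    image[mask] = fg

    for _ in range(config.n_distractors):
        d_angle = rng.uniform(0, 2 * np.pi)
        d_dist = rng.uniform(0.18, 0.38) * size
        d_center = center + d_dist * np.array([np.sin(d_angle), np.cos(d_angle)])
        d_center = np.clip(d_center, 4, size - 5)
        d_r = rng.uniform(0.4, 0.9) * np.sqrt(axes[0] * axes[1])
        d_axes = d_r * rng.uniform(0.7, 1.3, size=2)
        blob = _render_blob(size, d_center, d_axes, rng.uniform(0, np.pi),
                            base["coeffs"], rng.uniform(0, 2 * np.pi, size=4), amp)
        sign = rng.choice([-1.0, 1.0])
        level = bg + sign * rng.uniform(0.5, 1.0) * config.contrast
        image[blob & ~mask] = np.clip(level, 0.0, 1.0)

    if config.noise_sd > 0:
        image = image + rng.normal(0, config.noise_sd, size=image.shape)
    image = np.clip(image, 0.0, 1.0)

    return PhantomSlice(
        image=image.astype(np.float32),
        mask=mask.astype(np.uint8),
        case_id=case_seed,
        slice_id=slice_id,
    )


def assign_folds(config: PhantomConfig) -> FoldAssignment:
    """Randomly partition cases into 4 folds (case-level, seeded apart)."""
    if config.n_cases < N_FOLDS:
        raise ValueError(
            f"4-fold cross-validation needs at least {N_FOLDS} cases, got {config.n_cases}"
        )
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed & 0xFFFFFFFF, _FOLD_STREAM])
    )
    order = rng.permutation(config.n_cases)
    mapping = {}
    for fold, chunk in enumerate(np.array_split(order, N_FOLDS)):
        for case_id in chunk:
            mapping[int(case_id)] = fold
    return FoldAssignment(mapping)


def generate_dataset(config: PhantomConfig) -> tuple[list[PhantomSlice], FoldAssignment]:
    """All slices of all cases, plus a case-level 4-fold assignment."""
    folds = assign_folds(config)
    slices = [
        generate_phantom(config, case_id, slice_id)
        for case_id in range(config.n_cases)
        for slice_id in range(config.slices_per_case)
    ]
    return slices, folds


def crop_resize(image, mask, target, mode="crop"):
    """Label-guided square crop (or interpolated resize) of an image/mask pair.

    ``crop`` centers a target x target window on the mask bounding box,
    clamped to the image bounds; an empty mask falls back to a center crop
    with a warning. ``resize`` interpolates both arrays to target x target
    (bilinear image, nearest mask).
    """
    image = np.asarray(image)
    mask = np.asarray(mask)
    if image.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    h, w = image.shape
    if mode == "resize":
        zoom = (target / h, target / w)
        img_r = ndimage.zoom(image.astype(np.float64), zoom, order=1)
        msk_r = ndimage.zoom(mask.astype(np.uint8), zoom, order=0)
        return img_r.astype(image.dtype)[:target, :target], msk_r[:target, :target]
    if mode != "crop":
        raise ValueError(f"unknown mode {mode!r}")
    if target > min(h, w):
        raise ValueError(f"crop target {target} exceeds image size {image.shape}")
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        warnings.warn("empty mask: falling back to center crop", stacklevel=2)
        cr, cc = h // 2, w // 2
    else:
        cr = (rows.min() + rows.max()) // 2
        cc = (cols.min() + cols.max()) // 2
    r0 = int(np.clip(cr - target // 2, 0, h - target))
    c0 = int(np.clip(cc - target // 2, 0, w - target))
    return image[r0:r0 + target, c0:c0 + target], mask[r0:r0 + target, c0:c0 + target]


def scaled_config(config: PhantomConfig, **overrides) -> PhantomConfig:
    """Convenience for producing desk-scale variants of a config."""
    return replace(config, **overrides)
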