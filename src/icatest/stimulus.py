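"""Stimulus and backward-mask generation for the rapid categorization task.

The test presents 100 grayscale images (50 animal, 50 non-animal) for 100 ms
each, followed by a 20 ms blank inter-stimulus interval and a 250 ms dynamic
noise mask.  The mask is a sequence of 8 frames drawn from a pool of 16
high-contrast binary patterns: one white-noise image low-pass filtered at four
octave-spaced spatial scales, thresholded at the median, each scale then
rotated/mirrored into four variants.

Real photographic stimuli are copyrighted, so this module draws procedural
stand-ins: "animal" images are smooth organic blob silhouettes, "non-animal"
images are straight-edged polygonal objects, both embedded in cluttered noise
backgrounds whose strength encodes a difficulty scalar in [0, 1].
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

# Default presentation timings (milliseconds).
IMAGE_MS = 100.0
ISI_MS = 20.0
MASK_TOTAL_MS = 250.0
MASK_N_FRAMES = 8

N_MAIN = 100
N_PRACTICE = 10

MASK_VARIANTS = ("rot90", "rot180", "mirror_h", "mirror_v")
#: Gaussian low-pass widths per spatial scale at a 256 px canvas; scale 1 is
#: the coarsest (largest sigma), scale 4 the finest.
_SIGMA_AT_256 = {1: 8.0, 2: 4.0, 3: 2.0, 4: 1.0}

LABELS = ("animal", "non_animal")


class StimulusError(ValueError):
    """Invalid argument to a stimulus-generation operation."""


# ---------------------------------------------------------------------------
# Mask pool
# ---------------------------------------------------------------------------

@dataclass
class MaskPool:
    """Pool of 16 binary mask frames: 4 spatial scales x 4 variants.

    Attributes
    ----------
    frames : list of ndarray
        2-D uint8 images containing only the values {0, 255}.
    scale_of, variant_of : list
        Per-frame spatial scale (1..4, 1 = coarsest) and geometric variant.
    """

    frames: list[np.ndarray]
    scale_of: list[int]
    variant_of: list[str]
    size_px: int
    seed: int

    def validate(self) -> None:
        # frames are immutable by convention; skip re-checking a validated pool
        if getattr(self, "_validated", False):
            return
        if len(self.frames) != 16:
            raise StimulusError(f"mask pool must have 16 frames, got {len(self.frames)}")
        for s in range(1, 5):
            idx = [i for i, sc in enumerate(self.scale_of) if sc == s]
            if len(idx) != 4:
                raise StimulusError(f"scale {s} has {len(idx)} frames, expected 4")
            if len({self.variant_of[i] for i in idx}) != 4:
                raise StimulusError(f"scale {s} variants are not distinct")
        for i, f in enumerate(self.frames):
            vals = np.unique(f)
            if not np.all(np.isin(vals, (0, 255))):
                raise StimulusError(f"frame {i} is not binary {{0,255}}")
        self._validated = True

    def frames_of_scale(self, scale: int) -> list[int]:
        return [i for i, s in enumerate(self.scale_of) if s == scale]


@dataclass
class MaskSequence:
    """Ordered mask frame indices shown back-to-back after each image."""

    frame_ids: list[int]
    frame_duration_ms: float = MASK_TOTAL_MS / MASK_N_FRAMES

    @property
    def total_ms(self) -> float:
        return len(self.frame_ids) * self.frame_duration_ms


def _apply_variant(img: np.ndarray, variant: str) -> np.ndarray:
    if variant == "rot90":
        return np.rot90(img, 1)
    if variant == "rot180":
        return np.rot90(img, 2)
    if variant == "mirror_h":
        return img[:, ::-1]
    if variant == "mirror_v":
        return img[::-1, :]
    raise StimulusError(f"unknown variant {variant!r}")


def generate_mask_pool(size_px: int, seed: int) -> MaskPool:
    """Build the 16-frame binary mask pool from one white-noise draw.

    A single uniform white-noise image is low-pass filtered with Gaussian
    kernels at four octave-spaced widths (sigma 8, 4, 2, 1 px at 256 px,
    scaled with the canvas), each result is thresholded at its own median to a
    {0, 255} pattern, and each scale is expanded into four variants by
    rotation and mirroring (the unrotated original is not kept).
    Deterministic for a fixed seed.
    """
    if size_px < 32:
        raise StimulusError(f"size_px must be >= 32, got {size_px}")
    rng = np.random.default_rng(seed)
    noise = rng.random((size_px, size_px))

    frames: list[np.ndarray] = []
    scale_of: list[int] = []
    variant_of: list[str] = []
    for scale in range(1, 5):
        sigma = _SIGMA_AT_256[scale] * size_px / 256.0
        low = ndimage.gaussian_filter(noise, sigma=sigma, mode="wrap")
        binary = np.where(low > np.median(low), 255, 0).astype(np.uint8)
        for variant in MASK_VARIANTS:
            frames.append(_apply_variant(binary, variant).copy())
            scale_of.append(scale)
            variant_of.append(variant)

    pool = MaskPool(frames=frames, scale_of=scale_of, variant_of=variant_of,
                    size_px=size_px, seed=seed)
    pool.validate()
    return pool


def sample_mask_sequence(pool: MaskPool, rng: np.random.Generator) -> MaskSequence:
    """Draw an 8-frame mask sequence with each spatial scale appearing twice."""
    pool.validate()
    ids: list[int] = []
    for scale in range(1, 5):
        ids.extend(rng.choice(pool.frames_of_scale(scale), size=2, replace=False))
    order = rng.permutation(len(ids))
    return MaskSequence(frame_ids=[int(ids[i]) for i in order])


# ---------------------------------------------------------------------------
# Stimulus set
# ---------------------------------------------------------------------------

@dataclass
class StimulusSet:
    """Labelled grayscale images with difficulty and role assignments.

    100 main images (50 per label) plus two disjoint 10-image practice sets
    (5 per label each), mirroring the test's structure: a practice block
    familiarizes the participant, and a second block is offered after a
    failed first attempt.
    """

    images: list[np.ndarray]
    labels: list[str]
    difficulty: list[float]
    role: list[str]
    seed: int
    image_ids: list[str] = field(default_factory=list)

    def indices_of_role(self, role: str) -> list[int]:
        return [i for i, r in enumerate(self.role) if r == role]

    def validate(self) -> None:
        main = self.indices_of_role("main")
        if len(main) != N_MAIN:
            raise StimulusError(f"main set must have {N_MAIN} images, got {len(main)}")
        if sum(self.labels[i] == "animal" for i in main) != N_MAIN // 2:
            raise StimulusError("main set must contain 50 animal images")
        for role in ("practice_1", "practice_2"):
            idx = self.indices_of_role(role)
            if len(idx) != N_PRACTICE:
                raise StimulusError(f"{role} must have {N_PRACTICE} images")
            if sum(self.labels[i] == "animal" for i in idx) != N_PRACTICE // 2:
                raise StimulusError(f"{role} must contain 5 animal images")
        for img in self.images:
            if img.ndim != 2:
                raise StimulusError("stimulus images must be single-channel")


def _radial_silhouette(size: int, radius_fn, center, max_r) -> np.ndarray:
    """Boolean mask of a star-convex shape given its radius as a function of angle."""
    yy, xx = np.mgrid[0:size, 0:size]
    dy, dx = yy - center[0], xx - center[1]
    r = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)
    return r <= np.clip(radius_fn(theta), 0.0, max_r)


def _blob_radius_fn(rng: np.random.Generator, base_r: float):
    """Smooth wavy radius profile: an organic, animal-like silhouette."""
    n_harm = rng.integers(3, 6)
    ks = rng.integers(2, 7, size=n_harm)
    amps = rng.uniform(0.08, 0.25, size=n_harm) * base_r
    phases = rng.uniform(0, 2 * np.pi, size=n_harm)

    def fn(theta):
        r = np.full_like(theta, base_r, dtype=float)
        for k, a, p in zip(ks, amps, phases):
            r = r + a * np.cos(k * theta + p)
        return r

    return fn


def _polygon_radius_fn(rng: np.random.Generator, base_r: float):
    """Regular-polygon radius profile: a geometric, non-animal object."""
    n_sides = int(rng.integers(3, 7))
    rot = rng.uniform(0, 2 * np.pi)
    half = np.pi / n_sides
    apothem = base_r * np.cos(half)

    def fn(theta):
        a = np.mod(theta + rot, 2 * half) - half
        return apothem / np.cos(a)

    return fn


def _render_stimulus(rng: np.random.Generator, label: str, difficulty: float,
                     size: int) -> np.ndarray:
    """Draw one grayscale stimulus; higher difficulty = more clutter, less contrast."""
    bg_noise = ndimage.gaussian_filter(rng.random((size, size)), sigma=2.0)
    bg_noise = (bg_noise - bg_noise.min()) / (np.ptp(bg_noise) + 1e-12)
    clutter = 0.25 + 0.55 * difficulty
    img = 0.5 + (bg_noise - 0.5) * clutter

    base_r = size * rng.uniform(0.16, 0.30) * (1.0 - 0.35 * difficulty)
    center = (size / 2 + rng.uniform(-0.1, 0.1) * size,
              size / 2 + rng.uniform(-0.1, 0.1) * size)
    if label == "animal":
        radius_fn = _blob_radius_fn(rng, base_r)
    else:
        radius_fn = _polygon_radius_fn(rng, base_r)
    mask = _radial_silhouette(size, radius_fn, center, max_r=size / 2 - 2)

    contrast = 0.9 - 0.6 * difficulty
    shade = 0.5 + contrast * (0.5 if rng.random() < 0.5 else -0.5)
    img[mask] = img[mask] * (1 - contrast) + shade * contrast
    return np.clip(img * 255, 0, 255).astype(np.uint8)


def generate_stimulus_set(seed: int, size_px: int = 64) -> StimulusSet:
    """Procedurally generate the 120-image labelled stimulus set.

    Difficulties are spread evenly over [0, 1] within each label so both easy
    and hard exemplars exist, matching the task's varying-difficulty design.
    """
    rng = np.random.default_rng(seed)
    images, labels, diffs, roles, ids = [], [], [], [], []
    blocks = [("practice_1", N_PRACTICE), ("practice_2", N_PRACTICE), ("main", N_MAIN)]
    for role, n in blocks:
        for j in range(n):
            label = LABELS[j % 2]  # alternates -> exact 50/50 and 5/5 splits
            difficulty = float((j // 2) / max(1, n // 2 - 1))
            images.append(_render_stimulus(rng, label, difficulty, size_px))
            labels.append(label)
            diffs.append(difficulty)
            roles.append(role)
            ids.append(f"{role}_{j:03d}")
    sset = StimulusSet(images=images, labels=labels, difficulty=diffs,
                       role=roles, seed=seed, image_ids=ids)
    sset.validate()
    return sset


# ---------------------------------------------------------------------------
# Trial schedule
# ---------------------------------------------------------------------------

@dataclass
class ScheduleEntry:
    image_id: str
    image_ms: float
    isi_ms: float
    mask: MaskSequence


@dataclass
class TrialSchedule:
    """Per-administration presentation order: each main image exactly once,
    in a fresh random order, with a fresh mask sequence per trial."""

    entries: list[ScheduleEntry]
    order_seed: int

    @property
    def image_ids(self) -> list[str]:
        return [e.image_id for e in self.entries]


def build_trial_schedule(stimset: StimulusSet, pool: MaskPool,
                         order_seed: int) -> TrialSchedule:
    """Permute the 100 main images and attach timings and mask sequences."""
    stimset.validate()
    pool.validate()
    rng = np.random.default_rng(order_seed)
    main_idx = stimset.indices_of_role("main")
    order = rng.permutation(len(main_idx))
    entries = [
        ScheduleEntry(
            image_id=stimset.image_ids[main_idx[i]],
            image_ms=IMAGE_MS,
            isi_ms=ISI_MS,
            mask=sample_mask_sequence(pool, rng),
        )
        for i in order
    ]
    return TrialSchedule(entries=entries, order_seed=order_seed)


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

def save_mask_pool(pool: MaskPool, out_dir: str | Path) -> Path:
    """Write frames as 8-bit grayscale PNGs plus a JSON manifest; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"size_px": pool.size_px, "seed": pool.seed, "frames": []}
    for i, frame in enumerate(pool.frames):
        name = f"mask_s{pool.scale_of[i]}_{pool.variant_of[i]}.png"
        Image.fromarray(frame, mode="L").save(out / name)
        manifest["frames"].append(
            {"file": name, "scale": pool.scale_of[i], "variant": pool.variant_of[i]}
        )
    path = out / "mask_pool.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path


def save_stimulus_set(sset: StimulusSet, out_dir: str | Path) -> Path:
    """Write stimuli as grayscale PNGs plus a JSON manifest; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": sset.seed, "images": []}
    for i, img in enumerate(sset.images):
        name = f"{sset.image_ids[i]}.png"
        Image.fromarray(img, mode="L").save(out / name)
        manifest["images"].append(
            {"file": name, "image_id": sset.image_ids[i], "label": sset.labels[i],
             "difficulty": sset.difficulty[i], "role": sset.role[i]}
        )
    path = out / "stimuli.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path
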