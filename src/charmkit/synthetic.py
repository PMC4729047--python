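"""Synthetic microscopy-style image sets with controllable class
structure and batch artifacts.

Classes differ in texture/frequency content (stripes, checkerboards,
Gaussian blobs, band-limited filtered noise). Batch artifacts are
modeled as a global per-batch brightness offset — the canonical
image-wide acquisition artifact (e.g. lamp warm-up) — optionally
multiplicative, and optionally *confounded* with class: in the
confounded layout every batch belongs to exactly one class, so a
classifier can separate the classes from the artifact alone. That
layout is the leakage fixture used to demonstrate why validation must
group folds by batch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io import RawImage, SampleRecord

__all__ = [
    "ClassSpec",
    "SyntheticSpec",
    "make_class_image",
    "make_dataset",
    "write_dataset",
    "separable_spec",
    "confounded_spec",
    "null_spec",
]

TEXTURE_KINDS = ("stripes", "checkerboard", "gaussian_blobs", "filtered_noise")


@dataclass(frozen=True)
class ClassSpec:
    """One class's texture: kind, structure scale (pixels), contrast amplitude."""

    name: str
    kind: str = "stripes"
    scale: int = 8
    contrast: float = 0.5

    def __post_init__(self) -> None:
        if self.kind not in TEXTURE_KINDS:
            raise ValueError(f"unknown texture kind {self.kind!r}")
        if not 0.0 <= self.contrast <= 1.0:
            raise ValueError("contrast must lie in [0, 1]")


@dataclass
class SyntheticSpec:
    """Generative description of a labeled multi-batch image set."""

    classes: list[ClassSpec]
    n_per_class: int = 16
    image_size: int = 64
    noise_sd: float = 0.05
    n_batches: int = 8
    batch_offset: float = 0.0      # brightness offset amplitude, in [0, 1]
    multiplicative: bool = False   # gain (1 + offset) instead of additive
    confounded: bool = False       # batches nested within classes
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.classes) < 2:
            raise ValueError("need at least 2 classes")
        if self.image_size < 32:
            raise ValueError("image_size must be >= 32")
        if self.confounded and self.n_batches % len(self.classes):
            raise ValueError(
                "confounded layout needs n_batches divisible by the class count"
            )


def _texture(spec: ClassSpec, size: int, rng: np.random.Generator) -> np.ndarray:
    lo = 0.5 - spec.contrast / 2.0
    y, x = np.mgrid[0:size, 0:size]
    if spec.kind == "stripes":
        band = (x // spec.scale) % 2
        return lo + spec.contrast * band.astype(np.float64)
    if spec.kind == "checkerboard":
        board = (x // spec.scale + y // spec.scale) % 2
        return lo + spec.contrast * board.astype(np.float64)
    if spec.kind == "gaussian_blobs":
        n_blobs = max(3, (size // max(spec.scale, 1)) ** 2 // 4)
        img = np.zeros((size, size))
        for _ in range(n_blobs):
            cy, cx = rng.uniform(0, size, 2)
            img += np.exp(-(((y - cy) ** 2 + (x - cx) ** 2) / (2.0 * spec.scale**2)))
        return _to_contrast_band(img, spec.contrast)
    # filtered_noise: white noise low-passed at the structure scale
    img = ndimage.gaussian_filter(rng.standard_normal((size, size)), spec.scale)
    return _to_contrast_band(img, spec.contrast)


def _to_contrast_band(img: np.ndarray, contrast: float) -> np.ndarray:
    """Rescale an arbitrary field into [0.5 - c/2, 0.5 + c/2]."""
    rng_ = img.max() - img.min()
    if rng_ <= 0 or contrast == 0:
        return np.full_like(img, 0.5)
    return 0.5 - contrast / 2.0 + contrast * (img - img.min()) / rng_


def make_class_image(
    spec: ClassSpec,
    seed: int,
    size: int = 64,
    noise_sd: float = 0.0,
    offset: float = 0.0,
    multiplicative: bool = False,
    sample_id: str = "",
) -> RawImage:
    """Deterministic texture + additive Gaussian noise + batch offset,
    clamped to [0, 1]."""
    rng = np.random.default_rng(seed)
    img = _texture(spec, size, rng)
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, img.shape)
    if multiplicative:
        img = img * (1.0 + offset)
    else:
        img = img + offset
    return RawImage(
        pixels=np.clip(img, 0.0, 1.0), sample_id=sample_id or spec.name
    )


def make_dataset(
    spec: SyntheticSpec,
) -> tuple[dict[str, list[RawImage]], list[SampleRecord]]:
    """Generate the image set and its sample records.

    Batches are assigned round-robin across the pooled samples, or — in
    the confounded layout — nested within classes so each batch carries
    a single class. Per-batch brightness offsets are drawn uniformly in
    [-batch_offset, +batch_offset] and applied before clamping.
    """
    rng = np.random.default_rng(spec.seed)
    offsets = rng.uniform(-spec.batch_offset, spec.batch_offset, spec.n_batches)
    per_class_batches = spec.n_batches // len(spec.classes)

    samples: dict[str, list[RawImage]] = {}
    records: list[SampleRecord] = []
    global_idx = 0
    for ci, cls in enumerate(spec.classes):
        for i in range(spec.n_per_class):
            if spec.confounded:
                batch_idx = ci * per_class_batches + (i % per_class_batches)
            else:
                batch_idx = global_idx % spec.n_batches
            sid = f"{cls.name}_{i:03d}"
            img = make_class_image(
                cls,
                seed=int(rng.integers(2**31)),
                size=spec.image_size,
                noise_sd=spec.noise_sd,
                offset=float(offsets[batch_idx]),
                multiplicative=spec.multiplicative,
                sample_id=sid,
            )
            samples[sid] = [img]
            records.append(
                SampleRecord(
                    sample_id=sid,
                    channel_paths={"gray": f"{sid}.png"},
                    class_label=cls.name,
                    batch_id=f"b{batch_idx:02d}",
                )
            )
            global_idx += 1
    return samples, records


def write_dataset(spec: SyntheticSpec, outdir) -> str:
    """Write the image set as 8-bit PNGs plus a manifest CSV; returns the
    manifest path."""
    import os

    import imageio.v3 as iio

    os.makedirs(outdir, exist_ok=True)
    samples, records = make_dataset(spec)
    rows = []
    for rec in records:
        img = samples[rec.sample_id][0]
        fname = f"{rec.sample_id}.png"
        iio.imwrite(
            os.path.join(outdir, fname),
            np.round(img.pixels * 255).astype(np.uint8),
        )
        rows.append(
            {
                "sample_id": rec.sample_id,
                "class": rec.class_label,
                "batch": rec.batch_id,
                "channel_gray": fname,
            }
        )
    import pandas as pd

    manifest = os.path.join(outdir, "manifest.csv")
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


# ---------------------------------------------------------------------------
# canonical fixtures
# ---------------------------------------------------------------------------

def separable_spec(seed: int = 0, n_per_class: int = 16) -> SyntheticSpec:
    """Two well-separated texture classes (the benchmark-like layout:
    two balanced classes of 16 images). Deterministic periodic textures
    keep the class signal identical across generator seeds; only the
    pixel noise varies."""
    return SyntheticSpec(
        classes=[
            ClassSpec("stripes", kind="stripes", scale=4, contrast=0.5),
            ClassSpec("checker", kind="checkerboard", scale=6, contrast=0.5),
        ],
        n_per_class=n_per_class,
        image_size=64,
        noise_sd=0.05,
        n_batches=16,
        seed=seed,
    )


def confounded_spec(seed: int = 0) -> SyntheticSpec:
    """The batch-leakage fixture: zero texture contrast, so the only
    class signal is the per-batch brightness offset (batches nested in
    classes). Images within a batch are exact replicates — the limiting
    case of sub-images cropped from one field or repeated acquisitions
    of one well, which is how batch leakage arises in real benchmark
    sets. 2 classes x 15 images in 10 batches of 3 keeps the default
    k = 10 feasible for batch-grouped folds."""
    return SyntheticSpec(
        classes=[
            ClassSpec("neg", kind="filtered_noise", scale=4, contrast=0.0),
            ClassSpec("pos", kind="filtered_noise", scale=4, contrast=0.0),
        ],
        n_per_class=15,
        image_size=64,
        noise_sd=0.0,
        n_batches=10,
        batch_offset=0.2,
        confounded=True,
        seed=seed,
    )


def null_spec(seed: int = 0, n_per_class: int = 16) -> SyntheticSpec:
    """Identical class specs: no class signal at all (chance-level check)."""
    cls = dict(kind="filtered_noise", scale=4, contrast=0.4)
    return SyntheticSpec(
        classes=[ClassSpec("a", **cls), ClassSpec("b", **cls)],
        n_per_class=n_per_class,
        image_size=64,
        noise_sd=0.05,
        n_batches=16,
        seed=seed,
    )
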