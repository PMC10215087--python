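"""Deterministic synthetic 2-D segmentation tasks and standard-format I/O.

The generator emulates the shape of multi-organ segmentation benchmarks at
desk scale: every case is a small multi-channel image containing a few
compact foreground objects (ellipses or wobbly blobs carved from smoothed
noise) on a noisy background.  Object interiors receive a class-specific
mean intensity separated from the background by a configurable contrast,
and i.i.d. Gaussian noise is added on top, so task difficulty is governed
by the contrast-to-noise ratio alone.  Everything is a pure function of
the spec and its seed.

Datasets can be written to and read from an MSD-style NIfTI folder layout
(``imagesTr``/``labelsTr`` plus ``dataset.json``; one ``_0000``-suffixed
file per channel) or a paired-PNG layout for quick inspection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from PIL import Image


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic dataset."""

    n_cases: int = 200
    image_size: tuple[int, int] = (64, 64)
    in_channels: int = 1
    num_classes: int = 2
    objects_per_case: tuple[int, int] = (2, 4)
    object_kinds: tuple[str, ...] = ("ellipse", "blob")
    radius_range: tuple[float, float] = (5.0, 12.0)
    contrast: float = 0.5
    noise_sigma: float = 0.1
    seed: int = 0

    def validate(self) -> "SyntheticSpec":
        h, w = self.image_size
        if self.n_cases < 1 or h < 2 or w < 2:
            raise ValueError("n_cases and image size must be positive")
        if not 1 <= self.in_channels <= 4:
            raise ValueError("in_channels must be in 1..4")
        if not 2 <= self.num_classes <= 4:
            raise ValueError("num_classes must be in 2..4")
        lo, hi = self.objects_per_case
        if lo < 1 or hi < lo:
            raise ValueError("objects_per_case must be a nonempty range")
        if lo < self.num_classes - 1:
            raise ValueError(
                "objects_per_case lower bound must cover every foreground class"
            )
        rlo, rhi = self.radius_range
        if rlo <= 0 or rhi < rlo:
            raise ValueError("radius_range must be positive and ordered")
        if 2 * rlo + 2 > min(h, w):
            raise ValueError(
                f"objects (min radius {rlo}) do not fit a {h}x{w} image"
            )
        for kind in self.object_kinds:
            if kind not in ("ellipse", "blob"):
                raise ValueError(f"unknown object kind {kind!r}")
        if self.noise_sigma < 0 or self.contrast <= 0:
            raise ValueError("contrast must be > 0 and noise_sigma >= 0")
        return self


@dataclass
class SegmentationSample:
    """One case: image (C, H, W), integer label map (H, W), metadata."""

    image: np.ndarray
    label: np.ndarray
    case_id: str
    spacing: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self):
        if self.image.ndim != 3 or self.label.ndim != 2:
            raise ValueError("image must be (C, H, W) and label (H, W)")
        if self.image.shape[1:] != self.label.shape:
            raise ValueError(
                f"image {self.image.shape} and label {self.label.shape} disagree"
            )


def class_intensity(cls: int, contrast: float) -> float:
    """Mean interior intensity of class ``cls`` (background = 0)."""
    return contrast * cls


def _smooth_field(rng: np.random.Generator, h: int, w: int,
                  sigma: float = 4.0) -> np.ndarray:
    """Zero-mean, unit-std Gaussian-smoothed noise field (FFT filtering)."""
    noise = rng.standard_normal((h, w))
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.rfftfreq(w)[None, :]
    g = np.exp(-2.0 * np.pi**2 * sigma**2 * (fy**2 + fx**2))
    field = np.fft.irfft2(np.fft.rfft2(noise) * g, s=(h, w))
    std = field.std()
    if std < 1e-12:
        return np.zeros((h, w))
    return (field - field.mean()) / std


def _object_mask(rng: np.random.Generator, kind: str, h: int, w: int,
                 radius_range: tuple[float, float]) -> np.ndarray:
    rlo, rhi = radius_range
    rhi = min(rhi, (min(h, w) - 2) / 2.0)  # keep the object inside the frame
    r = rng.uniform(rlo, max(rlo, rhi))
    cy = rng.uniform(r, h - r)
    cx = rng.uniform(r, w - r)
    yy, xx = np.mgrid[0:h, 0:w]
    if kind == "ellipse":
        ry = r * rng.uniform(0.6, 1.0)
        rx = r * rng.uniform(0.6, 1.0)
        theta = rng.uniform(0, np.pi)
        dy, dx = yy - cy, xx - cx
        u = dy * np.cos(theta) + dx * np.sin(theta)
        v = -dy * np.sin(theta) + dx * np.cos(theta)
        return (u / ry) ** 2 + (v / rx) ** 2 <= 1.0
    # blob: disk boundary wobbled by thresholded smoothed noise
    dist = np.hypot(yy - cy, xx - cx)
    wobble = _smooth_field(rng, h, w, sigma=max(2.0, r / 3.0))
    return dist <= r * (1.0 + 0.3 * wobble)


def generate(spec: SyntheticSpec) -> list[SegmentationSample]:
    """Generate the dataset; bitwise deterministic given the spec."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    c = spec.num_classes
    samples = []
    for case in range(spec.n_cases):
        label = np.zeros((h, w), dtype=np.uint8)
        n_obj = int(rng.integers(spec.objects_per_case[0],
                                 spec.objects_per_case[1] + 1))
        # first cover every foreground class once, then draw extras freely
        classes = list(range(1, c)) + [
            int(rng.integers(1, c)) for _ in range(n_obj - (c - 1))
        ]
        for cls in classes:
            kind = spec.object_kinds[int(rng.integers(len(spec.object_kinds)))]
            mask = _object_mask(rng, kind, h, w, spec.radius_range)
            label[mask] = cls
        intensities = np.array(
            [class_intensity(j, spec.contrast) for j in range(c)]
        )
        clean = intensities[label]
        image = np.empty((spec.in_channels, h, w), dtype=np.float32)
        for ch in range(spec.in_channels):
            gain = 1.0 + 0.15 * ch  # modality-specific intensity scaling
            image[ch] = gain * clean + spec.noise_sigma * rng.standard_normal((h, w))
        samples.append(
            SegmentationSample(image=image, label=label,
                               case_id=f"case_{case:04d}")
        )
    return samples


def split(samples, n_val: int):
    """Deterministic tail split into (train, validation)."""
    if not 0 < n_val < len(samples):
        raise ValueError("n_val must split the dataset nontrivially")
    return samples[:-n_val], samples[-n_val:]


# ---------------------------------------------------------- MSD layout ----

def write_msd_layout(samples: list[SegmentationSample], root) -> None:
    """Write ``imagesTr``/``labelsTr`` NIfTI files plus ``dataset.json``."""
    root = Path(root)
    (root / "imagesTr").mkdir(parents=True, exist_ok=True)
    (root / "labelsTr").mkdir(parents=True, exist_ok=True)
    affine = np.eye(4)
    n_channels = samples[0].image.shape[0]
    num_classes = int(max(int(s.label.max()) for s in samples)) + 1
    for s in samples:
        for ch in range(s.image.shape[0]):
            img = nib.Nifti1Image(
                np.asarray(s.image[ch], dtype=np.float32), affine
            )
            nib.save(img, root / "imagesTr" / f"{s.case_id}_{ch:04d}.nii.gz")
        lab = nib.Nifti1Image(np.asarray(s.label, dtype=np.uint8), affine)
        nib.save(lab, root / "labelsTr" / f"{s.case_id}.nii.gz")
    meta = {
        "modality": {str(ch): f"synthetic_ch{ch}" for ch in range(n_channels)},
        "labels": {str(j): ("background" if j == 0 else f"class_{j}")
                   for j in range(num_classes)},
        "numTraining": len(samples),
    }
    (root / "dataset.json").write_text(json.dumps(meta, indent=2))


def read_msd_layout(root) -> list[SegmentationSample]:
    """Read a dataset written by :func:`write_msd_layout`."""
    root = Path(root)
    for sub in ("imagesTr", "labelsTr"):
        if not (root / sub).is_dir():
            raise FileNotFoundError(f"missing folder {root / sub}")
    meta_path = root / "dataset.json"
    if not meta_path.exists():
        raise FileNotFoundError(f"missing {meta_path}")
    meta = json.loads(meta_path.read_text())
    n_channels = len(meta.get("modality", {"0": ""}))
    samples = []
    for lab_path in sorted((root / "labelsTr").glob("*.nii.gz")):
        case_id = lab_path.name[: -len(".nii.gz")]
        label = np.asarray(nib.load(lab_path).dataobj).astype(np.uint8)
        channels = []
        for ch in range(n_channels):
            img_path = root / "imagesTr" / f"{case_id}_{ch:04d}.nii.gz"
            if not img_path.exists():
                raise FileNotFoundError(
                    f"missing image {img_path} for label {lab_path.name}"
                )
            channels.append(
                np.asarray(nib.load(img_path).dataobj).astype(np.float32)
            )
        samples.append(
            SegmentationSample(image=np.stack(channels), label=label,
                               case_id=case_id)
        )
    if not samples:
        raise FileNotFoundError(f"no label files found under {root / 'labelsTr'}")
    return samples


# ---------------------------------------------------------- PNG layout ----

def write_png_layout(samples: list[SegmentationSample], root) -> None:
    """8-bit paired PNG dialect: images quantized to [0, 255], raw labels."""
    root = Path(root)
    (root / "images").mkdir(parents=True, exist_ok=True)
    (root / "labels").mkdir(parents=True, exist_ok=True)
    for s in samples:
        for ch in range(s.image.shape[0]):
            arr = np.clip(s.image[ch], 0.0, 1.0)
            arr = np.round(arr * 255.0).astype(np.uint8)
            Image.fromarray(arr).save(root / "images" / f"{s.case_id}_{ch:04d}.png")
        Image.fromarray(s.label.astype(np.uint8)).save(
            root / "labels" / f"{s.case_id}.png"
        )


def read_png_layout(root, n_channels: int = 1) -> list[SegmentationSample]:
    root = Path(root)
    for sub in ("images", "labels"):
        if not (root / sub).is_dir():
            raise FileNotFoundError(f"missing folder {root / sub}")
    samples = []
    for lab_path in sorted((root / "labels").glob("*.png")):
        case_id = lab_path.stem
        label = np.asarray(Image.open(lab_path)).astype(np.uint8)
        channels = []
        for ch in range(n_channels):
            img_path = root / "images" / f"{case_id}_{ch:04d}.png"
            if not img_path.exists():
                raise FileNotFoundError(f"missing image {img_path}")
            channels.append(
                np.asarray(Image.open(img_path)).astype(np.float32) / 255.0
            )
        samples.append(
            SegmentationSample(image=np.stack(channels), label=label,
                               case_id=case_id)
        )
    if not samples:
        raise FileNotFoundError(f"no label files under {root / 'labels'}")
    return samples
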