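"""Volume I/O, preprocessing and training-time augmentation.

Volumes arrive as NIfTI image/label pairs and are turned into single-channel
slices at a fixed resolution (256x256 by default): images are resampled
bilinearly, integer label grids with nearest-neighbour interpolation (which
preserves binarity), and multi-organ labels are merged into a single
foreground class. Splitting is at the patient level so no patient leaks
between training and validation.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage
from skimage.transform import resize


@dataclass
class PatientVolume:
    """A per-patient image stack with integer labels and physical spacing."""

    patient_id: str
    image: np.ndarray            # (slices, H, W) float
    labels: np.ndarray           # (slices, H, W) non-negative int
    spacing: tuple = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.image = np.asarray(self.image)
        self.labels = np.asarray(self.labels)
        if self.image.shape != self.labels.shape:
            raise ValueError(
                f"image {self.image.shape} and labels {self.labels.shape} "
                "shapes differ")
        if self.image.ndim != 3:
            raise ValueError("expected (slices, H, W) arrays")
        if (self.labels < 0).any():
            raise ValueError("labels must be non-negative integers")
        self.spacing = tuple(float(s) for s in self.spacing)


@dataclass
class SegmentationSample:
    """One 2D slice with its binary mask."""

    image: np.ndarray
    mask: np.ndarray
    patient_id: str = ""
    slice_index: int = 0
    spacing: tuple = (1.0, 1.0)

    def __post_init__(self):
        self.image = np.asarray(self.image, dtype=np.float32)
        self.mask = np.asarray(self.mask)
        if self.image.shape != self.mask.shape:
            raise ValueError("image and mask shapes differ")
        if not np.isfinite(self.image).all():
            raise ValueError("image contains non-finite values")
        if not np.isin(self.mask, (0, 1)).all():
            raise ValueError("mask must be binary")
        self.mask = self.mask.astype(np.uint8)


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def load_volume(image_path, label_path, patient_id=None) -> PatientVolume:
    """Read an image/label NIfTI pair into slice-major (S, H, W) arrays."""
    image_path, label_path = Path(image_path), Path(label_path)
    for p in (image_path, label_path):
        if not p.exists():
            raise IOError(f"no such file: {p}")
    try:
        img = nib.load(str(image_path))
        lab = nib.load(str(label_path))
        image = np.asarray(img.dataobj, dtype=np.float32)
        labels = np.rint(np.asarray(lab.dataobj)).astype(np.int32)
    except Exception as exc:  # corrupt file
        raise IOError(f"failed to read NIfTI pair "
                      f"{image_path} / {label_path}: {exc}") from exc
    if image.shape != labels.shape:
        raise ValueError(
            f"image {image.shape} and label {labels.shape} shapes differ "
            f"({image_path})")
    zooms = img.header.get_zooms()[:3]
    # nibabel arrays are (i, j, k) with k the slice axis; go slice-major.
    image = np.transpose(image, (2, 0, 1))
    labels = np.transpose(labels, (2, 0, 1))
    spacing = (float(zooms[2]), float(zooms[0]), float(zooms[1]))
    pid = patient_id or image_path.name.split(".")[0]
    return PatientVolume(pid, image, labels, spacing)


def save_volume(volume: PatientVolume, image_path, label_path):
    """Write a PatientVolume back to an image/label NIfTI pair."""
    sz, sy, sx = volume.spacing
    affine = np.diag([sy, sx, sz, 1.0])
    image = np.transpose(volume.image, (1, 2, 0)).astype(np.float32)
    labels = np.transpose(volume.labels, (1, 2, 0)).astype(np.int16)
    nib.save(nib.Nifti1Image(image, affine), str(image_path))
    nib.save(nib.Nifti1Image(labels, affine), str(label_path))


def write_manifest(rows, path):
    """CSV manifest: patient_id, image path, label path."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["patient_id", "image", "label"])
        writer.writerows(rows)
    return Path(path)


def read_manifest(path):
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such manifest: {path}")
    with open(path, newline="") as fh:
        return [(r["patient_id"], r["image"], r["label"])
                for r in csv.DictReader(fh)]


def load_dataset(manifest_path):
    """Load every volume listed in a manifest (paths relative to it)."""
    base = Path(manifest_path).parent
    volumes = []
    for pid, image, label in read_manifest(manifest_path):
        ip, lp = Path(image), Path(label)
        if not ip.is_absolute():
            ip, lp = base / ip, base / lp
        volumes.append(load_volume(ip, lp, patient_id=pid))
    return volumes


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def resample_slice(grid, out_size=(256, 256), is_label=False) -> np.ndarray:
    """Bilinear resampling for images, nearest-neighbour for label grids."""
    grid = np.asarray(grid)
    if grid.ndim != 2 or min(grid.shape) < 2:
        raise ValueError("input slice must be at least 2x2")
    if grid.shape == tuple(out_size):
        return grid.copy()
    if is_label:
        out = resize(grid.astype(np.float64), out_size, order=0,
                     preserve_range=True, anti_aliasing=False)
        return np.rint(out).astype(grid.dtype)
    out = resize(grid.astype(np.float64), out_size, order=1,
                 preserve_range=True, anti_aliasing=False)
    return out.astype(np.float32)


def merge_labels(labels) -> np.ndarray:
    """Collapse a multi-class integer label grid to binary foreground."""
    labels = np.asarray(labels)
    if (labels < 0).any():
        raise ValueError("labels must be non-negative")
    return (labels > 0).astype(np.uint8)


def normalize_intensity(grid, scheme="zscore", window=None) -> np.ndarray:
    """'zscore': per-slice standardization; 'window': clip + min-max to [0,1]."""
    x = np.asarray(grid, dtype=np.float32)
    if not np.isfinite(x).all():
        raise ValueError("non-finite intensities")
    if scheme == "zscore":
        sd = float(x.std())
        return (x - x.mean()) / (sd if sd > 1e-8 else 1.0)
    if scheme == "window":
        if window is None:
            raise ValueError("'window' scheme needs (low, high) bounds")
        lo, hi = float(window[0]), float(window[1])
        if hi <= lo:
            raise ValueError("window high must exceed low")
        return (np.clip(x, lo, hi) - lo) / (hi - lo)
    raise ValueError(f"unknown normalization scheme {scheme!r}")


def preprocess_volume(volume: PatientVolume, out_size=(256, 256),
                      scheme="zscore", window=None):
    """Resample, binarize and normalize every slice of a patient volume."""
    samples = []
    for k in range(volume.image.shape[0]):
        img = resample_slice(volume.image[k], out_size)
        lab = resample_slice(volume.labels[k], out_size, is_label=True)
        samples.append(SegmentationSample(
            image=normalize_intensity(img, scheme, window),
            mask=merge_labels(lab),
            patient_id=volume.patient_id, slice_index=k,
            spacing=volume.spacing[1:]))
    return samples


def select_training_slices(samples, mode="balanced", rng=None):
    """'balanced': all foreground slices + an equal number of random
    background slices; 'all': every slice."""
    if mode == "all":
        return list(samples)
    if mode != "balanced":
        raise ValueError(f"unknown slice selection mode {mode!r}")
    fg = [s for s in samples if s.mask.any()]
    bg = [s for s in samples if not s.mask.any()]
    if rng is None:
        rng = np.random.default_rng(0)
    k = min(len(fg), len(bg))
    chosen_bg = [bg[i] for i in rng.choice(len(bg), size=k, replace=False)] \
        if k else []
    return fg + chosen_bg


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------

def split_patients(patient_ids, train_fraction=0.7, seed=0):
    """Deterministic patient-level split; train size = round(f * n)."""
    ids = list(patient_ids)
    if len(ids) < 2:
        raise ValueError("need at least 2 patients to split")
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate patient ids")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    n_train = int(round(train_fraction * len(ids)))
    n_train = min(max(n_train, 1), len(ids) - 1)
    train = sorted(ids[i] for i in perm[:n_train])
    val = sorted(ids[i] for i in perm[n_train:])
    assert not set(train) & set(val), "patient leaked across split"
    return train, val


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AugmentBounds:
    """Geometric augmentation bounds: rotation (deg), zoom, relative shift."""

    max_rotation_deg: float = 10.0
    zoom_range: tuple = (0.75, 1.25)
    max_shift_fraction: float = 0.2


DEFAULT_AUGMENT = AugmentBounds()


def sample_augmentation_params(rng, bounds: AugmentBounds = DEFAULT_AUGMENT):
    return {
        "angle_deg": float(rng.uniform(-bounds.max_rotation_deg,
                                       bounds.max_rotation_deg)),
        "zoom": float(rng.uniform(*bounds.zoom_range)),
        "shift_frac": (float(rng.uniform(-bounds.max_shift_fraction,
                                         bounds.max_shift_fraction)),
                       float(rng.uniform(-bounds.max_shift_fraction,
                                         bounds.max_shift_fraction))),
    }


def apply_affine(sample: SegmentationSample, params) -> SegmentationSample:
    """Rotate/zoom/shift image (bilinear) and mask (nearest) identically.

    Out-of-bounds image pixels are filled with the slice minimum and mask
    pixels with background, so no phantom foreground appears.
    """
    h, w = sample.image.shape
    theta = np.deg2rad(params["angle_deg"])
    z = params["zoom"]
    ty = params["shift_frac"][0] * h
    tx = params["shift_frac"][1] * w
    c = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    rot = np.array([[np.cos(theta), -np.sin(theta)],
                    [np.sin(theta), np.cos(theta)]])
    matrix = rot.T / z                       # output -> input mapping
    offset = c - matrix @ (c + np.array([ty, tx]))
    img = ndimage.affine_transform(
        sample.image.astype(np.float64), matrix, offset=offset, order=1,
        mode="constant", cval=float(sample.image.min()))
    msk = ndimage.affine_transform(
        sample.mask, matrix, offset=offset, order=0, mode="constant", cval=0)
    return SegmentationSample(img.astype(np.float32), msk,
                              sample.patient_id, sample.slice_index,
                              sample.spacing)


def augment(sample: SegmentationSample, seed=None, rng=None,
            bounds: AugmentBounds = DEFAULT_AUGMENT) -> SegmentationSample:
    """Randomly rotated/zoomed/shifted copy of a sample, reproducible by seed."""
    if rng is None:
        rng = np.random.default_rng(seed)
    return apply_affine(sample, sample_augmentation_params(rng, bounds))
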