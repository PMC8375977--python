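"""Synthetic pancreas-like phantoms for fully self-contained experiments.

Each phantom slice is a noisy, smoothly varying background with a small,
low-contrast, elongated foreground target: a union of 2-4 overlapping
ellipses strung along a random curve, covering a configurable fraction of
the image (0.5-3% of pixels by default — the small-target regime that
motivates multi-scale feature extraction). Patient volumes are stacks of
slices in which the target drifts smoothly, so per-patient 3D metrics are
meaningful. Everything is deterministic given (seed, config).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .data_pipeline import (
    PatientVolume,
    SegmentationSample,
    save_volume,
    write_manifest,
)


@dataclass(frozen=True)
class PhantomConfig:
    image_size: tuple = (128, 128)
    n_patients: int = 16
    slices_per_patient: int = 8
    target_fraction_range: tuple = (0.005, 0.03)
    contrast: float = 3.0          # foreground mean offset, in noise-sd units
    noise_sd: float = 1.0
    seed: int = 0
    multi_label: bool = False
    drift: float = 2.0             # max centroid drift per slice, pixels

    def validate(self):
        lo, hi = self.target_fraction_range
        if not 0 < lo < hi < 0.1:
            raise ValueError("target fraction range must satisfy 0<lo<hi<0.1")
        if self.contrast < 0:
            raise ValueError("contrast must be non-negative")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        h, w = self.image_size
        if hi * h * w < 12:
            raise ValueError(
                f"fraction range {self.target_fraction_range} infeasible for "
                f"image size {self.image_size}")
        return self


@dataclass
class _Blob:
    """Parametric elongated blob: ellipses along a quadratic curve."""

    centers: np.ndarray     # (n, 2) in pixels
    axes: np.ndarray        # (n, 2) semi-axes (major, minor)
    angles: np.ndarray      # (n,) radians

    def shifted(self, dy, dx, dtheta=0.0):
        c = self.centers + np.array([dy, dx])
        return _Blob(c, self.axes.copy(), self.angles + dtheta)

    def scaled(self, factor):
        return _Blob(self.centers.copy(), self.axes * factor,
                     self.angles.copy())


def _rasterize(blob: _Blob, shape):
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    mask = np.zeros(shape, dtype=bool)
    for (cy, cx), (a, b), th in zip(blob.centers, blob.axes, blob.angles):
        dy, dx = yy - cy, xx - cx
        u = dy * np.cos(th) + dx * np.sin(th)
        v = -dy * np.sin(th) + dx * np.cos(th)
        mask |= (u / a) ** 2 + (v / b) ** 2 <= 1.0
    return mask


def _rasterize_labels(blob: _Blob, shape):
    """Integer labels {0,1,2}: ellipse index parity splits the blob."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    labels = np.zeros(shape, dtype=np.int32)
    half = (len(blob.centers) + 1) // 2
    for i, ((cy, cx), (a, b), th) in enumerate(
            zip(blob.centers, blob.axes, blob.angles)):
        dy, dx = yy - cy, xx - cx
        u = dy * np.cos(th) + dx * np.sin(th)
        v = -dy * np.sin(th) + dx * np.cos(th)
        inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        labels[inside & (labels == 0)] = 1 if i < half else 2
    return labels


def _sample_blob(cfg: PhantomConfig, rng) -> _Blob:
    h, w = cfg.image_size
    lo, hi = cfg.target_fraction_range
    area = rng.uniform(lo, hi) * h * w
    n_ell = int(rng.integers(2, 5))
    center = np.array([rng.uniform(0.3 * h, 0.7 * h),
                       rng.uniform(0.3 * w, 0.7 * w)])
    theta = rng.uniform(0, np.pi)
    curvature = rng.uniform(-0.3, 0.3)
    elong = rng.uniform(2.0, 4.0)
    # initial guess for semi-axes from the area budget
    a0 = np.sqrt(area * elong / (np.pi * n_ell))
    b0 = a0 / elong
    step = 1.2 * a0
    centers, angles = [], []
    for i in range(n_ell):
        s = (i - (n_ell - 1) / 2.0) * step
        ang = theta + curvature * s / max(a0, 1.0)
        centers.append(center + s * np.array([np.sin(ang), np.cos(ang)]))
        angles.append(ang)
    axes = np.column_stack([
        a0 * rng.uniform(0.8, 1.2, n_ell),
        b0 * rng.uniform(0.8, 1.2, n_ell)])
    blob = _Blob(np.array(centers), axes, np.array(angles))
    # rescale so the rasterized fraction lands inside the target range
    target = area
    for _ in range(6):
        m = _rasterize(blob, cfg.image_size)
        got = m.sum()
        if got == 0:
            blob = blob.scaled(1.5)
            continue
        ratio = target / got
        if lo * h * w <= got <= hi * h * w:
            return blob
        blob = blob.scaled(np.sqrt(ratio))
    return blob


def _background(cfg: PhantomConfig, rng):
    h, w = cfg.image_size
    smooth = ndimage.gaussian_filter(rng.normal(size=(h, w)), sigma=h / 8.0)
    sd = smooth.std()
    if sd > 1e-12:
        smooth *= cfg.noise_sd / sd
    return smooth + rng.normal(0.0, cfg.noise_sd, size=(h, w))


def _render(cfg: PhantomConfig, blob: _Blob, rng, patient_id="", index=0):
    mask = _rasterize(blob, cfg.image_size)
    image = _background(cfg, rng)
    image[mask] += cfg.contrast * cfg.noise_sd
    return SegmentationSample(image.astype(np.float32),
                              mask.astype(np.uint8), patient_id, index)


def generate_phantom_slice(cfg: PhantomConfig,
                           rng=None) -> SegmentationSample:
    """One phantom slice; foreground fraction lies in the configured range."""
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    h, w = cfg.image_size
    lo, hi = cfg.target_fraction_range
    for _ in range(8):
        blob = _sample_blob(cfg, rng)
        frac = _rasterize(blob, cfg.image_size).sum() / (h * w)
        if lo <= frac <= hi:
            return _render(cfg, blob, rng)
    raise ValueError(
        f"could not realise a foreground fraction in [{lo}, {hi}] "
        f"at image size {cfg.image_size}")


def generate_patient_volume(cfg: PhantomConfig, patient_id,
                            patient_index: int = 0) -> PatientVolume:
    """Slice-coherent stack: the blob drifts smoothly across slices."""
    cfg.validate()
    if cfg.slices_per_patient < 1:
        raise ValueError("slices_per_patient must be >= 1")
    rng = np.random.default_rng([cfg.seed, 7919 + patient_index])
    h, w = cfg.image_size
    lo, hi = cfg.target_fraction_range
    blob = _sample_blob(cfg, rng)
    images, labels = [], []
    for k in range(cfg.slices_per_patient):
        if k:
            dy, dx = rng.uniform(-cfg.drift, cfg.drift, size=2)
            blob = blob.shifted(dy, dx, rng.uniform(-0.05, 0.05))
            blob = blob.scaled(rng.uniform(0.95, 1.05))
            frac = _rasterize(blob, cfg.image_size).sum() / (h * w)
            if not lo <= frac <= hi and frac > 0:
                mid = np.sqrt(lo * hi)
                blob = blob.scaled(np.sqrt(mid / frac))
        image = _background(cfg, rng)
        mask = _rasterize(blob, cfg.image_size)
        image[mask] += cfg.contrast * cfg.noise_sd
        lab = (_rasterize_labels(blob, cfg.image_size) if cfg.multi_label
               else mask.astype(np.int32))
        images.append(image.astype(np.float32))
        labels.append(lab)
    return PatientVolume(str(patient_id), np.stack(images), np.stack(labels))


def generate_dataset(cfg: PhantomConfig):
    """All patient volumes for a configuration, deterministically."""
    cfg.validate()
    return [generate_patient_volume(cfg, f"phantom{i:03d}", i)
            for i in range(cfg.n_patients)]


def write_phantom_dataset(cfg: PhantomConfig, directory) -> Path:
    """Write NIfTI volumes + labels and a CSV manifest; returns its path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for vol in generate_dataset(cfg):
        ip = f"{vol.patient_id}_image.nii.gz"
        lp = f"{vol.patient_id}_label.nii.gz"
        save_volume(vol, directory / ip, directory / lp)
        rows.append((vol.patient_id, ip, lp))
    return write_manifest(rows, directory / "manifest.csv")


def phantom_slices(cfg: PhantomConfig, n: int, seed=None):
    """A flat list of n independent slices (convenience for harnesses)."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    return [generate_phantom_slice(cfg, rng) for _ in range(n)]
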