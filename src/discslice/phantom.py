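"""Synthetic paired-modality lumbar-slice phantoms.

The generator emulates the structure a traverse lumbar-spine slice stack
offers the pipeline: two co-located modalities related by a contrast
mapping, a known affine misalignment between them, a low-frequency
multiplicative bias field, additive noise, and four slice classes — one
mid-height slice per disc level (L3/L4, L4/L5, L5/S1) per patient and
"other" slices elsewhere in the stack.

The anatomy is deliberately minimal: a soft-tissue ellipse, a vertebral
body, a spinal canal, and — on mid-height slices only — a bright disc/CSF
pattern whose vertical position encodes the disc level.  This is the
smallest structure that makes the classes separable and the registration
problem non-trivial; it is not an anatomically realistic MRI simulation.

All randomness flows from one integer seed through per-record substreams
(``seed, patient, slice``) so each record is reproducible in isolation.

``true_transform`` on each record is the *corrective* transform: applying
it to the stored ``t2`` brings the anatomy back onto the ``t1`` grid, so a
successful registration should recover it directly.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .registration import (
    AffineTransform2D,
    apply_bias_field,
    image_center,
    transform_image,
)

__all__ = [
    "PhantomConfig",
    "PhantomRecord",
    "PhantomStudy",
    "apply_bias_field",
    "generate_study",
    "write_study",
]

LABELS = ("best_d3", "best_d4", "best_d5", "other_slices")


@dataclass(frozen=True)
class PhantomConfig:
    """Study-generation settings.

    ``class_pattern_contrast`` is the added intensity of the disc/canal
    pattern on mid-height slices (dimensionless, in [0, 1]); the default
    makes the four classes cleanly separable by template correlation on raw
    pixels.  Misalignment ranges are the half-widths of the uniform
    distributions the per-record T1->T2 misalignment is drawn from.
    """

    image_size: int = 128
    n_patients: int = 8
    slices_per_patient: int = 9
    class_pattern_contrast: float = 0.35
    max_translation: float = 6.0      # pixels
    max_rotation: float = 5.0         # degrees
    max_scale_offset: float = 0.03    # fraction
    modality_map: str = "invert"      # "invert" | "gamma" | "identity"
    bias_order: int = 2
    bias_amplitude: float = 0.15
    noise_sd: float = 0.02            # intensity units on a [0, 1] scale
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size < 32:
            raise ValueError("image_size must be at least 32")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.n_patients < 1 or self.slices_per_patient < 1:
            raise ValueError("counts must be positive")
        for v in (self.max_translation, self.max_rotation, self.max_scale_offset):
            if not np.isfinite(v) or v < 0:
                raise ValueError("misalignment ranges must be finite and >= 0")
        if self.modality_map not in ("invert", "gamma", "identity"):
            raise ValueError(f"unknown modality_map {self.modality_map!r}")
        if not 0.0 <= self.class_pattern_contrast <= 1.0:
            raise ValueError("class_pattern_contrast must lie in [0, 1]")


@dataclass
class PhantomRecord:
    t1: np.ndarray
    t2: np.ndarray
    true_transform: AffineTransform2D
    label: str
    patient_id: int
    slice_index: int  # 1-based within the patient's stack


@dataclass
class PhantomStudy:
    config: PhantomConfig
    records: list[PhantomRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def label_counts(self) -> dict[str, int]:
        counts = {lab: 0 for lab in LABELS}
        for r in self.records:
            counts[r.label] += 1
        return counts


def _ellipse(grid_y, grid_x, cx, cy, rx, ry, angle=0.0):
    ca, sa = np.cos(angle), np.sin(angle)
    dx = grid_x - cx
    dy = grid_y - cy
    u = (ca * dx + sa * dy) / rx
    v = (-sa * dx + ca * dy) / ry
    return u * u + v * v <= 1.0


def apply_modality_map(img: np.ndarray, name: str) -> np.ndarray:
    """Intensity transfer curve relating the two modalities.

    ``invert`` mimics the T1/T2 appearance flip of CSF (bright fluid on T2,
    dark on T1); ``gamma`` is a monotone nonlinear alternative.
    """
    if name == "invert":
        return 1.0 - img
    if name == "gamma":
        return np.power(np.clip(img, 0.0, 1.0), 0.5)
    if name == "identity":
        return img.copy()
    raise ValueError(f"unknown modality_map {name!r}")


def _mid_slice_positions(slices_per_patient: int) -> dict[int, str]:
    """1-based indices of the three mid-height slices within a stack.

    For the canonical 9-slice stack these are slices 2, 5 and 8; shorter or
    longer stacks place the three levels at evenly spaced interior indices.
    """
    n = slices_per_patient
    if n < 3:
        return {}
    if n == 9:
        picks = (2, 5, 8)
    else:
        picks = tuple(
            int(round((k + 1) * (n + 1) / 4.0)) for k in range(3)
        )
        # ensure distinct, in range
        picks = tuple(min(max(p, k + 1), n - (2 - k)) for k, p in enumerate(picks))
    return {picks[0]: "best_d3", picks[1]: "best_d4", picks[2]: "best_d5"}


def _draw_anatomy(size: int, rng: np.random.Generator, label: str,
                  contrast: float) -> np.ndarray:
    y, x = np.mgrid[0:size, 0:size].astype(float)
    c = (size - 1) / 2.0
    img = np.full((size, size), 0.05)

    jit = lambda s: rng.uniform(-s, s) * size  # noqa: E731

    # soft tissue
    img[_ellipse(y, x, c + jit(0.01), c + jit(0.01),
                 0.44 * size, 0.38 * size)] = 0.30
    # vertebral body, slightly below center
    body_cy = c + 0.10 * size + jit(0.01)
    img[_ellipse(y, x, c + jit(0.008), body_cy,
                 0.20 * size, 0.14 * size)] = 0.55
    # spinal canal behind the body
    canal_cy = body_cy - 0.20 * size
    img[_ellipse(y, x, c + jit(0.006), canal_cy,
                 0.05 * size, 0.045 * size)] = 0.75
    # posterior arch: spinous process and asymmetric transverse processes
    # (breaks rotational symmetry so orientation is identifiable)
    img[_ellipse(y, x, c + jit(0.004), canal_cy - 0.12 * size,
                 0.03 * size, 0.09 * size)] = 0.65
    img[_ellipse(y, x, c - 0.16 * size + jit(0.004), canal_cy - 0.02 * size,
                 0.10 * size, 0.030 * size, angle=0.35)] = 0.62
    img[_ellipse(y, x, c + 0.16 * size + jit(0.004), canal_cy - 0.02 * size,
                 0.10 * size, 0.030 * size, angle=-0.35)] = 0.58

    if label != "other_slices":
        # disc/CSF pattern: a bright annulus over the body plus a CSF dot,
        # vertical position encodes the disc level
        offset = {"best_d3": -0.16, "best_d4": 0.0, "best_d5": 0.16}[label]
        py = c + offset * size + jit(0.004)
        px = c + jit(0.004)
        outer = _ellipse(y, x, px, py, 0.13 * size, 0.085 * size)
        inner = _ellipse(y, x, px, py, 0.075 * size, 0.045 * size)
        img[outer & ~inner] += contrast
        img[_ellipse(y, x, px, py - 0.10 * size, 0.030 * size, 0.025 * size)] += contrast
    return np.clip(img, 0.0, 1.0)


def _sample_misalignment(cfg: PhantomConfig, rng: np.random.Generator,
                         center) -> AffineTransform2D:
    t = AffineTransform2D(
        tx=rng.uniform(-cfg.max_translation, cfg.max_translation),
        ty=rng.uniform(-cfg.max_translation, cfg.max_translation),
        rotation=np.deg2rad(rng.uniform(-cfg.max_rotation, cfg.max_rotation)),
        scale_x=1.0 + rng.uniform(-cfg.max_scale_offset, cfg.max_scale_offset),
        scale_y=1.0 + rng.uniform(-cfg.max_scale_offset, cfg.max_scale_offset),
        shear=0.0,
        center=center,
    )
    return t


def _sample_bias_coefficients(cfg: PhantomConfig,
                              rng: np.random.Generator) -> np.ndarray:
    n = (cfg.bias_order + 1) * (cfg.bias_order + 2) // 2
    coeffs = np.zeros(n)
    coeffs[0] = 1.0
    if n > 1:
        coeffs[1:] = rng.uniform(-cfg.bias_amplitude, cfg.bias_amplitude,
                                 size=n - 1) / max(cfg.bias_order, 1)
    return coeffs


def generate_study(config: PhantomConfig) -> PhantomStudy:
    """Generate a deterministic paired-modality phantom study.

    Every patient contributes ``slices_per_patient`` records; when the
    stack has at least 3 slices, exactly one per patient carries each
    mid-height label.  The stored T2 is the contrast-mapped anatomy warped
    by the sampled misalignment, multiplied by a positive polynomial bias
    field and degraded with clipped additive Gaussian noise; the record's
    ``true_transform`` undoes the warp.
    """
    cfg = config
    positions = _mid_slice_positions(cfg.slices_per_patient)
    study = PhantomStudy(config=cfg)
    for pid in range(cfg.n_patients):
        for sidx in range(1, cfg.slices_per_patient + 1):
            rng = np.random.default_rng([cfg.seed, pid, sidx])
            label = positions.get(sidx, "other_slices")
            t1 = _draw_anatomy(cfg.image_size, rng, label,
                               cfg.class_pattern_contrast)
            t2_clean = apply_modality_map(t1, cfg.modality_map)
            center = image_center(t1)
            mis = _sample_misalignment(cfg, rng, center)
            if mis.is_identity():
                t2 = t2_clean.copy()
            else:
                t2 = transform_image(t2_clean, mis.inverse())
            coeffs = _sample_bias_coefficients(cfg, rng)
            if cfg.bias_order > 0:
                t2 = apply_bias_field(t2, coeffs)
            if cfg.noise_sd > 0:
                t2 = np.clip(
                    t2 + cfg.noise_sd * rng.standard_normal(t2.shape), 0.0, 1.0
                )
            study.records.append(
                PhantomRecord(
                    t1=t1, t2=t2, true_transform=mis, label=label,
                    patient_id=pid, slice_index=sidx,
                )
            )
    return study


def write_study(study: PhantomStudy, out_dir: str | Path) -> Path:
    """Write a study as 16-bit grayscale PNG pairs plus a ground-truth CSV.

    Layout: ``t1/`` and ``t2/`` folders with alphabetically pairable file
    names, and ``ground_truth.csv`` with columns patient_id, slice_index,
    t1_path, t2_path, label, tx, ty, rot_deg, scale.  Returns the CSV path.
    """
    import imageio.v3 as iio

    out_dir = Path(out_dir)
    (out_dir / "t1").mkdir(parents=True, exist_ok=True)
    (out_dir / "t2").mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / "ground_truth.csv"
    with open(csv_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["patient_id", "slice_index", "t1_path", "t2_path",
                         "label", "tx", "ty", "rot_deg", "scale"])
        for r in study.records:
            stem = f"p{r.patient_id:03d}_s{r.slice_index:02d}.png"
            for sub, img in (("t1", r.t1), ("t2", r.t2)):
                arr = np.clip(img, 0.0, 1.0)
                iio.imwrite(out_dir / sub / stem,
                            (arr * 65535.0 + 0.5).astype(np.uint16))
            t = r.true_transform
            writer.writerow([
                r.patient_id, r.slice_index, f"t1/{stem}", f"t2/{stem}",
                r.label, f"{t.tx:.6f}", f"{t.ty:.6f}",
                f"{np.rad2deg(t.rotation):.6f}",
                f"{0.5 * (t.scale_x + t.scale_y):.6f}",
            ])
    return csv_path
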