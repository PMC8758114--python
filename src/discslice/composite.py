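"""3-channel composite images from a registered T1/T2 pair.

Channel 1 is the normalized T1 slice, channel 2 the normalized registered
T2 slice, and channel 3 the per-pixel Manhattan (L1) distance of the two —
for single-channel images simply ``|c1 - c2|``.  Channels are normalized
independently to [0, 1] with robust percentile clipping before the
difference is formed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize

__all__ = ["CompositeImage", "build_composite", "normalize_intensity",
           "prepare_for_backbone"]


@dataclass
class CompositeImage:
    """Ordered (T1, registered T2, |difference|) channel stack in [0, 1]."""

    channels: np.ndarray  # (H, W, 3)
    provenance: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return self.channels.shape[:2]

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=float)
        if self.channels.ndim != 3 or self.channels.shape[2] != 3:
            raise ValueError("composite requires an (H, W, 3) array")


def normalize_intensity(img: np.ndarray, lo_pct: float = 1.0,
                        hi_pct: float = 99.0) -> np.ndarray:
    """Robust affine rescale of an image into [0, 1].

    Values below the ``lo_pct`` percentile clip to 0 and above ``hi_pct``
    to 1; a constant image maps to all zeros.  Idempotent on already
    normalized non-degenerate images (up to the percentile clip).
    """
    if hi_pct <= lo_pct:
        raise ValueError("hi_pct must exceed lo_pct")
    img = np.asarray(img, dtype=float)
    lo, hi = np.percentile(img, [lo_pct, hi_pct])
    if hi <= lo:
        return np.zeros_like(img)
    return np.clip((img - lo) / (hi - lo), 0.0, 1.0)


def build_composite(t1: np.ndarray, t2_registered: np.ndarray,
                    lo_pct: float = 1.0, hi_pct: float = 99.0,
                    provenance: dict | None = None) -> CompositeImage:
    """Stack (T1, registered T2, |T1 - T2reg|) after per-channel scaling."""
    t1 = np.asarray(t1, dtype=float)
    t2_registered = np.asarray(t2_registered, dtype=float)
    if t1.shape != t2_registered.shape:
        raise ValueError("T1 and registered T2 must share a shape")
    c1 = normalize_intensity(t1, lo_pct, hi_pct)
    c2 = normalize_intensity(t2_registered, lo_pct, hi_pct)
    c3 = np.abs(c1 - c2)
    return CompositeImage(
        channels=np.stack([c1, c2, c3], axis=-1),
        provenance=provenance or {},
    )


def prepare_for_backbone(c: CompositeImage, target_size: int,
                         allowed_sizes: frozenset[int] | None = None
                         ) -> CompositeImage:
    """Bilinearly resize a composite to a backbone's square input size."""
    if allowed_sizes is None:
        from .features import backbone_input_sizes
        allowed_sizes = backbone_input_sizes()
    if target_size not in allowed_sizes:
        raise ValueError(
            f"target_size {target_size} is not a registered backbone input size"
        )
    if c.shape == (target_size, target_size):
        return CompositeImage(channels=c.channels.copy(),
                              provenance=dict(c.provenance))
    out = resize(c.channels, (target_size, target_size, 3), order=1,
                 mode="edge", anti_aliasing=False, preserve_range=True)
    return CompositeImage(channels=np.clip(out, 0.0, 1.0),
                          provenance=dict(c.provenance))
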