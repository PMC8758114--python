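"""Dataset loading, class-imbalance augmentation and repeat bookkeeping.

Ground-truth conventions follow the practical tool contract: two folders
of T1 and T2 images that pair up when file names are sorted
alphabetically, plus a CSV that either lists 1-based image indices per
class or carries explicit per-file labels.  Any image not named by the CSV
defaults to the majority ``other_slices`` class.

The four classes are, in fixed order: ``best_d3`` (mid-height L3/L4),
``best_d4`` (L4/L5), ``best_d5`` (L5/S1) and ``other_slices``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "AugmentPolicy",
    "CLASS_ORDER",
    "LabeledPair",
    "SplitPlan",
    "augment",
    "load_dataset",
    "make_splits",
]

CLASS_ORDER = ("best_d3", "best_d4", "best_d5", "other_slices")
MID_CLASSES = CLASS_ORDER[:3]


@dataclass
class LabeledPair:
    t1: np.ndarray
    t2: np.ndarray
    label: str
    t1_source: str = ""
    t2_source: str = ""
    pair_id: int = -1

    def __post_init__(self) -> None:
        if self.label not in CLASS_ORDER:
            raise ValueError(f"unknown label {self.label!r}")


@dataclass(frozen=True)
class AugmentPolicy:
    """Imbalance correction: duplicate the mid-height classes by
    ``minority_multiplier`` and subsample ``other_slices`` (without
    replacement) down to ``round(majority_ratio * multiplier * smallest
    mid-class count)``.  Defaults (x2, 1.5) reproduce the study's worked
    example: (513, 513, 513, 7371) -> (1026, 1026, 1026, 1539), total 4617.
    """

    minority_multiplier: int = 2
    majority_ratio: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.minority_multiplier < 1:
            raise ValueError("minority_multiplier must be >= 1")
        if self.majority_ratio <= 0:
            raise ValueError("majority_ratio must be positive")


@dataclass(frozen=True)
class SplitPlan:
    train: tuple[int, ...]
    test: tuple[int, ...]
    repeat_id: int
    seed: int


def _read_image(path: Path) -> np.ndarray:
    """Read a PNG or DICOM slice as a float array.

    DICOM stored values are rescaled by slope/intercept when present.
    """
    suffix = path.suffix.lower()
    if suffix in (".dcm", ".ima", ".dicom"):
        import pydicom

        ds = pydicom.dcmread(str(path))
        arr = ds.pixel_array.astype(float)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        return arr * slope + intercept
    import imageio.v3 as iio

    try:
        arr = np.asarray(iio.imread(str(path)), dtype=float)
    except Exception as exc:  # noqa: BLE001
        raise OSError(f"could not read image file {path}") from exc
    if arr.ndim == 3:
        arr = arr.mean(axis=-1)
    return arr


def _resample_to(img: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    if img.shape == shape:
        return img
    from skimage.transform import resize

    return resize(img, shape, order=1, mode="edge", anti_aliasing=True,
                  preserve_range=True)


def _labels_from_csv(csv_path: Path, n_pairs: int,
                     t1_names: list[str]) -> list[str]:
    labels = ["other_slices"] * n_pairs
    try:
        table = pd.read_csv(csv_path)
    except pd.errors.EmptyDataError:
        return labels
    if table.empty:
        return labels
    cols = {c.lower().strip(): c for c in table.columns}
    if "index" in cols and "label" in cols:
        # 1-based image indices into the alphabetically sorted listing
        for _, row in table.iterrows():
            idx = int(row[cols["index"]])
            if not 1 <= idx <= n_pairs:
                raise ValueError(f"CSV index {idx} out of range 1..{n_pairs}")
            labels[idx - 1] = str(row[cols["label"]]).strip()
    elif "t1_path" in cols and "label" in cols:
        by_name = {Path(str(p)).name: str(lab).strip()
                   for p, lab in zip(table[cols["t1_path"]],
                                     table[cols["label"]])}
        for i, name in enumerate(t1_names):
            if name in by_name:
                labels[i] = by_name[name]
    else:
        raise ValueError(
            "ground-truth CSV needs either (index, label) or "
            "(t1_path, label) columns"
        )
    for lab in labels:
        if lab not in CLASS_ORDER:
            raise ValueError(f"unknown label {lab!r} in ground truth")
    return labels


def load_dataset(t1_dir: str | Path, t2_dir: str | Path,
                 ground_truth: str | Path) -> list[LabeledPair]:
    """Load matched T1/T2 pairs and attach ground-truth labels.

    Files pair up by the alphabetical sort order of their names; the two
    folders must contain equally many images.  The T2 slice is resampled
    onto the T1 pixel grid if shapes differ.
    """
    t1_dir, t2_dir = Path(t1_dir), Path(t2_dir)
    exts = (".png", ".dcm", ".ima", ".dicom", ".tif", ".tiff")
    t1_files = sorted(p for p in t1_dir.iterdir()
                      if p.suffix.lower() in exts)
    t2_files = sorted(p for p in t2_dir.iterdir()
                      if p.suffix.lower() in exts)
    if len(t1_files) != len(t2_files):
        raise ValueError(
            f"pairing error: {len(t1_files)} T1 files vs "
            f"{len(t2_files)} T2 files"
        )
    labels = _labels_from_csv(Path(ground_truth), len(t1_files),
                              [p.name for p in t1_files])
    pairs = []
    for i, (p1, p2, lab) in enumerate(zip(t1_files, t2_files, labels)):
        t1 = _read_image(p1)
        t2 = _resample_to(_read_image(p2), t1.shape)
        pairs.append(LabeledPair(t1=t1, t2=t2, label=lab,
                                 t1_source=str(p1), t2_source=str(p2),
                                 pair_id=i))
    return pairs


def _counts(labels) -> dict[str, int]:
    labels = list(labels)
    return {c: int(sum(1 for lab in labels if lab == c)) for c in CLASS_ORDER}


def augment(pairs: list, policy: AugmentPolicy | None = None) -> list:
    """Rebalance classes by exact-copy oversampling and random subsampling.

    Mid-height classes are duplicated ``minority_multiplier`` times (exact
    copies, no jitter); ``other_slices`` is subsampled without replacement
    to ``round(majority_ratio * multiplier * min mid-class count)``.
    Deterministic given the policy seed.
    """
    policy = policy or AugmentPolicy()
    counts = _counts(p.label for p in pairs)
    for c in MID_CLASSES:
        if counts[c] == 0:
            raise ValueError(f"mid-height class {c} is empty")
    minority = min(counts[c] for c in MID_CLASSES)
    target_major = int(round(policy.majority_ratio
                             * policy.minority_multiplier * minority))
    if target_major > counts["other_slices"]:
        raise ValueError(
            f"majority target {target_major} exceeds available "
            f"{counts['other_slices']} other_slices pairs"
        )
    out = []
    for c in MID_CLASSES:
        members = [p for p in pairs if p.label == c]
        out.extend(members * policy.minority_multiplier)
    majors = [p for p in pairs if p.label == "other_slices"]
    rng = np.random.default_rng(policy.seed)
    keep = rng.choice(len(majors), size=target_major, replace=False)
    out.extend(majors[k] for k in sorted(keep))
    return out


def make_splits(dataset, n_repeats: int = 20, base_seed: int = 0,
                labels=None) -> list[SplitPlan]:
    """Stratified 80:20 train/test plans for the repeat protocol.

    ``dataset`` may be a list of labeled objects (``.label``) or a plain
    label sequence via ``labels``.  Per class, the test size is the floor
    of 20% (at least 1) and the remainder trains; the repeat seeds are
    spawned deterministically from ``base_seed``.
    """
    if labels is None:
        labels = [p.label for p in dataset]
    labels = list(labels)
    n = len(labels)
    counts = _counts(labels)
    for c, k in counts.items():
        if 0 < k < 5:
            raise ValueError(f"class {c} has only {k} members; need >= 5")
    seeds = np.random.SeedSequence(base_seed).generate_state(n_repeats)
    plans = []
    by_class = {c: sorted(i for i, lab in enumerate(labels) if lab == c)
                for c in CLASS_ORDER}
    for rep, seed in enumerate(seeds):
        rng = np.random.default_rng(seed)
        train: list[int] = []
        test: list[int] = []
        for c in CLASS_ORDER:
            members = by_class[c]
            if not members:
                continue
            n_test = max(1, int(np.floor(0.2 * len(members))))
            perm = rng.permutation(len(members))
            test.extend(members[j] for j in perm[:n_test])
            train.extend(members[j] for j in perm[n_test:])
        plans.append(SplitPlan(train=tuple(sorted(train)),
                               test=tuple(sorted(test)),
                               repeat_id=rep, seed=int(seed)))
        assert len(train) + len(test) == n
    return plans
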