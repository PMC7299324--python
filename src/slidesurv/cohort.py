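"""Case/slide data model, tissue detection, patch sampling and cohort splits.

A *case* is one patient: a clinical :class:`SurvivalRecord` plus one or more
desk-scale slide images.  Patches are sampled uniformly over the union of
tissue-eligible positions across **all** slides of a case, so a slide's
sampling weight is proportional to its eligible tissue area.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Mean Gregorian month length in days; used for the one-time days->months
#: conversion applied before any survival statistic.
DAYS_PER_MONTH = 30.44

#: Grayscale intensity below which a pixel counts as tissue (0-255 scale).
DEFAULT_TISSUE_THRESHOLD = 220

#: Minimum fraction of tissue pixels for a patch position to be eligible.
DEFAULT_MIN_TISSUE_FRACTION = 0.5


class NoTissueError(RuntimeError):
    """Raised when a case has no tissue-eligible patch position."""


def days_to_months(days: float) -> int:
    """Convert survival days to whole months: ``floor(days / 30.44)``.

    Applied exactly once, when an analysis asks for months; records store days.
    """
    return int(math.floor(days / DAYS_PER_MONTH))


@dataclass(frozen=True)
class SurvivalRecord:
    """Clinical ground truth for one case.

    ``time_days`` is the event time for ``event == 1`` and the time of last
    follow-up for right-censored cases (``event == 0``).
    """

    case_id: str
    study: str
    time_days: float
    event: int
    stage: int | None = None
    age: float | None = None
    sex: str | None = None

    def __post_init__(self):
        if self.time_days <= 0:
            raise ValueError(f"time_days must be positive, got {self.time_days}")
        if self.event not in (0, 1):
            raise ValueError(f"event must be 0 or 1, got {self.event}")

    @property
    def time_months(self) -> int:
        return days_to_months(self.time_days)


class Slide:
    """One slide image with cached tissue mask and patch-eligibility grids."""

    def __init__(self, image: np.ndarray, slide_id: str = "slide",
                 tissue_threshold: float = DEFAULT_TISSUE_THRESHOLD):
        if image.ndim != 3 or image.shape[2] != 3:
            raise ValueError("slide image must be HxWx3 RGB")
        self.image = np.ascontiguousarray(image)
        self.slide_id = slide_id
        self.tissue_threshold = tissue_threshold
        self._mask: np.ndarray | None = None
        self._eligible: dict[tuple[int, float], np.ndarray] = {}

    @property
    def shape(self) -> tuple[int, int]:
        return self.image.shape[:2]

    @property
    def tissue_mask(self) -> np.ndarray:
        if self._mask is None:
            self._mask = detect_tissue(self.image, self.tissue_threshold)
        return self._mask

    def eligible_mask(self, patch_px: int,
                      min_tissue_fraction: float = DEFAULT_MIN_TISSUE_FRACTION) -> np.ndarray:
        """Boolean grid over top-left positions: True where a ``patch_px``
        window fits inside the slide and covers >= ``min_tissue_fraction``
        tissue pixels."""
        key = (patch_px, min_tissue_fraction)
        if key not in self._eligible:
            self._eligible[key] = eligible_positions(
                self.tissue_mask, patch_px, min_tissue_fraction)
        return self._eligible[key]

    def patch(self, x: int, y: int, patch_px: int) -> np.ndarray:
        return self.image[y:y + patch_px, x:x + patch_px]


@dataclass
class Case:
    record: SurvivalRecord
    slides: list[Slide]

    def __post_init__(self):
        if not self.slides:
            raise ValueError(f"case {self.record.case_id} has no slides")

    @property
    def case_id(self) -> str:
        return self.record.case_id


@dataclass
class PatchSet:
    """A sampled bag of fixed-size RGB patches with 0-based top-left coords."""

    patches: np.ndarray                      # (n, patch_px, patch_px, 3) uint8
    coords: list[tuple[str, int, int]]       # (slide_id, x, y)

    def __len__(self) -> int:
        return len(self.patches)


def detect_tissue(image: np.ndarray, threshold: float = DEFAULT_TISSUE_THRESHOLD) -> np.ndarray:
    """Pixel-intensity tissue mask: grayscale (channel mean) below threshold.

    An all-background image yields an empty mask; that is not an error here —
    sampling from such a slide is.
    """
    gray = image.astype(np.float64).mean(axis=2)
    return gray < threshold


def eligible_positions(mask: np.ndarray, patch_px: int,
                       min_tissue_fraction: float = DEFAULT_MIN_TISSUE_FRACTION) -> np.ndarray:
    """Per-position eligibility via an integral image over the tissue mask.

    Returns a boolean array of shape ``(H - patch_px + 1, W - patch_px + 1)``
    (empty if the patch does not fit).
    """
    H, W = mask.shape
    if H < patch_px or W < patch_px:
        return np.zeros((0, 0), dtype=bool)
    ii = np.zeros((H + 1, W + 1), dtype=np.int64)
    np.cumsum(np.cumsum(mask, axis=0), axis=1, out=ii[1:, 1:])
    P = patch_px
    counts = (ii[P:, P:] - ii[:-P, P:] - ii[P:, :-P] + ii[:-P, :-P])
    return counts >= min_tissue_fraction * P * P


def informative_sampling_probability(p: float, n: int) -> float:
    """Probability that none of ``n`` i.i.d. uniformly sampled patches is
    informative when a fraction ``p`` of patch positions are: ``(1 - p)**n``.

    This decays exponentially in ``n``, which is the argument for why a small
    bag of randomly sampled patches suffices under weak (case-level) labels.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0, 1], got {p}")
    if n < 0:
        raise ValueError(f"n must be >= 0, got {n}")
    return float((1.0 - p) ** n)


def sample_patches(case: Case, n: int, rng: np.random.Generator,
                   patch_px: int = 256,
                   min_tissue_fraction: float = DEFAULT_MIN_TISSUE_FRACTION) -> PatchSet:
    """Sample ``n`` patches i.i.d. uniform (with replacement) over the union
    of tissue-eligible positions of all slides in the case."""
    grids = [s.eligible_mask(patch_px, min_tissue_fraction) for s in case.slides]
    counts = np.array([int(g.sum()) for g in grids], dtype=np.int64)
    total = int(counts.sum())
    if total == 0:
        raise NoTissueError(
            f"case {case.record.case_id}: no tissue-eligible {patch_px}px "
            f"patch position on any of its {len(case.slides)} slide(s)")
    flat = [np.flatnonzero(g.ravel()) for g in grids]
    slide_idx = rng.choice(len(case.slides), size=n, p=counts / total)
    patches = np.empty((n, patch_px, patch_px, 3), dtype=case.slides[0].image.dtype)
    coords: list[tuple[str, int, int]] = []
    for k, si in enumerate(slide_idx):
        pos = int(flat[si][rng.integers(counts[si])])
        w = grids[si].shape[1]
        y, x = divmod(pos, w)
        patches[k] = case.slides[si].patch(x, y, patch_px)
        coords.append((case.slides[si].slide_id, x, y))
    return PatchSet(patches=patches, coords=coords)


# ---------------------------------------------------------------------------
# Augmentation

_IDENTITY_ORIENTATION = 0


def dihedral(patch: np.ndarray, k: int) -> np.ndarray:
    """Apply one of the 8 dihedral orientations (k in 0..7): k % 4 quarter
    rotations, then a horizontal flip if k >= 4.  k = 0 is the identity."""
    out = np.rot90(patch, k % 4)
    if k >= 4:
        out = np.fliplr(out)
    return np.ascontiguousarray(out)


def augment(patch: np.ndarray, rng: np.random.Generator,
            brightness: float = 0.15, contrast: float = 0.15,
            saturation: float = 0.15, hue: float = 0.02,
            orientation: bool = True) -> np.ndarray:
    """Random dihedral orientation followed by colour jitter.

    Stands in for stain-normalisation-based augmentation: orientation plus
    bounded brightness/contrast/saturation/hue perturbation.  With all jitter
    bounds at zero the output is a pure dihedral transform (bitwise identical
    to the input for the identity orientation).
    """
    k = int(rng.integers(8)) if orientation else _IDENTITY_ORIENTATION
    out = dihedral(patch, k)
    if not (brightness or contrast or saturation or hue):
        return out
    x = out.astype(np.float64) / 255.0
    if brightness:
        x = x + rng.uniform(-brightness, brightness)
    if contrast:
        m = x.mean()
        x = m + (x - m) * (1.0 + rng.uniform(-contrast, contrast))
    if saturation:
        gray = x.mean(axis=2, keepdims=True)
        x = gray + (x - gray) * (1.0 + rng.uniform(-saturation, saturation))
    if hue:
        from skimage.color import hsv2rgb, rgb2hsv
        hsv = rgb2hsv(np.clip(x, 0.0, 1.0))
        hsv[..., 0] = (hsv[..., 0] + rng.uniform(-hue, hue)) % 1.0
        x = hsv2rgb(hsv)
    return (np.clip(x, 0.0, 1.0) * 255.0).round().astype(patch.dtype)


# ---------------------------------------------------------------------------
# Stratified split

@dataclass(frozen=True)
class SplitAssignment:
    """Mapping case_id -> {'train', 'tune', 'test'}; a pure function of the
    case-id set (with its records) and the seed."""

    mapping: dict[str, str]
    seed: int

    def cases(self, split: str) -> list[str]:
        return sorted(cid for cid, s in self.mapping.items() if s == split)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"case_id": sorted(self.mapping), "split": [self.mapping[c] for c in sorted(self.mapping)]})

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path, seed: int = -1) -> "SplitAssignment":
        df = pd.read_csv(path)
        return cls(mapping=dict(zip(df["case_id"].astype(str), df["split"])), seed=seed)


SPLIT_NAMES = ("train", "tune", "test")


def _largest_remainder(n: int, weights: tuple[int, ...]) -> list[int]:
    total = sum(weights)
    exact = [n * w / total for w in weights]
    base = [int(math.floor(e)) for e in exact]
    rem = n - sum(base)
    order = sorted(range(len(weights)), key=lambda i: (-(exact[i] - base[i]), i))
    for i in order[:rem]:
        base[i] += 1
    return base


def stratified_split(records: list[SurvivalRecord], seed: int,
                     ratio: tuple[int, int, int] = (2, 1, 1)) -> SplitAssignment:
    """Assign cases to train/tune/test (default 2:1:1), stratified within each
    study on the event indicator crossed with time terciles cut at the study's
    25th and 75th time percentiles (linear-interpolation percentiles over all
    the study's cases).  Each stratum is allocated by largest-remainder
    rounding after a seeded shuffle."""
    if not records:
        raise ValueError("no records to split")
    rng = np.random.default_rng(seed)
    mapping: dict[str, str] = {}
    for study in sorted({r.study for r in records}):
        recs = sorted((r for r in records if r.study == study), key=lambda r: r.case_id)
        if len(recs) < 8:
            warnings.warn(f"study {study} has only {len(recs)} cases; "
                          "stratified 2:1:1 split may be unbalanced")
        times = np.array([r.time_days for r in recs], dtype=np.float64)
        p25, p75 = np.percentile(times, [25, 75])
        strata: dict[tuple[int, int], list[str]] = {}
        for r in recs:
            t = r.time_days
            tercile = 0 if t <= p25 else (1 if t <= p75 else 2)
            strata.setdefault((r.event, tercile), []).append(r.case_id)
        for key in sorted(strata):
            ids = strata[key]
            perm = rng.permutation(len(ids))
            counts = _largest_remainder(len(ids), ratio)
            start = 0
            for split_name, c in zip(SPLIT_NAMES, counts):
                for j in perm[start:start + c]:
                    mapping[ids[j]] = split_name
                start += c
    return SplitAssignment(mapping=mapping, seed=seed)


# ---------------------------------------------------------------------------
# Clinical table I/O

CLINICAL_COLUMNS = ["case_id", "study", "time_days", "event", "stage", "age", "sex"]


def records_to_frame(records: list[SurvivalRecord]) -> pd.DataFrame:
    return pd.DataFrame([{
        "case_id": r.case_id, "study": r.study, "time_days": r.time_days,
        "event": r.event, "stage": r.stage, "age": r.age, "sex": r.sex,
    } for r in records], columns=CLINICAL_COLUMNS)


def frame_to_records(df: pd.DataFrame) -> list[SurvivalRecord]:
    out = []
    for row in df.itertuples(index=False):
        stage = None if pd.isna(row.stage) else int(row.stage)
        age = None if pd.isna(row.age) else float(row.age)
        sex = None if (isinstance(row.sex, float) and pd.isna(row.sex)) else row.sex
        out.append(SurvivalRecord(case_id=str(row.case_id), study=str(row.study),
                                  time_days=float(row.time_days), event=int(row.event),
                                  stage=stage, age=age, sex=sex))
    return out


def read_clinical_csv(path: str | Path) -> list[SurvivalRecord]:
    return frame_to_records(pd.read_csv(path))


def write_clinical_csv(records: list[SurvivalRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, index=False)
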