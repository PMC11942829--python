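"""Dose-reduction simulation by frame summation, and dataset assembly.

In clinical practice all acquired frames are summed into the final static
image; summing only a fraction of them simulates a proportionally lower
administered activity.  The default ``alternating`` scheme takes every
other frame so the summed subset still spans the full 20-minute renogram
(a first-half block would over-weight uptake relative to washout).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Literal, Optional, Sequence, Tuple

import numpy as np

from .phantom import DynamicStudy, ROISet
from .study_io import StudyRecord

__all__ = [
    "SummedImage", "PairedSample",
    "select_frame_indices", "sum_frames", "preprocess",
    "build_dataset", "split_dataset",
]

Scheme = Literal["alternating", "first_block", "random"]


@dataclass(frozen=True)
class SummedImage:
    """A static image formed by summing a subset of a study's frames."""
    pixels: np.ndarray
    count_fraction: float
    study_id: str
    patient_age_years: float
    frame_indices: Tuple[int, ...] = ()

    def __post_init__(self):
        pixels = np.asarray(self.pixels, dtype=np.float64)
        if pixels.min() < 0:
            raise ValueError("summed image must be non-negative")
        object.__setattr__(self, "pixels", pixels)


@dataclass
class PairedSample:
    """A (reduced-count input, full-count reference) training pair."""
    input_image: SummedImage        # count_fraction 0.5 by default
    reference_image: SummedImage    # count_fraction 1.0
    rois: Optional[ROISet]
    split: str = ""

    def __post_init__(self):
        if self.input_image.study_id != self.reference_image.study_id:
            raise ValueError("paired images must come from the same study")
        if self.input_image.pixels.shape != self.reference_image.pixels.shape:
            raise ValueError("paired images must share spatial shape")

    @property
    def study_id(self) -> str:
        return self.input_image.study_id


def select_frame_indices(n_frames: int, fraction: float,
                         scheme: Scheme = "alternating",
                         seed: int = 0) -> np.ndarray:
    """Indices of the frames whose counts enter the reduced-dose sum."""
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must lie in (0, 1]")
    k = int(round(fraction * n_frames))
    if k < 1:
        raise ValueError("fraction selects no frames")
    if k >= n_frames:
        return np.arange(n_frames)
    if scheme == "alternating":
        step = n_frames / k
        idx = np.unique((np.arange(k) * step).astype(int))
        # rounding collisions can only shrink the set; pad from unused frames
        if idx.size < k:
            unused = np.setdiff1d(np.arange(n_frames), idx)
            idx = np.sort(np.concatenate([idx, unused[: k - idx.size]]))
        return idx
    if scheme == "first_block":
        return np.arange(k)
    if scheme == "random":
        rng = np.random.default_rng(seed)
        return np.sort(rng.choice(n_frames, size=k, replace=False))
    raise ValueError(f"unknown scheme '{scheme}'")


def sum_frames(study: DynamicStudy, fraction: float = 1.0,
               scheme: Scheme = "alternating", seed: int = 0) -> SummedImage:
    """Pixel-wise sum of ``round(fraction * n_frames)`` selected frames."""
    idx = select_frame_indices(study.n_frames, fraction, scheme, seed)
    pixels = study.frames[idx].sum(axis=0).astype(np.float64)
    return SummedImage(pixels=pixels, count_fraction=fraction,
                       study_id=study.study_id,
                       patient_age_years=study.patient_age_years,
                       frame_indices=tuple(int(i) for i in idx))


def preprocess(image: SummedImage | np.ndarray, target_size: int = 128) -> np.ndarray:
    """Resize to ``target_size`` squared and max-normalize into [0, 1].

    An all-zero image is returned as all zeros (no division is attempted).
    """
    pixels = image.pixels if isinstance(image, SummedImage) else np.asarray(image)
    pixels = pixels.astype(np.float64)
    if pixels.size == 0:
        raise ValueError("empty image")
    if pixels.shape != (target_size, target_size):
        from skimage.transform import resize
        pixels = resize(pixels, (target_size, target_size),
                        preserve_range=True, anti_aliasing=True)
        pixels = np.clip(pixels, 0.0, None)
    peak = pixels.max()
    if peak > 0:
        pixels = pixels / peak
    return pixels.astype(np.float32)


def build_dataset(studies: Sequence[StudyRecord],
                  scheme: Scheme = "alternating",
                  fractions: Tuple[float, float] = (1.0, 0.5),
                  ) -> Tuple[List[PairedSample], int]:
    """One (reduced, full) pair per study; returns pairs and the image count.

    The image inventory counts both members of every pair, matching the
    accounting of a paired 100%/50% dataset (n studies -> 2n images).
    """
    if not studies:
        raise ValueError("need at least one study")
    full_fraction, reduced_fraction = fractions
    pairs: List[PairedSample] = []
    for record in studies:
        if record.rois is None:
            raise ValueError(
                f"study {record.study.study_id} has no ROIs; cannot build pairs")
        reference = sum_frames(record.study, full_fraction, scheme)
        reduced = sum_frames(record.study, reduced_fraction, scheme)
        pairs.append(PairedSample(input_image=reduced, reference_image=reference,
                                  rois=record.rois))
    return pairs, 2 * len(pairs)


def split_dataset(items: Sequence, fractions: Tuple[float, float, float] = (0.67, 0.16, 0.17),
                  seed: int = 0, group_ids: Optional[Sequence[str]] = None,
                  ) -> List[str]:
    """Assign each item to train/val/test.

    Counts follow floor(n * fraction) for train and val with the remainder
    going to test (200 items -> 134/32/34 at 67/16/17%).  When ``group_ids``
    is given, items sharing an id always land in the same split so no study
    straddles the train/test boundary.
    """
    n = len(items)
    if n < 3:
        raise ValueError("need at least one item per split")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    n_train = int(np.floor(n * fractions[0]))
    n_val = int(np.floor(n * fractions[1]))
    targets = {"train": n_train, "val": n_val, "test": n - n_train - n_val}

    rng = np.random.default_rng(seed)
    if group_ids is None:
        group_ids = [str(i) for i in range(n)]
    if len(group_ids) != n:
        raise ValueError("group_ids must align with items")
    groups: Dict[str, List[int]] = {}
    for i, gid in enumerate(group_ids):
        groups.setdefault(str(gid), []).append(i)
    order = list(groups)
    rng.shuffle(order)

    assignment = [""] * n
    remaining = dict(targets)
    for gid in order:
        members = groups[gid]
        # fill train, then val, then test; oversized groups spill forward
        for split in ("train", "val", "test"):
            if remaining[split] >= len(members):
                choice = split
                break
        else:
            choice = max(remaining, key=remaining.get)
        remaining[choice] -= len(members)
        for i in members:
            assignment[i] = choice
    return assignment
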