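"""Duplication scanning from per-position read depth.

The scan smooths a depth track with a centred rolling median (window 999 by
default) to remove outliers, subsamples every 1000th position, and calls
maximal runs of sampled points whose ratio to the chromosome-wide background
median is approximately 2, reflecting likely tandem duplications.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "DepthTrack",
    "SampledProfile",
    "DuplicationSegment",
    "rolling_median",
    "subsample",
    "detect_duplications",
    "scan_track",
]


@dataclass(frozen=True)
class DepthTrack:
    """Per-position coverage for one chromosome; depths[i] is position i+1."""

    chrom: str
    depths: np.ndarray

    def __post_init__(self):
        d = np.asarray(self.depths)
        if d.ndim != 1:
            raise ValueError("depth track must be one-dimensional")
        if len(d) and d.min() < 0:
            raise ValueError("depths must be non-negative")
        object.__setattr__(self, "depths", d)

    def __len__(self) -> int:
        return len(self.depths)


@dataclass(frozen=True)
class SampledProfile:
    chrom: str
    sample_positions: np.ndarray  # 1-based, exact multiples of step
    values: np.ndarray
    window: int
    step: int

    def __post_init__(self):
        p = np.asarray(self.sample_positions)
        v = np.asarray(self.values, dtype=float)
        if len(p) != len(v):
            raise ValueError("positions and values differ in length")
        if len(v) and v.min() < 0:
            raise ValueError("profile values must be non-negative")
        if len(p) > 1 and not np.all(np.diff(p) == self.step):
            raise ValueError("sample positions must increase by exactly step")
        object.__setattr__(self, "sample_positions", p)
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class DuplicationSegment:
    chrom: str
    start_pos: int
    end_pos: int
    copy_ratio: float
    n_points: int

    def __post_init__(self):
        if self.copy_ratio <= 0:
            raise ValueError("copy ratio must be positive")
        if self.n_points < 1:
            raise ValueError("segment must contain at least one point")


def rolling_median(
    track: DepthTrack,
    window: int = 999,
    edges: Literal["truncate", "drop"] = "truncate",
) -> DepthTrack:
    """Centred rolling median, length-preserving.

    ``edges='truncate'`` (default) takes the median of however much of the
    window fits at chromosome ends; ``edges='drop'`` leaves raw values within
    half a window of either end untouched by marking them with the plain
    input (no median defined there).
    """
    if window % 2 == 0:
        raise ValueError(f"window must be odd, got {window}")
    if window < 1 or window > len(track):
        raise ValueError(f"window {window} out of range for track length {len(track)}")
    s = pd.Series(track.depths)
    med = s.rolling(window, center=True, min_periods=1).median().to_numpy()
    if edges == "drop":
        half = window // 2
        out = track.depths.astype(float).copy()
        if half:
            out[half:-half] = med[half:-half]
        else:
            out = med
        med = out
    elif edges != "truncate":
        raise ValueError(f"unknown edge mode {edges!r}")
    return DepthTrack(track.chrom, med)


def subsample(track: DepthTrack, step: int = 1000, window: int = 999) -> SampledProfile:
    """Take values at positions step, 2*step, ... <= track length.

    ``window`` is carried along as metadata describing the smoothing already
    applied to ``track``.
    """
    if step < 1:
        raise ValueError(f"step must be >= 1, got {step}")
    positions = np.arange(step, len(track) + 1, step)
    values = track.depths[positions - 1] if len(positions) else np.array([])
    return SampledProfile(track.chrom, positions, values, window=window, step=step)


def detect_duplications(
    profile: SampledProfile,
    ratio_lo: float = 1.75,
    ratio_hi: float = 2.25,
    min_run: int = 50,
) -> list[DuplicationSegment]:
    """Call maximal runs of >= min_run consecutive sampled points whose
    value / background-median ratio lies in [ratio_lo, ratio_hi].

    The background is the median over the whole profile, robust as long as
    duplications cover less than half the chromosome.  Output is invariant
    under uniform scaling of all depths.
    """
    if len(profile) == 0:
        raise ValueError("cannot scan an empty profile")
    background = float(np.median(profile.values))
    if background == 0:
        raise ValueError("background median depth is zero — no usable coverage")

    ratio = profile.values / background
    mask = (ratio >= ratio_lo) & (ratio <= ratio_hi)

    segments: list[DuplicationSegment] = []
    boundaries = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    for i0, i1 in zip(boundaries[::2], boundaries[1::2]):  # [i0, i1) is a run
        n = i1 - i0
        if n < min_run:
            continue
        seg_values = profile.values[i0:i1]
        segments.append(
            DuplicationSegment(
                chrom=profile.chrom,
                start_pos=int(profile.sample_positions[i0]),
                end_pos=int(profile.sample_positions[i1 - 1]),
                copy_ratio=float(np.median(seg_values) / background),
                n_points=n,
            )
        )
    return segments


def sampled_median_profile(
    track: DepthTrack, window: int = 999, step: int = 1000
) -> SampledProfile:
    """Rolling median evaluated only at the sampled positions.

    Identical to ``subsample(rolling_median(track, window), step)`` with
    truncate edge handling, but skips the medians nobody looks at."""
    if window % 2 == 0:
        raise ValueError(f"window must be odd, got {window}")
    if step < 1:
        raise ValueError(f"step must be >= 1, got {step}")
    half = window // 2
    n = len(track)
    positions = np.arange(step, n + 1, step)
    values = np.empty(len(positions))
    for k, pos in enumerate(positions):
        i = pos - 1
        values[k] = np.median(track.depths[max(0, i - half) : min(n, i + half + 1)])
    return SampledProfile(track.chrom, positions, values, window=window, step=step)


def scan_track(
    track: DepthTrack,
    window: int = 999,
    step: int = 1000,
    ratio_lo: float = 1.75,
    ratio_hi: float = 2.25,
    min_run: int = 50,
    edges: Literal["truncate", "drop"] = "truncate",
) -> tuple[SampledProfile, list[DuplicationSegment]]:
    """Full scan: rolling median -> subsample -> segment calling.

    With the default truncate edge handling the sampled medians are computed
    directly (fast path); 'drop' edges go through the full-length smoother.
    """
    if edges == "truncate":
        profile = sampled_median_profile(track, window=window, step=step)
    else:
        smoothed = rolling_median(track, window=window, edges=edges)
        profile = subsample(smoothed, step=step, window=window)
    return profile, detect_duplications(profile, ratio_lo, ratio_hi, min_run)
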