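"""Column-sum wavelet profile (SCWS), above-mean segmentation (SCWSS) and the
seven wavelet features.

The scalogram is collapsed by summing coefficient magnitudes column-wise over
the first ``n_layers_sum`` layers (default 20), one power value per base.
Maximal runs of positions strictly above the profile mean form the segment
set; each segment carries its length, mean power, and the corrected midpoint
statistic

    FMid = 0.5 * (P_end - P_start) / P_end

which is bounded by 0.5 and needs no dataset-level standardization, so it is
well-defined for a single transcript. Seven summary features are then taken:
segment count, length mean/variance, FMid mean, and three statistics gated by
a 30-base length floor (about the shortest known protein) and a top-third
length rank, which together decouple the features from raw transcript length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .signal_transform import Scalogram

WAVELET_FEATURE_NAMES = (
    "Count", "LenMean", "LenVar", "MidMean", "30Count", "30PwMean", "30LenCount",
)

#: Shortest-known-protein floor, in bases; segments must be strictly longer.
LENGTH_FLOOR = 30


@dataclass
class ScwsProfile:
    power: np.ndarray
    n_layers_sum: int

    @property
    def mean_power(self) -> float:
        return float(self.power.mean())


@dataclass
class Segment:
    """A maximal above-mean run; positions are 0-based, end exclusive."""

    p_start: int
    p_end: int
    mean_power: float

    @property
    def length(self) -> int:
        return self.p_end - self.p_start

    @property
    def fmid(self) -> float:
        return fmid(self.p_start, self.p_end)


@dataclass
class WaveletFeatures:
    count: int
    len_mean: float
    len_var: float
    mid_mean: float
    count30: int
    pw_mean30: float
    len_count30: float

    def as_dict(self) -> dict[str, float]:
        return dict(zip(WAVELET_FEATURE_NAMES, (
            float(self.count), self.len_mean, self.len_var, self.mid_mean,
            float(self.count30), self.pw_mean30, self.len_count30,
        )))


def scws(scalogram: Scalogram, n_layers_sum: int | None = None) -> ScwsProfile:
    """Column sum of |coefficients| over layers 1..n_layers_sum."""
    if n_layers_sum is None:
        n_layers_sum = scalogram.params.n_layers_sum
    if not 1 <= n_layers_sum <= scalogram.coeffs.shape[0]:
        raise ValueError(
            f"n_layers_sum={n_layers_sum} outside 1..{scalogram.coeffs.shape[0]}"
        )
    power = np.abs(scalogram.coeffs[:n_layers_sum]).sum(axis=0)
    return ScwsProfile(power, n_layers_sum)


def fmid(p_start: int, p_end: int) -> float:
    """Corrected midpoint statistic 0.5*(p_end - p_start)/p_end, in (0, 0.5]."""
    if p_end <= 0 or p_start < 0 or p_end <= p_start:
        raise ValueError(f"need 0 <= p_start < p_end, got ({p_start}, {p_end})")
    return 0.5 * (p_end - p_start) / p_end


def segments_above_mean(profile: ScwsProfile) -> list[Segment]:
    """Maximal runs of positions with power strictly above the profile mean."""
    power = np.asarray(profile.power, dtype=float)
    if power.size == 0:
        raise ValueError("profile is empty")
    above = power > power.mean()
    # run boundaries via sign changes of the padded mask
    mask = np.concatenate(([False], above, [False])).astype(np.int8)
    edges = np.flatnonzero(np.diff(mask))
    segs = []
    for start, end in zip(edges[::2], edges[1::2]):
        segs.append(Segment(int(start), int(end), float(power[start:end].mean())))
    return segs


def wavelet_features(
    segments: list[Segment],
    third_rule: str = "top_rank",
    variance_mode: str = "population",
) -> WaveletFeatures:
    """The seven segment-set summaries; every mean over an empty set is 0.

    ``third_rule`` picks how "greater than 1/3 of the total number of sorted
    fragments" is read: ``top_rank`` keeps the top ceil(count/3) segments by
    length (descending, ties broken by earlier start); ``length_vs_count``
    keeps segments whose length exceeds count/3.
    """
    if third_rule not in ("top_rank", "length_vs_count"):
        raise ValueError(f"unknown third_rule {third_rule!r}")
    if variance_mode not in ("population", "sample"):
        raise ValueError(f"unknown variance_mode {variance_mode!r}")

    n = len(segments)
    if n == 0:
        return WaveletFeatures(0, 0.0, 0.0, 0.0, 0, 0.0, 0.0)

    lengths = np.array([s.length for s in segments], dtype=float)
    len_mean = float(lengths.mean())
    ddof = 0 if variance_mode == "population" else 1
    len_var = float(lengths.var(ddof=ddof)) if n > ddof else 0.0
    mid_mean = float(np.mean([s.fmid for s in segments]))

    if third_rule == "top_rank":
        ranked = sorted(segments, key=lambda s: (-s.length, s.p_start))
        subset = ranked[: math.ceil(n / 3)]
    else:
        subset = [s for s in segments if s.length > n / 3]
    long_subset = [s for s in subset if s.length > LENGTH_FLOOR]
    count30 = len(long_subset)
    pw_mean30 = float(np.mean([s.mean_power for s in long_subset])) if long_subset else 0.0

    long_all = [s for s in segments if s.length > LENGTH_FLOOR]
    len_count30 = float(np.mean([s.length for s in long_all])) if long_all else 0.0

    return WaveletFeatures(n, len_mean, len_var, mid_mean,
                           count30, pw_mean30, len_count30)
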