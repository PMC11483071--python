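"""Marker-positive cell counting in z-sampled confocal stacks.

The estimator: segment nuclei on 2D slices sampled every ``interval_um``
micrometres, call a nucleus marker-positive when its **median** marker-channel
intensity strictly exceeds a global Otsu-derived threshold, and sum the
per-slice positive counts across the stack.  The per-slice sum is an
abundance index, not a deduplicated 3D cell count: a nucleus can intersect
zero or several sampled planes depending on its size relative to the
interval.  Group comparisons therefore use between-group differences of the
index, with a robustness sweep over threshold multipliers and slice widths.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from skimage.filters import gaussian

from ._otsu import otsu_threshold
from .io_formats import CountingSettings, ImageStack, SweepSettings
from .segmentation import NucleusROI, SegParams, run_backend

__all__ = [
    "PositiveCallSet",
    "CountEstimate",
    "RobustnessTable",
    "GroupComparison",
    "otsu_threshold",
    "select_threshold_slices",
    "median_intensity",
    "call_positive",
    "sample_slices",
    "marker_threshold",
    "estimate_counts",
    "combine_sides",
    "robustness_sweep",
    "compare_groups",
]


@dataclass
class PositiveCallSet:
    slice_index: int
    medians: np.ndarray  # per-ROI median marker intensity
    calls: np.ndarray  # per-ROI boolean, True iff median > threshold
    threshold: float

    @property
    def n_positive(self) -> int:
        return int(self.calls.sum())


@dataclass
class CountEstimate:
    sample_id: str
    side: str
    slice_indices: list[int]
    per_slice_counts: list[int]
    params: dict

    def __post_init__(self) -> None:
        if list(self.slice_indices) != sorted(set(self.slice_indices)):
            raise ValueError("slice indices must be strictly increasing")
        if len(self.slice_indices) != len(self.per_slice_counts):
            raise ValueError("one count per sampled slice required")

    @property
    def total(self) -> int:
        return int(sum(self.per_slice_counts))


@dataclass
class RobustnessTable:
    """Grid of (threshold multiplier, interval) -> per-sample totals and the
    per-group mean difference and its sign."""

    rows: list[dict] = field(default_factory=list)

    def signs(self) -> set[int]:
        return {row["sign"] for row in self.rows}

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.rows)


@dataclass
class GroupComparison:
    mean_a: float
    mean_b: float
    t: float
    df: float
    p: float

    def __post_init__(self) -> None:
        if not 0 <= self.p <= 1:
            raise ValueError("p must lie in [0, 1]")
        if self.t * (self.mean_a - self.mean_b) < 0:
            raise ValueError("t sign must match the mean-difference sign")


# ---------------------------------------------------------------------------
# thresholding
# ---------------------------------------------------------------------------

def select_threshold_slices(stack: ImageStack, settings: CountingSettings | None = None,
                            rule: str | None = None) -> list[int]:
    """Indices of slices that contain target-cell signal; their pooled marker
    pixels feed :func:`otsu_threshold`.

    Default rule ("signal"): keep slices whose smoothed marker-channel
    maximum exceeds the stack-wide background quantile of smoothed marker
    intensities.  ``rule="all"`` keeps every slice.
    """
    settings = settings or CountingSettings()
    rule = rule or settings.slice_rule
    if rule == "all":
        return list(range(stack.n_slices))
    if rule != "signal":
        raise ValueError(f"unknown slice rule {rule!r}")
    sigma = settings.slice_smoothing_sigma_px
    smoothed = np.stack([
        gaussian(s, sigma=sigma, preserve_range=True) if sigma > 0 else np.asarray(s, float)
        for s in stack.marker
    ])
    if np.ptp(smoothed) == 0:
        raise ValueError(
            "no marker signal in any slice; supply a manual threshold"
        )
    cutoff = np.quantile(smoothed, settings.background_quantile)
    indices = [i for i in range(stack.n_slices) if smoothed[i].max() > cutoff]
    if not indices:
        raise ValueError(
            "no slice passes the signal rule; supply a manual threshold"
        )
    return indices


def marker_threshold(stacks: Sequence[ImageStack],
                     settings: CountingSettings | None = None) -> float:
    """Otsu threshold from the pooled signal-slice marker pixels of one or
    more stacks (pool both sides of an animal for a per-animal threshold)."""
    settings = settings or CountingSettings()
    if settings.fixed_marker_threshold is not None:
        return float(settings.fixed_marker_threshold)
    pooled = []
    for stack in stacks:
        for i in select_threshold_slices(stack, settings):
            pooled.append(np.asarray(stack.marker[i], dtype=float).ravel())
    return otsu_threshold(np.concatenate(pooled))


# ---------------------------------------------------------------------------
# per-ROI calls
# ---------------------------------------------------------------------------

def median_intensity(roi: NucleusROI, marker_slice: np.ndarray) -> float:
    """Median marker intensity over the ROI's pixel set (even cardinality:
    mean of the two central values)."""
    marker_slice = np.asarray(marker_slice)
    if len(roi.pixels) == 0:
        raise ValueError("empty pixel set")
    rows, cols = roi.pixels[:, 0], roi.pixels[:, 1]
    if rows.max() >= marker_slice.shape[0] or cols.max() >= marker_slice.shape[1]:
        raise ValueError("ROI pixels outside slice bounds")
    return float(np.median(marker_slice[rows, cols]))


def call_positive(rois: Sequence[NucleusROI], marker_slice: np.ndarray,
                  threshold: float, slice_index: int = 0) -> PositiveCallSet:
    """Strict call: positive iff the median *exceeds* the threshold."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    medians = np.array([median_intensity(r, marker_slice) for r in rois])
    return PositiveCallSet(
        slice_index=slice_index,
        medians=medians,
        calls=medians > threshold,
        threshold=float(threshold),
    )


def sample_slices(n_slices: int, z_spacing_um: float, interval_um: float) -> list[int]:
    """Slice indices at a fixed physical interval: ``round(k*interval/spacing)``
    for k = 0, 1, ... while < n_slices; round-half-to-even; duplicates
    collapsed."""
    if interval_um < z_spacing_um:
        raise ValueError("sampling interval must be >= z spacing")
    step = interval_um / z_spacing_um
    indices: list[int] = []
    k = 0
    while True:
        idx = round(k * step)  # Python round = round-half-to-even
        if idx >= n_slices:
            break
        if not indices or idx != indices[-1]:
            indices.append(idx)
        k += 1
    return indices


# ---------------------------------------------------------------------------
# the estimator
# ---------------------------------------------------------------------------

def estimate_counts(
    stack: ImageStack,
    *,
    seg_params: SegParams | None = None,
    interval_um: float = 5.0,
    threshold: float | None = None,
    counting: CountingSettings | None = None,
    backend: str = "classical",
    _slice_cache: dict | None = None,
) -> CountEstimate:
    """Segment each sampled slice, call marker-positive nuclei, and sum.

    ``threshold`` defaults to the per-stack pooled Otsu threshold; pass a
    per-animal threshold explicitly to share it across sides.
    ``_slice_cache`` (keyed by slice index) lets a sweep reuse segmentations
    across grid cells; it never changes results.
    """
    seg_params = seg_params or SegParams()
    counting = counting or CountingSettings(interval_um=interval_um)
    if threshold is None:
        threshold = marker_threshold([stack], counting)
    indices = sample_slices(stack.n_slices, stack.z_spacing_um, interval_um)
    counts = []
    for i in indices:
        if _slice_cache is not None and i in _slice_cache:
            rois = _slice_cache[i]
        else:
            rois = run_backend(backend, stack.nuclear[i], seg_params)
            if _slice_cache is not None:
                _slice_cache[i] = rois
        calls = call_positive(rois, stack.marker[i], threshold, slice_index=i)
        counts.append(calls.n_positive)
    return CountEstimate(
        sample_id=stack.sample_id,
        side=stack.side,
        slice_indices=indices,
        per_slice_counts=counts,
        params={
            "threshold": float(threshold),
            "interval_um": float(interval_um),
            "backend": backend,
            "seg_params": repr(seg_params),
        },
    )


def combine_sides(left: CountEstimate, right: CountEstimate) -> int:
    """Per-animal total from independently imaged left and right head sides."""
    for est, name in ((left, "left"), (right, "right")):
        if est is None:
            raise ValueError(f"missing {name} side estimate")
    if left.sample_id != right.sample_id:
        raise ValueError(
            f"side estimates from different animals: {left.sample_id!r} vs "
            f"{right.sample_id!r}"
        )
    if left.params != right.params:
        raise ValueError("parameter mismatch between sides")
    return left.total + right.total


def robustness_sweep(
    groups: Mapping[str, Sequence[ImageStack]],
    *,
    seg_params: SegParams | None = None,
    sweep: SweepSettings | None = None,
    counting: CountingSettings | None = None,
    base_thresholds: Mapping[str, float] | None = None,
) -> RobustnessTable:
    """Recompute the count estimate over the full multiplier x interval grid
    for two groups and report the per-cell group mean difference and sign.

    ``groups`` maps exactly two group labels to their stacks (one stack per
    sample).  ``base_thresholds`` maps sample_id to a precomputed base Otsu
    threshold; missing entries are computed per stack.
    """
    if len(groups) != 2:
        raise ValueError("robustness_sweep compares exactly two groups")
    seg_params = seg_params or SegParams()
    sweep = sweep or SweepSettings()
    counting = counting or CountingSettings()
    (label_a, stacks_a), (label_b, stacks_b) = groups.items()

    thresholds: dict[str, float] = dict(base_thresholds or {})
    caches: dict[str, dict] = {}
    for stack in list(stacks_a) + list(stacks_b):
        if stack.sample_id not in thresholds:
            thresholds[stack.sample_id] = marker_threshold([stack], counting)
        caches.setdefault(stack.sample_id, {})

    def totals(stacks, mult, interval):
        return [
            estimate_counts(
                s,
                seg_params=seg_params,
                interval_um=interval,
                threshold=mult * thresholds[s.sample_id],
                counting=counting,
                _slice_cache=caches[s.sample_id],
            ).total
            for s in stacks
        ]

    table = RobustnessTable()
    for mult in sweep.threshold_multipliers:
        for interval in sweep.intervals_um:
            ta = totals(stacks_a, mult, interval)
            tb = totals(stacks_b, mult, interval)
            diff = float(np.mean(ta) - np.mean(tb))
            table.rows.append(
                {
                    "multiplier": mult,
                    "interval_um": interval,
                    f"totals_{label_a}": ta,
                    f"totals_{label_b}": tb,
                    f"mean_{label_a}": float(np.mean(ta)),
                    f"mean_{label_b}": float(np.mean(tb)),
                    "diff": diff,
                    "sign": int(np.sign(diff)),
                }
            )
    return table


# ---------------------------------------------------------------------------
# group comparison
# ---------------------------------------------------------------------------

def compare_groups(totals_a: Sequence[float], totals_b: Sequence[float]) -> GroupComparison:
    """Unpaired two-tailed Student t-test (pooled variance), closed form.

    Zero pooled variance with equal means gives t = 0, p = 1; with unequal
    means it is an error (the statistic is undefined).
    """
    a = np.asarray(totals_a, dtype=float)
    b = np.asarray(totals_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    na, nb = a.size, b.size
    mean_a, mean_b = a.mean(), b.mean()
    df = na + nb - 2
    pooled_var = (((a - mean_a) ** 2).sum() + ((b - mean_b) ** 2).sum()) / df
    if pooled_var == 0:
        if mean_a == mean_b:
            return GroupComparison(mean_a=mean_a, mean_b=mean_b, t=0.0, df=df, p=1.0)
        raise ValueError("zero pooled variance with unequal means: t undefined")
    se = np.sqrt(pooled_var * (1.0 / na + 1.0 / nb))
    t = (mean_a - mean_b) / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return GroupComparison(
        mean_a=float(mean_a), mean_b=float(mean_b), t=float(t), df=float(df),
        p=float(min(p, 1.0)),
    )
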