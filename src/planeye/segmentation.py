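"""Per-slice 2D nucleus segmentation with a pluggable backend contract.

The default ("classical") backend is a watershed pipeline: Gaussian smooth →
optional rolling-ball background subtraction → foreground threshold →
Euclidean distance transform → peak seeds → watershed split → area/border
filter.  Any registered backend must return :class:`NucleusROI` objects
satisfying the same invariants (disjoint pixel sets, unique labels, area =
pixel count); an adapter to a trained deep-learning segmenter can be
registered through the same contract.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.filters import gaussian
from skimage.measure import regionprops
from skimage.restoration import rolling_ball
from skimage.segmentation import watershed

from .io_formats import SegmentationSettings
from ._otsu import otsu_threshold

__all__ = [
    "SegParams",
    "NucleusROI",
    "segment_slice",
    "filter_rois",
    "run_backend",
    "register_backend",
    "registered_backends",
    "audit_rois",
]

# SegParams is the settings dataclass housed in io_formats (single home for
# config schemas); re-exported here under the segmentation-facing name.
SegParams = SegmentationSettings


@dataclass
class NucleusROI:
    """One segmented 2D nucleus on one slice."""

    slice_index: int
    label: int
    pixels: np.ndarray  # (n, 2) array of (row, col) indices
    centroid: tuple[float, float]  # (x, y) in pixels
    bbox: tuple[int, int, int, int]  # (min_row, min_col, max_row, max_col)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=int)
        if self.pixels.ndim != 2 or self.pixels.shape[1] != 2:
            raise ValueError("pixels must be an (n, 2) array of (row, col)")
        if len(self.pixels) == 0:
            raise ValueError("ROI must contain at least one pixel")

    @property
    def area(self) -> int:
        return len(self.pixels)

    def touches_border(self, shape: tuple[int, int]) -> bool:
        r, c = self.pixels[:, 0], self.pixels[:, 1]
        return bool(
            (r.min() == 0) or (c.min() == 0)
            or (r.max() == shape[0] - 1) or (c.max() == shape[1] - 1)
        )


def _label_image_to_rois(labels: np.ndarray, slice_index: int) -> list[NucleusROI]:
    rois = []
    for prop in regionprops(labels):
        rr, cc = np.nonzero(labels == prop.label)
        cy, cx = prop.centroid  # regionprops returns (row, col)
        rois.append(
            NucleusROI(
                slice_index=slice_index,
                label=int(prop.label),
                pixels=np.column_stack([rr, cc]),
                centroid=(float(cx), float(cy)),
                bbox=tuple(int(v) for v in prop.bbox),
            )
        )
    return rois


def segment_slice(
    image: np.ndarray,
    params: SegParams | None = None,
    *,
    slice_index: int = 0,
) -> list[NucleusROI]:
    """Segment nuclei in a single 2D slice of the nuclear channel.

    Deterministic for fixed input and parameters: watershed seeds are
    labelled in (row, col) order.  An all-zero or constant image yields an
    empty list, not an error.
    """
    params = params or SegParams()
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("segment_slice expects a 2D image")
    if np.any(image < 0):
        raise ValueError("image intensities must be non-negative")
    if image.size == 0 or np.ptp(image) == 0:
        return []

    work = image
    if params.smoothing_sigma_px > 0:
        work = gaussian(work, sigma=params.smoothing_sigma_px, preserve_range=True)
    if params.background_radius_px > 0:
        background = rolling_ball(work, radius=params.background_radius_px)
        work = work - background
        work = np.clip(work, 0, None)
    if np.ptp(work) == 0:
        return []

    if params.threshold_mode == "fixed":
        if params.fixed_threshold is None:
            raise ValueError("threshold_mode='fixed' requires fixed_threshold")
        thresh = params.fixed_threshold
    else:
        thresh = otsu_threshold(work.ravel())
    mask = work > thresh
    if not mask.any():
        return []

    distance = ndimage.distance_transform_edt(mask)
    peaks = peak_local_max(
        distance,
        min_distance=max(1, int(params.min_separation_px)),
        labels=mask,
        exclude_border=False,
    )
    if len(peaks) == 0:
        labels = ndimage.label(mask)[0]
    else:
        # seed labels assigned in (row, col) order for determinism
        order = np.lexsort((peaks[:, 1], peaks[:, 0]))
        peaks = peaks[order]
        markers = np.zeros(mask.shape, dtype=int)
        markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
        labels = watershed(-distance, markers=markers, mask=mask)

    rois = _label_image_to_rois(labels, slice_index)
    return filter_rois(rois, params, image_shape=image.shape)


def filter_rois(
    rois: Sequence[NucleusROI],
    params: SegParams,
    *,
    image_shape: tuple[int, int] | None = None,
) -> list[NucleusROI]:
    """Apply inclusive area bounds and the border policy; order preserved."""
    out = []
    for roi in rois:
        if not params.min_area_px <= roi.area <= params.max_area_px:
            continue
        if (
            params.border_policy == "drop"
            and image_shape is not None
            and roi.touches_border(image_shape)
        ):
            continue
        out.append(roi)
    return out


# ---------------------------------------------------------------------------
# backend registry
# ---------------------------------------------------------------------------

Backend = Callable[[np.ndarray, SegParams], list[NucleusROI]]

_BACKENDS: dict[str, Backend] = {}


def register_backend(name: str, fn: Backend) -> None:
    _BACKENDS[name] = fn


def registered_backends() -> list[str]:
    return sorted(_BACKENDS)


def run_backend(backend_name: str, image: np.ndarray, params: SegParams) -> list[NucleusROI]:
    if backend_name not in _BACKENDS:
        raise ValueError(
            f"unknown segmentation backend {backend_name!r}; "
            f"registered: {registered_backends()}"
        )
    rois = _BACKENDS[backend_name](image, params)
    audit_rois(rois)
    return rois


def audit_rois(rois: Sequence[NucleusROI]) -> None:
    """Check the ROI invariants: unique labels and disjoint pixel sets within
    each slice; area equals pixel-set cardinality (by construction)."""
    by_slice: dict[int, list[NucleusROI]] = {}
    for roi in rois:
        by_slice.setdefault(roi.slice_index, []).append(roi)
    for slice_index, group in by_slice.items():
        labels = [r.label for r in group]
        if len(labels) != len(set(labels)):
            raise AssertionError(f"duplicate labels on slice {slice_index}")
        seen: set[tuple[int, int]] = set()
        for roi in group:
            px = set(map(tuple, roi.pixels))
            if seen & px:
                raise AssertionError(f"overlapping ROIs on slice {slice_index}")
            seen |= px


register_backend("classical", lambda image, params: segment_slice(image, params))


def _try_register_stardist() -> None:
    """Register an adapter to the StarDist 2D segmenter if it is installed.

    Optional: the classical backend is the default and the only one tests
    require.  The published probability/NMS thresholds are taken from
    ``SegParams.stardist_prob_thresh`` / ``stardist_nms_thresh``.
    """
    try:
        from stardist.models import StarDist2D  # type: ignore
    except ImportError:
        return

    def _stardist_backend(image: np.ndarray, params: SegParams) -> list[NucleusROI]:
        from csbdeep.utils import normalize  # type: ignore

        model = StarDist2D.from_pretrained("2D_versatile_fluo")
        labels, _ = model.predict_instances(
            normalize(image),
            prob_thresh=params.stardist_prob_thresh,
            nms_thresh=params.stardist_nms_thresh,
        )
        rois = _label_image_to_rois(labels, 0)
        return filter_rois(rois, params, image_shape=image.shape)

    register_backend("stardist", _stardist_backend)


_try_register_stardist()
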