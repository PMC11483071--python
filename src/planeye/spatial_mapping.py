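"""Bilateral-eye-landmark coordinate normalization.

Planarians lack a fixed size, so positions of ectopic eyes and eye
progenitors are compared across animals in a common frame anchored to the
two original eyes: a similarity transform (translation, rotation, uniform
scale, and a reflection when needed) maps the left eye to (-1, 0) and the
right eye to (1, 0), so one unit equals one-half of the inter-eye distance.
The supplied anterior direction fixes the y-axis: y > 0 is anterior of the
inter-eye axis.  Anterior is always declared per animal, never inferred
from image content (pixel y points down; normalized y points anterior).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import AnimalLandmarks, MappingSettings
from .marker_quant import GroupComparison, compare_groups

__all__ = [
    "RegistrationTransform",
    "NormalizedPointSet",
    "registration_transform",
    "normalize_points",
    "normalize_landmarks",
    "posterior_most_eye",
    "count_anterior",
    "compare_ap_positions",
    "export_distribution",
    "read_distribution",
]


@dataclass
class RegistrationTransform:
    """Similarity map p -> A @ p + t from pixel space to the normalized
    frame; ``flipped`` records whether a y-reflection was composed to put
    the anterior indicator in the +y half-plane."""

    matrix: np.ndarray  # (2, 2)
    translation: np.ndarray  # (2,)
    rotation: float  # radians, rotation of the inter-eye axis onto +x
    scale: float  # 2 / inter-eye distance
    flipped: bool
    animal_id: str = ""

    def apply(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        single = points.ndim == 1
        pts = np.atleast_2d(points)
        out = pts @ self.matrix.T + self.translation
        return out[0] if single else out


@dataclass
class NormalizedPointSet:
    """Points in the (x, y) frame with units of one-half inter-eye distance;
    y > 0 is anterior of the inter-eye axis."""

    animal_id: str
    condition: str
    points: np.ndarray  # (n, 2)
    point_types: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        if not self.point_types:
            self.point_types = ["ectopic_eye"] * len(self.points)
        if len(self.point_types) != len(self.points):
            raise ValueError("one type label per point required")

    def of_type(self, point_type: str) -> np.ndarray:
        mask = [t == point_type for t in self.point_types]
        return self.points[np.asarray(mask, dtype=bool)] if len(self.points) else self.points


def registration_transform(
    landmarks: AnimalLandmarks,
    settings: MappingSettings | None = None,
) -> RegistrationTransform:
    """Transform mapping the animal's eyes exactly to (-1,0) and (1,0).

    Steps: translate the eye midpoint to the origin, rotate the inter-eye
    axis onto the x-axis with the left eye at negative x, scale by
    2/(inter-eye distance), and compose a y-flip if the anterior indicator
    would land in the y <= 0 half-plane.  The anterior direction must not be
    parallel to the inter-eye axis within the angular tolerance.
    """
    settings = settings or MappingSettings()
    left, right = landmarks.left_eye, landmarks.right_eye
    axis = right - left
    d = float(np.hypot(*axis))
    if d == 0:
        raise ValueError("degenerate landmarks: zero inter-eye distance")
    u = axis / d
    # reject anterior directions parallel to the inter-eye axis
    cross = abs(u[0] * landmarks.anterior[1] - u[1] * landmarks.anterior[0])
    if cross < np.sin(np.deg2rad(settings.anterior_tolerance_deg)):
        raise ValueError(
            f"animal {landmarks.animal_id!r}: anterior direction is within "
            f"{settings.anterior_tolerance_deg} degrees of the inter-eye axis"
        )
    rot = np.array([[u[0], u[1]], [-u[1], u[0]]])  # rotates u onto +x
    scale = 2.0 / d
    matrix = scale * rot
    midpoint = (left + right) / 2.0
    flipped = False
    if (matrix @ landmarks.anterior)[1] <= 0:
        matrix = np.diag([1.0, -1.0]) @ matrix
        flipped = True
    translation = -matrix @ midpoint
    return RegistrationTransform(
        matrix=matrix,
        translation=translation,
        rotation=float(np.arctan2(-u[1], u[0])),
        scale=scale,
        flipped=flipped,
        animal_id=landmarks.animal_id,
    )


def normalize_points(
    points_px: np.ndarray,
    transform: RegistrationTransform,
    *,
    point_types: Sequence[str] | None = None,
    condition: str = "",
) -> NormalizedPointSet:
    """Apply the registration transform to pixel points, preserving labels."""
    points_px = np.asarray(points_px, dtype=float).reshape(-1, 2)
    normalized = transform.apply(points_px) if len(points_px) else points_px
    return NormalizedPointSet(
        animal_id=transform.animal_id,
        condition=condition,
        points=normalized,
        point_types=list(point_types) if point_types is not None else [],
    )


def normalize_landmarks(
    landmarks: AnimalLandmarks,
    settings: MappingSettings | None = None,
) -> NormalizedPointSet:
    """Normalize an animal's extra points using its own eye landmarks."""
    transform = registration_transform(landmarks, settings)
    pts = landmarks.extra_points
    return normalize_points(
        pts[["px", "py"]].to_numpy(dtype=float) if len(pts) else np.empty((0, 2)),
        transform,
        point_types=list(pts["point_type"]),
        condition=landmarks.condition,
    )


def posterior_most_eye(points: NormalizedPointSet) -> np.ndarray:
    """The ectopic-eye point with minimum y; ties broken by larger \\|x\\|,
    then by input order."""
    eyes = points.of_type("ectopic_eye")
    if len(eyes) == 0:
        raise ValueError(f"animal {points.animal_id!r} has no ectopic-eye points")
    y_min = eyes[:, 1].min()
    tied = eyes[eyes[:, 1] == y_min]
    return tied[np.argmax(np.abs(tied[:, 0]))].copy()


def count_anterior(points: NormalizedPointSet) -> int:
    """Number of points strictly anterior to the inter-eye axis (y > 0)."""
    if len(points.points) == 0:
        return 0
    return int((points.points[:, 1] > 0).sum())


def compare_ap_positions(
    posterior_most_y_a: Sequence[float],
    posterior_most_y_b: Sequence[float],
) -> GroupComparison:
    """Unpaired two-tailed t-test on per-animal posterior-most y positions
    (e.g. RNAi dose contrast)."""
    return compare_groups(posterior_most_y_a, posterior_most_y_b)


def export_distribution(
    point_sets: Sequence[NormalizedPointSet],
    path: str | Path,
    plot_path: str | Path | None = None,
) -> pd.DataFrame:
    """Write the pooled scatter table (animal, condition, type, x, y) as CSV;
    optionally also a scatter plot."""
    rows = []
    for ps in point_sets:
        for (x, y), ptype in zip(ps.points, ps.point_types):
            rows.append(
                {
                    "animal_id": ps.animal_id,
                    "condition": ps.condition,
                    "point_type": ptype,
                    "x_coord": x,
                    "y_coord": y,
                }
            )
    df = pd.DataFrame(
        rows, columns=["animal_id", "condition", "point_type", "x_coord", "y_coord"]
    )
    df.to_csv(path, index=False)
    if plot_path is not None:
        _plot_distribution(df, plot_path)
    return df


def read_distribution(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"animal_id": str, "condition": str})


def _plot_distribution(df: pd.DataFrame, plot_path: str | Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for (condition, ptype), sub in df.groupby(["condition", "point_type"]):
        ax.scatter(sub["x_coord"], sub["y_coord"], s=12, alpha=0.6,
                   label=f"{condition}:{ptype}")
    ax.scatter([-1, 1], [0, 0], marker="x", c="k", label="original eyes")
    ax.axhline(0, lw=0.5, c="gray")
    ax.set_xlabel("ML position (half inter-eye distance)")
    ax.set_ylabel("AP position (half inter-eye distance)")
    ax.legend(fontsize=7)
    fig.savefig(plot_path, dpi=150, bbox_inches="tight")
    plt.close(fig)
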