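"""Readers/writers and the package-wide coordinate and calibration conventions.

All file parsing and writing lives here.  Conventions:

* Pixel coordinates in files are 0-based, ``x`` = column, ``y`` = row, with
  ``y`` increasing **downward** (raster convention).
* Physical units are micrometres (µm) for z positions, z spacing, pixel size
  and nucleus radii.
* Image channels are never inferred from page order: readers take an explicit
  channel mapping (one TIFF file per channel, declared in the manifest).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "ImageStack",
    "AnimalLandmarks",
    "PipelineConfig",
    "SegmentationSettings",
    "CountingSettings",
    "SweepSettings",
    "QCSettings",
    "MappingSettings",
    "read_stack",
    "write_stack",
    "read_landmarks",
    "write_landmarks",
    "load_config",
    "write_config",
    "write_results",
    "read_results_table",
]

LANDMARK_COLUMNS = [
    "animal_id",
    "lx_px",
    "ly_px",
    "rx_px",
    "ry_px",
    "anterior_dx",
    "anterior_dy",
    "point_type",
    "px",
    "py",
    "condition",
]

POINT_TYPES = ("ectopic_eye", "original_eye", "progenitor")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ImageStack:
    """A two-channel calibrated confocal stack.

    ``nuclear`` and ``marker`` are ``(n_slices, height, width)`` arrays of
    non-negative intensities; the nuclear channel carries the DNA stain used
    for segmentation, the marker channel the FISH signal (e.g. *opsin*).
    """

    nuclear: np.ndarray
    marker: np.ndarray
    z_spacing_um: float
    pixel_size_um: float
    sample_id: str = ""
    side: str = ""

    def __post_init__(self) -> None:
        self.nuclear = np.asarray(self.nuclear)
        self.marker = np.asarray(self.marker)
        if self.nuclear.ndim != 3 or self.marker.ndim != 3:
            raise ValueError("channels must be 3D (n_slices, height, width)")
        if self.nuclear.shape != self.marker.shape:
            raise ValueError(
                f"channel shape mismatch: nuclear {self.nuclear.shape} "
                f"vs marker {self.marker.shape}"
            )
        if not (self.z_spacing_um > 0 and self.pixel_size_um > 0):
            raise ValueError("z_spacing_um and pixel_size_um must be > 0")
        if np.any(self.nuclear < 0) or np.any(self.marker < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def n_slices(self) -> int:
        return self.nuclear.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.nuclear.shape


@dataclass
class AnimalLandmarks:
    """Per-animal pixel landmarks: the two original eyes, the anterior
    direction, and any extra digitized points (ectopic eyes, original eyes
    of reference animals, progenitors)."""

    animal_id: str
    left_eye: np.ndarray  # (x, y) px
    right_eye: np.ndarray  # (x, y) px
    anterior: np.ndarray  # unit direction in the pixel frame (y-down)
    extra_points: pd.DataFrame = None  # columns: point_type, px, py
    condition: str = ""

    def __post_init__(self) -> None:
        self.left_eye = np.asarray(self.left_eye, dtype=float)
        self.right_eye = np.asarray(self.right_eye, dtype=float)
        anterior = np.asarray(self.anterior, dtype=float)
        if np.allclose(self.left_eye, self.right_eye):
            raise ValueError(
                f"animal {self.animal_id!r}: left and right eyes coincide"
            )
        norm = np.hypot(*anterior)
        if norm == 0 or not np.isfinite(norm):
            raise ValueError(f"animal {self.animal_id!r}: anterior vector is zero")
        self.anterior = anterior / norm
        if self.extra_points is None:
            self.extra_points = pd.DataFrame(columns=["point_type", "px", "py"])
        bad = set(self.extra_points["point_type"]) - set(POINT_TYPES)
        if bad:
            raise ValueError(f"unknown point types: {sorted(bad)}")


# ---------------------------------------------------------------------------
# pipeline configuration
# ---------------------------------------------------------------------------

@dataclass
class SegmentationSettings:
    backend: str = "classical"
    smoothing_sigma_px: float = 1.0
    background_radius_px: float = 0.0  # 0 disables background subtraction
    threshold_mode: str = "global-otsu"  # or "fixed"
    fixed_threshold: float | None = None
    min_separation_px: int = 5
    min_area_px: int = 20
    max_area_px: int = 2500
    border_policy: str = "drop"  # or "keep"
    # recorded defaults for the optional deep-learning backend; unused by
    # the classical backend
    stardist_prob_thresh: float = 0.60
    stardist_nms_thresh: float = 0.5

    def __post_init__(self) -> None:
        if self.smoothing_sigma_px < 0:
            raise ValueError("smoothing sigma must be >= 0")
        if not self.min_area_px < self.max_area_px:
            raise ValueError("min area must be < max area")
        if self.border_policy not in ("keep", "drop"):
            raise ValueError("border_policy must be 'keep' or 'drop'")
        if self.threshold_mode not in ("global-otsu", "fixed"):
            raise ValueError("threshold_mode must be 'global-otsu' or 'fixed'")


@dataclass
class CountingSettings:
    interval_um: float = 5.0
    threshold_scope: str = "per_animal"  # or "per_stack"
    slice_rule: str = "signal"  # or "all"
    background_quantile: float = 0.95
    slice_smoothing_sigma_px: float = 1.0
    fixed_marker_threshold: float | None = None

    def __post_init__(self) -> None:
        if self.interval_um <= 0:
            raise ValueError("sampling interval must be > 0")
        if self.threshold_scope not in ("per_animal", "per_stack"):
            raise ValueError("threshold_scope must be per_animal or per_stack")
        if self.slice_rule not in ("signal", "all"):
            raise ValueError("slice_rule must be 'signal' or 'all'")
        if not 0 < self.background_quantile < 1:
            raise ValueError("background_quantile must be in (0, 1)")


@dataclass
class SweepSettings:
    threshold_multipliers: tuple[float, ...] = (0.9, 1.0, 1.1)
    intervals_um: tuple[float, ...] = (2.5, 5.0, 7.5, 10.0)

    def __post_init__(self) -> None:
        self.threshold_multipliers = tuple(float(m) for m in self.threshold_multipliers)
        self.intervals_um = tuple(float(i) for i in self.intervals_um)
        if not self.threshold_multipliers or not self.intervals_um:
            raise ValueError("sweep grids must be nonempty")
        if any(m <= 0 for m in self.threshold_multipliers):
            raise ValueError("threshold multipliers must be positive")
        if any(i <= 0 for i in self.intervals_um):
            raise ValueError("sweep intervals must be positive")


@dataclass
class QCSettings:
    match_radius_um: float = 2.5  # default: mean nucleus radius

    def __post_init__(self) -> None:
        if self.match_radius_um <= 0:
            raise ValueError("match radius must be > 0")


@dataclass
class MappingSettings:
    anterior_tolerance_deg: float = 5.0

    def __post_init__(self) -> None:
        if not 0 < self.anterior_tolerance_deg < 90:
            raise ValueError("anterior tolerance must be in (0, 90) degrees")


@dataclass
class PipelineConfig:
    """Full pipeline configuration with defaults matching the published
    workflow: 5 µm sampling interval, ±10% threshold multipliers, sweep slice
    widths 2.5–10 µm."""

    segmentation: SegmentationSettings = field(default_factory=SegmentationSettings)
    counting: CountingSettings = field(default_factory=CountingSettings)
    sweep: SweepSettings = field(default_factory=SweepSettings)
    qc: QCSettings = field(default_factory=QCSettings)
    mapping: MappingSettings = field(default_factory=MappingSettings)
    seed: int = 0


_SECTION_TYPES = {
    "segmentation": SegmentationSettings,
    "counting": CountingSettings,
    "sweep": SweepSettings,
    "qc": QCSettings,
    "mapping": MappingSettings,
}


def _build_section(cls, mapping: dict, section: str):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - valid
    if unknown:
        raise ValueError(f"unknown keys in config section {section!r}: {sorted(unknown)}")
    kwargs = dict(mapping)
    for key in ("threshold_multipliers", "intervals_um"):
        if key in kwargs and kwargs[key] is not None:
            kwargs[key] = tuple(kwargs[key])
    return cls(**kwargs)


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML config; an empty file yields all defaults; unknown keys
    are rejected (fail-fast)."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    unknown = set(raw) - set(_SECTION_TYPES) - {"seed"}
    if unknown:
        raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
    kwargs = {}
    for section, cls in _SECTION_TYPES.items():
        if section in raw and raw[section] is not None:
            kwargs[section] = _build_section(cls, raw[section], section)
    if "seed" in raw:
        kwargs["seed"] = int(raw["seed"])
    return PipelineConfig(**kwargs)


def config_to_dict(config: PipelineConfig) -> dict:
    return dataclasses.asdict(config)


def write_config(config: PipelineConfig, path: str | Path) -> None:
    d = config_to_dict(config)
    for key in ("threshold_multipliers", "intervals_um"):
        d["sweep"][key] = list(d["sweep"][key])
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


# ---------------------------------------------------------------------------
# stacks
# ---------------------------------------------------------------------------

def read_stack(
    nuclear_path: str | Path,
    marker_path: str | Path,
    *,
    z_spacing_um: float | None,
    pixel_size_um: float | None,
    sample_id: str = "",
    side: str = "",
) -> ImageStack:
    """Read a two-channel stack from one TIFF per channel.

    Calibration must be declared explicitly; a missing value is an error,
    never silently assumed.
    """
    if z_spacing_um is None or pixel_size_um is None:
        raise ValueError(
            "stack calibration (z_spacing_um, pixel_size_um) must be declared"
        )
    nuclear = tifffile.imread(str(nuclear_path))
    marker = tifffile.imread(str(marker_path))
    if nuclear.ndim == 2:
        nuclear = nuclear[None]
    if marker.ndim == 2:
        marker = marker[None]
    return ImageStack(
        nuclear=nuclear,
        marker=marker,
        z_spacing_um=float(z_spacing_um),
        pixel_size_um=float(pixel_size_um),
        sample_id=sample_id,
        side=side,
    )


def write_stack(stack: ImageStack, nuclear_path: str | Path, marker_path: str | Path) -> None:
    tifffile.imwrite(str(nuclear_path), np.asarray(stack.nuclear, dtype=np.float32),
                     photometric="minisblack")
    tifffile.imwrite(str(marker_path), np.asarray(stack.marker, dtype=np.float32),
                     photometric="minisblack")


# ---------------------------------------------------------------------------
# landmark tables
# ---------------------------------------------------------------------------

def read_landmarks(path: str | Path) -> list[AnimalLandmarks]:
    """Read a landmark CSV (one row per extra point; animals with no extra
    points appear as a single row with empty point columns)."""
    df = pd.read_csv(path, dtype={"animal_id": str, "condition": str})
    missing = set(LANDMARK_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"landmark CSV missing columns: {sorted(missing)}")
    animals: list[AnimalLandmarks] = []
    for animal_id, group in df.groupby("animal_id", sort=False):
        eyes = group[["lx_px", "ly_px", "rx_px", "ry_px", "anterior_dx", "anterior_dy"]]
        if eyes.isna().any().any():
            raise ValueError(f"animal {animal_id!r}: missing eye or anterior values")
        if len(eyes.drop_duplicates()) > 1:
            raise ValueError(
                f"animal {animal_id!r}: conflicting eye/anterior coordinates"
            )
        row = group.iloc[0]
        pts = group.dropna(subset=["point_type"])[["point_type", "px", "py"]]
        condition = row["condition"] if pd.notna(row["condition"]) else ""
        animals.append(
            AnimalLandmarks(
                animal_id=str(animal_id),
                left_eye=np.array([row["lx_px"], row["ly_px"]], dtype=float),
                right_eye=np.array([row["rx_px"], row["ry_px"]], dtype=float),
                anterior=np.array([row["anterior_dx"], row["anterior_dy"]], dtype=float),
                extra_points=pts.reset_index(drop=True),
                condition=condition,
            )
        )
    return animals


def write_landmarks(animals: Sequence[AnimalLandmarks], path: str | Path) -> None:
    rows = []
    for a in animals:
        base = {
            "animal_id": a.animal_id,
            "lx_px": a.left_eye[0],
            "ly_px": a.left_eye[1],
            "rx_px": a.right_eye[0],
            "ry_px": a.right_eye[1],
            "anterior_dx": a.anterior[0],
            "anterior_dy": a.anterior[1],
            "condition": a.condition,
        }
        if len(a.extra_points) == 0:
            rows.append({**base, "point_type": None, "px": None, "py": None})
        else:
            for _, p in a.extra_points.iterrows():
                rows.append(
                    {**base, "point_type": p["point_type"], "px": p["px"], "py": p["py"]}
                )
    pd.DataFrame(rows, columns=LANDMARK_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

def write_results(tables: dict[str, pd.DataFrame], out_dir: str | Path,
                  summary: dict | None = None) -> dict:
    """Write result tables as CSV plus a JSON manifest/summary; returns the
    manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"tables": {}, "summary": summary or {}}
    for name, table in tables.items():
        fname = f"{name}.csv"
        table.to_csv(out_dir / fname, index=False)
        manifest["tables"][name] = fname
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=float))
    return manifest


def read_results_table(out_dir: str | Path, name: str) -> pd.DataFrame:
    return pd.read_csv(Path(out_dir) / f"{name}.csv")
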