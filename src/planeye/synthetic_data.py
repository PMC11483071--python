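"""Ground-truthed synthetic inputs for both pipelines.

Two generators:

* :func:`generate_stack` renders confocal-like two-channel z-stacks.  Nuclei
  are hard spheres (optionally Gaussian-blurred) on a calibrated voxel grid,
  so in-slice cross-sections are discs; the marker channel carries an
  elevated per-cell constant intensity for the marker-positive subset.
  Placement uses rejection sampling with a minimum center-to-center
  distance.

* :func:`generate_animal_population` draws "true" positions of ectopic eyes
  and eye progenitors in the normalized bilateral-eye frame from a
  configurable 2D Gaussian mixture, then embeds each animal in pixel space
  under a random similarity pose (the image y-axis points down; the anterior
  direction is recorded explicitly).  Registering the emitted landmarks and
  normalizing the embedded points recovers the true normalized coordinates,
  which makes the generator a round-trip oracle for the mapping pipeline.

Both generators are bit-deterministic for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .io_formats import AnimalLandmarks, ImageStack, write_landmarks, write_stack

__all__ = [
    "StackSimConfig",
    "GroundTruthCell",
    "MixtureComponent",
    "AnimalSimConfig",
    "generate_stack",
    "generate_animal_population",
    "write_fixtures",
]

_MAX_PLACEMENT_ATTEMPTS = 10_000


@dataclass
class StackSimConfig:
    """Geometry, intensity and noise model for one synthetic stack.

    Intensities are arbitrary units (a.u.); physical sizes are µm.  Defaults
    emulate a small planarian-eye field at 40x: 0.3 µm slices, ~2.5 µm
    nucleus radius, and a marker channel whose positive cells are well
    separated from negatives.
    """

    width_px: int = 96
    height_px: int = 96
    n_slices: int = 40
    z_spacing_um: float = 0.3
    pixel_size_um: float = 0.5
    n_cells: int = 20
    radius_mean_um: float = 2.5
    radius_sd_um: float = 0.25
    fraction_positive: float = 0.5
    marker_mean_positive: float = 180.0
    marker_mean_negative: float = 20.0
    nuclear_mean: float = 150.0
    background: float = 5.0
    noise_sd: float = 4.0
    poisson_scale: float = 0.0  # 0 disables shot noise
    min_distance_um: float = 5.5
    blur_sigma_px: float = 0.0
    seed: int = 0
    sample_id: str = ""
    side: str = ""

    def __post_init__(self) -> None:
        for name in ("z_spacing_um", "pixel_size_um", "radius_mean_um",
                     "nuclear_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 <= self.fraction_positive <= 1:
            raise ValueError("fraction_positive must lie in [0, 1]")
        if self.marker_mean_positive <= self.marker_mean_negative:
            raise ValueError(
                "marker_mean_positive must exceed marker_mean_negative"
            )
        if self.min_distance_um < 0 or self.noise_sd < 0 or self.background < 0:
            raise ValueError("min distance, noise sd and background must be >= 0")


@dataclass
class GroundTruthCell:
    cell_id: int
    x_um: float
    y_um: float
    z_um: float
    radius_um: float
    marker_positive: bool
    marker_intensity: float


def _place_centers(config: StackSimConfig, rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample cell centers (µm) respecting the minimum distance."""
    x_max = config.width_px * config.pixel_size_um
    y_max = config.height_px * config.pixel_size_um
    z_max = (config.n_slices - 1) * config.z_spacing_um
    margin = config.radius_mean_um
    if x_max <= 2 * margin or y_max <= 2 * margin:
        raise ValueError("image too small for the configured nucleus radius")
    centers: list[np.ndarray] = []
    for _ in range(config.n_cells):
        for attempt in range(_MAX_PLACEMENT_ATTEMPTS):
            c = np.array([
                rng.uniform(margin, x_max - margin),
                rng.uniform(margin, y_max - margin),
                rng.uniform(min(margin, z_max / 2), max(z_max - margin, z_max / 2)),
            ])
            if all(np.linalg.norm(c - prev) >= config.min_distance_um for prev in centers):
                centers.append(c)
                break
        else:
            raise RuntimeError(
                f"could not place {config.n_cells} cells with minimum "
                f"center-to-center distance {config.min_distance_um} µm in "
                f"{_MAX_PLACEMENT_ATTEMPTS} attempts per cell"
            )
    return np.array(centers).reshape(config.n_cells, 3)


def generate_stack(config: StackSimConfig) -> tuple[ImageStack, list[GroundTruthCell]]:
    """Render a two-channel stack plus its ground-truth cell table."""
    rng = np.random.default_rng(config.seed)
    centers = _place_centers(config, rng)
    radii = np.clip(
        rng.normal(config.radius_mean_um, config.radius_sd_um, config.n_cells),
        0.5 * config.radius_mean_um,
        None,
    )
    n_pos = int(round(config.fraction_positive * config.n_cells))
    positive = np.zeros(config.n_cells, dtype=bool)
    if config.n_cells:
        positive[rng.choice(config.n_cells, size=n_pos, replace=False)] = True
    marker_levels = np.where(
        positive, config.marker_mean_positive, config.marker_mean_negative
    )

    shape = (config.n_slices, config.height_px, config.width_px)
    nuclear = np.zeros(shape, dtype=float)
    marker = np.zeros(shape, dtype=float)
    zs = np.arange(config.n_slices) * config.z_spacing_um
    px = config.pixel_size_um

    for (cx, cy, cz), r, level in zip(centers, radii, marker_levels):
        # bounding box of the sphere in voxel indices
        z_lo = int(np.searchsorted(zs, cz - r))
        z_hi = int(np.searchsorted(zs, cz + r, side="right"))
        c_lo = max(int((cx - r) / px) - 1, 0)
        c_hi = min(int((cx + r) / px) + 2, config.width_px)
        r_lo = max(int((cy - r) / px) - 1, 0)
        r_hi = min(int((cy + r) / px) + 2, config.height_px)
        if z_lo >= z_hi or c_lo >= c_hi or r_lo >= r_hi:
            continue
        zz = zs[z_lo:z_hi, None, None]
        yy = (np.arange(r_lo, r_hi) + 0.5)[None, :, None] * px
        xx = (np.arange(c_lo, c_hi) + 0.5)[None, None, :] * px
        inside = (xx - cx) ** 2 + (yy - cy) ** 2 + (zz - cz) ** 2 <= r**2
        sub = (slice(z_lo, z_hi), slice(r_lo, r_hi), slice(c_lo, c_hi))
        nuclear[sub] = np.where(inside, config.nuclear_mean, nuclear[sub])
        marker[sub] = np.where(inside, level, marker[sub])

    if config.blur_sigma_px > 0:
        sigma = (0, config.blur_sigma_px, config.blur_sigma_px)
        nuclear = ndimage.gaussian_filter(nuclear, sigma)
        marker = ndimage.gaussian_filter(marker, sigma)

    nuclear += config.background
    marker += config.background
    if config.poisson_scale > 0:
        nuclear = rng.poisson(nuclear * config.poisson_scale) / config.poisson_scale
        marker = rng.poisson(marker * config.poisson_scale) / config.poisson_scale
    if config.noise_sd > 0:
        nuclear = nuclear + rng.normal(0, config.noise_sd, shape)
        marker = marker + rng.normal(0, config.noise_sd, shape)
    nuclear = np.clip(nuclear, 0, None).astype(np.float32)
    marker = np.clip(marker, 0, None).astype(np.float32)

    stack = ImageStack(
        nuclear=nuclear,
        marker=marker,
        z_spacing_um=config.z_spacing_um,
        pixel_size_um=config.pixel_size_um,
        sample_id=config.sample_id,
        side=config.side,
    )
    truth = [
        GroundTruthCell(
            cell_id=i,
            x_um=float(centers[i, 0]),
            y_um=float(centers[i, 1]),
            z_um=float(centers[i, 2]),
            radius_um=float(radii[i]),
            marker_positive=bool(positive[i]),
            marker_intensity=float(marker_levels[i]),
        )
        for i in range(config.n_cells)
    ]
    return stack, truth


# ---------------------------------------------------------------------------
# animal populations
# ---------------------------------------------------------------------------

@dataclass
class MixtureComponent:
    weight: float
    mean: tuple[float, float]  # normalized (x, y)
    cov: Sequence[Sequence[float]] = ((0.04, 0.0), (0.0, 0.04))


def _validate_mixture(components: Sequence[MixtureComponent], name: str) -> None:
    if components and not np.isclose(sum(c.weight for c in components), 1.0):
        raise ValueError(f"{name} mixture weights must sum to 1")


@dataclass
class AnimalSimConfig:
    """Population of synthetic animals with known normalized-point
    distributions.

    Extra-point positions are drawn in the normalized frame from per-type
    Gaussian mixtures, then embedded in pixel space with a random similarity
    pose whose scale is half the animal's inter-eye distance.  With
    ``mirror=True`` half the animals (in expectation) receive a
    reflection-handed pose; the normalized ground truth is unaffected.
    """

    n_animals: int = 8
    inter_eye_range_px: tuple[float, float] = (80.0, 160.0)
    angle_range_rad: tuple[float, float] = (-np.pi, np.pi)
    image_size_px: tuple[int, int] = (1024, 1024)
    condition: str = "control"
    ectopic_mixture: list[MixtureComponent] = field(default_factory=list)
    progenitor_mixture: list[MixtureComponent] = field(default_factory=list)
    n_ectopic_range: tuple[int, int] = (1, 3)
    n_progenitor_range: tuple[int, int] = (0, 0)
    mirror: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.inter_eye_range_px[0] <= 0:
            raise ValueError("inter-eye distance must be > 0")
        _validate_mixture(self.ectopic_mixture, "ectopic")
        _validate_mixture(self.progenitor_mixture, "progenitor")


def _draw_mixture(components: Sequence[MixtureComponent], n: int,
                  rng: np.random.Generator) -> np.ndarray:
    if n == 0 or not components:
        return np.empty((0, 2))
    weights = np.array([c.weight for c in components])
    idx = rng.choice(len(components), size=n, p=weights)
    out = np.empty((n, 2))
    for i, k in enumerate(idx):
        comp = components[k]
        out[i] = rng.multivariate_normal(comp.mean, np.asarray(comp.cov, dtype=float))
    return out


def generate_animal_population(
    config: AnimalSimConfig,
) -> tuple[list[AnimalLandmarks], list["NormalizedPointSet"]]:
    """Draw landmark tables plus the true normalized point sets per animal."""
    from .spatial_mapping import NormalizedPointSet  # avoid import cycle

    rng = np.random.default_rng(config.seed)
    animals: list[AnimalLandmarks] = []
    truths: list[NormalizedPointSet] = []
    w, h = config.image_size_px
    for i in range(config.n_animals):
        d = rng.uniform(*config.inter_eye_range_px)
        scale = d / 2.0
        angle = rng.uniform(*config.angle_range_rad)
        margin = 4 * scale
        cx = rng.uniform(margin, max(w - margin, margin + 1))
        cy = rng.uniform(margin, max(h - margin, margin + 1))
        center = np.array([cx, cy])
        # pixel y points down: the base embedding flips normalized y so that
        # "anterior" is a consistent pixel-space direction; a mirrored pose
        # omits the flip (opposite handedness), which registration undoes.
        handed = np.diag([1.0, -1.0])
        if config.mirror and rng.random() < 0.5:
            handed = np.diag([1.0, 1.0])
        rot = np.array([[np.cos(angle), -np.sin(angle)],
                        [np.sin(angle), np.cos(angle)]])
        embed = scale * rot @ handed

        def to_px(norm_pts: np.ndarray) -> np.ndarray:
            return norm_pts @ embed.T + center

        left_px, right_px = to_px(np.array([[-1.0, 0.0], [1.0, 0.0]]))
        anterior_px = embed @ np.array([0.0, 1.0])
        anterior_px = anterior_px / np.linalg.norm(anterior_px)

        n_ect = int(rng.integers(config.n_ectopic_range[0], config.n_ectopic_range[1] + 1))
        n_pro = int(rng.integers(config.n_progenitor_range[0], config.n_progenitor_range[1] + 1))
        ect = _draw_mixture(config.ectopic_mixture, n_ect, rng)
        pro = _draw_mixture(config.progenitor_mixture, n_pro, rng)
        true_points = np.vstack([ect, pro]) if len(ect) + len(pro) else np.empty((0, 2))
        types = ["ectopic_eye"] * len(ect) + ["progenitor"] * len(pro)
        px_points = to_px(true_points) if len(true_points) else true_points

        animal_id = f"{config.condition}_{i:03d}"
        animals.append(
            AnimalLandmarks(
                animal_id=animal_id,
                left_eye=left_px,
                right_eye=right_px,
                anterior=anterior_px,
                extra_points=pd.DataFrame(
                    {
                        "point_type": types,
                        "px": px_points[:, 0] if len(px_points) else [],
                        "py": px_points[:, 1] if len(px_points) else [],
                    }
                ),
                condition=config.condition,
            )
        )
        truths.append(
            NormalizedPointSet(
                animal_id=animal_id,
                condition=config.condition,
                points=true_points,
                point_types=types,
            )
        )
    return animals, truths


# ---------------------------------------------------------------------------
# study-condition presets
# ---------------------------------------------------------------------------

def two_group_stack_dataset(
    seed: int,
    *,
    n_per_group: int = 8,
    base_positive: int = 10,
    ratio: float = 1.5,
    count_cv: float = 0.12,
    n_negative: int = 6,
    template: StackSimConfig | None = None,
    group_labels: tuple[str, str] = ("control", "rnai"),
) -> dict[str, list[tuple[ImageStack, list[GroundTruthCell]]]]:
    """Two treatment groups of single-side stacks with a known ratio of true
    marker-positive cell numbers.

    Per-animal true positive counts are drawn around the group mean with
    coefficient of variation ``count_cv`` (biological animal-to-animal
    variability); ``ratio`` scales the second group's mean.  ``template``
    carries the stack geometry/intensity settings (its ``n_cells``,
    ``fraction_positive`` and ``seed`` are overridden per animal).
    """
    import dataclasses as _dc

    rng = np.random.default_rng(seed)
    template = template or StackSimConfig()
    out: dict[str, list[tuple[ImageStack, list[GroundTruthCell]]]] = {}
    for label, mean_pos in zip(group_labels, (base_positive, base_positive * ratio)):
        group = []
        for i in range(n_per_group):
            n_pos = max(2, int(round(rng.normal(mean_pos, count_cv * mean_pos))))
            cfg = _dc.replace(
                template,
                n_cells=n_pos + n_negative,
                fraction_positive=n_pos / (n_pos + n_negative),
                seed=int(rng.integers(0, 2**31 - 1)),
                sample_id=f"{label}_{i:02d}",
            )
            group.append(generate_stack(cfg))
        out[label] = group
    return out


def default_ectopic_mixture(kind: str = "broad_posterolateral") -> list[MixtureComponent]:
    """Ectopic-eye mixtures emulating observed phenotype classes: a broad
    bilateral posterolateral cloud versus a tight directly-posterior one."""
    if kind == "broad_posterolateral":
        return [
            MixtureComponent(0.5, (-1.5, -1.5), ((0.35, 0.0), (0.0, 0.5))),
            MixtureComponent(0.5, (1.5, -1.5), ((0.35, 0.0), (0.0, 0.5))),
        ]
    if kind == "tight_posterior":
        return [
            MixtureComponent(0.5, (-0.8, -1.0), ((0.08, 0.0), (0.0, 0.1))),
            MixtureComponent(0.5, (0.8, -1.0), ((0.08, 0.0), (0.0, 0.1))),
        ]
    raise ValueError(f"unknown ectopic mixture kind {kind!r}")


def default_progenitor_mixture() -> list[MixtureComponent]:
    """Progenitor 'trails': elongated posterior-lateral streams behind each
    eye (larger AP than ML variance)."""
    return [
        MixtureComponent(0.5, (-1.2, -1.2), ((0.12, 0.0), (0.0, 0.6))),
        MixtureComponent(0.5, (1.2, -1.2), ((0.12, 0.0), (0.0, 0.6))),
    ]


# ---------------------------------------------------------------------------
# fixture writing
# ---------------------------------------------------------------------------

def write_fixtures(
    stacks: Sequence[ImageStack],
    truths: Sequence[Sequence[GroundTruthCell]],
    landmark_tables: Sequence[AnimalLandmarks],
    out_dir: str | Path,
    *,
    configs: dict | None = None,
) -> dict:
    """Write TIFF stacks, ground-truth CSVs, a landmark CSV and a JSON
    manifest; everything round-trips through io_formats."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stacks": [], "landmarks": None, "configs": configs or {}}
    for k, (stack, truth) in enumerate(zip(stacks, truths)):
        stem = stack.sample_id or f"stack_{k:03d}"
        if stack.side:
            stem = f"{stem}_{stack.side}"
        nuc = f"{stem}_nuclear.tif"
        mrk = f"{stem}_marker.tif"
        tru = f"{stem}_truth.csv"
        write_stack(stack, out_dir / nuc, out_dir / mrk)
        pd.DataFrame(
            [
                {
                    "cell_id": c.cell_id,
                    "x_um": c.x_um,
                    "y_um": c.y_um,
                    "z_um": c.z_um,
                    "radius_um": c.radius_um,
                    "marker_positive": c.marker_positive,
                    "marker_intensity": c.marker_intensity,
                }
                for c in truth
            ],
            columns=["cell_id", "x_um", "y_um", "z_um", "radius_um",
                     "marker_positive", "marker_intensity"],
        ).to_csv(out_dir / tru, index=False)
        manifest["stacks"].append(
            {
                "sample_id": stack.sample_id,
                "side": stack.side,
                "nuclear": nuc,
                "marker": mrk,
                "truth": tru,
                "z_spacing_um": stack.z_spacing_um,
                "pixel_size_um": stack.pixel_size_um,
            }
        )
    if landmark_tables:
        write_landmarks(landmark_tables, out_dir / "landmarks.csv")
        manifest["landmarks"] = "landmarks.csv"
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
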