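import numpy as np
import pytest

from planeye import synthetic_data as sd


@pytest.fixture
def clean_stack_config():
    """Small noise-free stack: crisp discs, zero background, well-separated
    intensity classes."""
    return sd.StackSimConfig(
        width_px=64,
        height_px=64,
        n_slices=20,
        z_spacing_um=0.5,
        pixel_size_um=0.5,
        n_cells=8,
        radius_mean_um=2.5,
        radius_sd_um=0.0,
        fraction_positive=0.5,
        background=0.0,
        noise_sd=0.0,
        min_distance_um=7.0,
        blur_sigma_px=0.0,
        seed=11,
        sample_id="clean",
    )


@pytest.fixture
def clean_stack(clean_stack_config):
    return sd.generate_stack(clean_stack_config)


def well_separated_instance(rng):
    """Detection-like matching instance: <=4 truth cells with min spacing
    2.2x the match radius, jittered detections for ~80% of them, plus up to
    2 spurious detections away from the cells."""
    radius = float(rng.uniform(1.5, 3.0))
    m = int(rng.integers(0, 5))
    truth = []
    tries = 0
    while len(truth) < m and tries < 1000:
        c = rng.uniform(0, 30, 2)
        if all(np.hypot(*(c - t)) >= 2.2 * radius for t in truth):
            truth.append(c)
        tries += 1
    truth = np.array(truth).reshape(-1, 2)
    pred = []
    for t in truth:
        if rng.random() < 0.8:
            pred.append(t + rng.normal(0, 0.15 * radius, 2))
    n_fp = int(rng.integers(0, 3))
    while n_fp > 0:
        c = rng.uniform(0, 30, 2)
        if all(np.hypot(*(c - t)) >= 2.2 * radius for t in truth):
            pred.append(c)
            n_fp -= 1
    return np.array(pred).reshape(-1, 2), truth, radius


def disc_image(shape, centers_px, radius_px, value=100.0):
    """Noise-free 2D image of filled discs (pixel-center convention)."""
    img = np.zeros(shape, dtype=float)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    for cx, cy in centers_px:
        img[(xx - cx) ** 2 + (yy - cy) ** 2 <= radius_px**2] = value
    return img
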