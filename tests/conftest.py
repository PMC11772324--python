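import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from starchmorph.synthetic import (
    GranuleTruth,
    IntensityConfig,
    Lobe,
    PopulationSpec,
    render_object,
    sample_population,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

NOISELESS = IntensityConfig(pixel_noise_sd=0.0)


def make_singlet(
    a: float,
    b: float | None = None,
    theta: float = 0.0,
    boundary_noise: float = 0.0,
    hilum=(0.0, 0.0),
    render_seed: int = 42,
) -> GranuleTruth:
    """Hand-built single-lobe truth (semi-axes in um)."""
    b = a if b is None else b
    return GranuleTruth(
        id=0,
        class_label="singlet",
        semi_axes=(a, b, b),
        orientation=theta,
        lobes=(Lobe(0.0, 0.0, a, b, theta),),
        hilum_positions=(tuple(hilum),),
        true_volume=4.0 / 3.0 * np.pi * a * b * b,
        true_aspect_ratio=b / a,
        boundary_noise=boundary_noise,
        render_seed=render_seed,
    )


def make_fused(r_lobe: float, separation: float, render_seed: int = 43) -> GranuleTruth:
    c1 = (-separation / 2.0, 0.0)
    c2 = (separation / 2.0, 0.0)
    return GranuleTruth(
        id=0,
        class_label="fused",
        semi_axes=(separation / 2.0 + r_lobe, r_lobe, r_lobe),
        orientation=0.0,
        lobes=(
            Lobe(c1[0], c1[1], r_lobe, r_lobe, 0.0),
            Lobe(c2[0], c2[1], r_lobe, r_lobe, 0.0),
        ),
        hilum_positions=(c1, c2),
        true_volume=1.0,
        true_aspect_ratio=r_lobe / (separation / 2.0 + r_lobe),
        boundary_noise=0.0,
        render_seed=render_seed,
    )


def random_blob_mask(rng: np.random.Generator, side: int = 48) -> np.ndarray:
    """Random single-component blob mask (largest component of smoothed
    thresholded noise), area >= 16 px."""
    from scipy import ndimage

    while True:
        field = ndimage.gaussian_filter(rng.normal(size=(side, side)), sigma=5.0)
        mask = field > np.quantile(field, 0.75)
        labels, n = ndimage.label(mask, structure=np.ones((3, 3), bool))
        if n == 0:
            continue
        areas = np.bincount(labels.ravel())
        areas[0] = 0
        biggest = labels == areas.argmax()
        if biggest.sum() >= 16:
            return biggest


@pytest.fixture(scope="session")
def wt_truths():
    """Wild-type-like population: size-shape coupling on, no contamination."""
    return sample_population(PopulationSpec(n=2000, seed=101))


@pytest.fixture(scope="session")
def spherical_run():
    """Rendered + QC'd + measured spherical population (siPTST2b-like)."""
    from starchmorph.pipeline import run_population

    spec = PopulationSpec(
        n=400, shape_coupling=0.0, ar_noise_sd=0.0, boundary_noise=0.02, seed=102
    )
    return run_population(spec, pixel_size=0.5)


@pytest.fixture(scope="session")
def wt_run():
    """Rendered + QC'd + measured wild-type-like population."""
    from starchmorph.pipeline import run_population

    return run_population(PopulationSpec(n=600, seed=103), pixel_size=0.5)
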