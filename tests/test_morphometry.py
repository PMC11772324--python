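"""Shape statistics: radial circularity, moment aspect ratio, hila, density."""

import numpy as np
import pytest
from scipy import stats
from skimage.draw import disk, ellipse
from skimage.measure import regionprops

from conftest import NOISELESS, make_fused, make_singlet, random_blob_mask
from starchmorph import qc as qcmod
from starchmorph.morphometry import (
    HilumConfig,
    aspect_ratio,
    axis_lengths,
    boundary_radial_profile,
    circularity,
    circularity_from_distances,
    count_hila,
    measure,
    records_frame,
    size_shape_density,
)
from starchmorph.pipeline import measure_frames
from starchmorph.synthetic import PopulationSpec, render_object, sample_population


def disc_mask(r=50, pad=6):
    side = 2 * (r + pad) + 1
    m = np.zeros((side, side), bool)
    rr, cc = disk((side // 2, side // 2), r)
    m[rr, cc] = True
    return m


def ellipse_mask(a, b, rotation=0.0, pad=6):
    side = 2 * (max(a, b) + pad) + 1
    m = np.zeros((side, side), bool)
    rr, cc = ellipse(side // 2, side // 2, b, a, rotation=rotation)
    m[rr, cc] = True
    return m


def brute_force_profile(mask):
    """Loop-based oracle using the same 4-neighbour boundary convention."""
    ys, xs = np.nonzero(mask)
    cy, cx = ys.mean(), xs.mean()
    dists = []
    for y, x in zip(ys, xs):
        for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            yy, xx = y + dy, x + dx
            outside = not (0 <= yy < mask.shape[0] and 0 <= xx < mask.shape[1])
            if outside or not mask[yy, xx]:
                dists.append(np.hypot(y - cy, x - cx))
                break
    return np.array(dists)


class TestRadialProfile:
    def test_disc_distances_near_radius(self):
        d = boundary_radial_profile(disc_mask(50))
        assert d.min() >= 49 and d.max() <= 51

    def test_degenerate_masks_raise(self):
        one = np.zeros((5, 5), bool)
        one[2, 2] = True
        with pytest.raises(ValueError):
            boundary_radial_profile(one)
        with pytest.raises(ValueError, match="empty"):
            boundary_radial_profile(np.zeros((5, 5), bool))
        two = np.zeros((9, 9), bool)
        two[1:3, 1:3] = True
        two[6:8, 6:8] = True
        with pytest.raises(ValueError, match="components"):
            boundary_radial_profile(two)

    def test_translation_invariance(self):
        m = ellipse_mask(20, 12)
        big = np.zeros((120, 160), bool)
        big[10 : 10 + m.shape[0], 15 : 15 + m.shape[1]] = m
        shifted = np.zeros((120, 160), bool)
        shifted[40 : 40 + m.shape[0], 80 : 80 + m.shape[1]] = m
        np.testing.assert_allclose(
            np.sort(boundary_radial_profile(big)),
            np.sort(boundary_radial_profile(shifted)),
            atol=1e-9,
        )


class TestCircularity:
    def test_matches_brute_force_oracle_on_random_masks(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            mask = random_blob_mask(rng)
            d = brute_force_profile(mask)
            expected = circularity_from_distances(d)
            assert circularity(mask) == pytest.approx(expected, rel=1e-9)

    def test_ordering_disc_over_ellipses(self):
        """At equal area: disc > 2:1 ellipse > 4:1 ellipse."""
        c_disc = circularity(disc_mask(50))
        c_2to1 = circularity(ellipse_mask(71, 35))  # ~2:1, area ~ pi*50^2
        c_4to1 = circularity(ellipse_mask(100, 25))
        assert c_disc > c_2to1 > c_4to1
        assert c_disc >= 20

    def test_zero_variation_hits_cap(self):
        assert circularity_from_distances(np.full(32, 7.5)) == 1000.0
        assert circularity_from_distances(np.full(32, 7.5), cap=50.0) == 50.0

    def test_pixel_size_cancels(self):
        m = ellipse_mask(30, 18)
        assert circularity(m, 0.25) == pytest.approx(circularity(m, 0.5), rel=1e-12)


class TestAspectRatio:
    def test_disc_is_one(self):
        assert aspect_ratio(disc_mask(50)) == pytest.approx(1.0, abs=0.01)

    def test_axis_aligned_ellipse(self):
        assert aspect_ratio(ellipse_mask(80, 40)) == pytest.approx(0.5, abs=0.02)

    def test_rotation_invariance(self):
        base = aspect_ratio(ellipse_mask(80, 40))
        rot = aspect_ratio(ellipse_mask(80, 40, rotation=np.deg2rad(37)))
        assert rot == pytest.approx(base, abs=0.02)

    def test_agrees_with_regionprops_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            mask = random_blob_mask(rng)
            props = regionprops(mask.astype(np.uint8))[0]
            major, minor = axis_lengths(mask)
            assert major == pytest.approx(props.axis_major_length, rel=1e-9)
            assert minor == pytest.approx(props.axis_minor_length, rel=1e-9)

    def test_degenerate_raises(self):
        tiny = np.zeros((5, 5), bool)
        tiny[2, 2:4] = True
        with pytest.raises(ValueError):
            aspect_ratio(tiny)


def test_scale_invariance_of_shape_metrics():
    """Rendering the same granule at 0.25 and 0.5 um/px changes circularity
    and aspect ratio by < 2%."""
    t = make_singlet(10.0, 7.0, theta=0.3, boundary_noise=0.02)
    vals = {}
    for px in (0.25, 0.5):
        img = render_object(t, px, intensity_cfg=NOISELESS)
        mask = qcmod.mask_by_intensity(img)
        vals[px] = (circularity(mask, px), aspect_ratio(mask, px))
    for a, b in zip(vals[0.25], vals[0.5]):
        assert abs(a - b) / b < 0.02


class TestHila:
    def test_singlet_counts_one(self):
        t = make_singlet(8.0, hilum=(1.0, 0.5))
        img = render_object(t, 0.5)
        assert count_hila(img, qcmod.mask_by_intensity(img)) == 1

    def test_fused_counts_two(self):
        t = make_fused(r_lobe=7.0, separation=8.0)
        img = render_object(t, 0.5)
        assert count_hila(img, qcmod.mask_by_intensity(img)) == 2

    def test_multi_hilum_frequency_recovery(self):
        """Measured multi-hilum frequency over a rendered population with a
        5% fused fraction recovers the truth within 3 binomial SDs."""
        n = 2000
        spec = PopulationSpec(n=n, fused_fraction=0.05, seed=41)
        truths = sample_population(spec)
        counts = []
        for t in truths:
            img = render_object(t, 0.5)
            counts.append(count_hila(img, qcmod.mask_by_intensity(img)))
        freq = np.mean(np.array(counts) >= 2)
        sd = np.sqrt(0.05 * 0.95 / n)
        assert abs(freq - 0.05) <= 3 * sd

    def test_empty_mask_raises(self):
        t = make_singlet(6.0)
        img = render_object(t, 0.5)
        with pytest.raises(ValueError):
            count_hila(img, np.zeros_like(img.data, dtype=bool))


class TestMeasure:
    def test_disc_record_analytic(self):
        t = make_singlet(12.5)  # d = 25 um -> r = 50 px at 0.5 um/px
        img = render_object(t, 0.5, intensity_cfg=NOISELESS)
        rec = measure(img, qcmod.mask_by_intensity(img), frame_id=9)
        assert rec.area == pytest.approx(np.pi * 12.5**2, rel=0.03)
        assert rec.equivalent_diameter == pytest.approx(25.0, rel=0.02)
        assert rec.aspect_ratio == pytest.approx(rec.minor_axis / rec.major_axis, abs=1e-12)
        assert rec.frame_id == 9 and rec.n_hila == 1

    def test_batch_preserves_ids(self, wt_run):
        shapes = wt_run["shapes"]
        assert len(shapes) == len(wt_run["qc"].kept)
        assert list(shapes.frame_id) == wt_run["qc"].kept

    def test_aspect_ratio_recovery_mae(self):
        """Measured vs true aspect ratio over rendered singlets: MAE < 0.03."""
        truths = sample_population(PopulationSpec(n=2000, seed=43))
        errs = []
        for t in truths:
            if t.class_label != "singlet":
                continue
            img = render_object(t, 0.25)
            mask = qcmod.mask_by_intensity(img)
            errs.append(abs(aspect_ratio(mask) - t.true_aspect_ratio))
        assert np.mean(errs) < 0.03


class TestDensity:
    def test_spherical_population_flat_high_deciles(self, spherical_run):
        grid = size_shape_density(spherical_run["shapes"])
        assert np.all(grid.decile_medians > 0.9)
        assert grid.cell_masses.sum() == pytest.approx(1.0, abs=1e-9)

    def test_coupled_population_declining_deciles(self, wt_run):
        grid = size_shape_density(wt_run["shapes"])
        rho, _ = stats.spearmanr(np.arange(10), grid.decile_medians)
        assert rho < 0

    def test_too_few_records_raise(self, wt_run):
        with pytest.raises(ValueError):
            size_shape_density(wt_run["shapes"].head(5))

    def test_contour_levels_monotone(self, wt_run):
        grid = size_shape_density(wt_run["shapes"], levels=(0.25, 0.5, 0.75))
        assert np.all(np.diff(grid.contour_levels) <= 0)


def test_spherical_pipeline_median_aspect_ratio(spherical_run):
    """A spherical population with mild boundary noise keeps median aspect
    ratio >= 0.9 through render + QC + measurement."""
    assert spherical_run["shapes"].aspect_ratio.median() >= 0.9


def test_measure_frames_uses_broad_mask(wt_run):
    recs = measure_frames(wt_run["frames"], wt_run["qc"])
    assert len(recs) == len(wt_run["qc"].kept)
    df = records_frame(recs)
    assert (df.area > 0).all() and (df.aspect_ratio <= 1).all()
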