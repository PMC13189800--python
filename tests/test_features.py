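"""Descriptor suite: analytic anchors, independent oracles, invariances."""

import numpy as np
import pytest

from pollenmorph import detect as dt
from pollenmorph import features as ft
from pollenmorph import synthscene as ss


def _disk(r, frame=None, center=None):
    frame = frame or int(3 * r)
    c = center or frame // 2
    yy, xx = np.mgrid[0:frame, 0:frame]
    return (xx - c) ** 2 + (yy - c) ** 2 <= r ** 2


def _make_crop(img, center=(256.0, 256.0), radius=60.0):
    det = dt.Detection("t", center, radius)
    return dt.ParticleCrop(pixels=np.asarray(img), detection=det,
                           center_in_crop=center)


# ---------------------------------------------------------------- binarize

def test_binarize_dark_disk_area_within_5pct():
    p = ss.ParticleSpec("cypre", (256.0, 256.0), 100.0, mean_intensity=80,
                        texture_sd=4)
    mask = ft.binarize(ss.render_crop(p, rng_seed=1))
    assert mask.sum() == pytest.approx(np.pi * 100 ** 2, rel=0.05)


def test_binarize_flat_image_gives_empty_mask():
    assert not ft.binarize(np.full((128, 128), 77, dtype=np.uint8)).any()


def test_binarize_polarity_invariant_to_inversion():
    p = ss.ParticleSpec("cypre", (256.0, 256.0), 80.0, texture_sd=3)
    img = ss.render_crop(p, rng_seed=2)
    m1 = ft.binarize(img)
    m2 = ft.binarize(255 - img)
    assert (m1 == m2).mean() > 0.995  # identical up to threshold-boundary px


# ------------------------------------------------------------- circularity

@pytest.mark.parametrize("mask_name,expected,tol", [
    ("square", np.pi / 4, 0.05),
    ("disk", 1.0, 0.05),
])
def test_circularity_analytic_anchors(mask_name, expected, tol, square_mask,
                                      disk_mask):
    mask = {"square": square_mask, "disk": disk_mask}[mask_name]
    assert ft.circularity(mask) == pytest.approx(expected, abs=tol)


def test_circularity_thin_bar_matches_discrete_perimeter():
    bar = np.zeros((20, 120), bool)
    bar[10, 10:110] = True
    # exact discrete footprint: area 100, boundary 2*100 + 2*1
    assert ft.circularity(bar) == pytest.approx(4 * np.pi * 100 / 202 ** 2,
                                                abs=0.01)


def test_circularity_single_pixel_defined():
    m = np.zeros((9, 9), bool)
    m[4, 4] = True
    assert np.isfinite(ft.circularity(m))


# -------------------------------------------------------- inscribed_ratio

def test_inscribed_ratio_disk_annulus_halfdisk(disk_mask):
    assert ft.inscribed_ratio(disk_mask, 100) == pytest.approx(1.0, abs=0.02)
    assert ft.inscribed_ratio(_disk(50, frame=300), 100) == pytest.approx(
        0.5, abs=0.02)
    annulus = disk_mask & ~_disk(50, frame=300)
    # largest inscribed circle in the ring = half the ring width = 25
    assert ft.inscribed_ratio(annulus, 100) == pytest.approx(0.25, abs=0.02)


# ----------------------------------------------------------------- area

def test_area_px_counts():
    m = np.zeros((20, 20), bool)
    m[5:15, 5:15] = True
    assert ft.area_px(m) == 100
    assert ft.area_px(np.zeros((5, 5), bool)) == 0
    assert ft.area_px(_disk(50)) == pytest.approx(np.pi * 50 ** 2, rel=0.05)


# -------------------------------------------------------- centroid_shift

def test_centroid_shift_symmetric_disk_is_zero(disk_mask):
    assert ft.centroid_shift(disk_mask, (150.0, 150.0)) <= 0.5


def test_centroid_shift_half_disk_is_4r_over_3pi(disk_mask):
    half = disk_mask.copy()
    half[:, :150] = False
    shift = ft.centroid_shift(half, (150.0, 150.0))
    assert shift == pytest.approx(4 * 100 / (3 * np.pi), rel=0.02)


def test_centroid_shift_translation_property(disk_mask):
    half = disk_mask.copy()
    half[:, :150] = False
    base = ft.centroid_shift(half, (150.0, 150.0))
    rolled = np.roll(half, 25, axis=1)
    moved = ft.centroid_shift(rolled, (150.0, 150.0))
    assert moved == pytest.approx(base + 25, abs=0.01)


# ------------------------------------------------------------ fractal_dim

def _boxcount_oracle(boundary_pixels, sizes=(2, 4, 8, 16, 32, 64)):
    xs, ys = boundary_pixels
    counts = [len({(x // s, y // s) for x, y in zip(xs, ys)}) for s in sizes]
    return np.polyfit(np.log(1.0 / np.asarray(sizes, float)),
                      np.log(counts), 1)[0]


def test_fractal_dim_smooth_contours_near_one(disk_mask):
    bar = np.zeros((60, 200), bool)
    bar[28:32, 20:180] = True
    assert ft.fractal_dim(bar) == pytest.approx(1.0, abs=0.15)
    assert ft.fractal_dim(disk_mask) == pytest.approx(1.0, abs=0.15)


def test_fractal_dim_zigzag_exceeds_circle_and_matches_oracle(disk_mask):
    # square-wave (quadratic-Koch-like) boundary at two refinement scales
    yy, xx = np.mgrid[0:300, 0:300]
    wave = 20 * np.sign(np.sin(xx / 6.0)) + 8 * np.sign(np.sin(xx / 2.0))
    zig = yy > 150 + wave
    fd_zig = ft.fractal_dim(zig)
    assert fd_zig > ft.fractal_dim(disk_mask)
    b = ft._boundary(zig)
    ys, xs = np.nonzero(b)
    assert fd_zig == pytest.approx(_boxcount_oracle((xs, ys)), abs=1e-9)


def test_fractal_dim_tiny_contour_flagged_nan():
    m = np.zeros((10, 10), bool)
    m[4:6, 4:6] = True
    assert np.isnan(ft.fractal_dim(m))


# -------------------------------------------------------------- spike_cnt

def test_spike_cnt_flat_image_zero():
    assert ft.spike_cnt(np.full((512, 512), 128.0), (256, 256), 80) == 0


@pytest.mark.parametrize("k", [1, 2, 3])
def test_spike_cnt_recovers_rendered_furrows(k):
    hits = 0
    for seed in range(3):
        p = ss.ParticleSpec("cedar", (256.0, 256.0), 80.0, mean_intensity=90,
                            n_spikes=k, texture_sd=5)
        img = ss.render_crop(p, rng_seed=97 * seed + k)
        n = ft.spike_cnt(img.astype(float), (256.0, 256.0), 80.0)
        hits += abs(n - k) <= 1
    assert hits == 3


def test_spike_cnt_ignores_tangential_line():
    yy, xx = np.mgrid[0:512, 0:512]
    cov = np.clip(80 + 0.5 - np.hypot(xx - 256, yy - 256), 0, 1)
    img = 200.0 * (1 - cov) + 90 * cov
    img[214:218, 216:297] = 30  # chord, perpendicular to the radius
    assert ft.spike_cnt(img, (256.0, 256.0), 80.0) == 0
    img2 = 200.0 * (1 - cov) + 90 * cov
    img2[255:258, 266:332] = 30  # radial segment
    assert ft.spike_cnt(img2, (256.0, 256.0), 80.0) == 1


# ------------------------------------------------------------ radial_grad

def test_radial_grad_uniform_zero_and_two_level_exact():
    assert ft.radial_grad(np.full((300, 300), 90.0), (150, 150), 99) == 0.0
    yy, xx = np.mgrid[0:300, 0:300]
    d = np.hypot(xx - 150, yy - 150)
    img = np.full((300, 300), 100.0)
    img[d <= 33] = 200.0
    assert ft.radial_grad(img, (150.0, 150.0), 99.0) == pytest.approx(100.0)
    assert ft.radial_grad(-img, (150.0, 150.0), 99.0) == pytest.approx(-100.0)


def test_radial_grad_annulus_outside_image_flagged():
    # radius so large that the whole peripheral annulus misses the image
    assert np.isnan(ft.radial_grad(np.zeros((100, 100)), (50.0, 50.0), 250.0))


# ----------------------------------------------------------- edge_density

def test_edge_density_flat_zero_and_bounded():
    m = _disk(40, frame=200)
    assert ft.edge_density(np.full((200, 200), 100.0), m) == 0.0
    rng = np.random.default_rng(0)
    v = ft.edge_density(rng.uniform(0, 255, (200, 200)), m)
    assert 0.0 <= v <= 1.0


def test_edge_density_checkerboard_exceeds_flat_disk():
    m = _disk(40, frame=200)
    yy, xx = np.mgrid[0:200, 0:200]
    checker_in_disk = np.where(m, 255.0 * ((xx // 4 + yy // 4) % 2), 200.0)
    flat_disk = np.where(m, 80.0, 200.0)
    assert ft.edge_density(checker_in_disk, m) > ft.edge_density(flat_disk, m)


# -------------------------------------------------------- texture_entropy

def _lbp_entropy_oracle(img, mask):
    """Brute-force uniform-LBP histogram entropy (bits).

    Samples the 8-point unit circle with bilinear interpolation, classifies
    patterns as uniform (<= 2 bit transitions, binned by popcount) or
    non-uniform, and returns the Shannon entropy of that 10-bin histogram."""
    img = np.asarray(img, float)
    h, w = img.shape
    hist = np.zeros(10)
    ys, xs = np.nonzero(mask)
    for y, x in zip(ys, xs):
        if not (0 < y < h - 2 and 0 < x < w - 2):
            continue
        bits = []
        for k in range(8):
            th = 2 * np.pi * k / 8
            yy, xx = y + np.sin(th), x + np.cos(th)
            y0, x0 = int(np.floor(yy)), int(np.floor(xx))
            fy, fx = yy - y0, xx - x0
            v = (img[y0, x0] * (1 - fy) * (1 - fx)
                 + img[y0, x0 + 1] * (1 - fy) * fx
                 + img[y0 + 1, x0] * fy * (1 - fx)
                 + img[y0 + 1, x0 + 1] * fy * fx)
            bits.append(int(v >= img[y, x]))
        trans = sum(bits[i] != bits[(i + 1) % 8] for i in range(8))
        hist[sum(bits) if trans <= 2 else 9] += 1
    p = hist / hist.sum()
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def test_texture_entropy_constant_region_zero():
    m = np.ones((64, 64), bool)
    assert ft.texture_entropy(np.full((64, 64), 120.0), m) == 0.0


def test_texture_entropy_bounded_by_log2_bins():
    rng = np.random.default_rng(1)
    img = rng.integers(0, 256, (128, 128)).astype(np.uint8)
    v = ft.texture_entropy(img, np.ones((128, 128), bool))
    assert 0 <= v <= np.log2(10)


def test_texture_entropy_iid_noise_matches_bruteforce_oracle():
    rng = np.random.default_rng(2)
    img = rng.integers(0, 256, (320, 320)).astype(np.uint8)  # ~1e5 px
    mask = np.ones((320, 320), bool)
    ours = ft.texture_entropy(img, mask)
    oracle = _lbp_entropy_oracle(img, np.pad(np.ones((316, 316), bool), 2))
    assert ours == pytest.approx(oracle, rel=0.15)


def test_texture_entropy_small_interior_flagged():
    m = np.zeros((64, 64), bool)
    m[30:34, 30:34] = True
    assert np.isnan(ft.texture_entropy(np.zeros((64, 64)), m))


# ------------------------------------------------------- convex_def_ratio

def _hull_area_oracle(mask, scale=10):
    """Brute-force hull area at finer rasterization via shapely."""
    from shapely.geometry import MultiPoint

    ys, xs = np.nonzero(mask)
    pts = []
    for y, x in zip(ys, xs):  # pixel corners
        pts += [(x - 0.5, y - 0.5), (x + 0.5, y - 0.5), (x - 0.5, y + 0.5),
                (x + 0.5, y + 0.5)]
    return MultiPoint(pts).convex_hull.area


def test_convex_def_ratio_convex_masks_zero(disk_mask, square_mask):
    assert ft.convex_def_ratio(disk_mask) <= 0.02
    assert ft.convex_def_ratio(square_mask) <= 0.02


def test_convex_def_ratio_plus_sign_matches_hull_oracle():
    plus = np.zeros((330, 330), bool)
    u = 100
    for i, j in [(0, 1), (1, 0), (1, 1), (1, 2), (2, 1)]:
        plus[10 + i * u:10 + (i + 1) * u, 10 + j * u:10 + (j + 1) * u] = True
    v = ft.convex_def_ratio(plus)
    assert v == pytest.approx(2 / 7, abs=0.03)
    oracle = 1 - plus.sum() / _hull_area_oracle(plus)
    assert v == pytest.approx(oracle, abs=0.01)


def test_convex_def_ratio_in_unit_interval_for_random_masks():
    rng = np.random.default_rng(3)
    for _ in range(1000):
        m = rng.random((24, 24)) < rng.uniform(0.05, 0.6)
        if not m.any():
            continue
        assert 0.0 <= ft.convex_def_ratio(m) <= 1.0


# ------------------------------------------------------------ extract_all

def test_extract_all_intact_disk_composition():
    p = ss.ParticleSpec("cypre", (256.0, 256.0), 80.0, texture_sd=4)
    crop = _make_crop(ss.render_crop(p, rng_seed=4), radius=80.0)
    v = ft.extract_all(crop)
    assert v.circularity == pytest.approx(1.0, abs=0.05)
    assert v.convex_def_ratio == pytest.approx(0.0, abs=0.05)
    assert v.centroid_shift <= 3.0
    assert v.radius == 80.0
    assert not v.flags


def test_extract_all_burst_more_concave_than_intact():
    rng = np.random.default_rng(6)
    intact = ss.sample_particle("cypre", rng, center=(256.0, 256.0))
    burst = ss.sample_particle("cypre_brst", rng, center=(256.0, 256.0))
    vi = ft.extract_all(_make_crop(ss.render_crop(intact, rng_seed=7),
                                   radius=intact.radius))
    vb = ft.extract_all(_make_crop(ss.render_crop(burst, rng_seed=8),
                                   radius=burst.radius))
    assert vb.convex_def_ratio > vi.convex_def_ratio


def test_extract_all_empty_mask_flagged():
    crop = _make_crop(np.full((512, 512), 99, dtype=np.uint8))
    v = ft.extract_all(crop)
    assert "empty_mask" in v.flags
    assert np.isnan(v.circularity)


def test_extract_all_deterministic():
    p = ss.ParticleSpec("cedar", (256.0, 256.0), 75.0, n_spikes=2)
    crop = _make_crop(ss.render_crop(p, rng_seed=9), radius=75.0)
    assert ft.extract_all(crop).to_dict() == ft.extract_all(crop).to_dict()


# ------------------------------------------------------------- invariants

def test_scale_monotonicity_of_area_and_scale_invariants():
    small = _disk(40, frame=200)
    big = _disk(80, frame=400)
    assert ft.area_px(big) / ft.area_px(small) == pytest.approx(4.0, rel=0.02)
    assert ft.inscribed_ratio(big, 80) == pytest.approx(
        ft.inscribed_ratio(small, 40), abs=0.02)
    assert ft.circularity(big) == pytest.approx(ft.circularity(small),
                                                abs=0.02)
    assert abs(ft.convex_def_ratio(big) - ft.convex_def_ratio(small)) <= 0.02


def test_rotation_robustness_90_degrees():
    p = ss.ParticleSpec("cypre_brst", (256.0, 256.0), 70.0,
                        burst_concavity=0.3, texture_sd=6)
    img = ss.render_crop(p, rng_seed=10)
    m = ft.binarize(img)
    mr = ft.binarize(np.rot90(img))
    for f, args in [(ft.circularity, ()), (ft.convex_def_ratio, ())]:
        a, b = f(m, *args), f(mr, *args)
        assert abs(a - b) / abs(a) < 0.05
    assert abs(ft.area_px(m) - ft.area_px(mr)) / ft.area_px(m) < 0.05
    te_a = ft.texture_entropy(img, m)
    te_b = ft.texture_entropy(np.rot90(img).copy(), mr)
    assert abs(te_a - te_b) / te_a < 0.05


def test_core9_projection():
    p = ss.ParticleSpec("cypre", (256.0, 256.0), 60.0)
    v = ft.extract_all(_make_crop(ss.render_crop(p, rng_seed=11), radius=60.0))
    core = ft.to_core9(v)
    assert tuple(core.keys()) == ft.CORE9
    assert len(core) == 9
    assert ft.to_core9(core) == core  # idempotent
    assert "fractal_dim" not in core and "edge_density" not in core
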