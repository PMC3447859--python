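"""Segmentation pipeline: stage-level oracles and ground-truth recovery."""

import numpy as np
import pytest
from skimage import measure

from ihcquant import segment, stats, synth
from ihcquant.segment import (
    DegenerateFieldError,
    RGBField,
    SegmentationConfig,
    bandpass,
    flatfield_correct,
    isodata_threshold,
    optimize_alpha,
    remove_artifacts,
    segment_field,
    stain_contrast,
    suppress_nonspecific,
)


def _uniform_field(rgb, size=32):
    return RGBField(np.full((size, size, 3), 0.0) + np.asarray(rgb), 1.0, "u")


# ------------------------------------------------------- flat-field correction

def test_flatfield_constant_is_identity(small_field_config):
    img, _ = synth.generate_ihc_field(small_field_config)
    ff = RGBField(np.full_like(img.pixels, 0.7), 1.0, "ff")
    out = flatfield_correct(img, ff)
    assert np.allclose(out.pixels, img.pixels)


def test_flatfield_closed_form_flattens_proportional_scene():
    ff = synth.generate_flatfield(64, 64, 1.8, seed=4)
    k = 0.6
    scene = RGBField(np.clip(k * ff.pixels, 0, 1), 1.0, "s")
    out = flatfield_correct(scene, ff)
    expected = k * ff.pixels.mean(axis=(0, 1))
    assert np.allclose(out.pixels, expected[None, None, :], atol=1e-9)


def test_flatfield_shape_mismatch_fails(small_field_config):
    img, _ = synth.generate_ihc_field(small_field_config)
    ff = synth.generate_flatfield(64, 64, 1.2, seed=1)
    with pytest.raises(ValueError, match="dimensions"):
        flatfield_correct(img, ff)


def test_flatfield_mean_preserved_without_clipping(small_field_config):
    img, _ = synth.generate_ihc_field(small_field_config)
    scaled = RGBField(img.pixels * 0.5, 1.0, "half")  # headroom: no clipping
    ff = synth.generate_flatfield(128, 128, 1.3, seed=9)
    out = flatfield_correct(scaled, ff)
    for c in range(3):
        assert out.pixels[:, :, c].mean() == pytest.approx(
            scaled.pixels[:, :, c].mean(), rel=0.01
        )


# ------------------------------------------------- non-specific suppression

def test_suppression_scale_one_is_identity(small_field_config):
    img, _ = synth.generate_ihc_field(small_field_config)
    cfg = SegmentationConfig(offsector_saturation_scale=1.0)
    assert suppress_nonspecific(img, cfg) is img


def test_suppression_leaves_gray_pixels_unchanged():
    img = _uniform_field((0.5, 0.5, 0.5))
    out = suppress_nonspecific(img, SegmentationConfig())
    assert np.allclose(out.pixels, 0.5)


def test_suppression_desaturates_offsector_green_to_its_value():
    # saturated green: hue 120 deg, outside both stain sectors; with scale 0
    # the HSV round trip replaces it by its value (max channel) in all bands
    img = _uniform_field((0.2, 0.8, 0.3))
    out = suppress_nonspecific(img, SegmentationConfig())
    assert np.allclose(out.pixels, 0.8, atol=1e-9)


def test_suppression_keeps_stain_colors():
    for rgb in ((0.42, 0.28, 0.14), (0.35, 0.35, 0.65)):  # DAB, hematoxylin
        img = _uniform_field(rgb)
        out = suppress_nonspecific(img, SegmentationConfig())
        assert np.allclose(out.pixels, img.pixels, atol=1e-9)


def test_suppression_idempotent_at_scale_zero(small_field_config):
    img, _ = synth.generate_ihc_field(small_field_config)
    cfg = SegmentationConfig()
    once = suppress_nonspecific(img, cfg)
    twice = suppress_nonspecific(once, cfg)
    assert np.allclose(once.pixels, twice.pixels, atol=1e-7)


def test_suppression_rejects_bad_sectors(small_field_config):
    img, _ = synth.generate_ihc_field(small_field_config)
    with pytest.raises(ValueError, match="overlap"):
        suppress_nonspecific(img, SegmentationConfig(hue_sectors=((10, 60), (50, 90))))
    with pytest.raises(ValueError, match="empty"):
        suppress_nonspecific(img, SegmentationConfig(hue_sectors=((10, 10), (200, 260))))


# --------------------------------------------------------------- contrast

def test_stain_contrast_endpoints_and_arithmetic():
    img = _uniform_field((0.6, 0.3, 0.2))
    assert np.allclose(stain_contrast(img, 1.0), 0.6)
    assert np.allclose(stain_contrast(img, 0.0), -0.2)
    assert np.allclose(stain_contrast(img, 0.5), 0.2)
    with pytest.raises(ValueError):
        stain_contrast(img, 1.5)


# --------------------------------------------------------------- band-pass

def test_bandpass_removes_dc():
    out = bandpass(np.full((64, 64), 3.7), 4, 32)
    assert np.allclose(out, 0.0, atol=1e-9)
    assert abs(bandpass(np.random.default_rng(0).normal(size=(64, 64)), 4, 32).mean()) < 1e-12


def _sine_gain(period, small, large, width=1024):
    x = np.arange(width)
    row = np.sin(2 * np.pi * x / period)
    img = np.tile(row, (8, 1))
    out = bandpass(img, small, large)
    crop = out[:, width // 4 : -width // 4]  # avoid boundary-mode edge effects
    return np.ptp(crop) / 2.0  # input amplitude is 1


def test_bandpass_transfer_function():
    small, large = 4.0, 32.0
    # in-band period is retained (DoG transfer predicts ~0.73 at period 16)
    assert _sine_gain(16, small, large) >= 0.70
    # far above the upper stop the wave is strongly suppressed (~0.07 at 8*large)
    assert _sine_gain(8 * large, small, large) <= 0.20
    with pytest.raises(ValueError):
        bandpass(np.zeros((8, 8)), 4, 4)


# ----------------------------------------------------------------- isodata

def test_isodata_hand_examples():
    h = np.zeros(256, dtype=int)
    h[50] = 100
    h[200] = 100
    assert isodata_threshold(h) == 125
    h = np.zeros(256, dtype=int)
    h[0] = 77
    h[255] = 77
    assert isodata_threshold(h) == 127  # truncation of 127.5


def test_isodata_degenerate_single_level():
    with pytest.raises(DegenerateFieldError):
        isodata_threshold(np.full((40, 40), 0.5))


def test_isodata_matches_exhaustive_fixed_point_oracle():
    """Iterative intermeans lands on a fixed point of the update map."""
    rng = np.random.default_rng(123)
    levels = np.arange(256)
    for _ in range(100):
        h = rng.integers(0, 50, size=256)
        h[rng.integers(0, 256, size=200)] = 0  # sparse histograms too
        if np.count_nonzero(h) < 2:
            continue
        t = isodata_threshold(h)
        fixed = []
        for cand in range(int(np.flatnonzero(h)[0]), int(np.flatnonzero(h)[-1])):
            below = h[: cand + 1]
            above = h[cand + 1 :]
            if below.sum() == 0 or above.sum() == 0:
                continue
            m0 = np.dot(levels[: cand + 1], below) / below.sum()
            m1 = np.dot(levels[cand + 1 :], above) / above.sum()
            if int((m0 + m1) / 2) == cand:
                fixed.append(cand)
        assert t in fixed
        if len(fixed) == 1:
            assert t == fixed[0]


# ----------------------------------------------------------- adaptive alpha

def _red_blob_field(size=64):
    """Blobs differing from background only in the red channel."""
    img = np.full((size, size, 3), 0.45)
    yy, xx = np.mgrid[0:size, 0:size]
    for cx, cy in ((16, 16), (44, 40)):
        blob = (xx - cx) ** 2 + (yy - cy) ** 2 <= 8**2
        img[blob, 0] = 0.85
    return RGBField(img, 1.0, "redblobs")


def test_optimize_alpha_favors_red_when_only_red_informative():
    params = optimize_alpha(_red_blob_field(), SegmentationConfig())
    assert params.alpha >= 0.8


def test_optimize_alpha_degenerate_when_red_equals_blue():
    img = np.full((64, 64, 3), 0.5)
    img[:, :, 1] = np.linspace(0, 1, 64)[None, :]
    with pytest.raises(DegenerateFieldError):
        optimize_alpha(RGBField(img, 1.0, "rb-equal"), SegmentationConfig())


def test_optimize_alpha_near_grid_oracle(small_field_config):
    img, _ = synth.generate_ihc_field(small_field_config)
    sup = suppress_nonspecific(img, SegmentationConfig())
    params = optimize_alpha(sup, SegmentationConfig())
    curve = dict(params.metric_curve)
    assert curve[params.alpha] >= 0.95 * max(curve.values())


# --------------------------------------------------------- artifact removal

def _object_scene(rgb, size=40, radius=8):
    img = np.full((size, size, 3), 0.9)
    yy, xx = np.mgrid[0:size, 0:size]
    mask = (xx - size // 2) ** 2 + (yy - size // 2) ** 2 <= radius**2
    img[mask] = rgb
    field = RGBField(img, 1.0, "obj")
    labels = measure.label(mask, connectivity=2)
    return mask, labels, field


@pytest.mark.parametrize(
    "rgb,kept",
    [
        ((0.42, 0.28, 0.14), True),   # DAB: R/B = 3.0 >= tau
        ((0.35, 0.35, 0.65), False),  # hematoxylin: R/B = 0.54 < tau
        ((0.46, 0.40, 0.40), True),   # exactly tau*mean_B: boundary inclusive
    ],
)
def test_artifact_filter_color_rule(rgb, kept):
    mask, labels, field = _object_scene(rgb)
    new_mask, _, n_kept, n_rej = remove_artifacts(mask, labels, field,
                                                  SegmentationConfig())
    assert (n_kept == 1) == kept
    assert (n_rej == 1) == (not kept)
    assert bool(new_mask.any()) == kept


def test_artifact_filter_small_objects_and_empty_mask():
    mask, labels, field = _object_scene((0.42, 0.28, 0.14), radius=2)  # area < 20
    _, _, n_kept, n_rej = remove_artifacts(mask, labels, field, SegmentationConfig())
    assert n_kept == 0 and n_rej == 1
    empty = np.zeros((40, 40), dtype=bool)
    _, _, n_kept, n_rej = remove_artifacts(
        empty, empty.astype(int), field, SegmentationConfig()
    )
    assert n_kept == 0 and n_rej == 0


def test_artifact_cutoff_monotonicity(small_field_config):
    """Raising tau never increases kept objects or positive area of a mask."""
    img, _ = synth.generate_ihc_field(small_field_config)
    base = SegmentationConfig()
    corrected = img
    sup = suppress_nonspecific(corrected, base)
    params = optimize_alpha(sup, base)
    bits = segment._to_uint8(
        bandpass(stain_contrast(sup, params.alpha), base.bandpass_small,
                 base.bandpass_large)
    )
    raw_mask = bits > isodata_threshold(bits)
    raw_labels = measure.label(raw_mask, connectivity=2)
    prev_area, prev_objs = None, None
    for tau in (0.8, 1.15, 2.0, 3.5):
        cfg = SegmentationConfig(artifact_ratio_cutoff=tau)
        mask, _, n_kept, _ = remove_artifacts(raw_mask, raw_labels, corrected, cfg)
        if prev_area is not None:
            assert mask.sum() <= prev_area
            assert n_kept <= prev_objs
        prev_area, prev_objs = mask.sum(), n_kept


# ------------------------------------------------------------ full pipeline

def test_segment_field_recovers_ground_truth(small_field_config):
    img, gt = synth.generate_ihc_field(small_field_config)
    res = segment_field(img)
    inter = (res.mask & gt.mask).sum()
    dice = 2 * inter / (res.mask.sum() + gt.mask.sum())
    assert dice >= 0.8
    assert res.positive_area_px == res.mask.sum()
    assert res.area_fraction == res.positive_area_px / (128 * 128)
    assert res.positive_area_um2 == pytest.approx(
        res.positive_area_px * img.pixel_size**2
    )


def test_segmentation_recovery_over_seeds():
    """Median Dice >= 0.8 and median area error <= 20% across conditions."""
    rng = np.random.default_rng(0)
    dices, errors = [], []
    for seed in range(10):
        cfg = synth.SynthIHCConfig(
            width=192, height=192, seed=seed,
            target_fraction=float(rng.uniform(0.05, 0.4)),
            illum_gradient=1.4, noise_sd=0.03,
        )
        img, gt = synth.generate_ihc_field(cfg)
        res = segment_field(img)
        dices.append(2 * (res.mask & gt.mask).sum() / (res.mask.sum() + gt.mask.sum()))
        errors.append(abs(res.area_fraction - gt.realized_fraction)
                      / gt.realized_fraction)
    assert np.median(dices) >= 0.8
    assert np.median(errors) <= 0.2


def test_blank_field_degenerate_or_empty():
    cfg = synth.SynthIHCConfig(width=64, height=64, target_fraction=0.0,
                               n_blobs=0, n_nuclei=0, noise_sd=0.0, seed=0)
    img, _ = synth.generate_ihc_field(cfg)
    try:
        res = segment_field(img)
    except DegenerateFieldError:
        return
    assert res.area_fraction == 0.0


def test_flatfield_invariance_of_segmentation():
    """Shading then correcting with the known light field preserves the mask."""
    cfg = synth.SynthIHCConfig(width=128, height=128, seed=3, illum_gradient=1.0)
    img, _ = synth.generate_ihc_field(cfg)
    ff = synth.generate_flatfield(128, 128, 1.5, seed=77)
    shaded = RGBField(np.clip(img.pixels * ff.pixels, 0, 1), img.pixel_size, "sh")
    m_plain = segment_field(img).mask
    m_corrected = segment_field(shaded, ff).mask
    assert (m_plain ^ m_corrected).mean() <= 0.02


def test_pipeline_is_deterministic(small_field_config):
    img, _ = synth.generate_ihc_field(small_field_config)
    r1 = segment_field(img)
    r2 = segment_field(img)
    assert np.array_equal(r1.mask, r2.mask)
    assert r1.params.alpha == r2.params.alpha
    assert r1.threshold == r2.threshold


# ------------------------------------------------------------- summarization

def _fake_result(fraction):
    empty = np.zeros((32, 32), dtype=bool)
    return segment.SegmentationResult(
        mask=empty, labels=empty.astype(int), threshold=0,
        params=segment.ContrastParams(alpha=0.5, metric_curve=[]),
        positive_area_px=0, positive_area_um2=fraction * 1024,
        area_fraction=fraction, object_count=0, rejected_object_count=0,
    )


def test_quantify_section_textbook_and_degenerate():
    same = [_fake_result(0.25), _fake_result(0.25)]
    summary = segment.quantify_section(same, same, value="area_fraction")
    assert summary.control.sd == 0.0 and summary.control.sem == 0.0
    two = [_fake_result(0.2), _fake_result(0.3)]
    summary = segment.quantify_section(two, two, value="area_fraction")
    assert summary.control.mean == pytest.approx(0.25)
    assert summary.control.sem == pytest.approx(0.05)
    with pytest.raises(ValueError):
        segment.quantify_section([_fake_result(0.2)], two)
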