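import numpy as np
import pytest

import hdabquant as hq
from hdabquant.detection import (
    DetectionParams,
    expand_cells,
    filter_candidates,
    measure_features,
    preprocess,
    segment_nuclei,
)
from hdabquant.errors import InvalidParameterError, MeasurementError
from hdabquant.stains import StainChannels

PX = 0.5  # um/px used by the direct raster fixtures below


def _params(**kw):
    kw.setdefault("requested_pixel_size_um", PX)
    return DetectionParams(**kw)


def _disk_raster(shape, centers_px, r_px, value=1.0):
    img = np.zeros(shape)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    for cx, cy in centers_px:
        img = np.maximum(img, value * (np.hypot(xx - cx, yy - cy) <= r_px))
    return img


def test_params_validation():
    with pytest.raises(InvalidParameterError):
        DetectionParams(min_area_um2=400, max_area_um2=100)
    with pytest.raises(InvalidParameterError):
        DetectionParams(threshold_od=0.0)
    with pytest.raises(InvalidParameterError):
        DetectionParams(detection_image="dab")


def test_preprocess_flat_image_is_flat_then_zero():
    flat = np.full((64, 64), 0.4)
    pre, bg, px = preprocess(flat, PX, _params(background_radius_um=8))
    # opening of a constant is the constant; subtraction leaves zero
    assert np.allclose(pre, 0.0, atol=1e-9)
    assert np.allclose(bg, 0.4, atol=1e-9)
    pre_off, bg_off, _ = preprocess(flat, PX, _params(background_radius_um=0))
    assert np.allclose(pre_off, 0.4, atol=1e-6)
    assert not bg_off.any()


def test_preprocess_preserves_small_disk_over_wide_background():
    img = _disk_raster((128, 128), [(64, 64)], r_px=6, value=1.0)
    pre, _, _ = preprocess(img, PX, _params(background_radius_um=12, sigma_um=1.0))
    assert pre.max() > 0.2  # disk survives background subtraction


def test_segment_counts_blank_and_disjoint():
    assert segment_nuclei(np.zeros((64, 64)), PX, _params()).max() == 0
    two = _disk_raster((96, 96), [(24, 48), (72, 48)], r_px=8)
    labels = segment_nuclei(two, PX, _params())
    assert labels.max() == 2


def test_watershed_splits_dumbbell():
    """Two overlapping intensity cones with two maxima -> two nuclei."""
    yy, xx = np.mgrid[0:80, 0:80]
    r = 11.0
    cone = lambda cx, cy: np.clip(1 - np.hypot(xx - cx, yy - cy) / r, 0, None)
    dumbbell = np.maximum(cone(30, 40), cone(50, 40))
    labels = segment_nuclei(dumbbell, PX, _params(sigma_um=1.5))
    areas = np.bincount(labels.ravel())[1:]
    assert (areas * PX * PX >= _params().min_area_um2).sum() == 2


def test_area_filter_bounds():
    img = _disk_raster((96, 96), [(20, 20)], r_px=2)  # area ~3 um^2 < min 10
    img += _disk_raster((96, 96), [(60, 60)], r_px=8)
    labels = segment_nuclei(img, PX, _params())
    objs = filter_candidates(labels, np.zeros_like(img), PX, _params())
    assert len(objs) == 1
    assert objs[0].nucleus_mask.sum() * PX * PX >= _params().min_area_um2


def test_background_filter_drops_fold_candidates():
    img = _disk_raster((96, 96), [(30, 48), (70, 48)], r_px=8)
    background = np.zeros_like(img)
    background[:, 60:] = 0.6  # fold-like dark background under second disk
    labels = segment_nuclei(img, PX, _params())
    keep_all = filter_candidates(labels, background, PX, _params())
    filtered = filter_candidates(
        labels, background, PX, _params(max_background_intensity_od=0.3)
    )
    assert len(keep_all) == 2
    assert len(filtered) == 1


@pytest.mark.parametrize("param, values, direction", [
    ("threshold_od", [0.1, 0.2, 0.35, 0.5], "non-increasing"),
    ("min_area_um2", [5.0, 20.0, 40.0, 60.0], "non-increasing"),
    ("max_area_um2", [30.0, 60.0, 120.0, 400.0], "non-decreasing"),
])
def test_detection_count_monotonicity(clean_channels, param, values, direction):
    counts = []
    for v in values:
        p = DetectionParams(**{param: v})
        counts.append(len(hq.NucleusDetector(p).detect(clean_channels)))
    pairs = zip(counts, counts[1:])
    if direction == "non-increasing":
        assert all(a >= b for a, b in pairs), counts
    else:
        assert all(a <= b for a, b in pairs), counts


def test_translation_equivariance():
    # texture/noise-free scene: rolling is then an exact translation
    spec = hq.ImageSpec(seed=13, n_nuclei=30, width_px=320, height_px=320,
                        ecm_texture_od=0.0, noise_sd=0.0)
    rgb, gt, vec = hq.render_hdab_image(spec)
    shift_px = 6
    rolled = np.roll(rgb, (shift_px, shift_px), axis=(0, 1))
    detect = lambda im: hq.NucleusDetector().detect(
        hq.deconvolve(
            hq.rgb_to_od(im, vec.background_rgb, pixel_size_um=spec.pixel_size_um), vec
        )
    )
    a = detect(rgb)
    b = detect(rolled)
    assert len(a) == len(b)
    shift_um = shift_px * spec.pixel_size_um
    from scipy.spatial import cKDTree

    ca = np.asarray([o.centroid_um for o in a]) + shift_um
    cb = np.asarray([o.centroid_um for o in b])
    d, _ = cKDTree(cb).query(ca)
    assert d.max() < 0.5  # within one pixel (filter edge effects)


def test_cell_expansion_zero_keeps_nucleus(clean_channels):
    p = DetectionParams(cell_expansion_um=0.0)
    objs = hq.NucleusDetector(p).detect(clean_channels)
    for o in objs[:10]:
        assert np.array_equal(o.nucleus_mask, o.cell_mask)
        assert o.features["cell_area_um2"] == pytest.approx(
            o.features["nucleus_area_um2"]
        )


def test_cell_expansion_area_and_disjointness():
    # isolated disk: expanded area ~ pi (r+e)^2
    r_px, e_um = 8, 3.0
    img = _disk_raster((128, 128), [(64, 64)], r_px=r_px)
    p = _params(cell_expansion_um=e_um)
    labels = segment_nuclei(img, PX, p)
    objs = filter_candidates(labels, np.zeros_like(img), PX, p)
    objs = expand_cells(objs, img.shape, PX, p)
    expect = np.pi * (r_px * PX + e_um) ** 2
    got = objs[0].cell_mask.sum() * PX * PX
    assert got == pytest.approx(expect, rel=0.12)
    # two nuclei 2 um apart with 5 um expansion never overlap
    img2 = _disk_raster((128, 128), [(50, 64), (50 + 2 * r_px + 4, 64)], r_px=r_px)
    p2 = _params(cell_expansion_um=5.0)
    labels2 = segment_nuclei(img2, PX, p2)
    objs2 = filter_candidates(labels2, np.zeros_like(img2), PX, p2)
    objs2 = expand_cells(objs2, img2.shape, PX, p2)
    assert len(objs2) == 2
    full = np.zeros(img2.shape, dtype=int)
    for i, o in enumerate(objs2, 1):
        sub = full[o.cell_mask_slice]
        assert not ((sub > 0) & o.cell_mask).any()  # disjoint partition
        sub[o.cell_mask] = i


def _measure_mask(mask, px=PX, dab=0.0, hem=0.5):
    from hdabquant.detection import DetectionObject

    slc = (slice(0, mask.shape[0]), slice(0, mask.shape[1]))
    obj = DetectionObject(
        object_id="x", centroid_um=(0, 0),
        nucleus_polygon=None, cell_polygon=None,
        nucleus_mask_slice=slc, nucleus_mask=mask,
        cell_mask_slice=slc, cell_mask=mask,
    )
    ch = StainChannels(
        hematoxylin=np.full(mask.shape, hem),
        dab=np.full(mask.shape, dab),
        residual=np.zeros(mask.shape),
        pixel_size_um=px,
    )
    return measure_features(obj, ch)


def test_disk_circularity_near_one():
    yy, xx = np.mgrid[0:64, 0:64]
    disk = np.hypot(xx - 32, yy - 32) <= 10  # 5 um radius at 0.5 um/px
    feats = _measure_mask(disk)
    assert feats["nucleus_circularity"] >= 0.9


def test_square_circularity_near_pi_over_four():
    sq = np.zeros((64, 64), dtype=bool)
    sq[16:48, 16:48] = True
    feats = _measure_mask(sq)
    assert feats["nucleus_circularity"] == pytest.approx(np.pi / 4, abs=0.06)


def test_uniform_dab_field_mean(clean_channels):
    yy, xx = np.mgrid[0:32, 0:32]
    disk = np.hypot(xx - 16, yy - 16) <= 8
    feats = _measure_mask(disk, dab=0.37)
    assert feats["nucleus_dab_od_mean"] == pytest.approx(0.37, abs=1e-9)
    assert feats["cytoplasm_dab_od_mean"] == pytest.approx(0.37, abs=1e-9)


def test_degenerate_mask_raises():
    with pytest.raises(MeasurementError):
        _measure_mask(np.zeros((8, 8), dtype=bool))
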