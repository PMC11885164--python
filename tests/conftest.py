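import numpy as np
import pytest

import hdabquant as hq


@pytest.fixture(scope="session")
def vectors():
    return hq.default_hdab_vectors()


@pytest.fixture(scope="session")
def clean_scene():
    """One rendered clean field with ground truth (shared, read-only)."""
    spec = hq.ImageSpec(seed=7)
    rgb, gt, vec = hq.render_hdab_image(spec)
    return spec, rgb, gt, vec


@pytest.fixture(scope="session")
def clean_channels(clean_scene):
    spec, rgb, gt, vec = clean_scene
    od = hq.rgb_to_od(rgb, vec.background_rgb, pixel_size_um=spec.pixel_size_um)
    return hq.deconvolve(od, vec)


@pytest.fixture(scope="session")
def clean_objs(clean_channels):
    return hq.NucleusDetector(hq.DetectionParams()).detect(clean_channels)


def match_to_truth(objs, gt):
    """(n_true_hit, n_false, per-detection matched mask) vs ground truth."""
    from scipy.spatial import cKDTree

    cents = np.array([o.centroid_um for o in objs])
    tree = cKDTree(gt.centroids_um)
    d, idx = tree.query(cents)
    matched = d <= gt.radii_um[idx]
    tp = len(set(idx[matched]))
    fp = int((~matched).sum()) + int(matched.sum() - tp)
    return tp, fp, matched


def detection_precision_recall(objs, gt):
    tp, fp, _ = match_to_truth(objs, gt)
    fn = len(gt.labels) - tp
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    return precision, recall
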