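"""Nucleus detection on the deconvolved detection image.

The detector mirrors the classic watershed cell-detection recipe used in
digital pathology: smooth the stain-OD raster, subtract a morphological
local-background estimate (which also exposes tissue folds, whose
background is darker than usual), threshold, split merged nuclei at
intensity saddles with a marker-controlled watershed, filter by area and
local background, then expand each nucleus into an approximate cell region
by a nearest-nucleus constrained dilation.

All physical parameters are in micrometres; pixel geometry is derived from
the raster's pixel size.  Detections are ordered by (centroid y, centroid x)
so object identifiers are stable across runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage as ndi
from skimage import measure, morphology, segmentation, transform
from skimage.feature import peak_local_max

from .errors import InvalidParameterError, MeasurementError
from .stains import StainChannels

log = logging.getLogger(__name__)

LABEL_POSITIVE = "PositiveCell"
LABEL_NEGATIVE = "NegativeCell"
LABEL_NOCELL = "NoCell"
LABEL_UNCLASSIFIED = "Unclassified"
KNOWN_LABELS = (LABEL_POSITIVE, LABEL_NEGATIVE, LABEL_NOCELL)

#: Names of the per-object features, in canonical column order.
FEATURE_NAMES = (
    "nucleus_area_um2",
    "nucleus_perimeter_um",
    "nucleus_circularity",
    "nucleus_hematoxylin_od_mean",
    "nucleus_hematoxylin_od_max",
    "nucleus_dab_od_mean",
    "nucleus_dab_od_max",
    "cell_area_um2",
    "cell_dab_od_mean",
    "cytoplasm_dab_od_mean",
)


@dataclass
class DetectionParams:
    """Tunable cell-detection parameters (micrometre units).

    ``background_radius_um = 0`` disables local-background subtraction;
    a very large ``max_background_intensity_od`` disables fold/artifact
    rejection.  ``min_area_um2``/``max_area_um2`` bound accepted nucleus
    sizes; candidates larger than the maximum are first offered to the
    watershed splitter.
    """

    detection_image: str = "od_sum"  # or "hematoxylin"
    requested_pixel_size_um: float = 0.5
    background_radius_um: float = 8.0
    median_radius_um: float = 0.0
    sigma_um: float = 1.5
    min_area_um2: float = 10.0
    max_area_um2: float = 400.0
    threshold_od: float = 0.15
    max_background_intensity_od: float = 1e6
    cell_expansion_um: float = 5.0

    def __post_init__(self):
        if self.detection_image not in ("od_sum", "hematoxylin"):
            raise InvalidParameterError(
                f"detection_image must be 'od_sum' or 'hematoxylin', "
                f"got {self.detection_image!r}"
            )
        if self.requested_pixel_size_um <= 0 or self.sigma_um <= 0:
            raise InvalidParameterError("pixel size and sigma must be > 0")
        if self.background_radius_um < 0 or self.median_radius_um < 0:
            raise InvalidParameterError("radii must be >= 0")
        if not (0 < self.min_area_um2 < self.max_area_um2):
            raise InvalidParameterError("need 0 < min_area_um2 < max_area_um2")
        if self.threshold_od <= 0 or self.max_background_intensity_od <= 0:
            raise InvalidParameterError("OD thresholds must be > 0")
        if self.cell_expansion_um < 0:
            raise InvalidParameterError("cell_expansion_um must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "DetectionParams":
        return cls(**d)


@dataclass
class DetectionObject:
    """One detected nucleus/cell with morphometric and OD features."""

    object_id: str
    centroid_um: tuple  # (x, y), origin top-left, y downward
    nucleus_polygon: np.ndarray  # closed (N, 2) polygon, um, CCW
    cell_polygon: np.ndarray
    features: dict = field(default_factory=dict)
    label: str = LABEL_UNCLASSIFIED
    parent_region: str = "unassigned"
    # raster-space bookkeeping used internally for measurement
    nucleus_mask_slice: tuple = None
    nucleus_mask: np.ndarray = None
    cell_mask_slice: tuple = None
    cell_mask: np.ndarray = None


def _disk_radius_px(radius_um: float, px: float) -> int:
    return max(1, int(round(radius_um / px)))


def preprocess(det: np.ndarray, native_pixel_size_um: float, params: DetectionParams):
    """Resample, denoise and background-correct the detection raster.

    Returns ``(pre, background, pixel_size_um)`` where ``background`` is the
    local background estimate (zeros when disabled) used later to reject
    candidates over folds/artifacts.
    """
    det = np.asarray(det, dtype=float)
    px = float(native_pixel_size_um)
    req = params.requested_pixel_size_um
    if req > px * (1 + 1e-9):
        # Area-weighted downsampling keeps OD statistics stable.
        scale = px / req
        new_shape = (
            max(1, int(round(det.shape[0] * scale))),
            max(1, int(round(det.shape[1] * scale))),
        )
        det = transform.resize(
            det, new_shape, order=1, anti_aliasing=True, preserve_range=True
        )
        px = req
    if params.median_radius_um > 0:
        r = _disk_radius_px(params.median_radius_um, px)
        det = ndi.median_filter(det, footprint=morphology.disk(r))
    det = ndi.gaussian_filter(det, sigma=params.sigma_um / px)
    if params.background_radius_um > 0:
        if params.background_radius_um < params.sigma_um:
            log.warning(
                "background_radius_um (%.3g) < sigma_um (%.3g); background "
                "estimate may track the signal",
                params.background_radius_um,
                params.sigma_um,
            )
        r = _disk_radius_px(params.background_radius_um, px)
        background = morphology.opening(det, morphology.disk(r))
        det = np.clip(det - background, 0.0, None)
    else:
        background = np.zeros_like(det)
    return det, background, px


def segment_nuclei(pre: np.ndarray, pixel_size_um: float, params: DetectionParams):
    """Threshold and watershed-split the preprocessed raster.

    Returns a labelled integer image; merged nuclei (multiple regional
    maxima separated by more than sigma) are split at intensity saddles by
    a marker-controlled watershed seeded at the maxima.
    """
    mask = pre >= params.threshold_od
    if not mask.any():
        return np.zeros(pre.shape, dtype=np.int32)
    min_sep_px = max(1, int(round(params.sigma_um / pixel_size_um)))
    peaks = peak_local_max(
        pre, min_distance=min_sep_px, labels=measure.label(mask), exclude_border=False
    )
    if len(peaks) == 0:
        return measure.label(mask).astype(np.int32)
    markers = np.zeros(pre.shape, dtype=np.int32)
    # Deterministic marker numbering: peak_local_max orders by intensity;
    # renumber by (row, col) for run-to-run stability.
    order = np.lexsort((peaks[:, 1], peaks[:, 0]))
    for i, idx in enumerate(order, start=1):
        markers[tuple(peaks[idx])] = i
    labels = segmentation.watershed(-pre, markers=markers, mask=mask)
    return labels.astype(np.int32)


def filter_candidates(
    labels: np.ndarray,
    background: np.ndarray,
    pixel_size_um: float,
    params: DetectionParams,
):
    """Apply area and local-background filters; build DetectionObjects.

    Candidates whose mean local background OD exceeds
    ``max_background_intensity_od`` sit on folds or dense debris and are
    rejected.  Survivors get sub-pixel polygon outlines (marching squares)
    and stable ids ordered by (centroid y, centroid x).
    """
    px2 = pixel_size_um**2
    objs = []
    for rp in measure.regionprops(labels):
        area_um2 = rp.area * px2
        if area_um2 < params.min_area_um2 or area_um2 > params.max_area_um2:
            continue
        mean_bg = float(background[rp.slice][rp.image].mean())
        if mean_bg > params.max_background_intensity_od:
            continue
        poly = _mask_to_polygon_um(rp.image, rp.slice, pixel_size_um)
        cy, cx = rp.centroid
        objs.append(
            DetectionObject(
                object_id="",
                centroid_um=(cx * pixel_size_um, cy * pixel_size_um),
                nucleus_polygon=poly,
                cell_polygon=poly,
                nucleus_mask_slice=rp.slice,
                nucleus_mask=rp.image,
                cell_mask_slice=rp.slice,
                cell_mask=rp.image,
            )
        )
    objs.sort(key=lambda o: (o.centroid_um[1], o.centroid_um[0]))
    for i, o in enumerate(objs, start=1):
        o.object_id = f"obj-{i:05d}"
    return objs


def _mask_to_polygon_um(mask: np.ndarray, slc, pixel_size_um: float) -> np.ndarray:
    padded = np.pad(mask.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    if not contours:
        raise MeasurementError("candidate has no contour")
    contour = max(contours, key=len)  # outer boundary
    rc = contour - 1.0  # undo padding
    r0, c0 = slc[0].start, slc[1].start
    xy = np.stack([(rc[:, 1] + c0) * pixel_size_um, (rc[:, 0] + r0) * pixel_size_um], 1)
    # close the ring and orient counter-clockwise (image coords: y down)
    if not np.allclose(xy[0], xy[-1]):
        xy = np.vstack([xy, xy[:1]])
    area2 = np.sum(xy[:-1, 0] * xy[1:, 1] - xy[1:, 0] * xy[:-1, 1])
    if area2 > 0:  # clockwise in y-down convention -> reverse
        xy = xy[::-1]
    return xy


def expand_cells(objs, labels_shape, pixel_size_um: float, params: DetectionParams):
    """Grow nuclei into cell regions by ``cell_expansion_um``.

    Expansion is a nearest-nucleus partition (skimage ``expand_labels``),
    so neighbouring cells never overlap; zero expansion leaves the cell
    equal to the nucleus.
    """
    if params.cell_expansion_um == 0 or not objs:
        return objs
    lab = np.zeros(labels_shape, dtype=np.int32)
    for i, o in enumerate(objs, start=1):
        sub = lab[o.nucleus_mask_slice]
        sub[o.nucleus_mask] = i
    dist_px = params.cell_expansion_um / pixel_size_um
    expanded = segmentation.expand_labels(lab, distance=dist_px)
    slices = ndi.find_objects(expanded)
    for i, o in enumerate(objs, start=1):
        slc = slices[i - 1]
        cmask = expanded[slc] == i
        o.cell_mask_slice = slc
        o.cell_mask = cmask
        o.cell_polygon = _mask_to_polygon_um(cmask, slc, pixel_size_um)
    return objs


def measure_features(obj: DetectionObject, channels: StainChannels) -> dict:
    """Morphometry plus stain-OD statistics for one detection.

    Circularity is 4*pi*A/P^2 (1 for an ideal disk, pi/4 for a square in
    the continuum limit; the rasterized estimate carries a small positive
    bias at coarse pixel sizes).  Cytoplasm statistics are over cell-minus-nucleus; for a
    zero-expansion cell they fall back to the nucleus mean.
    """
    if obj.nucleus_mask is None or not obj.nucleus_mask.any():
        raise MeasurementError(f"object {obj.object_id} has an empty nucleus mask")
    px = channels.pixel_size_um
    px2 = px * px
    nmask, nslc = obj.nucleus_mask, obj.nucleus_mask_slice
    area = float(nmask.sum() * px2)
    if area <= 0:
        raise MeasurementError(f"object {obj.object_id} has zero area")
    perim = float(measure.perimeter(nmask, neighborhood=4) * px)
    circ = float(4 * np.pi * area / perim**2) if perim > 0 else 0.0
    hem_n = channels.hematoxylin[nslc][nmask]
    dab_n = channels.dab[nslc][nmask]
    cmask, cslc = obj.cell_mask, obj.cell_mask_slice
    dab_c = channels.dab[cslc][cmask]
    cell_area = float(cmask.sum() * px2)
    # cytoplasm = cell minus nucleus (in the cell's frame)
    nuc_in_cell = np.zeros_like(cmask)
    rr = slice(nslc[0].start - cslc[0].start, nslc[0].stop - cslc[0].start)
    cc = slice(nslc[1].start - cslc[1].start, nslc[1].stop - cslc[1].start)
    nuc_in_cell[rr, cc] = nmask
    cyto = cmask & ~nuc_in_cell
    dab_cyto = channels.dab[cslc][cyto] if cyto.any() else dab_n
    feats = {
        "nucleus_area_um2": area,
        "nucleus_perimeter_um": perim,
        "nucleus_circularity": min(circ, 1.0),
        "nucleus_hematoxylin_od_mean": float(hem_n.mean()),
        "nucleus_hematoxylin_od_max": float(hem_n.max()),
        "nucleus_dab_od_mean": float(dab_n.mean()),
        "nucleus_dab_od_max": float(dab_n.max()),
        "cell_area_um2": cell_area,
        "cell_dab_od_mean": float(dab_c.mean()),
        "cytoplasm_dab_od_mean": float(dab_cyto.mean()),
    }
    obj.features = feats
    return feats


class NucleusDetector:
    """End-to-end detector: channels -> measured DetectionObjects.

    Thin orchestration over :func:`preprocess`, :func:`segment_nuclei`,
    :func:`filter_candidates`, :func:`expand_cells` and
    :func:`measure_features`.
    """

    def __init__(self, params: DetectionParams | None = None):
        self.params = params or DetectionParams()

    def detect(self, channels: StainChannels):
        from .stains import detection_image

        p = self.params
        det = detection_image(channels, p.detection_image)
        pre, background, px = preprocess(det, channels.pixel_size_um, p)
        labels = segment_nuclei(pre, px, p)
        objs = filter_candidates(labels, background, px, p)
        objs = expand_cells(objs, pre.shape, px, p)
        meas = _resample_channels(channels, px)
        for o in objs:
            measure_features(o, meas)
        return objs


def _resample_channels(channels: StainChannels, pixel_size_um: float) -> StainChannels:
    """Bring stain channels onto the detector's working grid."""
    if abs(channels.pixel_size_um - pixel_size_um) < 1e-9:
        return channels
    scale = channels.pixel_size_um / pixel_size_um
    shape = (
        max(1, int(round(channels.hematoxylin.shape[0] * scale))),
        max(1, int(round(channels.hematoxylin.shape[1] * scale))),
    )

    def rs(a):
        return transform.resize(a, shape, order=1, anti_aliasing=True, preserve_range=True)

    return StainChannels(
        hematoxylin=rs(channels.hematoxylin),
        dab=rs(channels.dab),
        residual=rs(channels.residual),
        pixel_size_um=pixel_size_um,
    )
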