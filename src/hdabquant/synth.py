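"""Synthetic H-DAB images, rater tables and project fixtures.

Emulates the imaging conditions the pipeline targets: sparse nuclei in an
extracellular-matrix-dominated field (disc/cartilage-like low cellularity),
hematoxylin-counterstained nuclei with DAB chromogen over immunopositive
ones, diffuse ECM DAB texture, and two artifact classes that plague
real slides — dense DAB debris and fold-like high-OD streaks.  Nuclei are
soft-edged disks so area/circularity ground truth stays analytic.

Every generator is a pure function of its spec (including the seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage as ndi

from .errors import GenerationError, InvalidParameterError
from .stains import StainVectors, default_hdab_vectors, od_to_rgb

LABEL_POSITIVE = "PositiveCell"
LABEL_NEGATIVE = "NegativeCell"
LABEL_NOCELL = "NoCell"


@dataclass
class ImageSpec:
    """Conditions for one synthetic H-DAB field.

    Defaults describe a clean 256 x 256 um field at 0.5 um/px with 100
    chondrocyte-like nuclei (radius 4 +/- 1 um), strong nuclear
    counterstain, clearly separated DAB levels for positive vs negative
    cells, and faint diffuse ECM DAB.
    """

    width_px: int = 512
    height_px: int = 512
    pixel_size_um: float = 0.5
    n_nuclei: int = 100
    positive_fraction: float = 0.3
    nucleus_radius_um: float = 4.0
    nucleus_radius_jitter_um: float = 1.0
    dab_od_positive: float = 0.6
    dab_od_negative: float = 0.05
    hematoxylin_od: float = 0.6
    ecm_texture_od: float = 0.06
    n_artifacts: int = 0
    blur_sigma_um: float = 0.5
    noise_sd: float = 1.0  # 8-bit intensity units
    min_separation_um: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.positive_fraction <= 1.0):
            raise InvalidParameterError("positive_fraction must be in [0, 1]")
        if self.nucleus_radius_um <= 0 or self.pixel_size_um <= 0:
            raise InvalidParameterError("radii and pixel size must be > 0")


@dataclass
class GroundTruth:
    centroids_um: np.ndarray  # (n, 2) x, y
    radii_um: np.ndarray
    labels: list
    artifact_mask: np.ndarray  # bool, raster-shaped
    region_polygons: list  # [(name, [(x, y), ...])]

    @property
    def true_positivity_percent(self) -> float:
        n_pos = sum(1 for l in self.labels if l == LABEL_POSITIVE)
        n = len(self.labels)
        return 100.0 * n_pos / n if n else float("nan")


@dataclass
class RaterSpec:
    """Variance components for a subjects x raters positivity table.

    Defaults mirror a 17-slide, 3-rater reliability design with moderate
    between-slide spread and smaller rater bias/error.
    """

    n_subjects: int = 17
    k_raters: int = 3
    subject_sd: float = 10.0
    rater_bias_sd: float = 2.0
    error_sd: float = 5.0
    grand_mean: float = 50.0
    seed: int = 0

    def __post_init__(self):
        if min(self.subject_sd, self.rater_bias_sd, self.error_sd) < 0:
            raise InvalidParameterError("all sds must be >= 0")

    @property
    def theoretical_icc_single(self) -> float:
        """Absolute-agreement single-measure ICC implied by the components."""
        s2 = self.subject_sd**2
        return s2 / (s2 + self.rater_bias_sd**2 + self.error_sd**2)


def _place_nuclei(spec: ImageSpec, rng) -> tuple:
    w_um = spec.width_px * spec.pixel_size_um
    h_um = spec.height_px * spec.pixel_size_um
    centers, radii = [], []
    max_tries = max(2000, spec.n_nuclei * 500)
    tries = 0
    margin = spec.nucleus_radius_um + spec.nucleus_radius_jitter_um + 1.0
    while len(centers) < spec.n_nuclei:
        if tries >= max_tries:
            raise GenerationError(
                f"could not pack {spec.n_nuclei} non-overlapping nuclei "
                f"({len(centers)} placed)"
            )
        tries += 1
        r = spec.nucleus_radius_um + rng.uniform(
            -spec.nucleus_radius_jitter_um, spec.nucleus_radius_jitter_um
        )
        r = max(0.5, r)
        x = rng.uniform(margin, w_um - margin)
        y = rng.uniform(margin, h_um - margin)
        ok = True
        for (cx, cy), cr in zip(centers, radii):
            if (x - cx) ** 2 + (y - cy) ** 2 < (r + cr + spec.min_separation_um) ** 2:
                ok = False
                break
        if ok:
            centers.append((x, y))
            radii.append(r)
    return np.asarray(centers), np.asarray(radii)


def _soft_disk(shape, cx_px, cy_px, r_px, edge_px=1.0):
    y0 = max(0, int(cy_px - r_px - 3))
    y1 = min(shape[0], int(cy_px + r_px + 4))
    x0 = max(0, int(cx_px - r_px - 3))
    x1 = min(shape[1], int(cx_px + r_px + 4))
    yy, xx = np.mgrid[y0:y1, x0:x1]
    d = np.hypot(xx - cx_px, yy - cy_px)
    v = np.clip((r_px - d) / edge_px + 0.5, 0.0, 1.0)
    return (slice(y0, y1), slice(x0, x1)), v


def render_hdab_image(spec: ImageSpec, vectors: StainVectors | None = None,
                      *, quantize: bool = True):
    """Render one field; returns ``(rgb, ground_truth, vectors)``.

    OD maps for hematoxylin/DAB are composed from soft-edged nucleus disks,
    diffuse ECM texture and optional artifacts, passed through the forward
    Beer-Lambert model with the given stain vectors, blurred and noised.
    """
    vectors = vectors or default_hdab_vectors()
    rng = np.random.default_rng(spec.seed)
    shape = (spec.height_px, spec.width_px)
    px = spec.pixel_size_um
    hem = np.zeros(shape)
    dab = np.zeros(shape)

    centers, radii = (
        _place_nuclei(spec, rng) if spec.n_nuclei else (np.empty((0, 2)), np.empty(0))
    )
    n_pos = int(round(spec.n_nuclei * spec.positive_fraction))
    labels = [LABEL_POSITIVE] * n_pos + [LABEL_NEGATIVE] * (spec.n_nuclei - n_pos)
    labels = [labels[i] for i in rng.permutation(spec.n_nuclei)]
    for (x, y), r, lab in zip(centers, radii, labels):
        slc, v = _soft_disk(shape, x / px, y / px, r / px)
        hem[slc] = np.maximum(hem[slc], spec.hematoxylin_od * v)
        level = spec.dab_od_positive if lab == LABEL_POSITIVE else spec.dab_od_negative
        dab[slc] = np.maximum(dab[slc], level * v)

    if spec.ecm_texture_od > 0:
        tex = ndi.gaussian_filter(rng.standard_normal(shape), sigma=4.0 / px)
        tex = np.clip(tex / (tex.std() + 1e-12), 0, None) * spec.ecm_texture_od
        dab += tex

    artifact_mask = np.zeros(shape, dtype=bool)
    for i in range(spec.n_artifacts):
        if i % 2 == 0:
            _add_debris(dab, artifact_mask, rng, spec)
        else:
            _add_fold(hem, dab, artifact_mask, rng, spec)

    if spec.blur_sigma_um > 0:
        hem = ndi.gaussian_filter(hem, spec.blur_sigma_um / px)
        dab = ndi.gaussian_filter(dab, spec.blur_sigma_um / px)

    od = hem[..., None] * vectors.hematoxylin + dab[..., None] * vectors.dab
    rgb = od_to_rgb(od, vectors.background_rgb, quantize=False)
    if spec.noise_sd > 0:
        rgb = rgb + rng.normal(0.0, spec.noise_sd, rgb.shape)
    rgb = np.clip(rgb, 0, 255)
    if quantize:
        rgb = np.rint(rgb).astype(np.uint8)

    w_um, h_um = spec.width_px * px, spec.height_px * px
    region = ("tissue", [(0.0, 0.0), (w_um, 0.0), (w_um, h_um), (0.0, h_um)])
    gt = GroundTruth(
        centroids_um=centers,
        radii_um=radii,
        labels=labels,
        artifact_mask=artifact_mask,
        region_polygons=[region],
    )
    return rgb, gt, vectors


def _add_debris(dab, mask, rng, spec: ImageSpec):
    """Dense irregular DAB debris blob, larger than any nucleus."""
    px = spec.pixel_size_um
    shape = dab.shape
    r_um = rng.uniform(12.0, 18.0)
    cx = rng.uniform(r_um, spec.width_px * px - r_um) / px
    cy = rng.uniform(r_um, spec.height_px * px - r_um) / px
    slc, v = _soft_disk(shape, cx, cy, r_um / px, edge_px=3.0)
    bump = ndi.gaussian_filter(rng.standard_normal(v.shape), 2.0)
    v = np.clip(v * (1.0 + 0.4 * bump), 0, 1.2)
    dab[slc] = np.maximum(dab[slc], 0.9 * v)
    mask[slc] |= v > 0.3


def _add_fold(hem, dab, mask, rng, spec: ImageSpec):
    """Fold-like streak: a broad band of elevated OD in both stains."""
    px = spec.pixel_size_um
    h, w = hem.shape
    yy, xx = np.mgrid[0:h, 0:w]
    theta = rng.uniform(0, np.pi)
    c = rng.uniform(0.3, 0.7)
    d = (xx - c * w) * np.cos(theta) + (yy - c * h) * np.sin(theta)
    half_w_px = rng.uniform(10.0, 16.0) / px
    band = np.clip(1.0 - np.abs(d) / half_w_px, 0, 1)
    hem += 0.45 * band
    dab += 0.45 * band
    mask |= band > 0.2


def simulate_rater_table(spec: RaterSpec):
    """Simulate a subjects x raters positivity table.

    ``value[i, j] = grand_mean + subject_i + bias_j + error_ij`` with
    independent normal components; values are clipped to [0, 100] and the
    clip count is reported.  Returns ``(DataFrame, theoretical_icc)``.
    """
    rng = np.random.default_rng(spec.seed)
    subj = rng.normal(0, spec.subject_sd, spec.n_subjects)
    bias = rng.normal(0, spec.rater_bias_sd, spec.k_raters)
    err = rng.normal(0, spec.error_sd, (spec.n_subjects, spec.k_raters))
    vals = spec.grand_mean + subj[:, None] + bias[None, :] + err
    clipped = np.clip(vals, 0.0, 100.0)
    n_clipped = int((clipped != vals).sum())
    df = pd.DataFrame(
        clipped,
        index=[f"slide_{i + 1:02d}" for i in range(spec.n_subjects)],
        columns=[f"rater_{j + 1}" for j in range(spec.k_raters)],
    )
    df.attrs["n_clipped"] = n_clipped
    return df, spec.theoretical_icc_single


def harvest_training_set(objs, gt: GroundTruth, match_slack_um: float = 0.0):
    """Label detections from ground truth, the way a user annotates.

    A detection whose centroid falls within (radius + slack) of a true
    nucleus adopts that nucleus's label; unmatched detections — texture
    blobs, debris, fold fragments — become NoCell examples.  Returns a
    :class:`hdabquant.classify.TrainingSet`.
    """
    from .classify import TrainingSet

    ts = TrainingSet()
    if not objs:
        return ts
    if len(gt.labels):
        from scipy.spatial import cKDTree

        tree = cKDTree(gt.centroids_um)
        d, idx = tree.query(np.asarray([o.centroid_um for o in objs]))
    else:
        d = np.full(len(objs), np.inf)
        idx = np.zeros(len(objs), dtype=int)
    for o, dist, i in zip(objs, d, idx):
        if len(gt.labels) and dist <= gt.radii_um[i] + match_slack_um:
            ts.add(o.features, gt.labels[i], provenance=o.object_id)
        else:
            ts.add(o.features, LABEL_NOCELL, provenance=o.object_id)
    return ts


def write_image(path, rgb: np.ndarray, pixel_size_um: float):
    """Write a TIFF (with resolution tags) or PNG raster."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        per_cm = 10000.0 / pixel_size_um
        tifffile.imwrite(
            path, rgb, resolution=(per_cm, per_cm), resolutionunit="CENTIMETER"
        )
    else:
        import imageio.v3 as iio

        iio.imwrite(path, rgb)
    return path


def make_project_fixture(
    n_images: int,
    spec: ImageSpec,
    outdir,
    antibody: str = "IL1B",
    dab_cut: float = 0.25,
    classifier: str = "threshold",
):
    """Write a ready-to-run project: images, regions, annotations, inventory.

    Image ``i`` is rendered from ``spec`` with seed ``spec.seed + i``.  With
    ``classifier="threshold"`` the serialized model is a DAB-OD cut at
    ``dab_cut`` (deterministic baseline); with ``"forest"`` a random forest
    is trained on detections of the first image labelled from ground truth
    (artifact detections become NoCell examples).  Training point
    annotations are written either way.  Returns
    ``(ProjectConfig, ground_truths)``.
    """
    import dataclasses

    from .batch import ImageEntry, ProjectConfig
    from .classify import ThresholdCellClassifier
    from .regions import write_geojson_points, write_geojson_regions
    from .regions import RegionAnnotation
    from shapely.geometry import Polygon

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    vectors = default_hdab_vectors()
    entries, truths, inv_rows = [], [], []
    for i in range(n_images):
        ispec = dataclasses.replace(spec, seed=spec.seed + i)
        rgb, gt, _ = render_hdab_image(ispec, vectors)
        scan_id = f"SCAN{i + 1:03d}"
        img_name = f"{scan_id}.tiff"
        write_image(outdir / img_name, rgb, ispec.pixel_size_um)
        regions = [
            RegionAnnotation(name=name, geometry=Polygon(poly))
            for name, poly in gt.region_polygons
        ]
        region_name = f"{scan_id}.regions.geojson"
        write_geojson_regions(regions, outdir / region_name)
        entries.append(
            ImageEntry(
                path=img_name,
                id_slidescanning=scan_id,
                regions_geojson=region_name,
                pixel_size_um=ispec.pixel_size_um,
            )
        )
        truths.append(gt)
        inv_rows.append(
            {
                "ID_Slidescanning": scan_id,
                "sample_id": f"sample_{i + 1:02d}",
                "antibody": antibody,
            }
        )
        if i == 0 and len(gt.labels):
            pts = [tuple(c) for c in gt.centroids_um]
            write_geojson_points(
                pts, gt.labels, outdir / f"{scan_id}.training.geojson"
            )
    pd.DataFrame(inv_rows).to_csv(outdir / "inventory.csv", index=False)
    if classifier == "forest":
        model_file = "classifier.joblib"
        _train_fixture_forest(outdir, entries[0], vectors, spec, truths[0],
                              outdir / model_file)
    else:
        model_file = "classifier.json"
        ThresholdCellClassifier(dab_cut).save(outdir / model_file)
    config = ProjectConfig(
        project_name="synthetic-project",
        antibody=antibody,
        images=entries,
        classifier=model_file,
        stain_vectors=vectors.to_dict(),
        seed=spec.seed,
        base_dir=outdir,
    )
    yaml_payload = {
        "project_name": config.project_name,
        "antibody": config.antibody,
        "classifier": config.classifier,
        "seed": config.seed,
        "stain_vectors": config.stain_vectors,
        "images": [dataclasses.asdict(e) for e in entries],
    }
    (outdir / "project.yml").write_text(yaml.safe_dump(yaml_payload, sort_keys=False))
    return config, truths


def _train_fixture_forest(outdir, entry, vectors, spec, gt, model_path):
    from .classify import train_classifier
    from .detection import DetectionParams, NucleusDetector
    from .stains import deconvolve, rgb_to_od

    from .batch import load_image

    img, px = load_image(outdir / entry.path, entry.pixel_size_um)
    od = rgb_to_od(img, vectors.background_rgb, pixel_size_um=px)
    objs = NucleusDetector(DetectionParams()).detect(deconvolve(od, vectors))
    ts = harvest_training_set(objs, gt)
    model = train_classifier(ts, seed=spec.seed)
    model.save(model_path)
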