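"""Project-level batch analysis.

One project = one antibody.  For every image the pipeline runs
deconvolution -> region selection -> nucleus detection -> object
classification -> parent assignment, then writes one tab-separated results
file per image (named by the blinded scanner id, ``<ID_Slidescanning>.txt``)
into a results folder.  Sample identity is joined only in postprocessing,
preserving blinded analysis.

Results-file dialect (UTF-8, tab separator, "." decimal): one row per
detection with columns ``Image, Object ID, Classification, Parent,
Centroid X um, Centroid Y um`` followed by the feature columns of
:data:`hdabquant.detection.FEATURE_NAMES`.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .classify import classify, load_classifier
from .detection import (
    FEATURE_NAMES,
    LABEL_NEGATIVE,
    LABEL_NOCELL,
    LABEL_POSITIVE,
    DetectionParams,
    NucleusDetector,
)
from .errors import HdabQuantError, InvalidParameterError, UndefinedRateError
from .regions import assign_parent, read_geojson_regions, threshold_tissue
from .stains import StainVectors, deconvolve, default_hdab_vectors, rgb_to_od

log = logging.getLogger(__name__)

RESULTS_COLUMNS = (
    "Image",
    "Object ID",
    "Classification",
    "Parent",
    "Centroid X um",
    "Centroid Y um",
) + FEATURE_NAMES


@dataclass
class ImageEntry:
    path: str
    id_slidescanning: str
    control: bool = False
    pixel_size_um: float | None = None
    regions_geojson: str | None = None
    stain_vectors: dict | None = None
    detection_params: dict | None = None


@dataclass
class ProjectConfig:
    """One antibody, many images; see the project YAML schema in docs."""

    project_name: str
    antibody: str
    images: list
    classifier: str
    output_folder: str = "results"
    seed: int = 0
    stain_vectors: dict | None = None  # project-wide default vectors
    detection_params: dict | None = None
    regions_source: str = "geojson"  # or "thresholder"
    thresholder: dict = field(default_factory=dict)
    control_max_rate: float = 5.0
    base_dir: Path = field(default_factory=Path)

    def __post_init__(self):
        ids = [im.id_slidescanning for im in self.images]
        if len(set(ids)) != len(ids):
            raise InvalidParameterError("ID_Slidescanning values must be unique")

    @classmethod
    def from_yaml(cls, path) -> "ProjectConfig":
        path = Path(path)
        d = yaml.safe_load(path.read_text())
        images = [ImageEntry(**im) for im in d.pop("images")]
        return cls(images=images, base_dir=path.parent, **d)


def load_image(path, pixel_size_um=None):
    """Read an RGB raster; pixel size from TIFF resolution tags if present."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        with tifffile.TiffFile(path) as tf:
            page = tf.pages[0]
            img = page.asarray()
            if pixel_size_um is None:
                tags = page.tags
                if "XResolution" in tags and "ResolutionUnit" in tags:
                    num, den = tags["XResolution"].value
                    unit = tags["ResolutionUnit"].value
                    per_unit = num / den
                    if per_unit > 0:
                        unit_um = {2: 25400.0, 3: 10000.0}.get(int(unit))
                        if unit_um:
                            pixel_size_um = unit_um / per_unit
    else:
        import imageio.v3 as iio

        img = iio.imread(path)
    if pixel_size_um is None:
        raise InvalidParameterError(
            f"pixel size not found in {path.name}; set pixel_size_um in the project"
        )
    if img.ndim == 3 and img.shape[2] == 4:
        img = img[..., :3]
    return np.asarray(img), float(pixel_size_um)


def positivity_rate(n_pos: int, n_neg: int) -> float:
    """Percent positive of countable cells; NoCell never enters the rate."""
    if n_pos < 0 or n_neg < 0:
        raise InvalidParameterError("counts must be non-negative")
    if n_pos + n_neg == 0:
        raise UndefinedRateError("no countable (positive+negative) cells")
    return 100.0 * n_pos / (n_pos + n_neg)


@dataclass
class PositivityRecord:
    sample_id: str
    antibody: str
    image: str
    region: str
    n_positive: int
    n_negative: int
    n_nocell: int
    positivity_rate: float | None  # None marks undefined (no countable cells)
    pooled: bool = False


def positivity_records(objs, antibody: str, image_id: str, sample_id: str = ""):
    """Per-region records plus one pooled row (region ``ALL``, flagged).

    Unassigned detections are excluded from per-region counts and from the
    pooled row.
    """
    counts = {}
    for o in objs:
        if o.parent_region == "unassigned":
            continue
        c = counts.setdefault(o.parent_region, {"pos": 0, "neg": 0, "no": 0})
        if o.label == LABEL_POSITIVE:
            c["pos"] += 1
        elif o.label == LABEL_NEGATIVE:
            c["neg"] += 1
        elif o.label == LABEL_NOCELL:
            c["no"] += 1
    records = []

    def _mk(region, c, pooled=False):
        try:
            rate = positivity_rate(c["pos"], c["neg"])
        except UndefinedRateError:
            rate = None
        return PositivityRecord(
            sample_id, antibody, image_id, region, c["pos"], c["neg"], c["no"], rate,
            pooled=pooled,
        )

    for region in sorted(counts):
        records.append(_mk(region, counts[region]))
    if counts:
        pooled = {
            "pos": sum(c["pos"] for c in counts.values()),
            "neg": sum(c["neg"] for c in counts.values()),
            "no": sum(c["no"] for c in counts.values()),
        }
        records.append(_mk("ALL", pooled, pooled=True))
    return records


def write_results_file(objs, image_meta: dict, path) -> Path:
    """Write the per-image detection table in the documented TSV dialect."""
    rows = []
    image_name = image_meta.get("image", "")
    for o in objs:
        row = {
            "Image": image_name,
            "Object ID": o.object_id,
            "Classification": o.label,
            "Parent": o.parent_region,
            "Centroid X um": o.centroid_um[0],
            "Centroid Y um": o.centroid_um[1],
        }
        for f in FEATURE_NAMES:
            row[f] = o.features.get(f, float("nan"))
        rows.append(row)
    df = pd.DataFrame(rows, columns=list(RESULTS_COLUMNS))
    path = Path(path)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g", encoding="utf-8")
    return path


def _resolve_vectors(spec) -> StainVectors:
    if spec is None:
        return default_hdab_vectors()
    if isinstance(spec, StainVectors):
        return spec
    return StainVectors.from_dict(spec)


def _resolve_params(spec) -> DetectionParams:
    if spec is None:
        return DetectionParams()
    if isinstance(spec, DetectionParams):
        return spec
    return DetectionParams.from_dict(spec)


@dataclass
class RunSummary:
    project_name: str
    results_dir: Path
    statuses: dict = field(default_factory=dict)  # image id -> "ok" | "failed: ..."
    control_warnings: list = field(default_factory=list)
    records: list = field(default_factory=list)

    @property
    def status(self) -> str:
        ok = [s for s in self.statuses.values() if s == "ok"]
        if len(ok) == len(self.statuses):
            return "full"
        return "partial" if ok else "failed"


def run_project(config: ProjectConfig) -> RunSummary:
    """Run the whole project; per-image failures are recorded, not fatal.

    A missing classifier aborts before any image is processed.
    """
    base = Path(config.base_dir)
    results_dir = base / config.output_folder
    results_dir.mkdir(parents=True, exist_ok=True)
    model_path = base / config.classifier
    if not model_path.exists():
        raise HdabQuantError(f"classifier not found: {model_path}")
    model = load_classifier(model_path)
    summary = RunSummary(project_name=config.project_name, results_dir=results_dir)
    for entry in config.images:
        try:
            objs = _process_image(config, entry, model, base)
            out = results_dir / f"{entry.id_slidescanning}.txt"
            write_results_file(objs, {"image": entry.id_slidescanning}, out)
            recs = positivity_records(objs, config.antibody, entry.id_slidescanning)
            summary.records.extend(recs)
            if entry.control:
                for r in recs:
                    if r.pooled and r.positivity_rate is not None and (
                        r.positivity_rate > config.control_max_rate
                    ):
                        msg = (
                            f"control {entry.id_slidescanning}: positivity "
                            f"{r.positivity_rate:.2f}% exceeds "
                            f"{config.control_max_rate}%"
                        )
                        log.warning(msg)
                        summary.control_warnings.append(msg)
            summary.statuses[entry.id_slidescanning] = "ok"
        except Exception as exc:  # per-image isolation
            log.error("image %s failed: %s", entry.id_slidescanning, exc)
            summary.statuses[entry.id_slidescanning] = f"failed: {exc}"
    _write_run_log(config, summary)
    return summary


def _process_image(config, entry, model, base):
    img, px = load_image(base / entry.path, entry.pixel_size_um)
    vectors = _resolve_vectors(entry.stain_vectors or config.stain_vectors)
    params = _resolve_params(entry.detection_params or config.detection_params)
    od = rgb_to_od(img, vectors.background_rgb, pixel_size_um=px)
    channels = deconvolve(od, vectors)
    if entry.regions_geojson:
        regions = read_geojson_regions(base / entry.regions_geojson)
    elif config.regions_source == "thresholder":
        regions = threshold_tissue(img, px, **config.thresholder)
    else:
        regions = []
    objs = NucleusDetector(params).detect(channels)
    classify(objs, model)
    if regions:
        assign_parent(objs, regions)
    else:
        for o in objs:
            o.parent_region = "image"
    return objs


def _write_run_log(config, summary: RunSummary):
    from . import __version__

    payload = {
        "project_name": config.project_name,
        "antibody": config.antibody,
        "seed": config.seed,
        "version": __version__,
        "detection_params": dataclasses.asdict(_resolve_params(config.detection_params)),
        "statuses": summary.statuses,
        "control_warnings": summary.control_warnings,
    }
    (summary.results_dir / "run_log.json").write_text(json.dumps(payload, indent=2))
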