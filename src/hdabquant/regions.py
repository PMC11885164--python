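"""Regions of interest: manual polygons, automatic tissue thresholding.

Regions are named polygons (with optional holes for excluded folds) in
micrometre coordinates, serialized as GeoJSON FeatureCollections with a
``classification`` property — the dialect common digital-pathology
annotation tools export.  Detections are assigned to the smallest region
whose polygon (minus holes) contains their centroid.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi
from shapely.geometry import MultiPolygon, Point, Polygon, mapping, shape
from skimage import measure, morphology

from .stains import rgb_to_od

log = logging.getLogger(__name__)


@dataclass
class RegionAnnotation:
    """One named region: a shapely (Multi)Polygon in um, holes excluded."""

    name: str
    geometry: Polygon | MultiPolygon
    source: str = "manual"  # or "thresholder"

    @property
    def area_um2(self) -> float:
        return float(self.geometry.area)

    def contains_point(self, x_um: float, y_um: float) -> bool:
        return self.geometry.contains(Point(x_um, y_um))


def threshold_tissue(
    image: np.ndarray,
    pixel_size_um: float,
    od_floor: float = 0.08,
    min_region_area_um2: float = 1000.0,
    smooth_sigma_um: float = 2.0,
    background_rgb=(255.0, 255.0, 255.0),
    max_hole_area_um2: float | None = None,
):
    """Automatic tissue detection by total-OD thresholding.

    Pixels whose summed OD is below ``od_floor`` (bright background) are
    ignored; the mask is smoothed, small holes filled, and components below
    ``min_region_area_um2`` dropped.  Each surviving component becomes one
    ``RegionAnnotation`` named ``tissue``/``tissue_2``/... (stable order by
    top-left extent).
    """
    od = rgb_to_od(image, background_rgb, pixel_size_um=pixel_size_um).pixels
    total = od.sum(axis=2)
    if smooth_sigma_um > 0:
        total = ndi.gaussian_filter(total, sigma=smooth_sigma_um / pixel_size_um)
    mask = total >= od_floor
    px2 = pixel_size_um**2
    if max_hole_area_um2 is None:
        max_hole_area_um2 = min_region_area_um2
    mask = morphology.remove_small_holes(
        mask, max_size=max(1, int(max_hole_area_um2 / px2))
    )
    mask = morphology.remove_small_objects(
        mask, max_size=max(1, int(min_region_area_um2 / px2) - 1)
    )
    labels = measure.label(mask)
    regions = []
    props = sorted(
        measure.regionprops(labels), key=lambda rp: (rp.bbox[0], rp.bbox[1])
    )
    for i, rp in enumerate(props):
        poly = _mask_to_shapely(labels == rp.label, pixel_size_um)
        if poly is None or poly.area < min_region_area_um2:
            continue
        name = "tissue" if i == 0 else f"tissue_{i + 1}"
        regions.append(RegionAnnotation(name=name, geometry=poly, source="thresholder"))
    return regions


def _mask_to_shapely(mask: np.ndarray, pixel_size_um: float):
    padded = np.pad(mask.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    if not contours:
        return None
    polys = []
    for c in contours:
        xy = [((p[1] - 1) * pixel_size_um, (p[0] - 1) * pixel_size_um) for p in c]
        if len(xy) >= 4:
            poly = Polygon(xy)
            if poly.is_valid and poly.area > 0:
                polys.append(poly)
    if not polys:
        return None
    # Largest contour is the shell; others inside it are holes.
    polys.sort(key=lambda p: p.area, reverse=True)
    shell = polys[0]
    holes = [p for p in polys[1:] if shell.contains(p.representative_point())]
    out = shell
    for h in holes:
        out = out.difference(h)
    return out


def subtract_folds(region: RegionAnnotation, fold_polygons) -> RegionAnnotation:
    """Remove fold polygons from a region (they become holes).

    Folds disjoint from the region leave it unchanged with a logged
    warning.
    """
    geom = region.geometry
    changed = False
    for fold in fold_polygons:
        if not isinstance(fold, (Polygon, MultiPolygon)):
            fold = Polygon(fold)
        if not geom.intersects(fold):
            log.warning(
                "fold polygon disjoint from region %r; skipping", region.name
            )
            continue
        geom = geom.difference(fold)
        changed = True
    if not changed:
        return region
    return RegionAnnotation(name=region.name, geometry=geom, source=region.source)


def assign_parent(objs, regions):
    """Set each detection's parent_region by centroid containment.

    Overlapping/nested regions resolve to the smallest containing region;
    centroids in no region (or inside a hole) get ``"unassigned"`` and are
    excluded from per-region counts downstream.
    """
    ordered = sorted(regions, key=lambda r: r.area_um2)
    for o in objs:
        x, y = o.centroid_um
        o.parent_region = "unassigned"
        for r in ordered:
            if r.contains_point(x, y):
                o.parent_region = r.name
                break
    return objs


# ---------------------------------------------------------------------------
# GeoJSON I/O


def _classification_name(props: dict) -> str:
    c = props.get("classification", props.get("name", "region"))
    if isinstance(c, dict):
        return str(c.get("name", "region"))
    return str(c)


def read_geojson_regions(path) -> list:
    """Read polygon features (holes as interior rings) into regions."""
    data = json.loads(Path(path).read_text())
    feats = data["features"] if data.get("type") == "FeatureCollection" else [data]
    regions = []
    for f in feats:
        geom = shape(f["geometry"])
        if geom.geom_type not in ("Polygon", "MultiPolygon"):
            continue
        name = _classification_name(f.get("properties") or {})
        regions.append(RegionAnnotation(name=name, geometry=geom, source="manual"))
    return regions


def write_geojson_regions(regions, path):
    feats = [
        {
            "type": "Feature",
            "geometry": mapping(r.geometry),
            "properties": {"classification": {"name": r.name}, "source": r.source},
        }
        for r in regions
    ]
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": feats})
    )


def read_geojson_points(path):
    """Read point annotations -> (list of (x, y) um, list of labels)."""
    data = json.loads(Path(path).read_text())
    feats = data["features"] if data.get("type") == "FeatureCollection" else [data]
    pts, labels = [], []
    for f in feats:
        g = f["geometry"]
        if g["type"] != "Point":
            continue
        pts.append(tuple(g["coordinates"][:2]))
        labels.append(_classification_name(f.get("properties") or {}))
    return pts, labels


def write_geojson_points(points_um, labels, path):
    feats = [
        {
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [float(x), float(y)]},
            "properties": {"classification": {"name": str(lab)}},
        }
        for (x, y), lab in zip(points_um, labels)
    ]
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": feats})
    )
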