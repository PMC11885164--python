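"""H-DAB stain separation: optical density, stain vectors, colour deconvolution.

Chromogenic stains absorb light, so per-channel optical density
``OD_c = -log10(I_c / I0_c)`` combines (approximately) linearly over
co-localised stains.  A pixel's OD vector is then a non-negative mixture of
one unit vector per stain, and solving the per-pixel 3x3 linear system
("colour deconvolution") yields per-stain concentration maps.  The two
chromogens here are hematoxylin (blue, nuclear counterstain) and DAB
(brown, antibody-localised); a third residual axis completes the basis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import EstimationFailedError, InvalidParameterError

#: Canonical H-DAB absorption directions (Ruifrok & Johnston convention),
#: normalised at construction time.
_DEFAULT_HEMATOXYLIN = (0.65, 0.70, 0.29)
_DEFAULT_DAB = (0.27, 0.57, 0.78)

#: Intensity offset added before the log to avoid log(0) on black pixels.
DEFAULT_OD_EPSILON = 1.0


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise InvalidParameterError("zero-length stain vector")
    return v / n


@dataclass(frozen=True)
class StainVectors:
    """Unit OD-space absorption vectors for an H-DAB image.

    ``background_rgb`` is the white point I0 (intensity of unstained glass).
    """

    hematoxylin: np.ndarray
    dab: np.ndarray
    residual: np.ndarray = None  # type: ignore[assignment]
    background_rgb: np.ndarray = field(
        default_factory=lambda: np.array([255.0, 255.0, 255.0])
    )

    def __post_init__(self):
        h = _unit(self.hematoxylin)
        d = _unit(self.dab)
        if (h < -1e-12).any() or (d < -1e-12).any():
            raise InvalidParameterError("stain vectors must be non-negative")
        if self.residual is None:
            r = np.cross(h, d)
            if np.linalg.norm(r) < 1e-9:
                raise InvalidParameterError("hematoxylin and dab vectors are parallel")
            r = _unit(r)
        else:
            r = _unit(self.residual)
        bg = np.asarray(self.background_rgb, dtype=float)
        if bg.shape != (3,) or (bg < 1).any() or (bg > 255).any():
            raise InvalidParameterError("background_rgb components must be in [1, 255]")
        object.__setattr__(self, "hematoxylin", h)
        object.__setattr__(self, "dab", d)
        object.__setattr__(self, "residual", r)
        object.__setattr__(self, "background_rgb", bg)
        if not np.isfinite(np.linalg.cond(self.matrix)):
            raise InvalidParameterError("stain matrix is singular")

    @property
    def matrix(self) -> np.ndarray:
        """3x3 matrix whose columns are the stain vectors: OD = M @ concentrations."""
        return np.stack([self.hematoxylin, self.dab, self.residual], axis=1)

    def to_dict(self) -> dict:
        return {
            "hematoxylin": [float(x) for x in self.hematoxylin],
            "dab": [float(x) for x in self.dab],
            "residual": [float(x) for x in self.residual],
            "background_rgb": [float(x) for x in self.background_rgb],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StainVectors":
        return cls(
            hematoxylin=np.asarray(d["hematoxylin"], dtype=float),
            dab=np.asarray(d["dab"], dtype=float),
            residual=(
                np.asarray(d["residual"], dtype=float) if d.get("residual") else None
            ),
            background_rgb=np.asarray(
                d.get("background_rgb", [255.0, 255.0, 255.0]), dtype=float
            ),
        )


@dataclass
class ODImage:
    """Per-channel optical densities of an RGB image (all values >= 0)."""

    pixels: np.ndarray  # H x W x 3
    pixel_size_um: float

    def __post_init__(self):
        if self.pixel_size_um <= 0:
            raise InvalidParameterError("pixel_size_um must be > 0")


@dataclass
class StainChannels:
    """Per-stain concentration maps from colour deconvolution."""

    hematoxylin: np.ndarray  # H x W
    dab: np.ndarray
    residual: np.ndarray
    pixel_size_um: float


def default_hdab_vectors() -> StainVectors:
    """Canonical H-DAB stain vectors with a (255, 255, 255) white point."""
    return StainVectors(
        hematoxylin=np.array(_DEFAULT_HEMATOXYLIN),
        dab=np.array(_DEFAULT_DAB),
    )


def rgb_to_od(
    image: np.ndarray,
    background_rgb=(255.0, 255.0, 255.0),
    *,
    pixel_size_um: float = 1.0,
    epsilon: float = DEFAULT_OD_EPSILON,
) -> ODImage:
    """Convert an RGB raster to optical density.

    ``OD_c = -log10((I_c + epsilon) / I0_c)``, clipped below at zero, so a
    pixel at the white point maps to OD (0, 0, 0).
    """
    bg = np.asarray(background_rgb, dtype=float)
    if (bg <= 0).any():
        raise InvalidParameterError("background_rgb components must be positive")
    img = np.asarray(image, dtype=float)
    if img.ndim != 3 or img.shape[2] != 3:
        raise InvalidParameterError("expected an H x W x 3 RGB raster")
    od = -np.log10((img + epsilon) / bg)
    np.clip(od, 0.0, None, out=od)
    return ODImage(pixels=od, pixel_size_um=pixel_size_um)


def od_to_rgb(
    od: np.ndarray,
    background_rgb=(255.0, 255.0, 255.0),
    *,
    quantize: bool = True,
) -> np.ndarray:
    """Forward Beer-Lambert model: intensities ``I = I0 * 10**(-OD)``."""
    bg = np.asarray(background_rgb, dtype=float)
    rgb = bg * np.power(10.0, -np.asarray(od, dtype=float))
    if quantize:
        return np.clip(np.rint(rgb), 0, 255).astype(np.uint8)
    return rgb


def deconvolve(od: ODImage, vectors: StainVectors, *, clip: bool = True) -> StainChannels:
    """Solve the per-pixel 3x3 system separating OD into stain concentrations.

    Negative concentrations (noise pushing a pixel outside the stain cone)
    are clipped to zero after the unconstrained solve unless ``clip=False``.
    """
    m = vectors.matrix
    cond = np.linalg.cond(m)
    if not np.isfinite(cond) or cond > 1e12:
        raise InvalidParameterError("stain matrix is singular or ill-conditioned")
    inv = np.linalg.inv(m)
    conc = od.pixels @ inv.T
    if clip:
        np.clip(conc, 0.0, None, out=conc)
    return StainChannels(
        hematoxylin=conc[..., 0],
        dab=conc[..., 1],
        residual=conc[..., 2],
        pixel_size_um=od.pixel_size_um,
    )


def detection_image(channels: StainChannels, mode: str = "od_sum") -> np.ndarray:
    """Scalar raster nuclei are detected on.

    ``hematoxylin`` uses the counterstain alone; ``od_sum`` adds the DAB
    channel so nuclei masked by brown chromogen stay detectable.
    """
    if mode == "hematoxylin":
        return channels.hematoxylin
    if mode == "od_sum":
        return channels.hematoxylin + channels.dab
    raise InvalidParameterError(f"unknown detection image mode: {mode!r}")


def estimate_stain_vectors(
    image: np.ndarray,
    *,
    background_rgb=None,
    od_floor: float = 0.15,
    percentile: float = 1.0,
    min_pixels: int = 100,
    min_angle_deg: float = 8.0,
    epsilon: float = DEFAULT_OD_EPSILON,
) -> StainVectors:
    """Estimate H-DAB stain vectors from the OD point cloud.

    Percentile-bracketed extreme directions in the plane of the top two
    principal OD axes (the Macenko construction): pixels with OD magnitude
    above ``od_floor`` are projected onto that plane and the directions at
    the ``percentile`` / ``100 - percentile`` angular quantiles become the
    two stain vectors.  The vector absorbing more blue is labelled DAB.

    Raises :class:`EstimationFailedError` when fewer than ``min_pixels``
    stained pixels exist or when the two extremes are closer than
    ``min_angle_deg`` (a single stain population); callers should then fall
    back to :func:`default_hdab_vectors`.
    """
    img = np.asarray(image, dtype=float)
    if background_rgb is None:
        flat = img.reshape(-1, 3)
        bg = np.percentile(flat, 99, axis=0)
        bg = np.clip(bg, 1.0, 255.0)
    else:
        bg = np.asarray(background_rgb, dtype=float)
    od = rgb_to_od(img, bg, epsilon=epsilon).pixels.reshape(-1, 3)
    mag = np.linalg.norm(od, axis=1)
    pts = od[mag > od_floor]
    if pts.shape[0] < min_pixels:
        raise EstimationFailedError(
            f"only {pts.shape[0]} pixels above OD {od_floor}; "
            "fall back to default_hdab_vectors()"
        )
    # Plane of the top-2 principal directions of the stained OD cloud.
    _, _, vt = np.linalg.svd(pts - 0.0, full_matrices=False)
    basis = vt[:2]  # 2 x 3
    # Orient so projected coordinates are predominantly positive.
    for i in range(2):
        if (pts @ basis[i] < 0).mean() > 0.5:
            basis[i] = -basis[i]
    proj = pts @ basis.T  # N x 2
    phi = np.arctan2(proj[:, 1], proj[:, 0])
    lo, hi = np.percentile(phi, [percentile, 100.0 - percentile])
    if np.degrees(hi - lo) < min_angle_deg:
        raise EstimationFailedError(
            "stained pixels span a single direction; only one stain present? "
            "fall back to default_hdab_vectors()"
        )
    v1 = basis.T @ np.array([np.cos(lo), np.sin(lo)])
    v2 = basis.T @ np.array([np.cos(hi), np.sin(hi)])
    v1 = _unit(np.clip(v1, 0.0, None))
    v2 = _unit(np.clip(v2, 0.0, None))
    # DAB absorbs blue most strongly; hematoxylin red+green.
    if v1[2] > v2[2]:
        v1, v2 = v2, v1
    if np.degrees(np.arccos(np.clip(v1 @ v2, -1, 1))) < min_angle_deg:
        raise EstimationFailedError(
            "estimated stain vectors nearly parallel after clipping; "
            "fall back to default_hdab_vectors()"
        )
    return StainVectors(hematoxylin=v1, dab=v2, background_rgb=bg)


def angular_distance_deg(a, b) -> float:
    """Angle between two stain vectors in degrees (orientation-insensitive)."""
    a, b = _unit(a), _unit(b)
    return float(np.degrees(np.arccos(np.clip(abs(a @ b), -1.0, 1.0))))
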