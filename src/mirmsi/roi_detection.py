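"""Small-object detection on mean feature images.

Glomeruli (and single neurons) appear as compact bright objects on a mean
MIR image built from a few discriminative wavenumbers (e.g. around 1726 and
1142 cm^-1 for kidney cortex). Detection is deliberately simple and
auditable: threshold the 8-bit image inside a restriction mask (e.g. a
donut following the cortex outline), take connected components, and filter
by area and ellipse-equivalent eccentricity. Concordance between MIR- and
MSI-derived object sets is quantified by overlap matching and centroid
offsets in physical units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
from scipy import ndimage
from skimage.measure import label as cc_label, regionprops

from .hyperspectral import HyperCube, PlaneImage

__all__ = [
    "BlobParams",
    "ROIObject",
    "ConcordanceReport",
    "donut_mask",
    "mean_feature_image",
    "detect_blobs",
    "match_objects",
]


@dataclass(frozen=True)
class BlobParams:
    """Threshold/size/eccentricity filter settings (8-bit intensity scale).

    Defaults follow the glomeruli use case: threshold within 30-60 (45 if
    not auto-selected), area band 50-1000 px at 4.66 um pixels, maximum
    eccentricity 0.94.
    """

    threshold: int = 45
    min_area_px: int = 50
    max_area_px: int = 1000
    max_eccentricity: float = 0.94

    def __post_init__(self):
        if not (0 <= self.threshold <= 255):
            raise ValueError("threshold must be on the 8-bit scale")
        if not (0 < self.min_area_px < self.max_area_px):
            raise ValueError("need 0 < min area < max area")
        if not (0 <= self.max_eccentricity < 1):
            raise ValueError("eccentricity bound must be in [0, 1)")


@dataclass
class ROIObject:
    """One detected object, in pixel and physical coordinates."""

    mask: np.ndarray
    centroid_rc: tuple[float, float]
    centroid_um: tuple[float, float]
    area_px: int
    eccentricity: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.area_px != int(self.mask.sum()):
            raise ValueError("area does not match mask pixel count")


@dataclass
class ConcordanceReport:
    """MIR vs MSI object concordance: counts and centroid offsets (um)."""

    n_both: int
    n_a_only: int
    n_b_only: int
    distances_um: np.ndarray
    mean_um: float
    sd_um: float


def donut_mask(
    tissue: np.ndarray, inner_margin_px: float, outer_margin_px: float
) -> np.ndarray:
    """Band of pixels whose depth from the tissue boundary is in
    [inner, outer], measured inward.

    With margins (0, inf) this returns the whole tissue mask. An inverted
    margin pair yields an empty mask with a warning.
    """
    t = np.asarray(tissue, dtype=bool)
    if not t.any():
        raise ValueError("empty tissue mask")
    if inner_margin_px < 0 or outer_margin_px < 0:
        raise ValueError("margins must be >= 0")
    if inner_margin_px >= outer_margin_px:
        warnings.warn("inner margin >= outer margin: empty donut", stacklevel=2)
        return np.zeros_like(t)
    depth = ndimage.distance_transform_edt(t)
    return t & (depth > inner_margin_px) & (depth <= outer_margin_px)


def mean_feature_image(cube: HyperCube, wavenumbers) -> PlaneImage:
    """Pixelwise mean over selected bands, min-max rescaled to 0..255."""
    idx = [cube.axis.index_of(w) for w in wavenumbers]
    mean = cube.values[:, :, idx].mean(axis=2)
    lo, hi = float(mean.min()), float(mean.max())
    if hi == lo:
        warnings.warn("constant feature image; exporting zeros", stacklevel=2)
        scaled = np.zeros_like(mean)
    else:
        scaled = (mean - lo) / (hi - lo) * 255.0
    return PlaneImage(values=scaled, pixel_size_um=cube.pixel_size_um,
                      wavenumber=None, mode=cube.mode)


def detect_blobs(
    image: PlaneImage | np.ndarray,
    params: BlobParams,
    restriction_mask: np.ndarray | None = None,
    pixel_size_um: float | None = None,
) -> list[ROIObject]:
    """Threshold + connected components + size/eccentricity filtering.

    Components are 8-connected; objects touching the restriction-mask
    border are retained. Eccentricity uses the ellipse-equivalent
    (central image moment) definition. Empty results are allowed.
    """
    if isinstance(image, PlaneImage):
        v = image.values
        px = image.pixel_size_um
    else:
        v = np.asarray(image, dtype=float)
        px = pixel_size_um or 1.0
    binary = v >= params.threshold
    if restriction_mask is not None:
        binary &= np.asarray(restriction_mask, dtype=bool)
    labels = cc_label(binary, connectivity=2)
    out: list[ROIObject] = []
    for prop in regionprops(labels):
        if not (params.min_area_px <= prop.area <= params.max_area_px):
            continue
        if prop.eccentricity > params.max_eccentricity:
            continue
        mask = labels == prop.label
        cr, cc = prop.centroid
        out.append(ROIObject(
            mask=mask,
            centroid_rc=(float(cr), float(cc)),
            centroid_um=(float(cr) * px, float(cc) * px),
            area_px=int(prop.area),
            eccentricity=float(prop.eccentricity),
            provenance={"threshold": params.threshold},
        ))
    return out


def match_objects(
    set_a: list[ROIObject], set_b: list[ROIObject]
) -> ConcordanceReport:
    """Greedy overlap matching of two object sets in a common frame.

    A pair matches when the pixel masks overlap by at least one pixel (each
    object is used at most once, largest overlap first). Distances are
    centroid offsets in um of the matched pairs.
    """
    overlaps = []
    for i, a in enumerate(set_a):
        for j, b in enumerate(set_b):
            ov = int(np.logical_and(a.mask, b.mask).sum())
            if ov > 0:
                overlaps.append((ov, i, j))
    overlaps.sort(reverse=True)
    used_a: set[int] = set()
    used_b: set[int] = set()
    dists = []
    for ov, i, j in overlaps:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pa = np.asarray(set_a[i].centroid_um)
        pb = np.asarray(set_b[j].centroid_um)
        dists.append(float(np.linalg.norm(pa - pb)))
    d = np.asarray(dists)
    return ConcordanceReport(
        n_both=len(dists),
        n_a_only=len(set_a) - len(dists),
        n_b_only=len(set_b) - len(dists),
        distances_um=d,
        mean_um=float(d.mean()) if d.size else float("nan"),
        sd_um=float(d.std(ddof=1)) if d.size > 1 else float("nan"),
    )
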