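"""Transfer of MIR-defined ROIs into the MSI acquisition frame.

The whole-slide single-wavenumber (1656 cm^-1) reference image that teaches
the MS stage is co-registered with the matching plane of the hyperspectral
cube by affine registration under Mattes mutual information. The resulting
transform carries ROI masks into the reference frame, where they are
refined morphologically (small-hole removal, erosion or MALDI-pixel
expansion, iterative hole opening for donut-shaped regions) and exported as
polygons for the acquisition software.

The vendor acquisition format is proprietary; JSON is the canonical export
here and the XML dialect is a documented look-alike for tooling that
expects one polygon element per ROI.
"""

from __future__ import annotations

import json
import warnings
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk
from scipy import ndimage
from skimage import measure, morphology

from .hyperspectral import PlaneImage

__all__ = [
    "AffineTransform",
    "RegistrationConfig",
    "MorphologyConfig",
    "ROIPolygon",
    "register_affine",
    "apply_transform",
    "transform_points",
    "refine_roi",
    "polygonize",
    "rasterize",
    "export_acquisition",
    "import_acquisition",
]


@dataclass(frozen=True)
class AffineTransform:
    """2x3 affine mapping source (row, col) pixel coordinates to target."""

    matrix: np.ndarray  # shape (2, 3): [A | t]
    source_pixel_um: float = 1.0
    target_pixel_um: float = 1.0
    final_metric: float | None = None

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (2, 3):
            raise ValueError("affine matrix must be 2x3")
        if abs(np.linalg.det(m[:, :2])) < 1e-12:
            raise ValueError("affine linear part is singular")
        object.__setattr__(self, "matrix", m)

    @property
    def linear(self) -> np.ndarray:
        return self.matrix[:, :2]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:, 2]

    def inverse(self) -> "AffineTransform":
        A = self.linear
        Ainv = np.linalg.inv(A)
        t = -Ainv @ self.translation
        return AffineTransform(np.hstack([Ainv, t[:, None]]),
                               self.target_pixel_um, self.source_pixel_um)

    def to_json(self) -> dict:
        return {
            "matrix": self.matrix.ravel().tolist(),
            "source_pixel_um": self.source_pixel_um,
            "target_pixel_um": self.target_pixel_um,
        }

    @classmethod
    def from_json(cls, obj: dict) -> "AffineTransform":
        return cls(np.asarray(obj["matrix"], dtype=float).reshape(2, 3),
                   obj.get("source_pixel_um", 1.0), obj.get("target_pixel_um", 1.0))


@dataclass(frozen=True)
class RegistrationConfig:
    """Mattes-mutual-information affine registration settings.

    Linear interpolation, 32 histogram bins and a 3-level multiresolution
    schedule (shrink 4/2/1) are the defaults; full dense sampling keeps the
    optimisation deterministic irrespective of the seed.
    """

    histogram_bins: int = 32
    iterations: int = 300
    sampling_fraction: float = 1.0
    shrink_factors: tuple[int, ...] = (4, 2, 1)
    smoothing_sigmas: tuple[float, ...] = (2.0, 1.0, 0.0)
    seed: int = 0

    def __post_init__(self):
        if self.histogram_bins < 8:
            raise ValueError("need at least 8 histogram bins")
        if self.iterations < 1:
            raise ValueError("need at least one optimizer iteration")
        if not (0 < self.sampling_fraction <= 1):
            raise ValueError("sampling fraction must be in (0, 1]")


@dataclass(frozen=True)
class MorphologyConfig:
    """ROI refinement settings.

    ``erosion_factor`` is the disk structuring-element radius in pixels of
    the 4.66 um reference grid (the convention the factor is bound to);
    ``expansion_pixels`` counts MALDI pixels of ``maldi_step_um`` each,
    converted to reference pixels by ceil(count * step / pixel size).
    """

    small_hole_area_px: int = 0
    erosion_factor: int = 0
    expansion_pixels: int = 0
    maldi_step_um: float = 20.0
    mir_pixel_um: float = 4.66
    iterative_hole_opening: bool = False

    def __post_init__(self):
        if min(self.small_hole_area_px, self.erosion_factor,
               self.expansion_pixels) < 0:
            raise ValueError("morphology parameters must be >= 0")
        if self.erosion_factor and self.expansion_pixels:
            raise ValueError("choose erosion or expansion, not both")


@dataclass
class ROIPolygon:
    """Closed polygon in target-frame physical coordinates (um)."""

    vertices_um: np.ndarray  # (n, 2) as (row_um, col_um)
    name: str = ""
    closed: bool = True

    def __post_init__(self):
        v = np.asarray(self.vertices_um, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise ValueError("polygon needs at least 3 (row, col) vertices")
        self.vertices_um = v

    def area_um2(self) -> float:
        """Shoelace area."""
        r, c = self.vertices_um[:, 0], self.vertices_um[:, 1]
        return 0.5 * abs(np.dot(r, np.roll(c, -1)) - np.dot(c, np.roll(r, -1)))


# ---------------------------------------------------------------------------
# registration
# ---------------------------------------------------------------------------

def _to_sitk(plane: PlaneImage) -> sitk.Image:
    img = sitk.GetImageFromArray(plane.values.astype(np.float64))
    img.SetSpacing((1.0, 1.0))  # work in pixel units; physical handled outside
    return img


def register_affine(
    fixed: PlaneImage,
    moving: PlaneImage,
    config: RegistrationConfig | None = None,
) -> AffineTransform:
    """Affine registration of ``moving`` onto ``fixed`` by maximising
    Mattes mutual information.

    Returns the transform mapping fixed (row, col) pixel coordinates to
    moving coordinates (the resampling convention), with the final metric
    value attached. Raises if the optimisation fails to improve on the
    identity metric.
    """
    cfg = config or RegistrationConfig()
    if np.ptp(fixed.values) == 0 or np.ptp(moving.values) == 0:
        raise ValueError("registration inputs must be nonconstant")
    f_img, m_img = _to_sitk(fixed), _to_sitk(moving)

    initial = sitk.CenteredTransformInitializer(
        f_img, m_img, sitk.AffineTransform(2),
        sitk.CenteredTransformInitializerFilter.GEOMETRY,
    )
    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=cfg.histogram_bins)
    if cfg.sampling_fraction >= 1.0:
        reg.SetMetricSamplingStrategy(reg.NONE)
    else:
        reg.SetMetricSamplingStrategy(reg.REGULAR)
        reg.SetMetricSamplingPercentage(cfg.sampling_fraction, cfg.seed)
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=1.0, minStep=1e-6,
        numberOfIterations=cfg.iterations, relaxationFactor=0.5,
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetShrinkFactorsPerLevel(list(cfg.shrink_factors))
    reg.SetSmoothingSigmasPerLevel(list(cfg.smoothing_sigmas))
    reg.SetInitialTransform(initial, inPlace=False)
    out = reg.Execute(f_img, m_img)

    final_metric = reg.GetMetricValue()
    # sanity: the optimised metric must beat the untouched initial transform
    eval_reg = sitk.ImageRegistrationMethod()
    eval_reg.SetMetricAsMattesMutualInformation(cfg.histogram_bins)
    eval_reg.SetInterpolator(sitk.sitkLinear)
    eval_reg.SetInitialTransform(initial, inPlace=False)
    init_metric = eval_reg.MetricEvaluate(f_img, m_img)
    if final_metric > init_metric + 1e-9:
        raise RuntimeError(
            f"registration diverged: metric {final_metric:.5f} worse than "
            f"initial {init_metric:.5f}"
        )

    af = sitk.AffineTransform(out if not isinstance(out, sitk.CompositeTransform)
                              else out.GetNthTransform(0))
    A_xy = np.asarray(af.GetMatrix()).reshape(2, 2)
    c_xy = np.asarray(af.GetCenter())
    t_xy = np.asarray(af.GetTranslation())
    # SimpleITK works in (x, y) = (col, row); convert to (row, col)
    P = np.array([[0.0, 1.0], [1.0, 0.0]])
    A_rc = P @ A_xy @ P
    offset_xy = t_xy + c_xy - A_xy @ c_xy
    t_rc = P @ offset_xy
    return AffineTransform(
        np.hstack([A_rc, t_rc[:, None]]),
        source_pixel_um=fixed.pixel_size_um,
        target_pixel_um=moving.pixel_size_um,
        final_metric=float(final_metric),
    )


def apply_transform(
    mask: np.ndarray,
    transform: AffineTransform,
    output_shape: tuple[int, int] | None = None,
) -> np.ndarray:
    """Resample a binary mask through the transform (nearest neighbour,
    labels stay crisp). ``transform`` maps output coords to input coords
    following the resampling convention of :func:`register_affine`."""
    m = np.asarray(mask)
    shape = output_shape or m.shape
    out = ndimage.affine_transform(
        m.astype(np.float32), transform.linear, offset=transform.translation,
        output_shape=shape, order=0, mode="constant", cval=0.0,
    )
    return out > 0.5


def transform_points(points_rc: np.ndarray, transform: AffineTransform) -> np.ndarray:
    """Map (n, 2) (row, col) points exactly through the affine."""
    p = np.asarray(points_rc, dtype=float)
    return p @ transform.linear.T + transform.translation


# ---------------------------------------------------------------------------
# morphology
# ---------------------------------------------------------------------------

def refine_roi(mask: np.ndarray, config: MorphologyConfig) -> np.ndarray:
    """Refine a transferred ROI mask.

    Order: small-hole removal, then erosion (disk radius = erosion factor)
    or dilation by ceil(expansion_pixels * MALDI step / MIR pixel size)
    pixels; with iterative hole opening enabled, interior holes whose area
    is at or above the small-hole threshold are re-opened afterwards so
    donut-shaped measurement regions keep their topology. A zero-parameter
    config is the identity. Raises if erosion removes the ROI entirely.
    """
    m = np.asarray(mask, dtype=bool)
    big_holes = None
    if config.iterative_hole_opening:
        filled = ndimage.binary_fill_holes(m)
        holes = filled & ~m
        hole_labels, n = ndimage.label(holes)
        if n:
            areas = ndimage.sum_labels(np.ones_like(hole_labels), hole_labels,
                                       index=np.arange(1, n + 1))
            keep = [i + 1 for i, a in enumerate(areas)
                    if a >= max(config.small_hole_area_px, 1)]
            big_holes = np.isin(hole_labels, keep)
    if config.small_hole_area_px > 0:
        m = morphology.remove_small_holes(m, area_threshold=config.small_hole_area_px)
    if config.erosion_factor > 0:
        m = morphology.binary_erosion(m, morphology.disk(config.erosion_factor))
        if not m.any():
            raise ValueError("erosion removed the entire ROI")
    elif config.expansion_pixels > 0:
        n_px = int(np.ceil(config.expansion_pixels * config.maldi_step_um
                           / config.mir_pixel_um))
        m = morphology.binary_dilation(m, morphology.disk(n_px))
    if big_holes is not None:
        m = m & ~big_holes
    return m


# ---------------------------------------------------------------------------
# polygons
# ---------------------------------------------------------------------------

def _line_intersection(p0, p1, p2, p3):
    """Intersection of the lines (p0, p1) and (p2, p3); None if parallel."""
    d1, d2 = p1 - p0, p3 - p2
    cross = d1[0] * d2[1] - d1[1] * d2[0]
    if abs(cross) < 1e-9:
        return None
    s = ((p2[0] - p0[0]) * d2[1] - (p2[1] - p0[1]) * d2[0]) / cross
    return p0 + s * d1


def _reconstruct_corners(verts: np.ndarray, max_edge: float = 0.9,
                         guard: float = 1.0) -> np.ndarray:
    """Replace short corner-cut edges by the intersection of the adjacent
    segments. Marching squares truncates right-angle corners by ~0.7 px;
    extending the neighbouring segments restores the true corner."""
    n = len(verts)
    # start the ring right after its longest edge so the wrap-around edge is
    # never a candidate corner cut
    edges = np.linalg.norm(np.roll(verts, -1, axis=0) - verts, axis=1)
    verts = np.roll(verts, -(int(np.argmax(edges)) + 1), axis=0)
    out = []
    i = 0
    while i < n:
        j = (i + 1) % n
        if j > 0 and np.linalg.norm(verts[j] - verts[i]) <= max_edge:
            p0, p1 = verts[(i - 1) % n], verts[i]
            p2, p3 = verts[j], verts[(j + 1) % n]
            x = _line_intersection(p0, p1, p2, p3)
            if (x is not None and np.linalg.norm(x - p1) <= guard
                    and np.linalg.norm(x - p2) <= guard):
                out.append(x)
                i += 2
                continue
        out.append(verts[i])
        i += 1
    return np.asarray(out)


def _drop_collinear(verts: np.ndarray, eps: float = 1e-7) -> np.ndarray:
    """Remove vertices lying exactly on the segment between neighbours
    (Douglas-Peucker always keeps the arbitrary chain start point)."""
    n = len(verts)
    keep = []
    for i in range(n):
        a, b, c = verts[(i - 1) % n], verts[i], verts[(i + 1) % n]
        cross = (b[0] - a[0]) * (c[1] - b[1]) - (b[1] - a[1]) * (c[0] - b[0])
        if abs(cross) > eps:
            keep.append(i)
    return verts[keep] if len(keep) >= 3 else verts


def polygonize(
    mask: np.ndarray,
    pixel_size_um: float = 1.0,
    simplify_tolerance_px: float = 0.0,
    name_prefix: str = "roi",
) -> list[ROIPolygon]:
    """Marching-squares iso-contours at level 0.5, one polygon per
    connected component, optional Douglas-Peucker simplification (with
    corner reconstruction so axis-aligned masks keep their true corners).

    Vertex coordinates are converted to physical um. An empty mask yields
    an empty list.
    """
    m = np.asarray(mask, dtype=float)
    if not m.any():
        return []
    padded = np.pad(m, 1)
    contours = measure.find_contours(padded, 0.5)
    out = []
    for i, contour in enumerate(sorted(contours, key=len, reverse=True)):
        verts = contour - 1.0  # undo padding
        if np.allclose(verts[0], verts[-1]):
            verts = verts[:-1]
        if simplify_tolerance_px > 0:
            verts = _reconstruct_corners(verts)
            verts = measure.approximate_polygon(verts, simplify_tolerance_px)
            if len(verts) and np.allclose(verts[0], verts[-1]):
                verts = verts[:-1]
            if len(verts) >= 3:
                verts = _drop_collinear(verts)
        if len(verts) < 3:
            continue
        out.append(ROIPolygon(verts * pixel_size_um, name=f"{name_prefix}_{i}"))
    return out


def rasterize(polygon: ROIPolygon, shape: tuple[int, int],
              pixel_size_um: float = 1.0) -> np.ndarray:
    """Fill a polygon back onto a pixel grid (inverse of polygonize)."""
    from skimage.draw import polygon as draw_polygon

    v = polygon.vertices_um / pixel_size_um
    rr, cc = draw_polygon(v[:, 0], v[:, 1], shape=shape)
    out = np.zeros(shape, dtype=bool)
    out[rr, cc] = True
    return out


# ---------------------------------------------------------------------------
# acquisition export
# ---------------------------------------------------------------------------

def export_acquisition(
    polygons: list[ROIPolygon],
    path,
    teach_transform: AffineTransform | None = None,
    dialect: str = "json",
    maldi_step_um: float = 20.0,
    reference_pixel_um: float = 4.66,
) -> None:
    """Write an acquisition-region file.

    JSON schema: {"rois": [{"name", "vertices_um"}], "teach": 2x3 affine,
    "maldi_step_um"}. The XML dialect writes one <Polygon> element per ROI
    with integer pixel coordinates of the reference image, in byte-stable
    order.
    """
    if dialect == "json":
        doc = {
            "rois": [
                {"name": p.name, "vertices_um": p.vertices_um.tolist()}
                for p in polygons
            ],
            "teach": teach_transform.to_json() if teach_transform else None,
            "maldi_step_um": maldi_step_um,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1, sort_keys=True)
    elif dialect == "mis_xml":
        root = ET.Element("AcquisitionRegions", attrib={
            "maldi_step_um": repr(maldi_step_um)})
        for p in polygons:
            el = ET.SubElement(root, "Polygon", attrib={"name": p.name})
            px = np.round(p.vertices_um / reference_pixel_um).astype(int)
            el.text = " ".join(f"{r},{c}" for r, c in px)
        ET.ElementTree(root).write(path, encoding="unicode")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def acquisition_reduction(roi_pixels: int, full_pixels: int) -> float:
    """Fractional reduction in measured pixels when focusing acquisition on
    ROIs instead of the full tissue (e.g. 8483 glomerular ROI pixels versus
    216411 for the whole section)."""
    if full_pixels <= 0 or roi_pixels < 0 or roi_pixels > full_pixels:
        raise ValueError("need 0 <= roi_pixels <= full_pixels, full > 0")
    return 1.0 - roi_pixels / full_pixels


def import_acquisition(path) -> tuple[list[ROIPolygon], AffineTransform | None]:
    """Read back the JSON dialect written by :func:`export_acquisition`."""
    with open(path) as fh:
        doc = json.load(fh)
    polys = [ROIPolygon(np.asarray(r["vertices_um"]), name=r["name"])
             for r in doc["rois"]]
    teach = (AffineTransform.from_json(doc["teach"])
             if doc.get("teach") else None)
    return polys, teach
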