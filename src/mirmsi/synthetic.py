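"""Phantom generators with known ground truth.

Every downstream stage of the toolkit is testable without any instrument
data: this module fabricates (i) hyperspectral MIR cubes with labelled
geometric tissue regions, (ii) TIMS peak frames with Gaussian mobility
profiles and isotope envelopes, and (iii) CCS tables drawn from a
parallel-line quadratic model. All generators are pure functions of their
spec (seeds are explicit fields, never global state).

The phantoms emulate the band assignments used for segmentation (988, 1374,
1466, 1548, 1656, 1720/1726, 1740/1742 cm^-1) and the TIMS conditions of
the sulfatide work (mobility range ~0.8-1.87 Vs/cm^2, ramp times 120 and
480 ms); they make no attempt at realistic tissue morphology beyond
labelled regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .hyperspectral import HyperCube, PlaneImage, SpectralAxis
from .lipids import MolecularFormula, isotope_pattern
from .constants import C13_C12_DELTA

__all__ = [
    "GaussBand",
    "ClassProfile",
    "BlobSpec",
    "RingSpec",
    "GeometrySpec",
    "PhantomSpec",
    "PhantomROI",
    "make_mir_phantom",
    "TimsSpecies",
    "TimsPhantomSpec",
    "make_tims_phantom",
    "CcsPhantomSpec",
    "make_ccs_table",
    "make_registration_pair",
]


# ---------------------------------------------------------------------------
# MIR cube phantoms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GaussBand:
    """One Gaussian absorption band (center cm^-1, width cm^-1, amplitude)."""

    center: float
    width: float
    amplitude: float


@dataclass(frozen=True)
class ClassProfile:
    """A named tissue class with its absorption bands."""

    name: str
    bands: tuple[GaussBand, ...]

    def spectrum(self, axis: SpectralAxis) -> np.ndarray:
        wn = axis.wavenumbers
        lo, hi = wn[0], wn[-1]
        out = np.zeros_like(wn)
        for b in self.bands:
            if not (lo <= b.center <= hi):
                raise ValueError(
                    f"band center {b.center} cm^-1 outside axis [{lo}, {hi}]"
                )
            out += b.amplitude * np.exp(-0.5 * ((wn - b.center) / b.width) ** 2)
        return out


#: band vocabulary used across phantoms (cm^-1)
AMIDE_I, AMIDE_II = 1656.0, 1548.0
CH2_BEND, CH3_BEND = 1466.0, 1374.0
ESTER_CO = 1742.0
SULFOGAL = 988.0
GLOM_BANDS = (1726.0, 1142.0)


def protein_class(name: str = "tissue", amplitude: float = 1.0) -> ClassProfile:
    """Generic protein-dominated tissue (amide I/II)."""
    return ClassProfile(name, (
        GaussBand(AMIDE_I, 18.0, amplitude),
        GaussBand(AMIDE_II, 16.0, 0.6 * amplitude),
    ))


def lipid_class(name: str = "lipid_rich", amplitude: float = 1.0) -> ClassProfile:
    """Lipid-rich tissue: amide plus CH2 bending and ester C=O bands."""
    return ClassProfile(name, (
        GaussBand(AMIDE_I, 18.0, 0.8 * amplitude),
        GaussBand(AMIDE_II, 16.0, 0.5 * amplitude),
        GaussBand(CH2_BEND, 10.0, amplitude),
        GaussBand(ESTER_CO, 10.0, amplitude),
    ))


def sulfatide_class(name: str = "sulfatide_rich", amplitude: float = 1.0) -> ClassProfile:
    """Sulfatide-accumulating tissue: adds the 988 cm^-1 sulfogalactosyl band."""
    return ClassProfile(name, (
        GaussBand(AMIDE_I, 18.0, 0.8 * amplitude),
        GaussBand(AMIDE_II, 16.0, 0.5 * amplitude),
        GaussBand(CH2_BEND, 10.0, 0.9 * amplitude),
        GaussBand(SULFOGAL, 12.0, amplitude),
    ))


@dataclass(frozen=True)
class BlobSpec:
    """Planted elliptical objects of one class.

    Eccentricity follows the image-moment convention (0 = circle); blobs are
    rasterised as anti-aliased ellipses at pixel centers with random
    orientation and non-overlapping random placement inside the tissue.
    """

    count: int
    radius_px: float
    class_name: str
    eccentricity: float = 0.0

    def __post_init__(self):
        if self.count < 0:
            raise ValueError("blob count must be >= 0")
        if not (0 <= self.eccentricity < 1):
            raise ValueError("eccentricity must be in [0, 1)")


@dataclass(frozen=True)
class RingSpec:
    """Concentric ring layer of one class, radii in px from tissue center."""

    class_name: str
    r_inner_px: float
    r_outer_px: float


@dataclass(frozen=True)
class GeometrySpec:
    """Tissue layout: a background disk, optional ring layers, planted blobs."""

    background: str = "tissue"
    tissue_radius_frac: float = 0.42
    rings: tuple[RingSpec, ...] = ()
    blobs: tuple[BlobSpec, ...] = ()


@dataclass(frozen=True)
class PhantomSpec:
    """Full phantom specification; a pure function input."""

    shape: tuple[int, int] = (96, 96)
    pixel_size_um: float = 4.66
    classes: tuple[ClassProfile, ...] = ()
    geometry: GeometrySpec = field(default_factory=GeometrySpec)
    baseline_coeffs: tuple[float, ...] = ()  # polynomial in (wn - wn0)/range
    noise_sigma: float = 0.0
    axis: SpectralAxis = field(default_factory=SpectralAxis.default)
    seed: int = 0

    def __post_init__(self):
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be >= 0")
        names = [c.name for c in self.classes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate class names")


@dataclass
class PhantomROI:
    """Ground-truth planted object."""

    mask: np.ndarray
    centroid_rc: tuple[float, float]
    class_name: str
    radius_px: float
    eccentricity: float


def _ellipse_coverage(shape, center, a, b, theta):
    """Anti-aliased coverage of an ellipse with semi-axes a >= b."""
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]].astype(float)
    dr, dc = rr - center[0], cc - center[1]
    u = np.cos(theta) * dr + np.sin(theta) * dc
    v = -np.sin(theta) * dr + np.cos(theta) * dc
    # signed distance approximation from the implicit ellipse equation
    rho = np.sqrt((u / a) ** 2 + (v / b) ** 2)
    edge = (rho - 1.0) * min(a, b)  # approx. distance in px near the rim
    return np.clip(0.5 - edge, 0.0, 1.0)


def make_mir_phantom(spec: PhantomSpec):
    """Generate (cube, label image, ground-truth ROI list).

    Labels name the generating class per pixel (-1 outside the tissue);
    blobs overwrite rings overwrite the background. Deterministic for a
    fixed seed: the same spec yields bit-identical cubes.
    """
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.shape
    profiles = {c.name: c for c in spec.classes}
    geo = spec.geometry
    needed = {geo.background} | {r.class_name for r in geo.rings} | {
        b.class_name for b in geo.blobs
    }
    missing = needed - set(profiles) - {None}
    if missing:
        raise ValueError(f"geometry references undefined classes: {sorted(missing)}")

    class_names = [c.name for c in spec.classes]
    label = np.full((rows, cols), -1, dtype=int)
    coverage = np.zeros((rows, cols, len(class_names)))

    center = ((rows - 1) / 2.0, (cols - 1) / 2.0)
    r_t = geo.tissue_radius_frac * min(rows, cols)
    rr, cc = np.mgrid[0:rows, 0:cols].astype(float)
    dist = np.hypot(rr - center[0], cc - center[1])
    tissue = dist <= r_t

    bg_i = class_names.index(geo.background)
    label[tissue] = bg_i
    coverage[:, :, bg_i] = tissue.astype(float)

    for ring in geo.rings:
        i = class_names.index(ring.class_name)
        in_ring = (dist >= ring.r_inner_px) & (dist <= ring.r_outer_px) & tissue
        coverage[in_ring, :] = 0.0
        coverage[in_ring, i] = 1.0
        label[in_ring] = i

    rois: list[PhantomROI] = []
    occupied = np.zeros((rows, cols), dtype=bool)
    for blob in geo.blobs:
        i = class_names.index(blob.class_name)
        e = blob.eccentricity
        # area-preserving semi-axes: a*b = r^2, e^2 = 1 - (b/a)^2
        a = blob.radius_px / (1.0 - e * e) ** 0.25
        b = blob.radius_px ** 2 / a
        placed = 0
        attempts = 0
        while placed < blob.count:
            attempts += 1
            if attempts > 2000 * max(1, blob.count):
                raise RuntimeError("could not place blobs without overlap")
            crow = rng.uniform(a + 1, rows - a - 2)
            ccol = rng.uniform(a + 1, cols - a - 2)
            if np.hypot(crow - center[0], ccol - center[1]) > r_t - a - 1:
                continue
            theta = rng.uniform(0, np.pi)
            cov = _ellipse_coverage((rows, cols), (crow, ccol), a, b, theta)
            mask = cov > 0.5
            if not mask.any() or (mask & occupied).any():
                continue
            # keep planted objects well separated so they stay distinct
            # connected components after thresholding
            occupied |= ndimage.binary_dilation(mask, iterations=4)
            coverage[mask, :] = 0.0
            coverage[:, :, i] = np.where(mask, 1.0, coverage[:, :, i])
            # feather the rim into the class coverage for anti-aliasing
            rim = (cov > 0) & (cov < 1) & ~mask
            coverage[rim, i] = np.maximum(coverage[rim, i], cov[rim])
            label[mask] = i
            rois.append(PhantomROI(mask, (crow, ccol), blob.class_name,
                                   blob.radius_px, e))
            placed += 1

    wn = spec.axis.wavenumbers
    spectra = np.stack([profiles[n].spectrum(spec.axis) for n in class_names])
    if spec.baseline_coeffs:
        t = (wn - wn[0]) / (wn[-1] - wn[0])
        drift = np.polyval(list(reversed(spec.baseline_coeffs)), t)
    else:
        drift = np.zeros_like(wn)

    values = np.tensordot(coverage, spectra, axes=([2], [0]))
    values += (label >= 0)[:, :, None] * drift[None, None, :]
    if spec.noise_sigma > 0:
        values = values + rng.normal(0.0, spec.noise_sigma, size=values.shape)

    cube = HyperCube(values=values, axis=spec.axis,
                     pixel_size_um=spec.pixel_size_um, mode="absorbance")
    return cube, label, rois


# ---------------------------------------------------------------------------
# TIMS peak-frame phantoms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TimsSpecies:
    """One ion species in a mobility phantom."""

    mz: float
    inv_k0: float           # true reduced-mobility center, Vs/cm^2
    intensity: float
    formula: str | None = None  # enables an isotope envelope


@dataclass(frozen=True)
class TimsPhantomSpec:
    """Phantom TIMS frame.

    The mobility peak width follows sigma(ramp) = sigma_ref * ramp_ref/ramp
    (the resolving power of a TIMS scan grows with ramp time; the inverse
    law is this package's modelling choice). Defaults mirror the sulfatide
    acquisitions: mobility window 0.80-1.87 Vs/cm^2, ramps 120/480 ms.
    """

    species: tuple[TimsSpecies, ...]
    ramp_ms: float = 480.0
    sigma_ref: float = 0.012     # Vs/cm^2 at the reference ramp
    ramp_ref_ms: float = 120.0
    mobility_range: tuple[float, float] = (0.80, 1.87)
    mobility_bin: float = 0.001
    n_isotopes: int = 3
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.mobility_range
        for s in self.species:
            if not (lo <= s.inv_k0 <= hi):
                raise ValueError(f"mobility center {s.inv_k0} outside [{lo}, {hi}]")
        if self.ramp_ms <= 0 or self.ramp_ref_ms <= 0:
            raise ValueError("ramp times must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be >= 0")

    @property
    def sigma(self) -> float:
        """Mobility peak sigma at this ramp time (strictly decreasing in ramp)."""
        return self.sigma_ref * self.ramp_ref_ms / self.ramp_ms


def make_tims_phantom(spec: TimsPhantomSpec) -> pd.DataFrame:
    """Generate a peak list (columns x, y, mz, intensity, inv_k0).

    Each species contributes a Gaussian mobility profile (discretely
    normalised so the profile sums exactly to the species intensity) and,
    when a formula is given, an isotope envelope with peaks spaced by the
    13C-12C mass difference.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.mobility_range
    axis = np.arange(lo, hi + spec.mobility_bin / 2, spec.mobility_bin)
    rows = []
    for s in spec.species:
        if s.formula is not None:
            env = isotope_pattern(MolecularFormula.from_string(s.formula),
                                  spec.n_isotopes)
        else:
            env = [1.0]
        weights = np.exp(-0.5 * ((axis - s.inv_k0) / spec.sigma) ** 2)
        keep = weights > 1e-6
        weights = weights[keep] / weights[keep].sum()
        for j, rel in enumerate(env):
            mz_j = s.mz + j * C13_C12_DELTA
            for mob, w in zip(axis[keep], weights):
                rows.append((0, 0, mz_j, s.intensity * rel * w, mob))
    df = pd.DataFrame(rows, columns=["x", "y", "mz", "intensity", "inv_k0"])
    if spec.noise_sigma > 0 and len(df):
        df["intensity"] = np.clip(
            df["intensity"] + rng.normal(0, spec.noise_sigma, len(df)), 0, None
        )
    return df


# ---------------------------------------------------------------------------
# CCS tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CcsPhantomSpec:
    """CCS values on a parallel-line quadratic: CCS(x; g) = a x^2 + b x + c_g.

    Default scale mirrors experimental sulfatide series: intercept offsets
    of 25-30 A^2 between subclasses and replicate noise of 0.2 A^2.
    """

    quadratic: float = -0.05
    linear: float = 6.0
    intercepts: tuple[tuple[str, float], ...] = (("SM4", 160.0), ("SM3", 188.2))
    chain_range: tuple[int, int] = (32, 46)
    noise_sigma: float = 0.2
    n_replicates: int = 1
    double_bonds: int = 1
    oxygens: int = 2
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.chain_range
        if hi < lo:
            raise ValueError("chain-length range is empty")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be >= 0")


def make_ccs_table(spec: CcsPhantomSpec) -> pd.DataFrame:
    """Generate CCS records (columns shorthand, subclass, n, d, k, ccs_A2,
    source, replicate); reproducible for a fixed seed."""
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.chain_range
    rows = []
    for rep in range(spec.n_replicates):
        for subclass, c_g in spec.intercepts:
            for n in range(lo, hi + 1):
                ccs = spec.quadratic * n * n + spec.linear * n + c_g
                if spec.noise_sigma > 0:
                    ccs += rng.normal(0.0, spec.noise_sigma)
                rows.append({
                    "shorthand": f"{subclass} {n}:{spec.double_bonds};O{spec.oxygens}",
                    "subclass": subclass,
                    "n": n,
                    "d": spec.double_bonds,
                    "k": spec.oxygens,
                    "ccs_A2": ccs,
                    "source": "MSI",
                    "replicate": rep,
                })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# registration phantom pairs
# ---------------------------------------------------------------------------

def make_registration_pair(
    seed: int = 0,
    shape: tuple[int, int] = (128, 128),
    shift: tuple[float, float] = (5.0, 3.0),
    rotation_deg: float = 0.0,
    n_blobs: int = 12,
    noise_sigma: float = 0.01,
) -> tuple[PlaneImage, PlaneImage, np.ndarray]:
    """Fixed/moving single-wavenumber image pair with a known affine.

    The moving image is the fixed image resampled through the inverse of the
    known transform, so registering moving onto fixed should recover the
    transform. Returns (fixed, moving, true 2x3 matrix mapping fixed
    coordinates (row, col) to moving coordinates).
    """
    rng = np.random.default_rng(seed)
    rows, cols = shape
    img = np.zeros(shape)
    rr, cc = np.mgrid[0:rows, 0:cols].astype(float)
    for _ in range(n_blobs):
        r0 = rng.uniform(0.25 * rows, 0.75 * rows)
        c0 = rng.uniform(0.25 * cols, 0.75 * cols)
        s = rng.uniform(3.0, 9.0)
        amp = rng.uniform(0.4, 1.0)
        img += amp * np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * s * s))
    img += ndimage.gaussian_filter(rng.normal(0, 1, shape), 8) * 0.05

    th = np.deg2rad(rotation_deg)
    center = np.array([(rows - 1) / 2.0, (cols - 1) / 2.0])
    R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    t = center - R @ center + np.asarray(shift, dtype=float)
    matrix = np.hstack([R, t[:, None]])  # fixed (r,c) -> moving (r,c)

    # moving[y] = img(R^-1 (y - t)) so that moving(A x) = img(x), A = [R | t]
    moving = ndimage.affine_transform(
        img, R.T, offset=-R.T @ t, order=3, mode="constant", cval=0.0,
    )
    if noise_sigma > 0:
        img = img + rng.normal(0, noise_sigma, shape)
        moving = moving + rng.normal(0, noise_sigma, shape)
    fixed_p = PlaneImage(img, pixel_size_um=4.66, wavenumber=1656.0)
    moving_p = PlaneImage(moving, pixel_size_um=4.66, wavenumber=1656.0)
    return fixed_p, moving_p, matrix
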