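"""Hyperspectral mid-infrared data model and preprocessing.

A :class:`HyperCube` holds a rows x cols x bands absorbance (or
transmittance, or derivative) image over the fingerprint region, by default
950-1800 cm^-1 sampled every 4 cm^-1 as recorded by a QCL microscope in
sweep-scan mode. Preprocessing covers asymmetric-least-squares baseline
correction, spectral derivatives (central differences or Savitzky-Golay),
absorbance/transmittance conversion, spatial binning and band selection.

Coordinate convention: row-major, origin top-left, pixel centers at integer
indices, physical position = index * pixel size (um).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import h5py
import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
import tifffile
from scipy.signal import savgol_filter

__all__ = [
    "SpectralAxis",
    "HyperCube",
    "PlaneImage",
    "PreprocessConfig",
    "als_baseline",
    "baseline_correct",
    "spectral_derivative",
    "to_absorbance",
    "to_transmittance",
    "bin_spatial",
    "select_bands",
    "save_cube",
    "load_cube",
    "save_plane",
    "load_plane",
]

MODES = ("absorbance", "transmittance", "derivative1", "derivative2")


@dataclass(frozen=True)
class SpectralAxis:
    """Strictly increasing wavenumber axis (cm^-1)."""

    wavenumbers: np.ndarray

    def __post_init__(self):
        wn = np.asarray(self.wavenumbers, dtype=float)
        # a full acquisition axis has >= 2 bands; length-1 axes arise only
        # from band selection of reduced cubes
        if wn.ndim != 1 or wn.size < 1:
            raise ValueError("axis needs at least one wavenumber")
        if not np.all(np.diff(wn) > 0):
            raise ValueError("wavenumbers must be strictly increasing")
        object.__setattr__(self, "wavenumbers", wn)

    @classmethod
    def default(cls) -> "SpectralAxis":
        """Fingerprint region 950..1800 cm^-1, 4 cm^-1 sampling (213 bands)."""
        return cls(np.arange(950.0, 1801.0, 4.0))

    def __len__(self) -> int:
        return self.wavenumbers.size

    @property
    def spacing(self) -> float:
        d = np.diff(self.wavenumbers)
        if not np.allclose(d, d[0], rtol=0, atol=1e-6):
            raise ValueError("axis is not uniformly spaced")
        return float(d[0])

    def index_of(self, wavenumber: float, tolerance: float | None = None) -> int:
        """Nearest band index; error if further than ``tolerance``
        (default: half the grid spacing)."""
        wn = self.wavenumbers
        i = int(np.argmin(np.abs(wn - wavenumber)))
        tol = tolerance if tolerance is not None else 0.5 * self.spacing
        if abs(wn[i] - wavenumber) > tol + 1e-9:
            raise ValueError(
                f"requested wavenumber {wavenumber} cm^-1 is {abs(wn[i]-wavenumber):.3g}"
                f" cm^-1 from the nearest band (tolerance {tol:.3g})"
            )
        return i


@dataclass
class HyperCube:
    """rows x cols x bands hyperspectral image."""

    values: np.ndarray
    axis: SpectralAxis
    pixel_size_um: float
    mode: str = "absorbance"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 3:
            raise ValueError("cube values must be 3-D (rows, cols, bands)")
        if v.shape[2] != len(self.axis):
            raise ValueError(
                f"band count {v.shape[2]} does not match axis length {len(self.axis)}"
            )
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be positive")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if not np.all(np.isfinite(v)):
            raise ValueError("cube contains non-finite values")
        self.values = v

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def plane(self, wavenumber: float, tolerance: float | None = None) -> "PlaneImage":
        i = self.axis.index_of(wavenumber, tolerance)
        return PlaneImage(
            values=self.values[:, :, i].copy(),
            pixel_size_um=self.pixel_size_um,
            wavenumber=float(self.axis.wavenumbers[i]),
            mode=self.mode,
        )


@dataclass
class PlaneImage:
    """Single-wavenumber image, e.g. the 1656 cm^-1 amide-I reference used
    to teach the MSI stage."""

    values: np.ndarray
    pixel_size_um: float
    wavenumber: float | None = None
    mode: str = "absorbance"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("plane image must be 2-D")
        if not np.all(np.isfinite(v)):
            raise ValueError("plane contains non-finite values")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be positive")
        self.values = v


@dataclass(frozen=True)
class PreprocessConfig:
    """Preprocessing defaults.

    ALS defaults (smoothing 1e6, asymmetry 0.01, 10 iterations) are the
    standard settings for absorbance baselines in this kind of QCL data;
    the Savitzky-Golay defaults (window 7, order 3) are the usual choice
    for second derivatives of tissue spectra.
    """

    als_lambda: float = 1_000_000.0
    als_p: float = 0.01
    als_iterations: int = 10
    derivative_method: str = "finite_difference"  # or "savitzky_golay"
    sg_window: int = 7
    sg_order: int = 3
    binning: int = 1

    def __post_init__(self):
        if self.als_lambda <= 0:
            raise ValueError("ALS lambda must be positive")
        if not (0 < self.als_p < 1):
            raise ValueError("ALS asymmetry weight must be in (0, 1)")
        if self.als_iterations < 1:
            raise ValueError("ALS needs at least one iteration")
        if self.derivative_method not in ("finite_difference", "savitzky_golay"):
            raise ValueError("unknown derivative method")
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_order:
            raise ValueError("SG window must be odd and exceed the polynomial order")
        if self.binning < 1:
            raise ValueError("binning factor must be >= 1")


# ---------------------------------------------------------------------------
# baseline correction
# ---------------------------------------------------------------------------

def als_baseline(
    spectrum: np.ndarray,
    lam: float = 1_000_000.0,
    p: float = 0.01,
    n_iter: int = 10,
) -> np.ndarray:
    """Asymmetric-least-squares baseline (Eilers-style).

    Iteratively reweighted penalised least squares: points above the current
    baseline get weight ``p``, points below get ``1 - p``; smoothness is
    enforced by a second-difference penalty of strength ``lam``. A fixed
    iteration count is used rather than a convergence tolerance.
    """
    y = np.asarray(spectrum, dtype=float)
    if y.ndim != 1:
        raise ValueError("spectrum must be 1-D")
    m = y.size
    if m < 3:
        raise ValueError("spectrum must have at least 3 points")
    D = sp.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(m - 2, m), format="csc")
    penalty = lam * (D.T @ D)
    w = np.ones(m)
    z = y.copy()
    for _ in range(n_iter):
        W = sp.diags(w, 0, format="csc")
        z = spla.spsolve(W + penalty, w * y)
        w = np.where(y > z, p, 1.0 - p)
    return z


def baseline_correct(cube: HyperCube, config: PreprocessConfig | None = None) -> HyperCube:
    """Subtract the per-pixel ALS baseline from every spectrum."""
    cfg = config or PreprocessConfig()
    r, c, b = cube.shape
    flat = cube.values.reshape(-1, b)
    out = np.empty_like(flat)
    for i in range(flat.shape[0]):
        out[i] = flat[i] - als_baseline(flat[i], cfg.als_lambda, cfg.als_p, cfg.als_iterations)
    return replace(cube, values=out.reshape(r, c, b))


# ---------------------------------------------------------------------------
# derivatives
# ---------------------------------------------------------------------------

def spectral_derivative(
    cube: HyperCube,
    order: int,
    method: str | None = None,
    config: PreprocessConfig | None = None,
) -> HyperCube:
    """Per-pixel derivative of the spectra with respect to wavenumber.

    ``finite_difference`` uses central differences on the uniform grid with
    one-sided differences at the ends; ``savitzky_golay`` uses a polynomial
    filter (window/order from the config). Derivative cubes are treated as
    unit-less downstream; only the spectral shapes matter.
    """
    if order not in (1, 2):
        raise ValueError("derivative order must be 1 or 2")
    if cube.mode not in ("absorbance", "transmittance"):
        raise ValueError("derivative input must be absorbance or transmittance")
    cfg = config or PreprocessConfig()
    method = method or cfg.derivative_method
    h = cube.axis.spacing
    v = cube.values
    if method == "finite_difference":
        out = np.gradient(v, h, axis=2, edge_order=1)
        if order == 2:
            out = np.gradient(out, h, axis=2, edge_order=1)
    elif method == "savitzky_golay":
        if cfg.sg_window > v.shape[2]:
            raise ValueError("SG window exceeds the number of bands")
        out = savgol_filter(
            v, window_length=cfg.sg_window, polyorder=cfg.sg_order,
            deriv=order, delta=h, axis=2,
        )
    else:
        raise ValueError(f"unknown derivative method {method!r}")
    return replace(cube, values=out, mode=f"derivative{order}")


# ---------------------------------------------------------------------------
# absorbance / transmittance
# ---------------------------------------------------------------------------

def to_absorbance(cube: HyperCube, clamp: float = 1e-6) -> HyperCube:
    """A = -log10(T). Non-positive transmittance is clamped with a warning."""
    if cube.mode != "transmittance":
        raise ValueError("input must be in transmittance mode")
    t = cube.values
    if np.any(t <= 0):
        warnings.warn(
            f"clamping {int(np.sum(t <= 0))} non-positive transmittance values to {clamp}",
            stacklevel=2,
        )
        t = np.clip(t, clamp, None)
    return replace(cube, values=-np.log10(t), mode="absorbance")


def to_transmittance(cube: HyperCube) -> HyperCube:
    """T = 10**(-A)."""
    if cube.mode != "absorbance":
        raise ValueError("input must be in absorbance mode")
    return replace(cube, values=np.power(10.0, -cube.values), mode="transmittance")


# ---------------------------------------------------------------------------
# binning and band selection
# ---------------------------------------------------------------------------

def bin_spatial(cube: HyperCube, factor: int) -> HyperCube:
    """Mean-pool factor x factor pixel blocks; trailing partial blocks drop."""
    if factor < 1 or int(factor) != factor:
        raise ValueError("binning factor must be a positive integer")
    factor = int(factor)
    r, c, b = cube.shape
    if factor > r or factor > c:
        raise ValueError("binning factor exceeds image dimensions")
    if factor == 1:
        return replace(cube, values=cube.values.copy())
    rr, cc = r // factor, c // factor
    v = cube.values[: rr * factor, : cc * factor]
    v = v.reshape(rr, factor, cc, factor, b).mean(axis=(1, 3))
    return replace(cube, values=v, pixel_size_um=cube.pixel_size_um * factor)


def select_bands(
    cube: HyperCube,
    wavenumbers: "list[float]",
    tolerance: float | None = None,
) -> HyperCube:
    """Reduced cube with the bands nearest the requested wavenumbers,
    in request order. Errors name the offending wavenumber when outside
    tolerance (default: half the grid spacing)."""
    idx = [cube.axis.index_of(w, tolerance) for w in wavenumbers]
    seen: list[int] = []
    for i in idx:  # unique bands, axis kept increasing
        if i not in seen:
            seen.append(i)
    picked = np.asarray(sorted(seen))
    return replace(
        cube,
        values=cube.values[:, :, picked].copy(),
        axis=SpectralAxis(cube.axis.wavenumbers[picked]),
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def save_cube(cube: HyperCube, path) -> None:
    """Write a cube to an HDF5 container (datasets values/wavenumbers,
    attributes pixel_size_um, mode)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=cube.values)
        f.create_dataset("wavenumbers", data=cube.axis.wavenumbers)
        f.attrs["pixel_size_um"] = cube.pixel_size_um
        f.attrs["mode"] = cube.mode


def load_cube(path) -> HyperCube:
    with h5py.File(path, "r") as f:
        return HyperCube(
            values=f["values"][...],
            axis=SpectralAxis(f["wavenumbers"][...]),
            pixel_size_um=float(f.attrs["pixel_size_um"]),
            mode=str(f.attrs["mode"]),
        )


def save_plane(plane: PlaneImage, path, dtype=np.float32) -> None:
    """Write a single-wavenumber image as TIFF (32-bit float by default,
    uint8 for blob-detection exports)."""
    v = plane.values
    if np.dtype(dtype) == np.uint8:
        lo, hi = float(v.min()), float(v.max())
        v = np.zeros_like(v) if hi == lo else (v - lo) / (hi - lo) * 255.0
        v = np.round(v).astype(np.uint8)
    else:
        v = v.astype(dtype)
    meta = {}
    if plane.wavenumber is not None:
        meta["wavenumber_cm1"] = plane.wavenumber
    tifffile.imwrite(path, v, metadata={"pixel_size_um": plane.pixel_size_um,
                                        "mode": plane.mode, **meta})


def load_plane(path, pixel_size_um: float | None = None) -> PlaneImage:
    with tifffile.TiffFile(path) as tf:
        v = tf.asarray().astype(float)
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    return PlaneImage(
        values=v,
        pixel_size_um=pixel_size_um or float(meta.get("pixel_size_um", 1.0)),
        wavenumber=meta.get("wavenumber_cm1"),
        mode=str(meta.get("mode", "absorbance")),
    )
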