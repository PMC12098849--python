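"""Ion-mobility peak quality: clean/non-clean rules, EIMs and scheduling.

A target sulfatide peak is "non-clean" in qTOF mode when any other peak
within +-1.1 Da exceeds the intensity of the target's first isotopologue
(M+1); in TIMS mode the interferent must additionally fall within
+-0.005 Vs/cm^2 of the target's reduced mobility -- mobility separation
rescues near-isobars such as the SM4 38:2;O3 / SM4 39:1;O2 pair at
m/z 848.557/848.591. Extracted ion mobilograms (EIMs) are deconvolved as
Gaussian sums and isolation-window purity is computed from analytic
Gaussian integrals; mobility-scheduled parallel MS2 packs up to 15
non-overlapping precursors per acquisition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.signal import find_peaks
from scipy.special import erf

from .lipids import MolecularFormula, isotope_pattern

__all__ = [
    "CleanRuleConfig",
    "EIM",
    "GaussianComponent",
    "classify_clean",
    "extract_eim",
    "fit_gaussians",
    "purity_ratio",
    "schedule_precursors",
    "peaklist_from_csv",
    "peaklist_from_imzml",
]

PEAK_COLUMNS = ("x", "y", "mz", "intensity", "inv_k0")


@dataclass(frozen=True)
class CleanRuleConfig:
    """Interference rule windows: +-1.1 Da in mass, +-0.005 Vs/cm^2 in
    mobility (TIMS mode only)."""

    mass_window_da: float = 1.1
    mobility_window: float = 0.005
    isotope_ppm: float = 5.0  # tolerance for excluding the target's own envelope
    n_isotopes: int = 4

    def __post_init__(self):
        if self.mass_window_da <= 0 or self.mobility_window <= 0:
            raise ValueError("rule windows must be positive")


@dataclass
class EIM:
    """Extracted ion mobilogram: intensity vs reduced mobility."""

    mobility: np.ndarray
    intensity: np.ndarray
    mz_window: tuple[float, float]

    def __post_init__(self):
        mob = np.asarray(self.mobility, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        if mob.size != inten.size:
            raise ValueError("axis/intensity length mismatch")
        if mob.size and not np.all(np.diff(mob) > 0):
            raise ValueError("mobility axis must be increasing")
        if np.any(inten < 0):
            raise ValueError("negative intensities")
        self.mobility, self.intensity = mob, inten

    @property
    def total(self) -> float:
        return float(self.intensity.sum())


@dataclass(frozen=True)
class GaussianComponent:
    """One deconvolved mobility peak."""

    mean: float
    sigma: float
    amplitude: float

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")

    @property
    def area(self) -> float:
        return self.amplitude * self.sigma * np.sqrt(2 * np.pi)

    def integral(self, lo: float, hi: float) -> float:
        """Analytic integral of the Gaussian over [lo, hi]."""
        z = lambda x: (x - self.mean) / (self.sigma * np.sqrt(2))
        return 0.5 * self.area * (erf(z(hi)) - erf(z(lo)))


# ---------------------------------------------------------------------------
# clean / non-clean classification
# ---------------------------------------------------------------------------

def _is_own_isotopologue(mz: float, target_mz: float, config: CleanRuleConfig) -> bool:
    from .constants import C13_C12_DELTA

    for j in range(config.n_isotopes):
        ref = target_mz + j * C13_C12_DELTA
        if abs(mz - ref) <= config.isotope_ppm * 1e-6 * ref:
            return True
    return False


def classify_clean(
    peaklist: pd.DataFrame,
    target_mz: float,
    formula: MolecularFormula | str | None = None,
    mode: str = "qtof",
    config: CleanRuleConfig | None = None,
    target_inv_k0: float | None = None,
    m1_intensity: float | None = None,
) -> tuple[str, pd.DataFrame]:
    """Classify a target peak as ``"clean"`` or ``"non_clean"``.

    The reference intensity is the target's first isotopologue: measured
    when ``m1_intensity`` is given, otherwise theoretical (target intensity
    times the M+1/M ratio from the formula). Peaks matching the target's
    own isotope envelope within a ppm tolerance are not counted as
    interferents. Returns the verdict and the interferent rows.
    """
    if mode not in ("qtof", "tims"):
        raise ValueError("mode must be 'qtof' or 'tims'")
    cfg = config or CleanRuleConfig()
    df = peaklist

    target_rows = df[np.isclose(df["mz"], target_mz, rtol=0, atol=1e-6)]
    if target_rows.empty:
        raise ValueError(f"target m/z {target_mz} not present in the peak list")
    target_intensity = float(target_rows["intensity"].sum())
    if mode == "tims":
        if "inv_k0" not in df.columns or df["inv_k0"].isna().any():
            raise ValueError("TIMS mode requires mobilities for every peak")
        if target_inv_k0 is None:
            target_inv_k0 = float(
                (target_rows["inv_k0"] * target_rows["intensity"]).sum()
                / target_intensity
            )

    if m1_intensity is not None:
        ref = float(m1_intensity)
    else:
        if formula is None:
            raise ValueError("theoretical M+1 reference requires a formula")
        if isinstance(formula, str):
            formula = MolecularFormula.from_string(formula)
        env = isotope_pattern(formula, 2)
        ref = target_intensity * env[1]

    window = (df["mz"] >= target_mz - cfg.mass_window_da) & (
        df["mz"] <= target_mz + cfg.mass_window_da
    )
    cand = df[window].copy()
    own = cand["mz"].apply(lambda m: _is_own_isotopologue(m, target_mz, cfg))
    cand = cand[~own]
    cand = cand[cand["intensity"] > ref]
    if mode == "tims":
        cand = cand[(cand["inv_k0"] - target_inv_k0).abs() <= cfg.mobility_window]
    verdict = "non_clean" if len(cand) else "clean"
    return verdict, cand


# ---------------------------------------------------------------------------
# extracted ion mobilograms
# ---------------------------------------------------------------------------

def extract_eim(
    peaklist: pd.DataFrame,
    mz_center: float,
    tol: float = 0.01,
    tol_unit: str = "da",
    mobility_bin: float = 0.001,
) -> EIM:
    """Histogram peak intensities over mobility for an m/z window.

    ``tol_unit`` is ``"da"`` or ``"ppm"``; the default binning is
    0.001 Vs/cm^2. An empty selection yields an empty EIM with a warning.
    """
    if "inv_k0" not in peaklist.columns:
        raise ValueError("peak list has no mobility column")
    if tol_unit == "ppm":
        half = tol * 1e-6 * mz_center
    elif tol_unit == "da":
        half = tol
    else:
        raise ValueError("tol_unit must be 'da' or 'ppm'")
    sel = peaklist[(peaklist["mz"] - mz_center).abs() <= half]
    if sel.empty:
        warnings.warn(f"no peaks within {half} Da of {mz_center}", stacklevel=2)
        return EIM(np.array([]), np.array([]), (mz_center - half, mz_center + half))
    lo = np.floor(sel["inv_k0"].min() / mobility_bin) * mobility_bin
    hi = np.ceil(sel["inv_k0"].max() / mobility_bin) * mobility_bin
    edges = np.arange(lo, hi + 1.5 * mobility_bin, mobility_bin)
    hist, _ = np.histogram(sel["inv_k0"], bins=edges, weights=sel["intensity"])
    centers = 0.5 * (edges[:-1] + edges[1:])
    return EIM(centers, hist, (mz_center - half, mz_center + half))


def _gauss_sum(x, *params):
    y = np.zeros_like(x)
    for i in range(0, len(params), 3):
        a, mu, sig = params[i:i + 3]
        y = y + a * np.exp(-0.5 * ((x - mu) / sig) ** 2)
    return y


def fit_gaussians(
    eim: EIM,
    n_components: int,
    init: list[GaussianComponent] | None = None,
) -> tuple[list[GaussianComponent], float]:
    """Nonlinear least-squares fit of a sum of Gaussians to an EIM.

    Initialisation comes from the n largest local maxima unless provided;
    the fit is deterministic for a fixed initialisation. Returns the
    components (sorted by mean) and the residual sum of squares. A
    component whose amplitude collapses below 1% of the largest is the
    caller's signal that the model is over-parameterised.
    """
    x, y = eim.mobility, eim.intensity
    if x.size < 3 * n_components:
        raise ValueError("not enough EIM points for the requested components")
    dx = float(np.diff(x).min())
    if init is None:
        # seed from the largest local maxima, widths from FWHM; when fewer
        # maxima than components exist, surplus components share the
        # strongest peak with split amplitude
        from scipy.signal import peak_widths

        peaks, _ = find_peaks(y, height=y.max() * 0.01)
        if peaks.size == 0:
            peaks = np.array([int(np.argmax(y))])
        widths = peak_widths(y, peaks, rel_height=0.5)[0] * dx / 2.355
        order = np.argsort(-y[peaks])
        peaks, widths = peaks[order], widths[order]
        p0 = []
        for i in range(n_components):
            k = peaks[i % len(peaks)]
            reuse = i >= len(peaks)
            p0 += [y[k] / (2.0 if reuse else 1.0),
                   x[k] + (2 * dx if reuse else 0.0),
                   max(widths[i % len(widths)], dx)]
    else:
        p0 = []
        for c in init:
            p0 += [c.amplitude, c.mean, c.sigma]
    lower = [0.0, x[0], dx / 2] * n_components
    upper = [2.0 * float(y.max()) + 1e-12, x[-1],
             (x[-1] - x[0]) / 2 or 1.0] * n_components
    p0 = np.clip(p0, lower, upper)
    try:
        popt, _ = curve_fit(_gauss_sum, x, y, p0=p0, bounds=(lower, upper),
                            maxfev=20000)
    except RuntimeError as exc:
        rss = float(np.sum((y - _gauss_sum(x, *p0)) ** 2))
        raise RuntimeError(f"EIM fit did not converge (initial RSS {rss:.3g})") from exc
    comps = [
        GaussianComponent(amplitude=popt[i], mean=popt[i + 1], sigma=popt[i + 2])
        for i in range(0, len(popt), 3)
    ]
    comps.sort(key=lambda c: c.mean)
    rss = float(np.sum((y - _gauss_sum(x, *popt)) ** 2))
    return comps, rss


def purity_ratio(
    components: list[GaussianComponent],
    window: tuple[float, float],
    target_index: int = 0,
) -> dict:
    """AUC shares of each component inside an isolation window.

    Shares are normalised to the window total (they sum to 1); the
    target/interferent ratio is target AUC over the summed AUC of all
    other components within the window.
    """
    lo, hi = window
    if hi <= lo:
        raise ValueError("empty isolation window")
    areas = np.array([c.integral(lo, hi) for c in components])
    total = areas.sum()
    if total <= 0:
        raise ValueError("no signal inside the isolation window")
    shares = areas / total
    interferent = total - areas[target_index]
    ratio = float("inf") if interferent == 0 else float(areas[target_index] / interferent)
    return {
        "shares": shares,
        "target_share": float(shares[target_index]),
        "target_interferent_ratio": ratio,
    }


# ---------------------------------------------------------------------------
# iprm-PASEF scheduling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Precursor:
    """Candidate precursor with its fitted mobility interval."""

    name: str
    mobility_lo: float
    mobility_hi: float

    def overlaps(self, other: "Precursor") -> bool:
        return self.mobility_lo <= other.mobility_hi and other.mobility_lo <= self.mobility_hi


def schedule_precursors(
    candidates: list[Precursor], max_per_batch: int = 15
) -> list[list[Precursor]]:
    """Pack precursors into acquisitions of <= ``max_per_batch`` pairwise
    non-overlapping mobility intervals.

    Classic interval partitioning: candidates sorted by interval start are
    assigned to the lowest-indexed batch that has room and no mobility
    overlap; a new batch opens when none fits. Every candidate is assigned
    exactly once.
    """
    if max_per_batch < 1:
        raise ValueError("batch capacity must be >= 1")
    batches: list[list[Precursor]] = []
    for cand in sorted(candidates, key=lambda p: (p.mobility_lo, p.mobility_hi)):
        placed = False
        for batch in batches:
            if len(batch) < max_per_batch and not any(cand.overlaps(p) for p in batch):
                batch.append(cand)
                placed = True
                break
        if not placed:
            batches.append([cand])
    return batches


def precursor_from_component(
    name: str, component: GaussianComponent, n_sigma: float = 3.0
) -> Precursor:
    """Mobility interval mean +- n*sigma for scheduling."""
    return Precursor(name, component.mean - n_sigma * component.sigma,
                     component.mean + n_sigma * component.sigma)


# ---------------------------------------------------------------------------
# peak-list I/O
# ---------------------------------------------------------------------------

def peaklist_from_csv(path) -> pd.DataFrame:
    """Read a peak list CSV with columns x, y, mz, intensity[, inv_k0]."""
    df = pd.read_csv(path)
    missing = set(PEAK_COLUMNS[:4]) - set(df.columns)
    if missing:
        raise ValueError(f"peak list missing columns: {sorted(missing)}")
    return df


def peaklist_from_imzml(path, mobility_array: str | None = None) -> pd.DataFrame:
    """Flatten an imzML file into the tabular peak-list form.

    Mobility is taken from the named extra array when present (profile
    TIMS exports vary in how they encode 1/K0).
    """
    from pyimzml.ImzMLParser import ImzMLParser

    parser = ImzMLParser(str(path))
    rows = []
    for i, (x, y, *_rest) in enumerate(parser.coordinates):
        mzs, intensities = parser.getspectrum(i)
        for mz, inten in zip(mzs, intensities):
            rows.append((x, y, float(mz), float(inten), np.nan))
    return pd.DataFrame(rows, columns=list(PEAK_COLUMNS))
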