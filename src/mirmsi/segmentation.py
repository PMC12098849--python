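"""Tissue masking and feature-selective segmentation.

Tissue is separated from background by a two-component Gaussian mixture on
the mean amide-band intensity (amide I/II at 1656 and 1548 cm^-1). Regions
are then partitioned by k-means on a reduced cube of hand-picked
wavenumbers (e.g. 1466, 988, 1740, 1548, 1656 cm^-1 for the
sulfatide-accumulation use case), with the cluster count chosen by the
Calinski-Harabasz score. Z-score maps against a reference region support
box-plot style comparisons between modalities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import calinski_harabasz_score
from sklearn.mixture import GaussianMixture

from .hyperspectral import HyperCube

__all__ = [
    "TissueMask",
    "SegmentationResult",
    "FeatureSet",
    "tissue_mask",
    "kmeans_segment",
    "choose_k",
    "zscore_compare",
]

AMIDE_BANDS = (1548.0, 1656.0)


@dataclass
class TissueMask:
    """Binary tissue/background mask with provenance."""

    mask: np.ndarray
    bands: tuple[float, ...]
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")

    @property
    def n_foreground(self) -> int:
        return int(self.mask.sum())


@dataclass
class SegmentationResult:
    """Label image (0..k-1 inside the mask, -1 outside) plus diagnostics."""

    labels: np.ndarray
    k: int
    scores: dict[int, float]
    seed: int
    feature_wavenumbers: tuple[float, ...]

    def __post_init__(self):
        lab = np.asarray(self.labels)
        inside = lab[lab >= 0]
        if inside.size and inside.max() >= self.k:
            raise ValueError("labels exceed cluster count")
        self.labels = lab


@dataclass(frozen=True)
class FeatureSet:
    """Named wavenumber selection for one segmentation use case."""

    name: str
    wavenumbers: tuple[float, ...]
    derivative_mode: str = "derivative2"

    def __post_init__(self):
        if not self.wavenumbers:
            raise ValueError("feature set must contain at least one wavenumber")


#: canonical use-case feature sets
FEATURE_SETS = {
    "brain": FeatureSet("brain", (1466.0, 1742.0)),
    "spheroid": FeatureSet("spheroid", (1466.0, 1742.0)),
    "kidney_medulla": FeatureSet(
        "kidney_medulla", (1466.0, 988.0, 1740.0, 1548.0, 1656.0)
    ),
    "eae_lesion": FeatureSet(
        "eae_lesion", (1374.0, 1466.0, 1548.0, 1656.0, 1740.0)
    ),
}


def _masked_features(cube: HyperCube, mask: np.ndarray, standardize: bool):
    x = cube.values[mask]
    if standardize:
        mu = x.mean(axis=0)
        sd = x.std(axis=0)
        sd[sd == 0] = 1.0
        x = (x - mu) / sd
    return x


def tissue_mask(
    cube: HyperCube,
    amide_bands: tuple[float, float] = AMIDE_BANDS,
    seed: int = 0,
) -> TissueMask:
    """Two-component 1-D Gaussian mixture on the mean amide intensity.

    Foreground is the component with the higher mean. Deterministic for a
    fixed seed. Raises on an (all-constant) image where the mixture would be
    degenerate.
    """
    idx = [cube.axis.index_of(w) for w in amide_bands]
    amide = cube.values[:, :, idx].mean(axis=2)
    flat = amide.reshape(-1, 1)
    if np.ptp(flat) < 1e-12:
        raise ValueError("degenerate mixture: amide image is constant")
    gmm = GaussianMixture(n_components=2, random_state=seed, n_init=1,
                          covariance_type="full")
    resp = gmm.fit_predict(flat)
    fg_comp = int(np.argmax(gmm.means_.ravel()))
    mask = (resp == fg_comp).reshape(amide.shape)
    return TissueMask(
        mask=mask,
        bands=tuple(amide_bands),
        params={"means": gmm.means_.ravel().tolist(), "seed": seed},
    )


def kmeans_segment(
    cube: HyperCube,
    mask: TissueMask | np.ndarray,
    k: int,
    seed: int = 0,
    standardize: bool = True,
) -> SegmentationResult:
    """k-means on the per-pixel feature vectors of masked pixels.

    Uses k-means++ initialisation under the given seed; cluster labels are
    canonicalised by descending cluster size so the partition (not the
    arbitrary k-means ordering) defines the output. Per-band
    standardisation over masked pixels is on by default.
    """
    m = mask.mask if isinstance(mask, TissueMask) else np.asarray(mask, dtype=bool)
    if k < 2:
        raise ValueError("k must be >= 2")
    if m.sum() < k:
        raise ValueError(f"only {int(m.sum())} masked pixels for k={k}")
    x = _masked_features(cube, m, standardize)
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    raw = km.fit_predict(x)
    # canonical order: biggest cluster first
    sizes = np.bincount(raw, minlength=k)
    order = np.argsort(-sizes, kind="stable")
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(k)
    labels = np.full(m.shape, -1, dtype=int)
    labels[m] = remap[raw]
    return SegmentationResult(
        labels=labels, k=k, scores={},
        seed=seed, feature_wavenumbers=tuple(cube.axis.wavenumbers.tolist()),
    )


def choose_k(
    cube: HyperCube,
    mask: TissueMask | np.ndarray,
    k_range: range | tuple[int, int] = (2, 10),
    seed: int = 0,
    standardize: bool = True,
) -> tuple[int, dict[int, float]]:
    """Pick k by maximising the Calinski-Harabasz score.

    Ties break toward smaller k; all candidate scores are returned.
    """
    m = mask.mask if isinstance(mask, TissueMask) else np.asarray(mask, dtype=bool)
    if isinstance(k_range, tuple):
        candidates = list(range(k_range[0], k_range[1] + 1))
    else:
        candidates = list(k_range)
    if not candidates:
        raise ValueError("empty k range")
    n_px = int(m.sum())
    if any(k < 2 or k > n_px - 1 for k in candidates):
        raise ValueError("k candidates must lie in [2, n_pixels - 1]")
    x = _masked_features(cube, m, standardize)
    scores: dict[int, float] = {}
    for k in candidates:
        km = KMeans(n_clusters=k, random_state=seed, n_init=10)
        lab = km.fit_predict(x)
        scores[k] = float(calinski_harabasz_score(x, lab))
    best = max(sorted(scores), key=lambda k: (scores[k], -k))
    return best, scores


def zscore_compare(roi_values: np.ndarray, reference_values: np.ndarray):
    """Z-scores of ROI values against a reference region.

    Z = (x - mean_ref) / sd_ref with the population-SD convention. Returns
    (z array, summary dict with median and quartiles) suitable for box
    plots.
    """
    ref = np.asarray(reference_values, dtype=float).ravel()
    roi = np.asarray(roi_values, dtype=float).ravel()
    if ref.size < 2:
        raise ValueError("reference needs at least 2 values")
    sd = ref.std()  # population convention
    if sd == 0:
        raise ValueError("reference region has zero variance")
    z = (roi - ref.mean()) / sd
    q1, med, q3 = np.percentile(z, [25, 50, 75])
    summary = {
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "mean": float(z.mean()),
        "n": int(z.size),
    }
    return z, summary
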