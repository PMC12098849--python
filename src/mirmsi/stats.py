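"""Volcano statistics for ROI-grouped MSI feature intensities.

Per-feature two-sided t-tests (Welch by default) between two pixel or
replicate groups, Benjamini-Hochberg correction across features, and the
usual flagging rule (adjusted p below alpha and fold change beyond a
threshold, 3 by default). Observations should normally be per-replicate
aggregates; testing pixels directly pseudo-replicates and a warning says
so.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = ["VolcanoResult", "ttest_volcano", "bh_adjust", "aggregate_replicates"]


@dataclass
class VolcanoResult:
    """Per-feature fold changes, test statistics and flags."""

    table: pd.DataFrame  # feature, log2_fc, fold_change, t, p, q, flagged
    fc_threshold: float
    alpha: float

    @property
    def flagged(self) -> pd.DataFrame:
        return self.table[self.table["flagged"]]


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def ttest_volcano(
    matrix: pd.DataFrame,
    groups: np.ndarray,
    group_a: str,
    group_b: str,
    fc_threshold: float = 3.0,
    alpha: float = 0.05,
    equal_var: bool = False,
    pseudo_count: float = 0.0,
) -> VolcanoResult:
    """Two-sample volcano analysis over features (columns of ``matrix``).

    Fold change is the ratio of group means of raw intensities (log2 for
    plotting); a configurable pseudo-count guards against zero means. A
    feature with zero variance in both groups gets p = 1 with a warning.
    Flags require q < alpha and fold change >= threshold in either
    direction.
    """
    g = np.asarray(groups)
    a = matrix.loc[g == group_a]
    b = matrix.loc[g == group_b]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    if (matrix.to_numpy() < 0).any():
        raise ValueError("negative intensities in the feature matrix")

    mean_a = a.mean(axis=0) + pseudo_count
    mean_b = b.mean(axis=0) + pseudo_count
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = mean_a / mean_b
        log2_fc = np.log2(fc)

    t_stat, p = sps.ttest_ind(a, b, axis=0, equal_var=equal_var)
    degenerate = (a.std(axis=0) == 0) & (b.std(axis=0) == 0)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} features have zero variance in both "
            "groups; p set to 1", stacklevel=2,
        )
        p = np.where(degenerate, 1.0, p)
        t_stat = np.where(degenerate, 0.0, t_stat)
    p = np.nan_to_num(p, nan=1.0)
    q = bh_adjust(p)
    fc_arr = fc.to_numpy(dtype=float)
    beyond = (fc_arr >= fc_threshold) | (fc_arr <= 1.0 / fc_threshold)
    flagged = (q < alpha) & beyond
    table = pd.DataFrame({
        "feature": matrix.columns,
        "fold_change": fc_arr,
        "log2_fc": np.asarray(log2_fc, dtype=float),
        "t": np.asarray(t_stat, dtype=float),
        "p": p,
        "q": q,
        "flagged": flagged,
    })
    return VolcanoResult(table=table, fc_threshold=fc_threshold, alpha=alpha)


def aggregate_replicates(
    pixel_matrix: pd.DataFrame, replicate_ids: np.ndarray, how: str = "median"
) -> pd.DataFrame:
    """Collapse pixel observations to per-replicate aggregates (median by
    default) before testing, avoiding pseudo-replication."""
    if how not in ("median", "mean"):
        raise ValueError("how must be 'median' or 'mean'")
    grouped = pixel_matrix.groupby(np.asarray(replicate_ids))
    return grouped.median() if how == "median" else grouped.mean()
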