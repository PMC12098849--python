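"""Structure-CCS relationship modelling for homologous lipid series.

Across a homologous series, collision cross sections grow smoothly with
chain length; subclasses that differ only in head group run on parallel
curves. The parallel-line model fits CCS(x; g) = a x^2 + b x + c_g by
global least squares with the quadratic and linear amplitudes shared
across groups and subclass-specific intercepts, so that the intercept
difference DeltaCCS = c_A - c_B measures the head-group contribution
directly (e.g. ~28 A^2 per hexose between SM4 and SM3 series). Plain
linear (shared slope) and power-law y = b x^(2/3) + c_g fits are provided
for model comparison, plus prediction-deviation and cross-platform
metrics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "SeriesFit",
    "DeltaCCS",
    "fit_series",
    "delta_ccs",
    "mean_relative_deviation",
    "cross_platform_compare",
    "recalibrate_ccs",
    "inv_k0_to_ccs",
]

MODELS = ("poly2_parallel", "linear", "power23")


@dataclass
class SeriesFit:
    """Parallel-curve fit: shared shape coefficients, per-group intercepts."""

    model: str
    shared: dict[str, float]
    intercepts: dict[str, float]
    covariance: np.ndarray
    param_names: list[str]
    rss: float
    n_obs: int

    def predict(self, x: np.ndarray, group: str) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        c = self.intercepts[group]
        if self.model == "poly2_parallel":
            return self.shared["a"] * x**2 + self.shared["b"] * x + c
        if self.model == "linear":
            return self.shared["b"] * x + c
        if self.model == "power23":
            return self.shared["b"] * x ** (2.0 / 3.0) + c
        raise ValueError(self.model)


@dataclass
class DeltaCCS:
    """Intercept difference between two groups, with uncertainty."""

    group_a: str
    group_b: str
    value: float
    uncertainty: float
    n_replicates: int = 1


def _design(x: np.ndarray, groups: list[str], group_names: list[str], model: str):
    cols = []
    names = []
    if model == "poly2_parallel":
        cols += [x**2, x]
        names += ["a", "b"]
    elif model == "linear":
        cols += [x]
        names += ["b"]
    elif model == "power23":
        cols += [x ** (2.0 / 3.0)]
        names += ["b"]
    else:
        raise ValueError(f"unknown model {model!r}")
    for g in group_names:
        cols.append((np.asarray(groups) == g).astype(float))
        names.append(f"c[{g}]")
    return np.column_stack(cols), names


def fit_series(
    records: pd.DataFrame,
    model: str = "poly2_parallel",
    x_col: str = "n",
    y_col: str = "ccs_A2",
    group_col: str = "subclass",
) -> SeriesFit:
    """Global least squares over all groups with shared shape terms.

    Requires at least 3 distinct chain lengths per group for the quadratic
    model; raises naming the offending group on rank deficiency.
    """
    df = records
    group_names = sorted(df[group_col].unique())
    min_x = 3 if model == "poly2_parallel" else 2
    for g in group_names:
        nx = df.loc[df[group_col] == g, x_col].nunique()
        if nx < min_x:
            raise ValueError(
                f"group {g!r} has only {nx} distinct chain lengths "
                f"(needs >= {min_x} for {model})"
            )
    x = df[x_col].to_numpy(dtype=float)
    y = df[y_col].to_numpy(dtype=float)
    X, names = _design(x, df[group_col].tolist(), group_names, model)
    res = sm.OLS(y, X).fit()
    params = dict(zip(names, res.params))
    shared = {k: v for k, v in params.items() if not k.startswith("c[")}
    intercepts = {g: params[f"c[{g}]"] for g in group_names}
    if res.df_resid > 0:
        cov = np.asarray(res.cov_params())
    else:  # exact interpolation: no residual dof, covariance is all-zero
        cov = np.zeros((len(names), len(names)))
    return SeriesFit(
        model=model,
        shared=shared,
        intercepts=intercepts,
        covariance=cov,
        param_names=names,
        rss=float(res.ssr),
        n_obs=len(df),
    )


def delta_ccs(
    fit_or_records: "SeriesFit | pd.DataFrame",
    group_a: str,
    group_b: str,
    model: str = "poly2_parallel",
    replicate_col: str = "replicate",
) -> DeltaCCS:
    """DeltaCCS = c_A - c_B.

    Given a fit, the standard error comes from the parameter covariance.
    Given raw records with a replicate column, the parallel-line fit runs
    per replicate and the result is the mean +- sd across replicates.
    """
    if isinstance(fit_or_records, pd.DataFrame):
        df = fit_or_records
        if replicate_col in df.columns and df[replicate_col].nunique() > 1:
            values = []
            for _, sub in df.groupby(replicate_col):
                f = fit_series(sub, model=model)
                values.append(f.intercepts[group_a] - f.intercepts[group_b])
            v = np.asarray(values)
            return DeltaCCS(group_a, group_b, float(v.mean()),
                            float(v.std(ddof=1)), n_replicates=len(v))
        fit = fit_series(df, model=model)
    else:
        fit = fit_or_records
    for g in (group_a, group_b):
        if g not in fit.intercepts:
            raise ValueError(f"group {g!r} not in fit")
    ia = fit.param_names.index(f"c[{group_a}]")
    ib = fit.param_names.index(f"c[{group_b}]")
    value = fit.intercepts[group_a] - fit.intercepts[group_b]
    if group_a == group_b:
        return DeltaCCS(group_a, group_b, 0.0, 0.0)
    var = (fit.covariance[ia, ia] + fit.covariance[ib, ib]
           - 2 * fit.covariance[ia, ib])
    return DeltaCCS(group_a, group_b, float(value), float(np.sqrt(max(var, 0.0))))


def mean_relative_deviation(
    experimental: pd.DataFrame,
    predicted: pd.DataFrame,
    key: str = "shorthand",
    value_col: str = "ccs_A2",
) -> tuple[float, pd.DataFrame]:
    """Mean relative deviation eps_bar (%) between paired CCS values.

    eps = 100 * |CCS_exp - CCS_pred| / CCS_exp per pair, sign-less;
    eps_bar is their mean. Raises listing any unmatched keys.
    """
    e = experimental.set_index(key)[value_col]
    p = predicted.set_index(key)[value_col]
    missing = sorted(set(e.index) ^ set(p.index))
    if missing:
        raise ValueError(f"unmatched keys: {missing}")
    if (e <= 0).any():
        raise ValueError("experimental CCS must be positive")
    eps = 100.0 * (e - p).abs() / e
    table = pd.DataFrame({"experimental": e, "predicted": p, "epsilon_pct": eps})
    return float(eps.mean()), table.reset_index()


def cross_platform_compare(
    msi: pd.DataFrame,
    lc: pd.DataFrame,
    key: str = "shorthand",
    value_col: str = "ccs_A2",
) -> dict:
    """OLS of LC CCS against MSI CCS on shared species, plus R^2 and
    eps_bar. Needs at least 3 shared species."""
    shared = sorted(set(msi[key]) & set(lc[key]))
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared species (need >= 3)")
    xm = msi.set_index(key).loc[shared, value_col].to_numpy(dtype=float)
    yl = lc.set_index(key).loc[shared, value_col].to_numpy(dtype=float)
    X = sm.add_constant(xm)
    res = sm.OLS(yl, X).fit()
    eps = 100.0 * np.abs(xm - yl) / xm
    return {
        "slope": float(res.params[1]),
        "intercept": float(res.params[0]),
        "r2": float(res.rsquared),
        "eps_bar_pct": float(eps.mean()),
        "n": len(shared),
    }


def recalibrate_ccs(
    records: pd.DataFrame,
    reference_pairs: pd.DataFrame,
    value_col: str = "ccs_A2",
    off_col: str = "ccs_off",
    ref_col: str = "ccs_ref",
) -> pd.DataFrame:
    """Shift off-condition records onto the reference condition.

    The multiplicative factor is the mean ratio off/ref over the reference
    subset (e.g. SM3 species acquired at both gas flows); all records are
    divided by it, which zeroes the mean relative deviation of the
    reference subset by construction.
    """
    if reference_pairs.empty:
        raise ValueError("empty reference subset")
    factor = float((reference_pairs[off_col] / reference_pairs[ref_col]).mean())
    out = records.copy()
    out[value_col] = out[value_col] / factor
    out.attrs["recalibration_factor"] = factor
    return out


def inv_k0_to_ccs(inv_k0: float, charge: int, mz: float,
                  gas_mass_da: float = 28.0134, temperature_k: float = 305.0) -> float:
    """Mason-Schamp conversion helper (plumbing, not a calibrated claim).

    CCS = z/(1/K0 reciprocal...) -- uses the low-field Mason-Schamp form
    with nitrogen drift gas; exported CCS tables are the normal input path.
    """
    e = 1.602176634e-19
    kb = 1.380649e-23
    n0 = 2.686780111e25  # Loschmidt, m^-3
    amu = 1.66053906660e-27
    m_ion = abs(charge) * mz * amu
    m_gas = gas_mass_da * amu
    mu = m_ion * m_gas / (m_ion + m_gas)
    k0 = 1.0 / inv_k0  # cm^2/(V s)
    ccs_m2 = (3.0 * abs(charge) * e / (16.0 * n0)) * np.sqrt(
        2.0 * np.pi / (mu * kb * temperature_k)
    ) / (k0 * 1e-4)
    return float(ccs_m2 * 1e20)  # A^2
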