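"""Saturating divergence-curve fitting and between-sex parameter comparison.

Model: Y = 1 + a * (1 - b**X) with a the asymptotic divergence increment
and b in (0, 1) the per-unit retention rate, fitted by bounded nonlinear
least squares. Parameters are compared between sexes with Welch-type
t-tests on the asymptotic standard errors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = ["DivergenceSeries", "DivergenceCurveFit", "divergence_model",
           "fit_divergence_curve", "compare_parameters", "read_divergence_series"]


def divergence_model(x: np.ndarray, a: float, b: float) -> np.ndarray:
    return 1.0 + a * (1.0 - np.power(b, x))


@dataclass
class DivergenceSeries:
    x: np.ndarray
    y: np.ndarray
    sex: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.sex = np.asarray(self.sex)
        if not (len(self.x) == len(self.y) == len(self.sex)):
            raise ValueError("x, y, sex must have equal length")
        if np.any(~np.isfinite(self.y)):
            raise ValueError("divergence values must be finite")
        if np.any(self.x < 0):
            raise ValueError("time values must be >= 0")

    def for_sex(self, sex: str) -> tuple[np.ndarray, np.ndarray]:
        mask = self.sex == sex
        return self.x[mask], self.y[mask]


@dataclass
class DivergenceCurveFit:
    sex: str
    a: float
    b: float
    se_a: float
    se_b: float
    resid_var: float
    df: int
    n: int

    def predict(self, x: np.ndarray) -> np.ndarray:
        return divergence_model(np.asarray(x, dtype=float), self.a, self.b)


def fit_divergence_curve(series: DivergenceSeries, sex: str,
                         max_iter: int = 200) -> DivergenceCurveFit:
    """Fit Y = 1 + a(1 - b^X) for one sex by bounded least squares."""
    x, y = series.for_sex(sex)
    n = x.size
    if n < 3:
        raise ValueError(f"need >= 3 observations for sex {sex!r}, got {n}")
    a0 = max(float(np.max(y)) - 1.0, 1e-3)
    b0 = 0.5

    def resid(theta):
        a, b = theta
        return y - divergence_model(x, a, b)

    sol = optimize.least_squares(
        resid, x0=[a0, b0],
        bounds=([-np.inf, 1e-12], [np.inf, 1.0 - 1e-12]),
        max_nfev=max_iter * 10, xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    if not sol.success:
        raise RuntimeError(f"curve fit failed for sex {sex!r}: {sol.message}")
    a_hat, b_hat = sol.x
    df = n - 2
    rss = float(np.sum(sol.fun ** 2))
    resid_var = rss / df if df > 0 else np.nan
    J = sol.jac
    JtJ = J.T @ J
    try:
        cov = resid_var * np.linalg.inv(JtJ)
        se_a, se_b = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se_a = se_b = np.nan
    return DivergenceCurveFit(sex=sex, a=float(a_hat), b=float(b_hat),
                              se_a=float(se_a), se_b=float(se_b),
                              resid_var=resid_var, df=df, n=n)


def _welch(est1, est2, se1, se2, df1, df2) -> tuple[float, float, float]:
    var = se1 ** 2 + se2 ** 2
    if var <= 1e-20:  # numerically perfect fits
        raise ValueError("zero standard errors: fits are exact, compare "
                         "parameters directly")
    t = (est1 - est2) / np.sqrt(var)
    # Welch-Satterthwaite df from the two fits' residual dfs
    denom = se1 ** 4 / df1 + se2 ** 4 / df2
    df = var ** 2 / denom if denom > 0 else df1 + df2
    p = float(2.0 * stats.t.sf(abs(t), df))
    return float(t), float(df), p


def compare_parameters(fit_F: DivergenceCurveFit,
                       fit_M: DivergenceCurveFit) -> dict:
    """Welch-type t-tests comparing (a, b) between the two fits."""
    t_a, df_a, p_a = _welch(fit_F.a, fit_M.a, fit_F.se_a, fit_M.se_a,
                            fit_F.df, fit_M.df)
    t_b, df_b, p_b = _welch(fit_F.b, fit_M.b, fit_F.se_b, fit_M.se_b,
                            fit_F.df, fit_M.df)
    return {"t_a": t_a, "df_a": df_a, "p_a": p_a,
            "t_b": t_b, "df_b": df_b, "p_b": p_b}


def read_divergence_series(path) -> DivergenceSeries:
    """Read a TSV with columns time, divergence, sex."""
    df = pd.read_csv(path, sep="\t")
    required = {"time", "divergence", "sex"}
    if not required.issubset(df.columns):
        raise ValueError(f"missing columns: {sorted(required - set(df.columns))}")
    return DivergenceSeries(x=df["time"].to_numpy(),
                            y=df["divergence"].to_numpy(),
                            sex=df["sex"].to_numpy())
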