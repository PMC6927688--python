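"""Apparent ligand affinity from the fraction of asymmetric particles.

At equilibrium the closed (symmetric) occupancy follows the Hill–Langmuir
law c ⁿ/(c ⁿ + K_d ⁿ), so the asymmetric (non-closed, putatively open)
fraction is

    f(c) = 1 − c ⁿ / (c ⁿ + K_d ⁿ),       f(K_d) = 1/2.

The Hill coefficient n is fixed at 1 by default: the experiment reports a
single apparent K_d, and freeing n on a handful of binomially sampled
points mostly fits noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = ["TitrationSeries", "asymmetric_fraction", "fit_kd", "KdFit"]


@dataclass
class TitrationSeries:
    """Per-condition asymmetric particle counts with binomial errors."""

    table: pd.DataFrame  # columns: conc_mM, n, n_asym, fraction, se

    @classmethod
    def from_counts(cls, conc_mM, n, n_asym) -> "TitrationSeries":
        conc = np.asarray(conc_mM, dtype=float)
        n = np.asarray(n, dtype=int)
        k = np.asarray(n_asym, dtype=int)
        if np.any(conc < 0):
            raise ValueError("concentrations must be >= 0")
        if np.any(k < 0) or np.any(k > n):
            raise ValueError("need 0 <= n_asym <= n")
        p = k / n
        se = np.sqrt(p * (1 - p) / n)
        return cls(
            table=pd.DataFrame(
                {"conc_mM": conc, "n": n, "n_asym": k, "fraction": p, "se": se}
            )
        )


def asymmetric_fraction(labels: pd.DataFrame, conc_mM: float) -> pd.DataFrame:
    """One titration row from per-particle class labels at one condition.

    A particle counts as dynamically asymmetric when it spends ≥ 50% of its
    frames in a non-closed class (per-frame wobble should not flip the
    call).  ``labels`` needs columns molecule_id and class.
    """
    mols = labels["molecule_id"].unique()
    if len(mols) == 0:
        raise ValueError("no particles at this condition")
    n_asym = 0
    for m in mols:
        sub = labels.loc[labels["molecule_id"] == m, "class"]
        if (sub != "closed").mean() >= 0.5:
            n_asym += 1
    n = len(mols)
    p = n_asym / n
    return pd.DataFrame(
        {
            "conc_mM": [conc_mM],
            "n": [n],
            "n_asym": [n_asym],
            "fraction": [p],
            "se": [np.sqrt(p * (1 - p) / n)],
        }
    )


@dataclass
class KdFit:
    kd_mM: float
    hill: float
    kd_ci: tuple[float, float]  # bootstrap 95% CI
    fitted: pd.DataFrame  # conc + fitted fraction


def _model(c, kd, n):
    c = np.asarray(c, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = 1.0 - c**n / (c**n + kd**n)
    return np.where(c == 0, 1.0, f)


def fit_kd(
    series: TitrationSeries,
    fix_hill: float | None = 1.0,
    n_bootstrap: int = 200,
    seed: int = 0,
) -> KdFit:
    """Weighted least-squares Hill–Langmuir fit of the asymmetric fraction.

    Weights are the binomial standard errors (floored to avoid zero-error
    points dominating); the confidence interval comes from a parametric
    bootstrap over particles.  With ``fix_hill=None`` the Hill coefficient
    is fitted too.
    """
    tab = series.table
    if len(tab) < 4:
        raise ValueError("need >= 4 concentrations spanning the transition")
    c = tab["conc_mM"].to_numpy()
    y = tab["fraction"].to_numpy()
    n_particles = tab["n"].to_numpy()
    sigma = np.clip(tab["se"].to_numpy(), 0.02, None)
    if y.min() > 0.7 or y.max() < 0.3:
        import warnings

        warnings.warn("titration does not span the transition; K_d poorly constrained")

    def run_fit(yy):
        if fix_hill is not None:
            popt, _ = curve_fit(
                lambda cc, kd: _model(cc, kd, fix_hill),
                c, yy, p0=[np.median(c)], sigma=sigma, bounds=(1e-6, 1e4), maxfev=10000,
            )
            return popt[0], fix_hill
        popt, _ = curve_fit(
            _model, c, yy, p0=[np.median(c), 1.0],
            sigma=sigma, bounds=([1e-6, 0.2], [1e4, 8.0]), maxfev=10000,
        )
        return popt[0], popt[1]

    kd, hill = run_fit(y)
    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_bootstrap):
        yy = rng.binomial(n_particles, np.clip(y, 0, 1)) / n_particles
        try:
            boots.append(run_fit(yy)[0])
        except RuntimeError:
            continue
    if boots:
        lo, hi = np.percentile(boots, [2.5, 97.5])
    else:
        lo = hi = float("nan")
    fitted = pd.DataFrame({"conc_mM": c, "fitted_fraction": _model(c, kd, hill)})
    return KdFit(kd_mM=float(kd), hill=float(hill), kd_ci=(float(lo), float(hi)), fitted=fitted)
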