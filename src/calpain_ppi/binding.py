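"""Binding models and curve fitting for split-luciferase biosensor assays.

The split-Nanoluciferase (LgBiT/SmBiT) biosensor reads out a bimolecular
protein–protein interaction as luminescence (relative light units, RLU)
proportional to the concentration of the reconstituted complex.  This module
provides the quantitative layer:

* equilibrium occupancy models — the hyperbolic single-site isotherm, the
  exact mass-balance ("ligand depletion") quadratic solution, and a
  competitive three-species solver;
* a four-parameter logistic (4PL) fitter on log10 concentration, the engine
  behind every K_D, EC50 and IC50 estimate;
* the inflection-point K_D estimator (4PL with Hill slope fixed to 1, the
  first-order-kinetics assumption) and a depletion-corrected alternative
  that fits the quadratic mass-balance model directly;
* assay quality statistics: Z-factor, fold change over a luciferase-only
  control, and a zero-slope Wald test for concentration independence.

Concentrations are nanomolar throughout unless stated otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize

__all__ = [
    "TitrationDataset",
    "DoseResponseFit",
    "AssayQuality",
    "SlopeTest",
    "FlatResponseError",
    "occupancy_hyperbolic",
    "occupancy_quadratic",
    "competitive_complex",
    "fit_4pl",
    "estimate_kd",
    "fit_ec50",
    "fit_ic50",
    "z_factor",
    "fold_change",
    "slope_zero_test",
    "read_assay_csv",
]

_UNIT_TO_NM = {"nM": 1.0, "uM": 1e3, "mM": 1e6}


class FlatResponseError(ValueError):
    """Raised when a response series shows no dose dependence to fit."""


# --------------------------------------------------------------------------
# datasets
# --------------------------------------------------------------------------


@dataclass
class TitrationDataset:
    """A concentration series with replicate RLU readings.

    ``rlu`` has shape (len(concentrations_nM), n_replicates).  The fixed
    component is the binding partner held at constant concentration (the
    LgBiT-tagged subunit in the saturation assays); the titrant is the
    partner added at increasing concentration.
    """

    titrant: str
    concentrations_nM: np.ndarray
    rlu: np.ndarray
    fixed_component: str = ""
    fixed_conc_nM: float = 0.0
    ion: str = ""        # divalent-ion condition, e.g. "Ca" or "Mg"
    ion_conc_mM: float = 0.0

    def __post_init__(self) -> None:
        self.concentrations_nM = np.asarray(self.concentrations_nM, dtype=float)
        self.rlu = np.atleast_2d(np.asarray(self.rlu, dtype=float))
        if self.rlu.shape[0] != self.concentrations_nM.size:
            if self.rlu.shape[1] == self.concentrations_nM.size:
                self.rlu = self.rlu.T
            else:
                raise ValueError("rlu shape does not match concentration grid")
        if self.concentrations_nM.size < 5:
            raise ValueError("need at least 5 concentrations for fitting")
        if np.any(self.concentrations_nM <= 0):
            raise ValueError("concentrations must be > 0")
        if np.any(np.diff(self.concentrations_nM) <= 0):
            raise ValueError("concentrations must be strictly increasing")
        if np.any(self.rlu < 0) or not np.all(np.isfinite(self.rlu)):
            raise ValueError("rlu values must be finite and >= 0")

    @property
    def n_replicates(self) -> int:
        return self.rlu.shape[1]

    def mean_rlu(self) -> np.ndarray:
        return self.rlu.mean(axis=1)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, c in enumerate(self.concentrations_nM):
            for j in range(self.n_replicates):
                rows.append(
                    {
                        "concentration": c,
                        "unit": "nM",
                        "replicate": j + 1,
                        "rlu": self.rlu[i, j],
                        "ion": self.ion,
                        "ion_conc_mM": self.ion_conc_mM,
                    }
                )
        return pd.DataFrame(rows)


def read_assay_csv(path: str | Path, fixed_conc_nM: float = 0.0) -> TitrationDataset:
    """Load an assay CSV with columns concentration, unit, replicate, rlu.

    Units nM/uM/mM are converted to nM.  Optional ``ion``/``ion_conc_mM``
    columns record the divalent-ion condition.
    """
    df = pd.read_csv(path)
    required = {"concentration", "replicate", "rlu"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"assay CSV missing columns {sorted(missing)}")
    if "unit" in df.columns:
        bad = set(df["unit"]) - set(_UNIT_TO_NM)
        if bad:
            raise ValueError(f"unknown concentration units {sorted(bad)}")
        df["conc_nM"] = df["concentration"] * df["unit"].map(_UNIT_TO_NM)
    else:
        df["conc_nM"] = df["concentration"]
    wide = df.pivot_table(index="conc_nM", columns="replicate", values="rlu")
    ion = str(df["ion"].iloc[0]) if "ion" in df.columns else ""
    ion_mM = float(df["ion_conc_mM"].iloc[0]) if "ion_conc_mM" in df.columns else 0.0
    return TitrationDataset(
        titrant="titrant",
        concentrations_nM=wide.index.to_numpy(),
        rlu=wide.to_numpy(),
        fixed_conc_nM=fixed_conc_nM,
        ion=ion,
        ion_conc_mM=ion_mM,
    )


# --------------------------------------------------------------------------
# occupancy models
# --------------------------------------------------------------------------


def occupancy_hyperbolic(L, kd: float):
    """Fractional occupancy L/(kd+L) of a single site at free-ligand L.

    Valid when the ligand is in large excess so free ~= total; otherwise
    use :func:`occupancy_quadratic`.
    """
    if kd <= 0:
        raise ValueError("kd must be > 0")
    L = np.asarray(L, dtype=float)
    if np.any(L < 0):
        raise ValueError("concentration must be >= 0")
    out = L / (kd + L)
    return float(out) if out.ndim == 0 else out


def occupancy_quadratic(a0, b0: float, kd: float):
    """Exact complex concentration [AB] for totals a0, b0 at dissociation kd.

    Solves the mass balance [AB]^2 - (a0+b0+kd)[AB] + a0*b0 = 0 for the
    physical root::

        [AB] = ((a0+b0+kd) - sqrt((a0+b0+kd)^2 - 4*a0*b0)) / 2

    kd = 0 gives the stoichiometric limit min(a0, b0); b0 -> 0 recovers the
    hyperbolic occupancy per unit b0.  The expanded form below avoids the
    catastrophic cancellation of the textbook root when a0*b0 << (a0+b0+kd)^2.
    """
    a0 = np.asarray(a0, dtype=float)
    if np.any(a0 < 0) or b0 < 0 or kd < 0:
        raise ValueError("concentrations and kd must be >= 0")
    s = a0 + b0 + kd
    disc = np.sqrt(np.maximum(s * s - 4.0 * a0 * b0, 0.0))
    # (s - disc)/2 == 2*a0*b0/(s + disc), the numerically stable form
    with np.errstate(divide="ignore", invalid="ignore"):
        ab = np.where(s + disc > 0, 2.0 * a0 * b0 / (s + disc), 0.0)
    ab = np.minimum(ab, np.minimum(a0, b0))
    return float(ab) if ab.ndim == 0 else ab


def competitive_complex(
    a0: float, b0: float, i0: float, kd_ab: float, kd_ai: float
) -> float:
    """[AB] when A is shared between reporter B and competitor I.

    Solves the coupled mass balance by bracketed root finding on free [A]:
    ``f(A) = A + A*b0/(kd_ab+A) + A*i0/(kd_ai+A) - a0`` is strictly
    increasing on [0, a0], so a unique root exists.
    """
    for name, v in (("a0", a0), ("b0", b0), ("i0", i0)):
        if v < 0:
            raise ValueError(f"{name} must be >= 0")
    if kd_ab <= 0 or kd_ai <= 0:
        raise ValueError("dissociation constants must be > 0")
    if a0 == 0 or b0 == 0:
        return 0.0

    def balance(a_free: float) -> float:
        return (
            a_free
            + a_free * b0 / (kd_ab + a_free)
            + a_free * i0 / (kd_ai + a_free)
            - a0
        )

    a_free = optimize.brentq(balance, 0.0, a0, xtol=1e-15, rtol=1e-14)
    return a_free * b0 / (kd_ab + a_free)


# --------------------------------------------------------------------------
# 4PL fitting
# --------------------------------------------------------------------------


@dataclass
class DoseResponseFit:
    """Result of a sigmoid (or quadratic-occupancy) fit.

    ``midpoint`` is the concentration at half-maximal response — reported as
    K_D, EC50 or IC50 depending on the calling mode.  The standard error and
    95% CI are computed on log10(midpoint) and back-transformed, which is
    why the interval is asymmetric around the point estimate.
    """

    model: str
    bottom: float
    top: float
    hill: float
    midpoint: float
    log10_midpoint: float
    se_log10_midpoint: float
    ci95_low: float
    ci95_high: float
    rss: float
    converged: bool
    n_points_used: int
    direction: Literal["ascending", "descending"]
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "bottom": self.bottom,
            "top": self.top,
            "hill": self.hill,
            "midpoint_nM": self.midpoint,
            "log10_midpoint": self.log10_midpoint,
            "se_log10_midpoint": self.se_log10_midpoint,
            "ci95_low_nM": self.ci95_low,
            "ci95_high_nM": self.ci95_high,
            "rss": self.rss,
            "converged": self.converged,
            "n_points_used": self.n_points_used,
            "direction": self.direction,
            "notes": list(self.notes),
        }


def _four_pl(logx: np.ndarray, bottom: float, top: float, logm: float, h: float):
    return bottom + (top - bottom) / (1.0 + 10.0 ** ((logm - logx) * h))


def _flat_check(y: np.ndarray, rep_sd: float) -> None:
    span = float(np.ptp(y))
    if span == 0.0 or (rep_sd > 0 and span < 3.0 * rep_sd):
        raise FlatResponseError(
            "no dose dependence: response range is within replicate noise"
        )


def fit_4pl(
    x: np.ndarray,
    y: np.ndarray,
    direction: Literal["auto", "ascending", "descending"] = "auto",
    hill_fixed: float | None = None,
    rep_sd: float = 0.0,
) -> DoseResponseFit:
    """Least-squares four-parameter logistic fit on log10 concentration.

    Model: ``y = bottom + (top - bottom) / (1 + 10**((log10(m) - log10(x))*h))``
    with midpoint ``m`` and Hill slope ``h`` (fixed when ``hill_fixed`` is
    given).  Parameters are initialised from the response range and the
    half-range crossing of the data.  After fitting, the result is
    normalised so that ``top >= bottom`` and the sign of ``h`` encodes the
    direction.  ``rep_sd`` (replicate noise scale) feeds the flat-response
    guard: a range below 3x noise raises :class:`FlatResponseError`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or x.size != y.size:
        raise ValueError("x and y must be 1-D and the same length")
    if np.unique(x).size < 5:
        raise ValueError("need at least 5 distinct concentrations")
    if np.any(x <= 0):
        raise ValueError("concentrations must be > 0 for a log-scale fit")
    if not np.all(np.isfinite(y)):
        raise ValueError("responses must be finite")
    _flat_check(y, rep_sd)
    logx = np.log10(x)

    ascending = float(np.corrcoef(logx, y)[0, 1]) >= 0
    if direction != "auto":
        wanted = direction == "ascending"
        if wanted != ascending:
            warnings.warn(
                f"data look {'ascending' if ascending else 'descending'} but "
                f"{direction} was requested; fitting the observed direction",
                stacklevel=2,
            )
    lo, hi = float(np.min(y)), float(np.max(y))
    half = (lo + hi) / 2.0
    order = np.argsort(logx)
    # half-range crossing: first grid point whose response passes the midline
    ys = y[order]
    xs = logx[order]
    if ascending:
        above = np.nonzero(ys >= half)[0]
    else:
        above = np.nonzero(ys <= half)[0]
    logm0 = xs[above[0]] if above.size else float(np.median(xs))
    h0 = 1.0 if ascending else -1.0

    if hill_fixed is not None:
        h_init = abs(hill_fixed) * (1.0 if ascending else -1.0)

        def model(lx, bottom, top, logm):
            return _four_pl(lx, bottom, top, logm, h_init)

        p0 = [lo, hi, logm0]
    else:

        def model(lx, bottom, top, logm, h):
            return _four_pl(lx, bottom, top, logm, h)

        p0 = [lo, hi, logm0, h0]

    converged = True
    notes: list[str] = []
    try:
        popt, pcov = optimize.curve_fit(
            model, logx, y, p0=p0, maxfev=20000, xtol=1e-12, ftol=1e-12
        )
    except RuntimeError:
        converged = False
        notes.append("least-squares solver did not converge")
        popt = np.asarray(p0, dtype=float)
        pcov = np.full((len(p0), len(p0)), np.nan)

    if hill_fixed is not None:
        bottom, top, logm = popt
        h = h_init
        var_logm = pcov[2, 2]
    else:
        bottom, top, logm, h = popt
        var_logm = pcov[2, 2]
    if bottom > top:  # normalise so top >= bottom; h keeps the direction
        bottom, top = top, bottom
        h = -h
    se = float(np.sqrt(var_logm)) if np.isfinite(var_logm) and var_logm >= 0 else float("nan")
    ci_lo = 10.0 ** (logm - 1.959963984540054 * se) if np.isfinite(se) else float("nan")
    ci_hi = 10.0 ** (logm + 1.959963984540054 * se) if np.isfinite(se) else float("nan")
    resid = y - model(logx, *popt)
    return DoseResponseFit(
        model="4PL",
        bottom=float(bottom),
        top=float(top),
        hill=float(h),
        midpoint=float(10.0 ** logm),
        log10_midpoint=float(logm),
        se_log10_midpoint=se,
        ci95_low=float(ci_lo),
        ci95_high=float(ci_hi),
        rss=float(np.sum(resid**2)),
        converged=converged,
        n_points_used=int(x.size),
        direction="ascending" if h > 0 else "descending",
        notes=notes,
    )


def _pooled_rep_sd(ds: TitrationDataset) -> float:
    if ds.n_replicates < 2:
        return 0.0
    return float(np.mean(ds.rlu.std(axis=1, ddof=1)))


def estimate_kd(
    ds: TitrationDataset,
    method: Literal["inflection", "quadratic"] = "inflection",
) -> DoseResponseFit:
    """Dissociation constant from a saturation titration.

    ``method='inflection'`` is the first-order-kinetics estimator: a 4PL fit
    with Hill slope fixed to 1 on mean RLU vs log10 titrant; the inflection
    (midpoint) is reported as K_D.  It treats total titrant as free titrant
    and therefore overestimates K_D when the fixed component concentration
    is comparable to K_D (ligand depletion).

    ``method='quadratic'`` fits ``RLU = background + gain * [AB]`` with
    [AB] from the exact mass-balance quadratic at the dataset's fixed
    component concentration, removing the depletion bias.
    """
    means = ds.mean_rlu()
    rep_sd = _pooled_rep_sd(ds)
    if method == "inflection":
        fit = fit_4pl(
            ds.concentrations_nM, means, direction="ascending",
            hill_fixed=1.0, rep_sd=rep_sd,
        )
        fit.model = "4PL-inflection (hill=1)"
        return fit
    if method != "quadratic":
        raise ValueError(f"unknown method {method!r}")
    if ds.fixed_conc_nM <= 0:
        raise ValueError("quadratic method needs the fixed component concentration")
    _flat_check(means, rep_sd)
    b0 = ds.fixed_conc_nM
    x = ds.concentrations_nM

    def model(a0, background, gain, logkd):
        return background + gain * occupancy_quadratic(a0, b0, 10.0 ** logkd)

    lo, hi = float(means.min()), float(means.max())
    half = (lo + hi) / 2.0
    above = np.nonzero(means >= half)[0]
    logkd0 = np.log10(x[above[0]]) if above.size else np.log10(np.median(x))
    p0 = [lo, (hi - lo) / b0, logkd0]
    converged = True
    notes: list[str] = []
    try:
        popt, pcov = optimize.curve_fit(
            model, x, means, p0=p0, maxfev=20000, xtol=1e-12, ftol=1e-12
        )
    except RuntimeError:
        converged = False
        notes.append("least-squares solver did not converge")
        popt = np.asarray(p0)
        pcov = np.full((3, 3), np.nan)
    background, gain, logkd = popt
    var = pcov[2, 2]
    se = float(np.sqrt(var)) if np.isfinite(var) and var >= 0 else float("nan")
    resid = means - model(x, *popt)
    return DoseResponseFit(
        model="quadratic mass-balance",
        bottom=float(background),
        top=float(background + gain * b0),  # saturation: all fixed component bound
        hill=1.0,
        midpoint=float(10.0 ** logkd),
        log10_midpoint=float(logkd),
        se_log10_midpoint=se,
        ci95_low=float(10.0 ** (logkd - 1.959963984540054 * se)) if np.isfinite(se) else float("nan"),
        ci95_high=float(10.0 ** (logkd + 1.959963984540054 * se)) if np.isfinite(se) else float("nan"),
        rss=float(np.sum(resid**2)),
        converged=converged,
        n_points_used=int(x.size),
        direction="ascending",
        notes=notes,
    )


def fit_ec50(ds: TitrationDataset) -> DoseResponseFit:
    """EC50 from an ascending dose–response series (4PL, free Hill slope)."""
    fit = fit_4pl(
        ds.concentrations_nM, ds.mean_rlu(), direction="ascending",
        rep_sd=_pooled_rep_sd(ds),
    )
    if fit.direction != "ascending":
        fit.notes.append("expected ascending response; fitted descending data")
    return fit


def fit_ic50(ds: TitrationDataset) -> DoseResponseFit:
    """IC50 from a descending inhibition series (4PL, free Hill slope)."""
    fit = fit_4pl(
        ds.concentrations_nM, ds.mean_rlu(), direction="descending",
        rep_sd=_pooled_rep_sd(ds),
    )
    if fit.direction != "descending":
        fit.notes.append("expected descending response; fitted ascending data")
    return fit


# --------------------------------------------------------------------------
# assay quality
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class AssayQuality:
    mu_pos: float
    sd_pos: float
    mu_neg: float
    sd_neg: float
    n_pos: int
    n_neg: int
    z_factor: float


@dataclass(frozen=True)
class SlopeTest:
    slope: float
    intercept: float
    f_statistic: float
    p_value: float
    df_resid: int


def z_factor(pos: Sequence[float], neg: Sequence[float]) -> AssayQuality:
    """Screening-window Z-factor: 1 - 3*(sd_pos + sd_neg)/|mu_pos - mu_neg|.

    Sample standard deviations (ddof=1); at least 3 replicates per arm.
    Z > 0.5 is conventionally an excellent assay; Z <= 0 means the control
    distributions overlap.
    """
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    if pos.size < 3 or neg.size < 3:
        raise ValueError("need at least 3 replicates in each control arm")
    mu_p, mu_n = float(pos.mean()), float(neg.mean())
    if mu_p == mu_n:
        raise ValueError("Z-factor undefined: control means are equal")
    sd_p, sd_n = float(pos.std(ddof=1)), float(neg.std(ddof=1))
    z = 1.0 - 3.0 * (sd_p + sd_n) / abs(mu_p - mu_n)
    return AssayQuality(
        mu_pos=mu_p, sd_pos=sd_p, mu_neg=mu_n, sd_neg=sd_n,
        n_pos=int(pos.size), n_neg=int(neg.size), z_factor=float(z),
    )


def fold_change(sample_rlu: Sequence[float] | float, control_rlu: Sequence[float] | float) -> float:
    """Mean sample luminescence over mean control (LgBiT-alone) luminescence."""
    s = float(np.mean(np.asarray(sample_rlu, dtype=float)))
    c = float(np.mean(np.asarray(control_rlu, dtype=float)))
    if c <= 0:
        raise ValueError("control luminescence must be > 0")
    return s / c


def slope_zero_test(x: Sequence[float], y: Sequence[float]) -> SlopeTest:
    """OLS slope with a Wald F-test of slope == 0.

    Used to test whether a signal is independent of (log) concentration,
    e.g. the calcium insensitivity of the small-subunit homodimer.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.unique(x).size < 3:
        raise ValueError("need at least 3 distinct x values")
    X = sm.add_constant(x)
    res = sm.OLS(y, X).fit()
    slope = float(res.params[1])
    if res.ssr == 0.0 and slope == 0.0:
        f, p = 0.0, 1.0  # exactly constant response
    else:
        f = float(res.tvalues[1] ** 2)
        p = float(res.pvalues[1])
    return SlopeTest(
        slope=slope,
        intercept=float(res.params[0]),
        f_statistic=f,
        p_value=p,
        df_resid=int(res.df_resid),
    )
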