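"""Concentration-gradient sensitivity of the growth parameters.

For one component and one background combination, the growth parameter is
plotted across the component's log-concentration gradient, both axes are
rescaled to the unit square (x by the gradient range, y by the largest
parameter value on the gradient), a cubic polynomial is least-squares
fitted, and the sensitivity

    S = 1 - Area,    Area = integral of the fitted cubic over [0, 1],

is the area *above* the fitted curve inside the unit box.  S = 0 means the
parameter is flat at its maximum across the whole gradient (the component
does not matter); S near 1 means growth collapses over most of the
gradient.  Per-component sensitivities are the means of S over the
alternative backgrounds, one value per growth parameter (S_tau, S_r, S_K);
their sum is the global sensitivity S_g, and a set of balance criteria
(variance of the sensitivity shares, variance of the raw values, minimum
interior angle of a three-axis sensitivity triangle) quantifies how evenly
a component's influence spreads over the three growth phases.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import MediumDesign, PARAMETERS

logger = logging.getLogger(__name__)


@dataclass
class GradientSeries:
    """One component's gradient in one background: concentrations vs parameter."""

    component: str
    background_id: int
    concentrations: np.ndarray
    values: np.ndarray
    parameter: str

    def __post_init__(self) -> None:
        x = np.asarray(self.concentrations, float)
        p = np.asarray(self.values, float)
        if len(x) != len(p) or len(x) < 4:
            raise ValueError("gradient needs at least 4 matched levels")
        if np.any(np.diff(x) <= 0):
            raise ValueError("gradient concentrations must be strictly increasing")
        if not np.all(np.isfinite(p)) or np.any(p < 0):
            raise ValueError("parameter values must be finite and non-negative")
        object.__setattr__(self, "concentrations", x)
        object.__setattr__(self, "values", p)

    @property
    def p_max(self) -> float:
        return float(self.values.max())


@dataclass
class CubicFit:
    """Cubic fitted on unit-rescaled axes: y(u) = sum_k coeffs[k] * u**k."""

    coeffs: np.ndarray                # ascending powers, length 4
    component: str = ""
    parameter: str = ""


@dataclass
class BalanceCriteria:
    """Global sensitivity and the evenness measures of its three parts."""

    s_g: float
    v_s: float
    crit1: float
    crit2: float
    crit3: float
    crit4_deg: float
    degenerate: tuple[str, ...] = ("crit1", "crit2")


@dataclass
class PowerLawFit:
    """Continuous maximum-likelihood power-law fit to a sensitivity tail."""

    exponent: float
    xmin: float
    n_tail: int
    ks_distance: float


def _normalized_axes(series: GradientSeries, log_axis: bool = True):
    """Rescale the gradient to the unit square.

    The x axis is log10 concentration by default (gradients are designed on
    a log scale); zero levels map one decade below the smallest positive
    level.  Both axes are then rescaled so their maxima are one unit.
    """
    x = series.concentrations.copy()
    if log_axis:
        positive = x[x > 0]
        if len(positive) == 0:
            raise ValueError("gradient has no positive concentration")
        fill = np.log10(positive.min()) - 1.0
        x = np.where(x > 0, np.log10(np.where(x > 0, x, 1.0)), fill)
    u = (x - x[0]) / (x[-1] - x[0])
    y = series.values / series.p_max
    return u, y


def fit_gradient_curve(series: GradientSeries, log_axis: bool = True) -> CubicFit | None:
    """Least-squares cubic on the unit-rescaled gradient.

    Returns ``None`` ("undefined sensitivity") with a warning when the
    parameter is zero across the whole gradient, so the caller can exclude
    the background from the sensitivity mean.
    """
    if series.p_max == 0:
        logger.warning("undefined sensitivity: %s/%s background %d shows no growth",
                       series.component, series.parameter, series.background_id)
        return None
    u, y = _normalized_axes(series, log_axis=log_axis)
    coeffs = np.polynomial.polynomial.polyfit(u, y, deg=3)
    return CubicFit(coeffs=np.asarray(coeffs, float), component=series.component,
                    parameter=series.parameter)


def sensitivity_index(fit: CubicFit) -> float:
    """S = 1 - (analytic integral of the fitted cubic over the unit range).

    The raw value is clamped into [0, 1] with a warning when polynomial
    overshoot pushes it outside the unit box.
    """
    area = float(sum(c / (k + 1) for k, c in enumerate(fit.coeffs)))
    s = 1.0 - area
    if s < 0.0 or s > 1.0:
        logger.warning("sensitivity %.4f for %s/%s outside [0, 1]; clamped "
                       "(polynomial overshoot)", s, fit.component, fit.parameter)
        s = min(max(s, 0.0), 1.0)
    return s


def mean_sensitivity(per_background: list[float | None]) -> tuple[float, int]:
    """Mean of per-background S values, skipping undefined backgrounds.

    Returns the mean and the effective number of backgrounds; with no
    defined value the mean is NaN (undefined).
    """
    defined = [s for s in per_background if s is not None and not math.isnan(s)]
    if not defined:
        return math.nan, 0
    return float(np.mean(defined)), len(defined)


def balance_criteria(s_tau: float, s_r: float, s_k: float) -> BalanceCriteria:
    """Global sensitivity and the four evenness criteria.

    * ``v_s``   — sample variance (m - 1 = 2) of the shares S_p / S_g around
      their mean 1/3.
    * ``crit1``/``crit2`` — the first two printed criteria, which are
      algebraically constant (1 and 0) for any inputs; they are computed as
      printed and flagged degenerate.
    * ``crit3`` — sample variance of the raw S values around their mean.
    * ``crit4_deg`` — minimum interior angle (degrees) of the triangle whose
      vertices sit on three axes 120 degrees apart at radii S_tau, S_r,
      S_K; 60 degrees iff the three sensitivities are equal.
    """
    s = np.array([s_tau, s_r, s_k], float)
    if np.any(~np.isfinite(s)) or np.any(s < 0):
        raise ValueError("all three sensitivities must be finite and non-negative")
    s_g = float(s.sum())
    if s_g == 0:
        return BalanceCriteria(0.0, math.nan, math.nan, math.nan, math.nan, math.nan)
    shares = s / s_g
    m = 3
    v_s = float(((shares - 1.0 / m) ** 2).sum() / (m - 1))
    crit1 = float(s.sum() / s_g)
    s_prime = float(s.mean())
    crit2 = float((s.sum() - 3 * s_prime) / s_g)
    crit3 = float(((s - s_prime) ** 2).sum() / (m - 1))
    crit4 = _min_triangle_angle(s)
    return BalanceCriteria(s_g=s_g, v_s=v_s, crit1=crit1, crit2=crit2,
                           crit3=crit3, crit4_deg=crit4)


def _min_triangle_angle(radii: np.ndarray) -> float:
    """Minimum interior angle of the three-axis sensitivity triangle.

    Vertices lie at the given radii on three coplanar axes separated by
    120 degrees; the interior angles depend only on the radii, so the axis
    orientation is immaterial.
    """
    angles = np.deg2rad([90.0, 210.0, 330.0])
    verts = np.column_stack([radii * np.cos(angles), radii * np.sin(angles)])
    interior = []
    for i in range(3):
        a, b, c = verts[i], verts[(i + 1) % 3], verts[(i + 2) % 3]
        u, v = b - a, c - a
        nu, nv = np.linalg.norm(u), np.linalg.norm(v)
        if nu == 0 or nv == 0:
            return math.nan
        cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
        interior.append(math.degrees(math.acos(cosang)))
    return float(min(interior))


def component_sensitivity_table(
    design: MediumDesign,
    params: pd.DataFrame,
    log_axis: bool = True,
) -> pd.DataFrame:
    """Per-component sensitivity over a one-at-a-time gradient design.

    For every component, S is computed per background and parameter from
    the cubic fits, averaged over backgrounds, and summarised with the
    balance criteria.  Gradients with flagged/missing parameter values or
    fewer than four usable levels are excluded from the mean (the effective
    background count per parameter is reported).  One row per component.
    """
    rows = []
    for component in design.component_names:
        means, n_eff = {}, {}
        backgrounds = sorted(
            design.gradient_index.loc[
                design.gradient_index["target_component"] == component,
                "background_id"].unique())
        for param in PARAMETERS:
            per_bg: list[float | None] = []
            flag_col = f"flag_{param}"
            for b in backgrounds:
                ids = design.gradient_ids(component, int(b))
                ids = ids.intersection(params.index)
                values = params.loc[ids, param]
                if flag_col in params.columns:
                    values = values[~params.loc[ids, flag_col].astype(bool)]
                values = values.dropna()
                if len(values) < 4:
                    per_bg.append(None)
                    continue
                conc = design.combinations.loc[values.index, component].to_numpy()
                order = np.argsort(conc)
                series = GradientSeries(component, int(b), conc[order],
                                        values.to_numpy()[order], param)
                fit = fit_gradient_curve(series, log_axis=log_axis)
                per_bg.append(None if fit is None else sensitivity_index(fit))
            means[param], n_eff[param] = mean_sensitivity(per_bg)
        row = {"component": component,
               "s_tau": means["tau"], "s_rate": means["rate"],
               "s_capacity": means["capacity"],
               "n_eff_tau": n_eff["tau"], "n_eff_rate": n_eff["rate"],
               "n_eff_capacity": n_eff["capacity"]}
        if all(not math.isnan(means[p]) for p in PARAMETERS):
            crit = balance_criteria(means["tau"], means["rate"], means["capacity"])
            row.update({"s_g": crit.s_g, "v_s": crit.v_s, "crit1": crit.crit1,
                        "crit2": crit.crit2, "crit3": crit.crit3,
                        "crit4_deg": crit.crit4_deg})
        else:
            row.update({"s_g": math.nan, "v_s": math.nan, "crit1": math.nan,
                        "crit2": math.nan, "crit3": math.nan,
                        "crit4_deg": math.nan})
        rows.append(row)
    return pd.DataFrame(rows).set_index("component")


def fit_power_law(values, xmin: float | None = None) -> PowerLawFit:
    """Continuous maximum-likelihood power-law fit above a lower cutoff.

    The tail exponent is the Hill/MLE estimator
    ``alpha = 1 + n / sum(log(x / xmin))`` over values above ``xmin``
    (default: the sample median), with the Kolmogorov-Smirnov distance
    between the tail's empirical CDF and the fitted power law as the
    goodness measure.  Fewer than 10 tail values, or a degenerate tail,
    leave the fit undefined (ValueError).
    """
    x = np.asarray(values, float)
    x = x[np.isfinite(x) & (x > 0)]
    if len(x) < 10:
        raise ValueError("need at least 10 positive values for a power-law fit")
    if xmin is None:
        xmin = float(np.median(x))
    tail = np.sort(x[x >= xmin])
    if len(tail) < 10:
        raise ValueError("fewer than 10 values above the cutoff; fit undefined")
    if tail[0] == tail[-1]:
        raise ValueError("degenerate tail support; power-law fit undefined")
    log_ratio = np.log(tail / xmin)
    positive = log_ratio[log_ratio > 0]
    if positive.sum() == 0:
        raise ValueError("degenerate tail support; power-law fit undefined")
    alpha = 1.0 + len(tail) / log_ratio.sum()
    ecdf = np.arange(1, len(tail) + 1) / len(tail)
    model_cdf = 1.0 - (tail / xmin) ** (1.0 - alpha)
    ks = float(np.max(np.abs(ecdf - model_cdf)))
    return PowerLawFit(exponent=float(alpha), xmin=float(xmin),
                       n_tail=len(tail), ks_distance=ks)


def power_law_summary(sensitivity: pd.DataFrame) -> pd.DataFrame:
    """Power-law fits of the S_tau / S_rate / S_capacity / S_g distributions."""
    rows = []
    for col in ("s_tau", "s_rate", "s_capacity", "s_g"):
        try:
            fit = fit_power_law(sensitivity[col].dropna().to_numpy())
            rows.append({"distribution": col, "exponent": fit.exponent,
                         "xmin": fit.xmin, "n_tail": fit.n_tail,
                         "ks_distance": fit.ks_distance})
        except ValueError as exc:
            rows.append({"distribution": col, "exponent": math.nan,
                         "xmin": math.nan, "n_tail": 0, "ks_distance": math.nan,
                         "note": str(exc)})
    return pd.DataFrame(rows).set_index("distribution")
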