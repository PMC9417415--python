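"""Growth-parameter extraction from plate-reader OD600 time series.

Each well's optical-density trace is summarised by three read-off
parameters describing the lag, exponential and stationary phases:

* ``tau`` — lag time (hr): the time of the first read that starts a run of
  five consecutive strictly increasing OD readings.
* ``rate`` — maximal growth rate (1/hr): the largest mean of three
  consecutive log-OD slopes inside the exponential window (from ``tau`` to
  the read achieving the maximum OD).
* ``capacity`` — saturated population size (OD600): the mean of three
  consecutive OD readings whose window contains the global maximum.

These are deterministic rules applied to the raw readings; no parametric
curve (Gompertz, Baranyi, ...) is fitted.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel lag time for a curve that never shows sustained growth.
NO_GROWTH = math.nan

#: Number of consecutive strict OD increases that define the start of growth.
GROWTH_RUN_LENGTH = 5

#: Default replicate coefficient-of-variation threshold above which a
#: parameter is flagged unreliable.  Matches the upper end of typical
#: plate-reader biological-replicate variation (CV ~ 0.05-0.12).
DEFAULT_CV_THRESHOLD = 0.12


@dataclass(frozen=True)
class GrowthCurve:
    """One well's OD600 time series at a fixed sampling interval."""

    times: np.ndarray
    od: np.ndarray
    combination_id: str = ""
    replicate_id: int = 0

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        od = np.asarray(self.od, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "od", od)
        if times.ndim != 1 or od.ndim != 1 or len(times) != len(od):
            raise ValueError("times and od must be 1-D arrays of equal length")
        if len(times) < GROWTH_RUN_LENGTH + 1:
            raise ValueError(
                f"curve needs at least {GROWTH_RUN_LENGTH + 1} reads "
                f"({GROWTH_RUN_LENGTH} consecutive increases require "
                f"{GROWTH_RUN_LENGTH + 1} reads)"
            )
        steps = np.diff(times)
        if np.any(steps <= 0):
            raise ValueError("times must be strictly increasing")
        # constant sampling interval within 1 %
        if np.max(np.abs(steps - steps.mean())) > 0.01 * steps.mean():
            raise ValueError("sampling interval varies by more than 1 %")
        if np.any(od < 0):
            raise ValueError("OD readings must be non-negative")

    @property
    def dt(self) -> float:
        """Sampling interval in hours."""
        return float(np.mean(np.diff(self.times)))


@dataclass
class GrowthParameters:
    """Replicate-aggregated (tau, rate, capacity) for one medium combination."""

    combination_id: str
    tau: float
    rate: float
    capacity: float
    n_replicates: int
    cv: dict = field(default_factory=dict)
    unreliable: dict = field(default_factory=dict)


def detect_lag(curve: GrowthCurve) -> float:
    """Lag time: start of the first run of five consecutive strict increases.

    Returns :data:`NO_GROWTH` (NaN) when no such run exists; the resolution
    equals the sampling interval.
    """
    od = curve.od
    inc = np.diff(od) > 0
    for i in range(len(od) - GROWTH_RUN_LENGTH):
        if inc[i : i + GROWTH_RUN_LENGTH].all():
            return float(curve.times[i])
    return NO_GROWTH


def _exponential_window(curve: GrowthCurve, tau: float) -> tuple[np.ndarray, np.ndarray]:
    """Reads from the lag time up to (and including) the global OD maximum.

    Ties for the maximum resolve to the last occurrence, so a flat curve's
    window spans the whole trace (all slopes zero) instead of collapsing.
    """
    start = int(np.searchsorted(curve.times, tau))
    stop = len(curve.od) - 1 - int(np.argmax(curve.od[::-1]))
    if stop < start:
        stop = start
    return curve.times[start : stop + 1], curve.od[start : stop + 1]


def max_growth_rate(curve: GrowthCurve, tau: float | None = None) -> float:
    """Maximal specific growth rate (1/hr).

    Log-OD slopes are taken by central differences (``numpy.gradient``) over
    the window from the lag time to the read achieving the maximum OD; the
    result is the maximum over all means of three consecutive slopes.
    Non-positive OD readings inside the window are excluded with a warning.
    """
    if tau is None:
        tau = detect_lag(curve)
    if math.isnan(tau):
        return math.nan
    t, od = _exponential_window(curve, tau)
    keep = od > 0
    if not keep.all():
        logger.warning(
            "%s/%s: %d non-positive OD reads excluded from rate window",
            curve.combination_id, curve.replicate_id, int((~keep).sum()),
        )
        t, od = t[keep], od[keep]
    if len(od) < 4:
        raise ValueError("curve too short for rate estimation")
    slopes = np.gradient(np.log(od), t)
    if len(slopes) < 3:
        raise ValueError("curve too short for rate estimation")
    window_means = np.convolve(slopes, np.ones(3) / 3.0, mode="valid")
    return float(np.max(window_means))


def saturated_density(curve_or_od) -> float:
    """Saturated population size: mean of 3 consecutive reads containing the max.

    The window is centred on the global maximum when it is interior; when the
    maximum sits at an edge the window is the three reads nearest that edge.
    """
    od = curve_or_od.od if isinstance(curve_or_od, GrowthCurve) else np.asarray(curve_or_od, float)
    n = len(od)
    if n < 3:
        raise ValueError("need at least 3 reads for the saturation window")
    m = int(np.argmax(od))
    if m == 0:
        window = od[:3]
    elif m == n - 1:
        window = od[-3:]
    else:
        window = od[m - 1 : m + 2]
    return float(np.mean(window))


def extract_parameters(curve: GrowthCurve) -> dict:
    """(tau, rate, capacity) for a single curve; NaNs where undefined."""
    tau = detect_lag(curve)
    if math.isnan(tau):
        rate = math.nan
    else:
        try:
            rate = max_growth_rate(curve, tau)
        except ValueError:
            rate = math.nan
    return {"tau": tau, "rate": rate, "capacity": saturated_density(curve)}


def quality_flags(curve: GrowthCurve) -> set[str]:
    """Curve-level quality flags.

    ``no_growth``        — no run of five consecutive strict increases.
    ``sensor_saturated`` — the maximum OD value repeats exactly in four or
                           more consecutive reads (a hard sensor ceiling; a
                           genuine stationary plateau keeps drifting).
    """
    flags: set[str] = set()
    if math.isnan(detect_lag(curve)):
        flags.add("no_growth")
    od = curve.od
    peak = od.max()
    if peak > 0:
        at_peak = od == peak
        run, best = 0, 0
        for hit in at_peak:
            run = run + 1 if hit else 0
            best = max(best, run)
        if best >= 4:
            flags.add("sensor_saturated")
    return flags


def _cv(values: np.ndarray) -> float:
    values = np.asarray(values, float)
    if len(values) < 2:
        return 0.0
    mean = values.mean()
    if mean == 0:
        return math.nan
    return float(values.std(ddof=1) / mean)


def aggregate_replicates(
    curves: list[GrowthCurve], cv_threshold: float = DEFAULT_CV_THRESHOLD
) -> GrowthParameters:
    """Average (tau, rate, capacity) over biological replicates.

    A parameter is flagged unreliable when its replicate CV exceeds
    ``cv_threshold`` or any replicate carries the no-growth sentinel;
    flagged parameters should be omitted from downstream tables.  Flags are
    reported, never raised.
    """
    if not curves:
        raise ValueError("need at least one replicate")
    cid = curves[0].combination_id
    per_rep = pd.DataFrame([extract_parameters(c) for c in curves])
    no_growth = per_rep["tau"].isna().any()
    means, cvs, unreliable = {}, {}, {}
    for p in ("tau", "rate", "capacity"):
        vals = per_rep[p].to_numpy()
        defined = vals[~np.isnan(vals)]
        means[p] = float(defined.mean()) if len(defined) else math.nan
        cvs[p] = _cv(defined) if len(defined) else math.nan
        bad = no_growth if p in ("tau", "rate") else False
        unreliable[p] = bool(bad or (not math.isnan(cvs[p]) and cvs[p] > cv_threshold)
                             or len(defined) == 0)
    return GrowthParameters(
        combination_id=cid,
        tau=means["tau"], rate=means["rate"], capacity=means["capacity"],
        n_replicates=len(curves), cv=cvs, unreliable=unreliable,
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_curves_long(path) -> list[GrowthCurve]:
    """Read curves from long-format CSV (combination_id, replicate, time_hr, od600)."""
    df = pd.read_csv(path)
    required = {"combination_id", "replicate", "time_hr", "od600"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"long-format curve CSV missing columns: {sorted(missing)}")
    curves = []
    for (cid, rep), grp in df.groupby(["combination_id", "replicate"], sort=False):
        grp = grp.sort_values("time_hr")
        curves.append(GrowthCurve(grp["time_hr"].to_numpy(), grp["od600"].to_numpy(),
                                  combination_id=str(cid), replicate_id=int(rep)))
    return curves


def read_curves_wide(path, well_map: dict[str, str]) -> list[GrowthCurve]:
    """Read a wide plate-reader CSV: one time column plus one column per well.

    ``well_map`` maps well column names to combination ids; replicate ids are
    assigned in column order within each combination.
    """
    df = pd.read_csv(path)
    time_col = df.columns[0]
    curves = []
    counter: dict[str, int] = {}
    for well, cid in well_map.items():
        if well not in df.columns:
            raise ValueError(f"well column {well!r} not present in {path}")
        rep = counter.get(cid, 0)
        counter[cid] = rep + 1
        curves.append(GrowthCurve(df[time_col].to_numpy(), df[well].to_numpy(),
                                  combination_id=str(cid), replicate_id=rep))
    return curves


def write_curves_long(curves: list[GrowthCurve], path) -> None:
    frames = [
        pd.DataFrame({
            "combination_id": c.combination_id, "replicate": c.replicate_id,
            "time_hr": c.times, "od600": c.od,
        })
        for c in curves
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def parameters_table(
    curves: list[GrowthCurve], cv_threshold: float = DEFAULT_CV_THRESHOLD
) -> pd.DataFrame:
    """Replicate-aggregated parameter table over a batch of curves.

    One row per combination id: tau, rate, capacity, their replicate CVs and
    per-parameter unreliability flags.
    """
    by_cid: dict[str, list[GrowthCurve]] = {}
    for c in curves:
        by_cid.setdefault(c.combination_id, []).append(c)
    rows = []
    for cid, reps in by_cid.items():
        gp = aggregate_replicates(reps, cv_threshold=cv_threshold)
        rows.append({
            "combination_id": cid,
            "tau": gp.tau, "rate": gp.rate, "capacity": gp.capacity,
            "n_replicates": gp.n_replicates,
            "cv_tau": gp.cv["tau"], "cv_rate": gp.cv["rate"],
            "cv_capacity": gp.cv["capacity"],
            "flag_tau": gp.unreliable["tau"], "flag_rate": gp.unreliable["rate"],
            "flag_capacity": gp.unreliable["capacity"],
        })
    return pd.DataFrame(rows).set_index("combination_id")
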