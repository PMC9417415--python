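"""Synthetic medium designs, planted growth responses and noisy growth curves.

The generator emulates a combinatorial medium-design study: a panel of
medium components (ions, sugars, amino acids) whose concentrations span
log-scale gradients, where each assay varies exactly one component against
a fixed background combination of the others, with several alternative
backgrounds per target component.

Growth responses are planted: each of the three growth parameters (lag
time tau, maximal rate, saturated size) is driven predominantly by one
designated "decision-making" component through a saturating Hill-type
response on log concentration, plus small contributions from the remaining
components.  Curves follow lag-logistic population dynamics with additive
truncated-Gaussian measurement noise.  Every output is deterministic under
a fixed seed.

The generator plants statistical structure only; it makes no attempt to
emulate real medium chemistry (osmotic effects, ion speciation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .growth import GrowthCurve

PARAMETERS = ("tau", "rate", "capacity")

#: 41 medium components: the 20 proteinogenic amino acids plus sugars,
#: inorganic ions and vitamins typical of a defined bacterial medium.
DEFAULT_COMPONENTS = [
    "alanine", "arginine", "asparagine", "aspartate", "cysteine",
    "glutamate", "glutamine", "glycine", "histidine", "isoleucine",
    "leucine", "lysine", "methionine", "phenylalanine", "proline",
    "serine", "threonine", "tryptophan", "tyrosine", "valine",
    "glucose", "glycerol", "citrate", "ammonium", "nitrate",
    "sulfate", "phosphate", "potassium", "sodium", "chloride",
    "magnesium", "calcium", "iron", "zinc", "manganese",
    "copper", "cobalt", "molybdate", "borate", "thiamine", "biotin",
]

#: Default per-component concentration range (arbitrary mM-like units),
#: spanning four decades as log-scale medium gradients typically do.
DEFAULT_RANGE = (1e-3, 10.0)

#: Probability that a zero-allowed background component is left out of the
#: medium entirely (minimal concentrations sit at zero by design).
DEFAULT_ZERO_PROBABILITY = 0.2


@dataclass
class MediumDesign:
    """A combinatorial medium design with one-component-at-a-time gradients.

    ``combinations`` holds one row per medium combination (columns =
    component concentrations); ``gradient_index`` records, for the same
    rows, which component the combination's gradient varies
    (``target_component``), the gradient level index and the background id.
    """

    component_names: list[str]
    combinations: pd.DataFrame
    gradient_index: pd.DataFrame
    concentration_ranges: dict[str, tuple[float, float]] = field(default_factory=dict)

    def gradient_ids(self, component: str, background: int) -> pd.Index:
        """Combination ids of one gradient, ordered by increasing level."""
        gi = self.gradient_index
        mask = (gi["target_component"] == component) & (gi["background_id"] == background)
        return gi[mask].sort_values("level").index

    @property
    def n_backgrounds(self) -> int:
        return int(self.gradient_index["background_id"].max()) + 1


def generate_design(
    n_components: int = 41,
    levels_per_gradient: int = 6,
    n_backgrounds: int = 6,
    concentration_ranges: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
    component_names: list[str] | None = None,
    zero_probability: float = DEFAULT_ZERO_PROBABILITY,
) -> MediumDesign:
    """Generate a one-component-at-a-time log-gradient medium design.

    For every component, ``n_backgrounds`` background contexts are sampled
    (each non-target component uniform on its log-concentration range, set
    to exactly zero with probability ``zero_probability``), and the target
    component is swept over ``levels_per_gradient`` log-spaced levels
    between its range minimum and maximum.  The result contains
    ``n_components * n_backgrounds * levels_per_gradient`` combinations.
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if levels_per_gradient < 4:
        raise ValueError("insufficient gradient levels for cubic regression")
    if n_backgrounds < 1:
        raise ValueError("n_backgrounds must be >= 1")
    if component_names is None:
        if n_components <= len(DEFAULT_COMPONENTS):
            component_names = DEFAULT_COMPONENTS[:n_components]
        else:
            component_names = [f"component_{i:02d}" for i in range(n_components)]
    if len(component_names) != n_components:
        raise ValueError("component_names length must equal n_components")

    ranges = {name: DEFAULT_RANGE for name in component_names}
    if concentration_ranges:
        ranges.update(concentration_ranges)
    for name, (lo, hi) in ranges.items():
        if hi <= 0:
            raise ValueError(f"range maximum for {name!r} must be positive")
        if lo <= 0 or lo >= hi:
            raise ValueError(f"range for {name!r} must satisfy 0 < min < max")

    rng = np.random.default_rng(seed)
    rows, index_rows, ids = [], [], []
    for target in component_names:
        lo, hi = ranges[target]
        levels = np.logspace(math.log10(lo), math.log10(hi), levels_per_gradient)
        for b in range(n_backgrounds):
            background = {}
            for name in component_names:
                if name == target:
                    continue
                clo, chi = ranges[name]
                conc = 10.0 ** rng.uniform(math.log10(clo), math.log10(chi))
                if rng.random() < zero_probability:
                    conc = 0.0
                background[name] = conc
            for li, level in enumerate(levels):
                row = dict(background)
                row[target] = level
                rows.append(row)
                ids.append(f"{target}_bg{b}_L{li}")
                index_rows.append({"target_component": target,
                                   "level": li, "background_id": b})
    combinations = pd.DataFrame(rows, index=ids)[component_names]
    combinations.index.name = "combination_id"
    gradient_index = pd.DataFrame(index_rows, index=ids)
    gradient_index.index.name = "combination_id"
    return MediumDesign(list(component_names), combinations, gradient_index, ranges)


# ---------------------------------------------------------------------------
# Planted growth responses
# ---------------------------------------------------------------------------

#: Baseline and amplitude for each growth parameter: tau in hours, rate in
#: 1/hr, capacity in OD600 units.  The resulting ranges (lag 2.5-8.5 hr,
#: rate 0.25-1.25 /hr, capacity 0.1-1.0 OD) are typical of E. coli in
#: defined media, and together with the default measurement noise put the
#: replicate CVs of the extracted parameters in the 0.05-0.12 band a
#: plate-reader assay shows.
DEFAULT_BASELINES = {"tau": 2.5, "rate": 0.25, "capacity": 0.1}
DEFAULT_AMPLITUDES = {"tau": 6.0, "rate": 1.0, "capacity": 0.9}


@dataclass
class ResponseModel:
    """Planted map from medium composition to (tau, rate, capacity).

    Each parameter responds to its designated determinant component through
    a Hill-type logistic in log10 concentration,

        p = baseline + amplitude * h(log10 c),   h(x) = 1 / (1 + 10^-(x-m)/w),

    with midpoint ``m`` at the centre of the component's log range and width
    ``w`` (decades).  Every other component contributes through the same
    shape scaled by a small seeded weight (fraction ``minor_effect`` of the
    amplitude), so the determinant dominates each parameter's variance while
    the map stays realistically non-sparse.  The optional ``coupling``
    triple (c_tau_rate, c_tau_capacity, c_rate_capacity) mixes the three
    unit-scaled responses linearly to induce correlations among the
    parameters; it is off by default.
    """

    determinant_map: dict[str, str] = field(
        default_factory=lambda: {"tau": "serine", "rate": "sulfate", "capacity": "glucose"})
    baselines: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BASELINES))
    amplitudes: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_AMPLITUDES))
    hill_width: float = 0.8
    minor_effect: float = 0.02
    coupling: tuple[float, float, float] | None = None
    noise_sd: float = 0.01
    weight_seed: int = 0

    def __post_init__(self) -> None:
        if self.coupling is not None:
            c_tr, c_tk, c_rk = self.coupling
            if c_tk + c_rk > 1:
                raise ValueError("coupling weights must satisfy c_tau_K + c_rate_K <= 1")


def _hill(log_conc: np.ndarray, midpoint: float, width: float) -> np.ndarray:
    return 1.0 / (1.0 + 10.0 ** (-(log_conc - midpoint) / width))


def _log_conc(conc: np.ndarray) -> np.ndarray:
    """log10 concentration; zeros map to -inf (Hill response 0)."""
    with np.errstate(divide="ignore"):
        return np.log10(np.asarray(conc, float))


def ground_truth_parameters(design: MediumDesign, model: ResponseModel) -> pd.DataFrame:
    """Deterministic (tau, rate, capacity) per combination from the planted map.

    The returned table is indexed by combination id with columns
    ``tau``/``rate``/``capacity`` and carries no measurement noise; noise
    enters only through :func:`simulate_curves`.
    """
    for param, comp in model.determinant_map.items():
        if comp not in design.component_names:
            raise ValueError(
                f"determinant {comp!r} for {param!r} not in design; valid "
                f"components: {design.component_names}")

    conc = design.combinations
    mids = {name: np.mean([math.log10(lo), math.log10(hi)])
            for name, (lo, hi) in design.concentration_ranges.items()}
    # Hill level of every component for every combination
    levels = pd.DataFrame(
        {name: _hill(_log_conc(conc[name].to_numpy()), mids[name], model.hill_width)
         for name in design.component_names}, index=conc.index)

    wrng = np.random.default_rng(model.weight_seed)
    unit: dict[str, np.ndarray] = {}
    for param in PARAMETERS:
        det = model.determinant_map.get(param)
        u = levels[det].to_numpy().copy() if det else np.zeros(len(conc))
        for name in design.component_names:
            if name == det:
                continue
            w = model.minor_effect * wrng.normal()
            u = u + w * levels[name].to_numpy()
        unit[param] = u

    if model.coupling is not None:
        c_tr, c_tk, c_rk = model.coupling
        u_tau = np.clip(unit["tau"], 0.0, 1.0)
        u_rate = c_tr * (1.0 - u_tau) + (1.0 - c_tr) * np.clip(unit["rate"], 0.0, 1.0)
        u_cap = (c_tk * u_tau + c_rk * (1.0 - u_rate)
                 + (1.0 - c_tk - c_rk) * np.clip(unit["capacity"], 0.0, 1.0))
        unit = {"tau": u_tau, "rate": u_rate, "capacity": u_cap}

    out = {}
    for param in PARAMETERS:
        p = model.baselines[param] + model.amplitudes[param] * unit[param]
        floor = 1e-3 if param == "capacity" else 0.0
        out[param] = np.maximum(p, floor)
    table = pd.DataFrame(out, index=conc.index)
    table.index.name = "combination_id"
    return table


# ---------------------------------------------------------------------------
# Curve simulation
# ---------------------------------------------------------------------------

def lag_logistic(t: np.ndarray, tau: float, rate: float, capacity: float,
                 n0: float) -> np.ndarray:
    """Lag-logistic population dynamics evaluated on a time grid.

    OD(t) = n0 for t < tau, then the closed-form logistic
    K*n0 / (n0 + (K - n0) * exp(-r * (t - tau))) for t >= tau.
    """
    t = np.asarray(t, float)
    tj = t - tau
    with np.errstate(over="ignore"):
        denom = n0 + (capacity - n0) * np.exp(-rate * np.clip(tj, 0.0, None))
    grown = np.where(denom > 0, capacity * n0 / np.where(denom > 0, denom, 1.0), n0)
    return np.where(t < tau, n0, grown)


def simulate_curves(
    params: pd.DataFrame,
    t_max_hr: float = 24.0,
    dt_hr: float = 0.5,
    n0: float = 0.02,
    noise_sd: float = 0.001,
    n_replicates: int = 4,
    seed: int = 0,
    resolution: float = 0.001,
) -> list[GrowthCurve]:
    """Simulate noisy replicate growth curves from a parameter table.

    ``params`` is indexed by combination id with columns tau/rate/capacity.
    The measurement model is additive Gaussian noise (sd ``noise_sd`` OD
    units) truncated at zero, reported at the instrument's reading
    ``resolution`` (plate readers print OD to ~0.001); replicates share
    parameters but differ in noise draws.  With ``noise_sd=0`` the ideal
    dynamics are returned exactly (no instrument model).
    """
    if dt_hr <= 0:
        raise ValueError("dt_hr must be positive")
    if t_max_hr < dt_hr:
        raise ValueError("t_max_hr must be at least dt_hr")
    if n0 <= 0:
        raise ValueError("n0 must be positive")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    times = np.arange(0.0, t_max_hr + dt_hr / 2, dt_hr)
    rng = np.random.default_rng(seed)
    curves = []
    for cid, row in params.iterrows():
        tau, rate, cap = float(row["tau"]), float(row["rate"]), float(row["capacity"])
        if not all(map(math.isfinite, (tau, rate, cap))):
            raise ValueError(f"non-finite growth parameters for combination {cid!r}")
        clean = lag_logistic(times, tau, rate, cap, n0)
        for rep in range(n_replicates):
            if noise_sd == 0:
                od = clean
            else:
                od = np.maximum(clean + rng.normal(0.0, noise_sd, size=len(times)), 0.0)
                if resolution > 0:
                    od = np.round(od / resolution) * resolution
            curves.append(GrowthCurve(times, od.copy(), combination_id=str(cid),
                                      replicate_id=rep))
    return curves


def simulate_faulty_curves(
    n_curves: int,
    kind: str,
    t_max_hr: float = 24.0,
    dt_hr: float = 0.5,
    n0: float = 0.02,
    noise_sd: float = 0.001,
    sensor_max: float = 0.5,
    seed: int = 0,
) -> list[GrowthCurve]:
    """Known-bad curves for quality-filter testing.

    ``kind='no_growth'`` produces flat traces at the inoculum density;
    ``kind='sensor_saturated'`` produces logistic curves hard-clipped at the
    sensor ceiling ``sensor_max``.  Combination ids are prefixed ``bad_``
    so planted faults are identifiable in tests.
    """
    if kind not in ("no_growth", "sensor_saturated"):
        raise ValueError(f"unknown fault kind {kind!r}")
    times = np.arange(0.0, t_max_hr + dt_hr / 2, dt_hr)
    rng = np.random.default_rng(seed)
    curves = []
    for i in range(n_curves):
        if kind == "no_growth":
            od = np.full(len(times), n0)
            od = np.maximum(od + rng.normal(0.0, noise_sd, size=len(times)), 0.0)
        else:
            tau = rng.uniform(0.5, 4.0)
            rate = rng.uniform(0.5, 1.2)
            clean = lag_logistic(times, tau, rate, 2.0 * sensor_max, n0)
            od = np.maximum(clean + rng.normal(0.0, noise_sd, size=len(times)), 0.0)
            od = np.minimum(od, sensor_max)
        curves.append(GrowthCurve(times, od, combination_id=f"bad_{kind}_{i}",
                                  replicate_id=0))
    return curves


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_design_csv(design: MediumDesign, path) -> None:
    """One row per combination: component concentrations + gradient columns."""
    table = design.combinations.join(design.gradient_index)
    table.to_csv(path)


def read_design_csv(path) -> MediumDesign:
    table = pd.read_csv(path, index_col="combination_id")
    meta_cols = ["target_component", "level", "background_id"]
    missing = [c for c in meta_cols if c not in table.columns]
    if missing:
        raise ValueError(f"design CSV missing columns: {missing}")
    component_names = [c for c in table.columns if c not in meta_cols]
    combos = table[component_names]
    ranges = {}
    for name in component_names:
        positive = combos[name][combos[name] > 0]
        if len(positive):
            ranges[name] = (float(positive.min()), float(positive.max()))
    return MediumDesign(component_names, combos, table[meta_cols], ranges)
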