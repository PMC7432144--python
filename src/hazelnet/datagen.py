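"""Synthetic elicitation experiments with known ground-truth surfaces.

The generator emulates a randomized complete block design (RCBD) with a
factorial arrangement: 10 blend levels (five CE:CF elicitor ratios —
100:0, 75:25, 50:50, 25:75, 0:100 — plus five water:PDB sham ratios),
three total concentrations (2.5, 5 and 10 % v/v), two elicitor adding
days (13 and 17), harvests every 2 days after elicitation until culture
day 23, and three replicates.  Control (water:PDB) blends deliver no
microbe-associated molecular patterns and are encoded as
``ce_conc = cf_conc = 0`` whatever their nominal volume.

Ground-truth responses come from a smooth parametric surface family:
hump-shaped (Gaussian) dose responses in CE and CF with an optional
CE x CF synergy term, a linear elicitor-adding-day modifier, and
saturating harvest-time kinetics (on the absolute culture clock for
biomass, on time since elicitation for product accumulation).  Dry
weight, intracellular and extracellular paclitaxel are simulated
directly; total yield and the extracellular portion are derived from
the identity ``total = intra * dw + extra`` and
``portion = 100 * extra / total`` before independent Gaussian
measurement noise is added to each reported response.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

INPUT_COLUMNS = ["ce_conc", "cf_conc", "adding_day", "harvest_day"]
RESPONSE_COLUMNS = ["dw", "intra", "extra", "total", "portion"]
TABLE_COLUMNS = INPUT_COLUMNS[:4] + ["replicate"] + RESPONSE_COLUMNS

#: Human-readable units for every table column.
UNITS = {
    "ce_conc": "% v/v",
    "cf_conc": "% v/v",
    "adding_day": "culture day",
    "harvest_day": "culture day",
    "dw": "g/l",
    "intra": "ug/g DW",
    "extra": "ug/l",
    "total": "ug/l",
    "portion": "%",
}


class ConfigurationError(ValueError):
    """Raised when a design or surface configuration is invalid."""


@dataclass(frozen=True)
class Blend:
    """One blend level: CE and CF volume fractions of the elicitor dose.

    ``control=True`` marks a water:PDB sham blend, which carries no
    elicitor regardless of its nominal composition.
    """

    ce: float
    cf: float
    control: bool = False

    def __post_init__(self):
        if self.ce < 0 or self.cf < 0:
            raise ConfigurationError(f"negative blend fraction in {self}")
        if abs(self.ce + self.cf - 1.0) > 1e-9:
            raise ConfigurationError(
                f"blend fractions must sum to 1, got {self.ce + self.cf}"
            )

    @property
    def label(self) -> str:
        kind = "W:PDB" if self.control else "CE:CF"
        return f"{round(100 * self.ce)}:{round(100 * self.cf)} {kind}"


_RATIOS = [(1.0, 0.0), (0.75, 0.25), (0.5, 0.5), (0.25, 0.75), (0.0, 1.0)]
DEFAULT_BLENDS: tuple[Blend, ...] = tuple(
    [Blend(ce, cf) for ce, cf in _RATIOS]
    + [Blend(ce, cf, control=True) for ce, cf in _RATIOS]
)


@dataclass(frozen=True)
class DesignConfig:
    """Factorial layout of the elicitation experiment."""

    blend_levels: tuple[Blend, ...] = DEFAULT_BLENDS
    conc_levels: tuple[float, ...] = (2.5, 5.0, 10.0)
    adding_days: tuple[float, ...] = (13.0, 17.0)
    harvest_interval_days: int = 2
    final_day: float = 23.0
    n_replicates: int = 3

    def validate(self) -> None:
        for name in ("blend_levels", "conc_levels", "adding_days"):
            if len(getattr(self, name)) == 0:
                raise ConfigurationError(f"{name} must not be empty")
        if self.harvest_interval_days < 1:
            raise ConfigurationError("harvest_interval_days must be >= 1")
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be >= 1")
        for day in self.adding_days:
            if self.final_day <= day:
                raise ConfigurationError(
                    f"final_day {self.final_day} must exceed adding day {day}"
                )

    def harvest_days(self, adding_day: float) -> list[float]:
        """Harvest schedule for one adding day: every ``interval`` days
        after elicitation, up to and including ``final_day``."""
        days, k = [], 1
        while adding_day + k * self.harvest_interval_days <= self.final_day + 1e-9:
            days.append(adding_day + k * self.harvest_interval_days)
            k += 1
        return days


def generate_design(config: DesignConfig | None = None) -> pd.DataFrame:
    """Expand the factorial design into one row per flask observation.

    Responses are left as NaN; ``simulate_responses`` fills them.
    """
    config = config or DesignConfig()
    config.validate()
    rows = []
    for blend in config.blend_levels:
        for conc in config.conc_levels:
            ce = 0.0 if blend.control else blend.ce * conc
            cf = 0.0 if blend.control else blend.cf * conc
            for adding in config.adding_days:
                for harvest in config.harvest_days(adding):
                    for rep in range(1, config.n_replicates + 1):
                        rows.append((ce, cf, adding, harvest, rep))
    table = pd.DataFrame(
        rows, columns=INPUT_COLUMNS + ["replicate"]
    ).reindex(columns=TABLE_COLUMNS)
    return table


@dataclass(frozen=True)
class ResponseSurface:
    """Smooth ground truth for one simulated response.

    value = baseline
            * (1 + ce_amp*g(ce) + cf_amp*g(cf) + interaction_amp*g(ce)*g(cf))
            * (1 + adding_day_slope*(adding_day - 13))
            * (1 - exp(-harvest_rate*(clock - harvest_onset)))

    where g is a Gaussian dose bump re-anchored so g(0) = 0 (controls sit
    exactly at the baseline kinetics) and ``clock`` is either the
    absolute culture day or the time since elicitation.
    """

    baseline: float
    ce_amp: float = 0.0
    ce_opt: float = 5.0
    ce_width: float = 3.0
    cf_amp: float = 0.0
    cf_opt: float = 5.0
    cf_width: float = 3.0
    interaction_amp: float = 0.0
    adding_day_slope: float = 0.0
    harvest_rate: float = 0.3
    harvest_onset: float = 0.0
    harvest_clock: str = "post_elicitation"  # or "culture"

    def __post_init__(self):
        if self.ce_width <= 0 or self.cf_width <= 0:
            raise ConfigurationError("dose-response widths must be > 0")
        if self.harvest_clock not in ("post_elicitation", "culture"):
            raise ConfigurationError(
                f"unknown harvest_clock {self.harvest_clock!r}"
            )

    @staticmethod
    def _bump(x, opt, width):
        g = np.exp(-((x - opt) ** 2) / (2.0 * width**2))
        return g - np.exp(-(opt**2) / (2.0 * width**2))

    def value(self, ce, cf, adding_day, harvest_day):
        ce = np.asarray(ce, float)
        cf = np.asarray(cf, float)
        adding_day = np.asarray(adding_day, float)
        harvest_day = np.asarray(harvest_day, float)
        gce = self._bump(ce, self.ce_opt, self.ce_width)
        gcf = self._bump(cf, self.cf_opt, self.cf_width)
        dose = 1.0 + self.ce_amp * gce + self.cf_amp * gcf
        dose = dose + self.interaction_amp * gce * gcf
        timing = 1.0 + self.adding_day_slope * (adding_day - 13.0)
        clock = (
            harvest_day - adding_day
            if self.harvest_clock == "post_elicitation"
            else harvest_day
        )
        kinetics = 1.0 - np.exp(-self.harvest_rate * (clock - self.harvest_onset))
        out = self.baseline * dose * timing * kinetics
        return np.maximum(out, 0.0)


def _default_surfaces() -> dict[str, ResponseSurface]:
    # Biomass: dominated by saturating growth on the absolute culture
    # clock; elicitation perturbs it only mildly.
    dw = ResponseSurface(
        baseline=12.0,
        ce_amp=0.08, ce_opt=5.0, ce_width=3.0,
        cf_amp=0.04, cf_opt=5.0, cf_width=3.0,
        adding_day_slope=0.015,
        harvest_rate=0.18, harvest_onset=8.0, harvest_clock="culture",
    )
    # Intracellular product: strong hump-shaped elicitor dose response
    # with CE/CF synergy, accumulating after elicitation.
    intra = ResponseSurface(
        baseline=2.2,
        ce_amp=3.2, ce_opt=4.0, ce_width=2.5,
        cf_amp=4.0, cf_opt=5.5, cf_width=2.5,
        interaction_amp=1.2,
        adding_day_slope=0.05,
        harvest_rate=0.45, harvest_onset=0.0,
    )
    # Secreted product: slower post-elicitation rise, CF-heavier dose
    # optimum, late addition favoured.
    extra = ResponseSurface(
        baseline=8.0,
        ce_amp=4.5, ce_opt=5.0, ce_width=3.0,
        cf_amp=7.0, cf_opt=6.0, cf_width=3.0,
        interaction_amp=1.5,
        adding_day_slope=0.06,
        harvest_rate=0.30, harvest_onset=0.0,
    )
    return {"dw": dw, "intra": intra, "extra": extra}


@dataclass(frozen=True)
class SurfaceParams:
    """Ground truth for the three simulated responses plus the noise model.

    ``noise_sd`` gives an absolute measurement-noise standard deviation
    per reported response; when omitted, each response's noise sd is
    ``noise_fraction`` times the standard deviation of its noiseless
    values over the design being simulated.  ``block_sd`` adds an
    optional RCBD replicate (block) offset, as a fraction of each
    response's noiseless sd (default 0: no block effect).
    """

    surfaces: dict[str, ResponseSurface] = field(default_factory=_default_surfaces)
    noise_sd: dict[str, float] | None = None
    noise_fraction: float = 0.1
    block_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        missing = {"dw", "intra", "extra"} - set(self.surfaces)
        if missing:
            raise ConfigurationError(f"surfaces missing responses: {missing}")
        if self.noise_fraction < 0 or self.block_sd < 0:
            raise ConfigurationError("noise levels must be >= 0")
        if self.noise_sd is not None:
            bad = {k: v for k, v in self.noise_sd.items() if v < 0}
            if bad:
                raise ConfigurationError(f"negative noise_sd: {bad}")

    def replace(self, **kw) -> "SurfaceParams":
        return dataclasses.replace(self, **kw)


def true_response(params: SurfaceParams, response: str, ce, cf, adding_day,
                  harvest_day) -> np.ndarray:
    """Noiseless value of one of the five responses at given inputs."""
    if response in ("dw", "intra", "extra"):
        return params.surfaces[response].value(ce, cf, adding_day, harvest_day)
    dw = params.surfaces["dw"].value(ce, cf, adding_day, harvest_day)
    intra = params.surfaces["intra"].value(ce, cf, adding_day, harvest_day)
    extra = params.surfaces["extra"].value(ce, cf, adding_day, harvest_day)
    total = intra * dw + extra
    if response == "total":
        return total
    if response == "portion":
        with np.errstate(invalid="ignore", divide="ignore"):
            portion = np.where(total > 0, 100.0 * extra / total, 0.0)
        return portion
    raise KeyError(f"unknown response {response!r}")


def simulate_responses(design: pd.DataFrame,
                       params: SurfaceParams | None = None) -> pd.DataFrame:
    """Fill the five response columns of a design table.

    Total yield and the extracellular portion are computed from the
    simulated dry weight and paclitaxel pools before independent
    Gaussian noise is added to each reported response; every response is
    clipped at zero afterwards.  Deterministic for a given seed.
    """
    params = params or SurfaceParams()
    params.validate()
    missing = [c for c in INPUT_COLUMNS if c not in design.columns]
    if missing:
        raise ConfigurationError(f"design lacks input columns: {missing}")

    table = design.copy()
    clean = {
        resp: true_response(
            params, resp,
            table["ce_conc"].to_numpy(), table["cf_conc"].to_numpy(),
            table["adding_day"].to_numpy(), table["harvest_day"].to_numpy(),
        )
        for resp in RESPONSE_COLUMNS
    }
    sds = {
        resp: (
            params.noise_sd[resp]
            if params.noise_sd is not None
            else params.noise_fraction * float(np.std(clean[resp]))
        )
        for resp in RESPONSE_COLUMNS
    }

    rng = np.random.default_rng(params.seed)
    reps = (
        table["replicate"].to_numpy()
        if "replicate" in table.columns
        else np.ones(len(table), dtype=int)
    )
    rep_ids = np.unique(reps)
    for resp in RESPONSE_COLUMNS:
        values = clean[resp].astype(float).copy()
        if params.block_sd > 0:
            offsets = rng.normal(
                0.0, params.block_sd * float(np.std(clean[resp])), len(rep_ids)
            )
            values = values + offsets[np.searchsorted(rep_ids, reps)]
        values = values + rng.normal(0.0, sds[resp], len(table))
        table[resp] = np.maximum(values, 0.0)
    return table


@dataclass(frozen=True)
class TrueOptimum:
    """Grid-search argmax of a noiseless response surface."""

    inputs: dict[str, float]
    value: float
    grid_step: dict[str, float]


DEFAULT_BOUNDS = {
    "ce_conc": (0.0, 10.0),
    "cf_conc": (0.0, 10.0),
    "adding_day": (13.0, 17.0),
    "harvest_day": (13.0, 23.0),
}


def true_optimum(params: SurfaceParams,
                 bounds: dict[str, tuple[float, float]] | None = None,
                 response: str = "total",
                 grid_step: dict[str, float] | None = None) -> TrueOptimum:
    """Locate the maximum of the noiseless surface by dense grid search.

    The grid respects ``harvest_day > adding_day``; points violating the
    ordering are excluded.  This is a deliberately brute-force oracle
    used to validate stochastic optimizers.
    """
    if response not in RESPONSE_COLUMNS:
        raise KeyError(f"unknown response {response!r}")
    bounds = {**DEFAULT_BOUNDS, **(bounds or {})}
    step = {k: 0.25 for k in INPUT_COLUMNS}
    step.update(grid_step or {})

    axes = []
    for name in INPUT_COLUMNS:
        lo, hi = bounds[name]
        n = max(int(round((hi - lo) / step[name])) + 1, 1)
        axes.append(np.linspace(lo, hi, n))
    ce, cf, ad, hv = np.meshgrid(*axes, indexing="ij", sparse=False)
    ce, cf, ad, hv = (a.ravel() for a in (ce, cf, ad, hv))
    feasible = hv > ad
    if not feasible.any():
        raise ConfigurationError("no feasible grid point with harvest > adding")
    ce, cf, ad, hv = ce[feasible], cf[feasible], ad[feasible], hv[feasible]
    values = true_response(params, response, ce, cf, ad, hv)
    best = int(np.argmax(values))
    return TrueOptimum(
        inputs={
            "ce_conc": float(ce[best]),
            "cf_conc": float(cf[best]),
            "adding_day": float(ad[best]),
            "harvest_day": float(hv[best]),
        },
        value=float(values[best]),
        grid_step=step,
    )
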