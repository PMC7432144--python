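"""End-to-end workflow: simulate, split, fit, assess, optimize, report.

For each of the five culture responses (dry weight, intracellular,
extracellular and total paclitaxel, extracellular portion) the pipeline
fits a backward-elimination regression and an MLP surrogate on the
training subset, evaluates both on training and testing subsets, runs
VSE/VSR sensitivity on all data lines, and GA-optimizes the culture
inputs under the surrogate.  Optimal conditions are reported the way a
bioprocess scientist states them: total elicitor dose and integer
CE:CF blend label, plus the elapsed time between elicitation and
harvest in hours and minutes.

A fitted surrogate can be exported as a self-contained JSON estimator
(weights, scalers, metadata, schema version) together with a flat
closed-form prediction formula for spreadsheet users.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .datagen import (
    INPUT_COLUMNS,
    RESPONSE_COLUMNS,
    Blend,
    DesignConfig,
    SurfaceParams,
    generate_design,
    simulate_responses,
)
from .dataio import SplitIndex, split_train_test, write_table
from .evolve import GAConfig, GAResult, optimize_inputs, select_architecture
from .metrics import evaluate
from .neuralnet import MLPModel, TrainConfig, evaluate_model
from .regress import backward_eliminate
from .sensitivity import vsr_report

ESTIMATOR_SCHEMA_VERSION = 1


class EstimatorFormatError(ValueError):
    """An estimator file fails schema validation."""


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def blend_summary(ce_conc: float, cf_conc: float) -> tuple[float, str]:
    """Total elicitor dose (2 dp) and integer CE:CF blend label.

    The CE share is round-half-up of its percentage of the total; the CF
    share is the complement, so the label always sums to 100.  A zero
    dose is labelled "control".
    """
    if ce_conc < 0 or cf_conc < 0:
        raise ValueError("concentrations must be non-negative")
    total = round(ce_conc + cf_conc, 2)
    if ce_conc + cf_conc == 0:
        return 0.0, "control"
    ce_share = _round_half_up(100.0 * ce_conc / (ce_conc + cf_conc))
    return total, f"{ce_share}CE:{100 - ce_share}CF"


def elapsed_time(adding_day: float, harvest_day: float) -> tuple[float, str]:
    """Hours between elicitation and harvest, with an "H h and M min" text."""
    if harvest_day < adding_day:
        raise ValueError("harvest_day must not precede adding_day")
    hours = 24.0 * (harvest_day - adding_day)
    whole = int(math.floor(hours))
    minutes = _round_half_up((hours - whole) * 60.0)
    if minutes == 60:
        whole, minutes = whole + 1, 0
    text = f"{whole} h" if minutes == 0 else f"{whole} h and {minutes} min"
    return hours, text


@dataclass
class OptimizationResult:
    """GA-optimal culture inputs for one response, with derived quantities."""

    response: str
    ce_conc: float
    cf_conc: float
    adding_day: float
    harvest_day: float
    predicted: float
    total_conc: float
    blend_label: str
    elapsed_hours: float
    elapsed_text: str
    ga_result: GAResult | None = None

    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "ce_conc": self.ce_conc,
            "cf_conc": self.cf_conc,
            "adding_day": self.adding_day,
            "harvest_day": self.harvest_day,
            "predicted": self.predicted,
            "total_conc": self.total_conc,
            "blend_label": self.blend_label,
            "elapsed_hours": self.elapsed_hours,
            "elapsed_text": self.elapsed_text,
        }

    def describe(self) -> str:
        return (
            f"add {self.total_conc:.2f}% (v/v) of {self.blend_label} "
            f"(CE {self.ce_conc:.2f}%, CF {self.cf_conc:.2f}%) on day "
            f"{self.adding_day:.2f} and harvest {self.elapsed_text} after "
            f"elicitation -> predicted {self.response} = {self.predicted:.2f}"
        )


def make_optimization_result(response: str, ce_conc: float, cf_conc: float,
                             adding_day: float, harvest_day: float,
                             predicted: float,
                             ga_result: GAResult | None = None
                             ) -> OptimizationResult:
    total, label = blend_summary(ce_conc, cf_conc)
    hours, text = elapsed_time(adding_day, harvest_day)
    return OptimizationResult(
        response=response, ce_conc=ce_conc, cf_conc=cf_conc,
        adding_day=adding_day, harvest_day=harvest_day, predicted=predicted,
        total_conc=total, blend_label=label,
        elapsed_hours=hours, elapsed_text=text, ga_result=ga_result,
    )


# ---------------------------------------------------------------------------
# Portable estimator files

def export_estimator(model: MLPModel, path) -> None:
    """Write a fitted surrogate as a self-contained JSON estimator."""
    model.validate()
    payload = {
        "schema_version": ESTIMATOR_SCHEMA_VERSION,
        "package_version": __version__,
        "model": model.to_dict(),
        "formula": render_formula(model),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_estimator(path) -> MLPModel:
    """Load and validate a JSON estimator written by ``export_estimator``."""
    payload = json.loads(Path(path).read_text())
    version = payload.get("schema_version")
    if version != ESTIMATOR_SCHEMA_VERSION:
        raise EstimatorFormatError(
            f"unsupported estimator schema version {version!r}"
        )
    try:
        return MLPModel.from_dict(payload["model"])
    except (KeyError, ValueError, TypeError) as err:
        raise EstimatorFormatError(f"invalid estimator file: {err}") from err


def render_formula(model: MLPModel) -> str:
    """The surrogate's prediction as one flat closed-form expression.

    Variables are the raw (unscaled) inputs ce_conc, cf_conc,
    adding_day, harvest_day; the only function used is tanh, so the
    expression pastes into a spreadsheet or any expression evaluator.
    """
    num = lambda x: repr(float(x))
    scaled = []
    for i, name in enumerate(model.input_names):
        lo, hi = model.input_min[i], model.input_max[i]
        scaled.append(f"(2*({name} - {num(lo)})/({num(hi - lo)}) - 1)")
    units = []
    for j in range(model.n_hidden):
        terms = [num(model.hidden_biases[j])]
        terms += [
            f"{num(model.hidden_weights[j, i])}*{scaled[i]}" for i in range(4)
        ]
        units.append(f"{num(model.output_weights[j])}*tanh({' + '.join(terms)})")
    net = " + ".join([num(model.output_bias)] + units)
    tmin, tmax = model.target_min, model.target_max
    return f"{num(tmin)} + (({net}) + 1)*{num((tmax - tmin) / 2.0)}"


def load_config(path) -> "PipelineConfig":
    """Build a :class:`PipelineConfig` from a YAML file.

    The schema mirrors the dataclasses with flat key/value sections::

        seed: 1
        split_fraction: 0.7
        alpha: 0.05
        hidden_range: [2, 10]
        architecture_search: true
        fixed_n_hidden: 6
        responses: [dw, total]          # optional subset
        design:                          # DesignConfig fields
          conc_levels: [2.5, 5, 10]
          adding_days: [13, 17]
          harvest_interval_days: 2
          final_day: 23
          n_replicates: 3
          blend_levels:                  # [ce_fraction, cf_fraction, control]
            - [1.0, 0.0, false]
            - [0.5, 0.5, false]
            - [1.0, 0.0, true]
        surfaces:                        # per-response ResponseSurface fields
          dw: {baseline: 12.0, harvest_rate: 0.18, harvest_clock: culture}
        noise_fraction: 0.1
        block_sd: 0.0
        ga: {population_size: 50, generations: 500}
        train: {learning_rate: 0.05, max_epochs: 4000}

    Omitted keys keep their defaults.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs: dict = {}

    design_raw = dict(raw.get("design", {}))
    if "blend_levels" in design_raw:
        design_raw["blend_levels"] = tuple(
            Blend(float(b[0]), float(b[1]), bool(b[2]) if len(b) > 2 else False)
            for b in design_raw["blend_levels"]
        )
    for key in ("conc_levels", "adding_days"):
        if key in design_raw:
            design_raw[key] = tuple(float(v) for v in design_raw[key])
    if design_raw:
        kwargs["design"] = DesignConfig(**design_raw)

    defaults = SurfaceParams()
    surfaces = dict(defaults.surfaces)
    for resp, fields in (raw.get("surfaces") or {}).items():
        surfaces[resp] = dataclasses.replace(surfaces[resp], **fields)
    kwargs["surfaces"] = SurfaceParams(
        surfaces=surfaces,
        noise_fraction=float(raw.get("noise_fraction", defaults.noise_fraction)),
        block_sd=float(raw.get("block_sd", defaults.block_sd)),
    )

    if "ga" in raw:
        kwargs["ga"] = GAConfig(**raw["ga"])
    if "train" in raw:
        kwargs["train"] = TrainConfig(**raw["train"])
    if "hidden_range" in raw:
        kwargs["hidden_range"] = tuple(int(v) for v in raw["hidden_range"])
    if "responses" in raw:
        kwargs["responses"] = tuple(raw["responses"])
    for key in ("split_fraction", "alpha", "architecture_search",
                "fixed_n_hidden", "seed"):
        if key in raw:
            kwargs[key] = raw[key]
    return PipelineConfig(**kwargs)


# ---------------------------------------------------------------------------
# Full pipeline

@dataclass
class PipelineConfig:
    """Everything needed to reproduce one end-to-end run."""

    design: DesignConfig = field(default_factory=DesignConfig)
    surfaces: SurfaceParams = field(default_factory=SurfaceParams)
    responses: tuple[str, ...] = tuple(RESPONSE_COLUMNS)
    split_fraction: float = 0.7
    alpha: float = 0.05
    hidden_range: tuple[int, int] = (2, 10)
    train: TrainConfig = field(default_factory=TrainConfig)
    ga: GAConfig = field(default_factory=GAConfig)
    architecture_search: bool = True
    fixed_n_hidden: int = 6  # used when architecture_search is off
    seed: int = 0
    outdir: Path | None = None


@dataclass
class ResponseReport:
    response: str
    regression: dict
    regression_metrics_train: dict
    regression_metrics_test: dict
    n_hidden: int
    candidate_rmse: dict
    mlp_metrics_train: dict
    mlp_metrics_test: dict
    sensitivity: dict
    optimization: dict
    model: MLPModel
    ga_history: pd.DataFrame | None = None


@dataclass
class RunReport:
    config_echo: dict
    seeds: dict
    n_rows: int
    split: SplitIndex
    responses: dict[str, ResponseReport]
    comparison: pd.DataFrame  # regression vs MLP test R²
    table: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "package_version": __version__,
            "config": self.config_echo,
            "seeds": self.seeds,
            "n_rows": self.n_rows,
            "split": {
                "fraction": self.split.fraction,
                "seed": self.split.seed,
                "n_train": len(self.split.train_rows),
                "n_test": len(self.split.test_rows),
            },
            "responses": {
                name: {
                    "regression": r.regression,
                    "regression_metrics_train": r.regression_metrics_train,
                    "regression_metrics_test": r.regression_metrics_test,
                    "n_hidden": r.n_hidden,
                    "candidate_rmse": r.candidate_rmse,
                    "mlp_metrics_train": r.mlp_metrics_train,
                    "mlp_metrics_test": r.mlp_metrics_test,
                    "sensitivity": r.sensitivity,
                    "optimization": r.optimization,
                }
                for name, r in self.responses.items()
            },
            "comparison": self.comparison.to_dict(orient="list"),
        }


def _sub_seeds(seed: int, labels: list[str]) -> dict[str, int]:
    state = np.random.SeedSequence(seed).generate_state(len(labels))
    return {lab: int(s % (2**31)) for lab, s in zip(labels, state)}


def run_full_pipeline(config: PipelineConfig | None = None,
                      table: pd.DataFrame | None = None) -> RunReport:
    """Run every stage for every configured response.

    When ``table`` is given it is used as the experiment data; otherwise
    a synthetic experiment is generated from ``config.design`` and
    ``config.surfaces``.  All randomness derives from ``config.seed``.
    Writes report/model/comparison files when ``config.outdir`` is set.
    """
    config = config or PipelineConfig()
    labels = ["simulate", "split"] + [
        f"{stage}:{resp}"
        for resp in config.responses
        for stage in ("train", "ga")
    ]
    seeds = _sub_seeds(config.seed, labels)

    if table is None:
        design = generate_design(config.design)
        table = simulate_responses(
            design, config.surfaces.replace(seed=seeds["simulate"])
        )
    split = split_train_test(table, config.split_fraction, seeds["split"])
    train_idx, test_idx = list(split.train_rows), list(split.test_rows)
    X = table[INPUT_COLUMNS]
    X_train, X_test = X.iloc[train_idx], X.iloc[test_idx]

    reports: dict[str, ResponseReport] = {}
    comparison_rows = []
    for resp in config.responses:
        y = table[resp].to_numpy(float)
        y_train, y_test = y[train_idx], y[test_idx]

        reg = backward_eliminate(X_train.reset_index(drop=True), y_train,
                                 alpha=config.alpha)
        reg_train = evaluate(y_train, reg.predict(X_train))
        reg_test = evaluate(y_test, reg.predict(X_test))
        reg.metrics_train, reg.metrics_test = reg_train, reg_test

        train_seed = seeds[f"train:{resp}"]
        if config.architecture_search:
            lo, hi = config.hidden_range
            n_hidden, model, cache = select_architecture(
                X_train.to_numpy(float), y_train,
                hidden_range=range(lo, hi + 1),
                train_config=config.train,
                config=dataclasses.replace(config.ga, seed=seeds[f"ga:{resp}"]),
                train_seed=train_seed,
            )
        else:
            from .neuralnet import train as train_mlp

            n_hidden = config.fixed_n_hidden
            model = train_mlp(X_train.to_numpy(float), y_train, n_hidden,
                              config=config.train, seed=train_seed)
            cache = {}
        mlp_train = evaluate_model(model, X_train.to_numpy(float), y_train)
        mlp_test = evaluate_model(model, X_test.to_numpy(float), y_test)

        sens = vsr_report(model, X.to_numpy(float), y)
        dose_limit = float(
            (X_train["ce_conc"] + X_train["cf_conc"]).max()
        )
        opt = optimize_inputs(
            model,
            config=dataclasses.replace(config.ga, seed=seeds[f"ga:{resp}"] + 1),
            final_day=config.design.final_day,
            response=resp,
            dose_limit=dose_limit,
        )

        reports[resp] = ResponseReport(
            response=resp,
            regression=reg.to_dict(),
            regression_metrics_train=reg_train.to_dict(),
            regression_metrics_test=reg_test.to_dict(),
            n_hidden=n_hidden,
            candidate_rmse={str(k): v for k, v in sorted(cache.items())},
            mlp_metrics_train=mlp_train.to_dict(),
            mlp_metrics_test=mlp_test.to_dict(),
            sensitivity=sens.to_dict(),
            optimization=opt.to_dict(),
            model=model,
            ga_history=opt.ga_result.history if opt.ga_result else None,
        )
        comparison_rows.append({
            "response": resp,
            "regression_test_r2": reg_test.r2,
            "mlp_test_r2": mlp_test.r2,
            "mlp_minus_regression": mlp_test.r2 - reg_test.r2,
        })

    report = RunReport(
        config_echo={
            "seed": config.seed,
            "split_fraction": config.split_fraction,
            "alpha": config.alpha,
            "hidden_range": list(config.hidden_range),
            "architecture_search": config.architecture_search,
            "responses": list(config.responses),
            "ga": dataclasses.asdict(config.ga),
            "train": dataclasses.asdict(config.train),
        },
        seeds=seeds,
        n_rows=len(table),
        split=split,
        responses=reports,
        comparison=pd.DataFrame(comparison_rows),
        table=table,
    )
    if config.outdir is not None:
        _write_report(report, Path(config.outdir))
    return report


def _write_report(report: RunReport, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "models").mkdir(exist_ok=True)
    write_table(report.table, outdir / "table.csv")
    report.split.to_json(outdir / "split.json")
    report.comparison.to_csv(outdir / "comparison.csv", index=False)
    for resp, r in report.responses.items():
        export_estimator(r.model, outdir / "models" / f"{resp}.json")
        if r.ga_history is not None:
            r.ga_history.to_csv(outdir / f"ga_history_{resp}.csv", index=False)
    (outdir / "report.json").write_text(json.dumps(report.to_dict(), indent=1))
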