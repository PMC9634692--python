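"""Configuration-driven orchestration: generate/ingest, fit, report.

A run configuration (YAML or JSON) lists experiments — each either a path
to a band-intensity table or an inline synthetic design — with a fit
recipe (``kobs``, ``k1``, ``hydrolysis`` or ``ligation``), optional Monte
Carlo settings, and reporting instructions.  :func:`run` chains lane
normalization, rate-constant estimation, uncertainty propagation and
fold-change reporting, writing:

* ``rate_constants.csv`` — condition, parameter, estimate, sd, n, method;
* ``half_lives.csv`` — half-life rows with value(uncertainty) formatting;
* ``folds.csv`` — fold changes between named condition pairs with
  delta-method uncertainties;
* ``run.log`` — seeds, excluded points, per-experiment failures.

Re-running with the same config and seed reproduces identical tables.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, GlykinError
from .estimators import (
    ObservedTimeCourse,
    UncertaintySpec,
    censor_ligation,
    fit_k1,
    fit_kobs,
    half_life,
    mc_propagate,
)
from .gel import BandMap, read_band_table, to_timecourse
from .model import RateConstants
from .synth import (
    ExperimentDesign,
    NoiseModel,
    gen_extension_experiment,
    gen_hydrolysis_experiment,
    gen_ligation_experiment,
)

__all__ = [
    "RunConfig",
    "ExperimentSpec",
    "load_config",
    "run",
    "report_folds",
    "format_value_uncertainty",
]

logger = logging.getLogger(__name__)

RECIPES = ("kobs", "k1", "hydrolysis", "ligation")


@dataclass(frozen=True)
class ExperimentSpec:
    """One experiment of a run: data source plus fit recipe."""

    name: str
    recipe: str
    table: str | None = None
    tables: Mapping[str, str] | None = None  # ligation: amino/control/hydrolysis
    synthetic: Mapping[str, Any] | None = None
    fixed: Mapping[str, float] | None = None
    monte_carlo: Mapping[str, Any] | None = None
    observable: str | None = None
    censor_threshold: float = 0.02
    meta: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.recipe not in RECIPES:
            raise ConfigurationError(
                f"experiment {self.name!r}: unknown recipe {self.recipe!r}"
            )
        sources = [
            s is not None for s in (self.table, self.tables, self.synthetic)
        ]
        if sum(sources) != 1:
            raise ConfigurationError(
                f"experiment {self.name!r}: exactly one of table, tables or "
                "synthetic must be given"
            )
        if self.recipe == "ligation" and self.table is not None:
            raise ConfigurationError(
                f"experiment {self.name!r}: the ligation recipe needs the "
                "three-arm 'tables' mapping or a synthetic design"
            )


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration."""

    experiments: tuple[ExperimentSpec, ...]
    seed: int
    out_dir: str = "results"
    fold_pairs: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if not self.experiments:
            raise ConfigurationError("config defines no experiments")
        names = [e.name for e in self.experiments]
        if len(set(names)) != len(names):
            raise ConfigurationError(f"duplicate experiment names in {names}")
        known = set(names)
        for pair in self.fold_pairs:
            if len(pair) != 2:
                raise ConfigurationError(f"fold pair {pair!r} is not a pair")
            for name in pair:
                if name not in known:
                    raise ConfigurationError(
                        f"fold pair references unknown experiment {name!r}"
                    )
        has_stochastic = any(
            e.synthetic is not None or e.monte_carlo is not None
            for e in self.experiments
        )
        if has_stochastic and self.seed is None:
            raise ConfigurationError(
                "a seed is mandatory when any stochastic step is present"
            )


def load_config(source: str | Path | Mapping[str, Any],
                seed: int | None = None) -> RunConfig:
    """Load and validate a YAML/JSON config file or an equivalent mapping.

    ``seed`` overrides the config's seed when given (the CLI's --seed).
    """
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
        raw = yaml.safe_load(text)  # YAML is a superset of JSON
    else:
        raw = dict(source)
    if not isinstance(raw, Mapping):
        raise ConfigurationError("config root must be a mapping")
    experiments = tuple(
        ExperimentSpec(**exp) for exp in raw.get("experiments", [])
    )
    cfg_seed = seed if seed is not None else raw.get("seed")
    if cfg_seed is None:
        raise ConfigurationError("config must define a seed")
    return RunConfig(
        experiments=experiments,
        seed=int(cfg_seed),
        out_dir=str(raw.get("out_dir", "results")),
        fold_pairs=tuple(
            tuple(p) for p in raw.get("fold_pairs", [])
        ),
    )


def _design_from_spec(exp: ExperimentSpec, seed: int) -> ExperimentDesign:
    s = dict(exp.synthetic or {})
    etype = s.pop("type")
    rates = RateConstants(
        k1=float(s.pop("k1", 0.0)),
        k2=float(s.pop("k2", 0.0)),
        k3=float(s.pop("k3", 0.0)),
    )
    noise = NoiseModel(
        sd_multiplicative=float(s.pop("noise_sd", 0.05)),
        baseline=float(s.pop("noise_baseline", 0.0)),
    )
    design = ExperimentDesign(
        experiment_type=etype,
        condition=str(s.pop("condition", exp.name)),
        rates=rates,
        times=s.pop("times"),
        p_gly0=s.pop("p_gly0", None),
        n_replicates=int(s.pop("replicates", 3)),
        noise=noise,
        seed=seed,
        lane_total=float(s.pop("lane_total", 1e4)),
        lane_total_sd=float(s.pop("lane_total_sd", 0.2)),
    )
    if s:
        raise ConfigurationError(
            f"experiment {exp.name!r}: unknown synthetic key(s) {sorted(s)}"
        )
    return design


def _mc_spec(exp: ExperimentSpec, fixed: Mapping[str, float],
             seed: int) -> UncertaintySpec:
    mc = dict(exp.monte_carlo or {})
    return UncertaintySpec(
        p_gly0=(fixed["p_gly0"], float(mc.get("sd_p_gly0", 0.0))),
        k2=(fixed["k2"], float(mc.get("sd_k2", 0.0))),
        k3=(fixed["k3"], float(mc.get("sd_k3", 0.0))),
        n_draws=int(mc.get("n_draws", 1000)),
        seed=int(mc.get("seed", seed)),
    )


def _mean_sd(values: Sequence[float]) -> tuple[float, float]:
    arr = np.asarray(values, dtype=float)
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
    return float(np.mean(arr)), sd


def format_value_uncertainty(value: float, sd: float) -> str:
    """Concise value(uncertainty) notation with a one-significant-digit sd.

    72.3 +/- 2.1 -> "72(2)"; 20.14 +/- 0.9 -> "20.1(9)".  A zero or
    missing sd falls back to four significant digits.
    """
    if not math.isfinite(sd) or sd <= 0:
        return f"{value:.4g}"
    exponent = math.floor(math.log10(sd))
    sd_1 = round(sd, -exponent)
    if sd_1 >= 10 ** (exponent + 1):  # 0.95 -> 1 spills a digit
        exponent += 1
        sd_1 = round(sd, -exponent)
    digits = max(-exponent, 0)
    digit = int(round(sd_1 / 10 ** exponent))
    return f"{value:.{digits}f}({digit})"


def _fit_experiment(
    exp: ExperimentSpec, seed: int, out_dir: Path
) -> tuple[list[dict], list[dict]]:
    """Fit one experiment; returns (rate rows, half-life rows)."""
    rate_rows: list[dict] = []
    half_rows: list[dict] = []

    if exp.recipe == "ligation":
        return _fit_ligation(exp, seed)

    manifest = None
    if exp.synthetic is not None:
        design = _design_from_spec(exp, seed)
        if design.experiment_type == "hydrolysis_acidic":
            table, manifest = gen_hydrolysis_experiment(design)
        else:
            table, manifest = gen_extension_experiment(design)
        band_map = BandMap.for_type(design.experiment_type)
        logger.info("experiment %s: generated synthetic %s data (seed=%d)",
                    exp.name, design.experiment_type, seed)
    else:
        table = read_band_table(exp.table)
        band_map = BandMap.for_type(
            "hydrolysis_acidic" if exp.recipe == "hydrolysis" else "extension"
        )
    tcs = list(to_timecourse(table, band_map).values())

    if exp.recipe in ("kobs", "hydrolysis"):
        observable = exp.observable or (
            "primer_gly" if exp.recipe == "hydrolysis" else "primer"
        )
        fits = [fit_kobs(tc, observable) for tc in tcs]
        ks = [f.k_obs for f in fits]
        mean_k, sd_k = _mean_sd(ks)
        rate_rows.append({
            "condition": exp.name, "parameter": "k_obs",
            "estimate": mean_k, "sd": sd_k,
            "n_points": sum(f.n_points for f in fits),
            "method": "log_linear_ols", "seed": seed,
        })
        if exp.recipe == "hydrolysis":
            halves = [half_life(k) for k in ks]
            mean_h, sd_h = _mean_sd(halves)
            half_rows.append({
                "condition": exp.name,
                **dict(exp.meta),
                "half_life_h": mean_h, "sd": sd_h,
                "formatted": format_value_uncertainty(mean_h, sd_h),
                "n_replicates": len(halves),
            })
    elif exp.recipe == "k1":
        fixed = dict(exp.fixed or {})
        if not fixed and manifest is not None:
            # synthetic convenience: condition on the generator's truth
            fixed = {k: manifest[k] for k in ("k2", "k3", "p_gly0")}
            logger.info(
                "experiment %s: fixed inputs taken from synthetic manifest",
                exp.name,
            )
        for key in ("k2", "k3", "p_gly0"):
            if key not in fixed:
                raise ConfigurationError(
                    f"experiment {exp.name!r}: k1 recipe needs fixed "
                    f"input {key!r}"
                )
        if exp.monte_carlo is not None:
            fit = mc_propagate(tcs, _mc_spec(exp, fixed, seed))
            sd = fit.sd
            method = fit.method
        else:
            fit = fit_k1(tcs, fixed["k2"], fixed["k3"], fixed["p_gly0"])
            sd = np.nan
            method = fit.method
        if fit.n_excluded:
            logger.warning("experiment %s: excluded %d non-positive point(s)",
                           exp.name, fit.n_excluded)
        rate_rows.append({
            "condition": exp.name, "parameter": "k1",
            "estimate": fit.k1, "sd": sd, "n_points": fit.n_points,
            "method": method, "seed": seed,
        })
    return rate_rows, half_rows


def _replicate_sorted(tcs: Mapping) -> list[ObservedTimeCourse]:
    return [tcs[k] for k in sorted(tcs)]


def _fit_ligation(
    exp: ExperimentSpec, seed: int
) -> tuple[list[dict], list[dict]]:
    """Three-arm ligation recipe: k3 from the RNA control, k2 from the
    hydrolysis arm, then the censored nonlinear k1 fit."""
    if exp.synthetic is not None:
        design = _design_from_spec(exp, seed)
        amino, control, hydrolysis, manifest = gen_ligation_experiment(design)
        p_gly0 = manifest["p_gly0"]
    else:
        amino = read_band_table(exp.tables["amino"])
        control = read_band_table(exp.tables["control"])
        hydrolysis = read_band_table(exp.tables["hydrolysis"])
        fixed = dict(exp.fixed or {})
        if "p_gly0" not in fixed:
            raise ConfigurationError(
                f"experiment {exp.name!r}: ligation from tables needs a "
                "fixed p_gly0"
            )
        p_gly0 = fixed["p_gly0"]

    lig_map = BandMap.ligation()
    amino_tcs = _replicate_sorted(to_timecourse(amino, lig_map))
    ctrl_tcs = _replicate_sorted(to_timecourse(control, lig_map))
    hyd_tcs = _replicate_sorted(
        to_timecourse(hydrolysis, BandMap.hydrolysis_acidic())
    )

    k3_fits = [fit_kobs(tc, "primer") for tc in ctrl_tcs]
    k2_fits = [fit_kobs(tc, "primer_gly") for tc in hyd_tcs]
    k3, k3_sd = _mean_sd([f.k_obs for f in k3_fits])
    k2, k2_sd = _mean_sd([f.k_obs for f in k2_fits])

    censored = [
        censor_ligation(a, c, exp.censor_threshold)
        for a, c in zip(amino_tcs, ctrl_tcs)
    ]
    logger.info(
        "experiment %s: censoring kept %s of %d points per replicate",
        exp.name, [len(c) for c in censored], len(amino_tcs[0]),
    )

    fixed = {"k2": max(k2, 0.0), "k3": max(k3, 0.0), "p_gly0": p_gly0}
    if exp.monte_carlo is not None:
        mc = dict(exp.monte_carlo)
        mc.setdefault("sd_k2", k2_sd)
        mc.setdefault("sd_k3", k3_sd)
        exp = ExperimentSpec(**{**exp.__dict__, "monte_carlo": mc})
        fit = mc_propagate(censored, _mc_spec(exp, fixed, seed))
        sd = fit.sd
    else:
        fit = fit_k1(censored, fixed["k2"], fixed["k3"], fixed["p_gly0"])
        sd = np.nan
    rows = [
        {"condition": exp.name, "parameter": "k1", "estimate": fit.k1,
         "sd": sd, "n_points": fit.n_points, "method": fit.method,
         "seed": seed},
        {"condition": exp.name, "parameter": "k3",
         "estimate": k3, "sd": k3_sd,
         "n_points": sum(f.n_points for f in k3_fits),
         "method": "log_linear_ols", "seed": seed},
        {"condition": exp.name, "parameter": "k2",
         "estimate": k2, "sd": k2_sd,
         "n_points": sum(f.n_points for f in k2_fits),
         "method": "log_linear_ols", "seed": seed},
    ]
    return rows, []


def report_folds(
    rate_table: pd.DataFrame,
    pairs: Sequence[tuple[str, str]],
) -> pd.DataFrame:
    """Fold changes between condition pairs with delta-method uncertainty.

    For each (numerator, denominator) pair the primary rate of each
    condition is used (k1 if fitted, else k_obs); the fold sd assumes
    independent estimates: sd(f) = f * sqrt((sa/a)^2 + (sb/b)^2).
    """
    def primary(condition: str) -> tuple[float, float, str]:
        rows = rate_table[rate_table["condition"] == condition]
        if rows.empty:
            raise ConfigurationError(
                f"condition {condition!r} not present in the rate table"
            )
        for parameter in ("k1", "k_obs", "k3", "k2"):
            sel = rows[rows["parameter"] == parameter]
            if not sel.empty:
                row = sel.iloc[0]
                sd = float(row["sd"]) if math.isfinite(row["sd"]) else 0.0
                return float(row["estimate"]), sd, parameter
        raise ConfigurationError(
            f"condition {condition!r} has no rate parameter"
        )

    out = []
    for num, den in pairs:
        a, sa, pa = primary(num)
        b, sb, pb = primary(den)
        if b <= 0:
            raise ConfigurationError(
                f"fold denominator {den!r} has non-positive estimate {b!r}"
            )
        fold = a / b
        rel = 0.0
        if a != 0:
            rel = (sa / a) ** 2
        rel += (sb / b) ** 2
        out.append({
            "numerator": num, "denominator": den,
            "numerator_parameter": pa, "denominator_parameter": pb,
            "fold": fold, "sd": abs(fold) * math.sqrt(rel),
        })
    return pd.DataFrame(
        out, columns=["numerator", "denominator", "numerator_parameter",
                      "denominator_parameter", "fold", "sd"]
    )


def run(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Execute a full run; returns the results bundle.

    The bundle maps ``rates``, ``half_lives`` and ``folds`` to data frames
    and ``errors`` to a list of (experiment, message) for experiments that
    failed; all tables are also written to the output directory.
    """
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("glykin")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        logger.info("run seed=%d, %d experiment(s)",
                    config.seed, len(config.experiments))
        children = np.random.SeedSequence(config.seed).spawn(
            len(config.experiments)
        )
        rate_rows: list[dict] = []
        half_rows: list[dict] = []
        errors: list[tuple[str, str]] = []
        for exp, child in zip(config.experiments, children):
            exp_seed = int(child.generate_state(1)[0] % (2 ** 31))
            try:
                rates, halves = _fit_experiment(exp, exp_seed, out)
                rate_rows.extend(rates)
                half_rows.extend(halves)
            except GlykinError as exc:
                logger.error("experiment %s failed: %s", exp.name, exc)
                errors.append((exp.name, str(exc)))
        rate_table = pd.DataFrame(
            rate_rows,
            columns=["condition", "parameter", "estimate", "sd", "n_points",
                     "method", "seed"],
        )
        half_table = pd.DataFrame(half_rows)
        folds = (
            report_folds(rate_table, config.fold_pairs)
            if config.fold_pairs else pd.DataFrame(
                columns=["numerator", "denominator", "numerator_parameter",
                         "denominator_parameter", "fold", "sd"]
            )
        )
        rate_table.to_csv(out / "rate_constants.csv", index=False)
        half_table.to_csv(out / "half_lives.csv", index=False)
        folds.to_csv(out / "folds.csv", index=False)
        logger.info("wrote %d rate row(s), %d half-life row(s), "
                    "%d fold row(s)", len(rate_table), len(half_table),
                    len(folds))
        return {
            "rates": rate_table,
            "half_lives": half_table,
            "folds": folds,
            "errors": errors,
            "out_dir": out,
        }
    finally:
        root.removeHandler(handler)
        handler.close()


def simulate_only(config: RunConfig, out_dir: str | Path | None = None) -> list[Path]:
    """Generate and write every synthetic experiment's band tables and
    manifests without fitting (the CLI ``simulate`` verb)."""
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    children = np.random.SeedSequence(config.seed).spawn(
        len(config.experiments)
    )
    written: list[Path] = []
    for exp, child in zip(config.experiments, children):
        if exp.synthetic is None:
            continue
        exp_seed = int(child.generate_state(1)[0] % (2 ** 31))
        design = _design_from_spec(exp, exp_seed)
        if design.experiment_type == "ligation":
            amino, control, hydrolysis, manifest = gen_ligation_experiment(
                design
            )
            parts = {
                "amino": amino, "control": control, "hydrolysis": hydrolysis,
            }
            for tag, table in parts.items():
                path = out / f"{exp.name}_{tag}.csv"
                table.to_csv(path, index=False)
                written.append(path)
        else:
            if design.experiment_type == "hydrolysis_acidic":
                table, manifest = gen_hydrolysis_experiment(design)
            else:
                table, manifest = gen_extension_experiment(design)
            path = out / f"{exp.name}.csv"
            table.to_csv(path, index=False)
            written.append(path)
        manifest_path = out / f"{exp.name}_manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        written.append(manifest_path)
    return written
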