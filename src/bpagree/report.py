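"""End-to-end validation pipeline: simulate/load -> pair -> analyse -> report.

:func:`run_validation` executes every analysis stage for the systolic
and diastolic channels and assembles a single JSON-serialisable report
plus tidy TSV plot-data files.  All randomness (simulation, bootstrap)
flows from one master seed, so re-running with an identical config
reproduces the report byte-for-byte.  Stage failures are collected into
the report per variable; only configuration errors are fatal.
"""

from __future__ import annotations

import dataclasses
import json
import math
from importlib import metadata as _metadata
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bland_altman as ba
from . import classification as cls
from . import variability as bpv
from .core_data import CohortData, pair_measurements, read_measurements, write_measurements
from .synthetic_data import DeviceProfile, SimConfig, simulate_cohort, write_ground_truth
from .taffe import TaffeEstimator

SCHEMA_VERSION = 1

try:
    __version__ = _metadata.version("bpagree")
except _metadata.PackageNotFoundError:  # pragma: no cover
    __version__ = "unknown"

_CONFIG_KEYS = {
    "input_csv",
    "simulate",
    "device",
    "pairing_tolerance_s",
    "n_boot",
    "cutoff_sbp",
    "cutoff_dbp",
    "ppv_grid_sbp",
    "ppv_grid_dbp",
    "roc_grid_step",
    "variables",
    "seed",
}


@dataclasses.dataclass
class ReportConfig:
    """Validated pipeline configuration (one data source: CSV or simulation)."""

    input_csv: str | None = None
    sim: SimConfig | None = None
    device: DeviceProfile | None = None
    pairing_tolerance_s: float = 600.0
    n_boot: int = 500
    cutoff_sbp: float = 135.0
    cutoff_dbp: float = 85.0
    ppv_grid_sbp: tuple[float, float] = (125.0, 146.0)
    ppv_grid_dbp: tuple[float, float] = (75.0, 96.0)
    roc_grid_step: float = 0.1
    variables: tuple[str, ...] = ("sbp", "dbp")
    seed: int | None = None

    def __post_init__(self):
        if (self.input_csv is None) == (self.sim is None):
            raise ValueError(
                "configure exactly one data source: 'input_csv' or 'simulate'"
            )
        bad = set(self.variables) - {"sbp", "dbp"}
        if bad:
            raise ValueError(f"unknown variables: {sorted(bad)}")


def load_config(path) -> ReportConfig:
    """Read a YAML config; unknown keys are fatal (no silent typos)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config file must contain a mapping")
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    sim = None
    if "simulate" in raw:
        block = raw.pop("simulate") or {}
        try:
            sim = SimConfig(**block)
        except TypeError as exc:
            raise ValueError(f"bad 'simulate' block: {exc}") from None
    device = None
    if "device" in raw:
        block = raw.pop("device") or {}
        base = dataclasses.asdict(DeviceProfile.anchored_smartwatch())
        unknown = set(block) - set(base)
        if unknown:
            raise ValueError(f"unknown device keys: {sorted(unknown)}")
        base.update(block)
        device = DeviceProfile(**base)
    for key in ("ppv_grid_sbp", "ppv_grid_dbp"):
        if key in raw:
            raw[key] = tuple(raw[key])
    if "variables" in raw:
        raw["variables"] = tuple(raw["variables"])
    return ReportConfig(sim=sim, device=device, **raw)


def _jsonable(obj):
    """Recursively convert numpy scalars and NaN for strict JSON output."""
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.bool_, bool)):  # before int: bool is an int subclass
        return bool(obj)
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if math.isnan(f) or math.isinf(f) else f
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    return obj


def _taffe_section(est: TaffeEstimator) -> dict:
    fit = est.bias_fit_
    prec = est.precision_fit_
    return {
        "mu": est.mu_,
        "tau2": est.tau2_,
        "sigma1_2": est.sigma1_2_,
        "alpha": est.alpha_,
        "alpha_ci": list(est.alpha_ci_),
        "beta": est.beta_,
        "beta_ci": list(est.beta_ci_),
        "n_test": fit.n_test,
        "blup_range": list(fit.blup_range),
        "zero_bias_point": fit.zero_bias_point,
        "precision_coef": {k: list(v) for k, v in prec.coef.items()},
    }


def _ba_section(pairs: pd.DataFrame, variable: str) -> dict:
    classic = ba.classic_ba(pairs, variable)
    out = {
        "classic": dataclasses.asdict(classic),
        "iso": dataclasses.asdict(
            ba.iso_criterion_check(classic.mean_diff, classic.sd_diff)
        ),
    }
    try:
        out["log"] = dataclasses.asdict(ba.log_ba(pairs, variable))
    except ValueError as exc:
        out["log"] = {"error": str(exc)}
    try:
        out["regression"] = dataclasses.asdict(ba.regression_ba(pairs, variable))
    except ValueError as exc:
        out["regression"] = {"error": str(exc)}
    return out


def _classification_section(cohort: CohortData, variable: str, cfg: ReportConfig) -> dict:
    cutoff = cfg.cutoff_sbp if variable == "sbp" else cfg.cutoff_dbp
    mode = "systolic" if variable == "sbp" else "diastolic"
    cm, metrics = cls.screen_cohort(cohort, mode, cfg.cutoff_sbp, cfg.cutoff_dbp)
    scores, truth = cls.daytime_scores(cohort, variable)
    out = {
        "cutoff": cutoff,
        "confusion": dataclasses.asdict(cm),
        "metrics": dataclasses.asdict(metrics),
    }
    grid = cfg.ppv_grid_sbp if variable == "sbp" else cfg.ppv_grid_dbp
    try:
        roc = cls.roc_curve(scores, truth, cfg.roc_grid_step)
        out["roc"] = {
            "auc": roc.auc,
            "youden_j": roc.youden_j,
            "youden_cutoff": roc.youden_cutoff,
            "youden_threshold": roc.youden_threshold,
            "n_pos": roc.n_pos,
            "n_neg": roc.n_neg,
        }
        curve = cls.ppv_npv_curve(scores, truth, grid[0], grid[1])
        out["ppv_npv"] = {
            "optimal_cutoff": curve.optimal_cutoff,
            "optimal_ppv": curve.optimal_ppv,
            "optimal_npv": curve.optimal_npv,
            "best_ppv_cutoff": curve.best_ppv_cutoff,
            "best_npv_cutoff": curve.best_npv_cutoff,
        }
    except ValueError as exc:
        out["roc"] = {"error": str(exc)}
        out["ppv_npv"] = {"error": str(exc)}
    return out


def run_validation(
    config: ReportConfig,
    out_dir=None,
    echo=None,
) -> dict:
    """Run the full validation pipeline and return the report dict.

    With ``out_dir`` set, writes ``report.json`` and the TSV plot-data
    files (and, for simulated input, the measurement CSV plus
    ground-truth sidecar).  ``echo`` is an optional callable receiving
    one log line per stage.
    """
    log = echo or (lambda msg: None)
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    seed = config.seed
    truth = None
    if config.sim is not None:
        sim_cfg = config.sim if seed is None else dataclasses.replace(config.sim, seed=seed)
        seed = sim_cfg.seed
        cohort, truth = simulate_cohort(sim_cfg, profile_test=config.device)
        source = {"simulate": dataclasses.asdict(sim_cfg)}
        if config.device is not None:
            source["device"] = dataclasses.asdict(config.device)
        log(f"simulated cohort: {len(cohort)} readings, {len(cohort.patients)} patients")
    else:
        cohort = read_measurements(config.input_csv)
        seed = 0 if seed is None else seed
        source = {"input_csv": str(config.input_csv)}
        log(f"loaded cohort: {len(cohort)} readings, {len(cohort.patients)} patients")

    pairing = pair_measurements(cohort, config.pairing_tolerance_s)
    log(f"paired {pairing.n_pairs} of {pairing.n_test_total} test readings")

    report: dict = {
        "schema_version": SCHEMA_VERSION,
        "package": {"name": "bpagree", "version": __version__},
        "provenance": {
            "source": source,
            "seed": seed,
            "pairing_tolerance_s": config.pairing_tolerance_s,
            "n_boot": config.n_boot,
        },
        "load_report": (
            {
                **dataclasses.asdict(cohort.load_report),
                "rows_dropped": cohort.load_report.rows_dropped,
            }
            if cohort.load_report
            else None
        ),
        "pairing": {
            "n_pairs": pairing.n_pairs,
            "n_unpaired_test": pairing.n_unpaired_test,
            "n_test_total": pairing.n_test_total,
        },
    }

    estimators: dict[str, TaffeEstimator] = {}
    for variable in config.variables:
        section: dict = {}
        try:
            est = TaffeEstimator(
                variable=variable, n_boot=config.n_boot, random_state=seed
            ).fit(cohort)
            estimators[variable] = est
            section["taffe"] = _taffe_section(est)
            log(f"{variable}: taffe alpha={est.alpha_:.2f} beta={est.beta_:.3f}")
        except Exception as exc:
            section["taffe"] = {"error": str(exc)}
            log(f"{variable}: taffe failed ({exc})")
        try:
            section["bland_altman"] = _ba_section(pairing.pairs, variable)
        except Exception as exc:
            section["bland_altman"] = {"error": str(exc)}
        try:
            section["classification"] = _classification_section(cohort, variable, config)
        except Exception as exc:
            section["classification"] = {"error": str(exc)}
        report[variable] = section

    try:
        cm, metrics = cls.screen_cohort(
            cohort, "either", config.cutoff_sbp, config.cutoff_dbp
        )
        report["classification_either"] = {
            "confusion": dataclasses.asdict(cm),
            "metrics": dataclasses.asdict(metrics),
        }
    except Exception as exc:
        report["classification_either"] = {"error": str(exc)}

    try:
        table = bpv.cohort_variability_table(cohort)
        report["variability"] = table.to_dict(orient="records")
    except Exception as exc:
        report["variability"] = {"error": str(exc)}

    try:
        pp = bpv.pulse_pressure_stats(cohort)
        report["pulse_pressure"] = {
            "cohort_mean": pp.cohort_mean,
            "paired_test": dataclasses.asdict(pp.ttest),
        }
    except Exception as exc:
        report["pulse_pressure"] = {"error": str(exc)}

    report = _jsonable(report)

    if out is not None:
        (out / "report.json").write_text(
            json.dumps(report, sort_keys=True, indent=2) + "\n"
        )
        if truth is not None:
            write_measurements(cohort, out / "measurements.csv")
            write_ground_truth(truth, out / "ground_truth.csv")
        for variable, est in estimators.items():
            est.bias_table().to_csv(
                out / f"taffe_bias_{variable}.tsv", sep="\t", index=False
            )
            est.precision_table().to_csv(
                out / f"taffe_precision_{variable}.tsv", sep="\t", index=False
            )
        for variable in config.variables:
            try:
                ba.ba_plot_data(pairing.pairs, variable).to_csv(
                    out / f"ba_panel_{variable}.tsv", sep="\t", index=False
                )
            except ValueError:
                pass
            try:
                scores, truth_labels = cls.daytime_scores(cohort, variable)
                roc = cls.roc_curve(scores, truth_labels, config.roc_grid_step)
                pd.DataFrame(
                    {"threshold": roc.thresholds, "se": roc.se, "sp": roc.sp}
                ).to_csv(out / f"roc_{variable}.tsv", sep="\t", index=False)
                grid = config.ppv_grid_sbp if variable == "sbp" else config.ppv_grid_dbp
                curve = cls.ppv_npv_curve(scores, truth_labels, grid[0], grid[1])
                pd.DataFrame(
                    {"cutoff": curve.grid, "ppv": curve.ppv, "npv": curve.npv}
                ).to_csv(out / f"ppv_npv_{variable}.tsv", sep="\t", index=False)
            except ValueError:
                pass
        bpv.patient_variability(cohort).to_csv(
            out / "variability_patient.tsv", sep="\t", index=False
        )
        log(f"report written to {out / 'report.json'}")

    return report
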