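"""Requirement tables, reference comparisons, boxplot statistics and the
end-to-end pipeline.

Bundles the breeder-guideline and literature peak-intake reference
constants used for percent-change comparisons, the notched-boxplot
summary statistics (notch = median +/- 1.57*IQR/sqrt(n), an approximate
95% CI for the median; mean CI by seeded percentile bootstrap), and
``run_pipeline``, which chains data generation/ingest, filtering, phase
stratification, baseline and tanh fits, requirement estimation, bootstrap
inference and phase comparison into a reproducible output directory.
"""

from __future__ import annotations

import hashlib
import itertools
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .baseline import compare_linear_quadratic
from .bootstrap import (
    BootstrapDistribution,
    bootstrap_requirement,
    compare_phases,
    letter_display,
)
from .exceptions import SampleSizeError, ValidationError
from .neuron import FitConfig, fit_tanh_neuron
from .records import (
    NUTRIENT_UNITS,
    NUTRIENTS,
    PHASE_ORDER,
    RangeFilterConfig,
    complete_cases,
    compute_intakes,
    filter_records,
    read_records,
    stratify_by_phase,
)
from .requirement import RequirementEstimate, requirement_at_fraction
from .synthetic import generate_phase_dataset, scenario_by_name


def reference_table() -> pd.DataFrame:
    """Bundled reference constants for percent-change comparisons.

    ``ross308`` rows are the Ross 308 parent-stock guideline intakes at
    peak production; ``literature`` rows are previously reported optimal
    peak-lay intakes for the digestible amino acids.
    """
    rows = [
        ("ross308", "me", "mid", 468.0, "kcal/d"),
        ("ross308", "dlys", "mid", 1.036, "g/d"),
        ("ross308", "dmet", "mid", 0.635, "g/d"),
        ("ross308", "dthr", "mid", 0.919, "g/d"),
        ("literature", "dlys", "mid", 0.916, "g/d"),
        ("literature", "dmet", "mid", 0.424, "g/d"),
        ("literature", "dthr", "mid", 0.613, "g/d"),
    ]
    return pd.DataFrame(rows, columns=["source", "nutrient", "phase", "value", "units"])


def percent_change(value: float, reference: float, ndigits: int | None = 1) -> float:
    """100 * (value - reference) / reference, rounded to ``ndigits``."""
    if reference <= 0:
        raise ValidationError("reference must be positive")
    pct = 100.0 * (value - reference) / reference
    return pct if ndigits is None else round(pct, ndigits)


@dataclass
class BoxplotStats:
    median: float
    q1: float
    q3: float
    whisker_lo: float
    whisker_hi: float
    notch_lo: float
    notch_hi: float
    mean: float
    mean_ci: tuple[float, float]
    n: int


def boxplot_stats(samples, mean_ci_boot: int = 1000, seed: int = 0,
                  level: float = 0.95) -> BoxplotStats:
    """Notched-boxplot summary of a sample (e.g. bootstrap replicates).

    Quartiles by linear interpolation; whiskers at the most extreme data
    within 1.5*IQR of the quartiles; notch = median +/- 1.57*IQR/sqrt(n);
    mean CI by seeded percentile bootstrap of the mean.
    """
    s = np.sort(np.asarray(samples, dtype=float))
    n = s.size
    if n < 5:
        raise SampleSizeError(f"need >= 5 samples, got {n}")
    q1, med, q3 = np.quantile(s, [0.25, 0.5, 0.75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    whisk_lo = float(s[s >= lo_fence][0])
    whisk_hi = float(s[s <= hi_fence][-1])
    notch = 1.57 * iqr / np.sqrt(n)
    rng = np.random.default_rng(seed)
    boot_means = rng.choice(s, size=(mean_ci_boot, n), replace=True).mean(axis=1)
    ci = tuple(
        float(v) for v in np.quantile(boot_means, [(1 - level) / 2, (1 + level) / 2])
    )
    return BoxplotStats(
        median=float(med), q1=float(q1), q3=float(q3),
        whisker_lo=whisk_lo, whisker_hi=whisk_hi,
        notch_lo=float(med - notch), notch_hi=float(med + notch),
        mean=float(s.mean()), mean_ci=ci, n=n,
    )


def requirement_table(
    estimates: dict[tuple[str, str], RequirementEstimate],
    boots: dict[tuple[str, str], BootstrapDistribution],
    letters: dict[str, dict[str, str]],
    nutrients=NUTRIENTS,
    phases=PHASE_ORDER,
) -> pd.DataFrame:
    """One row per nutrient x phase: requirement, bootstrap CI, letter.

    Missing combinations appear as rows of NaN/empty, never as failures.
    """
    rows = []
    for nutrient in nutrients:
        for phase in phases:
            key = (nutrient, phase)
            est = estimates.get(key)
            boot = boots.get(key)
            ci = boot.ci if boot is not None and boot.ci else (np.nan, np.nan)
            rows.append({
                "nutrient": nutrient,
                "phase": phase,
                "units": NUTRIENT_UNITS.get(nutrient, ""),
                "req": est.req if est is not None and est.valid else np.nan,
                "ci_lo": ci[0],
                "ci_hi": ci[1],
                "letter": letters.get(nutrient, {}).get(phase, ""),
            })
    return pd.DataFrame(rows)


def _display_round(nutrient: str, value: float) -> float:
    """Presentation rounding: kcal/d to 1 decimal, g/d to 2 decimals."""
    if not np.isfinite(value):
        return value
    return round(value, 1 if nutrient == "me" else 2)


def _json_default(obj):
    if isinstance(obj, np.generic):
        return obj.item()
    return str(obj)


def _config_hash(config: dict) -> str:
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _dataset_seed(base_seed: int, nutrient: str, phase: str) -> int:
    tag = int.from_bytes(hashlib.sha256(f"{nutrient}:{phase}".encode()).digest()[:4])
    return int(np.random.SeedSequence([base_seed, tag]).generate_state(1)[0] % 2**31)


DEFAULT_CONFIG: dict = {
    "data": {"mode": "synthetic"},
    "filters": {"enabled": False},
    "nutrients": list(NUTRIENTS),
    "phases": list(PHASE_ORDER),
    "fit": {"n_restarts": 10, "max_iter": 300, "tol": 1e-9},
    "bootstrap": {"n_boot": 100, "ci_level": 0.95, "p": 0.95,
                  "replicate_restarts": 1},
    "report": {},
    "seed": 0,
}


def _merged_config(config: dict | None) -> dict:
    cfg = {k: (dict(v) if isinstance(v, dict) else v)
           for k, v in DEFAULT_CONFIG.items()}
    for k, v in (config or {}).items():
        if isinstance(v, dict) and isinstance(cfg.get(k), dict):
            cfg[k].update(v)
        else:
            cfg[k] = v
    return cfg


def _collect_datasets(cfg: dict) -> dict[tuple[str, str], tuple[np.ndarray, np.ndarray]]:
    """(nutrient, phase) -> complete-case (intake, response) arrays."""
    data_cfg = cfg["data"]
    seed = int(cfg["seed"])
    datasets: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
    if data_cfg.get("mode", "synthetic") == "synthetic":
        for nutrient in cfg["nutrients"]:
            for phase in cfg["phases"]:
                spec = scenario_by_name(f"{nutrient}-{phase}")
                records = generate_phase_dataset(
                    spec, seed=_dataset_seed(seed, nutrient, phase)
                )
                if cfg["filters"].get("enabled"):
                    fconf = _filter_config(cfg["filters"])
                    records, _ = filter_records(records, fconf)
                datasets[(nutrient, phase)] = complete_cases(records, nutrient)
    else:
        records = read_records(data_cfg["path"], data_cfg.get("schema", "intakes"))
        if data_cfg.get("schema") == "composition":
            records = [compute_intakes(r) for r in records]
        if cfg["filters"].get("enabled", True):
            fconf = _filter_config(cfg["filters"])
            records, _ = filter_records(records, fconf)
        by_phase = stratify_by_phase(records)
        for nutrient in cfg["nutrients"]:
            for phase in cfg["phases"]:
                datasets[(nutrient, phase)] = complete_cases(by_phase[phase], nutrient)
    return datasets


def _filter_config(filters: dict) -> RangeFilterConfig:
    kwargs = {}
    if "bounds" in filters:
        kwargs["bounds"] = {k: tuple(v) for k, v in filters["bounds"].items()}
    for key in ("iqr_multiplier", "iqr_reject"):
        if key in filters:
            kwargs[key] = filters[key]
    if "iqr_variables" in filters:
        kwargs["iqr_variables"] = tuple(filters["iqr_variables"])
    if "required_fields" in filters:
        kwargs["required_fields"] = tuple(filters["required_fields"])
    return RangeFilterConfig(**kwargs)


def run_pipeline(config: dict | None, out_dir) -> Path:
    """Run the full analysis and write its artifacts to ``out_dir``.

    Stages: simulate/ingest -> filter -> phase split -> baseline fits ->
    tanh fits -> requirements -> bootstrap -> phase comparisons -> report.
    Outputs are a pure function of (input data, config, seed); every file
    carries the config hash and seed in the run log.
    """
    cfg = _merged_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    fit_cfg = FitConfig(
        n_restarts=int(cfg["fit"].get("n_restarts", 10)),
        max_iter=int(cfg["fit"].get("max_iter", 300)),
        tol=float(cfg["fit"].get("tol", 1e-9)),
    )
    bcfg = cfg["bootstrap"]

    datasets = _collect_datasets(cfg)
    estimates: dict[tuple[str, str], RequirementEstimate] = {}
    boots: dict[tuple[str, str], BootstrapDistribution] = {}
    fit_reports: dict[str, dict] = {}

    for (nutrient, phase), (x, y) in sorted(datasets.items()):
        if x.size < 5:
            continue
        stage = f"{nutrient}-{phase}"
        try:
            ds_seed = _dataset_seed(seed, nutrient, phase)
            from dataclasses import replace as _replace
            fit = fit_tanh_neuron(x, y, _replace(fit_cfg, seed=ds_seed))
            baseline = compare_linear_quadratic(x, y)
            est = requirement_at_fraction(fit.params, float(bcfg.get("p", 0.95)))
            boot = bootstrap_requirement(
                x, y, _replace(fit_cfg, seed=ds_seed),
                n_boot=int(bcfg.get("n_boot", 100)),
                p=float(bcfg.get("p", 0.95)),
                ci_level=float(bcfg.get("ci_level", 0.95)),
                seed=ds_seed,
                replicate_restarts=int(bcfg.get("replicate_restarts", 1)),
                label=f"req{int(100 * float(bcfg.get('p', 0.95)))}:{stage}",
            )
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
        estimates[(nutrient, phase)] = est
        boots[(nutrient, phase)] = boot
        fit_reports[stage] = {
            "n": fit.n,
            "params": asdict(fit.params),
            "rmse": fit.rmse,
            "alpha": fit.alpha,
            "beta": fit.beta,
            "gamma": fit.gamma,
            "converged": fit.converged,
            "seed": ds_seed,
            "baseline": {
                "r": baseline.linear.r,
                "rmse_linear": baseline.rmse_linear,
                "rmse_quadratic": baseline.rmse_quadratic,
                "quadratic_term_p": baseline.quadratic_term_p,
                "improved": baseline.improved,
            },
            "requirement": {
                "p": est.p,
                "req": est.req,
                "asymptote": est.asymptote,
                "valid": est.valid,
                "reason": est.invalid_reason,
            },
            "bootstrap": {
                "n_requested": boot.n_requested,
                "n_failed": boot.n_failed,
                "ci": boot.ci,
                "point_estimate": boot.point_estimate,
            },
        }

    comparisons: dict[str, dict] = {}
    letters: dict[str, dict[str, str]] = {}
    for nutrient in cfg["nutrients"]:
        present = [ph for ph in cfg["phases"] if (nutrient, ph) in boots]
        pair_results = []
        for a, b in itertools.combinations(present, 2):
            pair_results.append(compare_phases(boots[(nutrient, a)], boots[(nutrient, b)]))
        if len(present) >= 2:
            points = {ph: boots[(nutrient, ph)].point_estimate for ph in present}
            relabeled = []
            for comp, (a, b) in zip(pair_results, itertools.combinations(present, 2)):
                comp.pair = (a, b)
                relabeled.append(comp)
            letters[nutrient] = letter_display(relabeled, points)
            comparisons[nutrient] = {
                f"{a}_vs_{b}": {"p_value": c.p_value, "significant": c.significant,
                                "estimate_diff": c.estimate_diff}
                for (a, b), c in zip(itertools.combinations(present, 2), relabeled)
            }

    table = requirement_table(estimates, boots, letters,
                              nutrients=cfg["nutrients"], phases=cfg["phases"])
    table["req_display"] = [
        _display_round(nut, val) for nut, val in zip(table["nutrient"], table["req"])
    ]
    table.to_csv(out / "requirement_table.csv", index=False)
    with open(out / "fits.json", "w") as fh:
        json.dump(fit_reports, fh, indent=2, sort_keys=True, default=_json_default)
    with open(out / "comparisons.json", "w") as fh:
        json.dump({"pairwise": comparisons, "letters": letters}, fh,
                  indent=2, sort_keys=True, default=_json_default)
    with open(out / "run_log.json", "w") as fh:
        json.dump(
            {"seed": seed, "config_hash": _config_hash(cfg),
             "config": cfg, "version": __version__},
            fh, indent=2, sort_keys=True, default=_json_default,
        )
    return out
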