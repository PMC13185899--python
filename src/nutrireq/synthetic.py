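"""Synthetic flock-week data with the structure the analysis assumes.

The generator draws nutrient intakes uniformly over a design range, places
the mean response on a tanh curve, adds homoscedastic Gaussian noise, and
assigns hen ages uniformly within the production phase — the data-generating
process under which the downstream fitting, requirement estimation and
bootstrap machinery are exercised and validated without the proprietary
field dataset.

`study_scenarios` provides twelve presets (4 nutrients x 3 phases) whose
true Req95 equals the published point estimates from the commercial
Ross 308 flock study, with phase sample sizes and noise SDs taken from the
published model RMSEs; curve ceilings and design geometry are assumed
defaults stored in `scenario_defaults.yaml`.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, replace

import numpy as np
import yaml

from .exceptions import ValidationError
from .neuron import TanhParams
from .records import PHASE_BOUNDS, NUTRIENTS, FlockWeekRecord
from .requirement import requirement_at_fraction


@dataclass(frozen=True)
class ScenarioSpec:
    """One simulated phase: design range, true curve, noise and size."""

    name: str
    phase: str
    nutrient: str
    n: int
    intake_range: tuple[float, float]
    true_params: TanhParams
    noise_sd: float
    seed: int | None = None

    def __post_init__(self) -> None:
        lo, hi = self.intake_range
        if not lo < hi:
            raise ValidationError("intake_range: lower must be < upper")
        if self.n < 4:
            raise ValidationError("n must be >= 4")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.phase not in PHASE_BOUNDS:
            raise ValidationError(f"unknown phase {self.phase!r}")
        if self.nutrient not in NUTRIENTS:
            raise ValidationError(f"unknown nutrient {self.nutrient!r}")

    @property
    def true_req95(self) -> float:
        return requirement_at_fraction(self.true_params, 0.95).req


def solve_params_for_requirement(
    req95: float,
    asymptote: float,
    lower_plateau: float,
    x_mid: float,
    p: float = 0.95,
) -> TanhParams:
    """Invert the requirement formula: build a curve with a chosen Req_p.

    Given the upper asymptote S, lower plateau L and the intake x_mid at
    which the curve crosses its midpoint (S+L)/2, returns the unique
    increasing tanh curve whose requirement at fraction ``p`` equals
    ``req95``: A = (S-L)/2, B = (S+L)/2, c = arctanh((p*S - B)/A) /
    (req95 - x_mid), b = -c * x_mid.
    """
    if not lower_plateau < asymptote:
        raise ValidationError("lower_plateau must be < asymptote")
    if not x_mid < req95:
        raise ValidationError("x_mid must be below the requirement")
    A = (asymptote - lower_plateau) / 2.0
    B = (asymptote + lower_plateau) / 2.0
    arg = (p * asymptote - B) / A
    if not abs(arg) < 1.0:
        raise ValidationError(
            f"target fraction unreachable: |(p*S - B)/A| = {abs(arg):.3f} >= 1"
        )
    c = float(np.arctanh(arg)) / (req95 - x_mid)
    return TanhParams(A=A, b=-c * x_mid, c=c, B=B)


def generate_phase_dataset(
    spec: ScenarioSpec, seed: int | None = None
) -> list[FlockWeekRecord]:
    """Draw one synthetic dataset for a scenario; deterministic given seed."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    lo, hi = spec.intake_range
    x = rng.uniform(lo, hi, size=spec.n)
    mean = spec.true_params.predict(x)
    y = mean + rng.normal(0.0, spec.noise_sd, size=spec.n)
    y = np.clip(y, 0.0, None)  # chick output cannot be negative
    age_lo, age_hi = PHASE_BOUNDS[spec.phase]
    ages = rng.integers(age_lo, age_hi + 1, size=spec.n)
    intake_field = f"{spec.nutrient}_intake"
    records = []
    for i in range(spec.n):
        records.append(
            FlockWeekRecord(
                flock_id=f"sim-{spec.name}-{i:05d}",
                age_weeks=int(ages[i]),
                chicks_per_hen_week=float(y[i]),
                **{intake_field: float(x[i])},
            )
        )
    return records


def _load_defaults() -> dict:
    ref = importlib.resources.files("nutrireq") / "scenario_defaults.yaml"
    return yaml.safe_load(ref.read_text())


def study_scenarios(defaults: dict | None = None) -> list[ScenarioSpec]:
    """The 12 presets (4 nutrients x 3 phases) emulating the field study.

    True Req95 per preset equals the published point estimate; sample
    sizes and noise SDs follow the published per-phase values; curve
    ceilings and design ranges come from the assumed defaults file.
    """
    cfg = defaults or _load_defaults()
    geom = cfg["geometry"]
    specs: list[ScenarioSpec] = []
    for nutrient, tbl in cfg["targets"].items():
        for phase, pcfg in cfg["phases"].items():
            req = float(tbl["req95"][phase])
            params = solve_params_for_requirement(
                req95=req,
                asymptote=float(pcfg["asymptote"]),
                lower_plateau=float(pcfg["plateau"]),
                x_mid=geom["x_mid_frac"] * req,
            )
            specs.append(
                ScenarioSpec(
                    name=f"{nutrient}-{phase}",
                    phase=phase,
                    nutrient=nutrient,
                    n=int(pcfg["n"]),
                    intake_range=(geom["x_lo_frac"] * req, geom["x_hi_frac"] * req),
                    true_params=params,
                    noise_sd=float(tbl["noise_sd"][phase]),
                )
            )
    return specs


def scenario_by_name(name: str) -> ScenarioSpec:
    """Look up a preset by its ``<nutrient>-<phase>`` name."""
    for spec in study_scenarios():
        if spec.name == name:
            return spec
    raise ValidationError(f"unknown scenario {name!r}")


def with_noise(spec: ScenarioSpec, noise_sd: float) -> ScenarioSpec:
    """A copy of a scenario with a different noise SD (e.g. 0 for closure tests)."""
    return replace(spec, noise_sd=noise_sd)
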