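"""Nonparametric bootstrap inference for nutrient requirements.

Case-resampling bootstrap: each replicate resamples flock-week records
with replacement, refits the tanh neuron (warm-started from the
full-data solution), and recomputes Req_p.  Percentile confidence
intervals come from the replicate quantiles; phase comparisons pair
replicate streams by index and compute a two-sided resampling p-value
with the (count+1)/(R+1) correction, summarized across phases by a
compact letter display.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .exceptions import InferenceError, SampleSizeError
from .neuron import AffineScaler, FitConfig, fit_tanh_neuron, original_to_scaled
from .requirement import requirement_at_fraction


@dataclass
class BootstrapDistribution:
    """Replicate values of one statistic plus its percentile CI."""

    label: str
    replicates: np.ndarray          # valid replicates only
    n_requested: int
    n_failed: int
    point_estimate: float
    ci_level: float
    ci: tuple[float, float] | None  # None when < 20 valid replicates
    seed: int
    failed_subseeds: list[int]      # sub-seeds of failed replicates, for replay


def _percentile_ci(values: np.ndarray, level: float) -> tuple[float, float]:
    lo, hi = np.quantile(values, [(1.0 - level) / 2.0, (1.0 + level) / 2.0])
    return float(lo), float(hi)


def bootstrap_requirement(
    x,
    y,
    fit_config: FitConfig | None = None,
    n_boot: int = 100,
    p: float = 0.95,
    ci_level: float = 0.95,
    seed: int = 0,
    replicate_restarts: int = 1,
    label: str = "req",
    max_failure_rate: float = 0.5,
) -> BootstrapDistribution:
    """Bootstrap distribution of Req_p under case resampling.

    Replicate r draws its resample indices and fit seed from the r-th
    child of ``SeedSequence(seed)``, so runs are deterministic and each
    failed replicate can be replayed from its logged sub-seed.  Replicates
    whose refit fails or whose requirement is invalid (non-saturating
    refit) are dropped and counted, not imputed.
    """
    cfg = fit_config or FitConfig()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 5:
        raise SampleSizeError(f"need >= 5 records to bootstrap, got {x.size}")

    full = fit_tanh_neuron(x, y, cfg)
    point = requirement_at_fraction(full.params, p)
    point_value = point.req if point.valid else float("nan")

    rep_cfg = replace(cfg, n_restarts=replicate_restarts)
    children = np.random.SeedSequence(seed).spawn(n_boot)
    values: list[float] = []
    failed: list[int] = []
    for child in children:
        sub_seed = int(child.generate_state(1)[0] % 2**31)
        rng = np.random.default_rng(child)
        idx = rng.integers(0, x.size, size=x.size)
        xb, yb = x[idx], y[idx]
        try:
            warm = original_to_scaled(full.params, AffineScaler.from_data(xb, yb))
            fit_b = fit_tanh_neuron(
                xb, yb, replace(rep_cfg, seed=sub_seed),
                initial_scaled_params=warm,
            )
            est = requirement_at_fraction(fit_b.params, p)
            if not est.valid or not np.isfinite(est.req):
                raise InferenceError(est.invalid_reason or "invalid requirement")
            values.append(est.req)
        except Exception:
            failed.append(sub_seed)
    n_failed = len(failed)
    if n_failed > max_failure_rate * n_boot:
        raise InferenceError(
            f"{n_failed}/{n_boot} bootstrap replicates failed (sub-seeds {failed[:5]}...)"
        )
    reps = np.asarray(values)
    ci = _percentile_ci(reps, ci_level) if reps.size >= 20 else None
    return BootstrapDistribution(
        label=label,
        replicates=reps,
        n_requested=n_boot,
        n_failed=n_failed,
        point_estimate=point_value,
        ci_level=ci_level,
        ci=ci,
        seed=seed,
        failed_subseeds=failed,
    )


@dataclass
class PhaseComparison:
    pair: tuple[str, str]
    diff_replicates: np.ndarray
    estimate_diff: float
    p_value: float
    significant: bool
    alpha: float = 0.05


def compare_phases(
    dist_a: BootstrapDistribution,
    dist_b: BootstrapDistribution,
    alpha: float = 0.05,
) -> PhaseComparison:
    """Two-sided bootstrap test of a difference in requirements.

    Differences pair replicate i of a with replicate i of b (phases use
    disjoint data, so index pairing is a valid deterministic choice);
    p = min(1, 2*min(P(diff<=0), P(diff>=0))) with the (count+1)/(R+1)
    correction, so p is floored at 2/(R+1).
    """
    R = min(dist_a.replicates.size, dist_b.replicates.size)
    if R < 20:
        raise InferenceError(f"need >= 20 valid replicates per phase, got {R}")
    d = dist_a.replicates[:R] - dist_b.replicates[:R]
    p_le = (int(np.sum(d <= 0)) + 1) / (R + 1)
    p_ge = (int(np.sum(d >= 0)) + 1) / (R + 1)
    p = min(1.0, 2.0 * min(p_le, p_ge))
    return PhaseComparison(
        pair=(dist_a.label, dist_b.label),
        diff_replicates=d,
        estimate_diff=dist_a.point_estimate - dist_b.point_estimate,
        p_value=float(p),
        significant=p < alpha,
        alpha=alpha,
    )


def letter_display(
    comparisons: list[PhaseComparison],
    point_estimates: dict[str, float],
) -> dict[str, str]:
    """Compact letter display: groups sharing a letter do not differ.

    Insert-and-absorb algorithm; letters are assigned in descending order
    of point estimate so 'a' marks the highest requirement.
    """
    groups = sorted(point_estimates, key=lambda g: -point_estimates[g])
    letter_sets: list[set[str]] = [set(groups)]
    for comp in comparisons:
        if not comp.significant:
            continue
        a, b = comp.pair
        new_sets: list[set[str]] = []
        for s in letter_sets:
            if a in s and b in s:
                new_sets.extend([s - {a}, s - {b}])
            else:
                new_sets.append(s)
        # absorb sets contained in another
        letter_sets = [
            s for s in new_sets
            if s and not any(s < t for t in new_sets)
        ]
        # drop duplicates, preserving order
        seen: list[set[str]] = []
        for s in letter_sets:
            if s not in seen:
                seen.append(s)
        letter_sets = seen

    # order letters by the best (highest-estimate) member of each set
    letter_sets.sort(key=lambda s: min(groups.index(g) for g in s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in groups}
    for letter, s in zip(alphabet, letter_sets):
        for g in groups:
            if g in s:
                out[g] += letter
    return out
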