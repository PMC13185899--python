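"""Asymptotic response and closed-form nutrient requirements.

For the fitted curve Response = A*tanh(c*x + b) + B (canonical A > 0),
the asymptotic response is A + B — the predicted ceiling under unlimited
nutrient supply.  The requirement at fraction p (default 0.95) is the
intake at which the predicted response reaches p of that ceiling:

    Req_p = (arctanh((p*(A + B) - B) / A) - b) / c

which exists iff the curve is increasing (c > 0) and the target lies
strictly inside the response range, |(p*(A+B) - B)/A| < 1.  A bisection
oracle solving the same level equation numerically is provided for
independent verification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import OracleError, ValidationError
from .neuron import TanhParams


@dataclass(frozen=True)
class RequirementEstimate:
    """Requirement at a response fraction, with validity diagnostics."""

    p: float
    req: float                 # nutrient units; nan when invalid
    asymptote: float           # A + B, response units
    target_response: float     # p * (A + B)
    valid: bool
    invalid_reason: str = ""


def asymptotic_response(params: TanhParams) -> float:
    """Predicted response ceiling A + B (requires canonical A > 0)."""
    if params.A <= 0:
        raise ValidationError("asymptote is defined for canonical params (A > 0)")
    return params.A + params.B


def requirement_at_fraction(params: TanhParams, p: float = 0.95) -> RequirementEstimate:
    """Closed-form intake achieving fraction ``p`` of the asymptotic response."""
    if not 0.0 < p < 1.0:
        raise ValidationError(f"p must be in (0, 1), got {p}")
    if params.A <= 0:
        raise ValidationError("requirement is defined for canonical params (A > 0)")
    asym = params.A + params.B
    target = p * asym
    arg = (target - params.B) / params.A
    if params.c <= 0:
        return RequirementEstimate(p, float("nan"), asym, target, False,
                                   "non-increasing curve")
    if not abs(arg) < 1.0:
        return RequirementEstimate(p, float("nan"), asym, target, False,
                                   "target outside response range")
    req = (np.arctanh(arg) - params.b) / params.c
    return RequirementEstimate(p, float(req), asym, target, True)


def requirement_oracle(params: TanhParams, p: float = 0.95,
                       tol: float = 1e-10) -> float:
    """Bisection solve of A*tanh(c*x+b)+B = p*(A+B); test-time cross-check.

    Independent of the closed form: only forward tanh evaluations.
    """
    if not 0.0 < p < 1.0:
        raise ValidationError(f"p must be in (0, 1), got {p}")
    if params.A <= 0:
        raise ValidationError("oracle requires canonical params (A > 0)")
    asym = params.A + params.B
    target = p * asym
    arg = (target - params.B) / params.A
    if params.c <= 0 or not abs(arg) < 1.0:
        raise OracleError("no root: curve non-increasing or target unreachable")

    def f(xv: float) -> float:
        return params.A * np.tanh(params.c * xv + params.b) + params.B - target

    center = -params.b / params.c  # tanh argument zero; f(center) = B - target
    step = 1.0 / abs(params.c)
    lo, hi = center - step, center + step
    for _ in range(200):
        if f(lo) < 0:
            break
        lo -= step
        step *= 2.0
    else:
        raise OracleError("could not bracket below")
    step = 1.0 / abs(params.c)
    for _ in range(200):
        if f(hi) > 0:
            break
        hi += step
        step *= 2.0
    else:
        raise OracleError("could not bracket above")

    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if hi - lo <= tol * max(1.0, abs(mid)):
            break
        if f(mid) < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
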