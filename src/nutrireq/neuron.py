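"""Single-neuron tanh dose-response model with Bayesian regularization.

The mean response is modeled as

    Response = A * tanh(c * Nutrient + b) + B

a smooth, monotone (for A*c > 0), saturating curve whose asymptote A + B
is the physiological response ceiling.  The four parameters are estimated
by penalized least squares in min-max scaled space: both axes are mapped
to [-1, 1], the objective is F = beta * E_D + alpha * E_W with
E_D = 1/2 * sum(residual^2) and E_W = 1/2 * ||w||^2, the inner solve is
damped least squares (Levenberg-Marquardt on penalty-augmented residuals),
and the hyperparameters alpha, beta are re-estimated after each inner
solve by the evidence approximation (MacKay):

    gamma = 4 - alpha * tr(H^-1),   H = beta * J'J + alpha * I
    alpha = gamma / (2 * E_W),      beta  = (n - gamma) / (2 * E_D)

iterated to joint convergence.  gamma in [0, 4] is the effective number
of parameters; as noise vanishes alpha/beta -> 0 and the fit approaches
ordinary least squares.  Multi-start optimization with a seeded generator
handles local minima and the (A, b, c, B) <-> (-A, -b, -c, B) sign
symmetry; reported parameters are back-transformed analytically to
original units and canonicalized to A > 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

from .exceptions import (
    DegenerateDesignError,
    NonConvergenceError,
    SampleSizeError,
    ValidationError,
)

_BETA_CAP = 1e12
_ALPHA_CAP = 1e8


@dataclass(frozen=True)
class TanhParams:
    """Parameters of Response = A*tanh(c*x + b) + B, in original units."""

    A: float
    b: float
    c: float
    B: float

    def predict(self, x):
        x = np.asarray(x, dtype=float)
        return self.A * np.tanh(self.c * x + self.b) + self.B

    def canonical(self) -> "TanhParams":
        """Resolve the tanh sign symmetry: report the A > 0 representative."""
        if self.A < 0:
            return TanhParams(-self.A, -self.b, -self.c, self.B)
        return self

    def as_array(self) -> np.ndarray:
        return np.array([self.A, self.b, self.c, self.B])


@dataclass(frozen=True)
class AffineScaler:
    """Min-max map of both axes onto [-1, 1] (degenerate span maps to 0)."""

    x_min: float
    x_max: float
    y_min: float
    y_max: float

    @classmethod
    def from_data(cls, x, y) -> "AffineScaler":
        return cls(float(np.min(x)), float(np.max(x)),
                   float(np.min(y)), float(np.max(y)))

    def _fwd(self, v, lo, hi):
        span = hi - lo
        if span <= 0:
            return np.zeros_like(np.asarray(v, dtype=float))
        return 2.0 * (np.asarray(v, dtype=float) - lo) / span - 1.0

    def _inv(self, s, lo, hi):
        span = hi - lo
        return (np.asarray(s, dtype=float) + 1.0) * span / 2.0 + lo

    def forward_x(self, x):
        return self._fwd(x, self.x_min, self.x_max)

    def inverse_x(self, xs):
        return self._inv(xs, self.x_min, self.x_max)

    def forward_y(self, y):
        return self._fwd(y, self.y_min, self.y_max)

    def inverse_y(self, ys):
        return self._inv(ys, self.y_min, self.y_max)

    def x_coeffs(self) -> tuple[float, float]:
        """(g, h) such that x_scaled = g*x + h."""
        span = self.x_max - self.x_min
        if span <= 0:
            return 0.0, 0.0
        return 2.0 / span, -(self.x_max + self.x_min) / span

    def y_coeffs(self) -> tuple[float, float]:
        span = self.y_max - self.y_min
        if span <= 0:
            return 0.0, 0.0
        return 2.0 / span, -(self.y_max + self.y_min) / span


def scaled_to_original(scaled: TanhParams, scaler: AffineScaler) -> TanhParams:
    """Analytic back-transformation of scaled-space parameters.

    With x_s = g_x*x + h_x and y_s = g_y*y + h_y, the scaled model
    y_s = A_s*tanh(c_s*x_s + b_s) + B_s is exactly the original-unit model
    with A = A_s/g_y, c = c_s*g_x, b = c_s*h_x + b_s, B = (B_s - h_y)/g_y.
    """
    gx, hx = scaler.x_coeffs()
    gy, hy = scaler.y_coeffs()
    if gy == 0.0:  # constant response: leave amplitude in scaled units
        gy = 1.0
    return TanhParams(
        A=scaled.A / gy,
        b=scaled.c * hx + scaled.b,
        c=scaled.c * gx,
        B=(scaled.B - hy) / gy,
    )


def original_to_scaled(params: TanhParams, scaler: AffineScaler) -> TanhParams:
    gx, hx = scaler.x_coeffs()
    gy, hy = scaler.y_coeffs()
    if gy == 0.0:
        gy = 1.0
    if gx == 0.0:
        raise DegenerateDesignError("degenerate x scaler")
    return TanhParams(
        A=params.A * gy,
        b=params.b - (params.c / gx) * hx,
        c=params.c / gx,
        B=params.B * gy + hy,
    )


@dataclass
class FitConfig:
    """Tuning knobs of the regularized fit.

    ``max_iter`` bounds the outer evidence-update loop; each pass runs a
    full damped-least-squares solve at the current hyperparameters.
    Convergence requires relative objective change < ``tol`` and relative
    hyperparameter change < ``hyper_tol``.
    """

    n_restarts: int = 10
    max_iter: int = 300
    tol: float = 1e-9
    hyper_tol: float = 1e-6
    seed: int | None = None


@dataclass
class TanhFit:
    params: TanhParams                # original units, canonical A > 0
    scaled_params: TanhParams         # scaled space, same sign convention as found
    scaler: AffineScaler
    rmse: float
    alpha: float
    beta: float
    gamma: float
    objective: float
    objective_trace: list[float]
    n: int
    n_restarts_used: int
    converged: bool
    seed: int | None

    def predict(self, x):
        return self.params.predict(x)


def _resid(w, xs, ys):
    a, b, c, bb = w
    return ys - (a * np.tanh(c * xs + b) + bb)


def _jac(w, xs):
    """Jacobian of the residual vector wrt (A, b, c, B) in scaled space."""
    a, b, c, _ = w
    t = np.tanh(c * xs + b)
    sech2 = 1.0 - t * t
    return -np.column_stack([t, a * sech2, a * sech2 * xs, np.ones_like(xs)])


def _fit_single_start(xs, ys, w0, cfg: FitConfig):
    """One restart: alternate LM inner solves with evidence updates."""
    n = xs.size
    w = np.asarray(w0, dtype=float)
    alpha, beta = 0.0, 1.0
    trace: list[float] = []
    prev_F = np.inf
    converged = False

    for _ in range(cfg.max_iter):
        lam = alpha / beta
        sqrt_lam = math.sqrt(lam)

        def aug_resid(wv):
            return np.concatenate([_resid(wv, xs, ys), sqrt_lam * wv])

        def aug_jac(wv):
            return np.vstack([_jac(wv, xs), sqrt_lam * np.eye(4)])

        sol = least_squares(aug_resid, w, jac=aug_jac, method="lm",
                            xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=400)
        w = sol.x
        r = _resid(w, xs, ys)
        ed = 0.5 * float(r @ r)
        ew = 0.5 * float(w @ w)
        J = _jac(w, xs)
        H = beta * (J.T @ J) + alpha * np.eye(4)
        try:
            h_inv_tr = float(np.trace(np.linalg.inv(H)))
        except np.linalg.LinAlgError:
            h_inv_tr = float(np.trace(np.linalg.pinv(H)))
        gamma = min(max(4.0 - alpha * h_inv_tr, 0.0), 4.0)
        new_alpha = min(gamma / max(2.0 * ew, 1e-300), _ALPHA_CAP)
        new_beta = min((n - gamma) / max(2.0 * ed, 1e-300), _BETA_CAP)
        F = new_beta * ed + new_alpha * ew
        trace.append(F)

        d_alpha = abs(new_alpha - alpha) / max(abs(alpha), 1e-12)
        d_beta = abs(new_beta - beta) / max(abs(beta), 1e-12)
        d_obj = abs(F - prev_F) / max(abs(prev_F), 1e-12)
        alpha, beta, prev_F = new_alpha, new_beta, F
        if d_obj < cfg.tol and d_alpha < cfg.hyper_tol and d_beta < cfg.hyper_tol:
            converged = True
            break

    return {
        "w": w,
        "alpha": alpha,
        "beta": beta,
        "gamma": gamma,
        "objective": prev_F,
        "ed": ed,
        "trace": trace,
        "converged": converged,
    }


def fit_tanh_neuron(
    x,
    y,
    config: FitConfig | None = None,
    initial_scaled_params: TanhParams | None = None,
) -> TanhFit:
    """Fit the tanh neuron to (intake, response) data.

    ``initial_scaled_params`` prepends a warm start (in scaled space) to
    the randomized restarts — used by the bootstrap to refit replicates
    from the full-data solution.  Restarts are drawn uniformly from
    [-1, 1]^4 under a generator seeded by ``config.seed``; the best
    converged restart by final objective F (ties by RMSE) wins.
    Deterministic given the seed.
    """
    cfg = config or FitConfig()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValidationError("x and y must have equal length")
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if x.size < 5:
        raise SampleSizeError(f"need >= 5 complete cases, got {x.size}")
    if np.ptp(x) == 0:
        raise DegenerateDesignError("nutrient intake is constant")

    scaler = AffineScaler.from_data(x, y)
    xs = scaler.forward_x(x)
    ys = scaler.forward_y(y)

    rng = np.random.default_rng(cfg.seed)
    starts: list[np.ndarray] = []
    if initial_scaled_params is not None:
        starts.append(initial_scaled_params.as_array())
    n_random = max(cfg.n_restarts - len(starts), 0)
    for _ in range(n_random):
        starts.append(rng.uniform(-1.0, 1.0, size=4))

    results = []
    for w0 in starts:
        try:
            results.append(_fit_single_start(xs, ys, w0, cfg))
        except np.linalg.LinAlgError:
            continue
    converged = [r for r in results if r["converged"]]
    pool = converged or results
    if not pool:
        raise NonConvergenceError(
            "all restarts failed", traces=[r["trace"] for r in results]
        )
    pool.sort(key=lambda r: (r["objective"], r["ed"]))
    best = pool[0]

    scaled = TanhParams(*best["w"])
    params = scaled_to_original(scaled, scaler).canonical()
    resid = y - params.predict(x)
    rmse = float(np.sqrt(np.mean(resid**2)))
    return TanhFit(
        params=params,
        scaled_params=scaled,
        scaler=scaler,
        rmse=rmse,
        alpha=best["alpha"],
        beta=best["beta"],
        gamma=best["gamma"],
        objective=best["objective"],
        objective_trace=best["trace"],
        n=int(x.size),
        n_restarts_used=len(results),
        converged=bool(converged),
        seed=cfg.seed,
    )


def predict(fit: TanhFit, x):
    """Evaluate the fitted curve in original units."""
    return fit.predict(x)


def fit_rmse(fit: TanhFit, x, y) -> float:
    """Root mean squared residual, sqrt(SSE/n) convention."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    r = y - fit.predict(x)
    return float(np.sqrt(np.mean(r**2)))


def curve_band(
    x,
    y,
    grid,
    fit_config: FitConfig | None = None,
    n_boot: int = 100,
    level: float = 0.95,
    seed: int = 0,
    max_failure_rate: float = 0.2,
):
    """Bootstrap confidence band for the predicted mean response.

    Case-resampling bootstrap: each replicate resamples records with
    replacement, refits (warm-started from the full-data solution), and
    the band is the pointwise percentile envelope of the replicate
    predictions on ``grid``.  Deterministic given ``seed``.  Fails if more
    than ``max_failure_rate`` of replicates cannot be refitted.

    Returns (mean, lower, upper) arrays over the grid, where ``mean`` is
    the full-data fitted curve.
    """
    from .exceptions import InferenceError

    cfg = fit_config or FitConfig()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    grid = np.asarray(grid, dtype=float)
    full = fit_tanh_neuron(x, y, cfg)
    warm = full.scaled_params

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_boot)
    preds = []
    n_failed = 0
    rep_cfg = replace(cfg, n_restarts=1)
    for child in children:
        rng = np.random.default_rng(child)
        idx = rng.integers(0, x.size, size=x.size)
        xb, yb = x[idx], y[idx]
        try:
            warm_b = original_to_scaled(
                full.params, AffineScaler.from_data(xb, yb)
            )
            fit_b = fit_tanh_neuron(
                xb, yb,
                replace(rep_cfg, seed=int(child.generate_state(1)[0] % 2**31)),
                initial_scaled_params=warm_b,
            )
            preds.append(fit_b.predict(grid))
        except Exception:
            n_failed += 1
    if n_failed > max_failure_rate * n_boot:
        raise InferenceError(
            f"{n_failed}/{n_boot} bootstrap replicates failed to refit"
        )
    preds = np.vstack(preds)
    lo = np.quantile(preds, (1.0 - level) / 2.0, axis=0)
    hi = np.quantile(preds, (1.0 + level) / 2.0, axis=0)
    return full.predict(grid), lo, hi
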