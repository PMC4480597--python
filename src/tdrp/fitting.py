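"""Constrained nonlinear least-squares fitting of the rate-decay models.

Two criteria mirror the two uses of the models:

* ``LSE_rbar`` — minimise squared residuals of the node-to-tip average rate
  rbar(t); describes the rate-decay curve itself.
* ``LSE_t`` — minimise squared residuals of the node age t predicted from
  the node's substitutions s by inverting the cumulative curve; this is the
  criterion that matters when the model is used to infer divergence dates.

All parameters are constrained positive (power-law beta additionally < 1)
by optimising in log / logit space.  Fits are multi-start from a seeded
Latin-hypercube over [1e-12, 1e3] per parameter on the natural scale, with
a Nelder-Mead polish of the best optimum.  The internal fitting unit is
Myr for t and substitutions/site/Myr for rates (conditioning); convert
reported rates to per-year with ``RateModelParams.to_unit``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, List, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import qmc

from .dataset import RateSampleSet
from .models import (
    BETA_EPS,
    RateModelKind,
    RateModelParams,
    YEARS_PER_MYR,
    _invert_bisect,
    average_rate,
)

__all__ = [
    "FitResult",
    "adjusted_r_squared",
    "fit_average_rate_model",
    "fit_time_model",
    "fit_ensemble",
]

N_STARTS = 20
#: natural-scale Latin-hypercube range per parameter
LHS_LO, LHS_HI = 1e-12, 1e3
K_FLOOR = 1e-30


class FitError(RuntimeError):
    """No multi-start converged; carries per-start diagnostics."""

    def __init__(self, msg, diagnostics=None):
        super().__init__(msg)
        self.diagnostics = diagnostics


@dataclass(frozen=True)
class FitResult:
    params: RateModelParams
    criterion: str  # "LSE_rbar" | "LSE_t"
    sse: float
    adj_r2: Optional[float]
    n_points: int
    n_starts_converged: int
    converged: bool


def adjusted_r_squared(r2: float, n_points: int, n_params: int) -> float:
    """1 - (1 - R^2)(n - 1)/(n - p - 1); requires n > p + 1."""
    if n_points <= n_params + 1:
        raise ValueError(
            f"adjusted R^2 needs n_points > n_params + 1 ({n_points} <= {n_params + 1})"
        )
    return 1.0 - (1.0 - r2) * (n_points - 1) / (n_points - n_params - 1)


# ---------------------------------------------------------------------------
# parameter transforms: optimisation space <-> natural space

_LOG_LO, _LOG_HI = math.log(1e-30), math.log(1e6)


def _to_x(kind: RateModelKind, p: RateModelParams) -> np.ndarray:
    x = [math.log(p.alpha)]
    if kind.is_power_law:
        b = min(max(p.beta, BETA_EPS * 1.01), 1 - BETA_EPS * 1.01)
        u = (b - BETA_EPS) / (1 - 2 * BETA_EPS)
        x.append(math.log(u / (1 - u)))
    else:
        x.append(math.log(p.beta))
    if kind.has_offset:
        x.append(math.log(max(p.k, K_FLOOR)))
    return np.array(x)


def _from_x(kind: RateModelKind, x: np.ndarray) -> RateModelParams:
    alpha = math.exp(min(x[0], 700))
    if kind.is_power_law:
        u = 1.0 / (1.0 + math.exp(-min(max(x[1], -700), 700)))
        beta = BETA_EPS + (1 - 2 * BETA_EPS) * u
        beta = min(max(beta, BETA_EPS * 1.0001), 1 - BETA_EPS * 1.0001)
    else:
        beta = math.exp(min(x[1], 700))
    k = max(math.exp(min(x[2], 700)), K_FLOOR) if kind.has_offset else 0.0
    return RateModelParams(kind=kind, alpha=alpha, beta=beta, k=k, time_unit="Myr")


def _lhs_starts(kind: RateModelKind, n_starts: int, seed) -> List[np.ndarray]:
    """Seeded Latin-hypercube starts, log-uniform over [1e-12, 1e3] per
    parameter (power-law beta mapped into its open unit interval)."""
    d = kind.n_free_params
    sampler = qmc.LatinHypercube(d=d, seed=np.random.default_rng(seed))
    u = sampler.random(n_starts)
    lo, hi = math.log(LHS_LO), math.log(LHS_HI)
    starts = []
    for row in u:
        x = [lo + (hi - lo) * row[0]]
        if kind.is_power_law:
            b = 0.02 + 0.96 * row[1]
            x.append(math.log(b / (1 - b)))
        else:
            x.append(lo + (hi - lo) * row[1])
        if kind.has_offset:
            x.append(lo + (hi - lo) * row[2])
        starts.append(np.array(x))
    return starts


# ---------------------------------------------------------------------------
# objectives (value + analytic gradient in the transformed space)


def _chain(kind: RateModelKind, x: np.ndarray, p: RateModelParams) -> np.ndarray:
    """d(natural param)/d(transformed coordinate), per coordinate."""
    out = [p.alpha]
    if kind.is_power_law:
        u = 1.0 / (1.0 + math.exp(-min(max(x[1], -700), 700)))
        out.append((1 - 2 * BETA_EPS) * u * (1 - u))
    else:
        out.append(p.beta)
    if kind.has_offset:
        out.append(p.k)
    return np.array(out)


def _rbar_objective(kind: RateModelKind, t: np.ndarray, rbar: np.ndarray) -> Callable:
    log_t = np.log(t)

    def sse_grad(x: np.ndarray):
        p = _from_x(kind, x)
        # np.float64: overflow becomes inf (penalised) instead of raising
        a, b, k = np.float64(p.alpha), np.float64(p.beta), np.float64(p.k)
        with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
            if kind.is_power_law:
                core = t ** (-b) / (1.0 - b)  # rbar = a*core + k
                model = a * core + k
                d_a = core
                d_b = a * core * (1.0 / (1.0 - b) - log_t)
            else:
                em = -np.expm1(-b * t)  # 1 - e^{-bt}
                core = em / (b * t)
                model = a * core + k
                d_a = core
                d_b = -a * core / b + a * np.exp(-b * t) / b
            resid = rbar - model
            grads = [-2.0 * resid @ d_a, -2.0 * resid @ d_b]
            if kind.has_offset:
                grads.append(-2.0 * resid.sum())
            g = np.array(grads) * _chain(kind, x, p)
            val = float(resid @ resid)
        if not math.isfinite(val):
            val = 1e200
            g = np.zeros_like(g)
        g = np.where(np.isfinite(g), g, 0.0)
        return val, g

    return sse_grad


def _newton_invert(
    is_power_law: bool, a: float, b: float, k: float, s: np.ndarray
) -> np.ndarray:
    """Invert the cumulative curve s(t) for the offset kinds, vectorized.

    s(t) is increasing and concave through the origin, so a Newton
    iteration started at an upper bound of the root (the k-only root s/k,
    or the offset-free closed-form root, whichever is smaller) steps once
    below the root and then converges monotonically from below.
    """
    with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
        t_k = s / k if k > 0 else np.full_like(s, np.inf)
        if is_power_law:
            t_part = ((1.0 - b) * s / a) ** (1.0 / (1.0 - b))
        else:
            z = s * b / a
            t_part = np.where(
                z < 1.0, -np.log1p(-np.minimum(z, 1.0 - 1e-16)) / b, np.inf
            )
        t = np.minimum(t_part, t_k)
        t = np.where(np.isfinite(t), t, np.inf)
        for _ in range(100):
            if is_power_law:
                f = a * t ** (1.0 - b) / (1.0 - b) + k * t
                r = a * t ** (-b) + k
            else:
                f = a / b * -np.expm1(-b * t) + k * t
                r = a * np.exp(-b * t) + k
            step = np.where(np.isfinite(t), (s - f) / r, 0.0)
            t = np.maximum(t + step, 0.0)
            if np.all(np.abs(step) <= 1e-14 * np.maximum(t, 1e-300)):
                break
    return t


def _time_objective(kind: RateModelKind, t: np.ndarray, s: np.ndarray) -> Callable:
    t_max = float(np.max(t))

    def sse_grad(x: np.ndarray):
        p = _from_x(kind, x)
        a, b, k = np.float64(p.alpha), np.float64(p.beta), np.float64(p.k)
        with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
            if kind is RateModelKind.PL:
                T = ((1.0 - b) * s / a) ** (1.0 / (1.0 - b))
            elif kind is RateModelKind.EX:
                z = s * b / a
                T = np.where(
                    z < 1.0, -np.log1p(-np.minimum(z, 1.0 - 1e-16)) / b, np.inf
                )
            else:
                T = _newton_invert(kind.is_power_law, a, b, k, s)
            ok = np.isfinite(T) & (T > 0)
            Ts = np.where(ok, T, 1.0)
            # implicit differentiation at s fixed: dT/dtheta = -(ds/dtheta)/r(T)
            if kind.is_power_law:
                pw = Ts ** (1.0 - b)
                ds_da = pw / (1.0 - b)
                ds_db = a * pw * (1.0 / (1.0 - b) ** 2 - np.log(Ts) / (1.0 - b))
                rate = a * Ts ** (-b) + k
            else:
                em = -np.expm1(-b * Ts)
                ds_da = em / b
                ds_db = -a * em / b**2 + a * Ts * np.exp(-b * Ts) / b
                rate = a * np.exp(-b * Ts) + k
            resid = np.where(ok, t - Ts, 0.0)
            # resid = t - T(s); d resid/dtheta = (ds/dtheta)/r
            g_a = 2.0 * resid @ np.where(ok, ds_da / rate, 0.0)
            g_b = 2.0 * resid @ np.where(ok, ds_db / rate, 0.0)
            grads = [g_a, g_b]
            if kind.has_offset:
                grads.append(2.0 * resid @ np.where(ok, Ts / rate, 0.0))
            val = float(resid @ resid)
            if not ok.all():
                # beyond EX saturation (or numerically unreachable): finite
                # penalty, continuous and increasing in the violation, so
                # optimisers can exit the infeasible region
                if kind is RateModelKind.EX:
                    pen = t_max * z[~ok]
                    val += float(pen @ pen)
                    # pen = t_max*s*b/a: d pen/da = -pen/a, d pen/db = pen/b
                    grads[0] += float(2.0 * pen @ (-pen / a))
                    grads[1] += float(2.0 * pen @ (pen / b))
                else:
                    val += 1e100
            g = np.array(grads[: 2 + int(kind.has_offset)]) * _chain(kind, x, p)
        if not math.isfinite(val):
            val = 1e200
            g = np.zeros_like(g)
        g = np.where(np.isfinite(g), g, 0.0)
        return val, g

    return sse_grad


# ---------------------------------------------------------------------------
# driver


def _minimize_multistart(
    obj: Callable,
    kind: RateModelKind,
    n_starts: int,
    seed,
    warm_starts: Sequence[np.ndarray] = (),
    polish: bool = True,
) -> tuple:
    starts = list(warm_starts) + _lhs_starts(kind, n_starts, seed)
    best = None
    n_conv = 0
    diagnostics = []
    for x0 in starts:
        try:
            res = optimize.minimize(
                obj, x0, method="L-BFGS-B", jac=True,
                options={"ftol": 1e-15, "gtol": 1e-12, "maxiter": 500},
            )
        except (ValueError, FloatingPointError) as exc:  # pragma: no cover
            diagnostics.append(str(exc))
            continue
        if res.success or res.fun < np.inf:
            n_conv += int(bool(res.success))
            if best is None or res.fun < best.fun:
                best = res
        diagnostics.append(f"{res.message}: f={res.fun:.3g}")
    if best is None:
        raise FitError(f"all {len(starts)} starts failed for {kind.value}", diagnostics)
    if polish:
        nm = optimize.minimize(
            lambda x: obj(x)[0], best.x, method="Nelder-Mead",
            options={"xatol": 1e-13, "fatol": 1e-300, "maxiter": 300},
        )
        if nm.fun <= best.fun:
            best = nm
    return best, n_conv


def _check_points(kind: RateModelKind, n: int, allow_interpolating: bool) -> None:
    need = kind.n_free_params + (1 if allow_interpolating else 2)
    if n < need:
        raise ValueError(
            f"{kind.value} ({kind.n_free_params} free parameters) needs at "
            f"least {need} points, got {n}"
        )


def _finish(
    kind: RateModelKind,
    criterion: str,
    best,
    n_conv: int,
    response: np.ndarray,
) -> FitResult:
    params = _from_x(kind, best.x)
    sse = float(best.fun)
    n = response.size
    p = kind.n_free_params
    adj = None
    if n > p + 1:
        ss_tot = float(np.sum((response - response.mean()) ** 2))
        r2 = 1.0 - sse / ss_tot if ss_tot > 0 else 1.0
        adj = adjusted_r_squared(r2, n, p)
    return FitResult(
        params=params, criterion=criterion, sse=sse, adj_r2=adj,
        n_points=n, n_starts_converged=n_conv, converged=n_conv > 0,
    )


def fit_average_rate_model(
    points: RateSampleSet,
    kind: Union[str, RateModelKind],
    n_starts: int = N_STARTS,
    seed=0,
    warm_starts: Sequence[np.ndarray] = (),
    polish: bool = True,
) -> FitResult:
    """Fit one model to (t, rbar) under least squared error of rbar.

    t in Myr, rbar internally in substitutions/site/Myr; the returned
    parameters carry ``time_unit="Myr"``.
    """
    kind = RateModelKind(kind if isinstance(kind, RateModelKind) else str(kind).upper())
    t = points.t_myr
    rbar = points.rbar_per_year * YEARS_PER_MYR  # s/n/Myr
    _check_points(kind, t.size, allow_interpolating=False)
    obj = _rbar_objective(kind, t, rbar)
    best, n_conv = _minimize_multistart(obj, kind, n_starts, seed, warm_starts, polish)
    return _finish(kind, "LSE_rbar", best, n_conv, rbar)


def fit_time_model(
    points: RateSampleSet,
    kind: Union[str, RateModelKind],
    n_starts: int = N_STARTS,
    seed=0,
    warm_starts: Sequence[np.ndarray] = (),
    allow_interpolating: bool = False,
    polish: bool = True,
) -> FitResult:
    """Fit one model to (s, t) under least squared error of predicted t.

    ``allow_interpolating=True`` accepts n = free params + 1 points (used by
    the three-node calibration schemes, where adjusted R^2 is suppressed).
    """
    kind = RateModelKind(kind if isinstance(kind, RateModelKind) else str(kind).upper())
    t, s = points.t_myr, points.s
    _check_points(kind, t.size, allow_interpolating)
    obj = _time_objective(kind, t, s)
    best, n_conv = _minimize_multistart(obj, kind, n_starts, seed, warm_starts, polish)
    return _finish(kind, "LSE_t", best, n_conv, t)


def fit_ensemble(
    sets: Sequence[RateSampleSet],
    kind: Union[str, RateModelKind],
    criterion: str = "LSE_rbar",
    n_starts: int = N_STARTS,
    seed=0,
) -> tuple[List[Optional[FitResult]], pd.DataFrame]:
    """Fit one model to every resampled set; summarise parameter spread.

    Returns the per-set fits (None where no start converged) and a summary
    frame of median and central 2.5/97.5 percentiles of alpha, beta, k and
    adjusted R^2 across converged fits.
    """
    if len(sets) == 0:
        raise ValueError("need at least one rate set")
    fit = fit_average_rate_model if criterion == "LSE_rbar" else fit_time_model
    # one shared multi-start seed: identical input sets yield identical fits
    start_seed = int(np.random.SeedSequence(seed).generate_state(1)[0])
    fits: List[Optional[FitResult]] = []
    for pts in sets:
        try:
            fits.append(fit(pts, kind, n_starts=n_starts, seed=start_seed))
        except FitError:
            fits.append(None)
    rows = {}
    ok = [f for f in fits if f is not None]
    for name in ("alpha", "beta", "k", "adj_r2"):
        vals = np.array(
            [getattr(f.params, name) if name != "adj_r2" else f.adj_r2 for f in ok],
            dtype=float,
        )
        vals = vals[np.isfinite(vals)]
        if vals.size:
            rows[name] = {
                "median": float(np.median(vals)),
                "q2.5": float(np.percentile(vals, 2.5)),
                "q97.5": float(np.percentile(vals, 97.5)),
            }
    return fits, pd.DataFrame(rows).T
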