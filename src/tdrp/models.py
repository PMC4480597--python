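"""Empirical substitution-rate decay models.

Four empirical descriptions of how the (apparent) substitution rate of a
lineage decays with the timescale ``t`` over which it is measured:

=====  ==========================================  ==========================
kind   instantaneous rate r(t)                     free parameters
=====  ==========================================  ==========================
VEX    alpha * exp(-beta * t) + k                  alpha, beta, k
EX     alpha * exp(-beta * t)                      alpha, beta
VPL    alpha * t**(-beta) + k                      alpha, beta, k
PL     alpha * t**(-beta)                          alpha, beta
=====  ==========================================  ==========================

``k`` is the stable long-term rate the vertically-translated models decay
towards.  Integrating r from 0 to t (the curves are forced through the
origin: no substitutions at time zero) gives the expected node-to-tip
substitutions per site s(t); dividing by t gives the node-to-tip average
rate rbar(t) = s(t)/t, the quantity observed on a dated phylogeny.

For the power-law kinds the integral through the origin is finite only for
beta < 1, so beta is constrained to (BETA_EPS, 1 - BETA_EPS) there.

Rates are substitutions/site/unit-time; the unit of t (``year`` or ``Myr``)
is recorded on the parameters and conversions between the two are exact.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, replace
from typing import Union

import numpy as np

__all__ = [
    "RateModelKind",
    "RateModelParams",
    "instantaneous_rate",
    "cumulative_substitutions",
    "average_rate",
    "invert_time",
]

#: open-interval margin for the power-law decay exponent
BETA_EPS = 1e-6

YEARS_PER_MYR = 1e6


class RateModelKind(str, enum.Enum):
    """The four empirical rate-decay model families."""

    VEX = "VEX"  # vertically-translated exponential
    EX = "EX"  # simple exponential
    VPL = "VPL"  # vertically-translated power law
    PL = "PL"  # simple power law

    @property
    def n_free_params(self) -> int:
        return 3 if self in (RateModelKind.VEX, RateModelKind.VPL) else 2

    @property
    def is_power_law(self) -> bool:
        return self in (RateModelKind.VPL, RateModelKind.PL)

    @property
    def has_offset(self) -> bool:
        return self in (RateModelKind.VEX, RateModelKind.VPL)


def _as_kind(kind: Union[str, RateModelKind]) -> RateModelKind:
    if isinstance(kind, RateModelKind):
        return kind
    return RateModelKind(str(kind).upper())


@dataclass(frozen=True)
class RateModelParams:
    """Parameters of one rate-decay model.

    Parameters
    ----------
    kind
        Model family (VEX, EX, VPL or PL).
    alpha
        Rate-scale parameter, > 0.  Units: substitutions/site/ut for the
        exponentials; substitutions/site/ut * ut**beta for the power laws.
    beta
        Decay parameter, > 0.  1/ut for the exponentials; dimensionless for
        the power laws, where additionally beta < 1.
    k
        Stable long-term rate (substitutions/site/ut), >= 0.  Only VEX and
        VPL carry it; it is forced to 0.0 for EX and PL.
    time_unit
        Unit of t: ``"year"`` or ``"Myr"``.
    """

    kind: RateModelKind
    alpha: float
    beta: float
    k: float = 0.0
    time_unit: str = "Myr"

    def __post_init__(self):
        object.__setattr__(self, "kind", _as_kind(self.kind))
        for name in ("alpha", "beta", "k"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if self.alpha <= 0:
            raise ValueError(f"alpha must be > 0, got {self.alpha}")
        if self.beta <= 0:
            raise ValueError(f"beta must be > 0, got {self.beta}")
        if self.kind.is_power_law and self.beta >= 1 - BETA_EPS:
            raise ValueError(
                f"power-law beta must lie in (0, {1 - BETA_EPS}) for the "
                f"cumulative curve through the origin to be finite; got {self.beta}"
            )
        if self.k < 0:
            raise ValueError(f"k must be >= 0, got {self.k}")
        if not self.kind.has_offset and self.k != 0.0:
            object.__setattr__(self, "k", 0.0)
        if self.time_unit not in ("year", "Myr"):
            raise ValueError(f"time_unit must be 'year' or 'Myr', got {self.time_unit!r}")

    # -- unit conversion ---------------------------------------------------

    def to_unit(self, time_unit: str) -> "RateModelParams":
        """Re-express the parameters with t measured in ``time_unit``.

        Exact: rates scale by 1e6 between years and Myr; the exponential
        decay constant scales inversely with the time unit; the power-law
        exponent is dimensionless and its alpha absorbs a factor
        ``c**(1-beta)`` where c is the unit ratio.
        """
        if time_unit == self.time_unit:
            return self
        if time_unit not in ("year", "Myr"):
            raise ValueError(f"time_unit must be 'year' or 'Myr', got {time_unit!r}")
        # rate scale factor: a rate per year is 1e6 times smaller than per Myr
        c = 1.0 / YEARS_PER_MYR if self.time_unit == "Myr" else YEARS_PER_MYR
        if self.kind.is_power_law:
            alpha = self.alpha * c ** (1.0 - self.beta)
            beta = self.beta
        else:
            alpha = self.alpha * c
            beta = self.beta * c
        return replace(self, alpha=alpha, beta=beta, k=self.k * c, time_unit=time_unit)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "kind": self.kind.value,
            "alpha": self.alpha,
            "beta": self.beta,
            "k": self.k,
            "time_unit": self.time_unit,
        }

    def to_json(self) -> str:
        # repr round-trips floats exactly (17 significant digits)
        return json.dumps(self.to_dict())

    @classmethod
    def from_dict(cls, d: dict) -> "RateModelParams":
        return cls(
            kind=_as_kind(d["kind"]),
            alpha=float(d["alpha"]),
            beta=float(d["beta"]),
            k=float(d.get("k", 0.0)),
            time_unit=d.get("time_unit", "Myr"),
        )

    @classmethod
    def from_json(cls, s: str) -> "RateModelParams":
        return cls.from_dict(json.loads(s))


# ---------------------------------------------------------------------------
# model evaluation


def _check_time(kind: RateModelKind, t: np.ndarray, allow_zero_pl: bool) -> None:
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    if not allow_zero_pl and kind.is_power_law and np.any(t == 0):
        raise ValueError(f"{kind.value} instantaneous rate is singular at t = 0")


def instantaneous_rate(params: RateModelParams, t) -> Union[float, np.ndarray]:
    """Instantaneous substitution rate r(t), substitutions/site/ut.

    Strictly decreasing in t; singular at t = 0 for the power-law kinds.
    """
    ts = np.asarray(t, dtype=float)
    _check_time(params.kind, ts, allow_zero_pl=False)
    if params.kind.is_power_law:
        r = params.alpha * ts ** (-params.beta) + params.k
    else:
        r = params.alpha * np.exp(-params.beta * ts) + params.k
    return float(r) if np.isscalar(t) or ts.ndim == 0 else r


def cumulative_substitutions(params: RateModelParams, t) -> Union[float, np.ndarray]:
    """Expected node-to-tip substitutions/site s(t) = integral of r over [0, t].

    s(0) = 0 and s is strictly increasing.
    """
    ts = np.asarray(t, dtype=float)
    _check_time(params.kind, ts, allow_zero_pl=True)
    a, b, k = params.alpha, params.beta, params.k
    if params.kind.is_power_law:
        s = a * ts ** (1.0 - b) / (1.0 - b) + k * ts
    else:
        s = a / b * -np.expm1(-b * ts) + k * ts
    return float(s) if np.isscalar(t) or ts.ndim == 0 else s


def average_rate(params: RateModelParams, t) -> Union[float, np.ndarray]:
    """Node-to-tip average rate rbar(t) = s(t)/t, substitutions/site/ut (t > 0)."""
    ts = np.asarray(t, dtype=float)
    if np.any(ts <= 0):
        raise ValueError("t must be > 0 for the average rate")
    out = cumulative_substitutions(params, ts) / ts
    return float(out) if np.isscalar(t) or ts.ndim == 0 else out


# ---------------------------------------------------------------------------
# inversion: time from substitutions


def ex_max_substitutions(params: RateModelParams) -> float:
    """EX saturates: s(t) -> alpha/beta as t -> inf (other kinds are unbounded)."""
    if params.kind is not RateModelKind.EX:
        return math.inf
    return params.alpha / params.beta


def invert_time(params: RateModelParams, s) -> Union[float, np.ndarray]:
    """The unique t with ``cumulative_substitutions(params, t) == s``.

    Closed form for PL and EX; for VEX/VPL a geometric bracket is expanded
    until s is straddled, then bisected to tolerance ``1e-10 + 1e-8*t``
    (s(t) is smooth and strictly increasing, so bracketing is safe).

    Raises
    ------
    ValueError
        If s < 0, or for EX if s >= alpha/beta (beyond the saturation
        asymptote, no finite t reaches it).
    """
    ss = np.asarray(s, dtype=float)
    scalar = np.isscalar(s) or ss.ndim == 0
    ss = np.atleast_1d(ss)
    if np.any(ss < 0):
        raise ValueError("s must be >= 0")
    a, b, k = params.alpha, params.beta, params.k
    kind = params.kind

    if kind is RateModelKind.PL:
        t = ((1.0 - b) * ss / a) ** (1.0 / (1.0 - b))
    elif kind is RateModelKind.EX:
        smax = a / b
        if np.any(ss >= smax):
            raise ValueError(
                f"EX model saturates at s = alpha/beta = {smax:g}; "
                "larger s is unreachable at any finite t"
            )
        t = -np.log1p(-ss * b / a) / b
    else:
        t = _invert_bisect(params, ss)
    t = np.where(ss == 0.0, 0.0, t)
    return float(t[0]) if scalar else t


def _invert_bisect(params: RateModelParams, s: np.ndarray) -> np.ndarray:
    # expanding geometric bracket [0, 2^j], then vectorized bisection;
    # 80 halvings over-satisfy the 1e-10 + 1e-8*t tolerance
    hi = np.ones_like(s)
    for _ in range(200):
        under = cumulative_substitutions(params, hi) < s
        if not under.any():
            break
        hi = np.where(under, hi * 2.0, hi)
    else:
        # s not reached by t = 2^200: numerically beyond any usable time
        # (possible during fitting when k collapses towards its floor)
        unreached = cumulative_substitutions(params, hi) < s
        hi = np.where(unreached, np.inf, hi)
    lo = np.zeros_like(s)
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        below = cumulative_substitutions(params, mid) < s
        lo = np.where(below, mid, lo)
        hi = np.where(below, hi, mid)
    return 0.5 * (lo + hi)
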