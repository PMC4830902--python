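"""The Bass mixed-influence diffusion model.

The Bass model describes the uptake of an innovation in a population as the
combination of an *external* (innovation/advertising) force ``p`` acting on
everyone who has not yet adopted, and an *internal* (imitation/word-of-mouth)
force ``q`` proportional to the fraction that already has.  The hazard of
adoption at time ``t`` is ``p + q * F(t) / m`` and the cumulative adopted
fraction follows the closed form

    F(t) = m * (1 - exp(-(p + q) t)) / (1 + (q / p) * exp(-(p + q) t))

with ``F(0) = 0`` and ``F(t) -> m`` as ``t -> inf``.  ``m`` is the market
potential, the asymptotic fraction of the population that will ever adopt
(1.0 here by default: the analysis treats the full weighted adult population
as addressable).  When ``q > p`` the cumulative curve is S-shaped with an
interior inflection at ``t* = ln(q/p) / (p + q)``; when ``q <= p`` adoption
decelerates from the start (the "inverse-J" regime).  For ``q = 0`` the
closed form reduces exactly to the pure-external exponential
``m * (1 - exp(-p t))``.

This module holds the parameter container and all closed-form quantities;
estimation from data lives in :mod:`phrdiffusion.model`.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "BassParams",
    "Trajectory",
    "CurveShape",
    "bass_cdf",
    "bass_rate",
    "discrete_trajectory",
    "inflection_time",
    "time_to_threshold",
    "curve_shape",
    "motivation_ratio",
]


class CurveShape(str, enum.Enum):
    """Qualitative shape of the cumulative adoption curve."""

    S_CURVE = "s_curve"      # q > p: slow start, interior inflection
    INVERSE_J = "inverse_j"  # q <= p: immediate deceleration


@dataclass(frozen=True)
class BassParams:
    """Bass diffusion parameters.

    Parameters
    ----------
    p : float
        External (innovation) influence coefficient, per year.  Must be > 0.
    q : float
        Internal (imitation) influence coefficient, per year.  Must be >= 0.
    m : float, optional
        Market potential as a fraction of the population, in (0, 1].
    start_year : int, optional
        Calendar year at which cumulative adoption is zero.
    """

    p: float
    q: float
    m: float = 1.0
    start_year: int = 0

    def __post_init__(self) -> None:
        if not self.p > 0:
            raise ValueError(f"external coefficient p must be > 0, got {self.p}")
        if self.q < 0:
            raise ValueError(f"internal coefficient q must be >= 0, got {self.q}")
        if not 0 < self.m <= 1:
            raise ValueError(f"market potential m must be in (0, 1], got {self.m}")

    @property
    def q_over_p(self) -> float:
        """Motivation coefficient ratio q/p (internal over external influence)."""
        return self.q / self.p

    def to_dict(self) -> dict:
        return {
            "p": self.p,
            "q": self.q,
            "m": self.m,
            "start_year": self.start_year,
            "q_over_p": self.q_over_p,
        }


@dataclass(frozen=True)
class Trajectory:
    """Cumulative adoption sampled at integer calendar years."""

    years: np.ndarray
    fractions: np.ndarray

    def __post_init__(self) -> None:
        years = np.asarray(self.years, dtype=int)
        fractions = np.asarray(self.fractions, dtype=float)
        if years.shape != fractions.shape:
            raise ValueError("years and fractions must have matching shapes")
        if np.any(np.diff(years) <= 0):
            raise ValueError("years must be strictly increasing")
        if np.any(np.diff(fractions) < -1e-12):
            raise ValueError("cumulative fractions must be nondecreasing")
        if np.any((fractions < -1e-12) | (fractions > 1 + 1e-12)):
            raise ValueError("cumulative fractions must lie in [0, 1]")
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "fractions", fractions)

    def __len__(self) -> int:
        return len(self.years)

    def value_at(self, year: int, before_start: float = 0.0) -> float:
        """Cumulative fraction at ``year``; ``before_start`` below the range."""
        if year < self.years[0]:
            return before_start
        idx = np.searchsorted(self.years, year)
        if idx >= len(self.years) or self.years[idx] != year:
            raise KeyError(f"year {year} not in trajectory")
        return float(self.fractions[idx])

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: year, full-precision fraction, 2-dp percent."""
        return pd.DataFrame(
            {
                "year": self.years,
                "cumulative_fraction": self.fractions,
                "percent": np.round(100 * self.fractions, 2),
            }
        )


def _check_t(t) -> np.ndarray:
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time since start must be nonnegative")
    return t_arr


def bass_cdf(params: BassParams, t):
    """Cumulative adopted fraction ``F(t)`` at ``t`` years since the start year.

    Accepts a scalar or array ``t >= 0``; returns the same shape.  The general
    closed form is evaluated directly; at ``q = 0`` it reduces analytically to
    the exponential limit ``m * (1 - exp(-p t))``.
    """
    t_arr = _check_t(t)
    p, q, m = params.p, params.q, params.m
    decay = np.exp(-(p + q) * t_arr)
    out = m * (1.0 - decay) / (1.0 + (q / p) * decay)
    if np.isscalar(t) or t_arr.ndim == 0:
        return float(out)
    return out


def bass_rate(params: BassParams, t):
    """Instantaneous adoption rate ``dF/dt`` at ``t`` years since start."""
    t_arr = _check_t(t)
    p, q, m = params.p, params.q, params.m
    decay = np.exp(-(p + q) * t_arr)
    out = m * (p + q) ** 2 / p * decay / (1.0 + (q / p) * decay) ** 2
    if np.isscalar(t) or t_arr.ndim == 0:
        return float(out)
    return out


def discrete_trajectory(
    params: BassParams, n_steps: int, steps_per_year: int = 1
) -> Trajectory:
    """Annual-step Bass recursion, reported at integer years.

    The discrete analogue of the closed form advances adoption by

        dN = (p + q * N / m) * (m - N) * dt

    with ``N(0) = 0`` and ``dt = 1 / steps_per_year``.  With annual steps the
    first increment is exactly ``p * m``.  As ``steps_per_year`` grows the
    terminal value converges to :func:`bass_cdf` at the same horizon.  This
    recursion is a diagnostic; all fitting and forecasting uses the
    continuous closed form.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if steps_per_year < 1:
        raise ValueError("steps_per_year must be >= 1")
    p, q, m = params.p, params.q, params.m
    dt = 1.0 / steps_per_year
    n = 0.0
    years = [params.start_year]
    values = [0.0]
    for step in range(1, n_steps * steps_per_year + 1):
        n = n + (p + q * n / m) * (m - n) * dt
        if step % steps_per_year == 0:
            years.append(params.start_year + step // steps_per_year)
            values.append(n)
    return Trajectory(np.array(years), np.array(values))


def inflection_time(params: BassParams) -> float | None:
    """Time of maximum adoption rate, ``t* = ln(q/p)/(p+q)``.

    Defined only in the S-curve regime ``q > p``; returns ``None`` otherwise
    (the rate is maximal at the origin and strictly decreasing).
    """
    if params.q <= params.p:
        return None
    return math.log(params.q / params.p) / (params.p + params.q)


def time_to_threshold(params: BassParams, target_fraction: float) -> float:
    """Years since start until cumulative adoption reaches ``target_fraction``.

    Closed-form inverse of :func:`bass_cdf`:
    ``t = -ln((m - F) / (m + (q/p) F)) / (p + q)``.
    """
    p, q, m = params.p, params.q, params.m
    if target_fraction < 0:
        raise ValueError("target fraction must be nonnegative")
    if target_fraction >= m:
        raise ValueError(
            f"target fraction {target_fraction} is unreachable: market potential is {m}"
        )
    decay = (m - target_fraction) / (m + (q / p) * target_fraction)
    return -math.log(decay) / (p + q)


def curve_shape(params: BassParams) -> CurveShape:
    """S-curve iff ``q > p`` strictly; the tie ``q == p`` is inverse-J."""
    return CurveShape.S_CURVE if params.q > params.p else CurveShape.INVERSE_J


def motivation_ratio(params: BassParams) -> float:
    """Ratio of internal to external influence, q/p."""
    if params.p <= 0:
        raise ValueError("p must be positive")
    return params.q / params.p
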