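"""Exact steady-state solutions for the fully-communicated, untargeted model.

Under full communication every finding enters the record, so a hypothesis
that has been investigated ``m`` times carries a tally ``s = 2k - m`` where
``k`` is its number of positive findings.  The number of findings per
hypothesis is geometric (each further act is a replication with probability
``r``), and findings are i.i.d. positive with probability ``1 - beta`` (true)
or ``alpha`` (false).  The steady-state mass of true hypotheses at tally
``s`` is therefore a geometric series of binomial probabilities::

    p_T(s) = b (1-r) sum_{m >= |s|, m = s mod 2} r^(m-1)
             C(m, (m+s)/2) (1-beta)^((m+s)/2) beta^((m-s)/2)

with the false-hypothesis masses obtained by the substitution
``1-beta -> alpha``, ``b -> 1-b``.  At ``s = 1`` the series has the closed
form implemented in :func:`p_true_s1_closed`.

These solutions require the simple regime: all communication probabilities 1,
no targeting, and replications with the same power/false-positive rate as
initial studies.  Outside it, use :mod:`replidyn.dynamics`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .core import ModelParams, TallyDistribution

__all__ = [
    "SeriesOptions",
    "SimpleRegimeError",
    "p_true_series",
    "p_false_series",
    "p_true_s1_closed",
    "steady_state_analytic",
]

# Below r_switch the closed form is 0/0-prone; the series is exact and cheap.
R_SWITCH = 1e-4
_LOG_SPACE_M = 60  # binomial coefficients go to log space above this m


class SimpleRegimeError(ValueError):
    """Parameters fall outside the regime the series solution covers."""


@dataclass(frozen=True)
class SeriesOptions:
    """Truncation control for the geometric–binomial series.

    The binomial factor of every term is at most 1, so the mass remaining
    after the term at ``m`` is bounded by the geometric tail
    ``r^(m-1) / (1-r)``; summation stops once that bound falls below
    ``tail_tolerance`` (or at ``m_max`` terms).
    """

    tail_tolerance: float = 1e-12
    m_max: int = 10_000

    def __post_init__(self) -> None:
        if self.tail_tolerance <= 0:
            raise ValueError("tail_tolerance must be positive")
        if self.m_max < 1:
            raise ValueError("m_max must be at least 1")


def _require_simple_regime(params: ModelParams) -> None:
    if not params.simple_regime:
        raise SimpleRegimeError(
            "series solution requires full communication, r_T=0, equal "
            "replication power/false-positive rate, and r < 1; use the "
            "renewal or time-stepping engine in replidyn.dynamics instead"
        )


def _binom_pmf(m: int, k: int, p: float) -> float:
    # Exact comb for small m; log-space for large m to avoid overflow.
    if p == 0.0:
        return 1.0 if k == 0 else 0.0
    if p == 1.0:
        return 1.0 if k == m else 0.0
    if m <= _LOG_SPACE_M:
        return math.comb(m, k) * p**k * (1.0 - p) ** (m - k)
    logpmf = (
        gammaln(m + 1)
        - gammaln(k + 1)
        - gammaln(m - k + 1)
        + k * math.log(p)
        + (m - k) * math.log1p(-p)
    )
    return float(np.exp(logpmf))


def _series(prefactor: float, p_up: float, r: float, s: int, opts: SeriesOptions) -> float:
    """Sum the series for one tally with up-step probability ``p_up``.

    Only values of ``m`` sharing the parity of ``s`` contribute (the binomial
    index ``(m+s)/2`` must be an integer); other ``m`` are skipped, not
    zeroed by force.
    """
    if prefactor == 0.0:
        return 0.0
    m0 = max(abs(s), 1)
    if (m0 + s) % 2 == 1:
        m0 += 1  # first m with the parity of s (s=0 starts at m=2)
    total = 0.0
    m = m0
    terms = 0
    while terms < opts.m_max:
        geom = r ** (m - 1) if m > 1 else 1.0
        if m > 1 and r < 1.0 and geom / (1.0 - r) < opts.tail_tolerance:
            break
        total += geom * _binom_pmf(m, (m + s) // 2, p_up)
        if r == 0.0:
            break  # only the m=1 term can survive
        m += 2
        terms += 1
    return prefactor * total


def p_true_series(params: ModelParams, s: int, opts: SeriesOptions = SeriesOptions()) -> float:
    """Steady-state mass of TRUE hypotheses at tally ``s`` (per initiated hypothesis)."""
    _require_simple_regime(params)
    return _series(params.b * (1.0 - params.r), params.power_new, params.r, s, opts)


def p_false_series(params: ModelParams, s: int, opts: SeriesOptions = SeriesOptions()) -> float:
    """Steady-state mass of FALSE hypotheses at tally ``s``.

    Same series with the change of variables ``1-beta -> alpha``,
    ``b -> 1-b``.
    """
    _require_simple_regime(params)
    return _series((1.0 - params.b) * (1.0 - params.r), params.alpha_new, params.r, s, opts)


def p_true_s1_closed(params: ModelParams) -> float:
    """Closed form for the true-hypothesis mass at tally ``s = 1``::

        b (1-r) / (2 beta r^2) * ((1 - 4 r^2 beta (1-beta))^(-1/2) - 1)

    Falls back to the series for ``r <= 1e-4`` or ``beta = 0``, where the
    expression degenerates to 0/0 (its limits are ``b(1-beta)`` and
    ``b(1-r)`` respectively, which the series yields directly).
    """
    _require_simple_regime(params)
    beta = 1.0 - params.power_new
    r = params.r
    if r <= R_SWITCH or beta == 0.0:
        return p_true_series(params, 1, SeriesOptions(tail_tolerance=1e-16))
    x = 4.0 * r * r * beta * (1.0 - beta)
    if x >= 1.0:  # unreachable for valid inputs (max 4*1*1/4 < 1 at r<1); guard anyway
        raise FloatingPointError("closed form singular: 4 r^2 beta (1-beta) >= 1")
    return params.b * (1.0 - r) / (2.0 * beta * r * r) * (1.0 / math.sqrt(1.0 - x) - 1.0)


def steady_state_analytic(
    params: ModelParams,
    s_min: int = -30,
    s_max: int = 30,
    opts: SeriesOptions = SeriesOptions(),
) -> TallyDistribution:
    """Full steady-state tally distribution from the series, per tally.

    The lattice is auto-expanded beyond the requested bounds until the mass on
    each boundary bin is below 1e-9 of the total, so no appreciable mass is
    silently dropped; the returned bounds may therefore be wider than
    requested.  Masses sum to 1 over all initiated hypotheses (full
    communication leaves nothing unpublished).
    """
    if s_min > -1 or s_max < 1:
        raise ValueError(f"invalid lattice bounds [{s_min}, {s_max}]")
    _require_simple_regime(params)
    for _ in range(64):
        tallies = np.arange(s_min, s_max + 1)
        mt = np.array([p_true_series(params, int(s), opts) for s in tallies])
        mf = np.array([p_false_series(params, int(s), opts) for s in tallies])
        total = mt.sum() + mf.sum()
        edge = mt[0] + mf[0] + mt[-1] + mf[-1]
        if edge < 1e-9 * max(total, 1e-300):
            break
        s_min -= 10
        s_max += 10
    return TallyDistribution(s_min, s_max, mt, mf, 0.0, 0.0, normalized=True)
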