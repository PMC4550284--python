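"""Precision, sensitivity, and specificity of tallies.

For a steady-state distribution with masses ``p_T(s)`` and ``p_F(s)`` over
published tallies::

    precision(s)   = p_T(s) / (p_T(s) + p_F(s))      Pr(true | s)
    sensitivity(s) = p_T(s) / sum_i p_T(i)           Pr(s | true)
    specificity(s) = p_F(s) / sum_i p_F(i)           Pr(s | false)

Precision doubles as the posterior probability that one particular hypothesis
with tally ``s`` is true.  Denominators run over published tallies only;
unpublished mass is excluded, and since all three quantities are ratios they
are invariant to how the distribution is normalized.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ModelParams, TallyDistribution
from .dynamics import steady_state

__all__ = ["MetricTable", "metric_table", "posterior_true", "write_tsv"]


@dataclass
class MetricTable:
    """Per-tally and cumulative tally metrics.

    ``precision[i]`` etc. refer to tally ``s_min + i``.  Precision is NaN
    ("missing") at tallies with no published mass — a 0/0 there has no
    epistemic meaning.  Optional ``precision_ci`` holds (low, high) percentile
    bounds per tally when estimated from several stochastic runs.
    """

    s_min: int
    s_max: int
    p_true: np.ndarray
    p_false: np.ndarray
    precision: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    aggregated_boundaries: bool = False
    precision_ci: np.ndarray | None = None  # shape (2, n) when present
    extras: dict = field(default_factory=dict)

    @property
    def tallies(self) -> np.ndarray:
        return np.arange(self.s_min, self.s_max + 1)

    def index(self, s: int) -> int:
        if not (self.s_min <= s <= self.s_max):
            raise IndexError(f"tally {s} outside [{self.s_min}, {self.s_max}]")
        return s - self.s_min

    def precision_at(self, s: int) -> float:
        return float(self.precision[self.index(s)])

    def sensitivity_ge(self, k: int) -> float:
        """Cumulative sensitivity Pr(tally >= k | true)."""
        return float(np.nansum(self.sensitivity[self.index(k) :])) if k <= self.s_max else 0.0

    def sensitivity_le(self, k: int) -> float:
        return float(np.nansum(self.sensitivity[: self.index(k) + 1])) if k >= self.s_min else 0.0

    def specificity_ge(self, k: int) -> float:
        return float(np.nansum(self.specificity[self.index(k) :])) if k <= self.s_max else 0.0

    def specificity_le(self, k: int) -> float:
        return float(np.nansum(self.specificity[: self.index(k) + 1])) if k >= self.s_min else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "tally": self.tallies,
                "p_true": self.p_true,
                "p_false": self.p_false,
                "precision": self.precision,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
            }
        )


def metric_table(
    dist: TallyDistribution,
    display_min: int | None = None,
    display_max: int | None = None,
) -> MetricTable:
    """Compute the metric table for a tally distribution.

    Metrics are computed on the full lattice (denominators include every
    published tally).  If a narrower display range is given, masses beyond it
    are folded onto the boundary bins first, mirroring how the distributions
    are plotted; the table is then flagged ``aggregated_boundaries``.
    """
    aggregated = False
    if display_min is not None or display_max is not None:
        display_min = dist.s_min if display_min is None else display_min
        display_max = dist.s_max if display_max is None else display_max
        aggregated = display_min > dist.s_min or display_max < dist.s_max
        dist = dist.aggregated(display_min, display_max)

    mt, mf = dist.mass_true, dist.mass_false
    tot = mt + mf
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(tot > 0, mt / np.where(tot > 0, tot, 1.0), np.nan)
    sum_t, sum_f = mt.sum(), mf.sum()
    if sum_t > 0:
        sensitivity = mt / sum_t
    else:
        warnings.warn("no published true mass: sensitivity undefined", stacklevel=2)
        sensitivity = np.full(mt.shape, np.nan)
    if sum_f > 0:
        specificity = mf / sum_f
    else:
        warnings.warn("no published false mass: specificity undefined", stacklevel=2)
        specificity = np.full(mf.shape, np.nan)
    return MetricTable(
        s_min=dist.s_min,
        s_max=dist.s_max,
        p_true=mt.copy(),
        p_false=mf.copy(),
        precision=precision,
        sensitivity=sensitivity,
        specificity=specificity,
        aggregated_boundaries=aggregated,
    )


def posterior_true(params: ModelParams, s: int, **kw) -> float:
    """Posterior probability that a hypothesis with tally ``s`` is true.

    Computes the steady state via the best applicable engine (analytic
    series, renewal, or time stepping) and returns the precision at ``s``.
    Returns NaN, with a warning, when the tally is unreachable under the
    given parameters (e.g. negative tallies when no negative finding is ever
    communicated).
    """
    lo = min(-30, s - 5)
    hi = max(30, s + 5)
    dist = steady_state(params, s_min=lo, s_max=hi, **kw)
    table = metric_table(dist)
    val = table.precision_at(s)
    if np.isnan(val):
        warnings.warn(
            f"tally {s} carries no published mass under these parameters; "
            "its precision is undefined",
            stacklevel=2,
        )
    return val


def write_tsv(table: MetricTable, path) -> None:
    """Write the fixed-column TSV: tally, p_true, p_false, precision, sensitivity, specificity."""
    df = table.to_frame()
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.12g")
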