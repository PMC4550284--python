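"""Core types: model parameters and tally-lattice distributions.

The model tracks hypotheses by their *tally* — the difference between the
number of published positive and published negative findings.  All engines
(analytic, renewal, time-stepping, stochastic) exchange data through the two
types defined here: :class:`ModelParams`, a validated record of every rate in
the model, and :class:`TallyDistribution`, masses of true and false hypotheses
on a bounded integer lattice of tallies.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, fields, replace
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "ModelParams",
    "TallyDistribution",
    "ValidationError",
    "validate_params",
    "null_model",
    "make_lattice",
    "load_params",
    "save_params",
]


class ValidationError(ValueError):
    """A model parameter is outside its admissible range."""


_PROB_FIELDS = (
    "b",
    "r",
    "power_new",
    "alpha_new",
    "power_rep",
    "alpha_rep",
    "c_new_pos",
    "c_new_neg",
    "c_rep_pos",
    "c_rep_neg",
    "r_T",
)


@dataclass(frozen=True)
class ModelParams:
    """All rates and probabilities of the discovery/replication model.

    Parameters
    ----------
    b
        Base rate: probability a newly investigated hypothesis is true.
        ``b = 0`` is permitted and yields the null model in which every
        published finding concerns a false hypothesis.
    r
        Fraction of research acts that are replications (the rest initiate
        novel hypotheses).
    a, n
        Activity rate and reference pool scale.  Their product ``A = a*n`` is
        the expected number of research acts per time step.  They set the time
        scale only; steady-state tally ratios are invariant to them.
    power_new, alpha_new
        Power ``1 - beta`` and false-positive rate ``alpha`` of an initial
        study: the probabilities that a study of a true (resp. false)
        hypothesis yields a positive finding.  The model assumes
        ``power_new > alpha_new``.
    power_rep, alpha_rep
        The same rates for replication studies.  Default to the initial-study
        values.
    c_new_pos, c_new_neg, c_rep_pos, c_rep_neg
        Communication probabilities: the chance a finding of the given kind
        and sign enters the public record.  Positive novel findings are always
        communicated (``c_new_pos`` is fixed at 1).
    r_T
        Fraction of replication effort confined to hypotheses whose current
        tally lies in ``target_set``; the remainder is allocated uniformly
        over the whole published pool.
    target_set
        Tallies eligible for targeted replication (frozenset of ints).
    """

    b: float
    r: float
    power_new: float
    alpha_new: float
    a: float = 1.0
    n: int = 1
    power_rep: float | None = None
    alpha_rep: float | None = None
    c_new_pos: float = 1.0
    c_new_neg: float = 1.0
    c_rep_pos: float = 1.0
    c_rep_neg: float = 1.0
    r_T: float = 0.0
    target_set: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.power_rep is None:
            object.__setattr__(self, "power_rep", self.power_new)
        if self.alpha_rep is None:
            object.__setattr__(self, "alpha_rep", self.alpha_new)
        object.__setattr__(self, "target_set", frozenset(int(s) for s in self.target_set))
        _check(self)

    # -- derived quantities -------------------------------------------------

    @property
    def acts_per_step(self) -> float:
        """Total research acts per time step, ``A = a*n``."""
        return self.a * self.n

    @property
    def full_communication(self) -> bool:
        return (
            self.c_new_neg == 1.0
            and self.c_rep_pos == 1.0
            and self.c_rep_neg == 1.0
        )

    @property
    def simple_regime(self) -> bool:
        """Full communication, untargeted, equal replication power.

        This is the regime in which the closed-form geometric–binomial series
        solution applies.
        """
        return (
            self.full_communication
            and self.r_T == 0.0
            and self.power_rep == self.power_new
            and self.alpha_rep == self.alpha_new
            and self.r < 1.0
        )

    def asdict(self) -> dict:
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        d["target_set"] = sorted(self.target_set)
        return d

    def replace(self, **kw) -> "ModelParams":
        return replace(self, **kw)


def _check(p: ModelParams) -> None:
    for name in _PROB_FIELDS:
        v = getattr(p, name)
        if not (isinstance(v, (int, float)) and math.isfinite(v) and 0.0 <= v <= 1.0):
            raise ValidationError(f"{name}={v!r} is not a probability in [0, 1]")
    if p.a <= 0:
        raise ValidationError(f"a={p.a!r} must be positive")
    if not (isinstance(p.n, (int, np.integer)) and p.n >= 1):
        raise ValidationError(f"n={p.n!r} must be a positive integer")
    if p.power_new <= p.alpha_new:
        raise ValidationError(
            "power_new must exceed alpha_new: the model assumes a study of a "
            "true hypothesis is more likely to come out positive than a study "
            f"of a false one (1 - beta > alpha); got {p.power_new} <= {p.alpha_new}"
        )
    if p.power_rep <= p.alpha_rep:
        warnings.warn(
            f"power_rep={p.power_rep} <= alpha_rep={p.alpha_rep}: replications "
            "are no more likely to confirm true hypotheses than false ones; "
            "the engines accept this but the regime is scientifically degenerate",
            stacklevel=3,
        )
    if p.c_new_pos != 1.0:
        raise ValidationError(
            "c_new_pos is fixed at 1: positive novel findings are always communicated"
        )
    if p.a * p.n < 1.0:
        raise ValidationError(
            f"a*n={p.a * p.n} < 1: expected acts per step must be at least 1"
        )
    if p.r_T > 0 and not p.target_set:
        raise ValidationError("r_T > 0 requires a non-empty target_set")


def validate_params(raw: ModelParams | Mapping) -> ModelParams:
    """Validate a parameter record (or mapping of field names) and return it.

    Defaults applied: ``a=1``, ``n=1``, ``power_rep=power_new``,
    ``alpha_rep=alpha_new``, ``r_T=0``, all communication probabilities 1.
    Raises :class:`ValidationError` naming the offending field otherwise.
    """
    if isinstance(raw, ModelParams):
        _check(raw)
        return raw
    known = {f.name for f in fields(ModelParams)}
    extra = set(raw) - known
    if extra:
        raise ValidationError(f"unknown parameter(s): {sorted(extra)}")
    return ModelParams(**dict(raw))


def null_model(params: ModelParams) -> ModelParams:
    """Return the same parameters with ``b = 0``.

    With a base rate of zero every hypothesis is false, yet positive findings
    are still produced (at rate alpha) and published; the resulting tally
    distribution is a null distribution of novel findings against which any
    regime with ``b > 0`` can be compared.  Idempotent.
    """
    return params.replace(b=0.0)


# ---------------------------------------------------------------------------
# Tally distributions


@dataclass
class TallyDistribution:
    """Masses of true and false hypotheses per integer tally.

    ``mass_true[i]`` and ``mass_false[i]`` hold the mass at tally
    ``s_min + i``; masses may be probabilities (``normalized=True``, summing
    to at most 1 over all initiated hypotheses) or raw counts.
    ``unpublished_true``/``unpublished_false`` book-keep hypotheses that were
    investigated but whose only finding was never communicated; they carry no
    tally and are excluded from all published-pool denominators.
    """

    s_min: int
    s_max: int
    mass_true: np.ndarray
    mass_false: np.ndarray
    unpublished_true: float = 0.0
    unpublished_false: float = 0.0
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.s_min > -1 or self.s_max < 1:
            raise ValueError(
                f"lattice [{self.s_min}, {self.s_max}] must contain both -1 and 1"
            )
        n = self.s_max - self.s_min + 1
        self.mass_true = np.asarray(self.mass_true, dtype=float)
        self.mass_false = np.asarray(self.mass_false, dtype=float)
        if self.mass_true.shape != (n,) or self.mass_false.shape != (n,):
            raise ValueError("mass arrays do not match lattice size")
        if (
            (self.mass_true < 0).any()
            or (self.mass_false < 0).any()
            or self.unpublished_true < 0
            or self.unpublished_false < 0
        ):
            raise ValueError("masses must be non-negative")

    # -- lattice helpers ----------------------------------------------------

    @property
    def tallies(self) -> np.ndarray:
        return np.arange(self.s_min, self.s_max + 1)

    def index(self, s: int) -> int:
        if not (self.s_min <= s <= self.s_max):
            raise IndexError(f"tally {s} outside lattice [{self.s_min}, {self.s_max}]")
        return s - self.s_min

    def mass_at(self, s: int, true: bool = True) -> float:
        arr = self.mass_true if true else self.mass_false
        return float(arr[self.index(s)])

    # -- aggregate quantities ------------------------------------------------

    @property
    def published_mass(self) -> float:
        return float(self.mass_true.sum() + self.mass_false.sum())

    @property
    def total_mass(self) -> float:
        return self.published_mass + self.unpublished_true + self.unpublished_false

    def normalize(self) -> "TallyDistribution":
        """Return a copy scaled so total initiated mass is 1."""
        tot = self.total_mass
        if tot <= 0:
            raise ValueError("cannot normalize an empty distribution")
        return TallyDistribution(
            self.s_min,
            self.s_max,
            self.mass_true / tot,
            self.mass_false / tot,
            self.unpublished_true / tot,
            self.unpublished_false / tot,
            normalized=True,
        )

    def aggregated(self, display_min: int, display_max: int) -> "TallyDistribution":
        """Fold mass outside ``[display_min, display_max]`` onto the boundary bins.

        Presentation helper: the probability above/below the highest/lowest
        displayed tally is added onto that boundary tally so no mass is hidden.
        """
        if display_min > self.s_min or display_max < self.s_max:
            lo, hi = self.index(display_min), self.index(display_max)
            mt = self.mass_true[lo : hi + 1].copy()
            mf = self.mass_false[lo : hi + 1].copy()
            mt[0] += self.mass_true[:lo].sum()
            mf[0] += self.mass_false[:lo].sum()
            mt[-1] += self.mass_true[hi + 1 :].sum()
            mf[-1] += self.mass_false[hi + 1 :].sum()
        else:
            lo = self.index(max(display_min, self.s_min))
            hi = self.index(min(display_max, self.s_max))
            mt = self.mass_true[lo : hi + 1].copy()
            mf = self.mass_false[lo : hi + 1].copy()
        return TallyDistribution(
            display_min,
            display_max,
            mt,
            mf,
            self.unpublished_true,
            self.unpublished_false,
            normalized=self.normalized,
        )

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "tally": self.tallies,
                "p_true": self.mass_true,
                "p_false": self.mass_false,
            }
        )


def make_lattice(s_min: int, s_max: int) -> TallyDistribution:
    """Zero-mass distribution over the tally lattice ``[s_min, s_max]``.

    Requires ``s_min <= -1`` and ``s_max >= 1`` so both novel-entry tallies
    are representable.
    """
    if s_min > -1 or s_max < 1:
        raise ValueError(f"invalid lattice bounds [{s_min}, {s_max}]")
    n = s_max - s_min + 1
    return TallyDistribution(s_min, s_max, np.zeros(n), np.zeros(n))


# ---------------------------------------------------------------------------
# Config round-trip (flat key/value, JSON-compatible; YAML accepted on read)


def save_params(params: ModelParams, path) -> None:
    with open(path, "w") as fh:
        json.dump(params.asdict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_params(path) -> ModelParams:
    with open(path) as fh:
        text = fh.read()
    try:
        raw = json.loads(text)
    except json.JSONDecodeError:
        # YAML accepted as a superset; note YAML 1.1 requires a decimal point
        # in scientific notation, so JSON is tried first
        import yaml

        raw = yaml.safe_load(text)
    if not isinstance(raw, Mapping):
        raise ValidationError(f"config file {path} is not a flat key/value mapping")
    return validate_params(raw)
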