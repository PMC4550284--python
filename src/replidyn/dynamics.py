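"""General deterministic steady states: renewal and time-stepping engines.

Two routes to the steady-state tally distribution when the closed-form series
of :mod:`replidyn.analytic` does not apply (partial communication, targeted
replication, or replication-specific power):

* :func:`steady_state_renewal` — a per-hypothesis renewal computation.  With
  constant total research activity and uniform selection among a linearly
  growing published pool, the number of replications a published hypothesis
  accumulates is geometric with continuation probability
  ``rho = lam / (1 + lam)``, where ``lam = r / ((1-r) * pi_pub)`` is the mean
  number of replications per published hypothesis and ``pi_pub`` the chance a
  novel investigation yields a communicated first finding.  The tally
  distribution is then a geometric mixture of powers of the per-replication
  transition kernel applied to the entry distribution.  Under full
  communication ``pi_pub = 1`` and ``rho = r``, recovering the series
  solution exactly.  Untargeted only.

* :func:`steady_state_timestep` — an expected-count time-stepping engine that
  mirrors the stochastic simulator act for act, including targeted
  replication.  Ratios converge (like 1/t) to the renewal solution; it is the
  slow-but-general route and the only one that handles ``r_T > 0``.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .analytic import steady_state_analytic
from .core import ModelParams, TallyDistribution

__all__ = [
    "TransitionKernel",
    "NovelInflow",
    "RenewalSolution",
    "PopulationState",
    "TimestepResult",
    "transition_kernel",
    "novel_inflow",
    "steady_state_renewal",
    "steady_state_timestep",
    "steady_state",
]

logger = logging.getLogger(__name__)

BOUNDARY_MASS_TOL = 1e-9  # auto-expand lattices until boundary mass is below this


@dataclass(frozen=True)
class TransitionKernel:
    """Per-replication tally-move probabilities.

    A replicated true hypothesis moves up (tally +1) when the replication is
    positive AND communicated, down when negative AND communicated, and stays
    put when the finding goes uncommunicated; likewise for false hypotheses
    with ``alpha_rep`` in place of ``power_rep``.
    """

    up_true: float
    down_true: float
    stay_true: float
    up_false: float
    down_false: float
    stay_false: float


def transition_kernel(params: ModelParams) -> TransitionKernel:
    up_t = params.power_rep * params.c_rep_pos
    down_t = (1.0 - params.power_rep) * params.c_rep_neg
    up_f = params.alpha_rep * params.c_rep_pos
    down_f = (1.0 - params.alpha_rep) * params.c_rep_neg
    return TransitionKernel(
        up_true=up_t,
        down_true=down_t,
        stay_true=1.0 - up_t - down_t,
        up_false=up_f,
        down_false=down_f,
        stay_false=1.0 - up_f - down_f,
    )


@dataclass(frozen=True)
class NovelInflow:
    """Expected per-step additions from novel investigations.

    Each step spends ``A (1-r)`` acts on novel hypotheses; positive first
    findings (always communicated) enter the published pool at tally +1,
    communicated negative first findings at -1, and uncommunicated negative
    findings leave the hypothesis permanently unpublished.
    """

    true_pos: float
    true_neg: float
    true_unpublished: float
    false_pos: float
    false_neg: float
    false_unpublished: float

    @property
    def published(self) -> float:
        return self.true_pos + self.true_neg + self.false_pos + self.false_neg

    @property
    def total(self) -> float:
        return self.published + self.true_unpublished + self.false_unpublished


def novel_inflow(params: ModelParams) -> NovelInflow:
    rate = params.acts_per_step * (1.0 - params.r)
    b, pw, al, cn = params.b, params.power_new, params.alpha_new, params.c_new_neg
    return NovelInflow(
        true_pos=rate * b * pw,
        true_neg=rate * b * (1.0 - pw) * cn,
        true_unpublished=rate * b * (1.0 - pw) * (1.0 - cn),
        false_pos=rate * (1.0 - b) * al,
        false_neg=rate * (1.0 - b) * (1.0 - al) * cn,
        false_unpublished=rate * (1.0 - b) * (1.0 - al) * (1.0 - cn),
    )


def publication_probability(params: ModelParams) -> float:
    """Chance a novel investigation yields a communicated (published) first finding."""
    b, pw, al, cn = params.b, params.power_new, params.alpha_new, params.c_new_neg
    return b * (pw + (1.0 - pw) * cn) + (1.0 - b) * (al + (1.0 - al) * cn)


def _kernel_step(v: np.ndarray, up: float, down: float, stay: float) -> np.ndarray:
    """One kernel application on a lattice vector; boundary mass is absorbed."""
    out = stay * v
    out[1:] += up * v[:-1]
    out[-1] += up * v[-1]
    out[:-1] += down * v[1:]
    out[0] += down * v[0]
    return out


def _poisson_propagate(
    v: np.ndarray, mu: float, up: float, down: float, stay: float, tail: float = 1e-12
) -> np.ndarray:
    """Expected state after each unit of mass receives Poisson(mu) kernel moves.

    This is the exact one-step expectation of the simulator's within-step
    protocol: replication targets are drawn with replacement against the
    start-of-step pool, so a hypothesis can be hit several times in a step
    and its hit count is Poisson-distributed with its bin's intensity.
    """
    if mu <= 0.0:
        return v.copy()
    w = math.exp(-mu)
    out = w * v
    y = v
    j = 0
    acc = w
    while acc < 1.0 - tail:
        j += 1
        y = _kernel_step(y, up, down, stay)
        w *= mu / j
        out += w * y
        acc += w
        if j > 10_000:  # unreachable for sane intensities; avoid spinning
            break
    return out


@dataclass
class RenewalSolution:
    """Steady state from the renewal (per-published-hypothesis) view."""

    pi_pub: float
    lam: float
    rho: float
    entry_true: dict
    entry_false: dict
    dist: TallyDistribution


def steady_state_renewal(
    params: ModelParams,
    s_min: int = -30,
    s_max: int = 30,
    tol: float = 1e-12,
) -> RenewalSolution:
    """Steady-state tally distribution for arbitrary communication, untargeted.

    Masses are per initiated hypothesis: published bins sum to ``pi_pub`` and
    the unpublished remainder is book-kept separately.  The geometric mixture
    over replication counts is truncated once the tail bound
    ``rho^k / (1-rho)`` drops below ``tol``.
    """
    if params.r_T > 0:
        raise ValueError(
            "renewal engine handles untargeted replication only (r_T=0); "
            "use steady_state_timestep for targeted effort"
        )
    if params.r >= 1.0:
        raise ValueError("r=1 leaves no inflow of novel hypotheses; no steady state")
    pi_pub = publication_probability(params)
    lam = params.r / ((1.0 - params.r) * pi_pub) if pi_pub > 0 else 0.0
    if lam > 1000.0:
        raise ValueError(
            f"mean replications per published hypothesis is {lam:.3g}: almost "
            "nothing is ever published and tallies diverge; this regime has no "
            "computable bounded-lattice steady state"
        )
    rho = lam / (1.0 + lam)
    kern = transition_kernel(params)

    # number of mixture terms needed for the requested tail bound
    if rho > 0:
        k_max = int(math.ceil((math.log(tol) + math.log1p(-rho)) / math.log(rho))) + 1
    else:
        k_max = 1
    half = min(k_max + 2, 4000)
    lo, hi = min(s_min, -half), max(s_max, half)
    width = hi - lo + 1
    b, pw, al, cn = params.b, params.power_new, params.alpha_new, params.c_new_neg
    entry_true = {1: b * pw, -1: b * (1.0 - pw) * cn}
    entry_false = {1: (1.0 - b) * al, -1: (1.0 - b) * (1.0 - al) * cn}

    acc_t = np.zeros(width)
    acc_f = np.zeros(width)
    vt = np.zeros(width)
    vf = np.zeros(width)
    for s, m in entry_true.items():
        vt[s - lo] = m
    for s, m in entry_false.items():
        vf[s - lo] = m
    w = 1.0 - rho
    for _ in range(k_max + 1):
        acc_t += w * vt
        acc_f += w * vf
        w *= rho
        if rho == 0.0 or w / (1.0 - rho) < tol * (1.0 - rho):
            break
        vt = _kernel_step(vt, kern.up_true, kern.down_true, kern.stay_true)
        vf = _kernel_step(vf, kern.up_false, kern.down_false, kern.stay_false)

    unpub_t = b * (1.0 - pw) * (1.0 - cn)
    unpub_f = (1.0 - b) * (1.0 - al) * (1.0 - cn)
    dist = _trim(acc_t, acc_f, lo, hi, s_min, s_max, unpub_t, unpub_f)
    return RenewalSolution(pi_pub, lam, rho, entry_true, entry_false, dist)


def _trim(
    mt: np.ndarray,
    mf: np.ndarray,
    lo: int,
    hi: int,
    s_min: int,
    s_max: int,
    unpub_t: float,
    unpub_f: float,
) -> TallyDistribution:
    """Shrink a wide internal lattice toward the requested bounds.

    Bounds are expanded past the request until the mass lying beyond them is
    below ``BOUNDARY_MASS_TOL`` of the total; that residue is folded onto the
    boundary bins so nothing is lost.
    """
    total = mt.sum() + mf.sum() + unpub_t + unpub_f
    cut = BOUNDARY_MASS_TOL * max(total, 1e-300)
    both = mt + mf
    lo2, hi2 = s_min, s_max
    while lo2 > lo and both[: lo2 - lo].sum() >= cut:
        lo2 -= 1
    while hi2 < hi and both[hi2 - lo + 1 :].sum() >= cut:
        hi2 += 1
    i, j = lo2 - lo, hi2 - lo
    out_t, out_f = mt[i : j + 1].copy(), mf[i : j + 1].copy()
    out_t[0] += mt[:i].sum()
    out_f[0] += mf[:i].sum()
    out_t[-1] += mt[j + 1 :].sum()
    out_f[-1] += mf[j + 1 :].sum()
    return TallyDistribution(lo2, hi2, out_t, out_f, unpub_t, unpub_f, normalized=True)


@dataclass
class PopulationState:
    """Expected counts of hypotheses by tally and truth after time stepping."""

    step: int
    s_min: int
    s_max: int
    mass_true: np.ndarray
    mass_false: np.ndarray
    unpublished_true: float
    unpublished_false: float
    cumulative_initiated: float
    cumulative_published: float
    converged: bool
    notes: list = field(default_factory=list)


@dataclass
class TimestepResult:
    state: PopulationState
    dist: TallyDistribution
    cohort_dist: TallyDistribution | None = None

    @property
    def converged(self) -> bool:
        return self.state.converged


def steady_state_timestep(
    params: ModelParams,
    s_min: int = -30,
    s_max: int = 30,
    n_steps: int = 200_000,
    tol: float = 1e-8,
    checkpoint: int = 50,
    init: TallyDistribution | None = None,
    cohort_from_step: int | None = None,
) -> TimestepResult:
    """Evolve expected counts step by step until the tally ratios settle.

    Each step spends a CONSTANT total of ``A = a*n`` research acts: ``A*r``
    replications and ``A*(1-r)`` novel investigations.  Untargeted
    replication effort is spread uniformly over the whole published pool
    (per-hypothesis intensity ``A*r*(1-r_T)/N``); targeted effort uniformly
    over pool members whose tally is in ``target_set`` (``A*r*r_T/N_T``).
    Convergence is declared when the max per-tally change in precision and
    sensitivity between checkpoints (every ``checkpoint`` steps) falls below
    ``tol``; hitting ``n_steps`` first is reported via ``converged=False``.

    ``init`` seeds the published pool with an arbitrary starting population
    (the steady ratios are independent of it).  ``cohort_from_step`` also
    tracks, and returns as ``cohort_dist``, the sub-population initiated at
    or after that step; these late cohorts see only small per-step
    replication intensities, so their expected-count dynamics match the
    stochastic simulator closely even at short horizons, which makes the
    cohort distribution the right object for finite-run cross-validation.
    """
    kern = transition_kernel(params)
    inflow = novel_inflow(params)
    A = params.acts_per_step
    rep_effort = A * params.r

    # generous internal lattice; boundary residue is checked at the end
    pi_pub = publication_probability(params)
    lam = params.r / ((1.0 - params.r) * pi_pub) if (params.r < 1 and pi_pub > 0) else 1.0
    rho = lam / (1.0 + lam)
    pad = 20
    if 0 < rho < 1:
        pad = max(pad, min(1500, int(math.log(1e-14) / math.log(rho)) + 10))
    lo, hi = s_min - pad, s_max + pad
    width = hi - lo + 1
    mt = np.zeros(width)
    mf = np.zeros(width)
    unpub_t = unpub_f = 0.0
    initiated = 0.0
    if init is not None:
        mt[init.s_min - lo : init.s_max - lo + 1] += init.mass_true
        mf[init.s_min - lo : init.s_max - lo + 1] += init.mass_false
        unpub_t += init.unpublished_true
        unpub_f += init.unpublished_false
        initiated += init.total_mass

    track_cohort = cohort_from_step is not None
    ct = np.zeros(width)
    cf = np.zeros(width)
    cohort_unpub_t = cohort_unpub_f = 0.0
    cohort_initiated = 0.0

    target_idx = None
    if params.r_T > 0:
        target_idx = np.array(sorted(params.target_set)) - lo
        target_idx = target_idx[(target_idx >= 0) & (target_idx < width)]
    notes: list[str] = []
    capped_warned = fallback_warned = False
    prev_prec = prev_sens = None
    converged = False
    step = 0
    wasted_replication = 0.0

    for step in range(1, n_steps + 1):
        N = mt.sum() + mf.sum()
        mu_u = mu_t = 0.0
        if N > 0:
            untargeted = rep_effort * (1.0 - params.r_T)
            targeted = rep_effort * params.r_T
            if targeted > 0:
                NT = mt[target_idx].sum() + mf[target_idx].sum()
                if NT > 0:
                    mu_t = targeted / NT
                else:
                    untargeted += targeted  # empty target bins: effort reverts to uniform
                    if not fallback_warned:
                        logger.info("target set unoccupied; targeted effort falls back to uniform")
                        notes.append("targeted effort fell back to uniform (empty target bins)")
                        fallback_warned = True
            mu_u = untargeted / N
            if mu_u + mu_t > 50.0:
                # start-up only: a near-empty pool would absorb absurd effort
                if not capped_warned:
                    logger.warning("per-hypothesis replication intensity capped at 50")
                    notes.append("replication intensity capped on some start-up steps")
                    capped_warned = True
                scale = 50.0 / (mu_u + mu_t)
                mu_u *= scale
                mu_t *= scale
        else:
            wasted_replication += rep_effort

        # replication moves: each unit of mass receives a Poisson number of
        # kernel applications set by its start-of-step bin's intensity
        # (uncommunicated findings are the kernel's stay mass)
        if mu_u > 0.0 or mu_t > 0.0:
            pairs = [(kern.up_true, kern.down_true, kern.stay_true, (mt, ct)),
                     (kern.up_false, kern.down_false, kern.stay_false, (mf, cf))]
            outputs = []
            for up, down, stay, (pop, coh) in pairs:
                vecs = (pop, coh) if track_cohort else (pop,)
                done = []
                for v in vecs:
                    if mu_t > 0.0:
                        in_target = np.zeros_like(v)
                        in_target[target_idx] = v[target_idx]
                        rest = v - in_target
                        new = _poisson_propagate(rest, mu_u, up, down, stay)
                        new += _poisson_propagate(in_target, mu_u + mu_t, up, down, stay)
                    else:
                        new = _poisson_propagate(v, mu_u, up, down, stay)
                    done.append(new)
                outputs.append(done)
            mt = outputs[0][0]
            mf = outputs[1][0]
            if track_cohort:
                ct = outputs[0][1]
                cf = outputs[1][1]

        # novel inflow
        mt[1 - lo] += inflow.true_pos
        mt[-1 - lo] += inflow.true_neg
        mf[1 - lo] += inflow.false_pos
        mf[-1 - lo] += inflow.false_neg
        unpub_t += inflow.true_unpublished
        unpub_f += inflow.false_unpublished
        initiated += inflow.total
        if track_cohort and step >= cohort_from_step:
            ct[1 - lo] += inflow.true_pos
            ct[-1 - lo] += inflow.true_neg
            cf[1 - lo] += inflow.false_pos
            cf[-1 - lo] += inflow.false_neg
            cohort_unpub_t += inflow.true_unpublished
            cohort_unpub_f += inflow.false_unpublished
            cohort_initiated += inflow.total

        if step % checkpoint == 0:
            tot = mt + mf
            with np.errstate(invalid="ignore", divide="ignore"):
                prec = np.where(tot > 0, mt / np.where(tot > 0, tot, 1.0), np.nan)
                sens = mt / mt.sum() if mt.sum() > 0 else np.full(width, np.nan)
            if prev_prec is not None:
                d1 = np.nanmax(np.abs(prec - prev_prec)) if np.isfinite(prec).any() else 0.0
                d2 = np.nanmax(np.abs(sens - prev_sens)) if np.isfinite(sens).any() else 0.0
                if max(d1, d2) < tol:
                    converged = True
                    break
            prev_prec, prev_sens = prec, sens

    if not converged:
        warnings.warn(
            f"time-stepping engine did not converge to tol={tol} within "
            f"{n_steps} steps; returning the state reached",
            stacklevel=2,
        )
        notes.append(f"not converged within {n_steps} steps")
    if wasted_replication:
        notes.append(
            f"{wasted_replication:g} replication acts fell on an empty pool (start-up)"
        )

    scale = initiated if initiated > 0 else 1.0
    dist = _trim(mt / scale, mf / scale, lo, hi, s_min, s_max, unpub_t / scale, unpub_f / scale)
    state = PopulationState(
        step=step,
        s_min=lo,
        s_max=hi,
        mass_true=mt,
        mass_false=mf,
        unpublished_true=unpub_t,
        unpublished_false=unpub_f,
        cumulative_initiated=initiated,
        cumulative_published=mt.sum() + mf.sum(),
        converged=converged,
        notes=notes,
    )
    cohort = None
    if track_cohort and cohort_initiated > 0:
        cohort = _trim(
            ct / cohort_initiated,
            cf / cohort_initiated,
            lo,
            hi,
            s_min,
            s_max,
            cohort_unpub_t / cohort_initiated,
            cohort_unpub_f / cohort_initiated,
        )
    return TimestepResult(state=state, dist=dist, cohort_dist=cohort)


def steady_state(params: ModelParams, s_min: int = -30, s_max: int = 30, engine: str = "auto", **kw) -> TallyDistribution:
    """Steady-state distribution via the best applicable engine.

    ``auto`` prefers the analytic series (simple regime), then the renewal
    engine (untargeted), then time stepping (fully general).
    """
    if engine == "auto":
        if params.simple_regime:
            engine = "analytic"
        elif params.r_T == 0 and params.r < 1.0:
            engine = "renewal"
        else:
            engine = "timestep"
    if engine == "analytic":
        return steady_state_analytic(params, s_min, s_max, **kw)
    if engine == "renewal":
        return steady_state_renewal(params, s_min, s_max, **kw).dist
    if engine == "timestep":
        return steady_state_timestep(params, s_min, s_max, **kw).dist
    raise ValueError(f"unknown engine {engine!r}")
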