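# Methods

## The model

A population of researchers investigates hypotheses in discrete time steps.
Each step spends a constant total of `A = a·n` research acts.  An act is a
replication with probability `r` — the target drawn uniformly (with
replacement) from the *published pool*, the hypotheses with at least one
communicated finding — and otherwise initiates a novel hypothesis, true with
base rate `b`.  A study of a true hypothesis yields a positive finding with
power `1−β` (`1−β_R` for replications); of a false one, with false-positive
rate `α` (`α_R`).  Findings enter the record with sign- and type-specific
communication probabilities: positive novel findings always (`c_N+ = 1`),
negative novel findings with `c_N−`, positive/negative replications with
`c_R+`/`c_R−`.  Only communicated findings move a hypothesis's tally
`s` (= published positives − published negatives); a hypothesis whose only
finding goes uncommunicated leaves the system permanently and is book-kept
as unpublished mass.  Optionally a fraction `r_T` of replication effort is
confined to hypotheses whose current tally lies in a target set, spread
uniformly over them.

Because study outcomes depend only on a hypothesis's truth, each replication
moves the tally +1 with probability `(1−β_R)c_R+` (true) or `α_R c_R+`
(false), −1 with `β_R c_R−` / `(1−α_R)c_R−`, else leaves it unchanged — a
biased lazy random walk, with truth setting the drift.  Replication
therefore acts like chromatography: false hypotheses drift toward negative
tallies faster than true ones drift positive (since `1−α > 1−β`), and
the communication probabilities tune the two diffusion rates separately.

The population never reaches a fixed population; it grows linearly.  What
converges are the *proportions* of true/false hypotheses per tally, and all
steady-state quantities here are those limiting proportions.  They are
equally readable as posterior probabilities for a single hypothesis given
its tally, so heterogeneous parameter values across hypotheses do not
invalidate the per-hypothesis reading.

## Engines

**Analytic series** (`replidyn.analytic`) — full communication, untargeted,
equal replication power.  The number of findings per hypothesis is geometric
(`P(m) = (1−r) r^(m−1)`: each subsequent act that touches the hypothesis is
a replication), findings are i.i.d. positive with probability `1−β` (true)
or `α` (false), and the tally after `m` findings with `k` positives is
`2k − m`.  The per-tally mass is a geometric series of binomial
probabilities, truncated when the geometric tail bound `r^(m−1)/(1−r)`
drops below `tail_tolerance` (default 1e−12; the binomial factor is ≤ 1 so
the bound is certified).  Binomial coefficients move to log space above
`m = 60`.  At `s = 1` a closed form exists; it is evaluated via the series
below `r = 1e−4` and at `β = 0`, where the expression degenerates to 0/0
while its limit is regular.

**Renewal engine** (`steady_state_renewal`) — arbitrary communication,
untargeted.  With constant total activity and uniform selection from a pool
growing linearly at rate `∝ π_pub` (the probability a novel investigation
produces a communicated first finding), a hypothesis born at fraction `u` of
a long run accumulates Poisson(`λ ln(1/u)`) replications, where
`λ = r/((1−r)π_pub)` is the mean replication load per published hypothesis.
Mixing `u` uniformly over (0,1) gives exactly a geometric count law with
continuation `ρ = λ/(1+λ)`; under full communication `π_pub = 1` and
`ρ = r`, recovering the series.  The tally distribution is the geometric
mixture of powers of the per-replication kernel applied to the entry
distribution (tally +1 with the positive first-finding mass, −1 with the
communicated-negative mass), truncated when `ρ^k/(1−ρ) < tol`.  Regimes with
`λ > 1000` are rejected: essentially nothing is published and tallies
spread without bound, so no bounded lattice holds the steady state.

**Time-stepping engine** (`steady_state_timestep`) — fully general,
including targeting; the expected-count mirror of the simulator.  Per step,
per-hypothesis replication intensities are `μ_u = A·r(1−r_T)/N` on the whole
pool and additionally `μ_t = A·r·r_T/N_T` on target bins (falling back to
uniform when the target bins are empty).  Each unit of mass then receives a
*Poisson(μ)* number of kernel moves — the exact expectation of the
simulator's protocol, in which targets are drawn with replacement against
the start-of-step pool, so one hypothesis can be hit several times per step.
A single-move Bernoulli update differs from this by a persistent O(μ²)
displacement bias that is material under heavy targeting; the Poisson
propagator removes it.  Intensities are capped at 50 (with a logged note)
only for the near-empty-pool start-up.  Novel inflow joins the pool at the
end of each step.  Convergence is declared when per-tally precision and
sensitivity change by less than `tol` (default 1e−8) between checkpoints 50
steps apart; hitting the step cap (default 200,000) is reported, never
silent.  Ratios converge like 1/t, so per-tally agreement with the analytic
limit at 1e−6 needs ~2×10⁵ steps.  The engine can also track the
sub-population initiated after a given step (`cohort_from_step`); those late
cohorts see only small intensities, making the cohort distribution the right
object for cross-validating the simulator at short horizons.

**Stochastic simulator** (`replidyn.simulate`) — seeded, vectorised per
step: act types are drawn per act (`round(A)` acts per step, deterministic
count), replications select targets (with replacement) from the
start-of-step pool, outcomes and communication are drawn per act, and novel
entries join the pool at the end of the step.  Draw order (act types →
replication target/finding/communication → novel truth/finding/
communication) is fixed, so runs are bit-reproducible per seed within this
implementation.  Replications drawn against an empty pool become novel acts
(counted).

## Lattice conventions

Computation lattices are auto-sized: internal bounds are padded by the
expected tally spread, boundary bins absorb (never drop) escaping mass, and
returned distributions are expanded beyond the requested bounds until less
than 1e−9 of the total mass lies outside, any residue being folded onto the
boundary bins.  Folding whole tails onto displayed boundary tallies is a
*presentation* operation (`TallyDistribution.aggregated`, mirroring how the
distributions are plotted); metrics are always computed on the full lattice
first.  Precision at an unoccupied tally is reported missing (NaN), not 0 or
1 — a 0/0 carries no epistemic content.  Sensitivity and specificity
denominators run over published tallies only; unpublished mass is tracked
but excluded, and since all three metrics are ratios they are independent of
the normalisation convention.

## Estimating steady states from finite runs

Simulator estimates use the *cumulative* population of a run.  The
early-run transient (tiny pool, high per-capita intensity) dilutes as
O(1/T), so long runs with no burn-in discard are the consistent estimator of
the steady proportions.  Discarding early *cohorts* is deliberately **off by
default** (`discard_fraction = 0`): the replication count of a hypothesis
born at run fraction `u` is Poisson(`λ ln(1/u)`), and the geometric count
law arises precisely from mixing `u` over the whole of (0,1); dropping early
cohorts removes the high-count tail and visibly biases the distribution
(e.g. at `λ ≈ 4.9`, the zero-replication share inflates from 0.169 to 0.187
with a 10% discard).  Cohort filtering *is* the right tool for one job —
comparing the simulator against the time-stepping engine at a matched finite
horizon, where both can track the same late cohort exactly — and the tests
use it that way.  Cross-engine agreement is asserted within 3 across-seed
standard errors of an 8-run mean (not per-bin binomial SEs, which badly
understate the variance of target-bin occupancy under heavy targeting),
plus a 5e−4 allowance for the deterministic engine's own finite-horizon
error.

## Problem sizes used in the tests

Deterministic checks run the series/renewal engines at tolerance 1e−12 to
1e−14 and the time-stepping engine to 1e5–2e5 steps.  Stochastic checks use
populations of roughly 5×10⁴–1.5×10⁵ published hypotheses per run (8–16
independent seeds), sizes at which the targeted-regime comparisons are
dominated by sampling noise rather than residual finite-horizon bias.

## Scenario catalogue

`builtin_scenarios()` encodes the communication regimes (only-positives,
only-negative-replications, suppressed-novel-negatives, full communication,
and a 20%-positive-replication variant), the targeted-replication settings,
and the differential-power settings (weak initial studies with strong
replications and vice versa, each with a suppressed-negative-replication
variant), plus "optimistic" and "pessimistic" research climates.  Two
details are not pinned down numerically anywhere and are flagged
non-canonical in the scenario notes: the climates' communication rates
(chosen all-1 optimistic; `c_N− = c_R− = 0.2`, `c_R+ = 0.5` pessimistic) and
the targeted scenarios' target ranges (read off shaded plot regions as
{1,2,3}, plus tally 0 in the wide variant).

## Known limitations

- Hypotheses are binary true/false; effect sizes, researcher bias, multiple
  testing, and incentive dynamics are out of scope.
- The renewal argument requires uniform selection within the pool; it does
  not cover targeting (`steady_state_timestep` does).
- The analytic/renewal solutions are long-run limits; real literatures are
  finite and young, and the simulator is the tool for such questions.
- Regimes where almost nothing is published (`λ > 1000`) have unbounded
  tally spread and are rejected rather than truncated.
- The simulator stores every published hypothesis; runs beyond ~10⁷
  published hypotheses are memory-hungry.
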