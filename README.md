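# replidyn

**Population dynamics of scientific discovery, replication, and selective
communication.**

How believable is a research finding, given only the published record?  In
many fields the public evidence about a hypothesis reduces to a *tally*: the
number of published positive findings minus the number of published negative
ones.  `replidyn` implements a population model of science in which

- each research act either initiates a **novel** hypothesis (probability
  `1−r`) or **replicates** one drawn at random from the published pool
  (probability `r`);
- a novel hypothesis is **true** with base rate `b`; a study of a true
  hypothesis comes out positive with power `1−β`, a study of a false one
  with false-positive rate `α` (replications may have their own `1−β_R`,
  `α_R`);
- each finding is **communicated** with a sign- and type-specific
  probability (`c_N−`, `c_R+`, `c_R−`; positive novel findings always appear),
  and only communicated findings move the tally;
- optionally, a fraction `r_T` of replication effort is **targeted** at
  hypotheses whose tally lies in a chosen set.

The model answers, for any parameter regime: *what fraction of hypotheses
with tally s are true?*  (the **precision** `Pr(true | s)`, equally readable
as a posterior probability for one hypothesis), and where the true and false
hypotheses sit (**sensitivity** `Pr(s | true)` and **specificity**
`Pr(s | false)`).

Under full communication the steady-state masses have a closed series form

```
p_T(s) = b(1−r) Σ_m  r^(m−1) · C(m, (m+s)/2) · (1−β)^((m+s)/2) · β^((m−s)/2)
```

(sum over m ≥ |s| with the parity of s; the false-side masses follow by
`1−β → α`, `b → 1−b`), with a closed form at `s = 1`.  Partial communication
is solved exactly by a renewal argument — the number of replications per
published hypothesis is geometric with continuation `ρ = λ/(1+λ)`,
`λ = r/((1−r)·π_pub)` — and arbitrary regimes (including targeting) by an
expected-count time-stepping engine.  A seeded stochastic simulator provides
the finite-population ground truth all deterministic engines are validated
against.

## Worked example

Suppressing novel negative findings while communicating every replication
(base rate 0.001, replication rate 0.2, power 0.8, α = 0.05) purifies the
positive tallies:

```
$ python examples/communication_regimes.py
regime          precision(3)  sens(>=3)  meaning
fig3a                  0.062      0.636  only positive findings ever published
fig3b                    nan      0.000  only negative replications published
fig3c                  0.862      0.549  novel negatives suppressed, replications fully published
fig3d                  0.807      0.020  everything published

With both replication channels open (third row), a tally of 3 is true
>80% of the time and holds over half of all published true hypotheses:
downward diffusion of false hypotheses purifies the positive tallies.
```

A tally of +3 in the third regime is true 86% of the time even though only
1 in 1000 novel hypotheses is true — false hypotheses diffuse downward
(rate `(1−α)c_R−`) faster than true ones diffuse upward (rate `(1−β)c_R+`),
so replication acts as a separation column for truth.  With only positive
findings published (first row) a tally of 3 is still mostly false; with only
negative replications published (second row) a tally of 3 is unreachable
(`nan`); with everything published (fourth row) precision is high but almost
no true hypothesis ever reaches a tally of 3, because replication effort is
swamped by following up novel negatives.  Other examples cover the
posterior-by-tally calculator, targeted replication, and stochastic
cross-validation (`examples/`).

The same results are available from the shell:

```sh
replidyn steady --scenario fig3c --out fig3c.tsv
replidyn posterior --scenario fig3c --tally 3
replidyn simulate --scenario fig3d --seed 1 --steps 2000 --set a=500
replidyn sweep --scenario optimistic --param b --grid 1e-4,1e-3,1e-2,0.1
```

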