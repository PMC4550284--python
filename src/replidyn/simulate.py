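"""Seeded finite-population Monte Carlo simulator of the discovery cycle.

Each time step executes ``round(a*n)`` research acts.  Every act is a
replication with probability ``r`` (targeted with probability ``r_T`` when a
target set is given), otherwise a novel investigation whose hypothesis is
true with probability ``b``.  Findings are drawn with the act-appropriate
power / false-positive rate, communicated with the act-and-sign-appropriate
communication probability, and communicated findings adjust tallies.  The
simulator is the ground-truth oracle for the deterministic engines: its
tally proportions converge to theirs by the law of large numbers.

Acts within one step are vectorised: replication targets are drawn (with
replacement) against the published pool as it stood at the start of the
step, and hypotheses initiated during a step join the pool only at its end
(exactly as the expected-count engine orders its update).  Per-act draw
order within a step is: act types, then replication
targets/findings/communication, then novel-act truths/findings/
communication.  Runs are bit-reproducible for a given seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .core import ModelParams, TallyDistribution
from .metrics import MetricTable, metric_table

__all__ = [
    "SimResult",
    "simulate",
    "estimate_metrics",
    "mean_investigations_published",
]


@dataclass
class SimResult:
    """Outcome of one seeded run.

    ``tally``, ``is_true``, ``reps`` and ``birth_step`` are aligned arrays
    over published hypotheses (those with a communicated first finding);
    hypotheses whose only finding went uncommunicated are counted in
    ``uncommunicated_novel_{true,false}`` only.
    """

    seed: int
    n_steps: int
    params: ModelParams
    tally: np.ndarray
    is_true: np.ndarray
    reps: np.ndarray
    birth_step: np.ndarray
    acts_novel: int
    acts_replication: int
    acts_targeted: int
    acts_fallback_novel: int  # replication drawn with an empty pool
    acts_target_fallback: int  # targeted act with empty target bins
    uncommunicated_novel_true: int
    uncommunicated_novel_false: int
    uncommunicated_rep: int
    initiated: int
    time_series: list = field(default_factory=list)

    @property
    def published(self) -> int:
        return self.tally.size

    def distribution(self, discard_fraction: float = 0.0) -> TallyDistribution:
        """Published counts per (tally, truth) as a TallyDistribution.

        ``discard_fraction`` drops hypotheses initiated during that initial
        fraction of the run (see the methods note for why the default is 0).
        """
        keep = self.birth_step >= discard_fraction * self.n_steps
        tal, tru = self.tally[keep], self.is_true[keep]
        if tal.size == 0:
            raise ValueError("no published hypotheses retained")
        lo, hi = min(int(tal.min()), -1), max(int(tal.max()), 1)
        nt = np.bincount(tal[tru] - lo, minlength=hi - lo + 1).astype(float)
        nf = np.bincount(tal[~tru] - lo, minlength=hi - lo + 1).astype(float)
        frac = 1.0 if discard_fraction == 0.0 else keep.mean()
        return TallyDistribution(
            lo,
            hi,
            nt,
            nf,
            unpublished_true=self.uncommunicated_novel_true * frac,
            unpublished_false=self.uncommunicated_novel_false * frac,
            normalized=False,
        )

    def investigation_histogram(self) -> np.ndarray:
        """Histogram of replication counts over published hypotheses."""
        return np.bincount(self.reps)

    def to_json(self, path) -> None:
        d = self.distribution()
        payload = {
            "seed": self.seed,
            "n_steps": self.n_steps,
            "params": self.params.asdict(),
            "initiated": self.initiated,
            "published": self.published,
            "acts": {
                "novel": self.acts_novel,
                "replication": self.acts_replication,
                "targeted": self.acts_targeted,
                "fallback_novel": self.acts_fallback_novel,
                "target_fallback": self.acts_target_fallback,
            },
            "uncommunicated": {
                "novel_true": self.uncommunicated_novel_true,
                "novel_false": self.uncommunicated_novel_false,
                "replication": self.uncommunicated_rep,
            },
            "tallies": d.tallies.tolist(),
            "count_true": d.mass_true.tolist(),
            "count_false": d.mass_false.tolist(),
            "investigation_histogram": self.investigation_histogram().tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")


def simulate(
    params: ModelParams,
    n_steps: int,
    seed: int,
    record_every: int = 0,
) -> SimResult:
    """Run the stochastic model for ``n_steps`` steps with the given seed.

    ``record_every > 0`` appends ``(step, published, n_true_published)`` to
    the result's time series at that cadence.
    """
    rng = np.random.default_rng(seed)
    A = int(round(params.acts_per_step))
    p = params
    targets = np.array(sorted(p.target_set), dtype=np.int64) if p.target_set else None

    cap = 1024
    tally = np.zeros(cap, dtype=np.int64)
    is_true = np.zeros(cap, dtype=bool)
    reps = np.zeros(cap, dtype=np.int64)
    birth = np.zeros(cap, dtype=np.int64)
    n_pub = 0

    acts_novel = acts_rep = acts_targeted = 0
    fallback_novel = target_fallback = 0
    unc_novel_t = unc_novel_f = unc_rep = 0
    initiated = 0
    series: list[tuple[int, int, int]] = []

    def grow(extra: int) -> None:
        nonlocal cap, tally, is_true, reps, birth
        need = n_pub + extra
        if need > cap:
            cap = max(cap * 2, need)
            tally = np.resize(tally, cap)
            is_true = np.resize(is_true, cap)
            reps = np.resize(reps, cap)
            birth = np.resize(birth, cap)

    for step in range(1, n_steps + 1):
        rep_mask = rng.random(A) < p.r
        n_rep = int(rep_mask.sum())
        n_nov = A - n_rep
        if n_rep and n_pub == 0:
            fallback_novel += n_rep  # nothing to replicate yet
            n_nov += n_rep
            n_rep = 0

        # replications first, against the pool as it stood at the start of
        # the step: hypotheses initiated this step are not yet replicable
        if n_rep:
            acts_rep += n_rep
            if targets is not None and p.r_T > 0:
                targ_mask = rng.random(n_rep) < p.r_T
                pool_t = np.flatnonzero(np.isin(tally[:n_pub], targets))
                n_t = int(targ_mask.sum())
                if n_t and pool_t.size:
                    acts_targeted += n_t
                else:
                    if n_t:
                        target_fallback += n_t
                    targ_mask[:] = False
                    n_t = 0
                idx = np.empty(n_rep, dtype=np.int64)
                if n_t:
                    idx[targ_mask] = pool_t[rng.integers(0, pool_t.size, n_t)]
                idx[~targ_mask] = rng.integers(0, n_pub, n_rep - n_t)
            else:
                idx = rng.integers(0, n_pub, n_rep)
            tru = is_true[idx]
            pos = np.where(tru, rng.random(n_rep) < p.power_rep, rng.random(n_rep) < p.alpha_rep)
            comm = np.where(pos, rng.random(n_rep) < p.c_rep_pos, rng.random(n_rep) < p.c_rep_neg)
            unc_rep += int((~comm).sum())
            delta = np.where(comm, np.where(pos, 1, -1), 0)
            np.add.at(tally, idx, delta)
            np.add.at(reps, idx, 1)

        # novel investigations enter the pool at the end of the step
        if n_nov:
            acts_novel += n_nov
            initiated += n_nov
            tru = rng.random(n_nov) < p.b
            pos = np.where(tru, rng.random(n_nov) < p.power_new, rng.random(n_nov) < p.alpha_new)
            comm = pos | (rng.random(n_nov) < p.c_new_neg)
            unc = ~comm
            unc_novel_t += int((unc & tru).sum())
            unc_novel_f += int((unc & ~tru).sum())
            k = int(comm.sum())
            if k:
                grow(k)
                sl = slice(n_pub, n_pub + k)
                tally[sl] = np.where(pos[comm], 1, -1)
                is_true[sl] = tru[comm]
                reps[sl] = 0
                birth[sl] = step
                n_pub += k

        if record_every and step % record_every == 0:
            series.append((step, n_pub, int(is_true[:n_pub].sum())))

    return SimResult(
        seed=seed,
        n_steps=n_steps,
        params=params,
        tally=tally[:n_pub].copy(),
        is_true=is_true[:n_pub].copy(),
        reps=reps[:n_pub].copy(),
        birth_step=birth[:n_pub].copy(),
        acts_novel=acts_novel,
        acts_replication=acts_rep,
        acts_targeted=acts_targeted,
        acts_fallback_novel=fallback_novel,
        acts_target_fallback=target_fallback,
        uncommunicated_novel_true=unc_novel_t,
        uncommunicated_novel_false=unc_novel_f,
        uncommunicated_rep=unc_rep,
        initiated=initiated,
        time_series=series,
    )


def estimate_metrics(
    results: "list[SimResult]",
    discard_fraction: float = 0.0,
    ci: tuple[float, float] = (2.5, 97.5),
) -> MetricTable:
    """Metric estimates pooled over runs, with percentile CIs across seeds.

    Point estimates come from the pooled counts of all runs; with at least 8
    independent seeds, per-tally precision confidence intervals are attached
    as the across-seed percentiles given by ``ci``.
    """
    if not results:
        raise ValueError("need at least one SimResult")
    dists = [res.distribution(discard_fraction) for res in results]
    lo = min(d.s_min for d in dists)
    hi = max(d.s_max for d in dists)
    width = hi - lo + 1
    mt = np.zeros(width)
    mf = np.zeros(width)
    per_seed_prec = np.full((len(dists), width), np.nan)
    for i, d in enumerate(dists):
        sl = slice(d.s_min - lo, d.s_max - lo + 1)
        mt[sl] += d.mass_true
        mf[sl] += d.mass_false
        tot = d.mass_true + d.mass_false
        with np.errstate(invalid="ignore", divide="ignore"):
            per_seed_prec[i, sl] = np.where(tot > 0, d.mass_true / np.where(tot > 0, tot, 1), np.nan)
    if mt.sum() + mf.sum() == 0:
        raise ValueError("no published hypotheses in any run")
    pooled = TallyDistribution(lo, hi, mt, mf)
    table = metric_table(pooled)
    if len(results) >= 8:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN tally columns
            table.precision_ci = np.nanpercentile(per_seed_prec, ci, axis=0)
    return table


def mean_investigations_published(result: SimResult) -> float:
    """Mean number of replications received per published hypothesis.

    Validates the renewal engine's ``lam``: under full communication it
    converges to ``r / (1-r)``.
    """
    if result.published == 0:
        raise ValueError("no published hypotheses")
    return float(result.reps.mean())
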