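"""How believable is a finding with a given published tally?

Computes the posterior probability that a hypothesis is true given its tally
(published positives minus published negatives), under an optimistic and a
pessimistic research climate.  The tally is the only public evidence in the
model, so this posterior is what a literature review alone can justify.
"""

from replidyn import get_scenario, metric_table, steady_state

for name in ("optimistic", "pessimistic"):
    params = get_scenario(name).params
    table = metric_table(steady_state(params))
    print(f"\n{name} climate  (b={params.b}, power={params.power_new}, alpha={params.alpha_new})")
    for s in (1, 2, 3, 5):
        print(f"  Pr(true | tally {s:+d}) = {table.precision_at(s):.3f}")

print(
    "\nA single positive finding (tally +1) is weak evidence unless the base "
    "rate is high; repeated positive replication separates truth from noise."
)
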