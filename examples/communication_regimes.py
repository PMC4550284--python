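"""Selective communication as epistemological chromatography.

Replication diffuses true hypotheses toward positive tallies (rate
(1-beta)*c_R+) and false ones toward negative tallies (rate (1-alpha)*c_R-).
This script compares four communication regimes at the same base rate and
study quality, showing how turning each communication channel on or off
changes the reliability of a tally of +3.
"""

from replidyn import get_scenario, metric_table, steady_state_renewal

print(f"{'regime':14s} {'precision(3)':>13s} {'sens(>=3)':>10s}  meaning")
for name, meaning in [
    ("fig3a", "only positive findings ever published"),
    ("fig3b", "only negative replications published"),
    ("fig3c", "novel negatives suppressed, replications fully published"),
    ("fig3d", "everything published"),
]:
    table = metric_table(steady_state_renewal(get_scenario(name).params).dist)
    p3 = table.precision_at(3)
    s3 = table.sensitivity_ge(3)
    print(f"{name:14s} {p3:13.3f} {s3:10.3f}  {meaning}")

print(
    "\nWith both replication channels open (third row), a tally of 3 is true "
    ">80% of the time and holds over half of all published true hypotheses: "
    "downward diffusion of false hypotheses purifies the positive tallies."
)
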