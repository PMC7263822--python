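"""Neutral decay of an A3G-like ORF under the New World monkey parameters.

Simulates 2,000 replicate copies of a random 1,150 bp ORF mutating freely
(substitutions plus 1-bp indels) for 20 million years and prints how many
are still "intact" — open, ATG-initiated and at the original length — at a
few census times, together with the 1st/5th-percentile crossing times.
"""
import numpy as np

import retrofossil as rf

rng = np.random.default_rng(1)
orf = rf.random_intact_orf(1150, rng, id="A3G_like")

config = rf.SimulationConfig(
    horizon_years=20e6,
    census_interval_years=50e3,
    n_replicates=2000,
    seed=1,
)
trajectory = rf.simulate_decay(orf, rf.PRESETS["nwm-like"], config)

print("time (My)  intact fraction")
for my in (0, 1, 2, 5, 10, 20):
    print(f"{my:9.1f}  {trajectory.fraction_at(my * 1e6):.4f}")

calls = rf.retention_percentiles(trajectory)
for p, t in sorted(calls.items(), reverse=True):
    when = f"{t / 1e6:.2f} My" if isinstance(t, float) else t
    print(f"intact fraction first drops to {p:.0%} at {when}")

print(
    "\nInterpretation: without selection, almost every copy of the ORF is\n"
    "broken by a stop codon or frameshift within a few million years, so\n"
    "an intact retrocopy tens of millions of years old is a strong\n"
    "candidate for selective retention."
)
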