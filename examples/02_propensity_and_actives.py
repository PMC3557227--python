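"""From simulated free/bound time courses to interface (active) residues.

Simulates limited-proteolysis peak lists for a protein alone and in
complex (sites 8 and 21 are 60% protected by the partner), computes the
relative cleavage propensity per site and time, and applies the 20%
relative-decrease criterion to call active residues.
"""

import itertools

import numpy as np

import footprintdock as fd
from footprintdock.synthetic import SimulationConfig

fill = itertools.cycle("GASTVLINQDEFHW")
seq = fd.ProteinSequence(
    "recA", "".join("K" if i + 1 in (5, 8, 12, 17, 21, 28) else next(fill)
                    for i in range(30))
)

cfg = SimulationConfig(
    sequence=seq,
    protected_sites=frozenset({8, 21}),
    protection=0.6,      # bound-state cleavage rate = 40% of free
    intensity_cv=0.10,   # triplicate log-normal intensity noise
    seed=1,
)
sim = fd.simulate_timecourse(cfg)
print(f"simulated {len(sim.peaklists)} peak lists "
      f"({len(sim.sites)} sites, times {cfg.times} min)")

free = fd.compute_propensity(seq, fd.TRYPSIN, sim.peaklists, "free", tol=0.2)
bound = fd.compute_propensity(seq, fd.TRYPSIN, sim.peaklists, "bound", tol=0.2)

print("site  mean P(free)  mean P(bound)  relative drop")
f, b = free.mean_over_time(), bound.mean_over_time()
for i, s in enumerate(free.sites):
    print(f"{s:>4}  {f[i]:12.3f}  {b[i]:13.3f}  {(f[i]-b[i])/f[i]:+13.1%}")

active = fd.derive_active(free, bound, fd.ComparisonConfig(threshold=0.20))
print(f"active residues (>=20% propensity drop): {active}")
# Sites 8 and 21 drop far past the threshold; unprotected sites drift
# slightly upward (share renormalisation) and are never called.
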