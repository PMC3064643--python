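"""Simulate one genealogy of a sexual-asexual complex, backward in time.

Ten clones share an asexual population of 25,000 individuals (broken-stick
sizes) next to two sexual demes totalling 25,000.  Under the decay model a
clone's chance of having been founded rises with its candidate age, so
looking backward every clone soon collapses into a single sexual founder.
"""

import numpy as np

from asexpop import CoalParams, run_coalescent

params = CoalParams(
    L_C=10, N_C=25_000, z_C=5, d_C=2, N_sex=25_000, z_sex=0,
    m_C=1e-3, hazard_mode="decay", f_prime=0.05,
)
rng = np.random.default_rng(1)
g = run_coalescent(params, rng)
s = g.summarize()

print(f"tips sampled:        {len(g.samples)}")
print(f"TMRCA:               {s['tmrca']:.0f} generations")
print(f"total tree length:   {s['total_length']:.0f} generations")
print(f"asexual tree length: {s['asexual_length']:.0f} generations")
print(f"asexual fraction:    {g.asexual_fraction():.3f}")
# The asexual fraction is the share of the genealogy that evolved inside
# unfounded clones -- the only part the "pruned" mutation overlay weights.
# Under strong decay it is small: clones are young, so most ancestry is
# spent in the sexual demes.
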