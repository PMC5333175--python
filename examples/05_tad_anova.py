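"""Per-domain element densities across subcompartment classes, with ANOVA + Tukey.

Each chromatin domain gets an element density (count per 100 kb of its length);
a one-way ANOVA across classes plus Tukey HSD produces compact letter groups:
classes sharing a letter are statistically inseparable at alpha = 0.05. B4 and
NA are excluded, as in the overlay analysis.
"""

import numpy as np

from cpglandscape.synthetic_data import SimulationConfig, simulate_partition, simulate_track
from cpglandscape.tad_overlay import anova_tukey, domain_densities

config = SimulationConfig(seed=1)
rng = np.random.default_rng(config.seed)
partition = simulate_partition(config, rng)

for name in ("CGI", "Alu", "L1"):
    track = simulate_track(config, partition, name, rng)
    dens = domain_densities(partition, track)
    res = anova_tukey(dens)
    print(f"{name}: F = {res.f:.1f}, p = {res.p:.2e}")
    for cls, row in res.class_stats.iterrows():
        print(f"  {cls}: mean {row['mean']:6.2f} +/- {row['sd']:5.2f} "
              f"(n={int(row['n'])})  group {res.letter_groups[cls]}")
# For the clustered tracks A1 stands apart with the highest density and the
# B2/B3 heterochromatic classes share a letter (a joint low-density group);
# for L1 the class means barely differ, so letters overlap broadly.
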