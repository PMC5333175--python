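"""Profile element densities along the DHS chromatin-accessibility scale.

Bins are grouped by their exact DHS count (one group per distinct value) and
each element's mean density per group is regressed on the group value. CGIs and
genes climb steeply with accessibility; L1 stays nearly flat.
"""

import numpy as np

from cpglandscape.binning import count_elements, make_bins
from cpglandscape.dhs_grouping import group_bins, profile_elements, profile_regression
from cpglandscape.synthetic_data import SimulationConfig, simulate_partition, simulate_track

config = SimulationConfig(seed=1)
rng = np.random.default_rng(config.seed)
partition = simulate_partition(config, rng)
grid = make_bins(config.assembly())

dhs = count_elements(grid, simulate_track(config, partition, "DHS", rng))
groups = group_bins(dhs)
print(f"{groups.n_groups} accessibility groups spanning DHS counts "
      f"{groups.group_values.min()}..{groups.group_values.max()}\n")

print(f"{'element':8s} {'r':>6s} {'slope':>8s} {'p':>10s}")
for name in ("CGI", "gene", "Alu", "L1"):
    track = simulate_track(config, partition, name, rng)
    prof = profile_elements(groups, count_elements(grid, track))
    corr, slope, _ = profile_regression(prof)
    print(f"{name:8s} {corr.r:6.3f} {slope:8.4f} {corr.p:10.2e}")
# r is the Pearson correlation of per-group mean density with DHS count; the
# slope is extra elements per bin per additional DHS site. The CGI and gene
# slopes are positive and tight (r near 1); L1's slope is near zero because its
# generated intensity does not depend on chromatin class.
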