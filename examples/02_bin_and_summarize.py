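"""Bin a synthetic genome at 100 kb and summarize each element's distribution.

Prints a per-track summary (mean/median/sd/min/max over usable bins plus the
number of occupied bins) and the dispersion verdict contrasting a clustered
(geometric) against a thin-tailed (Poisson) count model. CGIs, genes and Alus
are generated clustered; L1 is uniform Poisson and comes out binomial-like.
"""

import numpy as np

from cpglandscape.binning import count_elements, make_bins
from cpglandscape.distribution_stats import dispersion_diagnostic, summarize_counts
from cpglandscape.synthetic_data import (
    TRACKS,
    SimulationConfig,
    simulate_partition,
    simulate_track,
)

config = SimulationConfig(seed=1)
rng = np.random.default_rng(config.seed)
partition = simulate_partition(config, rng)
grid = make_bins(config.assembly())
print(f"{grid.n_usable} usable 100 kb bins over {len(config.assembly())} chromosomes\n")

print(f"{'element':8s} {'avg':>6s} {'median':>6s} {'sd':>6s} {'min':>4s} {'max':>4s} {'df':>5s}  verdict")
for name in TRACKS:
    track = simulate_track(config, partition, name, rng)
    counts = count_elements(grid, track)
    s = summarize_counts(counts)
    d = dispersion_diagnostic(counts)
    print(
        f"{name:8s} {s.avg:6.1f} {s.median:6.1f} {s.std_dev:6.1f} "
        f"{s.min:4d} {s.max:4d} {s.df:5d}  {d.verdict}"
    )
# "df" counts the usable bins holding at least one element. The clustered
# tracks show variance far above their mean (heavy-tailed verdict), while the
# uniform L1 track stays near variance = mean.
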