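import numpy as np
import pytest

from cpglandscape.binning import count_elements, make_bins
from cpglandscape.genome_model import GenomeAssembly
from cpglandscape.synthetic_data import (
    TRACKS,
    SimulationConfig,
    simulate_partition,
    simulate_track,
)


@pytest.fixture(scope="session")
def small_config():
    """A 130 Mb toy genome: big enough for class structure, fast to simulate."""
    return SimulationConfig(
        seed=11,
        chromosome_lengths=(40_000_000, 35_000_000, 30_000_000, 25_000_000),
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    """Partition, element tracks, bin grid and counts for the toy genome."""
    rng = np.random.default_rng(small_config.seed)
    partition = simulate_partition(small_config, rng)
    tracks = {
        name: simulate_track(small_config, partition, name, rng) for name in TRACKS
    }
    grid = make_bins(small_config.assembly())
    counts = {name: count_elements(grid, tr) for name, tr in tracks.items()}
    return {
        "config": small_config,
        "partition": partition,
        "tracks": tracks,
        "grid": grid,
        "counts": counts,
    }


@pytest.fixture
def toy_assembly():
    return GenomeAssembly((("chrA", 1_000_000), ("chrB", 500_000)))
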