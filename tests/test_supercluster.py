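"""Dense CGI run detection, positional classification, and planted-hotspot recovery."""

import numpy as np
import pandas as pd
import pytest

from cpglandscape.binning import BinCounts, count_elements, make_bins
from cpglandscape.genome_model import ElementTrack, GenomeAssembly, GenomicInterval
from cpglandscape.supercluster import (
    INTERSTITIAL,
    PERICENTROMERIC,
    SUBTELOMERIC,
    Supercluster,
    classify_position,
    classify_positions,
    detect_superclusters,
    supercluster_share,
)
from cpglandscape.synthetic_data import (
    Hotspot,
    SimulationConfig,
    simulate_partition,
    simulate_track,
)


def counts_from(values, chrom_order=None):
    values = {"chr1": values} if isinstance(values, list) else values
    chroms = chrom_order or list(values)
    asm = GenomeAssembly(tuple((c, len(values[c]) * 100_000) for c in chroms))
    grid = make_bins(asm, 100_000)
    arr = np.concatenate([values[c] for c in chroms])
    return BinCounts(grid, "CGI", np.asarray(arr))


class TestDetection:
    def test_basic_run_with_no_gap(self):
        c = counts_from([0, 0, 12, 14, 11, 0, 0, 0])
        [cl] = detect_superclusters(c, min_density=10, max_gap_bins=0, min_span=300_000)
        assert (cl.interval.start, cl.interval.end) == (200_000, 500_000)
        assert cl.n_cgis == 37 and cl.n_bins == 3
        assert cl.mean_density == pytest.approx(37 / 3)

    def test_gap_bin_bridged_inside_run(self):
        c = counts_from([12, 0, 14])
        [cl] = detect_superclusters(c, min_density=10, max_gap_bins=1, min_span=300_000)
        assert cl.n_bins == 3 and cl.n_cgis == 26  # span includes the gap bin
        assert detect_superclusters(c, min_density=10, max_gap_bins=0, min_span=300_000) == []

    def test_all_below_threshold_empty(self):
        assert detect_superclusters(counts_from([3, 5, 2, 9, 4])) == []

    def test_runs_never_cross_chromosomes(self):
        c = counts_from({"chr1": [0, 12, 13], "chr2": [14, 12, 0]})
        clusters = detect_superclusters(c, min_density=10, max_gap_bins=1, min_span=200_000)
        assert [cl.interval.chrom for cl in clusters] == ["chr1", "chr2"]

    def test_maximality_and_disjointness(self):
        rng = np.random.default_rng(2)
        vals = rng.poisson(3, 300)
        vals[40:50] = 20
        vals[55:60] = 25  # separated by 5 sub-threshold bins > max_gap
        c = counts_from(vals.tolist())
        clusters = detect_superclusters(c, min_density=10, max_gap_bins=1, min_span=300_000)
        ivs = [(cl.interval.start, cl.interval.end) for cl in clusters]
        assert ivs == sorted(ivs)
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            assert e1 <= s2  # disjoint
            # merging adjacent clusters would need > max_gap consecutive weak bins
            assert (s2 - e1) // 100_000 > 1

    def test_invariant_to_prepending_empty_chromosome(self):
        plain = counts_from({"chr1": [0, 12, 13, 14, 0]})
        padded = counts_from({"chr0": [0] * 10, "chr1": [0, 12, 13, 14, 0]})
        a = detect_superclusters(plain)
        b = detect_superclusters(padded)
        assert [(c.interval.chrom, c.interval.start, c.n_cgis) for c in a] == [
            (c.interval.chrom, c.interval.start, c.n_cgis) for c in b
        ]


class TestPositionClass:
    @pytest.fixture
    def assembly(self):
        return GenomeAssembly((("chr1", 100_000_000),))

    def centromeres(self):
        return ElementTrack(
            "centromere",
            pd.DataFrame({"chrom": ["chr1"], "start": [48_000_000], "end": [52_000_000]}),
        )

    def make_cluster(self, start, end):
        return Supercluster(GenomicInterval("chr1", start, end), 5, 60, 12.0)

    def test_three_positional_regimes(self, assembly):
        cen = self.centromeres()
        assert classify_position(self.make_cluster(0, 500_000), assembly, cen) == SUBTELOMERIC
        assert (
            classify_position(self.make_cluster(99_400_000, 99_900_000), assembly, cen)
            == SUBTELOMERIC
        )
        assert (
            classify_position(self.make_cluster(46_500_000, 47_000_000), assembly, cen)
            == PERICENTROMERIC
        )
        assert (
            classify_position(self.make_cluster(20_000_000, 20_500_000), assembly, cen)
            == INTERSTITIAL
        )

    def test_subtelomeric_takes_precedence_and_missing_centromeres_warn(self, assembly):
        near_both = self.make_cluster(500_000, 1_000_000)
        assert classify_position(near_both, assembly, self.centromeres()) == SUBTELOMERIC
        mid = self.make_cluster(49_000_000, 49_500_000)
        with pytest.warns(UserWarning, match="pericentromeric class unavailable"):
            assert classify_position(mid, assembly, None) == INTERSTITIAL


@pytest.fixture(scope="module")
def hotspot_study():
    """Low-clustering background CGIs plus dense 500 kb terminal hotspots.

    Hotspot density (~30 CGIs per bin) is 3x the detection threshold while
    the background (<= 2 per 100 kb on average) essentially never reaches it.
    """
    flat_cgi = {c: 1.8 for c in ("A1", "A2", "B1", "B2", "B3", "B4", "NA")}
    hotspots = []
    for i in range(6):
        hotspots.append(Hotspot(f"chr{i + 1}", "start", 500_000, 150))
        hotspots.append(Hotspot(f"chr{i + 1}", "end", 500_000, 150))
    cfg = SimulationConfig(
        seed=17,
        chromosome_lengths=(60_000_000,) * 6,
        hotspots=tuple(hotspots),
    )
    cfg.class_intensities["CGI"] = flat_cgi
    cfg.dispersion["CGI"] = 5.0
    rng = np.random.default_rng(cfg.seed)
    partition = simulate_partition(cfg, rng)
    cgi = simulate_track(cfg, partition, "CGI", rng)
    grid = make_bins(cfg.assembly(), include_partial=True)
    return cfg, cgi, count_elements(grid, cgi), hotspots


class TestShareAndRecovery:
    def test_trivial_shares(self):
        track = ElementTrack(
            "CGI", pd.DataFrame({"chrom": "chr1", "start": [0, 1000], "end": [500, 1500]})
        )
        assert supercluster_share([], track).share == 0.0
        one = Supercluster(GenomicInterval("chr1", 0, 100_000), 1, 2, 2.0)
        assert supercluster_share([one], track).share == 1.0

    def test_planted_hotspots_recovered_with_high_precision_and_recall(self, hotspot_study):
        cfg, _, counts, hotspots = hotspot_study
        clusters = detect_superclusters(counts)
        planted = [
            (h.chrom, 0 if h.where == "start" else cfg.assembly().lengths[h.chrom] - h.span,
             h.span)
            for h in hotspots
        ]
        def hits(cl):
            return any(
                cl.interval.chrom == c and cl.interval.start < s + span and cl.interval.end > s
                for c, s, span in planted
            )
        tp = sum(hits(cl) for cl in clusters)
        precision = tp / len(clusters)
        recall = sum(
            any(cl.interval.chrom == c and cl.interval.start < s + span and cl.interval.end > s
                for cl in clusters)
            for c, s, span in planted
        ) / len(planted)
        assert precision >= 0.95 and recall >= 0.95

    def test_share_and_span_match_planted_structure(self, hotspot_study):
        cfg, cgi, counts, hotspots = hotspot_study
        clusters = detect_superclusters(counts)
        classify_positions(clusters, cfg.assembly())
        report = supercluster_share(clusters, cgi)
        # true planted share measured from the generated track itself
        mids = cgi.midpoints()
        planted_inside = 0
        for h in hotspots:
            length = cfg.assembly().lengths[h.chrom]
            s = 0 if h.where == "start" else length - h.span
            on_chrom = cgi.df["chrom"].to_numpy() == h.chrom
            planted_inside += int(((mids >= s) & (mids < s + h.span) & on_chrom).sum())
        true_share = planted_inside / len(cgi)
        assert report.share == pytest.approx(true_share, abs=0.03)
        assert report.mean_span == pytest.approx(500_000, rel=0.2)
        assert all(cl.position_class == SUBTELOMERIC for cl in clusters)
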