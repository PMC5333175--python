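"""Synthetic genome fixtures with the statistical structure the analysis assumes.

The generator emits a complete study input set — multi-chromosome assembly, a
subcompartment partition with realistic class geometry, clustered (negative
binomial) CGI/gene/Alu tracks and thin-tailed (Poisson) L1/DHS tracks whose
per-bin means depend on the chromatin class, terminal CGI hotspots on demand,
and a U-shaped (two-mode) CGI methylation site table — so every pipeline stage
runs and is testable without any download. A single seeded generator is threaded
through all draws: the same seed gives byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import datasets
from .binning import make_bins
from .genome_model import (
    ElementTrack,
    GenomeAssembly,
    InputError,
    SubcompartmentPartition,
    write_bed,
    write_subcompartments,
)
from .tad_overlay import assign_bins

TRACKS = ("CGI", "gene", "Alu", "L1", "DHS")


@dataclass(frozen=True)
class Hotspot:
    """A planted dense tandem CGI run: ``where`` is 'start', 'end' or a bp offset."""

    chrom: str
    where: str | int
    span: int = 500_000
    cgi_count: int = 60


def _default_geometry() -> dict[str, tuple[int, float, float]]:
    return {
        cls: (n, mean_kb, sd_kb)
        for cls, (n, mean_kb, sd_kb, _total) in datasets.SUBCOMPARTMENT_GEOMETRY.items()
    }


def _default_intensities() -> dict[str, dict[str, float]]:
    # mean elements per 100 kb bin by chromatin class; chosen so the
    # share-weighted genome averages land near the published bin summaries
    # (CGI ~1.8, gene ~2.3, Alu ~40.9, L1 ~32.6, DHS ~101.8 per 100 kb) with
    # CGI/gene/DHS densities increasing from B3 heterochromatin to A1
    # euchromatin and L1 near-uniform.
    return {
        "CGI": {"A1": 5.0, "A2": 2.0, "B1": 2.2, "B2": 0.7, "B3": 0.5, "B4": 6.0, "NA": 1.0},
        "gene": {"A1": 7.0, "A2": 2.5, "B1": 2.6, "B2": 1.0, "B3": 0.7, "B4": 4.0, "NA": 1.2},
        "Alu": dict(datasets.ALU_CLASS_DENSITY, NA=35.0),
        "L1": {c: 32.6 for c in ("A1", "A2", "B1", "B2", "B3", "B4", "NA")},
        "DHS": {"A1": 190.0, "A2": 120.0, "B1": 115.0, "B2": 75.0, "B3": 55.0, "B4": 130.0, "NA": 80.0},
    }


def _default_dispersion() -> dict[str, float | None]:
    # negative-binomial size parameter per track; None = Poisson.
    return {"CGI": 1.0, "gene": 1.0, "Alu": 1.5, "L1": None, "DHS": None}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic genome.

    Defaults emulate the published setting: the hg19 subcompartment class
    geometry (scaled to the toy assembly length), the published per-class Alu
    densities, a ~20% hypermethylated CGI fraction from a two-mode (U-shaped)
    methylation score mixture, and clustered vs thin-tailed count families per
    track.
    """

    seed: int = 0
    chromosome_lengths: tuple[int, ...] = (
        90_000_000, 80_000_000, 70_000_000, 65_000_000,
        60_000_000, 50_000_000, 45_000_000, 40_000_000,
    )
    bin_size: int = 100_000
    class_geometry: dict[str, tuple[int, float, float]] = field(default_factory=_default_geometry)
    class_intensities: dict[str, dict[str, float]] = field(default_factory=_default_intensities)
    dispersion: dict[str, float | None] = field(default_factory=_default_dispersion)
    methylation_mixture: tuple[float, float, float] = (100.0, 800.0, 0.2)  # low, high, weight
    methylation_site_sd: float = 50.0
    sites_per_cgi: tuple[int, int] = (3, 15)
    hotspots: tuple[Hotspot, ...] = ()
    centromere_span: int = 3_000_000

    def assembly(self) -> GenomeAssembly:
        return GenomeAssembly(
            tuple((f"chr{i + 1}", int(l)) for i, l in enumerate(self.chromosome_lengths))
        )

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def simulate_partition(config: SimulationConfig, rng: np.random.Generator | None = None) -> SubcompartmentPartition:
    """Draw a subcompartment partition with the configured class geometry.

    Per class, domain count is scaled to the toy assembly length and lengths are
    drawn from a gamma distribution matched to the class mean/sd, then rescaled
    so each class's total length matches its configured genome share exactly
    (the length distribution keeps its shape; the shares become deterministic).
    Domains are placed sequentially in shuffled order; any chromosome tail left
    over is labeled NA.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    assembly = config.assembly()
    ref_total = datasets.SUBCOMPARTMENT_TOTAL_MB * 1e6
    scale = assembly.total_length / ref_total
    pieces: list[tuple[str, int]] = []
    for cls, (n_ref, mean_kb, sd_kb) in config.class_geometry.items():
        n = max(1, int(round(n_ref * scale)))
        mean, sd = mean_kb * 1e3, sd_kb * 1e3
        shape = (mean / sd) ** 2
        lengths = rng.gamma(shape, mean / shape, size=n)
        target = n_ref * mean * scale
        if lengths.sum() <= 0:
            raise InputError(f"infeasible geometry for class {cls}")
        lengths = lengths * (target / lengths.sum())
        lengths = np.maximum(lengths.round().astype(int), 10_000)
        pieces.extend((cls, int(l)) for l in lengths)
    order = rng.permutation(len(pieces))
    pieces = [pieces[i] for i in order]
    if sum(l for _, l in pieces) > assembly.total_length * 1.05:
        raise InputError("infeasible geometry: domains exceed assembly length")

    rows = []
    it = iter(pieces)
    piece = next(it, None)
    for chrom, length in assembly.chromosomes:
        pos = 0
        while piece is not None and pos < length:
            cls, l = piece
            end = min(pos + l, length)  # truncate at the chromosome boundary
            rows.append({"chrom": chrom, "start": pos, "end": end, "class_label": cls})
            pos = end
            piece = next(it, None)
        if pos < length:
            rows.append({"chrom": chrom, "start": pos, "end": length, "class_label": "NA"})
    return SubcompartmentPartition(pd.DataFrame(rows))


def _element_lengths(track: str, n: int, rng: np.random.Generator) -> np.ndarray:
    """Per-track element length model (bp); sub-bin structure beyond length is not modeled."""
    if track == "CGI":
        return np.maximum(rng.lognormal(np.log(1000), 0.5, n).astype(int), 200)
    if track == "Alu":
        return np.clip(rng.normal(300, 30, n).astype(int), 100, 400)
    if track == "L1":
        long = rng.random(n) < 0.10  # ~10% near-full-length copies
        out = rng.integers(500, 3000, n)
        out[long] = rng.integers(5000, 7000, long.sum())
        return out
    if track == "gene":
        return np.exp(rng.uniform(np.log(5_000), np.log(200_000), n)).astype(int)
    if track == "DHS":
        return rng.integers(100, 201, n)
    raise InputError(f"unknown track {track!r}")


def simulate_track(
    config: SimulationConfig,
    partition: SubcompartmentPartition,
    track_name: str,
    rng: np.random.Generator | None = None,
) -> ElementTrack:
    """Draw one element track with class-dependent per-bin counts.

    Per 100 kb bin, the count comes from a negative binomial (clustered tracks:
    CGI, gene, Alu) or Poisson (L1, DHS) with mean set by the bin's chromatin
    class; elements are placed uniformly within the bin. CGI hotspots configured
    in ``config.hotspots`` are added on top.
    """
    if track_name not in config.class_intensities:
        raise InputError(f"no intensities configured for track {track_name!r}")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    assembly = config.assembly()
    grid = make_bins(assembly, config.bin_size, include_partial=True)
    labels = assign_bins(grid, partition).labels
    intensities = config.class_intensities[track_name]
    mean = np.array([intensities.get(l, intensities.get("NA", 0.0)) for l in labels])
    # partial terminal bins scale their mean by bin length
    widths = (grid.bins["end"] - grid.bins["start"]).to_numpy()
    mean = mean * widths / config.bin_size
    k = config.dispersion.get(track_name)
    if k is None:
        counts = rng.poisson(mean)
    else:
        counts = np.where(
            mean > 0, rng.negative_binomial(k, k / (k + np.maximum(mean, 1e-12))), 0
        )
    chroms_rep, starts, ends = [], [], []
    bin_chrom = grid.bins["chrom"].to_numpy()
    bin_start = grid.bins["start"].to_numpy()
    chrom_len = assembly.lengths
    for i in np.flatnonzero(counts):
        n = int(counts[i])
        s = bin_start[i] + rng.integers(0, widths[i], n)
        l = _element_lengths(track_name, n, rng)
        e = np.minimum(s + l, chrom_len[bin_chrom[i]])
        keep = e > s
        chroms_rep.extend([bin_chrom[i]] * int(keep.sum()))
        starts.extend(s[keep].tolist())
        ends.extend(e[keep].tolist())
    if track_name == "CGI":
        for h in config.hotspots:
            length = chrom_len[h.chrom]
            if h.where == "start":
                h0 = 0
            elif h.where == "end":
                h0 = length - h.span
            else:
                h0 = int(h.where)
            s = h0 + rng.integers(0, max(h.span - 1500, 1), h.cgi_count)
            l = _element_lengths("CGI", h.cgi_count, rng)
            e = np.minimum(s + l, length)
            chroms_rep.extend([h.chrom] * h.cgi_count)
            starts.extend(s.tolist())
            ends.extend(np.maximum(e, s + 1).tolist())
    df = pd.DataFrame({"chrom": chroms_rep, "start": starts, "end": ends})
    if df.empty:
        df = pd.DataFrame(columns=["chrom", "start", "end"])
    return ElementTrack(track_name, df)


def simulate_methylation(
    config: SimulationConfig,
    cgi_track: ElementTrack,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw a 450K-style site table with a U-shaped score distribution.

    Each CGI gets 3-15 inner sites; the CGI's methylation mode is high
    (hypermethylated) with the configured weight, low otherwise, and site scores
    scatter around the mode. Channel intensities are back-solved so that the
    per-site beta score reproduces the drawn score exactly.
    """
    if len(cgi_track) == 0:
        raise InputError("cgi_track is empty")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    low, high, w = config.methylation_mixture
    lo_n, hi_n = config.sites_per_cgi
    total_intensity = 4000.0
    rows = []
    sid = 0
    for r in cgi_track.df.itertuples():
        n = int(rng.integers(lo_n, hi_n + 1))
        mode = high if rng.random() < w else low
        scores = np.clip(rng.normal(mode, config.methylation_site_sd, n), 0.0, 950.0)
        pos = np.sort(rng.integers(r.start, r.end, n))
        for p, sc in zip(pos, scores):
            i_meth = sc / 1000.0 * (total_intensity + 100.0)
            rows.append(
                {
                    "site_id": f"cg{sid:08d}",
                    "chrom": r.chrom,
                    "pos": int(p),
                    "i_meth": round(i_meth, 3),
                    "i_unmeth": round(total_intensity - i_meth, 3),
                }
            )
            sid += 1
    df = pd.DataFrame(rows)
    return df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def simulate_study(
    config: SimulationConfig, out_dir: str | Path, force: bool = False
) -> dict[str, Path]:
    """Write a complete fixture directory: assembly, partition, five element
    tracks, methylation sites, synthetic centromeres, and a manifest with the
    seed and config hash. Deterministic: same config, byte-identical files."""
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise InputError(f"{out} exists and is not empty (use force=True)")
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    assembly = config.assembly()
    paths: dict[str, Path] = {}

    paths["chrom_sizes"] = out / "chrom.sizes"
    with open(paths["chrom_sizes"], "w") as fh:
        for name, length in assembly.chromosomes:
            fh.write(f"{name}\t{length}\n")

    partition = simulate_partition(config, rng)
    paths["subcompartments"] = out / "subcompartments.bed"
    write_subcompartments(partition, paths["subcompartments"])

    cgi_track = None
    for track_name in TRACKS:
        track = simulate_track(config, partition, track_name, rng)
        p = out / f"{track_name.lower()}.bed"
        write_bed(track, p)
        paths[track_name] = p
        if track_name == "CGI":
            cgi_track = track

    sites = simulate_methylation(config, cgi_track, rng)
    paths["methylation"] = out / "methylation.tsv"
    sites.to_csv(paths["methylation"], sep="\t", index=False)

    paths["centromeres"] = out / "centromeres.bed"
    with open(paths["centromeres"], "w") as fh:
        for name, length in assembly.chromosomes:
            mid = length // 2
            half = config.centromere_span // 2
            fh.write(f"{name}\t{max(0, mid - half)}\t{min(length, mid + half)}\tcentromere\n")

    paths["manifest"] = out / "manifest.json"
    with open(paths["manifest"], "w") as fh:
        json.dump({"seed": config.seed, "config_hash": config.config_hash()}, fh, indent=2)
        fh.write("\n")
    return paths
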