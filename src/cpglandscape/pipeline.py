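"""End-to-end pipeline: read inputs, run every analysis stage, write a TSV report set.

Stage order mirrors the analysis narrative: bin-count summaries and dispersion
diagnostics, CGI/gene presence contingency with chi-square, DHS accessibility
profiles with regressions, subcompartment overlay (per-class breakdowns,
per-domain densities, ANOVA/Tukey), CGI methylation classification with
stratified accessibility profiles, and CGI supercluster detection. Every report
carries the config hash and package version; report bodies are deterministic.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .binning import count_elements, filter_track_by_length, make_bins, mask_bins
from .dhs_grouping import group_bins, profile_elements, profile_regression
from .distribution_stats import (
    chi_square_2x2,
    dispersion_diagnostic,
    presence_contingency,
    summarize_counts,
)
from .genome_model import (
    InputError,
    read_bed_track,
    read_chrom_sizes,
    read_methylation_table,
    read_subcompartments,
)
from .methylation import classify_and_stratify, score_cgis
from .supercluster import classify_positions, detect_superclusters, supercluster_share
from .tad_overlay import anova_tukey, assign_bins, class_density_breakdown, domain_densities

log = logging.getLogger("cpglandscape")


class StageError(RuntimeError):
    """A pipeline stage failed after inputs were read successfully."""


@dataclass
class RunConfig:
    """Paths and thresholds for a full pipeline run."""

    chrom_sizes: str
    tracks: dict[str, str]                 # track name -> BED path (CGI, gene, Alu, L1, DHS)
    subcompartments: str | None = None
    methylation: str | None = None
    gaps: str | None = None
    centromeres: str | None = None
    bin_size: int = 100_000
    max_gap_fraction: float = 0.5
    methylation_threshold: float = 400.0
    supercluster_min_density: int = 10
    supercluster_max_gap_bins: int = 1
    supercluster_min_span: int = 300_000
    exclude_classes: tuple[str, ...] = ("B4", "NA")
    small_gene_max_len: int = 20_000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        if "exclude_classes" in data and isinstance(data["exclude_classes"], list):
            data["exclude_classes"] = tuple(data["exclude_classes"])
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _write_tsv(df: pd.DataFrame, path: Path, header_comment: str) -> None:
    with open(path, "w") as fh:
        fh.write(header_comment)
        df.to_csv(fh, sep="\t", index=False)


def run_full_pipeline(config: RunConfig, out_dir: str | Path) -> Path:
    """Run every applicable stage and write the report directory; returns its path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = f"# cpglandscape {__version__} config={config.config_hash()}\n"
    summary_lines: list[str] = [
        "# CpG-landscape pipeline report",
        "",
        f"- package version: {__version__}",
        f"- config hash: `{config.config_hash()}`",
        "",
    ]

    stage = "input"
    try:
        assembly = read_chrom_sizes(config.chrom_sizes)
        tracks = {
            name: read_bed_track(path, name, assembly)
            for name, path in config.tracks.items()
        }
    except (OSError, InputError) as exc:
        raise InputError(f"stage {stage}: {exc}") from exc

    try:
        stage = "binning"
        grid = make_bins(assembly, config.bin_size)
        if config.gaps:
            gap_track = read_bed_track(config.gaps, "gap", assembly)
            grid = mask_bins(grid, gap_track, config.max_gap_fraction)
        counts = {name: count_elements(grid, tr) for name, tr in tracks.items()}
        log.info("grid: %d bins, %d usable", grid.n_bins, grid.n_usable)

        stage = "distribution summaries"
        rows, disp_rows = [], []
        for name, bc in counts.items():
            s = summarize_counts(bc)
            rows.append(
                {"element": name, "avg": round(s.avg, 2), "median": s.median,
                 "std_dev": round(s.std_dev, 2), "min": s.min, "max": s.max, "df": s.df}
            )
            d = dispersion_diagnostic(bc)
            disp_rows.append(
                {"element": name, "variance_mean_ratio": round(d.variance_mean_ratio, 3),
                 "loglik_geometric": round(d.loglik_geometric, 2),
                 "loglik_poisson": round(d.loglik_poisson, 2), "verdict": d.verdict}
            )
        _write_tsv(pd.DataFrame(rows), out / "summary.tsv", stamp)
        _write_tsv(pd.DataFrame(disp_rows), out / "dispersion.tsv", stamp)

        stage = "contingency"
        if "CGI" in counts and "gene" in counts:
            table = presence_contingency(counts["gene"], counts["CGI"])
            chi2, p, _ = chi_square_2x2(table)
            cont = pd.DataFrame(
                [{"a_neither": table.a, "b_cgi_only": table.b, "c_gene_only": table.c,
                  "d_both": table.d, "n": table.n,
                  "concordance": round(table.concordance, 4),
                  "chi_square": round(chi2, 1), "p": p}]
            )
            _write_tsv(cont, out / "contingency.tsv", stamp)
            summary_lines.append(
                f"- CGI/gene presence: concordance {table.concordance:.0%}, chi2 = {chi2:.0f}"
            )

        stage = "accessibility profiles"
        if "DHS" in counts:
            groups = group_bins(counts["DHS"])
            prof_frames, reg_rows = [], []
            for name in ("CGI", "gene", "Alu", "L1"):
                if name not in counts:
                    continue
                prof = profile_elements(groups, counts[name])
                f = prof.to_frame()
                f.insert(0, "element", name)
                prof_frames.append(f)
                corr, slope, intercept = profile_regression(prof)
                reg_rows.append(
                    {"element": name, "r": round(corr.r, 4), "t": round(corr.t, 2),
                     "df": corr.df, "p": corr.p, "slope": round(slope, 4),
                     "intercept": round(intercept, 4), "n_groups": prof.group_values.size}
                )
            _write_tsv(pd.concat(prof_frames), out / "dhs_profiles.tsv", stamp)
            _write_tsv(pd.DataFrame(reg_rows), out / "dhs_regressions.tsv", stamp)
            summary_lines.append(f"- DHS grouping: {groups.n_groups} accessibility groups")

        stage = "subcompartment overlay"
        if config.subcompartments:
            partition = read_subcompartments(config.subcompartments)
            assignment = assign_bins(grid, partition, exclude=config.exclude_classes)
            for name in ("CGI", "gene", "Alu"):
                if name in counts:
                    bd = class_density_breakdown(counts[name], assignment)
                    bd = bd.reset_index()
                    _write_tsv(bd, out / f"class_breakdown_{name.lower()}.tsv", stamp)
            anova_rows = []
            for name, tr in tracks.items():
                track = tr
                if name == "gene":
                    track = filter_track_by_length(tr, max_len=config.small_gene_max_len)
                dens = domain_densities(partition, track)
                res = anova_tukey(dens, exclude=config.exclude_classes)
                stats = res.class_stats.copy()
                stats.insert(0, "element", name)
                stats["letters"] = [res.letter_groups[c] for c in stats.index]
                stats["F"] = round(res.f, 2)
                stats["p"] = res.p
                anova_rows.append(stats.reset_index())
            _write_tsv(pd.concat(anova_rows), out / "anova_tukey.tsv", stamp)
            summary_lines.append(f"- subcompartment overlay: {len(partition)} domains")
        else:
            log.warning("no subcompartment file: TAD overlay stage skipped")

        stage = "methylation"
        if config.methylation and "CGI" in tracks and "DHS" in counts:
            sites = read_methylation_table(config.methylation)
            cgi_meth = score_cgis(tracks["CGI"], sites, config.methylation_threshold)
            _write_tsv(cgi_meth, out / "methylation_cgis.tsv", stamp)
            profiles = classify_and_stratify(cgi_meth, counts["DHS"])
            frames = []
            for cls, prof in profiles.items():
                f = prof.to_frame()
                f.insert(0, "meth_class", cls)
                frames.append(f)
            if frames:
                _write_tsv(pd.concat(frames), out / "methylation_profiles.tsv", stamp)
            n_hyper = int((cgi_meth["meth_class"] == "hypermethylated").sum())
            n_scored = int((cgi_meth["meth_class"] != "no_data").sum())
            summary_lines.append(
                f"- methylation: {n_hyper}/{n_scored} scored CGIs hypermethylated"
            )

        stage = "superclusters"
        if "CGI" in counts:
            clusters = detect_superclusters(
                counts["CGI"],
                min_density=config.supercluster_min_density,
                max_gap_bins=config.supercluster_max_gap_bins,
                min_span=config.supercluster_min_span,
            )
            cen = (
                read_bed_track(config.centromeres, "centromere", assembly)
                if config.centromeres
                else None
            )
            classify_positions(clusters, assembly, cen)
            with open(out / "superclusters.bed", "w") as fh:
                for c in clusters:
                    fh.write(
                        f"{c.interval.chrom}\t{c.interval.start}\t{c.interval.end}"
                        f"\t{c.position_class}\t{c.n_cgis}\n"
                    )
            if clusters:
                share = supercluster_share(clusters, tracks["CGI"])
                summary_lines.append(
                    f"- superclusters: {share.n_clusters} detected, "
                    f"{share.share:.1%} of CGIs inside, mean span {share.mean_span / 1e3:.0f} kb"
                )
            else:
                summary_lines.append("- superclusters: none detected")
    except InputError:
        raise
    except Exception as exc:
        raise StageError(f"stage {stage!r} failed: {exc}") from exc

    (out / "report.md").write_text("\n".join(summary_lines) + "\n")
    return out
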