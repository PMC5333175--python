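"""Coordinate types and readers for the genomic annotation formats the pipeline consumes.

All coordinates are 0-based half-open (the UCSC database convention); BED input is
consumed natively and any 1-based dialect is converted at the reader boundary.
Strand is retained on tracks but ignored by every density computation downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

SUBCOMPARTMENT_CLASSES = ("A1", "A2", "B1", "B2", "B3", "B4", "NA")

_TRACK_COLUMNS = ["chrom", "start", "end", "strand"]


class InputError(ValueError):
    """Malformed or inconsistent input data."""


@dataclass(frozen=True)
class GenomeAssembly:
    """Ordered chromosome names and lengths; the coordinate frame for everything else."""

    chromosomes: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        names = [n for n, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise InputError("duplicate chromosome names in assembly")
        for name, length in self.chromosomes:
            if length <= 0:
                raise InputError(f"chromosome {name!r} has non-positive length {length}")

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.chromosomes]

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    @property
    def total_length(self) -> int:
        return sum(l for _, l in self.chromosomes)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths

    def __len__(self) -> int:
        return len(self.chromosomes)


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise InputError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(require 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise InputError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class MethylationSite:
    """One CpG probe: identity, position and the two channel intensities.

    ``score`` is the beta value scaled to 0-1000 when given in input or after
    scoring from intensities; it is NaN until then.
    """

    site_id: str
    chrom: str
    pos: int
    i_meth: float = float("nan")
    i_unmeth: float = float("nan")
    score: float = float("nan")


class ElementTrack:
    """A named set of genomic intervals with aligned per-element attributes.

    Backed by a pandas DataFrame with columns ``chrom, start, end, strand`` plus one
    column per attribute (e.g. ``family``, ``score``, ``cpg_count``). Rows are kept
    sorted by (chrom, start, end); attributes stay aligned 1:1 with intervals.
    """

    def __init__(self, name: str, df: pd.DataFrame):
        missing = [c for c in _TRACK_COLUMNS[:3] if c not in df.columns]
        if missing:
            raise InputError(f"track frame missing columns {missing}")
        df = df.copy()
        if "strand" not in df.columns:
            df["strand"] = "."
        if (df["start"] < 0).any() or (df["start"] >= df["end"]).any():
            bad = df[(df["start"] < 0) | (df["start"] >= df["end"])].iloc[0]
            raise InputError(
                f"invalid interval {bad['chrom']}:{bad['start']}-{bad['end']} in track {name!r}"
            )
        df = df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
        self.name = name
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    def __repr__(self) -> str:
        return f"ElementTrack({self.name!r}, n={len(self)})"

    @property
    def intervals(self) -> list[GenomicInterval]:
        return [
            GenomicInterval(r.chrom, int(r.start), int(r.end), r.strand)
            for r in self.df.itertuples()
        ]

    @property
    def attribute_columns(self) -> list[str]:
        return [c for c in self.df.columns if c not in _TRACK_COLUMNS]

    def lengths(self) -> np.ndarray:
        return (self.df["end"] - self.df["start"]).to_numpy()

    def midpoints(self) -> np.ndarray:
        return ((self.df["start"] + self.df["end"]) // 2).to_numpy()

    def subset(self, mask) -> "ElementTrack":
        return ElementTrack(self.name, self.df[np.asarray(mask)])

    def with_name(self, name: str) -> "ElementTrack":
        return ElementTrack(name, self.df)


@dataclass
class SubcompartmentPartition:
    """Labeled chromatin domains (A1..B4, NA) tiling the assembly.

    ``domains`` has columns ``chrom, start, end, class_label``; domains are
    non-overlapping within a chromosome and sorted.
    """

    domains: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.domains
        bad = set(df["class_label"]) - set(SUBCOMPARTMENT_CLASSES)
        if bad:
            raise InputError(f"unknown subcompartment labels {sorted(bad)}")
        df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
        for chrom, sub in df.groupby("chrom", sort=False):
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            if (starts[1:] < ends[:-1]).any():
                i = int(np.argmax(starts[1:] < ends[:-1]))
                raise InputError(
                    f"overlapping domains on {chrom} near {ends[:-1][i]}"
                )
        self.domains = df

    def __len__(self) -> int:
        return len(self.domains)

    def class_counts(self) -> pd.Series:
        return self.domains["class_label"].value_counts()


# ---------------------------------------------------------------------------
# readers


def read_chrom_sizes(path: str | Path) -> GenomeAssembly:
    """Read a two-column whitespace-delimited chrom.sizes file."""
    records: list[tuple[str, int]] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise InputError(f"{path}:{lineno}: expected 'name length', got {line!r}")
            name = parts[0]
            try:
                length = int(parts[1])
            except ValueError as exc:
                raise InputError(f"{path}:{lineno}: length is not an integer") from exc
            if length <= 0:
                raise InputError(f"{path}:{lineno}: non-positive length {length}")
            if name in seen:
                raise InputError(f"{path}:{lineno}: duplicate chromosome {name!r}")
            seen.add(name)
            records.append((name, length))
    return GenomeAssembly(tuple(records))


def read_bed_track(
    path: str | Path,
    name: str,
    assembly: GenomeAssembly | None = None,
    strict: bool = False,
) -> ElementTrack:
    """Read a BED3/4/5/6 file into a sorted track.

    Column 4 (if present) is stored as the ``family`` attribute, column 5 as
    ``score``, column 6 as strand. Overlapping intervals are kept as-is; the
    reader never merges. Intervals on chromosomes absent from ``assembly`` are
    kept with a warning, or rejected when ``strict``.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) == 1:
                parts = line.split()
            if len(parts) < 3:
                raise InputError(f"{path}:{lineno}: BED line needs >= 3 columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise InputError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise InputError(f"{path}:{lineno}: start {start} >= end {end}")
            row = {"chrom": chrom, "start": start, "end": end}
            if len(parts) >= 4:
                row["family"] = parts[3]
            if len(parts) >= 5:
                try:
                    row["score"] = float(parts[4])
                except ValueError:
                    row["score"] = float("nan")
            if len(parts) >= 6 and parts[5] in ("+", "-"):
                row["strand"] = parts[5]
            rows.append(row)
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "family", "score", "strand"])
    df = df.dropna(axis=1, how="all")
    if rows and "family" in df.columns and df["family"].isna().all():
        df = df.drop(columns=["family"])
    if assembly is not None and len(df):
        unknown = ~df["chrom"].isin(assembly.names)
        if unknown.any():
            msg = f"{int(unknown.sum())} intervals on chromosomes absent from assembly"
            if strict:
                raise InputError(msg)
            warnings.warn(msg, stacklevel=2)
    if df.empty:
        df = pd.DataFrame(columns=["chrom", "start", "end"])
    return ElementTrack(name, df)


def write_bed(track: ElementTrack, path: str | Path) -> None:
    """Write a track as BED; ``family`` -> column 4, ``score`` -> column 5, strand -> 6."""
    cols = ["chrom", "start", "end"]
    df = track.df
    out = df[cols].copy()
    has_strand = (df["strand"] != ".").any()
    if "family" in df.columns or "score" in df.columns or has_strand:
        out["name"] = df["family"] if "family" in df.columns else track.name
    if "score" in df.columns or has_strand:
        out["score"] = df["score"] if "score" in df.columns else 0
    if has_strand:
        out["strand"] = df["strand"]
    out.to_csv(path, sep="\t", header=False, index=False)


_UCSC_LAYOUTS = {
    # column names after an optional leading bin column
    "cpgIslandExt": [
        "chrom", "chromStart", "chromEnd", "name", "length",
        "cpgNum", "gcNum", "perCpg", "perGc", "obsExp",
    ],
    "rmsk": [
        "swScore", "milliDiv", "milliDel", "milliIns", "genoName", "genoStart",
        "genoEnd", "genoLeft", "strand", "repName", "repClass", "repFamily",
        "repStart", "repEnd", "repLeft", "id",
    ],
    "refGene": [
        "name", "chrom", "strand", "txStart", "txEnd", "cdsStart", "cdsEnd",
        "exonCount", "exonStarts", "exonEnds", "score", "name2",
        "cdsStartStat", "cdsEndStat", "exonFrames",
    ],
}
_UCSC_LAYOUTS["ensGene"] = _UCSC_LAYOUTS["refGene"]


def read_ucsc_table(path: str | Path, dialect: str) -> ElementTrack:
    """Read a UCSC table dump (cpgIslandExt / rmsk / refGene / ensGene).

    A leading ``bin`` column is autodetected by field count. cpgIslandExt yields a
    CGI track with a ``cpg_count`` attribute; rmsk a repeat track with ``rep_name`` /
    ``rep_family`` attributes; refGene/ensGene a gene track deduplicated to one
    record per distinct transcription start site (TSS = txStart on '+', txEnd on
    '-'; identity key = chrom, strand, TSS).
    """
    if dialect not in _UCSC_LAYOUTS:
        raise InputError(f"unknown UCSC dialect {dialect!r}")
    layout = _UCSC_LAYOUTS[dialect]
    raw = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if raw.shape[1] == len(layout) + 1:
        raw = raw.iloc[:, 1:]  # drop leading bin column
    if raw.shape[1] != len(layout):
        raise InputError(
            f"{path}: {dialect} table needs {len(layout)} columns "
            f"(or +1 with a leading bin), got {raw.shape[1]}; layout: {layout}"
        )
    raw.columns = layout

    if dialect == "cpgIslandExt":
        df = pd.DataFrame(
            {
                "chrom": raw["chrom"],
                "start": raw["chromStart"].astype(int),
                "end": raw["chromEnd"].astype(int),
                "cpg_count": raw["cpgNum"].astype(int),
            }
        )
        return ElementTrack("CGI", df)

    if dialect == "rmsk":
        df = pd.DataFrame(
            {
                "chrom": raw["genoName"],
                "start": raw["genoStart"].astype(int),
                "end": raw["genoEnd"].astype(int),
                "strand": raw["strand"].where(raw["strand"].isin(["+", "-"]), "."),
                "rep_name": raw["repName"],
                "rep_class": raw["repClass"],
                "rep_family": raw["repFamily"],
            }
        )
        return ElementTrack("repeat", df)

    # gene dialects: deduplicate to distinct TSS
    strand = raw["strand"]
    tx_start = raw["txStart"].astype(int)
    tx_end = raw["txEnd"].astype(int)
    tss = tx_start.where(strand == "+", tx_end)
    genes = pd.DataFrame(
        {
            "chrom": raw["chrom"],
            "start": tx_start,
            "end": tx_end,
            "strand": strand.where(strand.isin(["+", "-"]), "."),
            "gene": raw["name2"].fillna(raw["name"]),
            "tss": tss,
        }
    )
    genes = genes.drop_duplicates(subset=["chrom", "strand", "tss"], keep="first")
    return ElementTrack("gene", genes)


_ALU_FAMILIES = ("AluJ", "AluS", "AluY")


def select_alu(repeats: ElementTrack) -> ElementTrack:
    """Subset an rmsk repeat track to the three major Alu families.

    rmsk repName prefixed AluJ/AluS/AluY maps to the ``family`` attribute;
    FLAM/FRAM and other SINE names are excluded.
    """
    names = repeats.df["rep_name"].astype(str)
    family = pd.Series(pd.NA, index=repeats.df.index, dtype="object")
    for fam in _ALU_FAMILIES:
        family[names.str.startswith(fam)] = fam
    keep = family.notna()
    df = repeats.df[keep].copy()
    df["family"] = family[keep]
    return ElementTrack("Alu", df)


def select_l1(repeats: ElementTrack) -> ElementTrack:
    """Subset an rmsk repeat track to LINE-1 elements (repFamily == 'L1')."""
    keep = repeats.df["rep_family"].astype(str) == "L1"
    return ElementTrack("L1", repeats.df[keep])


def read_subcompartments(path: str | Path) -> SubcompartmentPartition:
    """Read a BED4-like subcompartment partition (4th column = class label)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise InputError(f"{path}:{lineno}: need chrom start end class")
            label = parts[3]
            if label not in SUBCOMPARTMENT_CLASSES:
                raise InputError(
                    f"{path}:{lineno}: unknown class {label!r} "
                    f"(expected one of {SUBCOMPARTMENT_CLASSES})"
                )
            rows.append(
                {
                    "chrom": parts[0],
                    "start": int(parts[1]),
                    "end": int(parts[2]),
                    "class_label": label,
                }
            )
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "class_label"])
    return SubcompartmentPartition(df)


def write_subcompartments(partition: SubcompartmentPartition, path: str | Path) -> None:
    partition.domains.to_csv(path, sep="\t", header=False, index=False)


def read_methylation_table(path: str | Path) -> pd.DataFrame:
    """Read a methylation site TSV.

    Expected header columns: ``site_id chrom pos`` then either ``i_meth i_unmeth``
    (channel intensities) or ``score`` (precomputed 0-1000 beta score), or all
    three. Returns a DataFrame sorted by (chrom, pos) with a NaN ``score`` column
    when only intensities are given.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"site_id", "chrom", "pos"}
    if not required <= set(df.columns):
        raise InputError(f"{path}: methylation table needs columns {sorted(required)}")
    has_intensity = {"i_meth", "i_unmeth"} <= set(df.columns)
    if not has_intensity and "score" not in df.columns:
        raise InputError(f"{path}: need i_meth/i_unmeth or score columns")
    if has_intensity:
        if (df["i_meth"] < 0).any() or (df["i_unmeth"] < 0).any():
            raise InputError(f"{path}: negative intensity")
    if "score" not in df.columns:
        df["score"] = float("nan")
    return df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
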