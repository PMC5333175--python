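"""Subcompartment (TAD-class) overlay: bin labeling, per-class density breakdowns,
per-domain densities, and one-way ANOVA with Tukey HSD letter groups.

Domains (median length ~185 kb) are only about twice the 100 kb bin size, so each
bin takes the label of the class covering the majority of its length, with ties
broken deterministically toward the earlier class in (A1, A2, B1, B2, B3, B4, NA).
The ANOVA observational unit is the domain, with densities normalized per 100 kb
of domain length so bins and domains share a scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .binning import BinCounts, BinGrid
from .genome_model import (
    ElementTrack,
    InputError,
    SubcompartmentPartition,
    SUBCOMPARTMENT_CLASSES,
)

CLASS_ORDER = SUBCOMPARTMENT_CLASSES  # tie-break priority
UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class ClassAssignment:
    """Per-bin subcompartment label; 'unassigned' where no domain overlaps."""

    grid: BinGrid
    labels: np.ndarray  # dtype object, length n_bins

    @property
    def usable_labels(self) -> np.ndarray:
        return self.labels[self.grid.usable]


@dataclass(frozen=True)
class AnovaResult:
    f: float
    p: float
    class_stats: pd.DataFrame        # index class, columns n/mean/sd
    tukey: pd.DataFrame              # symmetric matrix of adjusted p-values
    letter_groups: dict[str, str]    # class -> letters; shared letter = not separable
    alpha: float


def assign_bins(
    grid: BinGrid,
    partition: SubcompartmentPartition,
    exclude: tuple[str, ...] = (),
) -> ClassAssignment:
    """Label each bin with the class covering the majority of its length.

    Classes in ``exclude`` (commonly B4 and NA, which the overlay analysis drops)
    are treated as absent, so bins they dominate become 'unassigned'.
    """
    labels = np.full(grid.n_bins, UNASSIGNED, dtype=object)
    starts = grid.bins["start"].to_numpy()
    ends = grid.bins["end"].to_numpy()
    cover = {}  # class -> per-bin covered bp
    for chrom, sub in partition.domains.groupby("chrom", sort=False):
        try:
            sl = grid.chrom_slice(chrom)
        except KeyError:
            continue
        for ds, de, label in zip(sub["start"], sub["end"], sub["class_label"]):
            if label in exclude:
                continue
            lo = sl.start + int(np.searchsorted(ends[sl], ds, side="right"))
            hi = sl.start + int(np.searchsorted(starts[sl], de, side="left"))
            arr = cover.setdefault(label, np.zeros(grid.n_bins))
            for i in range(lo, min(hi, sl.stop)):
                arr[i] += max(0, min(de, ends[i]) - max(ds, starts[i]))
    if cover:
        classes = [c for c in CLASS_ORDER if c in cover]
        mat = np.stack([cover[c] for c in classes])  # priority order: first wins ties
        best = np.argmax(mat, axis=0)
        covered = mat.max(axis=0) > 0
        labels[covered] = np.array(classes, dtype=object)[best[covered]]
    return ClassAssignment(grid, labels)


def class_density_breakdown(
    element_counts: BinCounts,
    assignment: ClassAssignment,
    cap: int | None = None,
) -> pd.DataFrame:
    """Stack the density histogram by chromatin class.

    Rows are density values (tail pooled at ``cap`` if given), columns are the
    classes present among usable bins; cell = number of usable bins of that class
    at that density. Row sums reproduce the plain density histogram.
    """
    x = element_counts.usable_counts
    labels = assignment.usable_labels
    if len(x) != len(labels):
        raise InputError("counts and assignment use different grids/masks")
    if cap is not None:
        x = np.minimum(x, cap)
    df = pd.DataFrame({"density": x, "class": labels})
    table = df.pivot_table(index="density", columns="class", aggfunc="size", fill_value=0)
    ordered = [c for c in (*CLASS_ORDER, UNASSIGNED) if c in table.columns]
    return table[ordered]


def domain_densities(
    partition: SubcompartmentPartition,
    track: ElementTrack,
    per_bp: int = 100_000,
) -> pd.DataFrame:
    """Element count and density (per 100 kb of domain length) for every domain.

    Elements are assigned to the domain containing their midpoint (consistent
    with bin counting); density = count * per_bp / domain length.
    """
    doms = partition.domains
    if (doms["end"] <= doms["start"]).any():
        raise InputError("zero-length domain")
    counts = np.zeros(len(doms), dtype=np.int64)
    mids_by_chrom = {
        chrom: np.sort(((sub["start"] + sub["end"]) // 2).to_numpy())
        for chrom, sub in track.df.groupby("chrom", sort=False)
    }
    for chrom, sub in doms.groupby("chrom", sort=False):
        mids = mids_by_chrom.get(chrom)
        if mids is None:
            continue
        lo = np.searchsorted(mids, sub["start"].to_numpy(), side="left")
        hi = np.searchsorted(mids, sub["end"].to_numpy(), side="left")
        counts[sub.index.to_numpy()] = hi - lo
    out = doms.copy()
    out["element_count"] = counts
    out["density"] = counts * per_bp / (out["end"] - out["start"])
    return out


def _compact_letter_display(classes: list[str], means: dict[str, float], sig: pd.DataFrame) -> dict[str, str]:
    """Insert-and-absorb compact letter display from a pairwise significance matrix."""
    order = sorted(classes, key=lambda c: -means[c])
    # greedy maximal non-significant groups in mean order
    groups: list[set[str]] = []
    for c in order:
        if not any(c in g for g in groups):
            g = {c}
            for o in order:
                if o not in g and all(not sig.loc[o, m] for m in g):
                    g.add(o)
            groups.append(g)
    # absorb redundant groups
    groups = [g for g in groups if not any(g < h for h in groups if h is not g)]
    letters = {c: "" for c in classes}
    for letter, g in zip("abcdefghijklmnopqrstuvwxyz", groups):
        for c in sorted(g, key=lambda c: -means[c]):
            letters[c] += letter
    return {c: "".join(sorted(letters[c])) for c in classes}


def anova_tukey(
    domain_density_frame: pd.DataFrame,
    alpha: float = 0.05,
    exclude: tuple[str, ...] = ("B4", "NA"),
) -> AnovaResult:
    """One-way fixed-effects ANOVA of per-domain densities by class + Tukey HSD.

    Classes in ``exclude`` or with fewer than 2 domains are dropped (with a
    warning for the latter). Returns the F test, per-class summaries, the matrix
    of Tukey-adjusted pairwise p-values, and a compact letter display: classes
    sharing a letter are not separable at ``alpha``.
    """
    df = domain_density_frame[~domain_density_frame["class_label"].isin(exclude)]
    sizes = df.groupby("class_label").size()
    small = sizes[sizes < 2].index.tolist()
    if small:
        warnings.warn(f"dropping classes with <2 domains: {small}")
        df = df[~df["class_label"].isin(small)]
    classes = sorted(df["class_label"].unique(), key=CLASS_ORDER.index)
    if len(classes) < 2:
        raise InputError("ANOVA needs at least 2 classes with >= 2 domains")
    samples = [df.loc[df["class_label"] == c, "density"].to_numpy() for c in classes]
    f, p = sps.f_oneway(*samples)
    stats = pd.DataFrame(
        {
            "n": [len(s) for s in samples],
            "mean": [float(np.mean(s)) for s in samples],
            "sd": [float(np.std(s, ddof=1)) for s in samples],
        },
        index=pd.Index(classes, name="class"),
    )
    hsd = pairwise_tukeyhsd(df["density"].to_numpy(), df["class_label"].to_numpy(), alpha=alpha)
    tukey = pd.DataFrame(1.0, index=classes, columns=classes)
    groups = [str(g) for g in hsd.groupsunique]
    k = 0
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            padj = float(hsd.pvalues[k])
            tukey.loc[groups[i], groups[j]] = padj
            tukey.loc[groups[j], groups[i]] = padj
            k += 1
    sig = tukey < alpha
    means = dict(zip(classes, stats["mean"]))
    letters = _compact_letter_display(classes, means, sig)
    return AnovaResult(
        f=float(f), p=float(p), class_stats=stats, tukey=tukey,
        letter_groups=letters, alpha=alpha,
    )
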