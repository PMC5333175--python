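"""450K-style methylation scoring of CpG sites and CpG islands.

A site's score is the Illumina beta value scaled to 0-1000:
score = 1000 * I_meth / (I_meth + I_unmeth + 100), the standard per-site
dialect with the 100-unit stabilizing offset. A CGI's score is the mean of its
inner sites' scores (methylation assumed homogeneous within the island); islands
scoring strictly above the threshold (default 400) are classified
hypermethylated, the rest hypomethylated, and islands holding no site carry no
class. With several cell lines, site scores are averaged across cell lines
first, then across sites (the order is immaterial when every site is measured
everywhere).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .binning import BinCounts, count_elements
from .dhs_grouping import AccessibilityGroups, GroupProfile, group_bins, profile_elements
from .genome_model import ElementTrack, InputError

HYPER = "hypermethylated"
HYPO = "hypomethylated"
NO_DATA = "no_data"

DEFAULT_THRESHOLD = 400.0
INTENSITY_OFFSET = 100.0
SCALE = 1000.0


def beta_score(i_meth, i_unmeth, offset: float = INTENSITY_OFFSET):
    """Scaled beta value of one site: 1000 * M / (M + U + offset); in [0, 1000)."""
    m = np.asarray(i_meth, float)
    u = np.asarray(i_unmeth, float)
    if (m < 0).any() or (u < 0).any():
        raise InputError("negative intensity")
    out = SCALE * m / (m + u + offset)
    return float(out) if out.ndim == 0 else out


def beta_score_pooled(i_meth, total_intensity: float):
    """Literal pooled-denominator variant: 1000 * I_k / (sum_m I_m + 100).

    Divides each site's methylated intensity by one shared intensity total; kept
    for fidelity experiments only — its scale depends on the pool size and is not
    comparable to the 0-1000 per-site scale the classification threshold assumes.
    """
    m = np.asarray(i_meth, float)
    if (m < 0).any() or total_intensity < 0:
        raise InputError("negative intensity")
    out = SCALE * m / (total_intensity + INTENSITY_OFFSET)
    return float(out) if out.ndim == 0 else out


def score_sites(sites: pd.DataFrame, cell_line_columns: list[str] | None = None) -> pd.DataFrame:
    """Fill the ``score`` column of a methylation site table.

    Precedence: explicit cell-line score columns are averaged per site; else an
    existing finite ``score`` is kept; else the score is computed from the
    i_meth/i_unmeth intensities.
    """
    out = sites.copy()
    if cell_line_columns:
        out["score"] = out[cell_line_columns].mean(axis=1)
        return out
    if "score" in out.columns and np.isfinite(out["score"]).all():
        return out
    if not {"i_meth", "i_unmeth"} <= set(out.columns):
        raise InputError("cannot score: no intensities and missing scores present")
    need = ~np.isfinite(out.get("score", pd.Series(np.nan, index=out.index)))
    out.loc[need, "score"] = beta_score(
        out.loc[need, "i_meth"].to_numpy(), out.loc[need, "i_unmeth"].to_numpy()
    )
    return out


def score_cgis(
    cgi_track: ElementTrack,
    sites: pd.DataFrame,
    threshold: float = DEFAULT_THRESHOLD,
    cell_line_columns: list[str] | None = None,
) -> pd.DataFrame:
    """Score every CGI as the mean of inner site scores and classify it.

    A site at position p belongs to a CGI [start, end) iff start <= p < end.
    Returns the CGI frame plus ``n_sites``, ``score`` and ``meth_class`` columns;
    islands without sites get NaN score and class 'no_data'. Classification is
    strict: score > threshold -> hypermethylated (exactly threshold is hypo).
    """
    sites = score_sites(sites, cell_line_columns)
    cgis = cgi_track.df.copy().reset_index(drop=True)
    n_sites = np.zeros(len(cgis), dtype=np.int64)
    score_sum = np.zeros(len(cgis))
    by_chrom = {c: s.sort_values("pos") for c, s in sites.groupby("chrom", sort=False)}
    for chrom, sub in cgis.groupby("chrom", sort=False):
        ch = by_chrom.get(chrom)
        if ch is None:
            continue
        pos = ch["pos"].to_numpy()
        sc = ch["score"].to_numpy(float)
        csum = np.concatenate([[0.0], np.cumsum(sc)])
        lo = np.searchsorted(pos, sub["start"].to_numpy(), side="left")
        hi = np.searchsorted(pos, sub["end"].to_numpy(), side="left")
        n_sites[sub.index.to_numpy()] = hi - lo
        score_sum[sub.index.to_numpy()] = csum[hi] - csum[lo]
    with np.errstate(invalid="ignore"):
        score = np.where(n_sites > 0, score_sum / np.maximum(n_sites, 1), np.nan)
    cgis["n_sites"] = n_sites
    cgis["score"] = score
    cgis["meth_class"] = np.where(
        n_sites == 0, NO_DATA, np.where(score > threshold, HYPER, HYPO)
    )
    return cgis


def classify_and_stratify(
    cgi_methylation: pd.DataFrame,
    dhs_counts: BinCounts,
) -> dict[str, GroupProfile]:
    """Profile hyper- and hypomethylated CGI densities along the DHS accessibility scale.

    The scored CGI frame is split by class ('no_data' dropped), each subset is
    binned on the DHS grid and profiled through the accessibility groups.
    Returns {class: GroupProfile}; empty classes are omitted with a warning.
    """
    groups = group_bins(dhs_counts)
    profiles: dict[str, GroupProfile] = {}
    for cls in (HYPO, HYPER):
        sub = cgi_methylation[cgi_methylation["meth_class"] == cls]
        if sub.empty:
            warnings.warn(f"no CGIs in class {cls!r}; profile omitted")
            continue
        track = ElementTrack(f"CGI_{cls}", sub[["chrom", "start", "end"]])
        counts = count_elements(dhs_counts.grid, track)
        profiles[cls] = profile_elements(groups, counts)
    return profiles
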