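"""Chromatin-accessibility grouping of genome bins and element profiling.

Bins are grouped by their exact DNase-hypersensitive-site (DHS) count, giving an
ordered accessibility scale; any other element's per-bin density is then profiled
along it and regressed on the group value. The machinery is generic: grouping by
gene count instead of DHS count yields gene-density-binned profiles the same way.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .binning import BinCounts
from .distribution_stats import CorrelationResult, correlation_t_test
from .genome_model import InputError


@dataclass(frozen=True)
class AccessibilityGroups:
    """Partition of the usable bins by distinct grouping-track count value."""

    grouping_track: str
    group_values: np.ndarray        # ascending distinct count values
    bin_indices: tuple[np.ndarray, ...]  # usable-bin index arrays, one per group

    @property
    def n_groups(self) -> int:
        return len(self.group_values)

    @property
    def sizes(self) -> np.ndarray:
        return np.array([len(ix) for ix in self.bin_indices])


@dataclass(frozen=True)
class GroupProfile:
    """Mean +/- SD density of one element track within each accessibility group."""

    element_track: str
    group_values: np.ndarray
    sizes: np.ndarray
    means: np.ndarray
    std_devs: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group_value": self.group_values,
                "size": self.sizes,
                "mean": self.means,
                "sd": self.std_devs,
            }
        )


def group_bins(grouping_counts: BinCounts) -> AccessibilityGroups:
    """Group usable bins by their exact count value in the grouping track.

    One group per distinct observed value, ordered ascending; every usable bin
    lands in exactly one group.
    """
    x = grouping_counts.usable_counts
    if len(x) == 0:
        raise InputError("no usable bins to group")
    values = np.unique(x)
    indices = tuple(np.flatnonzero(x == v) for v in values)
    return AccessibilityGroups(
        grouping_track=grouping_counts.track_name,
        group_values=values,
        bin_indices=indices,
    )


def profile_elements(groups: AccessibilityGroups, element_counts: BinCounts) -> GroupProfile:
    """Mean element density per accessibility group (same grid, usable bins)."""
    x = element_counts.usable_counts
    if groups.sizes.sum() != len(x):
        raise InputError("groups and element counts come from different grids/masks")
    means = np.array([float(np.mean(x[ix])) for ix in groups.bin_indices])
    sds = np.array(
        [float(np.std(x[ix], ddof=1)) if len(ix) > 1 else 0.0 for ix in groups.bin_indices]
    )
    return GroupProfile(
        element_track=element_counts.track_name,
        group_values=groups.group_values.astype(float),
        sizes=groups.sizes,
        means=means,
        std_devs=sds,
    )


def profile_regression(
    profile: GroupProfile,
    drop_zero_group: bool = False,
    weighted: bool = False,
) -> tuple[CorrelationResult, float, float]:
    """OLS of per-group mean density on group value; returns (correlation, slope, intercept).

    Groups are weighted equally by default (each group one point); ``weighted``
    weights by group size instead. ``drop_zero_group`` excludes the group with
    value 0 before fitting.
    """
    x = profile.group_values
    y = profile.means
    w = profile.sizes.astype(float)
    if drop_zero_group:
        keep = x != 0
        x, y, w = x[keep], y[keep], w[keep]
    if len(x) < 3:
        raise InputError("need at least 3 groups for regression")
    if np.std(y) == 0:
        raise InputError("constant profile: regression undefined")
    if not weighted:
        w = np.ones_like(w)
    wx, wy = np.average(x, weights=w), np.average(y, weights=w)
    cov = np.average((x - wx) * (y - wy), weights=w)
    var = np.average((x - wx) ** 2, weights=w)
    slope = float(cov / var)
    intercept = float(wy - slope * wx)
    corr = correlation_t_test(x, y)
    return corr, slope, intercept
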