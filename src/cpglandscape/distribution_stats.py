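"""Statistical toolbox for bin-count distributions.

Summary statistics of per-bin counts, 2x2 presence/absence contingency with the
Pearson chi-square, Pearson correlation with its Student-t significance, density
histograms and their correlation, a two-family dispersion diagnostic (geometric
vs Poisson — the discrete operationalization of "exponential" vs "binomial"
count distributions), and the generalized extreme studentized deviate (ESD,
Rosner) outlier test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .binning import BinCounts
from .genome_model import InputError


@dataclass(frozen=True)
class SummaryStats:
    """Per-track bin-count summary: mean, median, sample SD, range, and the
    number of usable bins holding at least one element (``df``)."""

    track_name: str
    avg: float
    median: float
    std_dev: float
    min: int
    max: int
    df: int


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Presence/absence cross-table of two tracks over the same usable bins.

    a = neither present, b = only the column trait, c = only the row trait,
    d = both present.
    """

    a: int
    b: int
    c: int
    d: int

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def concordance(self) -> float:
        """Fraction of bins where the two traits agree (both absent or both present)."""
        return (self.a + self.d) / self.n

    def transpose(self) -> "ContingencyTable2x2":
        return ContingencyTable2x2(self.a, self.c, self.b, self.d)


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    t: float
    df: int
    p: float


@dataclass(frozen=True)
class DispersionDiagnostic:
    variance_mean_ratio: float
    loglik_geometric: float
    loglik_poisson: float
    verdict: str  # "heavy-tailed/clustered" or "binomial-like"


@dataclass(frozen=True)
class EsdStep:
    index: int
    statistic: float
    critical_value: float
    is_outlier: bool


def _usable(values) -> np.ndarray:
    if isinstance(values, BinCounts):
        return np.asarray(values.usable_counts)
    return np.asarray(values)


def summarize_counts(bin_counts: BinCounts) -> SummaryStats:
    """Table-style distribution summary over usable bins."""
    x = _usable(bin_counts)
    if len(x) == 0:
        raise InputError("no usable bins to summarize")
    name = bin_counts.track_name if isinstance(bin_counts, BinCounts) else "counts"
    return SummaryStats(
        track_name=name,
        avg=float(np.mean(x)),
        median=float(np.median(x)),
        std_dev=float(np.std(x, ddof=1)) if len(x) > 1 else 0.0,
        min=int(np.min(x)),
        max=int(np.max(x)),
        df=int((x >= 1).sum()),
    )


def presence_contingency(counts_a: BinCounts, counts_b: BinCounts) -> ContingencyTable2x2:
    """Cross-tabulate presence (count >= 1) of two tracks over shared usable bins."""
    if isinstance(counts_a, BinCounts) and isinstance(counts_b, BinCounts):
        if counts_a.grid is not counts_b.grid and not counts_a.grid.bins.equals(
            counts_b.grid.bins
        ):
            raise InputError("contingency requires counts on the same grid")
    xa = _usable(counts_a) >= 1
    xb = _usable(counts_b) >= 1
    if len(xa) != len(xb):
        raise InputError("mismatched usable-bin vectors")
    a = int((~xa & ~xb).sum())
    b = int((~xa & xb).sum())
    c = int((xa & ~xb).sum())
    d = int((xa & xb).sum())
    return ContingencyTable2x2(a, b, c, d)


def chi_square_2x2(
    table: ContingencyTable2x2, continuity: str = "none"
) -> tuple[float, float, int]:
    """Pearson chi-square of a 2x2 table, df = 1.

    statistic = N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)); under ``yates`` the
    |ad - bc| term is reduced by N/2 before squaring.
    """
    if continuity not in ("none", "yates"):
        raise InputError(f"unknown continuity mode {continuity!r}")
    a, b, c, d = table.a, table.b, table.c, table.d
    n = table.n
    margins = {"a+b": a + b, "c+d": c + d, "a+c": a + c, "b+d": b + d}
    for name, m in margins.items():
        if m == 0:
            raise InputError(f"degenerate margin {name} = 0; chi-square undefined")
    det = abs(a * d - b * c)
    if continuity == "yates":
        det = max(0.0, det - n / 2)
    stat = n * det * det / (margins["a+b"] * margins["c+d"] * margins["a+c"] * margins["b+d"])
    p = float(sps.chi2.sf(stat, 1))
    return float(stat), p, 1


def correlation_t_test(x, y, df_convention: str = "n-2") -> CorrelationResult:
    """Pearson correlation with Student-t significance, t = r sqrt(n-2)/sqrt(1-r^2).

    p is two-sided from the t distribution. ``df_convention`` sets the degrees of
    freedom used for p: the standard "n-2" (default) or "n-1" for replicating
    reports that print that convention; the t statistic itself always uses n-2.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    if n != len(y):
        raise InputError("x and y must have equal length")
    if n < 3:
        raise InputError("need at least 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise InputError("correlation undefined for a constant vector")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    df = n - 2 if df_convention == "n-2" else n - 1
    if abs(r) >= 1.0 - 1e-15:
        return CorrelationResult(r=float(np.sign(r)), n=n, t=float(np.sign(r)) * math.inf, df=df, p=0.0)
    t = r * math.sqrt(n - 2) / math.sqrt(1 - r * r)
    p = 2 * float(sps.t.sf(abs(t), df))
    return CorrelationResult(r=r, n=n, t=t, df=df, p=p)


def density_histogram(bin_counts, cap: int | None = None) -> pd.Series:
    """Histogram of per-bin density values: count of usable bins per density.

    With ``cap``, all densities >= cap are pooled into the ``cap`` class (the
    tail class). Frequencies always sum to the number of usable bins.
    """
    x = _usable(bin_counts)
    if len(x) == 0:
        raise InputError("empty grid: no usable bins to histogram")
    if cap is not None:
        x = np.minimum(x, cap)
    vals, freq = np.unique(x, return_counts=True)
    return pd.Series(freq, index=vals.astype(int), name="n_bins")


def histogram_correlation(
    hist_a: pd.Series, hist_b: pd.Series, drop_zero_class: bool = False
) -> CorrelationResult:
    """Correlate two density histograms' frequencies over their common class axis.

    Classes absent from one histogram count as zero bins there. With
    ``drop_zero_class`` the density-0 class is excluded before correlating.
    """
    axis = hist_a.index.union(hist_b.index)
    if drop_zero_class:
        axis = axis[axis != 0]
    if len(axis) < 3:
        raise InputError("need at least 3 shared density classes")
    fa = hist_a.reindex(axis, fill_value=0).to_numpy(float)
    fb = hist_b.reindex(axis, fill_value=0).to_numpy(float)
    return correlation_t_test(fa, fb)


def expected_cpg_fraction(gc_content: float = 0.42) -> float:
    """Expected CpG dinucleotide frequency under base independence: (GC/2)^2."""
    if not (0 < gc_content < 1):
        raise InputError("gc_content must be in (0, 1)")
    return (gc_content / 2) ** 2


def dispersion_diagnostic(bin_counts, tolerance: float = 0.1) -> DispersionDiagnostic:
    """Contrast a clustered (geometric) against a thin-tailed (Poisson) count model.

    Both families are fit by maximum likelihood to the usable-bin counts; the
    verdict is "heavy-tailed/clustered" when the geometric log-likelihood wins
    AND the variance/mean ratio exceeds 1 + tolerance, else "binomial-like".
    """
    x = _usable(bin_counts).astype(float)
    if len(x) < 10:
        raise InputError("need at least 10 usable bins")
    m = float(np.mean(x))
    if m == 0:
        raise InputError("all counts zero; dispersion undefined")
    vmr = float(np.var(x) / m)
    # geometric on {0,1,...}: pmf p(1-p)^k, MLE p = 1/(1+mean)
    p_hat = 1.0 / (1.0 + m)
    ll_geom = float(len(x) * math.log(p_hat) + np.sum(x) * math.log1p(-p_hat))
    ll_pois = float(np.sum(sps.poisson.logpmf(x.astype(int), m)))
    heavy = (ll_geom > ll_pois) and (vmr > 1.0 + tolerance)
    return DispersionDiagnostic(
        variance_mean_ratio=vmr,
        loglik_geometric=ll_geom,
        loglik_poisson=ll_pois,
        verdict="heavy-tailed/clustered" if heavy else "binomial-like",
    )


def esd_outlier_test(values, max_outliers: int, alpha: float = 0.05) -> list[EsdStep]:
    """Generalized ESD (Rosner) test for up to ``max_outliers`` outliers.

    Iteratively removes the most mean-deviant value; step i compares
    R_i = max|x - mean|/sd against the two-sided critical value
    lambda_i = (n-i) t_{p, n-i-1} / sqrt((n-i-1+t^2)(n-i+1)),
    p = 1 - alpha/(2(n-i+1)). The declared outliers are the first k values where
    k is the largest i with R_i > lambda_i.
    """
    x = np.asarray(values, float)
    n = len(x)
    if n < 3:
        raise InputError("ESD needs at least 3 values")
    if not (1 <= max_outliers < n / 2):
        raise InputError("max_outliers must satisfy 1 <= k < n/2")
    if np.std(x) == 0:
        warnings.warn("zero variance: no outliers detectable")
        return []
    remaining = list(range(n))
    steps: list[tuple[int, float, float]] = []
    for i in range(1, max_outliers + 1):
        sub = x[remaining]
        sd = np.std(sub, ddof=1)
        if sd == 0:
            break
        dev = np.abs(sub - np.mean(sub))
        j = int(np.argmax(dev))
        r_i = float(dev[j] / sd)
        m = len(sub)
        p = 1 - alpha / (2 * m)
        t_crit = sps.t.ppf(p, m - 2)
        lam = float((m - 1) * t_crit / math.sqrt((m - 2 + t_crit**2) * m))
        steps.append((remaining[j], r_i, lam))
        remaining.pop(j)
    n_out = 0
    for i, (_, r_i, lam) in enumerate(steps, start=1):
        if r_i > lam:
            n_out = i
    return [
        EsdStep(index=idx, statistic=r, critical_value=lam, is_outlier=(i <= n_out))
        for i, (idx, r, lam) in enumerate(steps, start=1)
    ]
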