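"""Fisher-criterion (one-way ANOVA F) feature filtering and band summaries.

Each wavenumber of the preprocessed spectra is tested for a difference in
mean intensity across the three tissue classes.  Wavenumbers whose F
statistic exceeds the critical value of the F(k-1, n-k) distribution at
level alpha are retained; the rest are discarded.  Retained intensities are
then summed within biochemical band ranges, and each band-level sum is
re-tested for group differences to attach a significance tier
(ns / p<0.05 / p<0.001).

No multiple-testing correction is applied by default (a Benjamini-Hochberg
switch exists); the filter is a screening step, not an inference procedure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .spectra_io import Band, SpectrumSet, TISSUE_CLASSES


class FilterError(ValueError):
    pass


@dataclass
class GroupedMatrix:
    """Spectra as rows, wavenumbers as columns, one tissue label per row."""

    X: np.ndarray
    labels: np.ndarray
    wavenumbers: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        if self.X.ndim != 2:
            raise FilterError("X must be 2-D (spectra x wavenumbers)")
        if self.labels.shape != (self.X.shape[0],):
            raise FilterError("one label per row required")
        if self.wavenumbers.shape != (self.X.shape[1],):
            raise FilterError("one wavenumber per column required")
        for cls in self.present_classes():
            if np.sum(self.labels == cls) < 2:
                raise FilterError(
                    f"class {cls!r} has < 2 spectra; group variance undefined")

    def present_classes(self) -> list[str]:
        return [c for c in TISSUE_CLASSES if c in set(self.labels)]

    @classmethod
    def from_spectrum_set(cls, sset: SpectrumSet) -> "GroupedMatrix":
        labels = sset.labels()
        if any(l is None for l in labels):
            raise FilterError("all spectra need a tissue_class label")
        return cls(sset.intensity_matrix(), np.array(labels, dtype=object),
                   sset.axis.wavenumbers)


@dataclass
class FeatureMask:
    """Per-wavenumber F statistics, p-values and keep decisions."""

    wavenumbers: np.ndarray
    f_statistic: np.ndarray
    p_value: np.ndarray
    keep: np.ndarray
    alpha: float
    f_critical: float

    @property
    def n_kept(self) -> int:
        return int(self.keep.sum())


@dataclass
class BandSummary:
    """Per-spectrum band sums plus per-band group statistics."""

    bands: list[Band]
    sums: np.ndarray             # (n_spectra, n_bands)
    labels: np.ndarray
    group_means: pd.DataFrame    # rows = bands, columns = classes
    group_sems: pd.DataFrame
    significance: list[str]      # per band: 'ns', '*', '**'
    n_kept_per_band: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{b.component}_{int(b.lo)}_{int(b.hi)}" for b in self.bands]
        df = pd.DataFrame(self.sums, columns=cols)
        df.insert(0, "tissue_class", self.labels)
        return df


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def fisher_statistic(groups: Sequence[np.ndarray]) -> tuple[float, float]:
    """One-way ANOVA F statistic and upper-tail p-value for one wavenumber.

    F = (between-group mean square) / (within-group mean square) with
    df1 = k-1 and df2 = n-k.  Zero within-group variance yields F = +inf
    (p = 0) when group means differ and F = 0 (p = 1) when they coincide.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    if k < 2 or any(g.size < 2 for g in groups):
        raise FilterError("need >= 2 groups with >= 2 observations each")
    n = sum(g.size for g in groups)
    grand = np.concatenate(groups).mean()
    ssb = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df1, df2 = k - 1, n - k
    if ssw == 0.0:
        if ssb == 0.0:
            return 0.0, 1.0
        return float("inf"), 0.0
    f = (ssb / df1) / (ssw / df2)
    return float(f), float(stats.f.sf(f, df1, df2))


def fisher_statistics_matrix(m: GroupedMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Columnwise one-way ANOVA over all wavenumbers (vectorized)."""
    classes = m.present_classes()
    k = len(classes)
    n = m.X.shape[0]
    grand = m.X.mean(axis=0)
    ssb = np.zeros(m.X.shape[1])
    ssw = np.zeros(m.X.shape[1])
    for cls in classes:
        sub = m.X[m.labels == cls]
        gm = sub.mean(axis=0)
        ssb += sub.shape[0] * (gm - grand) ** 2
        ssw += ((sub - gm) ** 2).sum(axis=0)
    df1, df2 = k - 1, n - k
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / df1) / (ssw / df2)
    f = np.where(ssw == 0.0, np.where(ssb == 0.0, 0.0, np.inf), f)
    p = np.where(np.isinf(f), 0.0, stats.f.sf(np.where(np.isinf(f), 1.0, f), df1, df2))
    p = np.where((ssw == 0.0) & (ssb == 0.0), 1.0, p)
    return f, p


def fisher_discriminant_ratio(m: GroupedMatrix) -> np.ndarray:
    """Multi-class discriminant ratio (between-class over within-class
    variance, no degree-of-freedom scaling); sensitivity-analysis variant."""
    classes = m.present_classes()
    grand = m.X.mean(axis=0)
    ssb = np.zeros(m.X.shape[1])
    ssw = np.zeros(m.X.shape[1])
    for cls in classes:
        sub = m.X[m.labels == cls]
        ssb += sub.shape[0] * (sub.mean(axis=0) - grand) ** 2
        ssw += ((sub - sub.mean(axis=0)) ** 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = ssb / ssw
    return np.where(ssw == 0.0, np.where(ssb == 0.0, 0.0, np.inf), r)


def critical_value(alpha: float, df1: int, df2: int) -> float:
    """Upper-alpha quantile of the F(df1, df2) distribution."""
    if not (0 < alpha < 1):
        raise FilterError("alpha must be in (0, 1)")
    if df1 < 1 or df2 < 1:
        raise FilterError("degrees of freedom must be >= 1")
    return float(stats.f.isf(alpha, df1, df2))


def build_mask(m: GroupedMatrix, alpha: float = 0.05,
               bh_correct: bool = False) -> FeatureMask:
    """Columnwise Fisher filtering: keep wavenumbers with F > F_crit.

    ``bh_correct=True`` switches the keep rule to Benjamini-Hochberg on the
    columnwise p-values (off by default).
    """
    f, p = fisher_statistics_matrix(m)
    k = len(m.present_classes())
    df1, df2 = k - 1, m.X.shape[0] - k
    f_crit = critical_value(alpha, df1, df2)
    if bh_correct:
        keep = _benjamini_hochberg(p, alpha)
    else:
        keep = f > f_crit
    return FeatureMask(wavenumbers=m.wavenumbers.copy(), f_statistic=f,
                       p_value=p, keep=keep, alpha=alpha, f_critical=f_crit)


def _benjamini_hochberg(p: np.ndarray, alpha: float) -> np.ndarray:
    n = p.size
    order = np.argsort(p)
    thresh = alpha * (np.arange(1, n + 1)) / n
    passed = p[order] <= thresh
    keep = np.zeros(n, dtype=bool)
    if passed.any():
        cutoff = np.max(np.flatnonzero(passed))
        keep[order[:cutoff + 1]] = True
    return keep


def filter_matrix(m: GroupedMatrix, mask: FeatureMask) -> GroupedMatrix:
    """Drop columns with keep=False, retaining the wavenumber mapping."""
    if mask.keep.size != m.X.shape[1]:
        raise FilterError("mask length does not match column count")
    if not mask.keep.any():
        raise FilterError(
            "mask retains no wavenumbers; increase alpha or check the data")
    return GroupedMatrix(m.X[:, mask.keep], m.labels,
                         m.wavenumbers[mask.keep])


def aggregate_bands(m: GroupedMatrix, mask: FeatureMask | None,
                    bands: Sequence[Band]) -> BandSummary:
    """Sum retained intensities inside each biochemical band.

    ``mask=None`` sums over every wavenumber in the band (plain band
    integration).  Group significance tiers come from a fresh one-way ANOVA
    on the band sums: '*' for p < 0.05, '**' for p < 0.001.
    """
    if not bands:
        raise FilterError("band list is empty")
    keep = np.ones(m.X.shape[1], dtype=bool) if mask is None else mask.keep
    classes = m.present_classes()
    sums = np.zeros((m.X.shape[0], len(bands)))
    n_kept = np.zeros(len(bands), dtype=int)
    tiers: list[str] = []
    means = {}
    sems = {}
    for j, band in enumerate(bands):
        cols = band.mask(m.wavenumbers) & keep
        n_kept[j] = int(cols.sum())
        if n_kept[j] > 0:
            sums[:, j] = m.X[:, cols].sum(axis=1)
        row_means, row_sems = {}, {}
        for cls in classes:
            vals = sums[m.labels == cls, j]
            row_means[cls] = float(vals.mean())
            row_sems[cls] = float(vals.std(ddof=1) / np.sqrt(vals.size))
        means[j] = row_means
        sems[j] = row_sems
        if n_kept[j] == 0:
            tiers.append("ns")
            continue
        _, p = fisher_statistic([sums[m.labels == c, j] for c in classes])
        tiers.append("**" if p < 0.001 else "*" if p < 0.05 else "ns")
    idx = [f"{b.component}_{int(b.lo)}_{int(b.hi)}" for b in bands]
    return BandSummary(
        bands=list(bands), sums=sums, labels=m.labels.copy(),
        group_means=pd.DataFrame.from_dict(means, orient="index").set_axis(idx),
        group_sems=pd.DataFrame.from_dict(sems, orient="index").set_axis(idx),
        significance=tiers, n_kept_per_band=n_kept)
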