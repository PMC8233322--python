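"""Cell-census processing: outlier flagging, size classification, abundance statistics
and the conductivity-abundance exponential decay fit.

A census table is a pandas DataFrame with one row per depth-integrated water
sample and the schema::

    sample_id, total_cells_per_ml, c_lt1, c_1_2, c_2_6, c_6_10, c_10_15, c_gt15,
    [timestamp], [K_m_per_d], [outlier]

The six class columns carry abundances (cells/mL) in size fractions whose
nominal edges are held in :class:`SizeClassScheme`; the 10 um edge separates
the nominal bacteria (and archaea) from the larger algae, and the >15 um
fraction is reported separately because it can dominate carbon estimates.
Samples above an abundance threshold (default 1e5 cells/mL, proximate to
localised blooms or high particle loads) are flagged as outliers, never
deleted, so every statistic can be recomputed with the flag flipped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

OUTLIER_THRESHOLD = 1.0e5  # cells/mL, strict inequality

CLASS_COLUMNS = ["c_lt1", "c_1_2", "c_2_6", "c_6_10", "c_10_15", "c_gt15"]

__all__ = [
    "OUTLIER_THRESHOLD",
    "CLASS_COLUMNS",
    "SizeClassScheme",
    "CensusSummary",
    "DecayFit",
    "flag_outliers",
    "split_bacteria_algae",
    "census_summary",
    "fit_abundance_decay",
]


@dataclass(frozen=True)
class SizeClassScheme:
    """Six nominal size classes over boundaries (um).

    The default boundaries (1, 2, 6, 10, 15) define classes <1, 1-2, 2-6,
    6-10, 10-15 and >15 um.  The interior edges 2 and 6 um are configuration
    defaults, not measured quantities.  ``min_size`` is the analytical lower
    detection limit used as the lower edge of the first class.  The
    bacteria/algae split and the large-algae threshold must coincide with two
    of the boundaries.
    """

    boundaries: tuple[float, ...] = (1.0, 2.0, 6.0, 10.0, 15.0)
    min_size: float = 0.5
    bacteria_algae_split: float = 10.0
    large_algae_threshold: float = 15.0

    def __post_init__(self) -> None:
        b = self.boundaries
        if len(b) != 5:
            raise ValueError("exactly 5 boundaries (6 classes) are supported")
        if not all(lo < hi for lo, hi in zip(b, b[1:])):
            raise ValueError("boundaries must be strictly increasing")
        if not (0 < self.min_size < b[0]):
            raise ValueError("min_size must lie below the first boundary")
        if self.bacteria_algae_split not in b:
            raise ValueError("bacteria_algae_split must coincide with a boundary")
        if self.large_algae_threshold not in b:
            raise ValueError("large_algae_threshold must coincide with a boundary")
        if self.large_algae_threshold <= self.bacteria_algae_split:
            raise ValueError("large_algae_threshold must exceed bacteria_algae_split")

    @property
    def n_classes(self) -> int:
        return len(self.boundaries) + 1

    def class_edges(self) -> list[tuple[float, float | None]]:
        """(lower, upper) edge of each class; the last upper edge is open (None)."""
        lows = (self.min_size,) + self.boundaries
        highs = self.boundaries + (None,)
        return list(zip(lows, highs))

    def is_bacteria(self) -> np.ndarray:
        """Boolean per class: True below the bacteria/algae split."""
        return np.array([lo < self.bacteria_algae_split for lo, _ in self.class_edges()])

    def is_large_algae(self) -> np.ndarray:
        """Boolean per class: True at/above the large-algae threshold."""
        return np.array([lo >= self.large_algae_threshold for lo, _ in self.class_edges()])


def flag_outliers(samples: pd.DataFrame, threshold: float = OUTLIER_THRESHOLD) -> pd.DataFrame:
    """Return a copy with a boolean ``outlier`` column: total abundance strictly above threshold.

    Samples are flagged, never dropped; the operation is idempotent and
    monotone in the threshold.
    """
    totals = samples["total_cells_per_ml"].to_numpy(dtype=float)
    if np.any(totals < 0):
        raise ValueError("abundances must be non-negative")
    out = samples.copy()
    out["outlier"] = totals > threshold
    return out


def split_bacteria_algae(
    sample: pd.Series | pd.DataFrame,
    scheme: SizeClassScheme = SizeClassScheme(),
):
    """Partition class abundances into (bacteria, algae, large_algae) cells/mL.

    Bacteria are all classes below the split (default 10 um); algae the
    classes between the split and the large-algae threshold (10-15 um); the
    open-ended >15 um class is reported separately.  Totals are conserved:
    the three parts sum to the class-column sum.
    """
    values = sample[CLASS_COLUMNS]
    arr = np.asarray(values, dtype=float)
    bact_mask = scheme.is_bacteria()
    large_mask = scheme.is_large_algae()
    algae_mask = ~bact_mask & ~large_mask
    if arr.ndim == 1:
        return float(arr[bact_mask].sum()), float(arr[algae_mask].sum()), float(arr[large_mask].sum())
    return arr[:, bact_mask].sum(axis=1), arr[:, algae_mask].sum(axis=1), arr[:, large_mask].sum(axis=1)


@dataclass(frozen=True)
class CensusSummary:
    n: int
    mean: float
    sd: float | None
    min: float
    max: float
    n_outliers: int
    class_proportions: np.ndarray  # mean of per-sample proportions, sums to 1

    def __post_init__(self) -> None:
        if not math.isclose(float(np.sum(self.class_proportions)), 1.0, abs_tol=1e-9):
            raise ValueError("class proportions must sum to 1")


def census_summary(
    samples: pd.DataFrame,
    include_outliers: bool = False,
    threshold: float = OUTLIER_THRESHOLD,
) -> CensusSummary:
    """Abundance moments and mean size-class proportions over retained samples.

    Proportions are computed per sample, then averaged (so each sample gets
    equal weight regardless of its total abundance).
    """
    if "outlier" not in samples.columns:
        samples = flag_outliers(samples, threshold)
    retained = samples if include_outliers else samples[~samples["outlier"]]
    if len(retained) == 0:
        raise ValueError("no samples retained after outlier filtering")
    totals = retained["total_cells_per_ml"].to_numpy(dtype=float)
    classes = retained[CLASS_COLUMNS].to_numpy(dtype=float)
    class_sums = classes.sum(axis=1)
    if np.any(class_sums <= 0):
        raise ValueError("every sample needs a positive class-column sum")
    props = (classes / class_sums[:, None]).mean(axis=0)
    props = props / props.sum()
    sd = float(np.std(totals, ddof=1)) if len(totals) > 1 else None
    return CensusSummary(
        n=len(retained),
        mean=float(totals.mean()),
        sd=sd,
        min=float(totals.min()),
        max=float(totals.max()),
        n_outliers=int(samples["outlier"].sum()),
        class_proportions=props,
    )


@dataclass(frozen=True)
class DecayFit:
    """Exponential decay ``abundance = amplitude * exp(-rate * K)`` fitted by OLS
    of ln(abundance) on K; ``r2`` is on the log scale."""

    amplitude: float
    rate: float
    r2: float
    n_used: int
    n_dropped: int


def fit_abundance_decay(
    K: Sequence[float] | np.ndarray,
    abundance: Sequence[float] | np.ndarray,
    outlier: Sequence[bool] | np.ndarray | None = None,
) -> DecayFit:
    """Fit the inverse conductivity-abundance relation on paired observations.

    Outlier-flagged pairs are excluded; zero/negative abundances are dropped
    and counted in ``n_dropped``.  Requires at least 4 usable pairs with K > 0.
    """
    K = np.asarray(K, dtype=float)
    y = np.asarray(abundance, dtype=float)
    keep = np.ones(len(K), dtype=bool)
    if outlier is not None:
        keep &= ~np.asarray(outlier, dtype=bool)
    n_dropped = int(np.sum(keep & (y <= 0)))
    keep &= y > 0
    K, y = K[keep], y[keep]
    if len(K) < 4:
        raise ValueError("need at least 4 non-outlier pairs with positive abundance")
    if np.any(K <= 0):
        raise ValueError("K values must be positive")
    logy = np.log(y)
    slope, intercept = np.polyfit(K, logy, 1)
    pred = slope * K + intercept
    ss_res = float(np.sum((logy - pred) ** 2))
    ss_tot = float(np.sum((logy - logy.mean()) ** 2))
    # degenerate (constant) data explains nothing; clamp fp noise at zero
    r2 = 0.0 if ss_tot <= 1e-12 * max(1.0, float(np.sum(logy**2))) else max(0.0, 1.0 - ss_res / ss_tot)
    return DecayFit(
        amplitude=float(np.exp(intercept)),
        rate=float(-slope),
        r2=float(r2),
        n_used=len(K),
        n_dropped=n_dropped,
    )
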