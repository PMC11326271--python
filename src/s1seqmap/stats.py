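"""Quantitative summaries of resection maps.

The headline statistic is the mean resection length: after background
subtraction (value at +2.5 kb) and masking of signal below +100 bp and
above +2.5 kb, the co-oriented average profile is partitioned into 24 bins
of 100 bp and the mean is the fraction-weighted average of the bin
midpoints (150, 250, ..., 2450 nt). Companion summaries are the
central:resection signal ratio, the total signal per hotspot, per-hotspot
strengths for replicate scatter plots, and replicate CV.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .core import ContractError, CoorientedProfile, EndpointMap, Hotspot
from .profiles import subtract_background

__all__ = [
    "ResectionSummary",
    "ReplicateStats",
    "CENTRAL_WINDOW",
    "RESECTION_WINDOW",
    "TOTAL_WINDOW",
    "STRENGTH_WINDOW",
    "mean_resection_length",
    "central_resection_ratio",
    "total_signal",
    "hotspot_strength",
    "replicate_correlation",
    "replicate_cv",
    "cv_percent",
    "summarize_profile",
]

# windows in bp relative to the hotspot center
CENTRAL_WINDOW = (-1500, 100)     # [-1500, +100), half-open on the right
RESECTION_WINDOW = (100, 2500)    # [+100, +2500], inclusive
TOTAL_WINDOW = (-1500, 2500)      # inclusive
STRENGTH_WINDOW = (250, 2000)     # per-strand, inclusive, mirrored for bottom

_BIN_BP = 100
_N_BINS = 24
BIN_MIDPOINTS = np.arange(_N_BINS) * _BIN_BP + 150.0  # 150, 250, ..., 2450


@dataclass
class ResectionSummary:
    """All per-map summary quantities, computed from one unsmoothed
    co-oriented average profile."""

    mean_resection_length: float
    central_sum: float
    resection_sum: float
    central_resection_ratio: float
    total_signal: float
    background: float
    bin_fractions: np.ndarray = field(repr=False)

    def as_dict(self) -> dict[str, float]:
        return {
            "mean_resection_length": self.mean_resection_length,
            "central_sum": self.central_sum,
            "resection_sum": self.resection_sum,
            "central_resection_ratio": self.central_resection_ratio,
            "total_signal": self.total_signal,
            "background": self.background,
        }


@dataclass
class ReplicateStats:
    values: list[float]
    mean: float
    sd: float
    cv: float  # percent


def mean_resection_length(profile: CoorientedProfile) -> float:
    """Fraction-weighted mean resection length in nt.

    Expects the raw (unnormalized, unsmoothed) co-oriented average profile
    covering at least [+100, +2500]. Background (value at +2500) is
    subtracted, negatives clamped, signal outside [100, 2500] zeroed, and
    the remainder binned every 100 bp.
    """
    if profile.normalized != "none":
        raise ContractError("mean_resection_length expects an unnormalized profile")
    sub = subtract_background(profile)
    i = sub.index_of(100)
    j = sub.index_of(2500) + 1
    vals = sub.values[i:j]
    total = vals.sum()
    if total <= 0:
        raise ContractError("no resection signal in [100, 2500] after masking")
    offs = sub.offsets[i:j]
    bin_idx = np.minimum((offs - 100) // _BIN_BP, _N_BINS - 1)
    sums = np.bincount(bin_idx, weights=vals, minlength=_N_BINS)
    fractions = sums / total
    return float(fractions @ BIN_MIDPOINTS)


def _bin_fractions(profile: CoorientedProfile) -> tuple[np.ndarray, float]:
    sub = subtract_background(profile)
    i, j = sub.index_of(100), sub.index_of(2500) + 1
    vals = sub.values[i:j]
    total = vals.sum()
    bin_idx = np.minimum((sub.offsets[i:j] - 100) // _BIN_BP, _N_BINS - 1)
    sums = np.bincount(bin_idx, weights=vals, minlength=_N_BINS)
    return (sums / total if total > 0 else sums), float(total)


def central_resection_ratio(profile: CoorientedProfile) -> float:
    """Ratio of central-peak to resection-peak signal.

    The central window is [-1500, +100) half-open and the resection window
    [+100, +2500] inclusive, so offset +100 is counted once, in the
    resection window. Expects a background-subtracted, negative-clamped
    profile (apply :func:`~s1seqmap.profiles.subtract_background` first).
    """
    central = profile.window_sum(*CENTRAL_WINDOW, right_open=True)
    resection = profile.window_sum(*RESECTION_WINDOW)
    if resection <= 0:
        raise ContractError("resection sum is zero")
    return central / resection


def total_signal(profile: CoorientedProfile) -> float:
    """Sum of the unnormalized profile over offsets -1500..+2500 inclusive."""
    return profile.window_sum(*TOTAL_WINDOW)


def hotspot_strength(emap: EndpointMap, hotspot: Hotspot) -> float:
    """Per-hotspot signal: bottom-strand sum over [center-2000, center-250]
    plus top-strand sum over [center+250, center+2000], bounds inclusive.

    Windows are clipped at chromosome ends.
    """
    lo_bp, hi_bp = STRENGTH_WINDOW
    n = emap.layout.lengths[hotspot.chrom]
    c = hotspot.center
    b_lo, b_hi = max(c - hi_bp, 0), min(c - lo_bp + 1, n)
    t_lo, t_hi = max(c + lo_bp, 0), min(c + hi_bp + 1, n)
    total = 0.0
    if b_lo < b_hi:
        total += float(emap.bottom[hotspot.chrom][b_lo:b_hi].sum())
    if t_lo < t_hi:
        total += float(emap.top[hotspot.chrom][t_lo:t_hi].sum())
    return total


def replicate_correlation(a, b) -> float:
    """Pearson r between two replicates' per-hotspot strengths.

    Hotspots with 0 signal in either replicate are excluded; r is computed
    on log10-transformed values of the remainder. (The 1e-2 RPM floor used
    for scatter plotting is a display transform only and never enters r.)
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ContractError("replicates must share the hotspot list")
    keep = (a > 0) & (b > 0)
    if keep.sum() < 3:
        raise ContractError("fewer than 3 hotspots with signal in both replicates")
    return float(sps.pearsonr(np.log10(a[keep]), np.log10(b[keep])).statistic)


def cv_percent(mean: float, sd: float) -> float:
    """Coefficient of variation in percent, 100*SD/mean."""
    if mean <= 0:
        raise ContractError("CV undefined for non-positive mean")
    return 100.0 * sd / mean


def replicate_cv(values) -> ReplicateStats:
    """Mean, sample SD (n-1 denominator) and CV (%) across replicates."""
    vals = [float(v) for v in values]
    if len(vals) < 2:
        raise ContractError("replicate CV needs at least 2 values")
    mean = float(np.mean(vals))
    sd = float(np.std(vals, ddof=1))
    return ReplicateStats(values=vals, mean=mean, sd=sd, cv=cv_percent(mean, sd))


def summarize_profile(profile: CoorientedProfile) -> ResectionSummary:
    """Compute every per-map summary from one raw co-oriented profile."""
    sub = subtract_background(profile)
    fractions, _ = _bin_fractions(profile)
    return ResectionSummary(
        mean_resection_length=mean_resection_length(profile),
        central_sum=sub.window_sum(*CENTRAL_WINDOW, right_open=True),
        resection_sum=sub.window_sum(*RESECTION_WINDOW),
        central_resection_ratio=central_resection_ratio(sub),
        total_signal=total_signal(profile),
        background=float(sub.background),
        bin_fractions=fractions,
    )
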