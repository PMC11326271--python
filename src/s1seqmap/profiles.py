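"""Hotspot-anchored matrices, co-oriented average profiles, smoothing and
normalization.

The central objects are the :class:`~s1seqmap.core.AnchoredMatrix` (one row
per hotspot, one column per offset from the hotspot center) and the
:class:`~s1seqmap.core.CoorientedProfile` obtained by folding the bottom
strand through the hotspot center (x -> -x), combining with the top strand
and averaging across hotspots. Resection signal from both DSB sides then
accumulates at positive offsets while the S1-specific central signal, which
has opposite polarity, folds to negative offsets.
"""

from __future__ import annotations

import numpy as np

from .core import (
    AnchoredMatrix,
    ContractError,
    CoorientedProfile,
    EndpointMap,
    Hotspot,
)

__all__ = [
    "AnchoredMatrix",
    "CoorientedProfile",
    "DEFAULT_W",
    "HEATMAP_W",
    "HANN_DISPLAY",
    "HANN_FINE",
    "extract_matrix",
    "coorient",
    "average_profile",
    "hann_smooth",
    "subtract_background",
    "internal_normalize",
    "bin_matrix",
    "local_normalize",
    "hotspot_profile",
]

DEFAULT_W = 2500          # bp; required by the +2500 background convention
HEATMAP_W = 2000          # bp; 2*2000+1 matches the 4001-bp local window
HANN_DISPLAY = 151        # bp Hann window for display smoothing
HANN_FINE = 51            # bp Hann window for fine comparisons
BACKGROUND_OFFSET = 2500  # bp right of center
PEAK_SEARCH = (100, 2500)  # resection-peak search range, inclusive


def _window(vec: np.ndarray, center: int, W: int) -> tuple[np.ndarray, bool]:
    """Slice vec[center-W : center+W+1] with zero fill outside the array."""
    n = len(vec)
    lo, hi = center - W, center + W + 1
    if lo >= 0 and hi <= n:
        return vec[lo:hi], False
    out = np.zeros(2 * W + 1)
    src_lo, src_hi = max(lo, 0), min(hi, n)
    if src_lo < src_hi:
        out[src_lo - lo : src_hi - lo] = vec[src_lo:src_hi]
    return out, True


def extract_matrix(
    emap: EndpointMap, hotspots: list[Hotspot], W: int = DEFAULT_W
) -> AnchoredMatrix:
    """Build per-base strand matrices of map signal around hotspot centers.

    Row h, strand s, column W + x holds the map value at (center_h + x, s).
    Offsets falling outside the chromosome are zero-filled and the hotspot
    is flagged clipped.
    """
    if not hotspots:
        raise ContractError("empty hotspot list")
    n = len(hotspots)
    top = np.zeros((n, 2 * W + 1))
    bottom = np.zeros((n, 2 * W + 1))
    clipped = np.zeros(n, dtype=bool)
    for i, h in enumerate(hotspots):
        top[i], c1 = _window(emap.top[h.chrom], h.center, W)
        bottom[i], c2 = _window(emap.bottom[h.chrom], h.center, W)
        clipped[i] = c1 or c2
    return AnchoredMatrix(hotspots=list(hotspots), W=W, top=top, bottom=bottom, clipped=clipped)


def coorient(matrix: AnchoredMatrix) -> AnchoredMatrix:
    """Fold bottom-strand signal through the hotspot center and combine.

    combined[h, x] = top[h, x] + bottom[h, -x]. Mass is conserved exactly.
    """
    if matrix.top is None or matrix.bottom is None:
        raise ContractError("coorient needs both strand channels")
    if matrix.bin_size != 1:
        raise ContractError("coorient operates on per-base matrices")
    combined = matrix.top + matrix.bottom[:, ::-1]
    return AnchoredMatrix(
        hotspots=matrix.hotspots,
        W=matrix.W,
        combined=combined,
        clipped=matrix.clipped,
        normalization=matrix.normalization,
    )


def average_profile(matrix: AnchoredMatrix) -> CoorientedProfile:
    """Arithmetic mean over hotspot rows of the combined channel.

    Hotspots are weighted equally; units are RPM per hotspot when the map
    was RPM-normalized.
    """
    if matrix.combined is None:
        raise ContractError("average_profile needs a co-oriented matrix")
    W = matrix.W
    return CoorientedProfile(
        offsets=np.arange(-W, W + 1),
        values=matrix.combined.mean(axis=0),
        n_anchors=matrix.n_hotspots,
    )


def hann_weights(N: int) -> np.ndarray:
    """Symmetric Hann weights w[k] = 0.5*(1 - cos(2*pi*k/(N-1))), sum 1."""
    w = np.hanning(N)
    return w / w.sum()


def hann_smooth(profile: CoorientedProfile, N: int = HANN_DISPLAY) -> CoorientedProfile:
    """Smooth with an N-bp Hann window (N odd).

    At the array edges the weights falling outside the support are dropped
    and the remainder renormalized to sum 1, so a constant profile is a
    fixed point everywhere, edges included.
    """
    if N % 2 == 0 or N < 3 or N > len(profile.values):
        raise ContractError(f"Hann window must be odd and in [3, profile length]; got {N}")
    w = hann_weights(N)
    num = np.convolve(profile.values, w, mode="same")
    den = np.convolve(np.ones_like(profile.values), w, mode="same")
    return profile.replace(num / den, smoothing=N)


def subtract_background(profile: CoorientedProfile) -> CoorientedProfile:
    """Subtract the signal value 2,500 bp right of center; clamp negatives to 0."""
    b = profile.value_at(BACKGROUND_OFFSET)
    return profile.replace(np.maximum(profile.values - b, 0.0), background=b)


def internal_normalize(profile: CoorientedProfile) -> CoorientedProfile:
    """Background-subtract, then scale the resection peak to 1.

    The background is the value at +2,500 bp; negatives after subtraction
    are set to zero; the peak is the maximum over offsets [100, 2500] so
    the central signal cannot set the normalization scale. The output is
    invariant to any positive scaling of the input.
    """
    sub = subtract_background(profile)
    i, j = sub.index_of(PEAK_SEARCH[0]), sub.index_of(PEAK_SEARCH[1]) + 1
    peak = float(sub.values[i:j].max())
    if peak <= 0:
        raise ContractError("no resection signal: peak over [100, 2500] is zero")
    out = sub.replace(sub.values / peak, normalized="internal")
    out.extra["peak"] = peak
    return out


def bin_matrix(matrix: AnchoredMatrix, bin_size: int) -> AnchoredMatrix:
    """Sum per-base columns into bins tiling offsets left-to-right from -W.

    A final partial bin is allowed; total mass is conserved exactly.
    """
    if bin_size < 1:
        raise ContractError("bin size must be >= 1")
    if bin_size == 1:
        return matrix
    if matrix.bin_size != 1:
        raise ContractError("matrix is already binned")
    ncols = (matrix.top if matrix.top is not None else matrix.combined).shape[1]
    edges = np.arange(0, ncols, bin_size)

    def _bin(arr: np.ndarray | None) -> np.ndarray | None:
        return None if arr is None else np.add.reduceat(arr, edges, axis=1)

    return AnchoredMatrix(
        hotspots=matrix.hotspots,
        W=matrix.W,
        top=_bin(matrix.top),
        bottom=_bin(matrix.bottom),
        combined=_bin(matrix.combined),
        bin_size=bin_size,
        clipped=matrix.clipped,
        normalization=matrix.normalization,
    )


def local_normalize(matrix: AnchoredMatrix, window: int = 4001) -> AnchoredMatrix:
    """Divide each hotspot row by its total signal in a centered window.

    Both strands count jointly toward the row total, so each non-zero
    hotspot carries total weight 1 within the window and spatial patterns
    become comparable between hotspots of different strengths. All-zero
    rows are left as zero and flagged.
    """
    half = (window - 1) // 2
    if matrix.W < half:
        raise ContractError("matrix does not cover the normalization window")
    channels = matrix.channels()
    if not channels:
        raise ContractError("matrix has no signal channels")

    # column index range covering offsets [-half, +half]
    if matrix.bin_size == 1:
        lo, hi = matrix.W - half, matrix.W + half + 1
    else:
        # bins tile from -W in steps of bin_size; include bins intersecting the window
        ncols = next(iter(channels.values())).shape[1]
        starts = -matrix.W + np.arange(ncols) * matrix.bin_size
        ends = starts + matrix.bin_size
        inside = (ends > -half) & (starts <= half)
        lo, hi = int(np.argmax(inside)), int(len(inside) - np.argmax(inside[::-1]))

    totals = sum(arr[:, lo:hi].sum(axis=1) for arr in channels.values())
    zero = totals <= 0
    denom = np.where(zero, 1.0, totals)

    def _norm(arr: np.ndarray | None) -> np.ndarray | None:
        return None if arr is None else arr / denom[:, None]

    return AnchoredMatrix(
        hotspots=matrix.hotspots,
        W=matrix.W,
        top=_norm(matrix.top),
        bottom=_norm(matrix.bottom),
        combined=_norm(matrix.combined),
        bin_size=matrix.bin_size,
        clipped=matrix.clipped,
        zero_rows=zero,
        normalization=f"local:{window}",
    )


def hotspot_profile(
    emap: EndpointMap,
    hotspots: list[Hotspot],
    W: int = DEFAULT_W,
    smoothing: int | None = None,
) -> CoorientedProfile:
    """Convenience chain: extract, co-orient, average, optionally smooth."""
    prof = average_profile(coorient(extract_matrix(emap, hotspots, W)))
    if smoothing:
        prof = hann_smooth(prof, smoothing)
    return prof
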