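"""Scan for H-DNA-forming C(TC)n mirror repeats and profile signal at them.

Polypyrimidine-polypurine mirror repeats such as C(TC)20 can extrude an
intramolecular triplex (H-DNA) whose looped-out single strand is cleaved by
nuclease S1 under acidic conditions; under permissive pH these loci soak up
a large fraction of sequencing reads. The scanner reports every maximal
C(TC)^n run with n >= n_min on either strand; signal at hits is profiled
with map strands relabeled as pyrimidine/purine per hit, without the
co-orientation folding used for hotspots.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pyfaidx

from .core import ContractError, CoorientedProfile, EndpointMap, FormatError, MotifHit

__all__ = ["MotifHit", "find_mirror_repeats", "motif_profile", "write_motif_bed"]

DEFAULT_N_MIN = 20

# C(TC)^n on the top strand (pyrimidine strand +) and its reverse
# complement G(AG)^n (pyrimidine strand -). re.finditer yields leftmost,
# greedy (hence maximal) non-overlapping matches; runs containing N or any
# other letter break automatically.


def _patterns(n_min: int) -> list[tuple[re.Pattern, str]]:
    return [
        (re.compile(r"C(?:TC){%d,}" % n_min), "+"),
        (re.compile(r"G(?:AG){%d,}" % n_min), "-"),
    ]


def _scan_sequence(chrom: str, seq: str, n_min: int) -> list[MotifHit]:
    seq = seq.upper()
    hits = []
    for pattern, strand in _patterns(n_min):
        for m in pattern.finditer(seq):
            n = (m.end() - m.start() - 1) // 2
            hits.append(
                MotifHit(
                    chrom=chrom,
                    start=m.start(),
                    end=m.end(),
                    pyrimidine_strand=strand,
                    n=n,
                )
            )
    hits.sort(key=lambda h: h.start)
    return hits


def find_mirror_repeats(
    source: str | Path | dict[str, str], n_min: int = DEFAULT_N_MIN
) -> list[MotifHit]:
    """Find all maximal C(TC)^n mirror repeats with n >= n_min.

    ``source`` is a FASTA path or a {chrom: sequence} dict. Matching is
    case-insensitive; overlapping sub-repeats of a maximal run are not
    reported; runs are broken at N (or any non-ACGT character).
    """
    if n_min < 1:
        raise ContractError("n_min must be >= 1")
    if isinstance(source, dict):
        items = source.items()
    else:
        try:
            fasta = pyfaidx.Fasta(str(source))
        except Exception as exc:  # pyfaidx raises several classes
            raise FormatError(f"cannot parse FASTA {source}: {exc}") from exc
        items = ((name, str(fasta[name][:])) for name in fasta.keys())
    hits: list[MotifHit] = []
    for chrom, seq in items:
        hits.extend(_scan_sequence(chrom, seq, n_min))
    return hits


def motif_profile(
    emap: EndpointMap, hits: list[MotifHit], W: int = 1000
) -> tuple[CoorientedProfile, CoorientedProfile]:
    """Average strand-resolved signal around motif midpoints.

    Hits on the - pyrimidine strand are coordinate-flipped so all hits
    share one orientation, and map strands are relabeled per hit: for a +
    hit the top strand carries pyrimidine-strand reads, for a - hit the
    bottom strand does. Returns (pyrimidine profile, purine profile); the
    two read classes stay separate (no co-orientation folding).
    """
    if not hits:
        raise ContractError("empty motif hit list")
    width = 2 * W + 1
    pyr = np.zeros(width)
    pur = np.zeros(width)
    for hit in hits:
        top = _slice(emap.top[hit.chrom], hit.midpoint, W)
        bottom = _slice(emap.bottom[hit.chrom], hit.midpoint, W)
        if hit.pyrimidine_strand == "+":
            pyr += top
            pur += bottom
        else:
            pyr += bottom[::-1]
            pur += top[::-1]
    offsets = np.arange(-W, W + 1)
    n = len(hits)
    return (
        CoorientedProfile(offsets=offsets, values=pyr / n, n_anchors=n),
        CoorientedProfile(offsets=offsets, values=pur / n, n_anchors=n),
    )


def _slice(vec: np.ndarray, center: int, W: int) -> np.ndarray:
    out = np.zeros(2 * W + 1)
    lo, hi = max(center - W, 0), min(center + W + 1, len(vec))
    if lo < hi:
        out[lo - (center - W) : hi - (center - W)] = vec[lo:hi]
    return out


def write_motif_bed(hits: list[MotifHit], path: str | Path) -> None:
    """Export hits as BED6 with name CTC<n> and strand = pyrimidine strand."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.chrom}\t{h.start}\t{h.end}\tCTC{h.n}\t{h.n}\t{h.pyrimidine_strand}\n"
            )
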