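"""Readers and writers for the standard formats the pipeline touches.

Conventions: all coordinates are 0-based half-open on disk and in memory.
Endpoint BED6 files carry the integer count in the score column with one
width-1 interval per (position, strand) cell; profile TSVs carry their
provenance (smoothing window, normalization state, background) in ``#``
header lines.
"""

from __future__ import annotations

import warnings
from typing import Iterator

import numpy as np
import pandas as pd
import pysam

from .core import (
    BOTTOM,
    TOP,
    AlignmentRecord,
    CoorientedProfile,
    EndpointMap,
    FormatError,
    GenomeLayout,
    Hotspot,
)

__all__ = [
    "GenomeLayout",
    "AlignmentRecord",
    "Hotspot",
    "read_layout",
    "read_alignments",
    "read_chrom_sizes",
    "read_hotspot_bed",
    "write_hotspot_bed",
    "write_endpoint_bed",
    "read_endpoint_bed",
    "write_bedgraph",
    "write_profile_tsv",
    "read_profile_tsv",
    "write_fasta",
]


def read_layout(path: str) -> GenomeLayout:
    """Recover the genome layout from a SAM/BAM header."""
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        if fh.nreferences == 0:
            raise FormatError(f"{path}: SAM/BAM header declares no sequences")
        return GenomeLayout.from_dict(
            {name: fh.get_reference_length(name) for name in fh.references}
        )


def read_alignments(path: str) -> Iterator[AlignmentRecord]:
    """Stream aligned segments from a SAM/BAM file.

    Unaligned segments are skipped. Secondary/supplementary alignments are
    skipped too: endpoint assignment wants each template counted once.
    """
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        if fh.nreferences == 0:
            raise FormatError(f"{path}: SAM/BAM header declares no sequences")
        for seg in fh:
            if seg.is_unmapped or seg.is_secondary or seg.is_supplementary:
                continue
            span = seg.reference_length
            if not span:
                continue
            yield AlignmentRecord(
                query_name=seg.query_name,
                chrom=seg.reference_name,
                pos=seg.reference_start,
                span=span,
                is_reverse=seg.is_reverse,
                mapq=seg.mapping_quality,
                is_read1=(not seg.is_paired) or seg.is_read1,
                is_proper_pair=(not seg.is_paired) or seg.is_proper_pair,
                is_duplicate=seg.is_duplicate,
                mate_pos=seg.next_reference_start if seg.is_paired else None,
            )


def read_chrom_sizes(path: str) -> GenomeLayout:
    """Read a two-column ``chrom<TAB>length`` file into a GenomeLayout."""
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise FormatError(f"{path}: need at least 2 columns")
            lengths[fields[0]] = int(fields[1])
    return GenomeLayout.from_dict(lengths)


def _rank_hotspots(hotspots: list[Hotspot]) -> None:
    # descending strength; ties broken by genomic (chromosome, center) order,
    # which is the input order because the list is already sorted
    order = sorted(
        range(len(hotspots)), key=lambda i: (-hotspots[i].strength, i)
    )
    for rank0, i in enumerate(order):
        hotspots[i].rank = rank0 + 1


def read_hotspot_bed(path: str, layout: GenomeLayout) -> list[Hotspot]:
    """Read hotspot anchors from a BED file (>= 3 columns).

    Column 5, when present, is read as the strength score (default 0). The
    center is the integer midpoint floor((start+end)/2). Hotspots on
    chromosomes absent from ``layout`` are skipped with a warning.
    """
    hotspots: list[Hotspot] = []
    skipped = 0
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.split()
            if len(f) < 3:
                raise FormatError(f"{path}:{ln}: BED needs >= 3 columns")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            if start >= end:
                raise FormatError(f"{path}:{ln}: malformed interval {start}>={end}")
            if chrom not in layout:
                skipped += 1
                continue
            name = f[3] if len(f) > 3 and f[3] != "." else f"hs{ln}"
            strength = float(f[4]) if len(f) > 4 else 0.0
            center = (start + end) // 2
            if not 0 <= center < layout.lengths[chrom]:
                raise FormatError(f"{path}:{ln}: center outside chromosome")
            hotspots.append(Hotspot(name=name, chrom=chrom, center=center, strength=strength))
    if skipped:
        warnings.warn(f"{path}: skipped {skipped} hotspot(s) on unknown chromosomes")
    chrom_order = {c: i for i, c in enumerate(layout.names)}
    hotspots.sort(key=lambda h: (chrom_order[h.chrom], h.center))
    _rank_hotspots(hotspots)
    return hotspots


def write_hotspot_bed(hotspots: list[Hotspot], path: str, width: int = 2) -> None:
    """Write hotspots as BED intervals of ``width`` bp centered on each anchor."""
    half = width // 2
    with open(path, "w") as fh:
        for h in hotspots:
            fh.write(
                f"{h.chrom}\t{h.center - half}\t{h.center - half + width}\t"
                f"{h.name}\t{h.strength:g}\t.\n"
            )


def write_endpoint_bed(emap: EndpointMap, path: str) -> None:
    """Write a raw-count EndpointMap as BED6, one line per nonzero cell."""
    if emap.state != "raw":
        raise FormatError("endpoint BED holds integer counts; map must be raw")
    with open(path, "w") as fh:
        for chrom in emap.layout.names:
            for arrays, symbol in ((emap.top, "+"), (emap.bottom, "-")):
                vec = arrays[chrom]
                for pos in np.flatnonzero(vec):
                    fh.write(f"{chrom}\t{pos}\t{pos + 1}\t.\t{int(vec[pos])}\t{symbol}\n")


def read_endpoint_bed(path: str, layout: GenomeLayout) -> EndpointMap:
    """Read a BED6 endpoint file (score = integer count) into an EndpointMap."""
    emap = EndpointMap.zeros(layout)
    total = 0
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.split()
            if len(f) < 6:
                raise FormatError(f"{path}:{ln}: endpoint BED needs 6 columns")
            chrom, start, end, _, score, strand = f[:6]
            start, end = int(start), int(end)
            if end != start + 1:
                raise FormatError(f"{path}:{ln}: endpoint intervals must have width 1")
            if chrom not in layout:
                raise FormatError(f"{path}:{ln}: unknown chromosome {chrom!r}")
            try:
                count = int(score)
            except ValueError:
                raise FormatError(f"{path}:{ln}: non-integer count {score!r}") from None
            if count < 0:
                raise FormatError(f"{path}:{ln}: negative count")
            if strand == "+":
                emap.top[chrom][start] += count
            elif strand == "-":
                emap.bottom[chrom][start] += count
            else:
                raise FormatError(f"{path}:{ln}: strand must be + or -")
            total += count
    emap.total_raw = total
    return emap


def write_bedgraph(emap: EndpointMap, prefix: str) -> tuple[str, str]:
    """Export per-strand signal as two bedGraph files ``<prefix>.top.bedgraph``
    and ``<prefix>.bottom.bedgraph`` (width-1 intervals, nonzero cells only)."""
    paths = []
    for arrays, label in ((emap.top, "top"), (emap.bottom, "bottom")):
        out = f"{prefix}.{label}.bedgraph"
        with open(out, "w") as fh:
            for chrom in emap.layout.names:
                vec = arrays[chrom]
                for pos in np.flatnonzero(vec):
                    fh.write(f"{chrom}\t{pos}\t{pos + 1}\t{vec[pos]:g}\n")
        paths.append(out)
    return tuple(paths)


def write_profile_tsv(profile: CoorientedProfile, path: str) -> None:
    """Write a profile with its provenance header to a TSV file."""
    with open(path, "w") as fh:
        fh.write(f"# smoothing={profile.smoothing if profile.smoothing else 'none'}\n")
        fh.write(f"# normalized={profile.normalized}\n")
        bg = "none" if profile.background is None else repr(profile.background)
        fh.write(f"# background={bg}\n")
        fh.write(f"# n_anchors={profile.n_anchors}\n")
        fh.write("offset\tvalue\n")
        for off, val in zip(profile.offsets, profile.values):
            fh.write(f"{off}\t{val:.12g}\n")


def read_profile_tsv(path: str) -> CoorientedProfile:
    meta: dict[str, str] = {}
    with open(path) as fh:
        lines = fh.readlines()
    body = 0
    for line in lines:
        if not line.startswith("#"):
            break
        key, _, val = line[1:].strip().partition("=")
        meta[key.strip()] = val.strip()
        body += 1
    from io import StringIO

    table = pd.read_csv(StringIO("".join(lines[body:])), sep="\t")
    smoothing = meta.get("smoothing", "none")
    background = meta.get("background", "none")
    return CoorientedProfile(
        offsets=table["offset"].to_numpy(),
        values=table["value"].to_numpy(),
        smoothing=None if smoothing == "none" else int(smoothing),
        background=None if background == "none" else float(background),
        normalized=meta.get("normalized", "none"),
        n_anchors=int(meta.get("n_anchors", 0)),
    )


def write_fasta(sequences: dict[str, str], path: str, line_width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), line_width):
                fh.write(seq[i : i + line_width] + "\n")
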