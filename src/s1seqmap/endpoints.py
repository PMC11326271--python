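"""Convert filtered alignments into strand-specific endpoint signal.

The resection endpoint is counted at the nucleotide next to where the
biotinylated adaptor mapped: for the adaptor-proximal mate (read 1) this is
its first aligned genomic base — the leftmost aligned position for a
forward alignment (endpoint on the top strand) and the rightmost aligned
position for a reverse alignment (endpoint on the bottom strand). Only
properly paired, non-duplicate first mates with MAPQ >= the threshold
(default 20) contribute.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Iterator

from .core import BOTTOM, TOP, AlignmentRecord, ContractError, EndpointMap, GenomeLayout

__all__ = [
    "EndpointMap",
    "DEFAULT_MAPQ",
    "assign_endpoint",
    "build_endpoint_map",
    "to_rpm",
    "deduplicate_endpoints",
]

DEFAULT_MAPQ = 20

# rejection categories, in reporting order
REJECT_MATE2 = "mate2"
REJECT_LOW_MAPQ = "low_mapq"
REJECT_DUPLICATE = "duplicate"
REJECT_IMPROPER = "improper_pair"


@dataclass(frozen=True)
class Endpoint:
    chrom: str
    pos: int
    strand: str


def assign_endpoint(
    rec: AlignmentRecord, mapq_min: int = DEFAULT_MAPQ
) -> Endpoint | str:
    """Map one alignment to its endpoint cell, or return a rejection reason.

    Returns an :class:`Endpoint` for qualifying records and one of the
    rejection category strings otherwise.
    """
    if not rec.is_read1:
        return REJECT_MATE2
    if rec.is_duplicate:
        return REJECT_DUPLICATE
    if not rec.is_proper_pair:
        return REJECT_IMPROPER
    if rec.mapq < mapq_min:
        return REJECT_LOW_MAPQ
    if rec.is_reverse:
        return Endpoint(rec.chrom, rec.pos + rec.span - 1, BOTTOM)
    return Endpoint(rec.chrom, rec.pos, TOP)


def build_endpoint_map(
    records: Iterable[AlignmentRecord],
    layout: GenomeLayout,
    mapq_min: int = DEFAULT_MAPQ,
) -> tuple[EndpointMap, Counter]:
    """Count endpoints of accepted records into a raw EndpointMap.

    Returns the map and a Counter of rejection tallies per category.
    Each accepted record increments exactly one (position, strand) cell,
    so the map total equals the number of accepted records.
    """
    emap = EndpointMap.zeros(layout)
    rejects: Counter = Counter()
    accepted = 0
    for rec in records:
        out = assign_endpoint(rec, mapq_min)
        if isinstance(out, str):
            rejects[out] += 1
            continue
        if out.chrom not in layout:
            raise ContractError(f"record chromosome {out.chrom!r} absent from layout")
        if not 0 <= out.pos < layout.lengths[out.chrom]:
            raise ContractError(
                f"endpoint {out.chrom}:{out.pos} outside chromosome bounds"
            )
        emap.strand(out.strand)[out.chrom][out.pos] += 1
        accepted += 1
    emap.total_raw = accepted
    return emap, rejects


def to_rpm(emap: EndpointMap) -> EndpointMap:
    """Normalize a raw map to reads per million (RPM).

    Every cell is scaled by 1e6 / total raw endpoints, so the genome-wide
    sum over both strands becomes 1e6.
    """
    if emap.state != "raw":
        raise ContractError("to_rpm expects a raw-count map")
    total = emap.total_raw or int(round(emap.total()))
    if total <= 0:
        raise ContractError("empty library: no endpoints to normalize")
    scale = 1e6 / total
    out = emap.copy()
    for chrom in out.layout.names:
        out.top[chrom] *= scale
        out.bottom[chrom] *= scale
    out.state = "rpm"
    out.total_raw = total
    return out


def deduplicate_endpoints(
    records: Iterable[AlignmentRecord],
) -> Iterator[AlignmentRecord]:
    """Optional built-in PCR-duplicate removal.

    Among records sharing (chromosome, orientation, endpoint position, mate
    position) only the first encountered is kept. Off by default in the
    pipeline: when the upstream BAM already carries duplicate flags this
    would double-filter.
    """
    seen: set[tuple] = set()
    for rec in records:
        endpoint = rec.pos + rec.span - 1 if rec.is_reverse else rec.pos
        key = (rec.chrom, rec.is_reverse, endpoint, rec.mate_pos)
        if key in seen:
            continue
        seen.add(key)
        yield rec
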