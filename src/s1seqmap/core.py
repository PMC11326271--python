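"""Core data containers shared across the pipeline.

All genomic coordinates are 0-based, half-open (BED dialect). An interval
[a, a+1) denotes the single base at 0-based position a. Strands are "top"
(the reference/plus strand) and "bottom" (its complement); in BED output
they are written as "+" and "-".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

TOP = "top"
BOTTOM = "bottom"
STRANDS = (TOP, BOTTOM)


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


class ContractError(ValueError):
    """Raised when an operation's preconditions are violated."""


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome names with their lengths in bp."""

    names: tuple[str, ...]
    lengths: dict[str, int]

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ContractError("chromosome names must be unique")
        for name in self.names:
            if not name:
                raise ContractError("chromosome names must be non-empty")
            if self.lengths.get(name, 0) < 1:
                raise ContractError(f"chromosome {name!r} must have length >= 1")

    @classmethod
    def from_dict(cls, lengths: dict[str, int]) -> "GenomeLayout":
        return cls(tuple(lengths), dict(lengths))

    def __contains__(self, name: str) -> bool:
        return name in self.lengths

    def __len__(self) -> int:
        return len(self.names)


@dataclass(frozen=True)
class AlignmentRecord:
    """One aligned segment from a SAM/BAM file.

    ``pos`` is the 0-based leftmost aligned reference position and ``span``
    the number of reference bases consumed, so the rightmost aligned base
    sits at ``pos + span - 1``.
    """

    query_name: str
    chrom: str
    pos: int
    span: int
    is_reverse: bool
    mapq: int
    is_read1: bool
    is_proper_pair: bool
    is_duplicate: bool
    mate_pos: int | None = None

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ContractError("alignment position must be >= 0")
        if self.span < 1:
            raise ContractError("alignment span must be >= 1")
        if self.mapq < 0:
            raise ContractError("mapping quality must be >= 0")


@dataclass
class Hotspot:
    """A DSB hotspot anchor: genomic midpoint plus a strength score.

    Strength is in arbitrary units (e.g. SPO11-oligo RPM); rank 1 is the
    strongest hotspot once ranks are assigned.
    """

    name: str
    chrom: str
    center: int
    strength: float = 0.0
    rank: int | None = None

    def __post_init__(self) -> None:
        if self.strength < 0:
            raise ContractError("hotspot strength must be >= 0")


@dataclass
class EndpointMap:
    """Per-chromosome, per-strand base-resolution endpoint signal.

    In the ``raw`` state every cell holds an integer endpoint count; after
    RPM normalization (state ``rpm``) the genome-wide sum over both strands
    is 1e6 whenever any endpoints were counted.
    """

    layout: GenomeLayout
    top: dict[str, np.ndarray]
    bottom: dict[str, np.ndarray]
    state: str = "raw"
    total_raw: int = 0

    @classmethod
    def zeros(cls, layout: GenomeLayout) -> "EndpointMap":
        top = {c: np.zeros(layout.lengths[c]) for c in layout.names}
        bottom = {c: np.zeros(layout.lengths[c]) for c in layout.names}
        return cls(layout=layout, top=top, bottom=bottom)

    def strand(self, name: str) -> dict[str, np.ndarray]:
        if name == TOP:
            return self.top
        if name == BOTTOM:
            return self.bottom
        raise ContractError(f"unknown strand {name!r}")

    def total(self) -> float:
        return float(
            sum(a.sum() for a in self.top.values())
            + sum(a.sum() for a in self.bottom.values())
        )

    def copy(self) -> "EndpointMap":
        return EndpointMap(
            layout=self.layout,
            top={c: a.copy() for c, a in self.top.items()},
            bottom={c: a.copy() for c, a in self.bottom.items()},
            state=self.state,
            total_raw=self.total_raw,
        )

    def equals(self, other: "EndpointMap") -> bool:
        if self.layout.names != other.layout.names or self.state != other.state:
            return False
        return all(
            np.array_equal(self.top[c], other.top[c])
            and np.array_equal(self.bottom[c], other.bottom[c])
            for c in self.layout.names
        )


@dataclass
class AnchoredMatrix:
    """Hotspot x offset signal matrices, one per strand.

    At per-base resolution column j holds the signal at offset ``j - W``
    from each hotspot center. After :func:`~s1seqmap.profiles.coorient`
    the ``combined`` channel replaces the strand pair.
    """

    hotspots: list[Hotspot]
    W: int
    top: np.ndarray | None = None
    bottom: np.ndarray | None = None
    combined: np.ndarray | None = None
    bin_size: int = 1
    clipped: np.ndarray | None = None
    zero_rows: np.ndarray | None = None
    normalization: str = "none"

    @property
    def n_hotspots(self) -> int:
        return len(self.hotspots)

    def channels(self) -> dict[str, np.ndarray]:
        out = {}
        if self.top is not None:
            out["top"] = self.top
        if self.bottom is not None:
            out["bottom"] = self.bottom
        if self.combined is not None:
            out["combined"] = self.combined
        return out


@dataclass
class CoorientedProfile:
    """Average signal per offset around (co-oriented) anchors.

    Units are RPM per anchor until internal normalization makes the values
    dimensionless. Provenance flags record smoothing, the background value
    subtracted, and the normalization state.
    """

    offsets: np.ndarray
    values: np.ndarray
    smoothing: int | None = None
    background: float | None = None
    normalized: str = "none"
    n_anchors: int = 0
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.offsets = np.asarray(self.offsets, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.offsets.shape != self.values.shape:
            raise ContractError("offsets and values must have matching shape")
        if not np.all(np.isfinite(self.values)):
            raise ContractError("profile values must be finite")

    @property
    def W(self) -> int:
        return int(self.offsets.max())

    def index_of(self, offset: int) -> int:
        i = int(offset - self.offsets[0])
        if i < 0 or i >= len(self.offsets) or self.offsets[i] != offset:
            raise ContractError(f"offset {offset} outside profile support")
        return i

    def value_at(self, offset: int) -> float:
        return float(self.values[self.index_of(offset)])

    def window_sum(self, lo: int, hi: int, *, right_open: bool = False) -> float:
        """Sum of values over offsets lo..hi (inclusive, or [lo, hi) if
        ``right_open``)."""
        i = self.index_of(lo)
        j = self.index_of(hi) + (0 if right_open else 1)
        return float(self.values[i:j].sum())

    def replace(self, values: np.ndarray, **flags) -> "CoorientedProfile":
        kw = dict(
            offsets=self.offsets,
            values=values,
            smoothing=self.smoothing,
            background=self.background,
            normalized=self.normalized,
            n_anchors=self.n_anchors,
            extra=dict(self.extra),
        )
        kw.update(flags)
        return CoorientedProfile(**kw)


@dataclass(frozen=True)
class MotifHit:
    """A maximal C(TC)n mirror-repeat occurrence.

    ``pyrimidine_strand`` is "+" when the C(TC)n reading lies on the top
    strand and "-" when it lies on the bottom strand (i.e. the top strand
    reads G(AG)n). The interval is 0-based half-open and spans 2n+1 bases.
    """

    chrom: str
    start: int
    end: int
    pyrimidine_strand: str
    n: int
    maximal: bool = True

    def __post_init__(self) -> None:
        if self.end - self.start != 2 * self.n + 1:
            raise ContractError("mirror repeat must span 2n+1 bases")
        if self.pyrimidine_strand not in "+-":
            raise ContractError("pyrimidine strand must be + or -")

    @property
    def midpoint(self) -> int:
        return self.start + self.n
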