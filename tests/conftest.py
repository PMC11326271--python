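import numpy as np
import pytest

from s1seqmap import sim
from s1seqmap.core import AlignmentRecord, EndpointMap, GenomeLayout


@pytest.fixture(scope="session")
def small_config():
    """A small but structurally complete S1-seq simulation."""
    return sim.SimulationConfig(
        seed=11,
        chrom_lengths={"chrT": 1_500_000},
        n_hotspots=15,
        n_reads=60_000,
        n_motifs=8,
        ph=4.3,
        method="s1",
    )


@pytest.fixture(scope="session")
def small_sim(small_config):
    return sim.simulate(small_config)


@pytest.fixture
def toy_layout():
    return GenomeLayout.from_dict({"chrA": 10_000, "chrB": 5_000})


def random_alignments(rng, layout, n):
    """Toy alignments covering every accept/reject category."""
    recs = []
    for i in range(n):
        chrom = str(rng.choice(layout.names))
        span = int(rng.integers(30, 120))
        pos = int(rng.integers(0, layout.lengths[chrom] - span))
        recs.append(
            AlignmentRecord(
                query_name=f"q{i}",
                chrom=chrom,
                pos=pos,
                span=span,
                is_reverse=bool(rng.integers(2)),
                mapq=int(rng.integers(0, 60)),
                is_read1=bool(rng.integers(2)),
                is_proper_pair=bool(rng.random() < 0.9),
                is_duplicate=bool(rng.random() < 0.1),
                mate_pos=int(rng.integers(0, layout.lengths[chrom])),
            )
        )
    return recs


def brute_force_endpoint_map(records, layout, mapq_min=20):
    """Literal per-record restatement of the endpoint-assignment contract,
    kept independent of the implementation it checks."""
    emap = EndpointMap.zeros(layout)
    accepted = 0
    for r in records:
        if not r.is_read1:
            continue
        if r.is_duplicate:
            continue
        if not r.is_proper_pair:
            continue
        if r.mapq < mapq_min:
            continue
        if r.is_reverse:
            emap.bottom[r.chrom][r.pos + r.span - 1] += 1
        else:
            emap.top[r.chrom][r.pos] += 1
        accepted += 1
    emap.total_raw = accepted
    return emap


def random_sparse_map(seed, layout):
    """Random raw EndpointMap for round-trip property tests."""
    rng = np.random.default_rng(seed)
    emap = EndpointMap.zeros(layout)
    total = 0
    for chrom in layout.names:
        for arrays in (emap.top, emap.bottom):
            n = int(rng.integers(0, 40))
            pos = rng.integers(0, layout.lengths[chrom], size=n)
            counts = rng.integers(1, 6, size=n)
            np.add.at(arrays[chrom], pos, counts)
        total += int(emap.top[chrom].sum() + emap.bottom[chrom].sum())
    emap.total_raw = total
    return emap
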