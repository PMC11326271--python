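"""Generative simulator for nuclease-trimmed DSB-end sequencing maps.

Reads are partitioned into four labeled sources, mirroring the structure of
real S1-seq / Exo7/T-seq / ExoT-seq libraries:

* resection endpoints: a hotspot is chosen with probability proportional to
  its strength, a DSB side by fair coin, and a resection distance d drawn
  from a truncated gamma (default mean 1100 nt, shape 12, support
  [100, 2500] nt — a unimodal flank peak ~1 kb from the center). A
  right-side read lands on the top strand at center + d, a left-side read
  on the bottom strand at center - d.
* central signal, method-dependent: nuclease S1 cleaves recombination
  intermediates, giving reads offset from the center with opposite
  polarity (top strand at center - u, bottom at center + u, u half-normal);
  Exo7/T removes the SPO11-capped 2-nt 5' overhang, giving reads centered
  on the midpoint (center + {-1, 0, +1}, strand matching the DSB side);
  ExoT requires a free 3'-OH and produces no central signal at all.
* H-DNA background: at acidic pH, planted C(TC)20 mirror repeats soak up a
  read share proportional to rate(pH) x motif count; reads fall uniformly
  within a motif on its pyrimidine strand. The rate is a step function of
  pH (1.0 at <= 4.3, 0.05 at 4.5, 0 at >= 4.7).
* uniform noise: uniform position and strand genome-wide.

All randomness flows through numpy's PCG64 generator seeded from the
config seed, so identical (config, seed) gives byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .core import (
    BOTTOM,
    TOP,
    ContractError,
    EndpointMap,
    GenomeLayout,
    Hotspot,
    MotifHit,
)

__all__ = [
    "SimulationConfig",
    "GenomeOutputs",
    "PRNG_NAME",
    "hdna_rate",
    "simulate_genome",
    "simulate_endpoints",
    "simulate",
    "truth_mean_resection",
]

PRNG_NAME = "PCG64"
ORACLE_SEED = 271828
ORACLE_DRAWS = 1_000_000

_GENOME_STREAM = 0
_READ_STREAM = 1

METHODS = ("s1", "exo7t", "exot")
_DEFAULT_CENTRAL_FRACTION = {"s1": 0.2, "exo7t": 0.1, "exot": 0.0}


def hdna_rate(ph: float) -> float:
    """Per-motif H-DNA cleavage rate as a step function of S1-digestion pH."""
    if ph <= 4.3:
        return 1.0
    if ph < 4.7:
        return 0.05
    return 0.0


@dataclass
class SimulationConfig:
    """Full generative-model parameters; see the module docstring."""

    seed: int = 1
    chrom_lengths: dict[str, int] = field(default_factory=lambda: {"chrSim1": 5_000_000})
    n_hotspots: int = 100
    strength_logmean: float = 0.0
    strength_logsd: float = 1.0
    n_reads: int = 200_000
    resection_mean: float = 1100.0
    resection_shape: float = 12.0
    resection_min: int = 100
    resection_max: int = 2500
    method: str = "s1"
    central_fraction: float | None = None
    central_offset_scale: float = 150.0
    ph: float = 4.7
    n_motifs: int = 50
    motif_n: int = 20
    hdna_intensity_per_motif: float = 0.04
    noise_fraction: float = 0.05
    min_separation: int = 10_000

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ContractError(f"method must be one of {METHODS}")
        if self.central_fraction is None:
            self.central_fraction = _DEFAULT_CENTRAL_FRACTION[self.method]
        if self.method == "exot":
            # ExoT cannot produce central signal
            self.central_fraction = 0.0
        if not 0 <= self.central_fraction <= 1:
            raise ContractError("central_fraction must be in [0, 1]")
        if not 0 <= self.noise_fraction <= 1:
            raise ContractError("noise_fraction must be in [0, 1]")
        if self.n_reads < 1:
            raise ContractError("read budget must be >= 1")
        if self.resection_min > self.resection_max:
            raise ContractError("resection truncation bounds out of order")
        margin = 2 * self.resection_max + 1000
        for name, length in self.chrom_lengths.items():
            if length < margin:
                raise ContractError(
                    f"chromosome {name!r} shorter than 2*truncation+margin ({margin})"
                )

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        return cls(**d)


@dataclass
class GenomeOutputs:
    layout: GenomeLayout
    sequences: dict[str, str]
    hotspots: list[Hotspot]
    motifs: list[MotifHit]


_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _place(rng, length: int, count: int, margin: int, min_sep: int, avoid, avoid_sep: int):
    """Uniformly place ``count`` positions in [margin, length-margin) that are
    >= min_sep apart and >= avoid_sep from every position in ``avoid``."""
    avoid = np.asarray(sorted(avoid), dtype=np.int64)
    placed: list[int] = []
    tries = 0
    cap = 1000 * max(count, 1)
    while len(placed) < count:
        if tries > cap:
            raise ContractError("cannot place features: chromosome too crowded")
        tries += 1
        p = int(rng.integers(margin, length - margin))
        if placed and min(abs(p - q) for q in placed) < min_sep:
            continue
        if avoid.size:
            i = int(np.searchsorted(avoid, p))
            near = [avoid[j] for j in (i - 1, i) if 0 <= j < avoid.size]
            if near and min(abs(p - q) for q in near) < avoid_sep:
                continue
        placed.append(p)
    return sorted(placed)


def simulate_genome(config: SimulationConfig) -> GenomeOutputs:
    """Random genome with planted hotspots and C(TC)n motifs.

    Hotspot centers are >= ``min_separation`` apart; motifs are
    non-overlapping and >= ``min_separation`` from every hotspot. One base
    on each side of a planted motif is set to 'A' so the planted run is
    exactly maximal and the scanner recovers it with identical bounds.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, _GENOME_STREAM]))
    chroms = list(config.chrom_lengths)
    margin = config.resection_max + 2000

    # apportion hotspots and motifs across chromosomes by length
    lengths = np.array([config.chrom_lengths[c] for c in chroms], dtype=float)
    hot_per = _apportion(config.n_hotspots, lengths)
    motif_per = _apportion(config.n_motifs, lengths)

    sequences: dict[str, str] = {}
    hotspots: list[Hotspot] = []
    motifs: list[MotifHit] = []
    hs_index = 0
    for ci, chrom in enumerate(chroms):
        length = config.chrom_lengths[chrom]
        arr = _BASES[rng.integers(0, 4, size=length)]
        centers = _place(rng, length, hot_per[ci], margin, config.min_separation, [], 0)
        motif_len = 2 * config.motif_n + 1
        starts = _place(
            rng, length, motif_per[ci], margin, motif_len + 100, centers, config.min_separation
        )
        for s in starts:
            pyr = "+" if rng.integers(0, 2) == 0 else "-"
            unit = b"CTC" if pyr == "+" else b"GAG"
            motif = unit[:1] + unit[1:] * config.motif_n
            arr[s : s + motif_len] = np.frombuffer(motif, dtype="S1")
            # guard bases keep the planted run exactly maximal: a purine
            # cannot extend a pyrimidine run and vice versa
            guard = b"A" if pyr == "+" else b"C"
            arr[s - 1] = guard
            arr[s + motif_len] = guard
            motifs.append(
                MotifHit(chrom=chrom, start=s, end=s + motif_len, pyrimidine_strand=pyr, n=config.motif_n)
            )
        for c in centers:
            hs_index += 1
            hotspots.append(Hotspot(name=f"hs{hs_index}", chrom=chrom, center=c))
        sequences[chrom] = arr.tobytes().decode("ascii")

    strengths = rng.lognormal(config.strength_logmean, config.strength_logsd, len(hotspots))
    for h, s in zip(hotspots, strengths):
        h.strength = float(s)
    order = sorted(range(len(hotspots)), key=lambda i: (-hotspots[i].strength, i))
    for rank0, i in enumerate(order):
        hotspots[i].rank = rank0 + 1

    layout = GenomeLayout.from_dict(dict(config.chrom_lengths))
    return GenomeOutputs(layout=layout, sequences=sequences, hotspots=hotspots, motifs=motifs)


def _apportion(total: int, weights: np.ndarray) -> list[int]:
    """Largest-remainder apportionment of ``total`` items by weight."""
    if total == 0:
        return [0] * len(weights)
    raw = total * weights / weights.sum()
    base = np.floor(raw).astype(int)
    rem = total - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    base[order[:rem]] += 1
    return base.tolist()


def _truncated_gamma(rng, config: SimulationConfig, size: int) -> np.ndarray:
    """Rejection-sample the truncated gamma resection-distance model."""
    if config.resection_min == config.resection_max:
        return np.full(size, float(config.resection_min))
    shape = config.resection_shape
    scale = config.resection_mean / shape
    out = np.empty(size)
    filled = 0
    while filled < size:
        draws = rng.gamma(shape, scale, size=max(size - filled, 16))
        ok = draws[(draws >= config.resection_min) & (draws <= config.resection_max)]
        take = min(len(ok), size - filled)
        out[filled : filled + take] = ok[:take]
        filled += take
    return out


def simulate_endpoints(
    config: SimulationConfig, genome: GenomeOutputs
) -> tuple[EndpointMap, pd.DataFrame]:
    """Draw the read budget from the generative model.

    Returns the raw EndpointMap and a truth table with one row per read
    (label in {resection, central, hdna, noise}, anchor id, DSB side, true
    resection distance where applicable, and the emitted cell).
    """
    if config.n_reads < 1:
        raise ContractError("read budget must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, _READ_STREAM]))
    N = config.n_reads

    rate = hdna_rate(config.ph)
    w_hdna = rate * len(genome.motifs) * config.hdna_intensity_per_motif
    n_noise = int(round(N * config.noise_fraction))
    rest = N - n_noise
    n_hdna = int(round(rest * w_hdna / (w_hdna + 1.0))) if w_hdna > 0 else 0
    n_hot = rest - n_hdna

    chroms = list(genome.layout.names)
    chrom_code = {c: i for i, c in enumerate(chroms)}
    out_chrom = np.empty(N, dtype=np.int64)
    out_pos = np.empty(N, dtype=np.int64)
    out_strand = np.empty(N, dtype=np.int64)  # 0 = top, 1 = bottom
    label = np.empty(N, dtype=object)
    anchor = np.full(N, "", dtype=object)
    side = np.full(N, "", dtype=object)
    distance = np.full(N, np.nan)

    cursor = 0

    # --- uniform noise ---
    if n_noise:
        lengths = np.array([genome.layout.lengths[c] for c in chroms], dtype=float)
        ci = rng.choice(len(chroms), size=n_noise, p=lengths / lengths.sum())
        pos = rng.integers(0, np.array([genome.layout.lengths[c] for c in chroms])[ci])
        sl = slice(cursor, cursor + n_noise)
        out_chrom[sl], out_pos[sl] = ci, pos
        out_strand[sl] = rng.integers(0, 2, size=n_noise)
        label[sl] = "noise"
        cursor += n_noise

    # --- H-DNA motif reads ---
    if n_hdna:
        mi = rng.integers(0, len(genome.motifs), size=n_hdna)
        starts = np.array([m.start for m in genome.motifs])
        widths = np.array([m.end - m.start for m in genome.motifs])
        pyr_bottom = np.array([m.pyrimidine_strand == "-" for m in genome.motifs])
        mchrom = np.array([chrom_code[m.chrom] for m in genome.motifs])
        offset = rng.integers(0, widths[mi])
        sl = slice(cursor, cursor + n_hdna)
        out_chrom[sl] = mchrom[mi]
        out_pos[sl] = starts[mi] + offset
        out_strand[sl] = pyr_bottom[mi].astype(np.int64)
        label[sl] = "hdna"
        anchor[sl] = [f"motif{i}" for i in mi]
        cursor += n_hdna

    # --- hotspot reads ---
    if n_hot:
        strengths = np.array([h.strength for h in genome.hotspots], dtype=float)
        centers = np.array([h.center for h in genome.hotspots])
        hchrom = np.array([chrom_code[h.chrom] for h in genome.hotspots])
        hnames = np.array([h.name for h in genome.hotspots], dtype=object)
        hi = rng.choice(len(genome.hotspots), size=n_hot, p=strengths / strengths.sum())
        is_right = rng.integers(0, 2, size=n_hot).astype(bool)
        is_central = rng.random(n_hot) < config.central_fraction

        pos = np.empty(n_hot, dtype=np.int64)
        strand = np.empty(n_hot, dtype=np.int64)
        dist = np.full(n_hot, np.nan)

        res = ~is_central
        n_res = int(res.sum())
        if n_res:
            d = np.rint(_truncated_gamma(rng, config, n_res)).astype(np.int64)
            c = centers[hi[res]]
            right = is_right[res]
            pos[res] = np.where(right, c + d, c - d)
            strand[res] = np.where(right, 0, 1)  # right -> top, left -> bottom
            dist[res] = d

        n_cen = n_hot - n_res
        if n_cen:
            c = centers[hi[is_central]]
            right = is_right[is_central]
            if config.method == "s1":
                # opposite polarity: top strand left of center, bottom right
                u = np.rint(np.abs(rng.normal(0.0, config.central_offset_scale, n_cen))).astype(np.int64)
                pos[is_central] = np.where(right, c + u, c - u)
                strand[is_central] = np.where(right, 1, 0)  # right -> bottom
            elif config.method == "exo7t":
                eps = rng.integers(-1, 2, size=n_cen)  # the 2-nt 5' overhang
                pos[is_central] = c + eps
                strand[is_central] = np.where(right, 0, 1)
            else:  # pragma: no cover - exot forces central_fraction 0
                raise ContractError("exot cannot emit central reads")

        sl = slice(cursor, cursor + n_hot)
        out_chrom[sl] = hchrom[hi]
        out_pos[sl] = pos
        out_strand[sl] = strand
        label[sl] = np.where(is_central, "central", "resection")
        anchor[sl] = hnames[hi]
        side[sl] = np.where(is_right, "right", "left")
        distance[sl] = dist
        cursor += n_hot

    assert cursor == N
    # clip the rare tail landing outside the chromosome (placement margins
    # make this effectively impossible at default settings)
    lens = np.array([genome.layout.lengths[c] for c in chroms])
    out_pos = np.clip(out_pos, 0, lens[out_chrom] - 1)

    emap = EndpointMap.zeros(genome.layout)
    for ci, chrom in enumerate(chroms):
        mask = out_chrom == ci
        for s_code, arrays in ((0, emap.top), (1, emap.bottom)):
            m = mask & (out_strand == s_code)
            np.add.at(arrays[chrom], out_pos[m], 1)
    emap.total_raw = N

    truth = pd.DataFrame(
        {
            "label": pd.Categorical(label),
            "anchor": anchor,
            "side": pd.Categorical(side),
            "distance": distance,
            "chrom": pd.Categorical([chroms[i] for i in out_chrom]),
            "pos": out_pos,
            "strand": pd.Categorical(np.where(out_strand == 0, TOP, BOTTOM)),
        }
    )
    return emap, truth


def simulate(config: SimulationConfig) -> tuple[GenomeOutputs, EndpointMap, pd.DataFrame]:
    """Genome and endpoint simulation in one call."""
    genome = simulate_genome(config)
    emap, truth = simulate_endpoints(config, genome)
    return genome, emap, truth


def truth_mean_resection(
    config: SimulationConfig,
    n_draws: int = ORACLE_DRAWS,
    oracle_seed: int = ORACLE_SEED,
) -> float:
    """Brute-force Monte-Carlo mean of the integer-rounded truncated gamma.

    This is the independent oracle against which the profile-based
    resection-length estimator is validated; it shares nothing with the
    estimator but the distribution parameters.
    """
    if config.resection_min == config.resection_max:
        return float(config.resection_min)
    rng = np.random.default_rng(oracle_seed)
    draws = _truncated_gamma(rng, config, n_draws)
    return float(np.rint(draws).mean())
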