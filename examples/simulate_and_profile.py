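"""Simulate an S1-seq map and compute the co-oriented resection profile.

Builds a synthetic genome with DSB hotspots, draws half a million reads
from the S1-seq generative model, and runs the standard analysis chain:
RPM normalization, hotspot-anchored co-oriented averaging, Hann smoothing,
internal normalization, and the mean-resection-length estimate.
"""

from s1seqmap import endpoints, profiles, sim, stats

config = sim.SimulationConfig(
    seed=1,
    chrom_lengths={"chr1": 10_000_000},
    n_hotspots=100,
    n_reads=500_000,
    method="s1",
)
genome, emap, truth = sim.simulate(config)
rpm = endpoints.to_rpm(emap)

profile = profiles.hotspot_profile(rpm, genome.hotspots)          # raw average
smoothed = profiles.hann_smooth(profile, 151)                     # display
normalized = profiles.internal_normalize(smoothed)                # shape comparison

mean_len = stats.mean_resection_length(profile)
truth_len = sim.truth_mean_resection(config)

print(f"hotspots: {len(genome.hotspots)}, reads: {config.n_reads}")
print(f"estimated mean resection length: {mean_len:.0f} nt")
print(f"simulation truth (Monte-Carlo oracle): {truth_len:.0f} nt")
i, j = profile.index_of(100), profile.index_of(2500) + 1
peak_offset = profile.offsets[i:j][profile.values[i:j].argmax()]
print(f"resection peak position: +{peak_offset} bp")
print(f"normalized profile value at +2500 bp: {normalized.value_at(2500):.1f}")

# The estimate should sit within a few nt of the oracle: the profile-based
# estimator recovers the true resection-distance distribution mean. The peak
# near +1000 bp is the resection endpoint cluster ~1 kb from hotspot centers;
# the normalized profile is 0 at +2500 bp by the background definition.
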