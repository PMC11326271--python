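import numpy as np
import pytest

from s1seqmap import profiles
from s1seqmap.core import ContractError, CoorientedProfile, EndpointMap, GenomeLayout, Hotspot


def _map_with(layout, cells):
    """cells: list of (strand, chrom, pos, value)."""
    emap = EndpointMap.zeros(layout)
    emap.state = "rpm"
    for strand, chrom, pos, val in cells:
        emap.strand(strand)[chrom][pos] += val
    return emap


@pytest.fixture
def layout():
    return GenomeLayout.from_dict({"chrA": 100_000})


def _profile(values, W=None):
    values = np.asarray(values, dtype=float)
    W = (len(values) - 1) // 2 if W is None else W
    return CoorientedProfile(offsets=np.arange(-W, W + 1), values=values)


class TestExtractMatrix:
    def test_indexing_definition(self, layout):
        hs = [Hotspot("h", "chrA", 50_000)]
        emap = _map_with(layout, [("top", "chrA", 50_300, 5.0)])
        m = profiles.extract_matrix(emap, hs, W=2500)
        assert m.top[0, 2500 + 300] == 5.0
        assert m.bottom.sum() == 0

    def test_clipped_hotspot_zero_filled_and_flagged(self, layout):
        hs = [Hotspot("edge", "chrA", 100)]
        emap = _map_with(layout, [("top", "chrA", 0, 1.0)])
        m = profiles.extract_matrix(emap, hs, W=2500)
        assert m.clipped[0]
        assert m.top[0, 2500 - 100] == 1.0  # offset -100 is position 0
        assert m.top[0, : 2500 - 100].sum() == 0

    def test_mass_conservation_for_disjoint_windows(self, layout):
        hs = [Hotspot("a", "chrA", 20_000), Hotspot("b", "chrA", 80_000)]
        rng = np.random.default_rng(2)
        emap = EndpointMap.zeros(layout)
        emap.state = "rpm"
        for h in hs:
            pos = rng.integers(h.center - 2500, h.center + 2501, size=50)
            np.add.at(emap.top["chrA"], pos, 1.0)
        m = profiles.extract_matrix(emap, hs, W=2500)
        assert m.top.sum() == pytest.approx(emap.total())

    def test_empty_hotspot_list_errors(self, layout):
        with pytest.raises(ContractError):
            profiles.extract_matrix(EndpointMap.zeros(layout), [], W=2500)


class TestCoorient:
    @pytest.mark.parametrize("strand,offset,expected_offset", [
        ("top", 800, 800),
        ("bottom", -800, 800),
    ])
    def test_delta_lands_at_folded_offset(self, layout, strand, offset, expected_offset):
        hs = [Hotspot("h", "chrA", 50_000)]
        emap = _map_with(layout, [(strand, "chrA", 50_000 + offset, 3.0)])
        combined = profiles.coorient(profiles.extract_matrix(emap, hs, W=2500))
        assert combined.combined[0, 2500 + expected_offset] == 3.0
        assert combined.combined.sum() == 3.0

    def test_mirror_symmetric_input_doubles_top(self, layout):
        hs = [Hotspot("h", "chrA", 50_000)]
        rng = np.random.default_rng(4)
        emap = EndpointMap.zeros(layout)
        emap.state = "rpm"
        offsets = rng.integers(-2000, 2001, size=30)
        for x in offsets:
            emap.top["chrA"][50_000 + x] += 1.0
            emap.bottom["chrA"][50_000 - x] += 1.0
        m = profiles.extract_matrix(emap, hs, W=2500)
        combined = profiles.coorient(m)
        np.testing.assert_allclose(combined.combined[0], 2 * m.top[0])

    def test_mass_conserved(self, small_sim):
        genome, emap, _ = small_sim
        m = profiles.extract_matrix(emap, genome.hotspots, W=2500)
        combined = profiles.coorient(m)
        assert combined.combined.sum() == pytest.approx(m.top.sum() + m.bottom.sum())


class TestAverageProfile:
    def test_mean_over_rows_and_permutation_invariance(self, layout):
        hs = [Hotspot("a", "chrA", 20_000), Hotspot("b", "chrA", 80_000)]
        emap = _map_with(
            layout,
            [("top", "chrA", 20_500, 2.0), ("top", "chrA", 80_500, 4.0)],
        )
        prof = profiles.average_profile(
            profiles.coorient(profiles.extract_matrix(emap, hs, W=2500))
        )
        assert prof.value_at(500) == pytest.approx(3.0)
        prof_rev = profiles.average_profile(
            profiles.coorient(profiles.extract_matrix(emap, hs[::-1], W=2500))
        )
        np.testing.assert_array_equal(prof.values, prof_rev.values)
        assert prof.n_anchors == 2


class TestHannSmooth:
    def test_n3_is_identity(self):
        rng = np.random.default_rng(0)
        prof = _profile(rng.random(101))
        out = profiles.hann_smooth(prof, 3)
        np.testing.assert_allclose(out.values, prof.values, atol=1e-15)
        assert out.smoothing == 3

    def test_n5_interior_delta(self):
        vals = np.zeros(101)
        vals[50] = 1.0
        out = profiles.hann_smooth(_profile(vals), 5)
        np.testing.assert_allclose(out.values[48:53], [0.0, 0.25, 0.5, 0.25, 0.0], atol=1e-15)
        assert out.values[:48].sum() == 0 and out.values[53:].sum() == 0

    def test_constant_profile_fixed_point_including_edges(self):
        out = profiles.hann_smooth(_profile(np.full(301, 3.7)), 151)
        np.testing.assert_allclose(out.values, 3.7, rtol=1e-12)

    def test_interior_mass_conserved(self):
        vals = np.zeros(1001)
        vals[400:600] = np.random.default_rng(1).random(200)
        out = profiles.hann_smooth(_profile(vals), 151)
        assert out.values.sum() == pytest.approx(vals.sum(), rel=1e-9)

    @pytest.mark.parametrize("N", [4, 1, 9999])
    def test_bad_window_rejected(self, N):
        with pytest.raises(ContractError):
            profiles.hann_smooth(_profile(np.zeros(101)), N)


class TestInternalNormalize:
    def _toy_profile(self, seed=0):
        rng = np.random.default_rng(seed)
        W = 2500
        offs = np.arange(-W, W + 1)
        vals = 0.05 + np.exp(-0.5 * ((offs - 1000) / 300.0) ** 2)
        vals += 0.01 * rng.random(len(offs))
        return CoorientedProfile(offsets=offs, values=vals)

    def test_identity_properties(self):
        out = profiles.internal_normalize(self._toy_profile())
        assert out.value_at(2500) == 0.0
        i, j = out.index_of(100), out.index_of(2500) + 1
        assert out.values[i:j].max() == pytest.approx(1.0)
        assert (out.values >= 0).all()
        assert out.normalized == "internal"
        assert out.background is not None

    def test_scale_invariance(self):
        prof = self._toy_profile(3)
        a = profiles.internal_normalize(prof)
        b = profiles.internal_normalize(prof.replace(prof.values * 7.0))
        np.testing.assert_allclose(a.values, b.values, rtol=1e-9)

    def test_flat_profile_has_no_resection_signal(self):
        W = 2500
        flat = CoorientedProfile(offsets=np.arange(-W, W + 1), values=np.full(2 * W + 1, 2.0))
        with pytest.raises(ContractError, match="no resection signal"):
            profiles.internal_normalize(flat)

    def test_central_peak_cannot_set_scale(self):
        prof = self._toy_profile()
        vals = prof.values.copy()
        vals[prof.index_of(-100)] = 100.0  # huge central spike
        out = profiles.internal_normalize(prof.replace(vals))
        i, j = out.index_of(100), out.index_of(2500) + 1
        assert out.values[i:j].max() == pytest.approx(1.0)
        assert out.value_at(-100) > 1.0


class TestBinMatrix:
    def _matrix(self, W=100):
        hs = [Hotspot("h", "chrA", 0)]
        return profiles.AnchoredMatrix(
            hotspots=hs, W=W, top=np.ones((1, 2 * W + 1)), bottom=np.zeros((1, 2 * W + 1))
        )

    def test_bin1_is_identity(self):
        m = self._matrix()
        assert profiles.bin_matrix(m, 1) is m

    def test_full_bins_sum_per_base_values(self):
        out = profiles.bin_matrix(self._matrix(W=100), 50)
        assert out.top.shape == (1, 5)  # 201 columns -> 4 full bins + partial
        np.testing.assert_array_equal(out.top[0], [50, 50, 50, 50, 1])

    def test_mass_conserved_exactly(self, small_sim):
        genome, emap, _ = small_sim
        m = profiles.extract_matrix(emap, genome.hotspots, W=2000)
        out = profiles.bin_matrix(m, 40)
        assert out.top.sum() == m.top.sum()
        assert out.bottom.sum() == m.bottom.sum()


class TestLocalNormalize:
    def test_rows_sum_to_one_or_flagged(self, small_sim):
        genome, emap, _ = small_sim
        m = profiles.extract_matrix(emap, genome.hotspots, W=2000)
        out = profiles.local_normalize(m, window=4001)
        sums = out.top.sum(axis=1) + out.bottom.sum(axis=1)
        ok = np.isclose(sums, 1.0, rtol=1e-9) | out.zero_rows
        assert ok.all()

    def test_zero_row_left_zero_and_flagged(self, layout):
        hs = [Hotspot("h", "chrA", 50_000), Hotspot("z", "chrA", 10_000)]
        emap = _map_with(layout, [("top", "chrA", 50_100, 8.0)])
        out = profiles.local_normalize(profiles.extract_matrix(emap, hs, W=2000))
        assert not out.zero_rows[0] and out.zero_rows[1]
        assert out.top[1].sum() == 0
        assert out.top[0].sum() == pytest.approx(1.0)

    def test_invariant_to_global_scaling(self, layout):
        hs = [Hotspot("h", "chrA", 50_000)]
        emap = _map_with(layout, [("top", "chrA", 50_100, 8.0), ("bottom", "chrA", 49_000, 2.0)])
        scaled = emap.copy()
        scaled.top["chrA"] *= 11.0
        scaled.bottom["chrA"] *= 11.0
        a = profiles.local_normalize(profiles.extract_matrix(emap, hs, W=2000))
        b = profiles.local_normalize(profiles.extract_matrix(scaled, hs, W=2000))
        np.testing.assert_allclose(a.top, b.top, rtol=1e-12)
        np.testing.assert_allclose(a.bottom, b.bottom, rtol=1e-12)


def test_full_chain_folds_resection_signal_to_positive_offsets():
    """With no central signal, co-orientation puts essentially all hotspot
    mass at positive offsets; only uniform noise can land below zero."""
    from s1seqmap import endpoints, sim

    cfg = sim.SimulationConfig(
        seed=23,
        chrom_lengths={"chrT": 1_500_000},
        n_hotspots=12,
        n_reads=40_000,
        method="exot",
        n_motifs=0,
        noise_fraction=0.005,
    )
    genome, emap, _ = sim.simulate(cfg)
    prof = profiles.hotspot_profile(endpoints.to_rpm(emap), genome.hotspots)
    neg = prof.values[prof.offsets < 0].sum()
    assert neg < 0.01 * prof.values.sum()
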