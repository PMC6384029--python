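import numpy as np
import pytest
from hypothesis import given, strategies as st

from tripletomo import simulate
from tripletomo.quantify import (
    ClassCountTable,
    PROTEIN_DENSITY_DA_PER_A3,
    QuantifyError,
    fsc,
    mass_from_volume,
    measure_lengths,
    periodicity,
    resolution_at,
    segment_mips,
    swing_range,
    weighted_twist,
)

TABLE2_ANGLES = [93.0, 90.0, 87.0, 83.0]


class TestWeightedTwist:
    def test_equal_counts_give_plain_mean(self):
        t = ClassCountTable(TABLE2_ANGLES, np.ones((6, 4)))
        np.testing.assert_allclose(weighted_twist(t), 88.25)

    def test_single_class_returns_its_angle(self):
        t = ClassCountTable(TABLE2_ANGLES, [[0, 5, 0, 0]])
        assert weighted_twist(t)[0] == pytest.approx(90.0)

    def test_all_zero_counts_rejected(self):
        t = ClassCountTable(TABLE2_ANGLES, np.zeros((2, 4)))
        with pytest.raises(QuantifyError):
            weighted_twist(t)

    @given(st.integers(min_value=1, max_value=1000))
    def test_count_rescaling_invariance(self, scale):
        counts = np.array([[3.0, 1.0, 0.0, 2.0], [1.0, 1.0, 1.0, 1.0]])
        t1 = ClassCountTable(TABLE2_ANGLES, counts)
        t2 = ClassCountTable(TABLE2_ANGLES, counts * scale)
        np.testing.assert_allclose(weighted_twist(t1), weighted_twist(t2))

    def test_bounded_by_class_angles(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(1, 50, size=(6, 4)).astype(float)
        t = ClassCountTable(TABLE2_ANGLES, counts)
        tw = weighted_twist(t)
        assert np.all(tw >= min(TABLE2_ANGLES)) and np.all(tw <= max(TABLE2_ANGLES))


class TestSwingRange:
    def test_four_class_scheme_spans_10_degrees(self):
        t = ClassCountTable(TABLE2_ANGLES, np.ones((1, 4)))
        assert swing_range(t) == pytest.approx(10.0)

    def test_degenerate_pair_spans_zero(self):
        t = ClassCountTable([88.0, 88.0], np.ones((1, 2)))
        assert swing_range(t) == 0.0

    def test_six_class_scheme_spans_16_degrees(self):
        angles = [80.0, 83.0, 87.0, 90.0, 93.0, 96.0]
        t = ClassCountTable(angles, np.ones((1, 6)))
        assert swing_range(t) == pytest.approx(16.0)

    def test_single_class_rejected(self):
        t = ClassCountTable([90.0], np.ones((1, 1)))
        with pytest.raises(QuantifyError):
            swing_range(t)


def band_limited_halves(n, cutoff_per_vox, noise, seed=0):
    rng = np.random.default_rng(seed)
    f = np.fft.fftn(rng.normal(size=(n, n, n)))
    g = np.meshgrid(*[np.fft.fftfreq(n)] * 3, indexing="ij")
    r = np.sqrt(sum(x ** 2 for x in g))
    f[r > cutoff_per_vox] = 0
    sig = np.real(np.fft.ifftn(f))
    sig /= sig.std()
    return (sig + noise * rng.normal(size=sig.shape),
            sig + noise * rng.normal(size=sig.shape))


class TestFSC:
    def test_self_fsc_is_unity(self):
        v = np.random.default_rng(1).normal(size=(32, 32, 32))
        curve = fsc(v, v, 1.0)
        np.testing.assert_allclose(curve.correlation, 1.0, atol=1e-9)

    def test_band_limited_resolution_within_one_shell(self):
        """Halves sharing signal up to a known cutoff cross 0.143 there."""
        n, cutoff = 48, 0.2          # cutoff in cycles/voxel
        h1, h2 = band_limited_halves(n, cutoff, noise=0.15)
        curve = fsc(h1, h2, voxel_nm=1.0)
        res = resolution_at(curve)
        shell = 1.0 / (n * 1.0)
        assert abs(1.0 / res - cutoff) <= shell + 1e-9

    def test_pure_noise_gives_no_fine_resolution(self):
        rng = np.random.default_rng(2)
        h1 = rng.normal(size=(32, 32, 32))
        h2 = rng.normal(size=(32, 32, 32))
        res = resolution_at(fsc(h1, h2, 1.0))
        assert np.isnan(res) or res > 8.0

    def test_noise_ladder_monotone_degradation(self):
        n, cutoff = 48, 0.25
        resolutions = []
        for noise in (0.05, 4.0, 12.0):
            h1, h2 = band_limited_halves(n, cutoff, noise, seed=5)
            r = resolution_at(fsc(h1, h2, 1.0))
            resolutions.append(np.inf if np.isnan(r) else r)
        # monotone up to shell-level jitter
        assert all(b >= 0.98 * a for a, b in zip(resolutions, resolutions[1:]))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(QuantifyError):
            fsc(np.zeros((8, 8, 8)), np.zeros((16, 16, 16)))


class TestPeriodicity:
    def test_pinhead_repeat_recovered(self, flat_model, clean_config):
        vol = simulate.render_model(flat_model, clean_config)
        dec = simulate.render_model(flat_model, clean_config,
                                    include="decorations")
        mask = (dec > 0.05 * dec.max()).astype(float)
        assert periodicity(vol, mask, 1.0) == pytest.approx(8.0, abs=0.3)

    def test_tubulin_monomer_repeat_recovered(self, flat_model, clean_config):
        vol = simulate.render_model(flat_model, clean_config)
        walls = simulate.render_model(flat_model, clean_config,
                                      include="walls")
        mask = (walls > 0.2 * walls.max()).astype(float)
        assert periodicity(vol, mask, 1.0) == pytest.approx(4.0, abs=0.2)

    def test_constant_volume_rejected(self):
        with pytest.raises(QuantifyError):
            periodicity(np.ones((64, 8, 8)), None, 1.0)

    def test_axial_translation_invariance(self, flat_model, clean_config):
        vol = simulate.render_model(flat_model, clean_config)
        dec = simulate.render_model(flat_model, clean_config,
                                    include="decorations")
        mask = (dec > 0.05 * dec.max()).astype(float)
        p0 = periodicity(vol, mask, 1.0)
        p1 = periodicity(np.roll(vol, 16, axis=0), np.roll(mask, 16, axis=0), 1.0)
        assert p1 == pytest.approx(p0, abs=0.1)

    def test_intensity_scaling_invariance(self, flat_model, clean_config):
        vol = simulate.render_model(flat_model, clean_config)
        walls = simulate.render_model(flat_model, clean_config,
                                      include="walls")
        mask = (walls > 0.2 * walls.max()).astype(float)
        assert periodicity(37.0 * vol, mask, 1.0) == \
            periodicity(vol, mask, 1.0)


class TestMolecularWeight:
    def test_density_constant_is_exact(self):
        assert mass_from_volume(1000.0) == pytest.approx(849.0, abs=1e-12)
        assert mass_from_volume(1.0) == PROTEIN_DENSITY_DA_PER_A3

    def test_mip1_inventory_volume(self):
        """Volume of the 45 kDa cone-shaped lumen protein implied by the
        protein density."""
        assert mass_from_volume(53004.0) / 1000.0 == pytest.approx(45.0, abs=0.01)

    def test_segmentation_recovers_inserted_blob(self):
        rng = np.random.default_rng(0)
        model = np.zeros((40, 40, 40))
        model[5:35, 18:22, 18:22] = 1.0          # tubule wall stand-in
        amap = model + 0.01 * rng.normal(size=model.shape)
        amap[10:14, 26:30, 26:30] += 1.0          # 64-voxel decoration
        segs = segment_mips(amap, model, voxel_nm=1.0, threshold_sigma=5.0)
        assert len(segs) == 1
        assert segs[0].volume_a3 == pytest.approx(64 * 1000.0, rel=0.15)
        assert segs[0].mass_da == pytest.approx(
            PROTEIN_DENSITY_DA_PER_A3 * segs[0].volume_a3, abs=1e-9)

    def test_disjoint_blobs_masses_add(self):
        model = np.zeros((32, 32, 32))
        amap = model.copy()
        amap[4:8, 4:8, 4:8] = 2.0
        amap[20:26, 20:26, 20:26] = 2.0
        segs = segment_mips(amap, model, voxel_nm=1.0, threshold_sigma=3.0)
        assert len(segs) == 2
        total = sum(s.mass_da for s in segs)
        assert total == pytest.approx(
            mass_from_volume((64 + 216) * 1000.0), rel=1e-6)

    def test_empty_difference_gives_no_segments(self):
        model = np.random.default_rng(1).random((16, 16, 16))
        assert segment_mips(model, model, 1.0) == []


class TestMeasureLengths:
    def render_single_blade(self, model, cfg):
        return simulate.render_model(model, cfg, triplet_indices=[1])

    def test_full_length_tubule_recovered(self, flat_model, clean_config):
        vol = simulate.render_model(flat_model, clean_config,
                                    triplet_indices=[1])
        # trace along the A-tubule of triplet 1
        nz = vol.shape[0]
        pf_local = flat_model.triplet.pf_position("A1")
        pts = []
        for zi in range(nz):
            z_nm = -4.0 + zi  # rendering origin offset
            if not 0 <= z_nm <= flat_model.length_nm:
                continue
            pivot, u, v = flat_model.blade_frame(z_nm, 1)
            xy = pivot + pf_local[0] * u + pf_local[1] * v
            c = (vol.shape[1] - 1) / 2.0
            pts.append([zi, xy[1] + c, xy[0] + c])
        df, stats = measure_lengths(vol, [{
            "tubule": "A", "filament_id": 0, "points_vox": np.array(pts),
        }], voxel_nm=1.0)
        assert df.length_nm.iloc[0] == pytest.approx(100.0, abs=1.5)

    def test_zero_density_flagged(self):
        vol = np.zeros((20, 20, 20))
        df, _ = measure_lengths(vol, [{
            "tubule": "A", "filament_id": 0,
            "points_vox": np.array([[i, 10, 10] for i in range(20)]),
        }])
        assert df.zero_density.iloc[0]
        assert df.length_nm.iloc[0] == 0.0

    def test_trace_outside_volume_rejected(self):
        vol = np.zeros((10, 10, 10))
        with pytest.raises(QuantifyError):
            measure_lengths(vol, [{
                "tubule": "A", "points_vox": np.array([[0, 0, 0], [12, 0, 0]]),
            }])

    def test_stats_follow_generator_means(self, flat_model):
        """Mean measured length over simulated filaments tracks the
        configured extents (CLT-scale agreement)."""
        rng = np.random.default_rng(8)
        spec = {"A": (80.0, 8.0), "B": (60.0, 8.0), "C": (40.0, 8.0)}
        draws = [simulate.sample_tubule_lengths(rng, spec) for _ in range(300)]
        la = np.array([d["A"][1] - d["A"][0] for d in draws])
        se = 8.0 / np.sqrt(300)
        assert abs(la.mean() - 80.0) < 3 * se + 0.1
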