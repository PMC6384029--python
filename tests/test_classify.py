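import numpy as np
import pandas as pd
import pytest

from tripletomo.classify import (
    ClassificationError,
    classify_multireference,
    combined_intermediate_fraction,
    composite_linker_map,
    map_positional_classes,
    reciprocal_acl_classification,
    tubule_focus_mask,
)
from tripletomo.align import shift_volume
from tests.conftest import render_labelled_stack


def best_accuracy(assign, labels):
    """Accuracy up to permutation of the two class labels."""
    a = np.asarray(assign).astype(bool)
    lab = np.asarray(labels)
    return max((a == lab).mean(), (a != lab).mean())


class TestClassifyMultireference:
    def test_noise_free_populations_fully_separated(self, model, clean_config):
        stack, labels, poses, cfg = render_labelled_stack(
            model, 30, np.inf, seed=2)
        mask = tubule_focus_mask(model, cfg.box, cfg.voxel_nm, "B")
        _, assign = classify_multireference(stack, poses, 2, focus_mask=mask,
                                            seed=0)
        assert best_accuracy(assign, labels) == 1.0

    def test_noisy_populations_separated(self, model, labelled_stack_snr03):
        stack, labels, poses, cfg = labelled_stack_snr03
        mask = tubule_focus_mask(model, cfg.box, cfg.voxel_nm, "B")
        _, assign = classify_multireference(stack, poses, 2, focus_mask=mask,
                                            seed=0)
        assert best_accuracy(assign, labels) >= 0.95

    def test_objective_history_non_decreasing(self, model, labelled_stack_snr03):
        stack, labels, poses, cfg = labelled_stack_snr03
        mask = tubule_focus_mask(model, cfg.box, cfg.voxel_nm, "B")
        cmodel, _ = classify_multireference(stack, poses, 2, focus_mask=mask,
                                            seed=0)
        hist = np.asarray(cmodel.objective_history)
        assert np.all(np.diff(hist) >= -1e-3)

    def test_label_permutation_equivalence(self, model, labelled_stack_snr03):
        """Different seeds may permute labels but find the same partition."""
        stack, labels, poses, cfg = labelled_stack_snr03
        mask = tubule_focus_mask(model, cfg.box, cfg.voxel_nm, "B")
        _, a0 = classify_multireference(stack, poses, 2, focus_mask=mask, seed=0)
        _, a1 = classify_multireference(stack, poses, 2, focus_mask=mask, seed=3)
        agreement = max((a0 == a1).mean(), (a0 != a1).mean())
        assert agreement >= 0.95

    def test_singleton_classes_when_k_equals_n(self):
        rng = np.random.default_rng(0)
        stack = rng.normal(size=(4, 16, 16, 16))
        cmodel, assign = classify_multireference(stack, None, 4, seed=0,
                                                 tilt_range_deg=90.0)
        assert sorted(np.bincount(assign, minlength=4)) == [1, 1, 1, 1]
        assert cmodel.objective == pytest.approx(1.0, abs=1e-6)

    def test_more_classes_than_records_rejected(self):
        stack = np.zeros((3, 8, 8, 8))
        with pytest.raises(ClassificationError):
            classify_multireference(stack, None, 5)


class TestPositionalMapping:
    def make_records(self):
        return pd.DataFrame({
            "filament_id": [0, 0, 0, 1, 1, 2],
            "s_nm": [14.5, 43.5, 72.5, 14.5, 43.5, 20.0],
            "b_start": [0.0, 0.0, 0.0, 0.0, 0.0, 16.0],
            "b_end": [87.0, 87.0, 87.0, 87.0, 87.0, 24.0],
        })

    def test_segment_at_tubule_start_is_proximal(self):
        rec = self.make_records()
        flags = [True, False, False, False, False, False]
        labels, _ = map_positional_classes(rec, "B", flags)
        assert labels.iloc[0] == "proximal_end"

    def test_segment_at_tubule_end_is_distal(self):
        rec = self.make_records()
        flags = [False, False, True, False, False, False]
        labels, _ = map_positional_classes(rec, "B", flags)
        assert labels.iloc[2] == "distal_end"

    def test_whole_filament_incomplete_is_nascent(self):
        rec = self.make_records()
        flags = [True, True, True, False, False, False]
        labels, _ = map_positional_classes(rec, "B", flags)
        assert (labels.iloc[:3] == "nascent").all()

    def test_under_10nm_tubule_is_short(self):
        rec = self.make_records()
        flags = [False, False, False, False, False, True]
        labels, _ = map_positional_classes(rec, "B", flags)
        assert labels.iloc[5] == "short"

    def test_interior_segment_is_mid(self):
        rec = self.make_records()
        flags = [False, True, False, False, False, False]
        labels, _ = map_positional_classes(rec, "B", flags)
        assert labels.iloc[1] == "mid"

    def test_missing_extents_labelled_unknown(self):
        rec = self.make_records()
        rec.loc[0, "b_start"] = np.nan
        flags = [True, False, False, False, False, False]
        labels, summary = map_positional_classes(rec, "B", flags)
        assert labels.iloc[0] == "unknown"
        assert summary["n_unknown"] == 1
        assert summary["n_labelled"] == 0

    def test_fractions_sum_to_one(self):
        rec = self.make_records()
        flags = [True, True, True, True, True, True]
        _, summary = map_positional_classes(rec, "B", flags)
        assert sum(summary["fractions"].values()) == pytest.approx(1.0)

    def test_printed_b_intermediate_fractions_combine_to_88(self):
        """The three end-located classes of the B intermediate (28.7%,
        25.5%, 33.8%) together account for 88.0% of intermediates."""
        fractions = {"proximal_end": 0.287, "distal_end": 0.255,
                     "nascent": 0.338, "short": 0.070, "mid": 0.051}
        assert combined_intermediate_fraction(fractions) * 100 == \
            pytest.approx(88.0, abs=1e-9)


def rod_volume(angle_deg, box=32, seed=None, noise=0.0):
    """A rod of Gaussian blobs at a given in-plane angle (synthetic linker
    arm), plus a fixed anchor blob."""
    vol = np.zeros((box, box, box))
    c = (box - 1) / 2.0
    zz, yy, xx = np.meshgrid(*[np.arange(box)] * 3, indexing="ij")
    for r in np.arange(2.0, 12.0, 1.0):
        x = c + r * np.cos(np.radians(angle_deg))
        y = c + r * np.sin(np.radians(angle_deg))
        vol += np.exp(-((xx - x) ** 2 + (yy - y) ** 2) / (2 * 1.5 ** 2)
                      - (zz - c) ** 2 / (2 * 4.0 ** 2))
    vol += 2 * np.exp(-((xx - c) ** 2 + (yy - c) ** 2) / (2 * 2.0 ** 2)
                      - (zz - c) ** 2 / (2 * 6.0 ** 2))
    if noise > 0:
        rng = np.random.default_rng(seed)
        vol = vol + rng.normal(0, noise, vol.shape)
    return vol


class TestReciprocalACL:
    ANGLES = (83.0, 87.0, 90.0, 93.0)

    def make_stack(self, n_per=10, noise=0.05):
        vols, labels = [], []
        for j, ang in enumerate(self.ANGLES):
            for i in range(n_per):
                vols.append(rod_volume(ang, seed=100 * j + i, noise=noise))
                labels.append(j)
        return np.stack(vols), np.array(labels)

    def test_recovers_discrete_swing_angles(self):
        stack, labels = self.make_stack()
        cmodel, assign, keep = reciprocal_acl_classification(
            stack, None, "A_ref", 4, seed=1, tilt_range_deg=90.0,
            focus_mask=np.ones(stack[0].shape),
        )
        # estimate each class's angle by template matching
        cand = np.arange(75.0, 101.0, 0.5)
        templates = {a: rod_volume(a) for a in cand}
        est = []
        for avg in cmodel.averages:
            scores = [np.corrcoef(avg.ravel(), templates[a].ravel())[0, 1]
                      for a in cand]
            est.append(cand[int(np.argmax(scores))])
        est = sorted(est)
        for e, a in zip(est, sorted(self.ANGLES)):
            assert abs(e - a) <= 2.0

    def test_homogeneous_stack_splits_but_averages_agree(self):
        vols = [rod_volume(88.0, seed=i, noise=0.03) for i in range(24)]
        stack = np.stack(vols)
        cmodel, assign, keep = reciprocal_acl_classification(
            stack, None, "C_ref", 2, seed=0, tilt_range_deg=90.0,
            focus_mask=np.ones(stack[0].shape),
        )
        a0, a1 = cmodel.averages
        cc = np.corrcoef(a0.ravel(), a1.ravel())[0, 1]
        assert cc > 0.99

    def test_population_threshold_guard(self):
        stack, _ = self.make_stack(n_per=3)
        with pytest.raises(ClassificationError):
            reciprocal_acl_classification(
                stack, None, "A_ref", 2, seed=0, tilt_range_deg=90.0,
                focus_mask=np.ones(stack[0].shape),
                min_population_fraction=1.5,
            )

    def test_invalid_scheme_rejected(self):
        stack, _ = self.make_stack(n_per=2)
        with pytest.raises(ClassificationError):
            reciprocal_acl_classification(stack, None, "B_ref", 2)


class TestCompositeLinkerMap:
    def test_in_register_inputs_give_voxel_max(self):
        a = rod_volume(85.0)
        b = rod_volume(92.0)
        low = 0.5 * (a + b)
        comp, fits = composite_linker_map(a, b, low)
        oracle = np.maximum(a, b)
        cc = np.corrcoef(comp.ravel(), oracle.ravel())[0, 1]
        assert cc >= 0.99
        assert np.allclose(fits["A_side"]["shift_vox"], 0.0, atol=0.5)

    def test_recovers_constructed_displacement(self):
        a = rod_volume(85.0)
        shifted = shift_volume(a, 3.0, 0.0, 0.0)
        comp, fits = composite_linker_map(shifted, a, a)
        assert fits["A_side"]["shift_vox"][0] == pytest.approx(-3.0, abs=0.5)

    def test_disjoint_supports_add(self):
        box = 32
        a = np.zeros((box, box, box))
        b = np.zeros((box, box, box))
        a[8:12, 8:12, 8:12] = 1.0
        b[20:24, 20:24, 20:24] = 1.0
        low = a + b
        comp, _ = composite_linker_map(a, b, low, max_shift_vox=1.0,
                                       min_fit_score=0.05)
        assert comp.sum() == pytest.approx(a.sum() + b.sum(), rel=1e-6)

    def test_misdock_guard(self):
        rng = np.random.default_rng(0)
        a = rod_volume(85.0)
        junk = rng.normal(size=a.shape)
        with pytest.raises(ClassificationError):
            composite_linker_map(a, a, junk, min_fit_score=0.5)
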