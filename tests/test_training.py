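"""Split protocol, augmentation, learning-rate schedule, training loop."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gtvseg.image import Mask, Modality, Volume
from gtvseg.losses import LossConfig
from gtvseg.model import SegModelConfig, build_model, predict
from gtvseg.training import (
    AugmentConfig,
    SplitPlan,
    TrainConfig,
    augment,
    lr_at,
    stratified_split,
    train,
)


class TestStratifiedSplit:
    def _cases(self, rng, n=86):
        vols = rng.uniform(330, 57_900, size=n)
        return [(f"p{i:03d}", v) for i, v in enumerate(vols)]

    def test_cohort_of_86_gives_54_train(self, rng):
        plan = stratified_split(self._cases(rng), n_strata=18, per_stratum_train=3, seed=1)
        assert len(plan.train_ids) == 54
        assert len(plan.val_ids) == 18
        assert len(plan.test_ids) == 14
        all_ids = set(plan.train_ids) | set(plan.val_ids) | set(plan.test_ids)
        assert len(all_ids) == 86

    def test_deterministic_under_fixed_seed(self, rng):
        cases = self._cases(rng)
        assert stratified_split(cases, seed=7) == stratified_split(cases, seed=7)

    def test_strata_ordered_by_volume(self, rng):
        """Each stratum's training picks come from a contiguous volume band."""
        cases = self._cases(rng)
        plan = stratified_split(cases, n_strata=18, per_stratum_train=3, seed=0)
        vol = dict(cases)
        ordered = sorted(cases, key=lambda c: c[1])
        strata = np.array_split(np.arange(86), 18)
        train_set = set(plan.train_ids)
        for group in strata:
            picks = [ordered[i][0] for i in group if ordered[i][0] in train_set]
            assert len(picks) == 3

    def test_small_enumerated_example(self):
        # 10 cases, 5 strata of 2, one train pick each: 5 train, 5 remaining
        cases = [(f"c{i}", 10.0 * (i + 1)) for i in range(10)]
        plan = stratified_split(cases, n_strata=5, per_stratum_train=1, seed=0,
                                val_test_ratio=(1, 1))
        assert len(plan.train_ids) == 5
        assert len(plan.val_ids) + len(plan.test_ids) == 5
        # exactly one training case from each volume-adjacent pair
        for lo in range(0, 10, 2):
            pair = {f"c{lo}", f"c{lo + 1}"}
            assert len(pair & set(plan.train_ids)) == 1

    def test_quota_exceeding_stratum_raises(self):
        cases = [(f"c{i}", float(i)) for i in range(6)]
        with pytest.raises(ValueError, match="supply"):
            stratified_split(cases, n_strata=3, per_stratum_train=3)

    def test_overlapping_plan_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            SplitPlan(("a", "b"), ("b",), (), 1, 0)


def _aligned_triplet(rng, side=12):
    ct = Volume(data=rng.normal(size=(side,) * 3), spacing=(1, 1, 1), modality=Modality.CT)
    pet = Volume(data=rng.normal(size=(side,) * 3), spacing=(1, 1, 1), modality=Modality.PET)
    mask = np.zeros((side,) * 3)
    mask[3:8, 4:9, 3:7] = 1
    return ct, pet, Mask(data=mask, spacing=(1, 1, 1))


class TestAugment:
    def test_zero_rotation_no_flip_is_identity(self, rng):
        ct, pet, mask = _aligned_triplet(rng)
        cfg = AugmentConfig(max_rotation_deg=0.0, p_flip=0.0)
        ct2, pet2, mask2 = augment(ct, pet, mask, cfg, np.random.default_rng(0))
        np.testing.assert_allclose(ct2.data, ct.data, atol=1e-12)
        np.testing.assert_array_equal(mask2.data, mask.data)

    def test_certain_flip_twice_is_identity(self, rng):
        ct, pet, mask = _aligned_triplet(rng)
        cfg = AugmentConfig(max_rotation_deg=0.0, p_flip=1.0)
        a = augment(ct, pet, mask, cfg, np.random.default_rng(0))
        b = augment(*a, cfg, np.random.default_rng(1))
        np.testing.assert_allclose(b[0].data, ct.data, atol=1e-12)
        np.testing.assert_array_equal(b[2].data, mask.data)

    def test_shapes_spacing_binarity_preserved(self, rng):
        ct, pet, mask = _aligned_triplet(rng)
        cfg = AugmentConfig()
        ct2, pet2, mask2 = augment(ct, pet, mask, cfg, np.random.default_rng(3))
        assert ct2.shape == ct.shape and pet2.shape == pet.shape and mask2.shape == mask.shape
        assert ct2.spacing == ct.spacing
        assert set(np.unique(mask2.data)) <= {0, 1}

    def test_rotation_preserves_tumor_volume_within_tolerance(self, rng):
        side = 24
        mask = np.zeros((side,) * 3)
        x = np.arange(side) - side / 2 + 0.5
        r2 = x[:, None, None]**2 + x[None, :, None]**2 + x[None, None, :]**2
        mask[r2 <= 8**2] = 1  # centred sphere: rotation-invariant target
        m = Mask(data=mask, spacing=(1, 1, 1))
        ct = Volume(data=np.zeros((side,) * 3), spacing=(1, 1, 1), modality=Modality.CT)
        pet = Volume(data=np.zeros((side,) * 3), spacing=(1, 1, 1), modality=Modality.PET)
        cfg = AugmentConfig(max_rotation_deg=45.0, p_flip=0.0)
        before = m.n_foreground
        for seed in range(5):
            _, _, m2 = augment(ct, pet, m, cfg, np.random.default_rng(seed))
            assert abs(m2.n_foreground - before) / before < 0.05

    def test_misaligned_inputs_rejected(self, rng):
        ct, pet, mask = _aligned_triplet(rng)
        other = Volume(data=pet.data, spacing=pet.spacing, origin=(9, 9, 9), modality=Modality.PET)
        with pytest.raises(ValueError, match="same grid"):
            augment(ct, other, mask, AugmentConfig(), np.random.default_rng(0))


class TestLrSchedule:
    def test_maximum_at_restart(self):
        cfg = TrainConfig()
        assert lr_at(0.0, cfg) == pytest.approx(1e-3, abs=1e-15)
        assert lr_at(25.0, cfg) == pytest.approx(1e-3, abs=1e-15)

    def test_minimum_just_before_restart(self):
        cfg = TrainConfig()
        assert lr_at(24.9999999, cfg) == pytest.approx(1e-6, rel=1e-4)

    def test_analytic_midpoint(self):
        cfg = TrainConfig()
        assert lr_at(12.5, cfg) == pytest.approx((1e-3 + 1e-6) / 2, abs=1e-12)

    @given(st.floats(0.0, 500.0), st.floats(1.0, 100.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_bounded_and_periodic(self, epoch, period):
        cfg = TrainConfig(restart_period=period)
        lr = lr_at(epoch, cfg)
        assert cfg.lr_min - 1e-15 <= lr <= cfg.lr_max + 1e-15
        assert lr == pytest.approx(lr_at(epoch + period, cfg), rel=1e-9)

    def test_single_cycle_mode_clamps_at_minimum(self):
        cfg = TrainConfig(warm_restarts=False)
        assert lr_at(80.0, cfg) == pytest.approx(1e-6, rel=1e-6)


class TestTrainLoop:
    def _tiny_setup(self, rng, side=16):
        cfg = SegModelConfig(in_channels=2, base_width=4, n_levels=2, patch_size=side)
        data = {}
        for cid in ("a", "b"):
            ct, pet, mask = _aligned_triplet(rng, side)
            data[cid] = (ct, pet, mask)
        split = SplitPlan(("a",), ("b",), (), 1, 0)
        tc = TrainConfig(epochs=3, seed=0, augment=None,
                         loss=LossConfig().for_heads(cfg.n_heads))
        return cfg, data, split, tc

    def test_seeded_runs_reproduce_trajectories(self, rng):
        cfg, data, split, tc = self._tiny_setup(rng)
        r1 = train(build_model(cfg, seed=0), split, data, tc)
        r2 = train(build_model(cfg, seed=0), split, data, tc)
        np.testing.assert_allclose(r1.history["train_loss"], r2.history["train_loss"], rtol=1e-6)

    def test_best_checkpoint_at_least_as_good_as_final(self, rng):
        cfg, data, split, tc = self._tiny_setup(rng)
        res = train(build_model(cfg, seed=0), split, data, tc)
        assert res.best_val_dsc >= res.history["val_dsc"].iloc[-1] - 1e-9

    def test_loss_history_and_artifacts(self, rng, tmp_path):
        cfg, data, split, tc = self._tiny_setup(rng)
        model = build_model(cfg, seed=0)
        res = train(model, split, data, tc, out_dir=tmp_path)
        assert (tmp_path / "best.npz").exists()
        assert (tmp_path / "history.csv").exists()
        assert list(res.history.columns) == ["epoch", "lr", "train_loss", "val_dsc"]

    def test_empty_train_split_rejected(self, rng):
        cfg, data, _, tc = self._tiny_setup(rng)
        split = SplitPlan((), ("b",), (), 1, 0)
        with pytest.raises(ValueError, match="empty"):
            train(build_model(cfg, seed=0), split, data, tc)
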