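"""Training harness: patient-level splits, augmentation geometry, optimizer
construction, seeded loop determinism, resume, grids."""

import numpy as np
import pandas as pd
import pytest

from fsnet import nn
from fsnet.network import FSNet, FsNetConfig
from fsnet.phantom import PhantomSpec, generate_phantom
from fsnet.training import (AblationSettings, TrainConfig, augment,
                            load_checkpoint, make_optimizer, run_ablation,
                            save_checkpoint, split_dataset, train)


def _manifest(n_patients=10, slices_each=3):
    rows = [{"patient_id": f"P{p:03d}", "slice_index": s}
            for p in range(n_patients) for s in range(slices_each)]
    return pd.DataFrame(rows)


class TestSplit:
    def test_exact_fractions_at_patient_level(self):
        tr, va, te = split_dataset(_manifest(10), (0.6, 0.2, 0.2), seed=0)
        assert tr["patient_id"].nunique() == 6
        assert va["patient_id"].nunique() == 2
        assert te["patient_id"].nunique() == 2

    def test_partition_without_leakage(self):
        m = _manifest(7, 5)
        tr, va, te = split_dataset(m, seed=3)
        parts = [set(x["patient_id"]) for x in (tr, va, te)]
        assert parts[0] | parts[1] | parts[2] == set(m["patient_id"])
        assert not (parts[0] & parts[1] or parts[0] & parts[2] or parts[1] & parts[2])
        assert len(tr) + len(va) + len(te) == len(m)

    def test_deterministic_under_seed(self):
        m = _manifest(9)
        a = split_dataset(m, seed=5)
        b = split_dataset(m, seed=5)
        for x, y in zip(a, b):
            pd.testing.assert_frame_equal(x, y)
        c = split_dataset(m, seed=6)
        assert not all(x.equals(y) for x, y in zip(a, c))

    def test_too_few_patients(self):
        with pytest.raises(ValueError):
            split_dataset(_manifest(2), seed=0)


class TestAugment:
    @pytest.fixture
    def pair(self, tiny_pairs):
        return tiny_pairs[0]

    def test_identity_draw_returns_input(self, pair):
        # find a seed whose three coin flips all come up "skip"
        for seed in range(100):
            if np.all(np.random.default_rng(seed).random(3) >= 0.5):
                break
        out = augment(pair, seed)
        np.testing.assert_array_equal(out.ct, pair.ct)
        np.testing.assert_array_equal(out.mask, pair.mask)

    def test_mask_stays_binary_and_shapes_fixed(self, pair):
        for seed in range(8):
            out = augment(pair, seed)
            assert out.ct.shape == pair.ct.shape
            assert set(np.unique(out.mask)) <= {0, 1}

    def test_flip_is_an_involution(self, pair):
        for seed in range(100):
            draws = np.random.default_rng(seed).random(3)
            if draws[0] < 0.5 and np.all(draws[1:] >= 0.5):
                break
        once = augment(pair, seed)
        twice = augment(once, seed)
        np.testing.assert_allclose(twice.ct, pair.ct, atol=1e-6)
        np.testing.assert_array_equal(twice.mask, pair.mask)

    def test_same_transform_applied_to_all_channels(self, pair):
        out = augment(pair, 12345)
        # tumor stays bright on MRI within the transformed mask
        if out.mask.sum():
            assert out.mri[out.mask == 1].mean() > out.mri[out.mask == 0].mean()


class TestOptimizerFactory:
    def test_named_optimizers_and_decay(self):
        p = nn.Parameter(np.zeros(3))
        for name, cls in (("sgd", nn.SGD), ("adam", nn.Adam),
                          ("adabound", nn.AdaBound)):
            opt, sched = make_optimizer(TrainConfig(optimizer=name), [p])
            assert isinstance(opt, cls)
            assert opt.weight_decay == pytest.approx(5e-8)
            assert sched.set_epoch(99) == pytest.approx(opt.lr, rel=1e-9)
        with pytest.raises(ValueError):
            TrainConfig(optimizer="rmsprop")

    def test_lr_drops_by_factor_ten_after_epoch_100(self):
        p = nn.Parameter(np.zeros(1))
        opt, sched = make_optimizer(TrainConfig(optimizer="adam"), [p])
        assert sched.set_epoch(100) == pytest.approx(1e-3)
        assert sched.set_epoch(101) == pytest.approx(1e-4)


def _tiny_train_setup(seed=0, epochs=2):
    spec = PhantomSpec(image_size=32, n_samples=8, slices_per_patient=2, seed=seed)
    pairs = [generate_phantom(spec, i) for i in range(8)]
    cfg = FsNetConfig(channel_plan=(8, 16, 32, 64, 128), input_size=32,
                      fusion_widths=(8, 16, 32))
    tc = TrainConfig(epochs=epochs, batch_size=4, seed=seed, augment=True,
                     lr_drop_epoch=1000)
    return pairs, cfg, tc


class TestTrainLoop:
    def test_history_rows_and_columns(self, tmp_path):
        pairs, cfg, tc = _tiny_train_setup(epochs=3)
        nn.manual_seed(0)
        hist, best = train(FSNet(cfg), pairs[:6], pairs[6:], tc,
                           out_dir=str(tmp_path))
        assert len(hist) == 3
        for col in ("epoch", "lr", "train_loss", "mse", "ssim_loss", "bce",
                    "val_dc"):
            assert col in hist.columns
        assert (tmp_path / "history.csv").exists()
        assert (tmp_path / "best.npz").exists()
        assert best["state"] is not None

    def test_identical_seeds_reproduce_history_exactly(self):
        runs = []
        for _ in range(2):
            pairs, cfg, tc = _tiny_train_setup(seed=4, epochs=2)
            nn.manual_seed(4)
            hist, _ = train(FSNet(cfg), pairs[:6], pairs[6:], tc)
            runs.append(hist)
        pd.testing.assert_frame_equal(runs[0], runs[1])
        assert runs[0].to_csv() == runs[1].to_csv()

    def test_resume_reproduces_next_epoch(self):
        pairs, cfg, tc = _tiny_train_setup(seed=2, epochs=3)
        nn.manual_seed(2)
        full_hist, _ = train(FSNet(cfg), pairs[:6], None, tc)

        nn.manual_seed(2)
        model = FSNet(cfg)
        opt, sched = make_optimizer(tc, model.parameters())
        tc2 = TrainConfig(**{**tc.__dict__, "epochs": 2})
        train(model, pairs[:6], None, tc2, optimizer=opt, scheduler=sched)
        resumed, _ = train(model, pairs[:6], None, tc, start_epoch=3,
                           optimizer=opt, scheduler=sched)
        assert resumed["train_loss"].iloc[0] == pytest.approx(
            full_hist["train_loss"].iloc[2], abs=1e-6)

    def test_checkpoint_round_trip(self, tmp_path, tiny_pairs):
        pairs, cfg, tc = _tiny_train_setup(epochs=1)
        nn.manual_seed(1)
        model = FSNet(cfg)
        train(model, pairs[:4], None, tc)
        path = str(tmp_path / "ckpt.npz")
        save_checkpoint(path, model, {"note": "test"})
        loaded, meta = load_checkpoint(path)
        assert meta["note"] == "test"
        model.eval(), loaded.eval()
        ct = nn.Tensor(pairs[0].ct[None, None].astype(np.float32))
        mri = nn.Tensor(pairs[0].mri[None, None].astype(np.float32))
        np.testing.assert_array_equal(model(ct, mri, "inference")[0].data,
                                      loaded(ct, mri, "inference")[0].data)


class TestAblationHarness:
    SETTINGS = AblationSettings(n_samples=12, slices_per_patient=2, epochs=1)

    def test_grid_shapes(self):
        t3 = run_ablation("table3", self.SETTINGS)
        assert list(t3["cell"]) == ["a", "b", "c", "d"]
        t4 = run_ablation("table4", self.SETTINGS)
        assert list(t4["cell"]) == ["U-Net", "DECSAU-Net", "F-S-Net"]
        for col in ("acc", "ppv", "js", "dc"):
            assert t4[col].between(0, 1).all()

    def test_grid_is_deterministic(self):
        a = run_ablation("table4", self.SETTINGS)
        b = run_ablation("table4", self.SETTINGS)
        pd.testing.assert_frame_equal(a, b)

    def test_unknown_grid_rejected(self):
        with pytest.raises(ValueError):
            run_ablation("table9", self.SETTINGS)
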