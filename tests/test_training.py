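"""Training loop mechanics: schedule, early stopping, checkpoints,
volume inference, dataset evaluation, and the CLI surface."""

import numpy as np
import pytest
from typer.testing import CliRunner

from mambaseg.cli import app
from mambaseg.config import NetworkConfig, TrainConfig, tiny_network
from mambaseg.network import build_network
from mambaseg.nn import cosine_lr
from mambaseg.synthetic import SyntheticSpec, generate_dataset
from mambaseg.training import (
    EarlyStopper,
    build_slice_dataset,
    evaluate_dataset,
    load_checkpoint,
    predict_volume,
    save_checkpoint,
    train,
)


@pytest.fixture(scope="module")
def small_dataset(tmp_path_factory):
    spec = SyntheticSpec(volume_shape=(32, 32, 12), lesion_radius_range=(3.0, 5.0))
    out = tmp_path_factory.mktemp("ds")
    manifest = generate_dataset(spec, 8, out, seed=7, split=(0.5, 0.25, 0.25))
    return manifest


@pytest.fixture(scope="module")
def micro_cfg():
    return NetworkConfig(
        input_size=32, stage_channels=(4, 8, 12, 16), bridge_channels=24,
        stage_repeats=(1, 1, 1, 1), bridge_repeats=1, expansion=2,
        state_size=4, reduction=4,
    )


class TestSchedule:
    def test_cosine_closed_form_endpoints_and_midpoints(self):
        lr0, lr_min, total = 1e-4, 1e-6, 100
        for e in (0, 25, 50, 75, 100):
            expected = lr_min + (lr0 - lr_min) * (1 + np.cos(np.pi * e / total)) / 2
            assert cosine_lr(e, lr0, lr_min, total) == pytest.approx(expected, rel=1e-12)
        assert cosine_lr(0, lr0, lr_min, total) == pytest.approx(1e-4)
        assert cosine_lr(100, lr0, lr_min, total) == pytest.approx(1e-6)


class TestEarlyStopping:
    def test_fires_after_exactly_patience_flat_epochs(self):
        stopper = EarlyStopper(patience=10)
        assert not stopper.update(1.0)       # first value improves over inf
        fired_at = None
        for i in range(15):
            if stopper.update(1.0):
                fired_at = i
                break
        assert fired_at == 9                  # 10th non-improving epoch fires

    def test_resets_on_improvement(self):
        stopper = EarlyStopper(patience=3)
        values = [1.0, 0.9, 0.95, 0.95, 0.8, 0.85, 0.85, 0.85]
        fired = [stopper.update(v) for v in values]
        assert fired == [False] * 7 + [True]
        assert stopper.best == 0.8


class TestData:
    def test_slice_dataset_shapes_and_range(self, small_dataset):
        x, y = build_slice_dataset(small_dataset, "train", 32)
        assert x.ndim == 4 and x.shape[1:] == (3, 32, 32)
        assert y.shape == (x.shape[0], 32, 32)
        assert 0.0 <= x.min() and x.max() <= 1.0
        assert set(np.unique(y)) <= {0, 1}
        assert all(y[i].any() for i in range(len(y)))  # lesion-only filter

    def test_missing_split_aborts(self, small_dataset, micro_cfg):
        model = build_network(micro_cfg)
        cfg = TrainConfig(epochs=1)
        import pandas as pd
        df = pd.read_csv(small_dataset, sep="\t")
        df["split"] = "train"
        bad = small_dataset.parent / "bad_manifest.tsv"
        df.to_csv(bad, sep="\t", index=False)
        with pytest.raises(ValueError, match="val"):
            train(model, bad, cfg)


class TestTrainLoop:
    def test_short_run_reduces_training_loss_and_is_reproducible(self, small_dataset, micro_cfg):
        def run():
            model = build_network(micro_cfg)
            cfg = TrainConfig(lr0=3e-3, lr_min=3e-5, epochs=10, batch_size=4,
                              max_steps=30, seed=5, augment=False)
            return model, train(model, small_dataset, cfg)

        model, res = run()
        hist = res["history"]
        assert hist["train_loss"].iloc[-1] < hist["train_loss"].iloc[0]
        _, res2 = run()
        np.testing.assert_allclose(hist["train_loss"].values,
                                   res2["history"]["train_loss"].values, rtol=1e-6)

    def test_checkpoint_round_trip(self, small_dataset, micro_cfg, tmp_path):
        model = build_network(micro_cfg)
        path = save_checkpoint(model, TrainConfig(), tmp_path / "ck.npz")
        back = load_checkpoint(path)
        x = np.random.default_rng(0).uniform(0, 1, (1, 3, 32, 32)).astype(np.float32)
        np.testing.assert_array_equal(model.predict_batch(x).probabilities,
                                      back.predict_batch(x).probabilities)


class TestInference:
    def test_predict_volume_contracts(self, small_dataset, micro_cfg):
        import pandas as pd
        model = build_network(micro_cfg)
        df = pd.read_csv(small_dataset, sep="\t")
        img = small_dataset.parent / df.iloc[0]["image"]
        pred1 = predict_volume(model, img)
        pred2 = predict_volume(model, img)
        assert pred1.data.shape == (32, 32, 12)
        assert set(np.unique(pred1.data)) <= {0, 1}
        np.testing.assert_array_equal(pred1.data, pred2.data)

    def test_modality_mismatch_rejected(self, small_dataset, micro_cfg):
        import pandas as pd
        cfg4 = NetworkConfig(**{**micro_cfg.__dict__, "input_channels": 4})
        model = build_network(cfg4)
        df = pd.read_csv(small_dataset, sep="\t")
        img = small_dataset.parent / df.iloc[0]["image"]
        with pytest.raises(ValueError, match="modalities"):
            predict_volume(model, img)

    def test_ground_truth_self_evaluation_is_perfect(self, small_dataset):
        """evaluate_pair on gt vs gt through the dataset path gives DSC 1."""
        import pandas as pd
        from mambaseg.metrics import evaluate_pair
        from mambaseg.volume import load_nifti_volume
        df = pd.read_csv(small_dataset, sep="\t")
        gt = load_nifti_volume(small_dataset.parent / df.iloc[0]["mask"])
        r = evaluate_pair(gt.data, gt.data, spacing=gt.spacing)
        assert r.dsc == 1.0 and r.assd_mm == 0.0


class TestCli:
    def test_simulate_twice_is_identical(self, tmp_path):
        runner = CliRunner()
        for sub in ("a", "b"):
            result = runner.invoke(app, [
                "simulate", "--out", str(tmp_path / sub), "--n-volumes", "3", "--seed", "7",
            ], catch_exceptions=False)
            assert result.exit_code == 0
        assert (tmp_path / "a/manifest.tsv").read_bytes() == (tmp_path / "b/manifest.tsv").read_bytes()
        assert (tmp_path / "a/case000_image.nii.gz").read_bytes() == \
               (tmp_path / "b/case000_image.nii.gz").read_bytes()

    def test_train_with_missing_manifest_exits_nonzero(self, tmp_path):
        runner = CliRunner()
        result = runner.invoke(app, [
            "train", "--manifest", str(tmp_path / "none.tsv"), "--out", str(tmp_path / "o"),
        ])
        assert result.exit_code != 0
        assert not (tmp_path / "o" / "checkpoint.npz").exists()

    def test_summary_prints_tiny_stage_table(self):
        runner = CliRunner()
        result = runner.invoke(app, ["summary", "--preset", "tiny"], catch_exceptions=False)
        assert result.exit_code == 0
        assert "64x64" in result.output and "2x2" in result.output
        assert "284,826" in result.output or "trainable parameters" in result.output


def test_sweep_loss_grid_tabulates_settings(small_dataset, micro_cfg):
    from mambaseg.training import sweep_loss_grid
    base = TrainConfig(lr0=1e-3, epochs=1, batch_size=4, max_steps=3,
                       seed=0, augment=False)
    df = sweep_loss_grid(small_dataset, micro_cfg, base,
                         alphas=(0.75,), betas=(0.3,))
    assert list(df["parameter"]) == ["alpha", "beta"]
    assert ((df["miou"] >= 0) & (df["miou"] <= 1)).all()


def test_four_modality_volume_and_network(tmp_path):
    """Four-modality (T1/T1c/T2/FLAIR) case: generator, stacking, widened stem."""
    spec = SyntheticSpec(volume_shape=(32, 32, 12), n_modalities=4,
                         lesion_radius_range=(3.0, 5.0))
    manifest = generate_dataset(spec, 2, tmp_path, seed=3, split=(0.5, 0.5, 0.0))
    import pandas as pd
    from mambaseg.volume import load_multimodal_nifti
    df = pd.read_csv(manifest, sep="\t")
    mmv = load_multimodal_nifti(tmp_path / df.iloc[0]["image"])
    assert mmv.data.shape[-1] == 4
    cfg = NetworkConfig(input_size=32, input_channels=4,
                        stage_channels=(4, 8, 12, 16), bridge_channels=24,
                        stage_repeats=(1, 1, 1, 1), bridge_repeats=1,
                        expansion=2, state_size=4, reduction=4)
    pred = predict_volume(build_network(cfg), tmp_path / df.iloc[0]["image"])
    assert pred.data.shape == (32, 32, 12)


def test_evaluate_dataset_smoke(small_dataset, micro_cfg):
    model = build_network(micro_cfg)
    out = evaluate_dataset(model, small_dataset, "test")
    assert "dsc" in out["table"].columns
    assert 0.0 <= out["mean_dsc"] <= 1.0
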