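"""Disk round-trips, config serialization, and the command-line verbs."""

import hashlib
import json
from pathlib import Path

import numpy as np
import pytest
from click.testing import CliRunner

from uqgan import (GeneratorSpec, NetworkParameters, build_generator,
                   desk_spec, generate_classification_dataset,
                   generate_segmentation_dataset)
from uqgan.cli import main
from uqgan.config import RunConfig
from uqgan.io import (load_checkpoint, read_dataset, save_checkpoint,
                      write_dataset)


@pytest.fixture
def runner():
    return CliRunner()


def _tree_hash(root: Path) -> dict:
    return {p.relative_to(root).as_posix():
            hashlib.sha256(p.read_bytes()).hexdigest()
            for p in sorted(root.rglob("*")) if p.is_file()}


class TestDatasetIO:
    def test_roundtrip_preserves_masks_and_tags(self, tmp_path):
        ds = generate_segmentation_dataset(desk_spec((32, 32)), 6, seed=2)
        manifest = write_dataset(ds, tmp_path / "d")
        back = read_dataset(manifest)
        assert len(back) == 6
        for a, b in zip(ds, back):
            assert np.array_equal(a.mask, b.mask)  # masks are bit-exact
            assert np.abs(a.image - b.image).max() <= 1 / 255 + 1e-12
            assert b.domain_tag == a.domain_tag
            assert b.sample_id == a.sample_id

    def test_classification_labels_roundtrip(self, tmp_path):
        ds = generate_classification_dataset(8, 4, seed=3, image_size=(16, 16))
        back = read_dataset(write_dataset(ds, tmp_path / "c"))
        assert [s.label for s in back] == [s.label for s in ds]
        assert all(s.mask is None for s in back)

    def test_existing_manifest_requires_force(self, tmp_path):
        ds = generate_segmentation_dataset(desk_spec((16, 16)), 2, seed=1)
        write_dataset(ds, tmp_path / "d")
        with pytest.raises(FileExistsError):
            write_dataset(ds, tmp_path / "d")
        write_dataset(ds, tmp_path / "d", force=True)


class TestExports:
    def test_nifti_pseudo_volume(self, tmp_path):
        from uqgan.io import export_nifti
        import nibabel as nib
        ds = generate_segmentation_dataset(desk_spec((16, 16)), 4, seed=1)
        path = export_nifti(ds, tmp_path / "stack.nii.gz")
        vol = nib.load(path).get_fdata()
        assert vol.shape == (16, 16, 4)
        np.testing.assert_allclose(vol[..., 0], ds[0].image, atol=1e-6)

    def test_uncertainty_map_with_sidecar_scale(self, tmp_path):
        from uqgan.io import write_uncertainty_map
        import imageio.v3 as iio
        field = np.linspace(0, 0.5, 64).reshape(8, 8)
        path = write_uncertainty_map(tmp_path / "u.png", field)
        scale = json.loads(path.with_suffix(".json").read_text())["scale"]
        back = iio.imread(path).astype(float) * scale
        np.testing.assert_allclose(back, field, atol=scale)


class TestCheckpoints:
    def test_roundtrip(self, tmp_path):
        spec = GeneratorSpec(stacks=1, base_channels=4, noise_dim=4, n_down=2)
        G = build_generator(spec, seed=1)
        params = G.get_parameters()
        path = save_checkpoint(tmp_path / "ckpt.npz", params, spec,
                               extra={"seed": 1})
        loaded, lspec, meta = load_checkpoint(path)
        assert loaded == params
        assert lspec == spec and meta["seed"] == 1

    def test_version_mismatch_rejected(self, tmp_path, monkeypatch):
        import uqgan.io as io_mod
        spec = GeneratorSpec(stacks=1, base_channels=4, noise_dim=4, n_down=2)
        params = NetworkParameters([np.ones(3)])
        monkeypatch.setattr(io_mod, "CHECKPOINT_VERSION", 99)
        path = save_checkpoint(tmp_path / "c.npz", params, spec)
        monkeypatch.setattr(io_mod, "CHECKPOINT_VERSION", 1)
        with pytest.raises(ValueError, match="version"):
            load_checkpoint(path)


class TestRunConfig:
    def test_yaml_roundtrip(self, tmp_path):
        cfg = RunConfig(seed=5, n_images=17)
        path = cfg.to_yaml(tmp_path / "cfg.yaml")
        back = RunConfig.from_yaml(path)
        assert back.seed == 5 and back.n_images == 17
        assert back.imbalance == cfg.imbalance
        assert back.train == cfg.train
        assert back.discriminators == cfg.discriminators

    def test_unknown_task_rejected(self):
        with pytest.raises(ValueError, match="task"):
            RunConfig(task="detection")


class TestCli:
    def test_simulate_writes_dataset_and_is_deterministic(self, runner,
                                                          tmp_path):
        args = ["simulate", "--preset", "desk", "--n", "5", "--seed", "7"]
        r1 = runner.invoke(main, args + ["--out", str(tmp_path / "a")])
        assert r1.exit_code == 0, r1.output
        r2 = runner.invoke(main, args + ["--out", str(tmp_path / "b")])
        assert r2.exit_code == 0
        assert _tree_hash(tmp_path / "a") == _tree_hash(tmp_path / "b")
        assert (tmp_path / "a" / "manifest.csv").exists()
        assert len(list((tmp_path / "a" / "images").glob("*.png"))) == 5

    def test_simulate_refuses_overwrite_without_force(self, runner, tmp_path):
        args = ["simulate", "--preset", "desk", "--n", "2", "--seed", "1",
                "--out", str(tmp_path / "d")]
        assert runner.invoke(main, args).exit_code == 0
        assert runner.invoke(main, args).exit_code != 0
        assert runner.invoke(main, args + ["--force"]).exit_code == 0

    def test_simulate_ood_tagging(self, runner, tmp_path):
        r = runner.invoke(main, ["simulate", "--preset", "desk", "--n", "3",
                                 "--seed", "2", "--ood-shift",
                                 "--out", str(tmp_path / "o")])
        assert r.exit_code == 0, r.output
        import pandas as pd
        df = pd.read_csv(tmp_path / "o" / "manifest.csv")
        assert (df["domain_tag"] == "ood").all()

    def test_train_evaluate_ood_pipeline(self, runner, tmp_path):
        """Tiny seeded pipeline: simulate -> train -> evaluate -> ood."""
        d = tmp_path / "data"
        r = runner.invoke(main, ["simulate", "--preset", "desk", "--n", "10",
                                 "--seed", "3", "--out", str(d)])
        assert r.exit_code == 0, r.output
        run = tmp_path / "run"
        r = runner.invoke(main, ["train", "--data", str(d), "--seed", "3",
                                 "--epochs", "1", "--K", "1", "--sigma", "0",
                                 "--out", str(run)])
        assert r.exit_code == 0, r.output
        assert (run / "checkpoint.npz").exists()
        assert (run / "config.yaml").exists()
        assert (run / "history.csv").exists()
        r = runner.invoke(main, ["evaluate", "--run", str(run), "--data",
                                 str(d), "--out", str(run / "eval.json")])
        assert r.exit_code == 0, r.output
        report = json.loads((run / "eval.json").read_text())
        assert set(report) >= {"f1", "precision", "recall", "assd"}
        r = runner.invoke(main, ["ood", "--run", str(run), "--data", str(d),
                                 "--out", str(run / "scores.csv")])
        assert r.exit_code == 0, r.output
        import pandas as pd
        scores = pd.read_csv(run / "scores.csv")
        assert len(scores) == 10 and "score" in scores.columns

    def test_missing_checkpoint_is_clean_error(self, runner, tmp_path):
        d = tmp_path / "data"
        runner.invoke(main, ["simulate", "--preset", "desk", "--n", "2",
                             "--seed", "1", "--out", str(d)])
        empty = tmp_path / "empty"
        empty.mkdir()
        r = runner.invoke(main, ["evaluate", "--run", str(empty), "--data",
                                 str(d), "--out", str(tmp_path / "e.json")])
        assert r.exit_code != 0
        assert "checkpoint" in r.output
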