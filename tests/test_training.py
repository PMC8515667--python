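import numpy as np
import pytest

from sctgen.networks import AttentionGenerator, PatchDiscriminator
from sctgen.nn import Adam, Tensor
from sctgen.losses import LossReport
from sctgen.training import (
    TrainingConfig,
    _cycle_step,
    load_checkpoint,
    lr_schedule,
    save_checkpoint,
    shuffle_unpaired,
    synthesize_volume,
    train,
)
from sctgen.volume_io import HUVolume

TINY = dict(image_size=32, gen_channels=4, n_residual=1, disc_channels=4)


class TestLrSchedule:
    def test_endpoints_and_midpoint(self):
        cfg = TrainingConfig(epochs=100, decay_start=50)
        assert lr_schedule(0, cfg) == pytest.approx(1e-4)
        assert lr_schedule(49, cfg) == pytest.approx(1e-4)
        assert lr_schedule(75, cfg) == pytest.approx(5e-5)
        assert lr_schedule(100, cfg) == 0.0

    def test_out_of_range_rejected(self):
        cfg = TrainingConfig(epochs=10, decay_start=5)
        with pytest.raises(ValueError):
            lr_schedule(11, cfg)
        with pytest.raises(ValueError):
            lr_schedule(-1, cfg)


class TestShuffle:
    def test_reproducible_but_epoch_dependent(self):
        a0, b0 = shuffle_unpaired(10, 10, epoch=0, seed=3)
        a0b, b0b = shuffle_unpaired(10, 10, epoch=0, seed=3)
        a1, _ = shuffle_unpaired(10, 10, epoch=1, seed=3)
        np.testing.assert_array_equal(a0, a0b)
        np.testing.assert_array_equal(b0, b0b)
        assert not np.array_equal(a0, a1)

    def test_permutations_are_bijections(self):
        a, b = shuffle_unpaired(7, 7, epoch=2, seed=1)
        assert sorted(a) == list(range(7)) and sorted(b) == list(range(7))

    def test_unpaired_pools_shuffled_independently(self):
        a, b = shuffle_unpaired(50, 50, epoch=0, seed=0)
        assert not np.array_equal(a, b)

    def test_smaller_pool_wraps_around(self):
        a, b = shuffle_unpaired(3, 8, epoch=0, seed=0)
        assert len(a) == len(b) == 8
        assert sorted(set(a)) == [0, 1, 2]

    def test_paired_mode_preserves_pairing(self):
        a, b = shuffle_unpaired(6, 6, epoch=4, seed=9, paired=True)
        np.testing.assert_array_equal(a, b)

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            shuffle_unpaired(0, 5, epoch=0, seed=0)


class TestTrainLoop:
    def test_one_epoch_bookkeeping(self, tiny_dataset, tmp_path):
        cfg = TrainingConfig(mode="aggan", epochs=1, decay_start=1, seed=0,
                             checkpoint_every=1, **TINY)
        run = train(cfg, tiny_dataset, out_dir=tmp_path / "run")
        # 2 training volumes x 4 slices = 8 iterations
        assert len(run.loss_log) == 8
        assert len(run.checkpoint_paths) == 2  # cadence + final
        df = run.log_frame()
        for col in ("gan_d_ct", "gan_g_cbct_ct", "gan_d_cbct", "gan_g_ct_cbct",
                    "cycle_cbct", "cycle_ct", "idt_ct", "idt_cbct", "total"):
            assert col in df and np.isfinite(df[col]).all()

    def test_identical_seeds_reproduce_loss_logs(self, tiny_dataset):
        cfg = TrainingConfig(mode="cyclegan", epochs=1, decay_start=1, seed=4, **TINY)
        r1 = train(cfg, tiny_dataset)
        r2 = train(cfg, tiny_dataset)
        np.testing.assert_array_equal(
            r1.log_frame()["total"].values, r2.log_frame()["total"].values
        )

    def test_pix2pix_mode_runs_paired(self, tiny_dataset):
        cfg = TrainingConfig(mode="pix2pix", epochs=1, decay_start=1, seed=2, **TINY)
        run = train(cfg, tiny_dataset)
        assert set(run.nets) == {"g_cbct_ct", "d_ct"}
        assert all(np.isfinite(r.total()) for r in run.loss_log)

    def test_generator_step_leaves_discriminators_untouched(self):
        rng = np.random.default_rng(0)
        cfg = TrainingConfig(mode="aggan", epochs=1, decay_start=1, **TINY)
        gcfg = cfg.generator_config()
        nets = {"g_cbct_ct": AttentionGenerator(gcfg, rng=rng),
                "g_ct_cbct": AttentionGenerator(gcfg, rng=rng),
                "d_ct": PatchDiscriminator(4, rng=rng),
                "d_cbct": PatchDiscriminator(4, rng=rng)}
        opt_g = Adam(nets["g_cbct_ct"].parameters() + nets["g_ct_cbct"].parameters())

        class FrozenOpt:
            def __init__(self, params):
                self.params = params

            def zero_grad(self):
                for p in self.params:
                    p.grad = None

            def step(self, lr=None):  # discriminators held fixed
                pass

        opts_d = {k: FrozenOpt(nets[k].parameters()) for k in ("d_ct", "d_cbct")}

        class NoPool:
            def query(self, im):
                return im

        d_hash = {k: [p.data.copy() for p in nets[k].parameters()] for k in opts_d}
        g_hash = [p.data.copy() for p in nets["g_cbct_ct"].parameters()]
        a = Tensor(rng.uniform(-1, 1, (1, 32, 32)).astype(np.float32))
        b = Tensor(rng.uniform(-1, 1, (1, 32, 32)).astype(np.float32))
        _cycle_step(nets, opt_g, opts_d, {k: NoPool() for k in opts_d}, a, b,
                    cfg.weights, "image_mean", 1e-3, LossReport())
        for k, before in d_hash.items():
            for p, old in zip(nets[k].parameters(), before):
                np.testing.assert_array_equal(p.data, old)
        assert any(
            not np.array_equal(p.data, old)
            for p, old in zip(nets["g_cbct_ct"].parameters(), g_hash)
        )

    def test_mode_data_mismatch_rejected(self, tmp_path):
        manifest = {"paired": False, "records": [], "_root": str(tmp_path)}
        cfg = TrainingConfig(mode="aggan", epochs=1, decay_start=0, **TINY)
        with pytest.raises(ValueError):
            train(cfg, manifest)


class TestCheckpoints:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(1)
        cfg = TrainingConfig(**TINY)
        nets = {"g_cbct_ct": AttentionGenerator(cfg.generator_config(), rng=rng),
                "d_ct": PatchDiscriminator(4, rng=rng)}
        p = tmp_path / "ck.npz"
        save_checkpoint(p, nets, cfg, epoch=7)
        loaded, cfg2, epoch = load_checkpoint(p)
        assert epoch == 7 and cfg2 == cfg
        for k in nets:
            for (n1, p1), (n2, p2) in zip(
                sorted(nets[k].named_parameters()), sorted(loaded[k].named_parameters())
            ):
                assert n1 == n2
                np.testing.assert_array_equal(p1.data, p2.data)

    def test_corrupt_checkpoint_rejected(self, tmp_path):
        p = tmp_path / "bad.npz"
        np.savez(p, junk=np.zeros(3))
        with pytest.raises(ValueError):
            load_checkpoint(p)


class TestSynthesizeVolume:
    def test_geometry_preserved_and_deterministic(self, small_phantom):
        ct, _ = small_phantom
        gen = AttentionGenerator(
            TrainingConfig(**TINY).generator_config(), rng=np.random.default_rng(0)
        )
        out1 = synthesize_volume(ct, gen)
        out2 = synthesize_volume(ct, gen)
        assert out1.shape == ct.shape
        assert out1.spacing == ct.spacing and out1.origin == ct.origin
        np.testing.assert_array_equal(out1.voxels, out2.voxels)
        assert out1.voxels.min() >= -1000 and out1.voxels.max() <= 1500

    def test_identity_forced_generator_passes_input_through(self, rng):
        # background attention forced to 1: the end-to-end path reduces to
        # clip -> normalize -> (identity) -> denormalize
        cfg = TrainingConfig(**TINY)
        gen = AttentionGenerator(cfg.generator_config(), rng=np.random.default_rng(2))
        head = gen.attention_branch.head
        head.weight.data = np.zeros_like(head.weight.data)
        head.bias.data = np.full_like(head.bias.data, -50.0)
        head.bias.data[-1] = 50.0
        vol = HUVolume(rng.uniform(-1000, 1500, size=(3, 32, 32)))
        out = synthesize_volume(vol, gen)
        np.testing.assert_allclose(out.voxels, vol.voxels, atol=0.5)
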