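import numpy as np
import pytest

from netflics import forward as fw
from netflics import network as nw

TINY = dict(n_gates=32, n_meas=16, common_channels=4, gate_filters=2,
            gate_kernel=8, gate_stride=8, recon_c1=4, recon_c2=4,
            recon_k1=3, recon_k3=3, batch_size=8, rng_seed=0)


def tiny_cfg(**over):
    kw = dict(TINY)
    kw.update(over)
    return nw.NetConfig(**kw)


def toy_data(cfg, n, seed, tau_only_signal=True):
    """Synthetic paired data with a learnable linear structure: targets are
    simple functions of the measurement array."""
    rng = np.random.default_rng(seed)
    X = rng.random((n, cfg.n_gates, cfg.n_meas)).astype(np.float32) * 10
    base = X.mean(axis=(1, 2))
    Yi = np.tile(base[:, None, None], (1, 32, 32)).astype(np.float32) * 30
    Yt = (0.3 + 0.1 * (base[:, None, None] % 1.2)
          * np.ones((1, 32, 32))).astype(np.float32)
    return X, Yi, Yt


class TestConfig:
    def test_rejects_bad_values(self):
        with pytest.raises(ValueError):
            nw.NetConfig(lifetime_loss_weight=0)
        with pytest.raises(ValueError):
            nw.NetConfig(base_lr=-1)
        with pytest.raises(ValueError):
            nw.NetConfig(gate_kernel=48, gate_stride=48)  # does not tile 256

    def test_preset_lookup(self):
        cfg, n_tr, n_va = nw.preset_config("full")
        assert (n_tr, n_va) == (32000, 8000)
        with pytest.raises(ValueError):
            nw.preset_config("warp")


class TestShapes:
    def test_full_size_forward(self):
        cfg, *_ = nw.preset_config("smoke")
        model = nw.build_model(cfg)
        x = np.ones((2, 256, 512), dtype=np.float32)
        pi, pt = model.forward(x)
        assert pi.shape == (2, 32, 32) and pt.shape == (2, 32, 32)

    def test_reduced_measurement_variant(self):
        """The 400-pattern acquisition only resizes the first mapping."""
        cfg, *_ = nw.preset_config("smoke", n_meas=400)
        model = nw.build_model(cfg)
        pi, pt = model.forward(np.ones((1, 256, 400), dtype=np.float32))
        assert pi.shape == (1, 32, 32) and pt.shape == (1, 32, 32)
        assert model.dense.params["W"].shape[0] == 400

    def test_rejects_wrong_input_shape(self):
        model = nw.build_model(tiny_cfg())
        with pytest.raises(ValueError):
            model.forward(np.ones((1, 8, 8), dtype=np.float32))

    def test_inconsistent_bank_rejected(self, bank_toy):
        with pytest.raises(ValueError):
            nw.build_model(nw.NetConfig(), bank_toy)


class TestLossAndSchedule:
    def test_perfect_prediction_zero(self):
        a = np.ones((2, 4, 4))
        assert nw.loss_value(a, a, a, a) == 0.0

    def test_weighted_sum_contract(self):
        """MSE_int = 1 and MSE_tau = 0.001 at weight 1e5 give exactly 101."""
        pi = np.zeros((1, 1)); ti = np.ones((1, 1))          # MSE_int = 1
        pt = np.zeros((1, 1)); tt = np.full((1, 1), np.sqrt(0.001))
        assert nw.loss_value(pi, pt, ti, tt, 1e5) == pytest.approx(101.0, abs=1e-9)

    def test_doubling_weight_doubles_lifetime_term_only(self):
        rng = np.random.default_rng(0)
        pi, ti, pt, tt = (rng.random((2, 3, 3)) for _ in range(4))
        base_i = nw.loss_value(pi, pt, ti, tt, 0.0 + 1e-300)
        l1 = nw.loss_value(pi, pt, ti, tt, 1e5)
        l2 = nw.loss_value(pi, pt, ti, tt, 2e5)
        assert l2 - l1 == pytest.approx(l1 - base_i, rel=1e-9)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            nw.loss_value(np.ones((2, 2)), np.ones((2, 2)),
                          np.ones((3, 3)), np.ones((2, 2)))

    def test_learning_rate_schedule(self):
        assert nw.learning_rate(1e-3, 0) == 1e-3
        assert nw.learning_rate(1e-3, 9) == 1e-3
        assert nw.learning_rate(1e-3, 10) == 5e-4
        assert nw.learning_rate(1e-3, 19) == 5e-4
        assert nw.learning_rate(1e-3, 20) == 2.5e-4

    def test_gradients_match_loss(self):
        rng = np.random.default_rng(1)
        pi, ti, pt, tt = (rng.random((2, 4, 4)) for _ in range(4))
        loss, d_int, d_tau = nw.loss_and_grads(pi, pt, ti, tt, 1e3)
        eps = 1e-6
        pi2 = pi.copy(); pi2[0, 0, 0] += eps
        num = (nw.loss_value(pi2, pt, ti, tt, 1e3) - loss) / eps
        assert d_int[0, 0, 0] == pytest.approx(num, rel=1e-4)


def _num_grad(f, arr, eps=1e-6):
    g = np.zeros_like(arr)
    it = np.nditer(arr, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        old = arr[i]
        arr[i] = old + eps
        fp = f()
        arr[i] = old - eps
        fm = f()
        arr[i] = old
        g[i] = (fp - fm) / (2 * eps)
    return g


class TestLayerGradients:
    """Analytic backward passes against central finite differences."""

    @pytest.mark.parametrize("layer_factory,x_shape", [
        (lambda rng: nw.Dense(5, 7, rng, dtype=np.float64), (2, 3, 5)),
        (lambda rng: nw.Conv2d(3, 4, 3, rng, dtype=np.float64), (2, 6, 6, 3)),
        (lambda rng: nw.Conv2d(3, 2, 1, rng, dtype=np.float64), (2, 6, 6, 3)),
        (lambda rng: nw.BatchNorm2d(3, dtype=np.float64), (2, 6, 6, 3)),
        (lambda rng: nw.Conv1dGate(2, 4, 4, rng, dtype=np.float64), (2, 5, 5, 8)),
        (lambda rng: nw.Conv1dGate(2, 4, 2, rng, dtype=np.float64), (2, 5, 5, 8)),
        (lambda rng: nw.ResBlock(3, 3, rng, dtype=np.float64), (2, 6, 6, 3)),
        (lambda rng: nw.ReconBlock(3, 4, 2, 5, 3, rng, dtype=np.float64), (2, 6, 6, 3)),
    ], ids=["dense", "conv3", "conv1x1", "bn", "gateconv", "gateconv-overlap",
            "resblock", "reconblock"])
    def test_backward_matches_finite_differences(self, layer_factory, x_shape):
        rng = np.random.default_rng(0)
        layer = layer_factory(rng)
        x = rng.standard_normal(x_shape)
        y0 = layer.forward(x, training=True)
        proj = np.random.default_rng(2).standard_normal(y0.shape)

        def f():
            return float((layer.forward(x, training=True) * proj).sum())

        layer.forward(x, training=True)
        dx = layer.backward(proj)
        if dx is not None:
            assert np.allclose(_num_grad(f, x), dx, atol=1e-6)
        for name, p in layer.params.items():
            assert np.allclose(_num_grad(f, p), layer.grads[name], atol=1e-6), name


class TestPhysicsInit:
    def test_complete_bank_init_backprojects_exactly(self):
        """With all 1024 patterns, the initial dense mapping reproduces each
        gate image up to the deliberate `order` scale factor."""
        bank = fw.build_hadamard_bank(k=1024)
        cfg = nw.NetConfig(n_meas=1024, n_gates=4, gate_kernel=4, gate_stride=4)
        model = nw.build_model(cfg, bank)
        rng = np.random.default_rng(0)
        img = rng.random((32, 32))
        s = bank.matrix @ img.ravel()
        x = np.tile(s[None, None, :], (1, 4, 1)).astype(np.float32)
        h = model.dense.forward(x.astype(np.float64))
        rec = h[0, 0].reshape(32, 32) / bank.hadamard_order
        assert np.allclose(rec, img, atol=1e-4)


class TestTraining:
    def test_loss_decreases_on_toy_run(self):
        cfg = tiny_cfg(max_epochs=5, patience=5)
        X, Yi, Yt = toy_data(cfg, 64, 0)
        Xv, Yiv, Ytv = toy_data(cfg, 16, 1)
        model = nw.build_model(cfg)
        trained = nw.train(model, (X, Yi, Yt), (Xv, Yiv, Ytv))
        assert trained.history[-1]["train_loss"] < trained.history[0]["train_loss"]

    def test_history_schedule_and_early_stop_bound(self):
        cfg = tiny_cfg(max_epochs=30, patience=2, lr_halving_period=3)
        X, Yi, Yt = toy_data(cfg, 32, 0)
        model = nw.build_model(cfg)
        trained = nw.train(model, (X, Yi, Yt), (X[:8], Yi[:8], Yt[:8]))
        for e, entry in enumerate(trained.history):
            assert entry["lr"] == pytest.approx(1e-3 * 0.5 ** (e // 3))
        assert len(trained.history) <= trained.best_epoch + cfg.patience + 1
        best = min(h["val_lifetime_mae"] for h in trained.history)
        assert trained.history[trained.best_epoch]["val_lifetime_mae"] == best

    def test_reproducible_history(self):
        cfg = tiny_cfg(max_epochs=2)
        X, Yi, Yt = toy_data(cfg, 24, 0)
        runs = []
        for _ in range(2):
            trained = nw.train(nw.build_model(cfg), (X, Yi, Yt), (X[:8], Yi[:8], Yt[:8]))
            runs.append(trained.history)
        assert runs[0] == runs[1]

    def test_trained_beats_untrained(self):
        cfg = tiny_cfg(max_epochs=6, patience=6)
        X, Yi, Yt = toy_data(cfg, 64, 0)
        Xh, Yih, Yth = toy_data(cfg, 24, 9)
        untrained = nw.build_model(cfg)
        trained = nw.train(nw.build_model(cfg), (X, Yi, Yt), (Xh[:8], Yih[:8], Yth[:8]))
        def tau_mae(m):
            _, pt = m.forward(Xh)
            return float(np.abs(pt - Yth).mean())
        assert tau_mae(trained.model) < tau_mae(untrained)

    def test_rejects_empty_sets(self):
        cfg = tiny_cfg()
        X, Yi, Yt = toy_data(cfg, 4, 0)
        with pytest.raises(ValueError):
            nw.train(nw.build_model(cfg), (X[:0], Yi[:0], Yt[:0]), (X, Yi, Yt))


@pytest.fixture(scope="module")
def trained():
    cfg = tiny_cfg(max_epochs=1)
    X, Yi, Yt = toy_data(cfg, 16, 0)
    return nw.train(nw.build_model(cfg), (X, Yi, Yt), (X[:4], Yi[:4], Yt[:4]))


class TestPredict:

    def test_batch_count_and_method_tag(self, trained):
        cfg = trained.config
        X = toy_data(cfg, 7, 3)[0]
        results = nw.predict(trained, X)
        assert len(results) == 7
        assert all(r.method == "netflics" for r in results)
        assert results[0].intensity.shape == (32, 32)

    def test_idempotent(self, trained):
        X = toy_data(trained.config, 3, 4)[0]
        a = nw.predict(trained, X)
        b = nw.predict(trained, X)
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.intensity, rb.intensity)
            assert np.array_equal(ra.lifetime, rb.lifetime)

    def test_save_load_roundtrip(self, trained, tmp_path):
        path = str(tmp_path / "model")
        trained.save(path)
        loaded = nw.TrainedModel.load(path)
        X = toy_data(trained.config, 2, 5)[0]
        a = nw.predict(trained, X)
        b = nw.predict(loaded, X)
        assert np.array_equal(a[0].lifetime, b[0].lifetime)
        assert loaded.best_epoch == trained.best_epoch
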