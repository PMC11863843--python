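import numpy as np
import pytest

from irfg.errors import CatalogMismatchError
from irfg.preprocess import Spectrum, default_grid
from irfg.split_net import (
    SplitNet,
    SplitNetConfig,
    load_checkpoint,
    predict_labels,
    save_checkpoint,
    split_spectrum,
)


class TestSplitSpectrum:
    def test_default_boundary_sizes(self, grid):
        spec = Spectrum(grid, np.zeros(grid.size))
        x_fp, x_fg = split_spectrum(spec, 1800.0)
        assert x_fp.size == 1201  # 600..1800 inclusive
        assert x_fg.size == 2200  # 1801..4000
        assert x_fp.size + x_fg.size == 3401

    def test_boundary_on_grid_edge_rejected(self, grid):
        spec = Spectrum(grid, np.zeros(grid.size))
        with pytest.raises(ValueError):
            split_spectrum(spec, 600.0)
        with pytest.raises(ValueError):
            split_spectrum(spec, 4000.0)

    def test_concatenation_reconstitutes_spectrum(self, grid):
        rng = np.random.default_rng(0)
        spec = Spectrum(grid, rng.random(grid.size))
        x_fp, x_fg = split_spectrum(spec, 1800.0)
        np.testing.assert_array_equal(np.concatenate([x_fp, x_fg]), spec.intensities)


class TestPredictLabels:
    def test_threshold_compare(self):
        probs = np.array([0.6, 0.4] + [0.1] * 15)
        bits = predict_labels(probs)
        assert bits[0] == 1 and bits[1] == 0

    def test_exact_half_counts_as_present(self):
        assert predict_labels(np.full(17, 0.5))[0] == 1

    def test_all_zero_probabilities(self):
        np.testing.assert_array_equal(predict_labels(np.zeros(17)), np.zeros(17))


def tiny_net(tiny_grid, seed=0, n_outputs=17):
    cfg = SplitNetConfig(
        boundary=1050.0, head_hidden=4, concat_size=8, n_outputs=n_outputs, seed=seed
    )
    return SplitNet(cfg, tiny_grid)


class TestForward:
    def test_zero_params_give_half_everywhere(self, tiny_grid):
        net = tiny_net(tiny_grid)
        for value, _ in net.parameters():
            value[...] = 0.0
        out = net.forward(np.zeros(tiny_grid.size))
        np.testing.assert_allclose(out, 0.5)

    def test_inference_deterministic(self, tiny_grid):
        net = tiny_net(tiny_grid)
        x = np.random.default_rng(1).random(tiny_grid.size)
        np.testing.assert_array_equal(net.forward(x), net.forward(x))

    def test_outputs_strictly_inside_unit_interval(self, tiny_grid):
        net = tiny_net(tiny_grid)
        rng = np.random.default_rng(2)
        out = net.forward(rng.random((100, tiny_grid.size)))
        assert np.all(out > 0) and np.all(out < 1)

    def test_shape_mismatch_rejected(self, tiny_grid):
        net = tiny_net(tiny_grid)
        with pytest.raises(ValueError):
            net.forward(np.zeros(tiny_grid.size + 1))

    def test_initialization_reproducible_across_instances(self, tiny_grid):
        a, b = tiny_net(tiny_grid, seed=7), tiny_net(tiny_grid, seed=7)
        for (pa, _), (pb, _) in zip(a.parameters(), b.parameters()):
            np.testing.assert_array_equal(pa, pb)
        c = tiny_net(tiny_grid, seed=8)
        assert any(
            not np.array_equal(pa, pc)
            for (pa, _), (pc, _) in zip(a.parameters(), c.parameters())
        )


class TestHeadIsolation:
    def test_perturbing_fg_region_leaves_h1_unchanged(self, tiny_grid):
        net = tiny_net(tiny_grid)
        rng = np.random.default_rng(3)
        x = rng.random(tiny_grid.size)
        h1, h2 = net.head_outputs(x)
        x2 = x.copy()
        x2[net.n_fp :] = rng.random(net.n_fg)  # perturb every x_FG coordinate
        h1b, h2b = net.head_outputs(x2)
        np.testing.assert_array_equal(h1, h1b)
        assert not np.array_equal(h2, h2b)

    def test_perturbing_fp_region_leaves_h2_unchanged(self, tiny_grid):
        net = tiny_net(tiny_grid)
        rng = np.random.default_rng(4)
        x = rng.random(tiny_grid.size)
        _, h2 = net.head_outputs(x)
        x2 = x.copy()
        x2[: net.n_fp] = rng.random(net.n_fp)
        h1b, h2b = net.head_outputs(x2)
        np.testing.assert_array_equal(h2, h2b)


class TestGradients:
    def test_backprop_matches_finite_differences(self, tiny_grid):
        """Analytic gradients agree with central differences on a tiny net."""
        net = tiny_net(tiny_grid, n_outputs=3)
        rng = np.random.default_rng(5)
        x = rng.random((4, tiny_grid.size)).astype(np.float32)
        y = rng.integers(0, 2, (4, 3)).astype(np.float32)

        # disable dropout so the training-mode loss is a deterministic
        # function of the parameters (batchnorm batch stats are fine: the
        # batch is fixed)
        for layer in net._layers():
            if hasattr(layer, "p"):
                layer.p = 0.0

        def train_loss():
            z = net.forward_logits(x, training=True)
            return float(np.mean(np.logaddexp(0, z) - y * z))

        from irfg.split_net import _ReLU, _sigmoid

        def relu_masks():
            return [l._mask.copy() for l in net._layers() if isinstance(l, _ReLU)]

        z = net.forward_logits(x, training=True)
        base_masks = relu_masks()
        net.backward(((_sigmoid(z) - y) / z.size).astype(np.float32))
        grads = [(v, g.copy()) for v, g in net.parameters()]
        checked = 0
        for value, grad in grads:
            flat_v, flat_g = value.reshape(-1), grad.reshape(-1)
            for idx in rng.choice(flat_v.size, size=min(6, flat_v.size), replace=False):
                eps = 1e-3
                orig = flat_v[idx]
                flat_v[idx] = orig + eps
                up = train_loss()
                masks_up = relu_masks()
                flat_v[idx] = orig - eps
                down = train_loss()
                masks_down = relu_masks()
                flat_v[idx] = orig
                # finite differences are only valid where no ReLU unit
                # crosses its kink under the perturbation
                stable = all(
                    np.array_equal(b, u) and np.array_equal(b, d)
                    for b, u, d in zip(base_masks, masks_up, masks_down)
                )
                if not stable:
                    continue
                fd = (up - down) / (2 * eps)
                assert flat_g[idx] == pytest.approx(fd, abs=2e-4)
                checked += 1
        assert checked > 20


class TestCheckpoint:
    def test_round_trip_preserves_predictions(self, tiny_grid, tmp_path):
        net = tiny_net(tiny_grid, seed=11)
        x = np.random.default_rng(6).random((5, tiny_grid.size))
        path = tmp_path / "model.npz"
        save_checkpoint(net, path)
        loaded = load_checkpoint(path)
        np.testing.assert_allclose(loaded.forward(x), net.forward(x), atol=1e-7)

    def test_catalog_mismatch_refused(self, tiny_grid, tmp_path):
        from irfg.catalog import FunctionalGroupCatalog, DEFAULT_CATALOG

        net = tiny_net(tiny_grid)
        path = tmp_path / "model.npz"
        save_checkpoint(net, path)
        entries = list(DEFAULT_CATALOG.entries)
        entries[0] = ("alkane", "[CX4]")
        other = FunctionalGroupCatalog(tuple(entries))
        with pytest.raises(CatalogMismatchError):
            load_checkpoint(path, expected_catalog=other)
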