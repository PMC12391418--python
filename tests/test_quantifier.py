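"""Model construction, objective, training schedule and cross-validation."""

import numpy as np
import pandas as pd
import pytest

import sweatsers as sw
from sweatsers import quantifier as quant
from sweatsers._nn import AENet
from tests.conftest import FAST_SCHEDULE, GRID200, zero_noise_model
from tests.conftest import train_single_analyte


def tiny_config(**kw):
    base = dict(
        input_dim=24, hidden_width=16, hidden_layers=2, latent_dim=2,
        batch_size=8, max_epochs=5, schedule_epoch=3, seed=0,
        metabolites=("uric_acid",),
    )
    base.update(kw)
    return quant.QuantifierConfig(**base)


def tiny_dataset(n=40, n_points=24, seed=0):
    rng = np.random.default_rng(seed)
    conc = rng.uniform(0, 40, n)
    axis = np.linspace(0, 1, n_points)
    spectra = (
        0.3
        + 0.5 * np.outer(conc / 40, np.exp(-((axis - 0.4) / 0.08) ** 2))
        + rng.normal(0, 0.02, (n, n_points))
    )
    labels = pd.DataFrame({"uric_acid_uM": conc})
    ds = sw.SpectrumSet(
        grid=sw.WavenumberGrid(0, 1, n_points), spectra=spectra, labels=labels
    )
    return sw.normalize_set(ds)


class TestBuild:
    def test_default_architecture_matches_reference(self):
        cfg = quant.QuantifierConfig()
        model = quant.build(cfg)
        assert cfg.latent_dim == 2
        enc_shapes = [w.shape for w in model.net.enc_W]
        assert enc_shapes == [(1321, 1321)] * 4 + [(1321, 2)]
        dec_shapes = [w.shape for w in model.net.dec_W]
        assert dec_shapes == [(2, 1321)] + [(1321, 1321)] * 4
        assert model.net.head_W.shape == (2, 3)

    def test_same_seed_identical_parameters(self):
        a = quant.build(tiny_config(seed=7))
        b = quant.build(tiny_config(seed=7))
        for pa, pb in zip(a.net.parameters(), b.net.parameters()):
            np.testing.assert_array_equal(pa, pb)

    def test_different_seed_differs(self):
        a = quant.build(tiny_config(seed=7))
        b = quant.build(tiny_config(seed=8))
        assert any(
            not np.array_equal(pa, pb)
            for pa, pb in zip(a.net.parameters(), b.net.parameters())
        )

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            quant.QuantifierConfig(latent_dim=0)
        with pytest.raises(ValueError):
            quant.QuantifierConfig(lr_initial=0.0)


class TestTotalLoss:
    def test_matches_elementwise_oracle(self):
        """Hand-computed MSEs on a 2-spectrum toy batch."""
        model = quant.build(tiny_config(metabolites=sw.TARGET_ANALYTES))
        rng = np.random.default_rng(1)
        X = rng.uniform(0, 1, (2, 24))
        Y = rng.uniform(0, 1, (2, 3))
        recon, pred, total = quant.total_loss(model, X, Y)
        _, Xhat, Yhat = model.net.forward(X)
        recon_oracle = sum(
            (Xhat[i, j] - X[i, j]) ** 2 for i in range(2) for j in range(24)
        ) / (2 * 24)
        pred_oracle = sum(
            (Yhat[i, m] - Y[i, m]) ** 2 for i in range(2) for m in range(3)
        ) / (2 * 3)
        assert recon == pytest.approx(recon_oracle, rel=1e-12)
        assert pred == pytest.approx(pred_oracle, rel=1e-12)
        assert total == pytest.approx(recon_oracle + pred_oracle, rel=1e-12)

    def test_lambda_zero_reduces_to_reconstruction(self):
        model = quant.build(tiny_config(loss_weight_lambda=0.0, metabolites=sw.TARGET_ANALYTES))
        rng = np.random.default_rng(2)
        X = rng.uniform(0, 1, (4, 24))
        Y = rng.uniform(0, 1, (4, 3))
        recon, _, total = quant.total_loss(model, X, Y)
        assert total == recon

    def test_unscaled_labels_rejected(self):
        model = quant.build(tiny_config(metabolites=sw.TARGET_ANALYTES))
        X = np.random.default_rng(3).uniform(0, 1, (2, 24))
        with pytest.raises(ValueError, match="scaled to \\[0, 1\\]"):
            quant.total_loss(model, X, np.array([[2.0, 0.1, 0.1]] * 2))


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        """Analytic gradients of the total objective vs central differences.

        Biases are randomized first so no ReLU pre-activation sits exactly
        on the kink (the untrained all-zero biases can put it there).
        """
        rng = np.random.default_rng(0)
        net = AENet(7, 5, 2, 2, 3, rng)
        for b in net.enc_b + net.dec_b + [net.head_b]:
            b += rng.normal(0, 0.3, b.shape)
        X = rng.uniform(0, 1, (4, 7))
        Y = rng.uniform(0, 1, (4, 3))
        (_, _, total), grads = net.loss_and_grads(X, Y, 0.7)
        eps = 1e-6
        for p, g in zip(net.parameters(), grads):
            flat_idx = rng.choice(p.size, size=min(p.size, 10), replace=False)
            for fi in flat_idx:
                idx = np.unravel_index(fi, p.shape)
                old = p[idx]
                p[idx] = old + eps
                tp = net.losses(X, Y, 0.7)[2]
                p[idx] = old - eps
                tm = net.losses(X, Y, 0.7)[2]
                p[idx] = old
                num = (tp - tm) / (2 * eps)
                assert g[idx] == pytest.approx(num, rel=1e-4, abs=1e-9)

    def test_input_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(1)
        net = AENet(6, 4, 2, 2, 2, rng)
        for b in net.enc_b:
            b += rng.normal(0, 0.3, b.shape)
        X = rng.uniform(0, 1, (3, 6))
        eps = 1e-6
        for target in (("latent", 0), ("latent", 1), ("head", 1)):
            G = net.input_gradient(X, target)
            for i, j in [(0, 2), (1, 5), (2, 0)]:
                Xp = X.copy(); Xp[i, j] += eps
                Xm = X.copy(); Xm[i, j] -= eps

                def out(Xa):
                    Z = net.encode(Xa)
                    if target[0] == "latent":
                        return Z[i, target[1]]
                    return net.head(Z)[i, target[1]]

                num = (out(Xp) - out(Xm)) / (2 * eps)
                assert G[i, j] == pytest.approx(num, rel=1e-5, abs=1e-9)


class TestTrain:
    def test_schedule_switches_after_epoch_50(self):
        """The recorded learning rate drops exactly at epoch 51."""
        ds = tiny_dataset()
        cfg = tiny_config(max_epochs=52, schedule_epoch=50,
                          early_stop_patience=60)
        model = quant.train(
            quant.build(cfg), ds.subset(np.arange(30)),
            ds.subset(np.arange(30, 40)),
        )
        hist = model.history.set_index("epoch")
        assert hist.loc[50, "lr"] == cfg.lr_initial
        assert hist.loc[51, "lr"] == cfg.lr_late
        assert hist.loc[50, "weight_decay"] == cfg.weight_decay_initial
        assert hist.loc[51, "weight_decay"] == cfg.weight_decay_late

    def test_best_epoch_val_loss_not_worse_than_first(self):
        ds = tiny_dataset()
        cfg = tiny_config(max_epochs=30, lr_initial=1e-3)
        model = quant.train(
            quant.build(cfg), ds.subset(np.arange(30)),
            ds.subset(np.arange(30, 40)),
        )
        hist = model.history.set_index("epoch")
        best = model.history.attrs["best_epoch"]
        assert hist.loc[best, "val_total"] <= hist.loc[1, "val_total"]

    def test_training_determinism(self):
        ds = tiny_dataset()
        runs = []
        for _ in range(2):
            cfg = tiny_config(max_epochs=8, lr_initial=1e-3)
            m = quant.train(
                quant.build(cfg), ds.subset(np.arange(30)),
                ds.subset(np.arange(30, 40)),
            )
            runs.append(m)
        for pa, pb in zip(runs[0].net.parameters(), runs[1].net.parameters()):
            np.testing.assert_array_equal(pa, pb)
        pd.testing.assert_frame_equal(runs[0].history, runs[1].history)

    def test_empty_sets_rejected(self):
        ds = tiny_dataset()
        with pytest.raises(ValueError, match="non-empty"):
            quant.train(
                quant.build(tiny_config()), ds.subset(np.array([], dtype=int)),
                ds,
            )

    def test_unnormalized_input_rejected(self):
        raw = tiny_dataset().replace(normalized=False)
        with pytest.raises(ValueError, match="normalized"):
            quant.train(quant.build(tiny_config()), raw, raw)


class TestPredictEmbed:
    def test_predictions_bounded_by_training_range(self):
        ds = tiny_dataset()
        cfg = tiny_config(max_epochs=10, lr_initial=1e-3)
        model = quant.train(
            quant.build(cfg), ds.subset(np.arange(30)),
            ds.subset(np.arange(30, 40)),
        )
        preds = quant.predict(model, ds)["uric_acid"]
        lo, hi = model.label_min[0], model.label_max[0]
        assert preds.min() >= lo >= 0.0
        assert preds.max() <= hi

    def test_untrained_predict_fails(self):
        with pytest.raises(ValueError, match="untrained"):
            quant.predict(quant.build(tiny_config()), np.zeros((1, 24)))

    def test_wrong_vector_length_fails(self):
        ds = tiny_dataset()
        cfg = tiny_config(max_epochs=2)
        model = quant.train(
            quant.build(cfg), ds.subset(np.arange(30)),
            ds.subset(np.arange(30, 40)),
        )
        with pytest.raises(ValueError, match="points"):
            quant.predict(model, np.zeros((1, 10)))

    def test_embed_one_point_per_spectrum_and_deterministic(self):
        ds = tiny_dataset()
        model = quant.build(tiny_config())
        emb = quant.embed(model, ds)
        assert len(emb) == ds.n_spectra
        assert {"latent0", "latent1"} <= set(emb.columns)
        dup = quant.embed(model, np.vstack([ds.spectra[:1], ds.spectra[:1]]))
        np.testing.assert_array_equal(
            dup.iloc[0].to_numpy(), dup.iloc[1].to_numpy()
        )

    def test_monotone_predictions_on_clean_ramp(self, library):
        """Noise-free single-analyte ramp -> non-decreasing predictions."""
        model, _, _ = train_single_analyte(
            library, "uric_acid", noise=zero_noise_model()
        )
        ramp = np.linspace(0, 40, 21)
        spectra = np.stack(
            [
                sw.minmax_normalize(
                    sw.clean_spectrum(
                        library, {"uric_acid": c, "background": 1.0}, GRID200
                    )
                ).intensities
                for c in ramp
            ]
        )
        preds = quant.predict(model, spectra)["uric_acid"].to_numpy()
        assert np.all(np.diff(preds) >= -1e-9)


class TestCrossValidate:
    def test_row_count_and_heldout_arithmetic(self):
        """1476 spectra at a 75% split leave 369 held out per repeat."""
        rng = np.random.default_rng(0)
        n = 1476
        conc = rng.uniform(0, 40, n)
        spectra = np.clip(
            0.2 + np.outer(conc / 40, np.ones(12))
            + rng.normal(0, 0.05, (n, 12)),
            0, None,
        )
        ds = sw.normalize_set(
            sw.SpectrumSet(
                grid=sw.WavenumberGrid(0, 1, 12),
                spectra=spectra,
                labels=pd.DataFrame({"uric_acid_uM": conc}),
            )
        )
        cfg = quant.QuantifierConfig(
            input_dim=12, hidden_width=8, hidden_layers=2, max_epochs=2,
            metabolites=("uric_acid",), seed=0,
        )
        cv = quant.cross_validate(ds, cfg, n_repeats=2, seed=0)
        assert len(cv) == 2  # repeats x 1 metabolite
        assert (cv["n_heldout"] == 369).all()

    def test_too_small_dataset_rejected(self):
        ds = tiny_dataset(n=3)
        with pytest.raises(ValueError, match="too small"):
            quant.cross_validate(ds, tiny_config(), n_repeats=1)

    def test_save_load_round_trip(self, tmp_path):
        ds = tiny_dataset()
        cfg = tiny_config(max_epochs=4, lr_initial=1e-3)
        model = quant.train(
            quant.build(cfg), ds.subset(np.arange(30)),
            ds.subset(np.arange(30, 40)),
        )
        model.save(tmp_path / "model")
        back = quant.Quantifier.load(tmp_path / "model")
        np.testing.assert_array_equal(back.label_min, model.label_min)
        pd.testing.assert_frame_equal(
            quant.predict(back, ds), quant.predict(model, ds)
        )
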