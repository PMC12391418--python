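"""Semi-supervised autoencoder quantification of sweat metabolites.

The model compresses each min-max-normalized SERS spectrum through a
symmetric fully connected autoencoder with a 2-D latent bottleneck and
reads concentrations off the latent code with one logistic (linear +
sigmoid) unit per metabolite. Training minimizes

    total = MSE(decoder(encoder(x)), x) + lambda * MSE(head(encoder(x)), y)

with Adam, a scheduled learning-rate / weight-decay drop partway through
training, and early stopping on the validation total loss. Labels are
min-max scaled per metabolite over the training split; predictions are
inverse-scaled back to physical units, so the sigmoid head bounds them to
the training concentration range.

Evaluation follows repeated random-sampling cross-validation: fresh
random 75/25 splits, fresh training per repeat, held-out R^2 and RMSE per
metabolite.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._nn import AENet, Adam
from .spectra import TARGET_ANALYTES, SpectrumSet

LATENT_TARGETS = ("latent0", "latent1")


@dataclass
class QuantifierConfig:
    """Architecture and training schedule of the quantifier.

    Defaults reproduce the reference configuration: 1321-point input,
    four 1321-unit hidden layers per side, a 2-D latent layer, Adam with
    (lr, weight decay) = (1e-4, 1e-5) switching to (1e-5, 1e-6) after
    epoch 50, batch size 32, at most 150 epochs with early stopping.
    ``hidden_width=None`` means "same as the input dimension".
    """

    input_dim: int = 1321
    hidden_layers: int = 4
    hidden_width: int | None = None
    latent_dim: int = 2
    batch_size: int = 32
    max_epochs: int = 150
    lr_initial: float = 1e-4
    lr_late: float = 1e-5
    weight_decay_initial: float = 1e-5
    weight_decay_late: float = 1e-6
    schedule_epoch: int = 50
    early_stop_patience: int = 15
    loss_weight_lambda: float = 1.0
    seed: int = 0
    metabolites: tuple[str, ...] = TARGET_ANALYTES

    def __post_init__(self) -> None:
        self.metabolites = tuple(self.metabolites)
        counts = (
            self.input_dim, self.hidden_layers, self.latent_dim,
            self.batch_size, self.max_epochs, self.schedule_epoch,
            self.early_stop_patience,
        )
        if any(c < 1 for c in counts):
            raise ValueError("all counts must be >= 1")
        if self.hidden_width is not None and self.hidden_width < 1:
            raise ValueError("hidden_width must be >= 1")
        rates = (
            self.lr_initial, self.lr_late,
            self.weight_decay_initial, self.weight_decay_late,
        )
        if any(r <= 0 for r in rates):
            raise ValueError("rates must be positive")
        if not self.metabolites:
            raise ValueError("at least one metabolite must be modelled")

    @property
    def width(self) -> int:
        return self.hidden_width if self.hidden_width is not None else self.input_dim

    def to_dict(self) -> dict:
        d = asdict(self)
        d["metabolites"] = list(self.metabolites)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "QuantifierConfig":
        return cls(**data)


@dataclass
class Quantifier:
    """A (possibly trained) quantifier: network + label-scaling state."""

    config: QuantifierConfig
    net: AENet
    label_min: np.ndarray | None = None
    label_max: np.ndarray | None = None
    history: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def is_trained(self) -> bool:
        return self.label_min is not None

    # ---------------- label scaling ----------------
    def _scale_labels(self, Y: np.ndarray) -> np.ndarray:
        return (Y - self.label_min) / (self.label_max - self.label_min)

    def _unscale_labels(self, Y01: np.ndarray) -> np.ndarray:
        return self.label_min + Y01 * (self.label_max - self.label_min)

    # ---------------- persistence ----------------
    def save(self, directory: str | Path) -> None:
        """Archive as config JSON + parameter arrays (npz)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = {
            "config": self.config.to_dict(),
            "label_min": None if self.label_min is None else self.label_min.tolist(),
            "label_max": None if self.label_max is None else self.label_max.tolist(),
        }
        (directory / "config.json").write_text(json.dumps(meta, indent=2))
        params = {f"p{i}": p for i, p in enumerate(self.net.parameters())}
        np.savez(directory / "parameters.npz", **params)
        if len(self.history):
            self.history.to_csv(directory / "history.csv", index=False)

    @classmethod
    def load(cls, directory: str | Path) -> "Quantifier":
        directory = Path(directory)
        meta = json.loads((directory / "config.json").read_text())
        config = QuantifierConfig.from_dict(meta["config"])
        model = build(config)
        with np.load(directory / "parameters.npz") as data:
            model.net.set_parameters(
                [data[f"p{i}"] for i in range(len(data.files))]
            )
        if meta["label_min"] is not None:
            model.label_min = np.asarray(meta["label_min"], dtype=float)
            model.label_max = np.asarray(meta["label_max"], dtype=float)
        hist = directory / "history.csv"
        if hist.exists():
            model.history = pd.read_csv(hist)
        return model


def build(config: QuantifierConfig) -> Quantifier:
    """Untrained quantifier with seeded parameter initialization."""
    rng = np.random.default_rng(config.seed)
    net = AENet(
        input_dim=config.input_dim,
        width=config.width,
        n_hidden=config.hidden_layers,
        latent_dim=config.latent_dim,
        n_outputs=len(config.metabolites),
        rng=rng,
    )
    return Quantifier(config=config, net=net)


def _model_matrix(model: Quantifier, data: SpectrumSet | np.ndarray) -> np.ndarray:
    if isinstance(data, SpectrumSet):
        if not data.normalized:
            raise ValueError(
                "spectra must be min-max normalized before the model "
                "(preprocess.normalize_set)"
            )
        X = data.spectra
    else:
        X = np.asarray(data, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
    if X.shape[1] != model.config.input_dim:
        raise ValueError(
            f"spectra have {X.shape[1]} points, model expects "
            f"{model.config.input_dim}"
        )
    return X


def _label_matrix(model: Quantifier, data: SpectrumSet) -> np.ndarray:
    cols = [data.concentrations(m) for m in model.config.metabolites]
    return np.column_stack(cols)


def total_loss(
    model: Quantifier,
    spectra: np.ndarray,
    scaled_labels: np.ndarray,
) -> tuple[float, float, float]:
    """(reconstruction, prediction, total) on one batch.

    ``scaled_labels`` must already be min-max scaled to [0, 1] per
    metabolite; ``total = reconstruction + lambda * prediction``.
    """
    Y = np.asarray(scaled_labels, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if np.any((Y < 0) | (Y > 1)):
        raise ValueError(
            "labels must be scaled to [0, 1] before the loss (per-metabolite "
            "min-max over the training split)"
        )
    X = _model_matrix(model, spectra)
    return model.net.losses(X, Y, model.config.loss_weight_lambda)


def train(
    model: Quantifier,
    train_set: SpectrumSet,
    val_set: SpectrumSet,
) -> Quantifier:
    """Train in place and return the model with best-validation parameters.

    Adam runs with the initial learning rate / weight decay through
    ``schedule_epoch`` and the late values afterwards. Training stops at
    ``max_epochs`` or when the validation total loss has not improved for
    ``early_stop_patience`` epochs; the best-validation checkpoint is
    restored. The per-epoch history records losses and the active
    learning rate and weight decay.
    """
    if train_set.n_spectra == 0 or val_set.n_spectra == 0:
        raise ValueError("train and validation sets must be non-empty")
    cfg = model.config
    Xtr = _model_matrix(model, train_set)
    Xva = _model_matrix(model, val_set)
    Ytr_raw = _label_matrix(model, train_set)
    Yva_raw = _label_matrix(model, val_set)

    model.label_min = Ytr_raw.min(axis=0)
    model.label_max = Ytr_raw.max(axis=0)
    span = model.label_max - model.label_min
    if np.any(span == 0):
        flat = [m for m, s in zip(cfg.metabolites, span) if s == 0]
        raise ValueError(f"constant training labels for {flat}; cannot scale")
    Ytr = model._scale_labels(Ytr_raw)
    Yva = np.clip(model._scale_labels(Yva_raw), 0.0, 1.0)

    rng = np.random.default_rng(cfg.seed + 1)
    lam = cfg.loss_weight_lambda
    opt = Adam([p.shape for p in model.net.parameters()])
    n = Xtr.shape[0]
    best_val = np.inf
    best_params = model.net.copy_parameters()
    best_epoch = 0
    since_improved = 0
    rows = []

    for epoch in range(1, cfg.max_epochs + 1):
        late = epoch > cfg.schedule_epoch
        lr = cfg.lr_late if late else cfg.lr_initial
        wd = cfg.weight_decay_late if late else cfg.weight_decay_initial
        order = rng.permutation(n)
        tr_losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            losses, grads = model.net.loss_and_grads(Xtr[idx], Ytr[idx], lam)
            opt.step(model.net.parameters(), grads, lr, wd)
            tr_losses.append(losses)
        tr_recon, tr_pred, tr_total = np.mean(tr_losses, axis=0)
        va_recon, va_pred, va_total = model.net.losses(Xva, Yva, lam)
        rows.append(
            {
                "epoch": epoch,
                "lr": lr,
                "weight_decay": wd,
                "train_recon": tr_recon,
                "train_pred": tr_pred,
                "train_total": tr_total,
                "val_recon": va_recon,
                "val_pred": va_pred,
                "val_total": va_total,
            }
        )
        if va_total < best_val:
            best_val = va_total
            best_params = model.net.copy_parameters()
            best_epoch = epoch
            since_improved = 0
        else:
            since_improved += 1
            if since_improved >= cfg.early_stop_patience:
                break

    model.net.set_parameters(best_params)
    model.history = pd.DataFrame(rows)
    model.history.attrs["best_epoch"] = best_epoch
    return model


def predict(
    model: Quantifier,
    spectra: SpectrumSet | np.ndarray,
) -> pd.DataFrame:
    """Concentrations in physical units, one column per metabolite.

    Head outputs are inverse min-max scaled with the training-split label
    range, so predictions are non-negative and bounded by the training
    maximum (the sigmoid's codomain).
    """
    if not model.is_trained:
        raise ValueError("model is untrained; call train() first")
    X = _model_matrix(model, spectra)
    _, _, Yhat = model.net.forward(X)
    return pd.DataFrame(
        model._unscale_labels(Yhat), columns=list(model.config.metabolites)
    )


def embed(
    model: Quantifier,
    spectra: SpectrumSet | np.ndarray,
) -> pd.DataFrame:
    """Latent coordinates (one 2-D point per spectrum), labels attached."""
    X = _model_matrix(model, spectra)
    Z = model.net.encode(X)
    out = pd.DataFrame(
        Z, columns=[f"latent{i}" for i in range(model.config.latent_dim)]
    )
    if isinstance(spectra, SpectrumSet):
        for col in spectra.labels.columns:
            out[col] = spectra.labels[col].to_numpy()
    return out


def cross_validate(
    dataset: SpectrumSet,
    config: QuantifierConfig,
    n_repeats: int = 10,
    train_fraction: float = 0.75,
    seed: int = 0,
) -> pd.DataFrame:
    """Repeated random-sampling cross-validation.

    Each repeat draws a fresh random ``train_fraction`` split, trains a
    fresh model, and scores the held-out remainder. Returns one row per
    (repeat, metabolite) with held-out R^2 and RMSE in physical units.
    """
    from .evaluate import r_squared, rmse  # local import avoids a cycle

    n = dataset.n_spectra
    n_train = int(n * train_fraction)
    if n_train < 2 or n - n_train < 2:
        raise ValueError(
            f"dataset of {n} spectra is too small for a "
            f"{train_fraction:.0%} split"
        )
    ss = np.random.SeedSequence(seed)
    rows = []
    for repeat, child in enumerate(ss.spawn(n_repeats), start=1):
        rng = np.random.default_rng(child)
        perm = rng.permutation(n)
        tr, va = perm[:n_train], perm[n_train:]
        cfg_r = QuantifierConfig(
            **{**config.to_dict(), "seed": int(rng.integers(2**31 - 1))}
        )
        model = train(build(cfg_r), dataset.subset(tr), dataset.subset(va))
        preds = predict(model, dataset.subset(va))
        for m in cfg_r.metabolites:
            true = dataset.concentrations(m)[va]
            rows.append(
                {
                    "repeat": repeat,
                    "metabolite": m,
                    "r2": r_squared(preds[m].to_numpy(), true),
                    "rmse": rmse(preds[m].to_numpy(), true),
                    "n_heldout": len(va),
                    "best_epoch": model.history.attrs["best_epoch"],
                }
            )
    return pd.DataFrame(rows)
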