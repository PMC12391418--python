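"""Spectral feature attribution for the quantifier.

SHAP-style importances are computed with an expected-gradients estimator:
for each sample, attributions are averaged over random baselines drawn
from a background set and random interpolation points between baseline
and sample, using the encoder's analytic input gradients. Per-sample
attributions for a chosen latent coordinate (or analyte head output) are
squared and averaged across samples, giving a non-negative per-wavenumber
importance profile that highlights the spectral bands the model relies
on, independent of the sign of the concentration effect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .quantifier import Quantifier, _model_matrix
from .spectra import SpectrumSet, WavenumberGrid

DEFAULT_BACKGROUND_SIZE = 100
DEFAULT_N_DRAWS = 32


@dataclass
class ImportanceProfile:
    """Per-wavenumber mean-squared attribution scores."""

    grid: WavenumberGrid
    importance: np.ndarray
    n_samples: int
    n_background: int
    target: str

    def __post_init__(self) -> None:
        self.importance = np.asarray(self.importance, dtype=float)
        if self.importance.shape != (self.grid.n_points,):
            raise ValueError("importance length must match the grid")
        if np.any(self.importance < 0):
            raise ValueError("importance scores must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"wavenumber": self.grid.axis, "importance": self.importance}
        )


def _resolve_targets(model: Quantifier, target: str) -> list[tuple[str, int]]:
    if target.startswith("latent"):
        if target == "latent_sum":
            return [("latent", k) for k in range(model.config.latent_dim)]
        k = int(target.removeprefix("latent"))
        if not 0 <= k < model.config.latent_dim:
            raise ValueError(f"latent component {k} out of range")
        return [("latent", k)]
    if target in model.config.metabolites:
        return [("head", model.config.metabolites.index(target))]
    raise ValueError(
        f"unknown attribution target {target!r}; expected latent0/latent1/"
        f"latent_sum or one of {model.config.metabolites}"
    )


def _expected_gradients(
    model: Quantifier,
    X: np.ndarray,
    B: np.ndarray,
    target: tuple[str, int],
    rng: np.random.Generator,
    n_draws: int,
) -> np.ndarray:
    """Per-sample, per-feature attributions for one scalar output."""
    n, d = X.shape
    attr = np.zeros((n, d))
    for _ in range(n_draws):
        b = B[rng.integers(len(B), size=n)]
        alpha = rng.uniform(size=(n, 1))
        points = b + alpha * (X - b)
        grad = model.net.input_gradient(points, target)
        attr += grad * (X - b)
    return attr / n_draws


def shap_importance(
    model: Quantifier,
    samples: SpectrumSet,
    background: SpectrumSet,
    target: str = "latent_sum",
    n_draws: int = DEFAULT_N_DRAWS,
    seed: int = 0,
) -> ImportanceProfile:
    """Mean-squared SHAP importance profile over ``samples``.

    ``target`` selects the attributed scalar: ``latent0`` / ``latent1``
    (encoder only — the default analysis), ``latent_sum`` (importances of
    the latent coordinates added), or a metabolite name (head output).
    ``background`` supplies the baseline distribution; a random subset of
    up to 100 spectra is used.
    """
    if not model.is_trained:
        raise ValueError("model is untrained; explain a trained model")
    if background.n_spectra == 0:
        raise ValueError("background set is empty")
    X = _model_matrix(model, samples)
    B = _model_matrix(model, background)
    rng = np.random.default_rng(seed)
    if len(B) > DEFAULT_BACKGROUND_SIZE:
        B = B[rng.choice(len(B), DEFAULT_BACKGROUND_SIZE, replace=False)]

    importance = np.zeros(X.shape[1])
    for tgt in _resolve_targets(model, target):
        attr = _expected_gradients(model, X, B, tgt, rng, n_draws)
        importance += np.mean(attr**2, axis=0)
    return ImportanceProfile(
        grid=samples.grid,
        importance=importance,
        n_samples=X.shape[0],
        n_background=len(B),
        target=target,
    )


def attributions(
    model: Quantifier,
    samples: SpectrumSet,
    background: SpectrumSet,
    target: str = "latent0",
    n_draws: int = DEFAULT_N_DRAWS,
    seed: int = 0,
) -> np.ndarray:
    """Raw (signed) per-sample expected-gradients attributions for one
    scalar target; useful for the additivity diagnostic."""
    tgt, = _resolve_targets(model, target)
    X = _model_matrix(model, samples)
    B = _model_matrix(model, background)
    rng = np.random.default_rng(seed)
    return _expected_gradients(model, X, B, tgt, rng, n_draws)


def top_features(profile: ImportanceProfile, k: int) -> list[tuple[float, float]]:
    """The ``k`` highest-importance (wavenumber, score) pairs, descending;
    ties broken toward the lower wavenumber."""
    if k < 1:
        raise ValueError("k must be >= 1")
    n = profile.grid.n_points
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} grid points")
    # stable sort on (-score, wavenumber): lexsort's last key is primary
    axis = profile.grid.axis
    order = np.lexsort((axis, -profile.importance))[:k]
    return [(float(axis[i]), float(profile.importance[i])) for i in order]


def plot_importance(
    profile: ImportanceProfile,
    mean_spectrum: np.ndarray | None = None,
    ax=None,
):
    """Importance profile, optionally overlaid on the mean spectrum."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(profile.grid.axis, profile.importance, color="purple",
            label=f"importance ({profile.target})")
    ax.set_xlabel("Raman shift (cm$^{-1}$)")
    ax.set_ylabel("mean squared SHAP value")
    if mean_spectrum is not None:
        twin = ax.twinx()
        twin.plot(profile.grid.axis, mean_spectrum, color="gray", alpha=0.5,
                  label="mean spectrum")
        twin.set_ylabel("intensity (norm.)")
    ax.legend(loc="upper right")
    return ax
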