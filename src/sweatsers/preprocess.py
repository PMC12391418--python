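"""Raw-spectrum conditioning and univariate peak/SNR utilities.

The model-facing pipeline is: resample onto the uniform grid, optionally
remove the substrate background, then min-max scale each spectrum to
[0, 1]. Peak intensity extraction (window maximum over a two-endpoint
linear local baseline) and the peak/noise SNR ratio support the univariate
calibration and substrate-characterization analyses.
"""

from __future__ import annotations

import numpy as np

from .spectra import Spectrum, SpectrumSet, WavenumberGrid

DEFAULT_PEAK_HALF_WINDOW = 15.0  # cm^-1


def vectorize(
    raw: list[tuple[float, float]] | np.ndarray,
    grid: WavenumberGrid | None = None,
) -> Spectrum:
    """Resample a (wavenumber, intensity) trace onto the uniform grid.

    Linear interpolation; the raw axis must be sorted and cover the full
    grid range so no extrapolation happens.
    """
    grid = grid or WavenumberGrid()
    arr = np.asarray(raw, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("raw trace must be an (n, 2) wavenumber/intensity array")
    wn, inten = arr[:, 0], arr[:, 1]
    if np.any(np.diff(wn) < 0):
        raise ValueError("raw wavenumbers must be sorted ascending")
    if wn[0] > grid.start or wn[-1] < grid.end:
        raise ValueError(
            f"raw trace range [{wn[0]}, {wn[-1]}] does not cover the grid "
            f"[{grid.start}, {grid.end}]"
        )
    return Spectrum(grid, np.interp(grid.axis, wn, inten))


def minmax_normalize(spectrum: Spectrum) -> Spectrum:
    """Affine rescale of one spectrum to the [0, 1] range."""
    x = spectrum.intensities
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        raise ValueError("constant spectrum: min-max scaling is undefined")
    return spectrum.with_intensities((x - lo) / (hi - lo))


def normalize_set(dataset: SpectrumSet) -> SpectrumSet:
    """Min-max scale every spectrum in a set (rows independently).

    No-op if the set is already flagged normalized, so the scaling is
    never applied twice.
    """
    if dataset.normalized:
        return dataset
    x = dataset.spectra
    lo = x.min(axis=1, keepdims=True)
    hi = x.max(axis=1, keepdims=True)
    span = hi - lo
    if np.any(span == 0):
        bad = int(np.argmax((span == 0).ravel()))
        raise ValueError(f"spectrum row {bad} is constant; cannot normalize")
    return dataset.replace(spectra=(x - lo) / span, normalized=True)


def average_replicates(spectra: list[Spectrum]) -> Spectrum:
    """Pointwise mean of replicate spectra (shared grid required)."""
    if not spectra:
        raise ValueError("no spectra to average")
    grid = spectra[0].grid
    for s in spectra[1:]:
        if s.grid != grid:
            raise ValueError("replicates must share one grid")
    stack = np.stack([s.intensities for s in spectra])
    return Spectrum(grid, stack.mean(axis=0))


def subtract_background(
    spectrum: Spectrum,
    background: Spectrum,
    scale: float | None = None,
    fit_windows: list[tuple[float, float]] | None = None,
) -> Spectrum:
    """Remove a scaled reference background, clipping at zero.

    With ``scale=None`` the scale is the least-squares fit of the
    background to the spectrum, restricted to ``fit_windows``
    (``(low, high)`` wavenumber pairs over background-dominated bands)
    when given, else over the full axis.
    """
    if spectrum.grid != background.grid:
        raise ValueError("spectrum and background must share one grid")
    y, b = spectrum.intensities, background.intensities
    if scale is None:
        if fit_windows:
            mask = np.zeros(len(y), dtype=bool)
            for lo, hi in fit_windows:
                mask |= spectrum.grid.window((lo + hi) / 2, (hi - lo) / 2)
        else:
            mask = np.ones(len(y), dtype=bool)
        denom = float(np.dot(b[mask], b[mask]))
        if denom == 0:
            raise ValueError("background is zero over the fit windows")
        scale = float(np.dot(b[mask], y[mask])) / denom
    return spectrum.with_intensities(np.clip(y - scale * b, 0.0, None))


def peak_intensity(
    spectrum: Spectrum,
    center: float,
    half_window: float = DEFAULT_PEAK_HALF_WINDOW,
) -> float:
    """Baseline-corrected peak height near ``center``.

    Maximum intensity inside ``center +/- half_window`` minus a straight
    local baseline drawn through the window's two endpoint intensities.
    """
    grid = spectrum.grid
    if center - half_window < grid.start or center + half_window > grid.end:
        raise ValueError(
            f"window {center}+/-{half_window} cm^-1 extends outside the grid"
        )
    mask = grid.window(center, half_window)
    idx = np.flatnonzero(mask)
    ax, y = grid.axis[idx], spectrum.intensities[idx]
    x0, x1 = ax[0], ax[-1]
    y0, y1 = y[0], y[-1]
    baseline = y0 + (y1 - y0) * (ax - x0) / (x1 - x0) if x1 > x0 else y0
    return float(np.max(y - baseline))


def snr(signal_peak: float, noise_spectra: list[Spectrum]) -> float:
    """Signal-to-noise ratio: peak height over pooled noise SD.

    The noise SD pools all intensity samples of the blank (substrate-only)
    spectra, matching the definition of SNR as the analyte peak intensity
    over the standard deviation of the substrate noise signal.
    """
    if len(noise_spectra) < 2:
        raise ValueError("need at least 2 noise spectra")
    pooled = np.concatenate([s.intensities for s in noise_spectra])
    sd = float(pooled.std(ddof=1))
    if sd == 0:
        raise ValueError("noise spectra have zero variance")
    return float(signal_peak) / sd
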