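"""Core containers: wavenumber grid, single spectra and labeled spectrum sets.

A SERS spectrum is held as an intensity vector on a shared, uniformly spaced
Raman-shift axis. Labeled collections carry per-spectrum metabolite
concentrations (in each analyte's physiological unit) plus provenance
metadata, and are the common currency of the simulation, preprocessing and
modelling layers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: The three quantified sweat metabolites, in canonical order.
TARGET_ANALYTES: tuple[str, ...] = ("uric_acid", "lactate", "tyrosine")

#: Concentration unit per analyte (uric acid and tyrosine in micromolar,
#: lactate in millimolar — physiological sweat ranges differ by ~1000x).
ANALYTE_UNITS: dict[str, str] = {
    "uric_acid": "uM",
    "lactate": "mM",
    "tyrosine": "uM",
}

#: Label column name used in tabular exports for each target analyte.
LABEL_COLUMNS: dict[str, str] = {
    name: f"{name}_{ANALYTE_UNITS[name]}" for name in TARGET_ANALYTES
}


@dataclass(frozen=True)
class WavenumberGrid:
    """Uniform Raman-shift axis in cm^-1, inclusive of both endpoints.

    The default covers 457-1674 cm^-1 with 1321 points (spacing ~0.9220
    cm^-1), the axis the quantification model is dimensioned for.
    """

    start: float = 457.0
    end: float = 1674.0
    n_points: int = 1321

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(
                f"grid start ({self.start}) must be below end ({self.end})"
            )
        if self.n_points < 2:
            raise ValueError("grid needs at least 2 points")

    @property
    def axis(self) -> np.ndarray:
        """Strictly increasing, uniformly spaced wavenumber axis."""
        return np.linspace(self.start, self.end, self.n_points)

    @property
    def spacing(self) -> float:
        return (self.end - self.start) / (self.n_points - 1)

    def index_of(self, wavenumber: float) -> int:
        """Index of the grid point closest to ``wavenumber``."""
        if not self.start <= wavenumber <= self.end:
            raise ValueError(
                f"{wavenumber} cm^-1 outside grid range "
                f"[{self.start}, {self.end}]"
            )
        return int(round((wavenumber - self.start) / self.spacing))

    def window(self, center: float, half_width: float) -> np.ndarray:
        """Boolean mask of grid points within ``center +/- half_width``."""
        ax = self.axis
        return (ax >= center - half_width) & (ax <= center + half_width)


@dataclass(frozen=True)
class Spectrum:
    """One intensity vector on a :class:`WavenumberGrid`."""

    grid: WavenumberGrid
    intensities: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "intensities", arr)
        if arr.ndim != 1 or arr.shape[0] != self.grid.n_points:
            raise ValueError(
                f"intensity vector length {arr.shape} does not match grid "
                f"({self.grid.n_points} points)"
            )
        if not np.all(np.isfinite(arr)):
            raise ValueError("spectrum contains non-finite intensities")

    def with_intensities(self, intensities: np.ndarray) -> "Spectrum":
        return Spectrum(self.grid, intensities)


@dataclass
class SpectrumSet:
    """Labeled matrix of spectra sharing one grid.

    Parameters
    ----------
    grid : shared wavenumber axis.
    spectra : (n_spectra, n_points) intensity matrix.
    labels : per-spectrum concentrations; one column per analyte, named as
        in :data:`LABEL_COLUMNS` for the targets.
    metadata : per-spectrum provenance (``combo_id``, ``replicate``,
        ``source``); aligned row-for-row with ``spectra``.
    normalized : whether each row has already been min-max scaled to [0, 1]
        (recorded so the model never double-normalizes).
    """

    grid: WavenumberGrid
    spectra: np.ndarray
    labels: pd.DataFrame
    metadata: pd.DataFrame = field(default_factory=pd.DataFrame)
    normalized: bool = False

    def __post_init__(self) -> None:
        self.spectra = np.asarray(self.spectra, dtype=float)
        if self.spectra.ndim != 2:
            raise ValueError("spectra must be a 2-D matrix")
        if self.spectra.shape[1] != self.grid.n_points:
            raise ValueError(
                f"spectra have {self.spectra.shape[1]} points, grid has "
                f"{self.grid.n_points}"
            )
        if not np.all(np.isfinite(self.spectra)):
            raise ValueError("spectra contain non-finite intensities")
        if len(self.labels) != self.n_spectra:
            raise ValueError(
                f"{len(self.labels)} label rows for {self.n_spectra} spectra"
            )
        if len(self.metadata) == 0:
            self.metadata = pd.DataFrame(index=range(self.n_spectra))
        elif len(self.metadata) != self.n_spectra:
            raise ValueError("metadata rows do not match spectra rows")
        self.labels = self.labels.reset_index(drop=True)
        self.metadata = self.metadata.reset_index(drop=True)

    @property
    def n_spectra(self) -> int:
        return self.spectra.shape[0]

    @property
    def n_points(self) -> int:
        return self.spectra.shape[1]

    @property
    def analytes(self) -> list[str]:
        names = []
        for col in self.labels.columns:
            for name, labelled in LABEL_COLUMNS.items():
                if col == labelled:
                    names.append(name)
        return names

    def concentrations(self, analyte: str) -> np.ndarray:
        """Label vector for one analyte, in its physiological unit."""
        col = LABEL_COLUMNS.get(analyte, analyte)
        if col not in self.labels.columns:
            raise KeyError(f"no label column for analyte {analyte!r}")
        return self.labels[col].to_numpy(dtype=float)

    def subset(self, indices: np.ndarray) -> "SpectrumSet":
        indices = np.asarray(indices)
        return SpectrumSet(
            grid=self.grid,
            spectra=self.spectra[indices],
            labels=self.labels.iloc[indices],
            metadata=self.metadata.iloc[indices],
            normalized=self.normalized,
        )

    def spectrum(self, i: int) -> Spectrum:
        return Spectrum(self.grid, self.spectra[i])

    def replace(self, **changes) -> "SpectrumSet":
        return replace(self, **changes)
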