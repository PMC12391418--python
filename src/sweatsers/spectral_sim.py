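"""Synthetic labeled SERS mixture spectra.

Forward model: each analyte contributes a set of Lorentzian bands whose
height scales with concentration (linearly by default, or through a
Langmuir saturation curve), on top of a fixed substrate/artificial-sweat
background. Measurement noise is decomposed into a multiplicative
per-spectrum gain (log-normal, parameterized by its coefficient of
variation), a smooth additive polynomial baseline drift, and white noise.

The default mixture design mirrors the structure of the training corpus
used for the quantification model: three target metabolites (uric acid,
lactate, tyrosine) drawn from discrete physiological level sets, 41
distinct concentration combinations, and 36 replicate spectra per
combination — 1476 spectra in total.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .chrono import ChamberRecord
from .spectra import (
    ANALYTE_UNITS,
    LABEL_COLUMNS,
    TARGET_ANALYTES,
    Spectrum,
    SpectrumSet,
    WavenumberGrid,
)

#: Discrete concentration level sets per target analyte, in each analyte's
#: physiological unit (uric acid / tyrosine in uM, lactate in mM).
LEVEL_SETS: dict[str, tuple[float, ...]] = {
    "uric_acid": (0.0, 2.5, 5.0, 10.0, 20.0, 40.0),
    "lactate": (0.0, 1.0, 2.0, 5.0, 10.0, 20.0),
    "tyrosine": (0.0, 50.0, 67.0, 100.0, 150.0, 200.0),
}

#: Primary SERS band center per target analyte (cm^-1).
PRIMARY_BANDS: dict[str, float] = {
    "uric_acid": 635.0,
    "lactate": 859.0,
    "tyrosine": 1353.0,
}

_DESIGN_SEED = 202508  # fixes the default 41-combination draw


@dataclass(frozen=True)
class PeakDef:
    """One Lorentzian band: center and FWHM in cm^-1, relative height in
    (0, 1] of the analyte's strongest band."""

    center: float
    fwhm: float = 12.0
    relative_amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError("fwhm must be positive")
        if not 0 < self.relative_amplitude <= 1:
            raise ValueError("relative_amplitude must be in (0, 1]")

    def lineshape(self, axis: np.ndarray) -> np.ndarray:
        """Unit-height Lorentzian evaluated on ``axis``."""
        hwhm = self.fwhm / 2.0
        return 1.0 / (1.0 + ((axis - self.center) / hwhm) ** 2)


@dataclass(frozen=True)
class Component:
    """Spectral signature and response of one chemical species.

    ``sensitivity`` is peak intensity per unit concentration (the analyte's
    own unit); ``saturation_scale``, when set, switches the response to a
    Langmuir form ``sensitivity * s * c / (s + c)`` that plateaus at high
    concentration.
    """

    peaks: tuple[PeakDef, ...]
    sensitivity: float
    saturation_scale: float | None = None

    def __post_init__(self) -> None:
        if len(self.peaks) == 0:
            raise ValueError("component needs at least one peak")
        if self.sensitivity <= 0:
            raise ValueError("sensitivity must be positive")
        if self.saturation_scale is not None and self.saturation_scale <= 0:
            raise ValueError("saturation_scale must be positive")

    def response(self, concentration: float) -> float:
        """Peak-height response at ``concentration``."""
        c = float(concentration)
        if c < 0:
            raise ValueError("concentration must be non-negative")
        if self.saturation_scale is None:
            return self.sensitivity * c
        s = self.saturation_scale
        return self.sensitivity * s * c / (s + c)


@dataclass
class ComponentLibrary:
    """Named map of :class:`Component` signatures."""

    components: dict[str, Component]

    def __post_init__(self) -> None:
        missing = [a for a in TARGET_ANALYTES if a not in self.components]
        if missing:
            raise ValueError(
                f"library must include all target analytes; missing {missing}"
            )

    def __getitem__(self, name: str) -> Component:
        try:
            return self.components[name]
        except KeyError:
            raise KeyError(
                f"unknown analyte {name!r}; library has "
                f"{sorted(self.components)}"
            ) from None

    def __contains__(self, name: str) -> bool:
        return name in self.components

    def names(self) -> list[str]:
        return list(self.components)

    def to_dict(self) -> dict:
        return {
            name: {
                "sensitivity": comp.sensitivity,
                "saturation_scale": comp.saturation_scale,
                "peaks": [
                    {
                        "center": p.center,
                        "fwhm": p.fwhm,
                        "relative_amplitude": p.relative_amplitude,
                    }
                    for p in comp.peaks
                ],
            }
            for name, comp in self.components.items()
        }

    @classmethod
    def from_dict(cls, data: dict) -> "ComponentLibrary":
        comps = {}
        for name, spec in data.items():
            comps[name] = Component(
                peaks=tuple(PeakDef(**p) for p in spec["peaks"]),
                sensitivity=spec["sensitivity"],
                saturation_scale=spec.get("saturation_scale"),
            )
        return cls(comps)

    def save(self, path: str | Path) -> None:
        _dump_structured(self.to_dict(), Path(path))

    @classmethod
    def load(cls, path: str | Path) -> "ComponentLibrary":
        return cls.from_dict(_load_structured(Path(path)))


@dataclass
class MixtureDesign:
    """Concentration combinations and replicate count for one dataset.

    ``combinations`` holds one row per combination: a ``combo_id`` column
    plus one concentration column per species (plain analyte names, each in
    its own unit).
    """

    combinations: pd.DataFrame
    replicates_per_combo: int

    def __post_init__(self) -> None:
        if "combo_id" not in self.combinations.columns:
            raise ValueError("combinations need a combo_id column")
        ids = self.combinations["combo_id"]
        if ids.duplicated().any():
            raise ValueError("combo_ids must be unique")
        conc = self.combinations.drop(columns="combo_id")
        if (conc.to_numpy(dtype=float) < 0).any():
            raise ValueError("concentrations must be non-negative")
        if self.replicates_per_combo < 1:
            raise ValueError("replicates_per_combo must be >= 1")

    @property
    def n_combinations(self) -> int:
        return len(self.combinations)

    @property
    def n_planned_spectra(self) -> int:
        return self.n_combinations * self.replicates_per_combo

    @property
    def species(self) -> list[str]:
        return [c for c in self.combinations.columns if c != "combo_id"]

    def save(self, path: str | Path) -> None:
        payload = {
            "replicates_per_combo": self.replicates_per_combo,
            "combinations": self.combinations.to_dict(orient="records"),
        }
        _dump_structured(payload, Path(path))

    @classmethod
    def load(cls, path: str | Path) -> "MixtureDesign":
        data = _load_structured(Path(path))
        return cls(
            combinations=pd.DataFrame(data["combinations"]),
            replicates_per_combo=int(data["replicates_per_combo"]),
        )


@dataclass
class NoiseModel:
    """Per-measurement signal fluctuation model.

    amplitude_cv : coefficient of variation of the log-normal per-spectrum
        gain (unit mean) — hotspot-to-hotspot enhancement variability.
    baseline_order / baseline_scale : order and intensity scale of the
        random additive polynomial baseline drift.
    white_sigma : standard deviation of additive white noise.
    seed : RNG seed; the same seed and design reproduce the dataset bit for
        bit.
    """

    amplitude_cv: float = 0.30
    baseline_order: int = 4
    baseline_scale: float = 0.80
    white_sigma: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.amplitude_cv, self.baseline_scale, self.white_sigma) < 0:
            raise ValueError("noise scales must be non-negative")
        if self.baseline_order < 0:
            raise ValueError("baseline_order must be >= 0")


def _dump_structured(payload: dict, path: Path) -> None:
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(payload, indent=2))
    else:
        path.write_text(yaml.safe_dump(payload, sort_keys=False))


def _load_structured(path: Path) -> dict:
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def default_library() -> ComponentLibrary:
    """Component library for the three target metabolites plus a fixed
    artificial-sweat/substrate background.

    Primary band centers are 635 cm^-1 (uric acid), 859 cm^-1 (lactate) and
    1353 cm^-1 (tyrosine). Secondary bands are plausible minor features
    placed to create cross-analyte spectral overlap; only the primary
    centers are treated as normative. Sensitivities are scaled so each
    analyte's physiological maximum yields unit primary-peak response.
    Optional background species carry single weak stub bands and default to
    zero concentration.
    """
    lib = {
        "uric_acid": Component(
            peaks=(
                PeakDef(635.0, 12.0, 1.0),
                PeakDef(1010.0, 14.0, 0.45),
                PeakDef(1345.0, 16.0, 0.30),
            ),
            sensitivity=1.0 / 40.0,  # per uM; unit response at 40 uM
        ),
        "lactate": Component(
            peaks=(
                PeakDef(859.0, 12.0, 1.0),
                PeakDef(1045.0, 14.0, 0.50),
                PeakDef(1460.0, 18.0, 0.35),
            ),
            sensitivity=1.0 / 20.0,  # per mM; unit response at 20 mM
        ),
        "tyrosine": Component(
            peaks=(
                PeakDef(1353.0, 12.0, 1.0),
                PeakDef(830.0, 14.0, 0.40),
                PeakDef(1210.0, 14.0, 0.35),
            ),
            sensitivity=1.0 / 200.0,  # per uM; unit response at 200 uM
        ),
        # Fixed substrate + artificial-sweat matrix: broad fluorocarbon/PDMS
        # bands plus a urea-like sharp feature. Driven at concentration 1 by
        # the default design; breaks the scale-invariance of per-spectrum
        # min-max normalization so absolute concentration is identifiable.
        "background": Component(
            peaks=(
                PeakDef(700.0, 160.0, 0.55),
                PeakDef(1100.0, 200.0, 0.70),
                PeakDef(1450.0, 150.0, 0.45),
                PeakDef(1008.0, 14.0, 0.60),
            ),
            sensitivity=0.5,
        ),
        # Optional variable background species (stub signatures).
        "urea": Component((PeakDef(1008.0, 12.0, 1.0),), sensitivity=0.02),
        "glucose": Component((PeakDef(1125.0, 14.0, 1.0),), sensitivity=0.1),
        "creatinine": Component((PeakDef(680.0, 12.0, 1.0),), sensitivity=0.5),
        "ascorbic_acid": Component(
            (PeakDef(1320.0, 14.0, 1.0),), sensitivity=0.5
        ),
        "glycine": Component((PeakDef(893.0, 12.0, 1.0),), sensitivity=0.1),
        "alanine": Component((PeakDef(850.0, 12.0, 1.0),), sensitivity=0.1),
        "glutamate": Component((PeakDef(940.0, 12.0, 1.0),), sensitivity=0.1),
    }
    return ComponentLibrary(lib)


def default_design(replicates_per_combo: int = 36) -> MixtureDesign:
    """41-combination mixture design over the printed per-analyte level sets.

    The exact combinations of the reference training corpus are not public;
    this stand-in draws 41 distinct (uric acid, lactate, tyrosine) tuples
    from the level sets with a fixed internal seed, anchoring the all-zero
    and all-maximum corners, and adds the fixed background at concentration
    1. With the default 36 replicates the design plans 41 x 36 = 1476
    spectra.
    """
    rng = np.random.default_rng(_DESIGN_SEED)
    levels = [LEVEL_SETS[a] for a in TARGET_ANALYTES]
    anchors = [
        tuple(lv[0] for lv in levels),
        tuple(lv[-1] for lv in levels),
    ]
    chosen: list[tuple[float, ...]] = list(anchors)
    seen = set(anchors)
    while len(chosen) < 41:
        tup = tuple(float(rng.choice(lv)) for lv in levels)
        if tup not in seen:
            seen.add(tup)
            chosen.append(tup)
    rows = []
    for i, tup in enumerate(chosen, start=1):
        row = {"combo_id": i}
        row.update(dict(zip(TARGET_ANALYTES, tup)))
        row["background"] = 1.0
        rows.append(row)
    return MixtureDesign(
        combinations=pd.DataFrame(rows),
        replicates_per_combo=replicates_per_combo,
    )


def clean_spectrum(
    library: ComponentLibrary,
    concentrations: dict[str, float],
    grid: WavenumberGrid | None = None,
) -> Spectrum:
    """Noise-free mixture spectrum for the given concentrations.

    Each analyte contributes ``response(c) * sum_peaks rel_amp *
    Lorentzian(center, fwhm)``; contributions add linearly across analytes.
    """
    grid = grid or WavenumberGrid()
    axis = grid.axis
    total = np.zeros(grid.n_points)
    for name, conc in concentrations.items():
        if conc < 0:
            raise ValueError(f"negative concentration for {name!r}")
        comp = library[name]
        height = comp.response(conc)
        if height == 0.0:
            continue
        for peak in comp.peaks:
            total += height * peak.relative_amplitude * peak.lineshape(axis)
    return Spectrum(grid, total)


def generate_dataset(
    library: ComponentLibrary,
    design: MixtureDesign,
    noise: NoiseModel,
    grid: WavenumberGrid | None = None,
) -> SpectrumSet:
    """Noisy replicate spectra for every combination in ``design``.

    Per replicate: clean spectrum x log-normal gain (unit mean, CV =
    ``amplitude_cv``) + random polynomial baseline + white noise, clipped
    at zero. Row count is ``n_combinations * replicates_per_combo``;
    reproducible bit for bit from ``noise.seed``.
    """
    if design.n_combinations == 0:
        raise ValueError("design has no combinations")
    grid = grid or WavenumberGrid()
    rng = np.random.default_rng(noise.seed)
    x = np.linspace(-1.0, 1.0, grid.n_points)

    # log-normal with unit mean: sigma^2 = ln(1 + cv^2), mu = -sigma^2/2
    cv = noise.amplitude_cv
    sigma = np.sqrt(np.log1p(cv**2)) if cv > 0 else 0.0
    mu = -0.5 * sigma**2

    rows, label_rows, meta_rows = [], [], []
    for _, combo in design.combinations.iterrows():
        conc = {s: float(combo[s]) for s in design.species}
        clean = clean_spectrum(library, conc, grid).intensities
        for rep in range(1, design.replicates_per_combo + 1):
            gain = float(np.exp(rng.normal(mu, sigma))) if sigma > 0 else 1.0
            if noise.baseline_scale > 0:
                coeffs = rng.uniform(-1, 1, noise.baseline_order + 1)
                drift = np.polyval(coeffs, x)
                # fluorescence-like drift: non-negative, random shape
                baseline = noise.baseline_scale * (drift - drift.min())
            else:
                baseline = 0.0
            white = (
                rng.normal(0.0, noise.white_sigma, grid.n_points)
                if noise.white_sigma > 0
                else 0.0
            )
            y = np.clip(clean * gain + baseline + white, 0.0, None)
            rows.append(y)
            label = {
                LABEL_COLUMNS.get(s, s): conc[s]
                for s in design.species
            }
            label_rows.append(label)
            meta_rows.append(
                {
                    "combo_id": int(combo["combo_id"]),
                    "replicate": rep,
                    "source": "synthetic",
                }
            )
    return SpectrumSet(
        grid=grid,
        spectra=np.asarray(rows),
        labels=pd.DataFrame(label_rows),
        metadata=pd.DataFrame(meta_rows),
    )


def simulate_chrono_injection(
    profile: list[tuple[float, float]],
    flow_rate: float,
    chamber_volume: float,
    n_chambers: int | None = None,
) -> list[ChamberRecord]:
    """Sequential chamber filling under a piecewise-constant inlet profile.

    ``profile`` is a list of ``(concentration, duration_minutes)`` segments
    injected at constant ``flow_rate`` (uL/min) into chambers of
    ``chamber_volume`` (uL). Each chamber's label is the volume-weighted
    (here time-weighted, flow being constant) mean inlet concentration over
    its fill window. Only completely filled chambers are returned.
    """
    if flow_rate <= 0 or chamber_volume <= 0:
        raise ValueError("flow_rate and chamber_volume must be positive")
    for conc, dur in profile:
        if dur <= 0:
            raise ValueError("profile durations must be positive")
        if conc < 0:
            raise ValueError("profile concentrations must be non-negative")

    total_time = sum(dur for _, dur in profile)
    fill_time = chamber_volume / flow_rate
    n_full = int(np.floor(total_time / fill_time + 1e-12))
    if n_chambers is not None:
        n_full = min(n_full, n_chambers)

    # segment boundaries for piecewise integration
    starts = np.cumsum([0.0] + [dur for _, dur in profile[:-1]])
    ends = starts + np.array([dur for _, dur in profile])
    concs = np.array([c for c, _ in profile])

    records = []
    for i in range(n_full):
        t0, t1 = i * fill_time, (i + 1) * fill_time
        overlap = np.clip(np.minimum(ends, t1) - np.maximum(starts, t0), 0, None)
        mean_conc = float(np.dot(overlap, concs) / (t1 - t0))
        records.append(
            ChamberRecord(
                index=i + 1,
                volume=chamber_volume,
                fill_start=t0,
                fill_end=t1,
                concentration=mean_conc,
            )
        )
    return records
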