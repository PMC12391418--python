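"""Dataset IO, pipeline configuration, fixtures and the end-to-end runner.

The tabular interchange format is a plain CSV: one spectrum per row, one
column per grid wavenumber (numeric headers) followed by label and
metadata columns (``uric_acid_uM``, ``lactate_mM``, ``tyrosine_uM``,
``combo_id``, ``replicate``, ``source``). A column-mapping hint lets the
reader ingest externally produced tables whose label columns are named
differently.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import chrono as chrono_mod
from . import evaluate as evaluate_mod
from . import explain as explain_mod
from . import preprocess
from . import quantifier as quant_mod
from . import spectral_sim as sim
from .spectra import LABEL_COLUMNS, SpectrumSet, WavenumberGrid

log = logging.getLogger("sweatsers")

_META_COLUMNS = ("combo_id", "replicate", "source")


def write_spectra_table(dataset: SpectrumSet, path: str | Path) -> None:
    """Write a SpectrumSet to the package CSV schema."""
    path = Path(path)
    wn_cols = [f"{w:.4f}" for w in dataset.grid.axis]
    frame = pd.DataFrame(dataset.spectra, columns=wn_cols)
    for col in dataset.labels.columns:
        frame[col] = dataset.labels[col].to_numpy()
    for col in dataset.metadata.columns:
        frame[col] = dataset.metadata[col].to_numpy()
    frame.to_csv(path, index=False)


def read_spectra_table(
    path: str | Path,
    column_map: dict[str, str] | None = None,
) -> SpectrumSet:
    """Read a spectra CSV into a validated SpectrumSet.

    Columns with numeric headers are taken as intensities at that
    wavenumber; the rest are labels/metadata. ``column_map`` renames file
    columns to canonical names first (e.g. ``{"UA": "uric_acid_uM"}``),
    which is how externally deposited layouts are ingested.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path} is empty") from None
    if len(frame) == 0:
        raise ValueError(f"{path} contains no spectra rows")
    if column_map:
        frame = frame.rename(columns=column_map)

    wn, wn_cols, other_cols = [], [], []
    for col in frame.columns:
        try:
            wn.append(float(col))
            wn_cols.append(col)
        except ValueError:
            other_cols.append(col)
    if len(wn_cols) < 2:
        raise ValueError(
            f"{path}: found {len(wn_cols)} numeric wavenumber columns; "
            "need at least 2"
        )
    order = np.argsort(wn)
    wn = np.asarray(wn)[order]
    wn_cols = [wn_cols[i] for i in order]
    spacing = np.diff(wn)
    if spacing.min() <= 0 or np.ptp(spacing) > 1e-3 * spacing.mean():
        raise ValueError(f"{path}: wavenumber columns are not uniformly spaced")

    spectra = (
        frame[wn_cols].apply(pd.to_numeric, errors="coerce").to_numpy(float)
    )
    bad = ~np.isfinite(spectra)
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(
            f"{path}: non-numeric or missing intensity at row {r}, "
            f"column {wn_cols[c]!r}"
        )
    grid = WavenumberGrid(float(wn[0]), float(wn[-1]), len(wn))
    label_cols = [c for c in other_cols if c not in _META_COLUMNS]
    meta_cols = [c for c in other_cols if c in _META_COLUMNS]
    labels = frame[label_cols].copy()
    for col in LABEL_COLUMNS.values():
        if col in labels.columns and labels[col].isna().any():
            r = int(labels[col].isna().idxmax())
            raise ValueError(f"{path}: missing label {col!r} at row {r}")
    dataset = SpectrumSet(
        grid=grid,
        spectra=spectra,
        labels=labels,
        metadata=frame[meta_cols].copy(),
    )
    log.info(
        "read %d spectra x %d points from %s (labels: %s)",
        dataset.n_spectra, dataset.n_points, path, list(labels.columns),
    )
    return dataset


def make_fixtures(scale: str = "small", seed: int = 0) -> SpectrumSet:
    """Seeded synthetic datasets for tests and examples.

    ``small``: 6 combinations x 4 replicates on a 200-point grid (fast);
    ``paper``: the full 41 x 36 design on the 1321-point grid.
    """
    library = sim.default_library()
    if scale == "small":
        grid = WavenumberGrid(457.0, 1674.0, 200)
        full = sim.default_design()
        design = sim.MixtureDesign(
            combinations=full.combinations.head(6).copy(),
            replicates_per_combo=4,
        )
    elif scale == "paper":
        grid = WavenumberGrid()
        design = sim.default_design()
    else:
        raise ValueError(f"unknown fixture scale {scale!r}")
    noise = sim.NoiseModel(seed=seed)
    return sim.generate_dataset(library, design, noise, grid)


# ----------------------------------------------------------------------
# pipeline configuration
# ----------------------------------------------------------------------
@dataclass
class PipelineConfig:
    """Resolved configuration of one end-to-end run; round-trips through
    YAML losslessly and is written next to every run's outputs."""

    grid_start: float = 457.0
    grid_end: float = 1674.0
    grid_points: int = 1321
    design_file: str | None = None
    replicates_per_combo: int = 36
    noise: dict = field(default_factory=lambda: asdict(sim.NoiseModel()))
    quantifier: dict = field(
        default_factory=lambda: quant_mod.QuantifierConfig().to_dict()
    )
    cv_repeats: int = 10
    train_fraction: float = 0.75
    chrono_profile: list = field(
        default_factory=lambda: [[40.0, 8.0], [10.0, 8.0], [20.0, 8.0]]
    )
    chrono_flow_rate: float = chrono_mod.DEFAULT_FLOW_RATE_UL_MIN
    chrono_chamber_volume: float = chrono_mod.DEFAULT_CHAMBER_VOLUME_UL
    chrono_replicates: int = 6
    explain_samples: int = 50
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        return cls(**data)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Simulate -> preprocess -> cross-validate -> evaluate -> explain ->
    chrono-profile, persisting every stage's outputs under ``outdir``.

    Returns a dict of in-memory artifacts (dataset, cv metrics, report,
    importance profiles, chrono profile). Fully reproducible from the
    config: the global seed feeds the simulator, the cross-validation
    splits and the explainer.
    """
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.save(outdir / "config.yaml")
    (outdir / "VERSION").write_text(__version__ + "\n")
    grid = WavenumberGrid(config.grid_start, config.grid_end, config.grid_points)
    library = sim.default_library()

    # --- stage 1: data ---
    log.info("stage simulate: building dataset")
    if config.design_file:
        design = sim.MixtureDesign.load(config.design_file)
    else:
        design = sim.default_design(config.replicates_per_combo)
        design = sim.MixtureDesign(
            combinations=design.combinations,
            replicates_per_combo=config.replicates_per_combo,
        )
    noise = sim.NoiseModel(**{**config.noise, "seed": config.seed})
    dataset = sim.generate_dataset(library, design, noise, grid)
    write_spectra_table(dataset, outdir / "dataset.csv")

    # --- stage 2: preprocess ---
    log.info("stage preprocess: min-max normalization")
    normed = preprocess.normalize_set(dataset)

    # --- stage 3: cross-validation ---
    qcfg = quant_mod.QuantifierConfig.from_dict(
        {**config.quantifier, "input_dim": grid.n_points}
    )
    log.info("stage crossval: %d repeats", config.cv_repeats)
    cv = quant_mod.cross_validate(
        normed, qcfg,
        n_repeats=config.cv_repeats,
        train_fraction=config.train_fraction,
        seed=config.seed,
    )
    cv.to_csv(outdir / "cv_metrics.csv", index=False)

    # --- stage 4: final model + evaluation ---
    log.info("stage train: final model")
    rng = np.random.default_rng(config.seed)
    perm = rng.permutation(normed.n_spectra)
    n_train = int(normed.n_spectra * config.train_fraction)
    train_set = normed.subset(perm[:n_train])
    val_set = normed.subset(perm[n_train:])
    model = quant_mod.train(quant_mod.build(qcfg), train_set, val_set)
    model.save(outdir / "model")
    preds = quant_mod.predict(model, val_set)
    report = evaluate_mod.report(
        cv,
        predictions={m: preds[m].to_numpy() for m in qcfg.metabolites},
        truths={m: val_set.concentrations(m) for m in qcfg.metabolites},
    )
    (outdir / "report.json").write_text(
        json.dumps(report.to_json_dict(), indent=2)
    )

    # --- stage 5: explain ---
    log.info("stage explain: SHAP importance profiles")
    n_expl = min(config.explain_samples, val_set.n_spectra)
    samples = val_set.subset(np.arange(n_expl))
    profiles = {}
    for target in ("latent0", "latent1"):
        prof = explain_mod.shap_importance(
            model, samples, train_set, target=target, seed=config.seed
        )
        prof.to_frame().to_csv(outdir / f"importance_{target}.csv", index=False)
        profiles[target] = prof

    # --- stage 6: chrono profile ---
    log.info("stage profile: chrono-sampled step injection")
    records = sim.simulate_chrono_injection(
        [tuple(seg) for seg in config.chrono_profile],
        flow_rate=config.chrono_flow_rate,
        chamber_volume=config.chrono_chamber_volume,
    )
    chamber_preds: dict[int, dict[str, np.ndarray]] = {}
    for rec in records:
        combo = pd.DataFrame(
            [{
                "combo_id": rec.index,
                "uric_acid": rec.concentration,
                "lactate": 5.0,
                "tyrosine": 100.0,
                "background": 1.0,
            }]
        )
        cdesign = sim.MixtureDesign(combo, config.chrono_replicates)
        cnoise = sim.NoiseModel(
            **{**config.noise, "seed": config.seed + 1000 + rec.index}
        )
        cset = preprocess.normalize_set(
            sim.generate_dataset(library, cdesign, cnoise, grid)
        )
        cpred = quant_mod.predict(model, cset)
        chamber_preds[rec.index] = {
            m: cpred[m].to_numpy() for m in qcfg.metabolites
        }
    profile = chrono_mod.assemble_profile(records, chamber_preds)
    profile.to_csv(outdir / "chrono_profile.csv", index=False)
    rate = chrono_mod.estimate_sweat_rate(records)
    rate.to_csv(outdir / "sweat_rate.csv", index=False)

    log.info("run complete: artifacts in %s", outdir)
    return {
        "dataset": dataset,
        "cv_metrics": cv,
        "report": report,
        "model": model,
        "importance": profiles,
        "chrono_profile": profile,
        "sweat_rate": rate,
    }
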