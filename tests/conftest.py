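import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import sweatsers as sw
from sweatsers import quantifier as quant

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: Desk-scale grid: same spectral range, 200 points.
GRID200 = sw.WavenumberGrid(457.0, 1674.0, 200)

#: Scaled-down training schedule used for desk-scale runs: the reference
#: schedule's shape (initial phase, late phase with 10x smaller rate and
#: decay, early stopping) at a tenth of the epochs budget.
FAST_SCHEDULE = dict(
    max_epochs=60,
    schedule_epoch=40,
    lr_initial=1e-3,
    lr_late=1e-4,
    early_stop_patience=10,
)


@pytest.fixture(scope="session")
def library():
    return sw.default_library()


@pytest.fixture(scope="session")
def desk_design():
    """Full 41-combination design with 12 replicates (desk scale)."""
    full = sw.default_design()
    return sw.MixtureDesign(full.combinations, replicates_per_combo=12)


@pytest.fixture(scope="session")
def desk_dataset(library, desk_design):
    """41 x 12 spectra on the 200-point grid, default measurement noise."""
    return sw.generate_dataset(
        library, desk_design, sw.NoiseModel(seed=11), GRID200
    )


def zero_noise_model(seed=11):
    return sw.NoiseModel(0.0, 0, 0.0, 0.0, seed=seed)


@pytest.fixture(scope="session")
def clean_dataset(library, desk_design):
    """Same design, zero measurement noise."""
    return sw.generate_dataset(library, desk_design, zero_noise_model(), GRID200)


def single_analyte_dataset(library, analyte, replicates=12, seed=3,
                           noise=None, grid=GRID200):
    """Dataset in which only one analyte varies (over its level set), on
    top of the fixed background."""
    rows = [
        {"combo_id": i, analyte: c, "background": 1.0}
        for i, c in enumerate(sw.spectral_sim.LEVEL_SETS[analyte], start=1)
    ]
    design = sw.MixtureDesign(pd.DataFrame(rows), replicates)
    if noise is None:
        noise = sw.NoiseModel(seed=seed)
    return sw.generate_dataset(library, design, noise, grid)


def train_single_analyte(library, analyte, seed=3, noise=None):
    """Train a per-metabolite quantifier on a single-analyte dataset;
    returns (model, train subset, heldout subset)."""
    ds = sw.normalize_set(
        single_analyte_dataset(library, analyte, seed=seed, noise=noise)
    )
    rng = np.random.default_rng(0)
    perm = rng.permutation(ds.n_spectra)
    n_train = int(ds.n_spectra * 0.75)
    cfg = quant.QuantifierConfig(
        input_dim=ds.n_points, seed=0, metabolites=(analyte,), **FAST_SCHEDULE
    )
    train_set = ds.subset(perm[:n_train])
    heldout = ds.subset(perm[n_train:])
    model = quant.train(quant.build(cfg), train_set, heldout)
    return model, train_set, heldout


@pytest.fixture(scope="session")
def uric_acid_model(library):
    return train_single_analyte(library, "uric_acid")
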