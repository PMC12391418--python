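"""Generate a synthetic labeled SERS mixture dataset.

Builds the default 41-combination mixture design over the physiological
level sets of uric acid, lactate and tyrosine, renders each combination
as a Lorentzian-band mixture spectrum on the 457-1674 cm^-1 grid, and
applies the calibrated measurement-noise model (per-spectrum gain,
baseline drift, white noise).
"""

import sweatsers as sw

design = sw.default_design()  # 41 combinations x 36 replicates
dataset = sw.generate_dataset(
    sw.default_library(), design, sw.NoiseModel(seed=1), sw.WavenumberGrid()
)

print(f"combinations:        {design.n_combinations}")
print(f"replicates/combo:    {design.replicates_per_combo}")
print(f"spectra generated:   {dataset.n_spectra} x {dataset.n_points} points")
print(f"label columns:       {list(dataset.labels.columns)}")
levels = sorted(float(v) for v in dataset.labels["uric_acid_uM"].unique())
print(f"uric acid levels:    {levels}")
# 41 x 36 = 1476 spectra of length 1321: the geometry of the training
# corpus the quantification model is dimensioned for.
sw.write_spectra_table(dataset, "dataset.csv")
print("wrote dataset.csv (one spectrum per row, wavenumber columns + labels)")
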