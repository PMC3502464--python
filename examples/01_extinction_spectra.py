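"""Inspect the embedded hemoglobin extinction table.

Loads the packaged oxy/deoxyhemoglobin molar extinction compilation, resamples
it onto the default 76-band acquisition grid, and prints the wavelengths that
drive oximetry: the isosbestic point (where the two curves cross and OD is
blind to saturation) and the red band where deoxy-Hb dominates.
"""

from oximap import isosbestic_wavelength, load_reference_table, make_band_grid, resample

table = load_reference_table()
print(f"table span: {table.span[0]:.0f}-{table.span[1]:.0f} nm, {len(table.wavelengths)} rows")

bands = make_band_grid(450, 700, 76)
on_grid = resample(table, bands)
print(f"resampled to {len(on_grid.wavelengths)} acquisition bands")

iso = isosbestic_wavelength(table)
at_iso = resample(table, [iso])
at_660 = resample(table, [660.0])
print(f"isosbestic point: {iso:.0f} nm "
      f"(eps_oxy = eps_deoxy = {at_iso.eps_oxy[0]:.0f} cm^-1 M^-1)")
print(f"at 660 nm: eps_oxy = {at_660.eps_oxy[0]:.0f}, eps_deoxy = {at_660.eps_deoxy[0]:.0f}"
      " -> deoxygenated blood is far more absorbing in the red,"
      " which is why venous blood looks dark")
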