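"""Render a super-resolution image and its wide-field reference.

Each localization becomes a unit-mass Gaussian whose width adapts to the
local Nyquist resolution; the wide-field reference blurs the same positions
with a 250 nm-FWHM kernel for a side-by-side resolution comparison.
"""

import numpy as np

import smlmclem as sm

emitters = sm.generate_structure(
    "membrane_pair",
    {"spacing": 300.0, "length": 3000.0, "density_per_um": 3000.0},
    field_of_view=(4000.0, 4000.0),
    seed=7,
)
rng = np.random.default_rng(8)
observed = emitters.positions + rng.normal(0, 15.0, emitters.positions.shape)
records = [sm.Localization(i, x, y, 500.0, 5.0, 130.0)
           for i, (x, y) in enumerate(observed)]
table = sm.LocalizationTable.from_records(records, {"pixel_size_nm": 80.0})

res = sm.compute_density_resolution(table, 15.0,
                                    field_of_view=emitters.field_of_view)
settings = sm.RenderSettings(out_pixel=10.0)
sr, color = sm.render_sr_image(table, res, settings,
                               field_of_view=emitters.field_of_view)
wf = sm.render_widefield_reference(table, 250.0, settings,
                                   field_of_view=emitters.field_of_view)

prof_sr = sm.line_profile(sr, (200, 150), (200, 250), width=15, n_samples=101)
prof_wf = sm.line_profile(wf, (200, 150), (200, 250), width=15, n_samples=101)
print(f"{len(table)} localizations rendered at {settings.out_pixel:.0f} nm/px")
print(f"SR raster mass {sr.sum():.0f} (one unit per localization)")
print(f"profile across the membranes: "
      f"{sm.count_resolved_peaks(prof_sr.intensities)} resolved peaks in SR, "
      f"{sm.count_resolved_peaks(prof_wf.intensities)} in wide-field")
# The 300 nm membrane spacing is resolved in the SR image but appears as a
# single ridge at the 250 nm diffraction-limited resolution.
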