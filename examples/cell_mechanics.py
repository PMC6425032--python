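"""Single-cell mechanics: AFM stiffness, trap calibration, tether force,
FM-dye surface area.

Hertz-model fit of a force-indentation approach curve (spherical 10 um
probe, 0.03 N/m cantilever, fit restricted to indentations below 0.5 um),
equipartition calibration of an optical trap from thermal bead motion,
membrane tether force from a hold-segment displacement, and the relative
surface-area increase reported by an FM-dye trace.
"""

import numpy as np

from phagokit import mechanics as mech
from phagokit import synthgen as sg

cfg = sg.SynthConfig(seed=0)

# --- AFM / Hertz -----------------------------------------------------------
curve, truth = sg.gen_afm_curve(cfg, young_modulus_pa=4500.0, contact_z_m=1e-6,
                                force_noise_sd_n=0.01 * 2e-9)
fit = mech.find_contact_and_fit(curve)
print(f"Hertz fit: E = {fit.young_modulus_pa:.0f} Pa (truth 4500 Pa), "
      f"contact at z0 = {fit.contact_z_m * 1e6:.3f} um (truth 1.000 um), "
      f"{fit.n_points} points below {fit.max_depth_m * 1e6:.1f} um depth")

# --- optical trap ----------------------------------------------------------
trace, trap_truth = sg.gen_trap_trace(cfg, stiffness_n_per_m=1e-3,
                                      temperature_k=295.0, n=100_000)
cal = mech.calibrate_trap(trace, temperature_k=295.0)
print(f"trap calibration: Var(x) = {cal.variance_m2:.3e} m^2 -> "
      f"k = {cal.stiffness_n_per_m * 1e3:.3f} pN/nm "
      f"(programmed 1e-3 N/m = 1 pN/nm)")

tether, tether_truth = sg.gen_tether_trace(cfg, stiffness_n_per_m=1e-3,
                                           tether_force_n=40e-12)
res = mech.tether_force(tether, cal)
print(f"tether force: {res.force_n * 1e12:.2f} pN "
      f"(programmed {tether_truth['tether_force_n'] * 1e12:.0f} pN from a "
      f"{tether_truth['offset_m'] * 1e9:.0f} nm hold offset)")

# --- FM dye ---------------------------------------------------------------
fm, fm_truth = sg.gen_fm_trace(cfg, area_increase_pct=40.0, n=120)
area = mech.fm_area_increase(fm)
print(f"FM-dye surface area: +{area.final_increase_pct:.1f} % at "
      f"{area.t_s[-1] / 60:.0f} min (programmed +{fm_truth['area_increase_pct']:.0f} "
      "% plateau; membrane added by exocytosis during spreading)")
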