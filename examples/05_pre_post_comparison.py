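"""The study question end to end: what does filling the septal defect do?

Both geometries (orifice open vs filled) are driven identically: the
pulmonary-vein side at higher inlet pressure than the vena-cava side, the
outlets free.  With the defect open, oxygen-rich blood jets left-to-right
through the orifice, contaminating the low-oxygen side and dissipating
energy in the jet's shear; filling the defect removes both effects.
"""

from septalflow import FluidParams, compare_pre_post, plane_flux
from septalflow import make_two_chamber_phantom
from septalflow.pipeline import default_port_pressures, simulate_phantom

results, specs = {}, {}
for tag, is_open in (("open", True), ("filled", False)):
    spec = make_two_chamber_phantom(defect_open=is_open, port_radius=5.0)
    res = simulate_phantom(spec.ground_truth_mask, spec.port_labels,
                           FluidParams(omega_f=1.0, omega_g=1.6),
                           default_port_pressures(), max_steps=3000)
    specs[tag], results[tag] = spec, res
    print(f"{tag:6s}: {res.steps} steps, max speed "
          f"{res.diagnostics['max_speed']:.4f} (lattice units)")

x0 = specs["open"].orifice_plane()
for tag in ("open", "filled"):
    fl = plane_flux(results[tag], 0, x0)
    print(f"orifice plane flux ({tag:6s}): mass {fl['mass_flux']:+.4f}, "
          f"oxygen {fl['scalar_flux']:+.4f}")

report = compare_pre_post(results["open"], results["filled"])
print(f"total entropy generation: open {report.total_entropy_open:.3e}, "
      f"filled {report.total_entropy_filled:.3e} "
      f"(ratio {report.total_entropy_open / report.total_entropy_filled:.3f})")
print(f"high-dissipation tail mass (top decade): "
      f"open {report.tail_mass_open[0]:.4f}, "
      f"filled {report.tail_mass_filled[0]:.4f}")
print(f"mean C_b at the pulmonary-artery outlet: "
      f"open {report.outlet_mean_cb_open['pulmonary_artery']:+.3f}, "
      f"filled {report.outlet_mean_cb_filled['pulmonary_artery']:+.3f}")
# Read-out: the filled geometry has exactly zero orifice flux, lower total
# and high-tail entropy generation, and its pulmonary-artery outlet stays
# at C_b = -1 — the open defect shifts it toward 0 by admixed
# oxygen-rich blood.  These are the directions the operation is meant to
# restore.
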