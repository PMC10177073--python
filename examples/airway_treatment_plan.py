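"""Plan fiber powers and times for a synthetic airway tumor.

Builds a synthetic stand-in for a segmented thoracic geometry — an
ellipsoidal tumor beside a bronchus, with a major blood vessel as the
critical structure — solves one steady irradiance field per cylindrical
diffuser fiber, and runs the domination-sub-maps optimizer: each fiber's
power is pushed as high as the 8.6 mW/cm^2 / 9.5 J/cm^2 critical-structure
limits allow, powers snap DOWN to the laser's 20 mW calibration grid, and
treatment times stretch so every fiber still delivers its planned surface
fluence.
"""

import numpy as np

import ipdtplan as ip

# fibers enter from the bronchus (below the tumor, running along x) at a
# 35 and 38 degree insertion angle
c35, s35 = np.cos(np.radians(35)), np.sin(np.radians(35))
c38, s38 = np.cos(np.radians(38)), np.sin(np.radians(38))
fibers = [
    ip.CDFPlacement((-1.30, -1.10, 0.0), (c35, s35, 0.0), 1.5,
                    intensity=100.0, treatment_time=500.0),
    ip.CDFPlacement((-0.90, -1.25, 0.35), (c38, s38, 0.0), 1.2,
                    intensity=100.0, treatment_time=500.0),
]
scene = ip.make_airway_scene(
    tumor_semiaxes=(1.1, 0.9, 0.9),
    vessel_specs=[((-2.0, 1.55, -2.0), (2.0, 1.55, 2.0), 0.4)],
    bronchus_spec=((-2.0, -1.7, 0.0), (2.0, -1.7, 0.0), 0.5),
    margin=0.8,
    target_h=0.45,
    cdfs=fibers,
)
print(f"scene: {scene.n_nodes} nodes, {scene.n_tets} tets; "
      f"tumor {scene.region_volume('tumor'):.1f} cm^3, "
      f"vessel {scene.region_volume('critical_structure'):.1f} cm^3")

for check in ip.check_placement_constraints(fibers[0], scene):
    print(f"  placement: {check.name} = {check.measured:.2f} "
          f"({'pass' if check.passed else 'FAIL'}, limit {check.limit})")

maps = ip.solve_per_cdf_maps(scene, ip.DEFAULT_PROPERTIES)
plan = ip.optimize_plan(maps, ip.SafetyLimits(), initial_time=500.0)

print()
for i, (p, s, t) in enumerate(zip(plan.powers_mw, plan.intensities_mw_per_cm,
                                  plan.times_s)):
    print(f"fiber {i}: {p:.0f} mW ({s:.0f} mW/cm) for {t:.0f} s")
print(f"critical-structure maxima: "
      f"{plan.safety['cs_max_irradiance_mW_cm2']:.2f} mW/cm^2 (limit 8.6), "
      f"{plan.safety['cs_max_fluence_J_cm2']:.2f} J/cm^2 (limit 9.5)")
print(f"tumor DRVH (>=8.6 mW/cm^2): {plan.dose.drvh_at_8p6:.1f}% | "
      f"effective rate-based dose DVH (>=8.6 and >=45 J/cm^2): "
      f"{plan.dose.effective_dose_dvh:.1f}%")
print("The DRVH is the tumor fraction reaching the therapeutic dose rate;")
print("the effective-dose DVH additionally requires the 45 J/cm^2 fluence.")
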