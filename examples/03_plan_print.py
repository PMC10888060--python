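"""Plan a deposition: the printing speed needed for a target strand radius.

At 100 kPa the free extrudate swells to ~1.77x the nozzle radius.  To deposit
a strand back at the nozzle radius the print head must outrun the extrudate
(speed ratio = swell ratio squared), stretching the strand as it lands.
"""

import extruflow as xf

rheology = xf.PowerLawRheology(222.0, 0.23)
swell_law = xf.SwellLaw(1.57, 1.38e-10, 3.15)
nozzle = xf.NozzleGeometry.gauge_22()
pressure = 100e3  # Pa

vex = xf.predict_extrusion_speed(rheology, swell_law, nozzle, pressure)
print(f"extrusion speed at 100 kPa : {vex * 1e3:.2f} mm/s")

for ratio in (1.5, 1.0, 0.75, 0.5):
    plan = xf.plan_print(rheology, swell_law, nozzle, pressure,
                         ratio * nozzle.inner_radius)
    print(f"target Rp/R = {ratio:4.2f} -> vp = {plan.printing_speed * 1e3:6.2f} mm/s  "
          f"POI = {plan.poi:6.2f} 1/(Pa m)  [{plan.regime_flag.value}]")

print("\nFiner strands need quadratically faster printing (vp = Q / pi Rp^2);")
print("POI = 1/(2 Rp tau_w) rises with finer strands but falls with pressure.")
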