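"""Planning chart: extrusion and printing speeds over the pressure range.

Tabulates the extrusion speed v_ex(dP) and, for a family of target radius
ratios Rp/R, the required printing speed — the chart an operator reads to
choose pressure and feed rate together.  Exports CSV alongside.
"""

import extruflow as xf

rheology = xf.PowerLawRheology(222.0, 0.23)
swell_law = xf.SwellLaw(1.57, 1.38e-10, 3.15)
nozzle = xf.NozzleGeometry.gauge_22()

chart = xf.speed_map(
    rheology, swell_law, nozzle,
    pressure_grid=[p * 1e3 for p in range(70, 131, 10)],
    radius_ratios=[0.5, 0.75, 1.0, 1.5],
)
df = chart.to_dataframe()
print(df.to_string(index=False, float_format=lambda v: f"{v:8.3f}"))
chart.to_csv("speed_map.csv")
print("\nwrote speed_map.csv; columns vp_mm_s_ratio_<r> give the printing speed")
print("needed to deposit a strand of radius r x nozzle radius at each pressure.")
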