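"""From PPFD to daily light integral, incident light, and harvest traits.

Shows the light budget for one mizuna unit: DLI from PPFD and photoperiod,
daily incident light from the fitted canopy trajectory, and the three
harvest traits (LUE, SLA, canopy overlap ratio).
"""

from canolux import (
    LightTreatment,
    SigmoidFit,
    compute_dli,
    compute_lue,
    compute_overlap_ratio,
    compute_sla,
    integrate_incident_light,
    predict_daily,
)
from canolux.light import MEASURED_PPFDS

print("PPFD (umol m-2 s-1) -> DLI (mol m-2 d-1) at a 16-h photoperiod:")
for p in MEASURED_PPFDS:
    print(f"  {p:5.0f} -> {compute_dli(p, 16.0):6.2f}")

# one mizuna unit at PPFD 210: fitted sigmoid evaluated daily, then summed
treatment = LightTreatment(ppfd=210.0, photoperiod_h=16.0)
fit = SigmoidFit(a=340.0, x0=18.0, b=3.0, r_squared=0.999,
                 residual_sd=2.0, converged=True, n_points=8)
series = predict_daily(fit, harvest_day=27)
incident = integrate_incident_light(series, treatment)
print(f"\ntotal incident light over 28 days: "
      f"{incident.total_incident:.3f} mol/plant")

dry_weight, leaf_area = 5.0, 800.0
pcs_harvest = float(series.pcs[-1])
print(f"dry weight {dry_weight} g, leaf area {leaf_area} cm2, "
      f"PCS at harvest {pcs_harvest:.0f} cm2 give:")
print(f"  LUE            = {compute_lue(dry_weight, incident.total_incident):.2f} g/mol")
print(f"  SLA            = {compute_sla(leaf_area, dry_weight):.0f} cm2/g")
print(f"  overlap ratio  = {compute_overlap_ratio(leaf_area, pcs_harvest):.2f}")
print("LUE is biomass per mol of light intercepted by the canopy footprint;")
print("the overlap ratio >1 quantifies leaves stacked above the footprint.")
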