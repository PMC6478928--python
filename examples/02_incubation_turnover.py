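"""Turnover time and DOC from a 181-day laboratory incubation.

CO₂ trapped in NaOH between trap changes and DOC recovered at leach days
are normalised to the soil's initial organic carbon; τᵢ is the stock
divided by the annualised output flux.
"""

import numpy as np

from socturn.incubation import (
    LEACH_DAYS,
    TRAP_DAYS,
    IncubationSeries,
    TrapSpec,
    cumulative_doc,
    flag_saturation,
    tau_incubation,
)

# a soil respiring ~5%/181 d of its OC, first-order shape, DOC ~1% of losses
k = 1.0 / 10.0  # true lab decomposition rate, yr⁻¹
t = np.concatenate([[0.0], np.asarray(TRAP_DAYS, float)]) / 365.25
stock_g = 50.0 * 40.0 / 1000.0  # 50 g OC/kg soil × 40 g dry soil
co2 = stock_g * np.diff(-np.exp(-k * t))
doc = np.full(len(LEACH_DAYS), 0.01 * co2.sum() / len(LEACH_DAYS))

series = IncubationSeries(
    site_id="demo", co2c_per_interval=tuple(co2), doc_per_leach=tuple(doc),
    toc_initial=50.0, dry_mass=40.0,
)
trap = TrapSpec()  # 20 ml 1 M NaOH: capacity 0.1201 g C
print(f"trap capacity {trap.capacity_gc * 1000:.1f} mg C; "
      f"saturated: {flag_saturation(series, trap)}")
res = tau_incubation(series, trap)
print(f"annual flux {res.annual_flux:.1f} g C kg⁻¹ OC yr⁻¹  →  "
      f"τᵢ = {res.tau_i:.1f} yr; {100 * res.cum_loss_frac:.1f}% of OC lost in 181 d")
print(f"cumulative DOC {cumulative_doc(series):.2f} g C kg⁻¹ OC "
      f"(~{100 * cumulative_doc(series) / (1000 * res.cum_loss_frac):.0f}% of losses)")
# τᵢ ≈ 10.3 yr: the ~2.5% high bias is the linear annualisation of an
# exponentially declining flux.
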