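"""Non-Condon rate enhancement for the named reduced-unit model cases.

Computes the full momentum-coupling rate and its Condon reference (NDC
kernel frozen at t = 0) for case I-A over a range of energy gaps, in the
reduced units where k_B = ħ = ω_c = 1 and θ = 1.
"""

import numpy as np

from ndcrate import RateInput, gap_scan, rate, table2_case
from ndcrate.correlations import TimeGrid, corr_closed_form

nc = table2_case("I-A")
corr = corr_closed_form(nc.params, nc.thermo, TimeGrid(40.0, 0.004))

print("case I-A (omega_h = 5 omega_c, NDC carried entirely by the vibration)")
print(" gap    k (full)    k (Condon)   ratio")
for gap in (5.0, 10.0, 15.0, 20.0, 25.0, 30.0):
    r = rate(RateInput(gap, corr))
    print(f"{gap:4.0f} {r.k:12.4e} {r.k_condon:12.4e} {r.k / r.k_condon:7.2f}")
print("The growing ratio is the non-Condon momentum effect: D(t) oscillates "
      "at omega_h, letting the vibration absorb an extra quantum, which "
      "matters more the deeper the rate sits in the energy-gap-law tail.")

gaps = np.linspace(20.0, 25.0, 26)[:-1]
means = {}
for cid in ("I-A", "I-B", "I-C"):
    c = table2_case(cid)
    means[cid] = gap_scan(
        corr_closed_form(c.params, c.thermo, TimeGrid(40.0, 0.004)), gaps
    )["k"].mean()
print("\nperiod-averaged rates over gap in [20, 25):")
for cid, v in means.items():
    print(f"  {cid}: {v:.3f}")
print("Ordering I-A > I-B > I-C: NDC weight on the high-frequency vibration "
      "(A) beats Ohmic-dominated NDC (B, C), and a positive cross sign (B) "
      "beats the negative one (C).")
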