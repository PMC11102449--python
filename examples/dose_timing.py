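"""Dose and timing variants of the triple therapy.

Modifies the best-performing protocol (siRNA + Px-478 + DC): shifting the
DC injection day, re-spacing the siRNA schedule, and alternating the two
drugs daily.  Expected directions (clearest at larger replicate counts):
denser siRNA dosing and starting the alternation with siRNA give
equal-or-smaller tumors; DC-timing differences are small because every
variant clears the tumor.
"""

import tmesim as tm
from tmesim import variant_protocol

params = tm.make_default_parameters()
base = tm.group_protocol("siRNA+Px-478+DC")
seeds = range(4)

variants = {
    "DC on day 6": {"dc_day": 6},
    "DC on day 7 (base)": {"dc_day": 7},
    "DC on day 8": {"dc_day": 8},
    "siRNA every day": {"s_every": 1},
    "siRNA every 3 days": {"s_every": 3},
    "alternate, siRNA first": {"alternate_start": "siRNA"},
    "alternate, Px-478 first": {"alternate_start": "Px-478"},
}

print(f"{'variant':<26} {'avg volume mm^3':>16} {'day-18 volume':>14}")
for label, mod in variants.items():
    s = tm.run_replicates(params, variant_protocol(base, mod), seeds,
                          horizon_days=18)
    print(f"{label:<26} {s.mean_tumor_volume:>16.2f} "
          f"{s.final_tumor_volume:>14.2f}")

print("\nThe average-volume column integrates the whole course, so it")
print("rewards early control even when every variant ends at zero.")
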