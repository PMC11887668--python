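"""In-vivo and plate-assay summaries: tumor growth, fly survival, fluorescence.

Caliper tumor volume uses [(length + width)/2] x length x width; growth is
summarised per arm and day as percent of the vehicle arm.  Fly survival is
the percent of flies alive at each time point.  Autophagy/caspase plate
readouts are normalized to Hoechst (cell density) and then to the control
wells.
"""

import numpy as np
import pandas as pd

from slscreen import growth_curve, normalize_assay, survival_percent, tumor_volume

# --- xenograft growth ------------------------------------------------------
print(f"tumor volume, 12 x 8 mm caliper read: {tumor_volume(12, 8):.0f} mm^3")

rng = np.random.default_rng(0)
rows = []
for arm, rate in (("vehicle", 0.25), ("CQ", 0.12)):
    for day in (0, 3, 6, 9):
        for animal in range(6):
            ell = (150 * np.exp(rate * day)) ** (1 / 3) * rng.normal(1, 0.03)
            rows.append({"arm": arm, "animal_id": f"{arm}{animal}", "day": day,
                         "length": ell, "width": ell})
curve = growth_curve(pd.DataFrame(rows), vehicle_arm="vehicle")
treated = curve[curve["arm"] == "CQ"]
for _, r in treated.iterrows():
    print(f"  day {int(r['day'])}: CQ arm {r['mean_volume']:.0f} mm^3 "
          f"= {r['percent_of_control']:.0f}% of vehicle")

# --- fly survival ----------------------------------------------------------
alive = [20, 19, 16, 9, 2]
pct = survival_percent(alive, 20)
print("fly survival (%):", ", ".join(f"{p:.0f}" for p in pct))

# --- autophagy assay -------------------------------------------------------
readings = pd.DataFrame(
    {
        "well": ["A1", "A2", "B1", "B2"],
        "signal": [210.0, 190.0, 520.0, 480.0],
        "hoechst": [100.0, 95.0, 110.0, 105.0],
        "group": ["control", "control", "test", "test"],
    }
)
out = normalize_assay(readings)
test_fold = out.loc[out["group"] == "test", "fold_over_control"]
print(f"autophagy signal, fold over control: {test_fold.mean():.2f}")
# A fold over control well above 1 indicates autophagosome accumulation in
# the test (NF1-deficient) cells relative to controls at matched density.
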