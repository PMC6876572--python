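"""Occupancy-gated model: end occupancy vs depolymerization rate, and
subunits removed per binding event.

Combines the single-molecule rate constants (02) with the saturation
fit (03): the fractional end occupancy cK_A/(1 + cK_A) parallels the
fractional velocity c/(c + K_M), and the ratio of the catalytic
efficiency k_cat/K_M to k_on gives the mean number of subunits removed
per hexamer binding event.

Writes results/occupancy_velocity.tsv and results/derived.json.
"""

import json
from pathlib import Path

from capdep import (
    KineticParams,
    MMFitResult,
    catalytic_efficiency,
    occupancy_velocity_table,
    subunits_per_event,
)

OUT = Path(__file__).resolve().parent.parent / "results"

rates = json.loads((OUT / "rate_constants.json").read_text())
mm = json.loads((OUT / "mm_fit.json").read_text())

fit = MMFitResult(
    K_M=mm["K_M_nM"] * 1e-9,
    k_cat=mm["k_cat_subunits_per_s"],
    se_K_M=mm["se_K_M_nM"] * 1e-9,
    se_k_cat=mm["se_k_cat_subunits_per_s"],
)
params = KineticParams(
    k_on=rates["k_on_per_M_per_s"], k_off=rates["k_off_per_s"], c=83e-9
)

table = occupancy_velocity_table(params, fit, [8.3e-9, 83e-9])
table.to_csv(OUT / "occupancy_velocity.tsv", sep="\t", index=False)
print("occupancy vs fractional velocity:")
for row in table.itertuples(index=False):
    print(
        f"  {row.concentration_M * 1e9:5.1f} nM:  occupancy {row.occupancy_fraction:.0%}"
        f"   velocity {row.velocity_fraction:.0%}"
    )

eff = catalytic_efficiency(fit)
spe = subunits_per_event(
    eff.value, params.k_on, eff.se, rates["se_k_on_per_M_per_s"]
)
print(f"k_cat/K_M = {eff.value:.3g} +/- {eff.se:.2g} subunits/s/M")
print(f"subunits removed per binding event = {spe.value:.0f} +/- {spe.se:.0f}")
print(f"  ({spe.value * 2.7:.0f} nm of filament per ~40 nm hexamer)")

(OUT / "derived.json").write_text(
    json.dumps(
        {
            "catalytic_efficiency_per_M_per_s": eff.value,
            "se_catalytic_efficiency_per_M_per_s": eff.se,
            "subunits_per_event": spe.value,
            "se_subunits_per_event": spe.se,
            "filament_nm_per_event": spe.value * 2.7,
        },
        indent=2,
    )
    + "\n"
)
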