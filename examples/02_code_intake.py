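"""Turn item-level intake records into eating occasions and serving vectors.

Items consumed simultaneously (same reported start time, or within a merge
window) form one eating occasion if they jointly contribute at least 210 kJ.
Discretionary servings are energy / 600 kJ; core-group servings sum the
items' pre-resolved serving equivalences.  Modelled outcomes are
ln(servings + 1).
"""

from eodiet.intake_coding import FoodItem, eos_to_frame, group_items_into_eos

items = [
    # breakfast at 07:30 — cereal (grains) with milk (dairy)
    FoodItem("P001", 1, 450.0, 650.0, group="grains", servings_per_unit=1.5),
    FoodItem("P001", 1, 450.0, 350.0, group="dairy_alt", servings_per_unit=0.8),
    # a 09:00 coffee below the 210 kJ threshold: never becomes an EO
    FoodItem("P001", 1, 540.0, 120.0, group="dairy_alt", servings_per_unit=0.2),
    # afternoon snack — 900 kJ of discretionary food = 1.5 servings
    FoodItem("P001", 1, 930.0, 900.0, discretionary=True),
]

eos = group_items_into_eos(items, simultaneity_window=0.0)
print(f"{len(items)} items -> {len(eos)} eating occasions "
      "(the 120 kJ coffee is below the 210 kJ rule)\n")
print(eos_to_frame(eos).to_string(index=False))
print("\nlog_servings_* columns are the ln(x+1) outcomes the models are fit on.")
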