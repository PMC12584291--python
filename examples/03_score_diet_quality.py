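"""Score daily diet quality with the 12-component Dietary Guideline Index.

Each component maps a daily intake quantity to 0-10 points, proportionally
between a zero-score cut-off and a full-score target; totals range 0-120.
A fully adherent day scores exactly 120.
"""

from eodiet.diet_quality import (
    daily_totals_from_servings,
    default_dgi_components,
    full_score_day,
    score_day,
)
from eodiet.synthetic_cohort import default_truth, generate_cohort, generate_occasions

perfect = score_day(full_score_day())
print(f"fully adherent synthetic day: total DGI = {perfect.total:.0f} / 120\n")

cohort = generate_cohort(5, seed=3)
occ = generate_occasions(cohort, default_truth(), seed=4)
print("daily DGI for simulated participant-days (typical diets score far below 120):")
for (pid, day), rows in list(occ.groupby(["participant_id", "day_index"]))[:5]:
    s = score_day(daily_totals_from_servings(rows), participant_id=pid, day_index=day)
    comps = " ".join(f"{c:4.1f}" for c in s.component_scores)
    print(f"  {pid} day {day}: total {s.total:6.1f}   components [{comps}]")

print("\ncomponents:", "; ".join(c.description for c in default_dgi_components()[:4]), "...")
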