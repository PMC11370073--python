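"""Study-design arithmetic: effect sizes, composites, play deficits.

The small closed-form computations used around the pipeline: the
standardized effect size of a 5-minute change in daily activity, the
composite conventions (energetic play = walk + run + moderate-vigorous
games; total PA = LPA + energetic play), and the energetic-play deficit
relative to the 60 min/day recommendation.
"""

from actitraj import models
from actitraj.guidelines import energetic_play_deficit

es = models.cohens_d(5.0, 42.0)
print(f"effect size of a 5 min/day change (SD 42 min/day): "
      f"d = {es.value:.4f} -> {es.rounded:.2f}")

boys2 = models.sum_composites(lpa=320.7, walk=15.2, run=2.0, mv_act_g=17.4)
print(f"\nboys age 2: energetic play = 15.2 + 2.0 + 17.4 = "
      f"{boys2['energetic_play']:.1f} min/day")
print(f"boys age 2: total PA = 320.7 + {boys2['energetic_play']:.1f} = "
      f"{boys2['total_pa']:.1f} min/day")

deficit = energetic_play_deficit(35.2)
print(f"\na child averaging 35.2 min/day of energetic play needs "
      f"{deficit:.1f} more min/day to reach the 60-min recommendation")
print("\nd = delta/SD standardizes a mean difference; deficits are clamped"
      "\nat zero for children already meeting the recommendation.")
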