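"""Sweep the reward-value difference and trace the preference per profile.

One side keeps value 1, the other takes 1 + dV for dV in {-1, 0, 1, 2, 3};
'pref' is the fraction of choices on the varying-value side.  Trackers
follow the value difference; Explorers barely react; Non-Switchers entrench
on one side when the stakes rise.
"""

from tmaze import default_profile_priors, delta_v_sweep
from tmaze.random_utils import child_rng

priors = {p.profile: p for p in default_profile_priors()}
triplets = {
    name: [priors[name].draw_triplet(child_rng(4, i, j)) for j in range(10)]
    for i, name in enumerate(priors)
}

sweep = delta_v_sweep(triplets, n_replicates=100, seed=4)
table = sweep.table
for desc in ("pref", "side_bias"):
    print(f"\nmean {desc} by value difference:")
    print(
        table[table.descriptor == desc]
        .pivot(index="group", columns="dv", values="mean")
        .round(3)
    )
print(
    "\nAt dV=0 every profile is indifferent (pref 0.5); the Tracker row "
    "rises steeply with dV while the Explorer row stays flat, and the "
    "Non-Switcher side bias grows once one side clearly pays more."
)
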