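"""Predict behavior across a reward-context change.

Animals fitted in a water (1) vs sucrose (3) context are simulated through
a continuous 12-session run whose second half swaps to saccharin (1) vs
nicotine+saccharin (0.3).  'pref' is measured toward the varying-value side
(sucrose, then nicotine), so a value below 0.5 in the second block means
nicotine avoidance.
"""

from tmaze import cross_context_prediction, default_profile_priors
from tmaze.random_utils import child_rng

priors = {p.profile: p for p in default_profile_priors()}
triplets, labels = [], []
for i, (name, prior) in enumerate(priors.items()):
    for j in range(10):
        triplets.append(prior.draw_triplet(child_rng(5, i, j)))
        labels.append(name)

cc = cross_context_prediction(triplets, labels=labels, seed=5)
pv = cc.pivot_table(index="label", columns="block", values="pref")[["WS", "SaN"]]
print("mean preference for the varying-value side, per block:")
print(pv.round(3))
print(
    "\nTrackers reverse (they tracked sucrose, now avoid nicotine); "
    "Explorers hardly move — the same latent parameters predict both "
    "contexts without refitting."
)
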