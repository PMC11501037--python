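# tmaze

Decision profiling of mice foraging in a T-maze, as a reusable Python
library.

Mice living in an automated group cage earn all their fluid by entering a
T-maze whose two arms deliver solutions of different value (e.g. water vs
5% sucrose), with the side of the higher-value solution swapped twice a
week.  Individuals differ strikingly in how they handle this trade-off, and
the analysis implemented here turns each animal's raw choice sequence into
an interpretable behavioral profile:

1. **Choice descriptors** — five per-animal statistics: global switching
   (*Switch*), the probability of changing side after a low- or high-value
   outcome (*SwWat*, *SwSuc*), the per-session preference for the
   higher-value side (*Pref*) and the session-averaged side bias
   (*SideBias*).
2. **Archetypal analysis** — the descriptor matrix X (n animals x 5) is
   decomposed as X ≈ A Z with simplex rows A (each animal a convex
   combination of k = 3 archetypes) and archetypes Z constrained to the
   convex hull of the data.  The archetypes are named **Tracker** (follows
   the high-value side), **Explorer** (near-random sampling) and
   **Non-Switcher** (sticks to one side).
3. **Reinforcement-learning model** — per animal, a delta-rule learner
   V ← V + α(R − V) with softmax choice
   P_R = 1/(1 + exp(−[β(V_R − V_L) + χ(C_R − C_L)])),
   fitted by bounded maximum likelihood (α ∈ (0,1], β ∈ (0,20],
   χ ∈ [−2,2]) and compared against the nested χ = 0 model by BIC and a
   likelihood-ratio test.
4. **Generative simulation** — fitted (α, β, χ) triplets replayed through
   new reward contexts: value-difference sweeps, parameter-attribution
   shuffles, and the prediction of saccharin-vs-nicotine behavior from
   water-vs-sucrose fits.
5. **Home-cage RFID metrics** — residency episodes, occupancy, activity
   (NbD), occupancy entropy (EnA), first- and second-order transition
   probabilities, and their correlation with archetypal composition.
6. **Synthetic cohorts** — a generator that emulates the study design
   (three latent profiles, alternating 50-choice sessions, deterministic
   rewards 1/3/0.3, profile-correlated RFID streams) with a ground-truth
   manifest, so the entire pipeline runs and validates without animal data.

The package is aimed at behavioral neuroscientists modelling individual
choice strategies, and at anyone needing a tested reference implementation
of archetypal analysis or softmax-with-perseveration model fitting on
choice sequences.

## Worked example

Fit the decision model to a simulated animal with known parameters
(`examples/03_fit_decision_model.py`):

```python
from tmaze import (FitConfig, LatentTriplet, compare_models, fit_mouse,
                   fit_reduced, simulate_mouse, standard_schedule)

true = LatentTriplet(alpha=0.3, beta=0.8, chi=0.8)
record = simulate_mouse(true, standard_schedule(), seed=3)
full = fit_mouse(record, FitConfig(seed=3))
reduced = fit_reduced(record, FitConfig(seed=3))
comparison = compare_models(full, reduced)
```

prints

```
true:   alpha=0.3, beta=0.8, chi=0.8
fitted: alpha=0.225, beta=1.058, chi=0.794 (nll=100.5 over 300 trials)
reduced (chi=0) nll=107.0
delta BIC=7.5, LRT p=0.000286
```

The fitted triplet recovers the generating parameters from 300 choices;
the positive BIC difference and small likelihood-ratio p say the
perseveration term χ is doing real work — this animal repeats its previous
side beyond what the learned values explain.

The other scripts in `examples/` walk through cohort generation,
descriptors + archetypes, the value-difference sweep, the cross-context
(sucrose → nicotine) prediction, and the home-cage metrics, each printing
a short interpretation of its numbers.

A thin CLI mirrors the library stages
(`tmaze simulate-cohort | descriptors | archetypes | fit | sweep |
attribution | predict-san | tracking | report | run-all`); see
`tmaze --help`.

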