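# dmdibl

An instance-based-learning (IBL / ACT-R) model of the Stroop Color and Word
Task for studying working-memory alterations in Duchenne Muscular Dystrophy
(DMD), stratified by the Dp140 dystrophin isoform. The package is written
for computational cognitive modellers and neurogenetics researchers who
want a tested, reusable pipeline around the model: a synthetic-cohort
generator standing in for undeposited human data, exhaustive grid-search
parameter fitting, RAVLT/digit-span index scoring, Dp140 CNV
classification, and a group-comparison statistics report.

## The model

Declarative memory holds *instances* — (color, word) situation slots plus
an outcome — each with a history of retrieval events on a discrete event
clock. Naming a Stroop item is a retrieval governed by the ACT-R
activation equation

    A_i = B_i + Σ_l P_l · M_li + ε_i
    B_i = ln( Σ_{t_i} (t − t_i)^(−d) )          (base level; decay d)
    ε_i = s · ln((1 − u)/u),  u ~ Uniform(0,1)  (logistic noise, scale s)
    RT  = F · e^(−f · A_i)                      (latency law; seconds)

with M_li ∈ [−1, 0] the mismatch between a requested and a stored slot
value and P_l the per-slot penalty. A session runs three 45-second sheets
— word reading, color naming, incongruent color-word naming — on one
memory store; on the color-word sheet the printed word enters the probe as
a second requested slot, so partial matching penalizes every candidate and
interference (the Stroop effect) emerges as slower retrievals and a lower
completion count. The four scalars (F, f, d, s) are fit per group by
enumerating a lattice (the paper-style "hit and trial" search) against
per-sheet word counts; model-vs-human mean-square deviation (MSD) is
reported over sheet means and over subjects.

## Worked example

```python
from dmdibl import FITTED_PARAMS, TaskConfig, simulate_sessions, grid_fit
from dmdibl.fitting import mean_counts
from dmdibl.synthetic_cohort import gen_model_subjects

cfg = TaskConfig()                      # 4 colors, 100 items, 45 s per sheet
for label in ("control", "dmd"):
    sessions = simulate_sessions(FITTED_PARAMS[label], cfg, 20, seed=7)
    print(label, mean_counts(sessions))

# recover the DMD operating point from its own forward simulations
data = gen_model_subjects(FITTED_PARAMS["dmd"], 53, seed=20200720)
fit = grid_fit(data, sessions_per_point=53, base_seed=20200720)
print(fit.params, fit.fitness)
```

prints (counts are mean completed items on the word / color / color-word
sheets over 20 sessions):

```
control {'word': 44.0, 'color': 43.2, 'color_word': 41.9}
dmd     {'word': 43.9, 'color': 43.05, 'color_word': 40.2}
ModelParams(F=1.0, f=0.005, d=4.0, s=2.0, ...) 0.0
```

The control parameter set (slower decay of the latency exponent, f=0.003,
stronger recency weighting, d=5) completes more color-word items than the
DMD set (f=0.005, d=4): the model's interference cost is larger for the
DMD group. The grid search, sharing random numbers with the generating
run, recovers the DMD row exactly (fitness 0).

The same pipeline is scriptable from the shell:

```bash
dmdibl simulate --params control --n 20 --seed 7 --out sessions.csv
dmdibl recover  --group dmd --n 53 --seed 1 --out recovered.json
dmdibl classify --mutations mutations.csv --out calls.csv
dmdibl report   --seed 1 --out comparison.csv
```

Every command writes a plain-text run log with the seed and the resolved
configuration next to its output.

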