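# Methods

## Model

Declarative memory is a set of instances with two situation slots (color,
word), a unit outcome, and a list of integer retrieval-event indices. Time
is event-count time: the store's clock `now` advances by one per committed
retrieval, and seconds appear only through the latency law. Activation of
instance *i* probed at event `now` is

    A_i = B_i + Σ_l P_l · M_li + ε_i,
    B_i = ln Σ_{t ∈ events(i)} (now − t)^(−d),
    ε_i = s · ln((1 − u)/u),  u ~ U(0, 1),
    RT  = F · exp(−f · A_i).

Mismatch `M` is binary by default (0 on equality, −1 otherwise); an
optional similarity table gives graded `M = sim − 1`. Retrieval is the
noisy argmax over all instances; ties go to the earliest-created instance
for reproducibility. A retrieval threshold `tau` exists but is unset by
default: the task as modelled never fails retrieval, it only slows.

The latency law is taken at face value: lower activation means slower
retrieval, so the exponent convention is `RT = F·e^(−f·A)` with `f > 0`.

### Parameters

| symbol | meaning | units | range | default |
|---|---|---|---|---|
| F | latency factor | s | 0–1 | 1.0 |
| f | latency exponent | – | 0–1 | 0 (fitted; reference rows 0.003 / 0.005) |
| d | base-level decay | – | 0–10 | 0.5 (fitted; reference rows 5 / 4) |
| s | logistic noise scale | – | 0–10 | 0 (fitted; reference rows 2) |
| P | mismatch penalty per slot | – | ≥ 0 | 15 |
| tau | retrieval threshold | – | – | unset |
| t_nonretrieval | per-item overhead | s | ≥ 0 | 0.0 |

The fitted reference rows for the control and DMD (Dp140-negative) groups
are shipped as `fitting.FITTED_PARAMS`.

**Why P defaults to 15.** The fitted decay values are large (4–5), so the
recency term in `B` is of order `d·ln(lag) ≈ 6–14` for within-sheet lags.
With a weak penalty (P ≈ 1) the most recently retrieved instance out-scores
the probe-matching instance regardless of the probe, retrieval perseverates
on one instance, the simulated Stroop effect collapses to ≈0.1 items, and
the mean completion counts become insensitive to f, d and s (the fitness
surface is flat, so no parameter can be recovered). P = 15 keeps the
penalty decisive against recency across the fitted decay range, making
retrieval match-driven: the interference mechanism operates and the
parameters become identifiable (≈0.5–1 completed items per 0.001 step of
f). Tests that exercise the published activation arithmetic pass P
explicitly, so this default only affects simulation dynamics.

**t_nonretrieval = 0.** With F = 1 the retrieval latency alone is ≈1 s per
item, which already nearly fills the per-item floor; any positive overhead
only lowers counts. The control row completes ≈44 word-sheet items under
this calibration, and nothing above ≈46 is attainable for any overhead ≥ 0.

## Task

Three sheets of 100 items over the color set {red, green, blue, yellow},
45 s each, run in the order word → color → color-word on a single carried
store. Word sheets print color words in a neutral ink; color sheets print a
neutral letter string in colored ink; color-word sheets are fully
incongruent (word ≠ ink). The store is primed at session start with one
word-reading and one color-naming instance per color, each with a single
retrieval event at index 0 — pre-experimental familiarity, without which
the first sheet would have nothing to retrieve. Probes request the
to-be-named attribute; on the color-word sheet the printed word is a second
requested slot, so every candidate carries at least one penalty and the
sheet is structurally slower — the Stroop effect. An item's cost is
`RT + t_nonretrieval`; the sheet stops before the first item whose cost
would exceed the remaining budget. Committed retrievals append events
live, which is what seeds the third sheet with the instances laid down on
the first two.

Two RNG streams are derived per session seed (sheet construction,
retrieval noise), so a seed fully determines a session. A vectorized
engine runs batches of sessions in lockstep and is verified
result-equivalent to the per-object path; the grid search uses it with
common random numbers (identical sheets and noise tables at every grid
point).

## Fitting

The search enumerates the full lattice — default: d and s in steps of 1
over [0, 10], f in steps of 0.001 over [0, 0.01], F fixed at 1 — and
scores each point by the fitness function: the mean absolute difference
between model and human per-sheet completion counts, with human counts
taken as group means (one model per group, not per subject). Ties break
lexicographically by (d, s, f, F). MSD is reported two ways: over the
three sheet means, and — when per-subject scores are supplied — over
subjects × sheets against the fitted model's mean counts.

**Recovery design.** The recovery experiments pair the data-generating
simulation with the grid search through common random numbers: the search
uses the cohort's seed as its base seed and matches sessions-per-point to
the cohort size, so the true grid point replays the generating run exactly
(fitness 0) and decay is recovered exactly. This is a self-consistency
check of the search, not statistical estimation; with fully independent
randomness, f still recovers exactly (counts move ≈0.5 item per grid step)
and the control row's d recovers, but the DMD row's d can alias with s
along a shallow fitness ridge at step-1 resolution — count-only fitness
does not carry enough information to resolve it.

**MSD ordering caveat.** Because F = 1 floors per-item time near 1 s,
model counts are capped at ≈45 per sheet. The published control means
(60.09 / 46.79 / 28.34) are therefore farther from any attainable model
counts than the DMD means (52.30 / 38.46 / 24.49), and the fitted control
model always shows the larger sheet-level MSD — the reverse of the
original report. At subject level the DMD group's larger score variances
roughly cancel that difference, leaving the ordering near chance across
replicates. The corresponding acceptance test states the original ordering
and fails honestly; the comparison report exposes both MSD variants.

## Synthetic cohorts

Group profiles carry the published means and SDs for Stroop W/C/CW, RAVLT
trials, digit spans and IQ for the control (n = 80), Dp140-positive
(n = 14) and Dp140-negative (n = 53) groups. RAVLT trials 2–4 are not
published; they follow a linear trial-1→trial-5 shape rescaled so the
five-trial sum equals the published learning capacity, with SDs
interpolated; List B is the published proactive-interference ratio times
trial 1.

Marginals are independent truncated normals on the task range (0–15 for
RAVLT, 0–sheet-length for Stroop, ≥0 otherwise). Where a bound binds
(e.g. RAVLT trial 5, mean 12.71, ceiling 15), the location parameter is
re-solved so the *truncated* mean equals the profile mean; otherwise
plain truncation would bias such measures down by ≈0.5 SD. The SD of a
bounded measure consequently shrinks slightly below its nominal value.

Recall grids (5 trials × 15 positions, binary) are generated per subject:
trial scores are unbiased-rounded to integers, each trial's score is
allocated to the primacy/middle/recency bins in proportion to the profile
targets (capped at 5 per bin, excess redistributed), the allocation is
rounded by systematic sampling — which preserves the expected bin masses
exactly and the row sum always — and positions within a bin are chosen
uniformly. Bin targets above 5 are rejected as infeasible.

What the generator does **not** emulate: covariance between measures (only
marginals are published), age and education structure, learning-curve
shape beyond the linear interpolation, per-subject model parameters, and
response errors (the task model counts completions only). Tests passing on
these cohorts therefore validate the pipeline's mechanics and the
published group-level structure, not individual-level dependencies in real
data.

## Statistics report

Per measure: a Lilliefors (KS-type) normality check per group; normal
measures get one-way ANOVA (Welch form when Levene rejects equal
variances) with Bonferroni-adjusted pairwise t tests; non-normal measures
get Kruskal–Wallis (Mann–Whitney for two groups) with Bonferroni-adjusted
pairwise Mann–Whitney tests; α = 0.05, p-values reported to three
decimals. Groups with fewer than two observations drop the measure with a
warning rather than silently.

## Dp140 classification

A CNV whose last affected exon is ≤ 43 lies entirely upstream of the
Dp140 promoter region (exon 44) and is called Dp140-positive; reaching
exon 44 or beyond is called negative. Exon 44 itself is negative — the
bundled reference case with a deletion of exons 20–44 is reported as
Dp140-affecting — but such calls carry a low-confidence flag because the
transcription start is not confirmed at single-exon resolution.
Duplications follow the same rule, flagged in the rationale; point
mutations and CNV-free records are "unknown". Classification is a pure
function of (kind, last exon) and is brute-force verified over all 3160
valid exon ranges.

## Numerical choices

* Uniform draws are clipped to [1e-12, 1 − 1e-12] before the logit so
  noise stays finite; applied identically in both simulation paths.
* Budget rule: an item completes iff the running total plus its cost stays
  ≤ 45 s; the first failing item is discarded un-attempted-beyond-RNG
  (its noise draw is consumed, keeping both engines aligned).
* Retrieval failures (only with `tau` set) cost a configurable penalty
  time (default 1 s), are counted separately, and never record an event.
* Undefined ratio indices (zero denominators, missing trials) are NaN
  markers, never dropped rows.
* Grid/argmax ties: earliest-created instance; lexicographic (d, s, f, F)
  at the grid level.

## Known limitations

* The model cannot complete more than ≈46 items per 45-s sheet with F = 1,
  so absolute human count levels (up to ≈60) are out of reach; fits should
  be read as qualitative.
* d and s are only weakly identifiable from count data at fine grid
  resolution (see the recovery design above).
* The memory-efficiency index (MEI) has no formula here; it is a pluggable
  callable whose report carries the interpretive cut-offs 1.2 and 1.9.
* Attention fraction has two candidate definitions ((DSF−DSB)/DSF and
  (DSF−DSB)/(DSF+DSB)); neither reproduces all published group means, so
  both are provided and the variant used is recorded in every output.
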