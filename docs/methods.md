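# Methods

This note records the models implemented by `swarmfs`, the parameters that
matter, the choices made where the printed method is silent, and what the
synthetic benchmark does and does not demonstrate.

## Sailfish optimizer

The optimizer minimizes a real objective over a box. Two populations
interact: `NumSD` sardines (default 60) and
`NumSF = max(1, round(NumSD · percent))` sailfish (`percent` default 0.3,
giving 18). Bookkeeping tracks the *elite* (best sailfish fitness ever seen)
and the *injured* (best sardine of the current iteration); the returned
solution is the best position ever evaluated in either population.

Per iteration k (0-based):

- prey density `Pd = 1 − NumSF/(NumSF + NumSD)` with the *current* sardine
  count, so Pd shrinks as prey are captured;
- `μ_k = 2·r·Pd − Pd` with one uniform draw r per iteration; each sailfish
  then gets its own fresh scalar r in
  `SF_i ← elite − μ_k·r_i·((elite + injured)/2 − SF_i)`;
- attack power `ATK = A·(1 − 2·k·ε)` (defaults A = 4, ε = 0.001: ATK decays
  linearly from 4, crossing the 0.5 regime switch at k = 437 and 0 at 500).
  While ATK ≥ 0.5 every sardine updates every coordinate as
  `SD ← r·(elite − SD + ATK)` with a fresh r per entry; below 0.5 only
  `α = ⌊NumSD·ATK⌋` sardines update `β = ⌊d·ATK⌋` coordinates each (both
  floored, at least 1 while ATK > 0, coordinate sets drawn per sardine);
- capture: sailfish are served worst-first (ties to the lower index); each
  may capture the best remaining sardine whose fitness is *strictly* lower
  than its own, adopting its position; the captured sardine leaves the
  school.

All positions are clipped to the box after every update; non-finite
objective values become +inf with a logged warning.

**Prey replenishment.** Because each of the 18 sailfish may capture one
sardine per iteration, a 60-sardine school can be consumed within roughly
ten iterations. Stopping there would waste most of any realistic iteration
budget and collapse the search to a short greedy phase, so when the school
empties mid-run it is re-initialized from the continuing tent-chaos stream
(uniformly, when chaos initialization is disabled). The elite record is
never lost, so the best-so-far history remains non-increasing. Depletion
still matters dynamically: Pd, and with it the sailfish step size, shrinks
as the school thins within each replenishment cycle.

**Chaos initialization.** Both populations are carved row-major out of a
single tent-map stream started at T₀ = 0.9 (breakpoint 0.7). The raw map
can land exactly on 0 or 1 (0.7 → 1.0 → 0.0 → stuck); any iterate outside
(ε, 1−ε) with ε = 1e−12 is replaced by 0.9 plus a counter-indexed
machine-epsilon jitter — deterministic, and the sequence never collapses.
Uniform pseudo-random initialization is a drop-in alternative
(`chaos_init=False`); every invariant holds either way.

## Binary wrapper feature selection

The continuous search runs over `[−4, 4]^D`: the logistic transfer maps ±4
to selection probabilities 0.982/0.018, so the box spans near-certainty in
both directions. Each objective call binarizes the candidate — bit d set
when a uniform draw falls below `T(x_d)` — using a counter-based random
stream (`default_rng([seed, eval_index])`): reproducible from the search
seed alone, yet fresh per evaluation. An all-zero mask is repaired by
setting one random bit, since the fitness is undefined for an empty subset.

The fitness `ω·γ(S) + (1−ω)·|S|/D` uses ω = 0.99, the customary wrapper
weighting that prioritizes error over parsimony. γ(S) is the stratified
5-fold cross-validated misclassification rate of a 1-nearest-neighbour
classifier with per-fold z-scoring — cheap, deterministic, and standard for
wrapper selection; any scikit-learn-style estimator (including the package's
own recurrent classifier) can be substituted. The hot-path 1-NN is a
vectorized distance-matrix implementation; a test pins it to the equivalent
scikit-learn pipeline on sampled masks. Fold assignment comes from
scikit-learn's `StratifiedKFold`, keyed by a `cv_seed` (default 0) that is
deliberately *separate* from the search seed: the error landscape must stay
frozen across searches, otherwise repeated runs could "improve" merely by
re-drawing favorable splits, and the exhaustive-enumeration bound (the
selector can never beat the enumerated optimum) would not be well defined.

Error estimates are memoized per distinct mask, so classifier work is
bounded by the number of distinct masks visited (typically a few thousand
for D = 13). The returned result is the best mask ever evaluated, not the
final swarm state.

**Budget.** The selection driver defaults to 500 iterations, the same
budget the continuous optimizer uses on benchmark functions. On replicates
of the default synthetic table (below), the masks returned at this budget
coincide with the global optimum found by exhaustively enumerating all
2^13 − 1 subsets with the same frozen estimator; at 100 iterations the
search still lands within a few percent of the optimum but does not
reliably reach it.

## Rat swarm optimizer and hyperparameter tuning

RSO is implemented exactly as printed: `P ← A·P_i + C·(P_best − P_i)`,
`P_i ← P_best − P`, with `A = R − x·R/max_iter` annealed from one
per-iteration draw R ~ U[1, 5] and C ~ U[0, 2] fresh per agent.
Note the first term scales the agent's *position*, not its distance to the
best, so early iterations push agents through the origin region; as A → 0
the update contracts onto the best point. The behavior is kept as printed
rather than "fixed".

Hyperparameter tuning minimizes the recurrent classifier's stratified
inner-CV error over a continuous box with coordinates log₂(hidden size) ∈
[2, 6], log₁₀(learning rate) ∈ [−4, −1], and epochs ∈ [10, 100]; integers
are rounded at decode time and decoded points are cached. This trio is the
minimal credible tuning set for a small recurrent classifier; batch size
and initialization scale are left fixed.

## The bidirectional recurrent classifier

The gated cell follows a nonstandard printed form (named *paper-GRU* in the
code) that mixes GRU and LSTM conventions:

```
i   = σ(W_xi x_t + W_hi h_{t−1} + b_i)
f   = σ(W_xf x_t + W_hf h_{t−1} + b_f)
g   = tanh(W_xg x_t + W_hg (i ⊙ h_{t−1}) + b_g)
h_t = (1 − f) ⊙ h_{t−1} + f ⊙ g
```

The i-gate enters only through the reset product inside g; f interpolates
between the old state and the candidate. The cell is implemented verbatim —
no substitution of a textbook GRU — and its hand-derived backward pass is
gated on a central-difference oracle (max relative error ~1e−5, threshold
1e−4, with the relative error floored at 1e−6 absolute scale to keep
finite-difference roundoff on near-zero components from registering as
disagreement).

Tabular rows enter the recurrence as length-D sequences of scalars (one
selected feature per time step, in column order); features are z-scored
with training-set statistics inside the estimator, so cross-validation
never leaks test-fold moments. One cell reads the sequence forward, a
second backward; the two final hidden states are concatenated (width 2H)
into a linear softmax readout. Training is plain mini-batch gradient
descent on the cross-entropy (defaults: hidden 8, learning rate 0.05,
50 epochs, batch 16, uniform ±0.1 initialization from the run seed);
a non-finite loss aborts with the epoch named. Prediction is the argmax,
ties to the lower class index. Models serialize to a single JSON file
(shape manifest plus weight lists).

## Synthetic benchmark

`SyntheticSpec` defaults to n = 300 subjects, D = 13 features of which the
first m = 4 are informative (class-conditional means differing by
effect = 2 noise SDs), balanced classes — mirroring the dimensionality of a
13-feature hand-drawing table with a 4-feature signal. The generator
emulates the *shape* of such tables, not their physiology: real screening
features are correlated, non-Gaussian, and informative to varying degrees,
whereas these columns are independent Gaussians that are either fully
informative or pure noise. Passing the recovery tests therefore shows the
selector finds a planted signal under the stated fitness; it does not
certify performance on clinical data.

One property of the ω = 0.99 fitness is worth stating plainly: the size
penalty per feature (0.01/13 ≈ 0.00077) is smaller than one CV-error
quantum at n = 300 (0.99/300 ≈ 0.0033), so a noise column that spuriously
removes even a single misclassification is *correctly* kept by the printed
objective. On some data realizations the globally optimal mask therefore
carries several noise columns; the recovery test's 8-of-10 margin reflects
exactly this, and the selector returning the enumerated global optimum is
the strongest claim the method supports.

## Pipeline

Stage order is fixed: feature selection on the full table, then stratified
outer cross-validation (default 10 folds; the bundled configs and tests use
3 for speed) on the selected columns. Within each outer training fold the
tuner runs nested 3-fold inner CV, so the test fold never influences
hyperparameters — stricter than anything the source method states.
Per-fold confusion counts are summed into the aggregate report; the
aggregate accuracy/DR/FAR are computed from the summed counts.

All randomness derives from one master seed via a `SeedSequence` spawned in
a fixed order (feature selection first, then one tuning and one training
seed per outer fold); a run report is byte-identical across repeats up to
its timestamp and carries the config hash for provenance.

## Problem sizes and numerical choices

Tests and the acceptance script use: 10-d sphere on [−100, 100]^10 (the
conventional benchmark box) with 60 sardines/500 iterations and 30 rats/300
iterations; D = 10 tables for exhaustive 1023-mask enumeration; D = 13
tables for recovery; a 2-unit, 3-step cell for the gradient oracle; and a
reduced pipeline (n = 150, 3 outer/2 inner folds, small tuning box) for the
end-to-end determinism check. Boundary handling is clipping throughout;
α/β rounding is floor-with-minimum-1; capture ties break toward lower
indices; the attack-power iteration index is 0-based.

## Known limitations

- The capture rule plus replenishment makes the effective exploration/
  exploitation balance depend on the sailfish:sardine ratio; extreme
  `percent` values (near 1) turn the method into near-random restarts.
- The selection fitness is noisy at small n (CV error quantized at 1/n);
  reported error rates are wrapper-internal estimates, optimistically
  biased for the selected mask, and should not be read as generalization
  error — the pipeline's outer CV exists for that.
- The recurrent classifier is a small dense numpy implementation; it is
  deliberately compact, single-threaded and CPU-bound, suitable for tables
  with tens of features, not for long sequences.
- Class labels must be binary throughout the pipeline (the cell and metrics
  support the multi-class readout, but DR/FAR are defined for one positive
  class).
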