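# Methods

## Fusion model

Given K classifiers' predicted probability matrices `P₁ … P_K` (each N×C,
rows on the probability simplex), the weighted-average ensemble is the
convex combination `P(w) = Σₖ wₖ Pₖ` with `wₖ ≥ 0`, `Σₖ wₖ = 1`. Fusion
operates on probabilities, not logits: the inputs are the models'
calibrated (or at least normalized) posteriors, and convexity guarantees
`P(w)` is itself row-stochastic, so fused outputs can be evaluated, saved
and re-fused like any single model's output. Simple averaging is the
special case `w = (1/K, …, 1/K)`. Hard predictions are the per-row
argmax with ties broken toward the lowest class index — an arbitrary but
deterministic rule that makes every pipeline stage reproducible.

Weight vectors are validated, never silently renormalized: an off-simplex
vector (beyond 1e-9) is a caller bug and raises. On file ingest the
opposite stance applies: serialized softmax rows routinely sum to
1 ± 1e-3 because of rounding, so rows within that band are accepted and
divided by their sums (with an explicit `renormalize` flag widening
acceptance to any positive row sum), and the strict 1e-6 row-sum
invariant is enforced only after that normalization.

## Metrics

All metrics derive from per-class one-vs-rest confusion counts
(TP, FP, FN, TN, which partition N for every class):

- precision `TP/(TP+FP)`, recall `TP/(TP+FN)`,
  F1 `TP/(TP+½(FN+FP))` — the last form is algebraically `2PR/(P+R)`
  whenever `P+R > 0`, which the test suite checks by fuzzing;
- overall accuracy as the fraction of samples whose argmax prediction
  matches the truth (the multi-class reading of the binary
  `(TP+TN)/(TP+TN+FP+FN)` form);
- aggregation across classes: `macro` (unweighted mean), `weighted`
  (support-weighted mean — the default, chosen because it makes
  aggregated recall coincide exactly with overall accuracy for
  single-label data, a useful internal consistency check), and `micro`
  (metrics of the pooled counts, which all equal accuracy for
  single-label data);
- top-k accuracy: the true class is ranked among the k largest fused
  probabilities, ties again resolved toward lower class indices.

Degenerate 0/0 ratios (a class absent from both truth and predictions,
or an empty predicted class) return 0 with a logged warning rather than
raising: with many classes such cases are routine, and a fitness
evaluation inside the optimizer must never abort on them. scikit-learn's
implementations are used in the test suite as an independent reference
(agreement to 1e-9 on hundreds of random instances), never in the
package's own computation path.

## Genetic algorithm

A chromosome is a K-vector on the weight simplex; its fitness is the
accuracy of the fused ensemble's argmax predictions on the bundle the
caller supplies (the library takes no position on train/validation
splits; the CLI offers `--holdout FRACTION` for a seeded split, fitting
on the remainder and logging holdout accuracy).

Per generation: `elitism` best chromosomes are copied unchanged (default
1, which makes the best-fitness trace provably non-decreasing); parents
are chosen by tournament (default, size 3, drawn without replacement) or
roulette-wheel selection (fitness-proportional, uniform fallback when all
fitnesses are 0); with probability `crossover_rate` (0.9) parents
exchange a block of coordinates — for K=2 the classic swap producing raw
offspring `(α₁, β₂)` and `(α₂, β₁)`, for K>2 a random proper subset —
and since the raw offspring generally leave the simplex each is divided
by its coordinate sum (a zero sum resets to uniform weights); each
offspring then mutates with probability 0.2 by perturbing one coordinate
with `δ ~ U(−0.05, +0.05)` clipped to [0, 1] and rescaling the remaining
coordinates so the sum returns to 1. The run stops after
`max_generations` (50) or when the best fitness reaches an optional
`fitness_target`. All randomness flows from one seeded numpy Generator;
fitness ties are broken toward the earlier-evaluated chromosome, so runs
are bit-reproducible and CLI outputs byte-identical per seed.

**Initialization.** The first K+1 chromosomes are deterministic
baselines — the K vertex vectors (each single model alone) and the
equal-weight point — followed by uniform simplex draws (symmetric
Dirichlet(1)). Seeding the population with the known baselines is
standard practice in ensemble weight optimization and gives two
guarantees that pure random initialization lacks: with elitism the
optimizer can never return a fitness below the best standalone model or
the simple average, and when one model strictly dominates (a flat
fitness plateau over a wide range of weights), the returned weight is
the clean boundary solution rather than an arbitrary point of the
plateau picked up by the tie-break.

**Oracle.** `grid_search_oracle` evaluates fitness on every simplex grid
point with spacing `step` (rounded to the nearest 1/M so points are
exact), breaking ties toward the lexicographically smallest weight
vector. It is exponential in K and therefore guarded to K ≤ 3; its role
is verification, not optimization. The acceptance checks require the GA
to come within 0.005 of the step-0.01 grid maximum and never exceed the
step-0.001 maximum (fitness is piecewise constant in the weights with
plateau widths far above 0.001 at these problem sizes, so the fine grid
attains the true maximum).

**Default problem sizes.** The seeded verification scenarios use N=500
samples, C=5 classes, K=2 models, 20 seeds per check — large enough for
binomial noise to sit well below the effects being measured, small
enough that the full test suite runs in seconds.

## Synthetic classifier outputs

The generator emulates test-time softmax outputs without any images or
trained networks. Per sample: a true label from the class priors
(default uniform, default C=44 mirroring a fine-grained tumor-category
label space; tests use C=5 for speed); per model, a Bernoulli correct
event at that model's target accuracy. Error correlation uses a shared
latent draw: with probability ρ all models reuse one uniform variate for
the correct/incorrect decision (equally accurate models then fail on
exactly the same samples at ρ=1), otherwise each model draws its own —
chosen over a Gaussian copula for exact analyzability. On an error, the
intended argmax class is drawn from a per-model confusion-bias
distribution over wrong classes (default uniform).

The emitted row is a Dirichlet draw with concentration κ (`sharpness`,
default 50) on the intended class and 1 elsewhere — soft, realistic rows
rather than one-hot votes, so fusion genuinely exercises probability
arithmetic. Erroneous rows use a lower concentration `error_sharpness`
(default κ/8, at least 2), reflecting the systematic confidence gap of
trained softmax classifiers between their correct and incorrect
predictions. This asymmetry is load-bearing: with equal sharpness both
ways, a confidently-wrong row and a confidently-right row average to an
exact tie and complementary errors yield no fusion gain at any weight;
with it, a moderately confident correct model outvotes a less confident
wrong one, which is precisely the regime where weighted fusion helps and
weight selection has an interior optimum to find.

Named fixtures: `scenario_s1` (two 0.80-accuracy models, N=500, C=5,
independent errors routed to disjoint classes — shift-by-1 vs shift-by-2
confusions — κ=50 correct / 6 wrong; standalone ≈ 0.79, oracle-optimal
fused ≈ 0.95 at an interior weight near 0.5), `scenario_perfect_vs_random`
(0.99999 vs 0.22 accuracy, very sharp rows; the optimum is the boundary),
and `scenario_random_pair` (a randomized family with accuracies in
(0.55, 0.95), sharpness in (20, 100), error sharpness in (3, 10),
correlation in (0, 0.5)).

What passing tests do and do not show: the simulator produces exactly
row-stochastic, per-model-exchangeable outputs with a single global
error-correlation mechanism and class-symmetric confidence. Real model
ensembles have heteroscedastic confidence across classes, calibration
error, and sample-dependent correlation structure; results here verify
the fusion/optimization machinery, not any claim about a particular real
dataset or backbone.

## Numerical and design notes

- Simplex tolerance 1e-9 everywhere a weight vector is validated;
  probability-row tolerance 1e-6 internally, 1e-3 on ingest.
- Argmax, top-k ranking, and grid tie-breaks are all index-deterministic,
  so every reported number is reproducible bit-for-bit from a seed.
- Columns are never reordered on read: class order comes from the first
  model's header and others must match exactly, because silent column
  permutation is a corruption hazard with no numeric symptom. Rows are
  aligned by sample id.
- The fitness landscape is piecewise constant (accuracy of argmax), so
  gradient methods are inapplicable and population search plus an
  exhaustive grid oracle is a natural fit.

## Known limitations

- `grid_search_oracle` is restricted to K ≤ 3; for larger ensembles the
  GA runs unverified (its structural contracts still hold).
- Fitness equals accuracy; no multi-objective or top-k-based fitness.
- No probability calibration, ROC/AUC, or confidence intervals.
- The simulator draws rows independently given the correctness events;
  it does not model feature-level similarity between backbones.
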