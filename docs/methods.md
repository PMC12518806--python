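# Methods

This note documents the models, parameter choices, numerical conventions
and known limitations of the package. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Problem setting

The task is multi-class classification of medicine records: short
free-text fields (uses, side effects, composition) plus tabular context
(manufacturer, a review-percentage triplet summing to 100), labelled with
a condition category. The pipeline is: text cleaning → n-gram
featurization (+ context columns) → wrapper feature selection by a hybrid
ant-colony optimizer → a fused logistic-regression / random-forest
classifier → multi-class evaluation.

## Text preprocessing

Normalization lowercases, removes punctuation (Unicode category P) and
digit characters, maps intra-word hyphens to spaces and collapses
whitespace; so "500mg" becomes "mg" — digits go, unit words stay, which
keeps composition text informative. Tokens are whitespace-split, filtered
against a compact standard English stoplist (configurable from a
one-word-per-line file), and lemmatized through a static lemma table
(dictionary lookup; unknown tokens and non-string elements pass through
unchanged). A static table rather than a model-backed lemmatizer keeps
the test suite hermetic and the chain exactly idempotent. The `Uses`
field is always processed; `Side_effects` and `Composition` are behind
flags because real catalogues vary in how much cleaning those fields
tolerate.

## Featurization

The vocabulary is all unigrams and bigrams with document frequency ≥
`min_df`, in first-occurrence order (deterministic, diff-friendly).
Values are raw counts by default; tf-idf (idf = ln(N/df), so a gram in
every document weighs zero) is behind a flag — counts are the minimal
reading of "text to numbers", and the flag preserves the common
alternative. Context features are the review triplet scaled to [0, 1]
and one-hot manufacturer indicators: the non-text columns actually
present in the schema. Cosine similarity is exposed as its own matrix;
a zero-norm document is defined to be orthogonal to everything while
keeping 1 on its own diagonal, so the "diagonal is always 1" property
survives degenerate rows. By default similarity stays out of the feature
matrix; a flag can append each document's top-k similarity scores.

## HACO feature selection

Features are nodes of a complete directed graph; an ant's "path" is an
ordered K-subset and "edges" are consecutive selections. This graph
realization is a design choice: route language is transplanted onto
feature selection, so some mapping had to be fixed.

* Transition law: `Q_ji ∝ τ_ji^α · η_i^β · a_ji`, normalized over the
  non-taboo features, zero elsewhere. The first feature is drawn from
  the per-node pheromone marginal (column mean of τ) and η, with no
  adaptive factor — there is no incoming edge yet.
* Heuristic information η: absolute point-biserial correlation with the
  label (binary) or the square root of the correlation ratio
  (multi-class), scaled so the best feature scores 1. If all scores are
  zero, η is uniform.
* Adaptive factor: `a_ji = M·s / (M·s + δ·P_d(j,i)·η_i/η_max)` with
  P_d the cumulative traversal count since the first iteration
  (cumulative, not per-iteration — the discounting of over-used edges is
  meant to strengthen over time).
* Fitness and cost: fitness is stratified k-fold (default 3)
  cross-validated accuracy of a logistic model on the subset; cost is
  `(1 − fitness) + λ_size·K/n_features` with λ_size = 0.01 and a floor
  of 1e−6 so deposits stay finite on perfect subsets. Fitness values are
  cached per subset (order does not change them).
* Pheromone update: `τ(s+1) = ρ(s)·τ(s) + Σ_l Δτ^l + Δτ*`, clamped into
  [τ_min, τ_max] = [0.1, 1.0]; trails start at τ_max (max–min
  ant-system convention). Per-ant deposits are `P(s)/K_L`; the elitist
  deposit is `δ·P/L*` on the incumbent best path only.
* Intensity schedule: P(s) is piecewise-constant (P1=1, P2=0.5, P3=0.25
  over thirds of the run) — strong early reinforcement, gentler late.
* Evaporation: the "curve decay" schedule
  `ρ(s) = [S(τ_max−τ_min)s + Sτ_min − τ_max]/(S−1)` is linear and
  *increasing* in s and can exceed 1; it is implemented as written, with
  a default clamp into (0, 1] and a switch to disable the clamp. A
  constant-ρ override exists for the classic ant-system mode. For S = 1
  the schedule is undefined (division by S−1); the engine then uses the
  s = 1 algebraic value, τ_max, clamped.
* Boundary mutation: with probability 0.1 one selected feature whose
  pheromone marginal lies in the central band
  [τ_min + q·range, τ_max − q·range] (q = 0.25) is swapped for a uniform
  unselected feature; taboo set and traversal counts are kept
  consistent. Features at the extremes are deliberately immune: strongly
  marked features are kept, strongly unmarked ones are not re-injected.
* Defaults: M = 20 ants, S = 30 iterations, α = 1, β = 2, δ = 1,
  K = 10% of features (min 2), 3 CV folds, seed 0. A single seeded
  generator is shared across ants in a fixed order, so runs are exactly
  reproducible.

The plain-ACO baseline is the same engine with δ = 0, constant P,
constant ρ and mutation off; GA (tournament / uniform crossover /
bit-flip, elitist), binary PSO and simulated annealing (geometric
schedule, `exp(−Δcost/T)` acceptance) search over variable-size masks
under a size cap and consume the identical fitness evaluator. The PSO
position rule uses a V-shaped transfer — each bit flips with probability
|tanh(v)| — so zero velocity leaves a particle in place, which makes the
all-weights-zero configuration exactly stationary.

## Logistic forest

Logistic regression is fit by Newton–Raphson on the binomial
log-likelihood: `β ← β − G⁻¹∇`, with a doubling ridge (from 1e−8) on a
singular Hessian and step-halving so the log-likelihood never decreases.
Complete separation (‖β‖ beyond 50, or fitted probabilities saturating
onto the labels) is flagged as non-convergence. The ensemble partitions
features at random into N near-equal subspaces (sizes differ by at most
one), fits one model per subspace and averages member probabilities; the
partition count is raised automatically when features outnumber training
samples so each member keeps q < N. Multi-class is one-vs-rest with
renormalized scores.

Trees are CART-style: exhaustive search over midpoints of consecutive
distinct values on `m_try` random features (default √p), maximizing the
Gini impurity decrease; ties break to the lowest feature index, then the
lowest threshold. Forests grow on bootstrap resamples with per-tree
seeds spawned from the forest seed. Prediction is majority vote with
vote-fraction probabilities; ties go to the smallest class index
(documented, deterministic). Gini importance accumulates
(node-fraction)·δj over all nodes splitting on a feature.

Fusion: `average` mode returns `w_lr·p_lr + w_rf·p_rf`; `majority` mode
lets each model vote its argmax, resolves disagreement by the
higher-weighted model, and falls back to averaging at equal weights —
a two-model "majority" is otherwise undefined. Weights are
context-aware: a map from a context key to a weight pair, keyed by
default on the candidate class of the base-weight average; the shipped
default weighs the forest more heavily (0.3/0.7) when the candidate is
cancer. Weights renormalize to sum 1 after any override. The default
mode is `average`; both are first-class.

## Evaluation

Macro averaging is the default for multi-class precision / recall / F1 /
F2 (micro by flag). Recall is TP/(TP+FN); F2 = 5PR/(4P+R). AUC-ROC is
one-vs-rest, macro-averaged, trapezoidal; with a single observed true
class it is reported as missing rather than guessed. RMSE is the root of
the mean *squared* label-code error and MAE the mean absolute error —
on a classification task these are a reporting convention over integer
class codes, not a modelling choice, and MSE is squared (an
absolute-value "MSE" would duplicate MAE and contradict the RMSE
definition). The split protocol is stratified 80/20 by default, seeded.

## Synthetic data

The corpus generator emulates the catalogue schema: themed, disjoint
planted-token sets per class (cough / pain / cancer / fever /
infections), each token included in a class document independently with
probability `planted_token_prob` (the separability dial), plus Poisson
noise tokens from a random lowercase vocabulary, numerals and
punctuation injected into the raw text so preprocessing is exercised,
balanced labels, and review triplets summing to 100. Defaults: 1,000
documents, 5 classes, 3 planted tokens per class, noise rate 12, noise
vocabulary 200, dial 0.9. Three planted tokens per class keeps the dial
live: a class-c document carries no class-c token with probability
(1−p)³, so corpus difficulty genuinely rises as p falls; with many
planted tokens per class every setting of the dial saturates at
ceiling accuracy and the dial (and any model ordering) becomes
unobservable. The feature-table generator plants a logistic signal on
`n_informative` standard-normal columns with ±`effect_size`
coefficients.

What the generator does *not* emulate: realistic token frequency
distributions (Zipfian text), correlated vocabulary across classes,
label noise, or any statistical property of real drug catalogues beyond
the schema. Passing tests therefore demonstrate mechanism correctness
and recoverability of planted structure, not expected accuracy on real
data.

## Problem sizes

The shipped simulations use desk-scale sizes chosen to make the
statistical checks stable: selector recovery on 800 × 50 tables over 10
seeds; baseline-selector recovery on 400 × 50 tables; the end-to-end
experiment on 1,000-document corpora over 5 seeds; the
construction-path sampling oracle at 10,000 draws on 4 features. These
are the package's own choices of scale.

## Known limitations

* The evaporation "decay" schedule is increasing and clamps at 1 for
  most of a run at the default bounds; the constant-ρ override is the
  practical alternative.
* Trees are exact but pure-Python/numpy; very wide corpora
  (tens of thousands of n-grams) will be slow — raise `min_df` or rely
  on the selector.
* One-vs-rest logistic scores are renormalized, not calibrated.
* The lemma table is intentionally small; domain-specific inflections
  outside it pass through unlemmatized.
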