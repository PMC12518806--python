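# dtiforest

Context-aware classification of drug descriptions: an ant-colony wrapper
feature selector with dynamic pheromone schedules, fused logistic-
regression / random-forest ("logistic forest") classification, and n-gram
+ cosine text featurization — packaged as scikit-learn-style estimators
with a small CLI, and exercisable entirely on synthetic medicine corpora
with known ground truth.

## Who this is for

Practitioners classifying free-text medicine records (uses, side effects,
composition) into condition categories (e.g. cough / pain / cancer /
fever / infections), and anyone studying wrapper feature selection by
metaheuristics on text-derived feature spaces. The package ships its own
corpus generator, so every stage is testable without external data; real
catalogues in the same CSV schema (Medicine Name, Composition, Uses,
Side_effects, Manufacturer, review-percentage triplet) load through the
same reader.

## The method

**Featurization.** Text fields are normalized (lowercase, punctuation and
digits removed), tokenized, stopword-filtered and lemmatized, then
counted over a unigram+bigram vocabulary. Context features — the
review-percentage triplet scaled to [0, 1] and one-hot manufacturer
indicators — are appended. Cosine similarity
`S_ij = x_i·x_j / (‖x_i‖‖x_j‖)` between document vectors is available as
a separate matrix (identical documents score 1, disjoint-support
documents 0, opposed vectors −1).

**HACO feature selection.** Features are nodes of a graph; an ant builds
an ordered subset of K features by roulette over

    Q_ji ∝ τ_ji^α · η_i^β · a_ji ,
    a_ji = M·s / (M·s + δ·P_d(j,i)·η_i/η_max) ,

where τ is a bounded per-edge pheromone, η a feature–label association
score and P_d the cumulative traversal count. Subset fitness is the
cross-validated accuracy of a logistic model on the subset. Pheromone
evolves as `τ(s+1) = ρ(s)·τ(s) + Σ_l Δτ^l + Δτ*` with per-ant deposits
`P(s)/K_L`, an elitist deposit `δ·P/L*` on the incumbent best path, a
piecewise-constant intensity schedule P(s), a linear "curve decay"
evaporation schedule ρ(s) clamped into (0, 1], and a symmetric boundary
mutation that swaps a mid-pheromone feature for an unselected one.
GA, binary-PSO, simulated-annealing and plain-ACO baselines share the
identical fitness evaluator.

**Logistic forest.** A subspace logistic ensemble (Newton–Raphson fits on
a random near-equal feature partition, member-mean probability,
one-vs-rest for multi-class) is fused with a random forest (Gini
impurity `j(s) = 1 − Σ e_i²`, exhaustive midpoint threshold search
maximizing `δj(s) = j(s) − e_q j(s_q) − e_p j(s_p)`, majority vote, Gini
importance `J_H(Θ) = Σ nodes-on-Θ weighted δj`). Fusion is weighted
probability averaging (or a two-model vote); the weights are
context-aware — by default the forest is weighted more heavily when the
candidate class is cancer.

## Worked example

```python
from dtiforest.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig.from_dict({
    "synth": {"n_documents": 1000, "n_classes": 5,
              "planted_token_prob": 0.9},
    "featurize": {"min_df": 3},
    "selector": {"method": "haco",
                 "params": {"n_ants": 20, "max_iterations": 30}},
    "classifier": {"n_trees": 15, "max_depth": 12},
    "seed": 1,
})
res = run_pipeline(cfg)
print(res.n_features_total, len(res.selected_features))
print(round(res.report.accuracy, 3), round(res.report.f1, 3),
      round(res.report.kappa, 3))
```

prints

```
894 89
1.0 1.0 1.0
```

i.e. on a 1,000-document synthetic five-class corpus the vectorizer
produced 894 n-gram + context features, the ant-colony selector kept 89
of them (the planted class vocabulary plus a few bigrams), and the fused
classifier labelled the held-out 200 documents perfectly (accuracy, macro
F1 and Cohen's kappa all 1.0 on this seed; harder corpora — lower
`planted_token_prob` — yield intermediate scores).

The same pipeline is available from the shell:

```bash
dti synth --seed 3 --out corpus.csv
dti run --config cfg.yaml --seed 1 --out results/
dti ablate --config cfg.yaml
dti compare-selectors --config cfg.yaml
```

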