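# probfuse

Ensemble fusion of multi-class classifier probability outputs, with
genetic-algorithm selection of the fusion weights.

## The problem

When several trained classifiers (say, two deep networks fine-tuned for a
fine-grained medical-imaging task with dozens of tumor categories) each
emit a softmax probability vector per image, combining those vectors
usually beats any single model — *if* the models make complementary
mistakes and the combination weights are chosen well. `probfuse`
implements that last mile, model-agnostically: it takes each model's
N×C row-stochastic probability matrix as a CSV file and does everything
downstream of inference.

- **Fusion** — simple averaging, and weighted averaging
  `P = Σₖ wₖ Pₖ` with weights on the simplex (`wₖ ≥ 0`, `Σ wₖ = 1`;
  for two models the familiar `(α, β)` with `α + β = 1`). Hard labels are
  the per-row argmax.
- **Metrics** — overall accuracy, one-vs-rest per-class precision
  `TP/(TP+FP)`, recall `TP/(TP+FN)`, and F1 `TP/(TP+½(FN+FP))`, with
  micro / macro / support-weighted aggregation, and top-k accuracy.
- **Weight selection** — a genetic algorithm over simplex-constrained
  weight vectors whose fitness is the fused ensemble's accuracy:
  tournament or roulette selection, coordinate-exchange crossover with
  simplex repair, sum-preserving mutation, elitism. An exhaustive
  simplex grid search serves as an independent oracle for K ≤ 3.
- **Simulation** — a generator of realistic synthetic softmax outputs
  for K imperfect, possibly correlated classifiers (per-model accuracy,
  Dirichlet sharpness, shared-error correlation, targeted confusion
  structure), so the whole pipeline is testable without any trained
  models or image data.

## Worked example

Generate the canonical complementary-error scenario (two models of ~0.80
accuracy on 500 samples over 5 classes, whose errors go to disjoint
classes), then compare fixed and GA-selected fusion weights:

```sh
probfuse simulate --scenario s1 --seed 7 --outdir demo
probfuse compare --matrix demo/model_1.csv --matrix demo/model_2.csv \
    --labels demo/labels.csv \
    --setting 1,0 --setting 0,1 --setting equal --setting ga \
    --seed 7 --topk 3 --out demo/table.csv
```

which prints:

```
            setting  accuracy  precision   recall       f1  top_1_accuracy  top_3_accuracy
     weights (1, 0)  0.792000   0.793001 0.792000 0.791682        0.792000        0.898000
     weights (0, 1)  0.794000   0.795699 0.794000 0.793658        0.794000        0.914000
              equal  0.958000   0.958098 0.958000 0.957891        0.958000        0.976000
ga (0.4842, 0.5158)  0.960000   0.960200 0.960000 0.959887        0.960000        0.976000
```

The vertex settings `(1,0)` and `(0,1)` reproduce each model's standalone
metrics (0.792 and 0.794 accuracy). Because the two models fail on
*different* samples and are less confident when wrong, averaging lets the
correct model outvote the wrong one: equal weights already reach 0.958,
and the GA's interior optimum `(0.484, 0.516)` nudges that to 0.960 —
matching the exhaustive grid-search maximum on this instance. The
support-weighted recall column equals the accuracy column, an exact
identity for single-label data. Weight selection alone can be run with

```sh
probfuse optimize --matrix demo/model_1.csv --matrix demo/model_2.csv \
    --labels demo/labels.csv --seed 7 --out demo/weights.csv --trace demo/trace.csv
# best fitness 0.960000; weights written to demo/weights.csv
```

The same workflow is available as a library: `simulate`,
`assemble_bundle`, `simple_average` / `weighted_average` / `predict`,
`evaluate`, `optimize`, `grid_search_oracle` in the `probfuse` package.

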