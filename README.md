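# alignsim

Cross-modal **systems alignment** for concept learning: simulation and
analysis tools for the idea that a learner who knows some word–object
mappings can infer new ones *without supervision*, because similarity
relations among items are mirrored across the visual and linguistic
systems.

The package is aimed at computational cognitive scientists studying early
vocabulary growth. It provides:

- **Alignment scoring** — the alignment score between two systems is the
  Spearman correlation ρ_s between the upper triangles of their pairwise
  distance matrices under a candidate mapping; a two-alternative
  forced-choice task scores both pairings of two unknown words/objects via
  concatenated probe-distance columns and picks the higher.
- **Agent simulation** — knowledge states grown month-by-month from an
  age-of-acquisition (AoA) table (WordBank/MB-CDI item-trajectory CSV,
  months 16–24, with monthly quotas n_m = Δ round(Σ_i p_{i,m})), for
  AoA-matched and random-control agent populations, evaluated with
  forced-choice probes and aggregated with 95% CIs.
- **Structural features** — neighborhood-graph (10th-percentile distance
  threshold) and global-similarity features of knowledge states, plus a
  logistic-regression classifier with recursive feature elimination and
  AIC-based model-size selection.
- **Generative structural agents** — agents with an internal model
  (target feature values x̂, feature weights w) that pick concepts by
  softmax over s = −|A − x̂·1ᵀ|·w; trained by Adam on either an
  AoA-matching MSE loss or a differentiable *soft alignment loss* (the
  probability-weighted margin between incorrect- and correct-mapping
  alignment scores), with analytic gradients.
- **Synthetic worlds** — paired embedding systems with mirrored structure
  (latent Gaussian clusters observed through per-modality isometries plus
  controllable noise) and density-biased acquisition tables, so the whole
  pipeline is testable without external data.

Embeddings are read from whitespace-delimited text (GloVe `.txt` dialect);
AoA tables from CSV. Training GloVe itself is out of scope — the package
consumes precomputed embeddings.

## Worked example

```python
import numpy as np
import alignsim as al

# a 60-concept synthetic world: mirrored visual/linguistic systems with
# noise coupled to concept density, and a density-biased AoA table
world = al.make_fixture("planted60")
d_vis, d_lin = world.pair.distance_matrices()
print(round(al.alignment_score(d_vis, d_lin), 3))

for condition in ("aoa", "control"):
    config = al.AgentConfig(agent_condition=condition, n_agents=30,
                            probes_per_month=30, seed=11)
    result = al.run_experiment(config, world.pair, world.table,
                               world.schedule)
    acc = result.summary.groupby("month")["mean_accuracy"].mean()
    print(condition, acc.round(3).to_dict())
```

prints

```
0.724
aoa {16: 0.828, 17: 0.812, 18: 0.803, 19: 0.81, 20: 0.812, 21: 0.819, 22: 0.811, 23: 0.816, 24: 0.811}
control {16: 0.723, 17: 0.725, 18: 0.718, 19: 0.751, 20: 0.776, 21: 0.773, 22: 0.779, 23: 0.808, 24: 0.813}
```

The true mapping's alignment score (0.72) is far above chance (0) despite
heavy noise, so forced-choice inference is possible at all; agents whose
vocabularies grow like children's (dense, early-acquired concepts first)
start around 83% accuracy with only 3 known concepts, some 10 points above
random-control agents, whose accuracy only catches up as their states grow
— the density advantage is strongest when little is known.

A command-line interface mirrors the library:

```sh
alignsim make-world --n-concepts 60 --density-bias 5 --seed 1 --out world/
alignsim simulate --visual world/visual_embeddings.txt \
    --linguistic world/linguistic_embeddings.txt --aoa-csv world/aoa_table.csv \
    --condition aoa --n-agents 30 --seed 1 --out runs/aoa.csv
alignsim train-agent --kind task_optimized --visual world/visual_embeddings.txt \
    --linguistic world/linguistic_embeddings.txt --aoa-csv world/aoa_table.csv \
    --epochs 40 --seed 1 --out runs/task_model.json
```

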