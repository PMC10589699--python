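# Methods

`alignsim` implements a systems-alignment account of early cross-modal
concept learning: an agent that knows some word–object mappings can infer
new ones by exploiting the fact that similarity relations among items are
mirrored across the visual and linguistic systems (second-order
isomorphism). This note records the model, the estimators, the synthetic
data the package is validated on, and the numerical and design choices
that were genuinely open.

## The alignment model

A *system* is the set of pairwise distances among concepts in one
embedding space. Given a visual system and a linguistic system over a
shared vocabulary, the **alignment score** of a candidate cross-system
mapping is the Spearman rank correlation ρ_s between the upper triangles
of the two pairwise distance matrices, with item order given by the
mapping. Average ranks are used for ties; a constant upper triangle makes
the correlation undefined and raises an error rather than returning 0, so
degenerate inputs surface loudly.

In the **two-alternative forced choice**, an agent holding a knowledge
state S (concepts with known mappings) sees two unknown words and two
unknown objects and must choose between the two possible pairings. Because
only the two probe items move between candidates, the decision reduces to
correlating concatenated *probe columns*: for each modality, the vector of
distances from each probe item to every member of S, concatenated in
candidate order (length 2|S|). The candidate with the higher correlation
wins; ties (equal within 1e-12) are broken uniformly at random and
flagged. The package also implements the full-score route (alignment score
over S ∪ {probes} for both candidates) and measures, rather than assumes,
the agreement of the two (the acceptance suite requires ≥ 99% agreement of
non-tied decisions on 500 random small worlds).

The minimum knowledge-state size for probing is 2: concatenated vectors
shorter than 4 entries make rank correlations fragile, and empirical
schedules start at 17 concepts, so the bound never binds at scale.

## Distance metric

The interconcept metric is Euclidean distance on raw embedding
coordinates, with cosine distance available by configuration. Nothing in
the alignment construction depends on this choice beyond the rank order of
distances; the switch exists so sensitivity can be checked.

## Acquisition schedules

The acquisition table holds cumulative monthwise production probabilities
p_{i,m} (the WordBank/MB-CDI item-trajectory layout), restricted to months
16–24, where the instrument tracks true vocabulary closely.
Non-monotone rows are clipped to their running maximum with a warning.
The monthly schedule is derived as N_m = round(Σ_i p_{i,m}) (ties rounded
away from zero), with per-month increments n_m by differencing: applied to
cumulative probabilities, the sum formula yields the cumulative count, and
differencing keeps the state sizes exactly consistent with it. On the
WordBank English (American) trajectories this gives cumulative counts
(17, 21, 36, 45, 49, 55, 68, 77, 83) over months 16–24 — 21 concepts
after month 17 and 83 after month 24.

**AoA agents** add n_m concepts each month, sampling one at a time without
replacement with probability proportional to p_{i,m} renormalized over
unacquired table concepts. If all remaining probabilities are zero (never
the case empirically, possible in synthetic tables), the distribution
falls back to uniform with a warning. **Control agents** sample uniformly
without replacement from the concepts outside the AoA set (a config flag
switches the pool to the full shared vocabulary instead). Probe pairs are
drawn fresh each month,
independently, from the unacquired AoA set (*aoa* condition) or the full
unacquired vocabulary (*unconstrained* condition).

Populations of agents (default 100; 30 in the bundled directional tests)
use independent per-agent RNG streams spawned from one seed, so results
are bitwise reproducible. Accuracy summaries report the mean across agents
with a normal-approximation 95% CI (mean ± 1.96·SEM); a percentile CI is
available by config. Probes per month defaults to 50 per condition: large
enough for stable per-agent accuracies, small enough for desk runs.

## Structural features

The neighborhood graph keeps concept pairs whose distance is strictly
below the 10th percentile (linear interpolation) of the upper-triangle
distance distribution; it may be disconnected. Knowledge-state features
are computed per modality and averaged (configurable to a single modality
or separate features):

- `degree_full`, `degree_knowledge` — mean member degree in the
  full-system graph / in the subgraph induced by the state (full-system
  threshold, restricted-subgraph degrees);
- `mean_dist_knowledge`, `min_dist_knowledge`, `min_dist_full` — mean over
  members of the mean/min distance to other members or to the full system;
- `mean_dim_coverage` — per-dimension span of the state divided by the
  full-system span, averaged over dimensions and modalities ("dimension
  coverage" admits several formalizations; the span ratio is the one this
  package uses, and zero-range dimensions are skipped with a warning);
- `skew_degree_knowledge` — adjusted Fisher–Pearson sample skewness of the
  within-state degree distribution (0 for constant inputs).

Clustering-coefficient and betweenness features exist behind a flag but
are excluded from classifier selection by default: they are far more
expensive than the rest and add little to the separation. State features
require ≥ 3 members (skewness needs three values).

The AoA-vs-Control **state classifier** is an L2-penalized logistic
regression (liblinear, max 10,000 iterations) on an 80/20 split, with
min-max feature normalization fitted on the training split only.
Recursive feature elimination is run for every feature count k; the k
minimizing the training-split AIC (computed from the log-likelihood, as
no installed routine provides AIC over an RFE path) is selected, and
held-out accuracy/precision/recall/F1 are reported.

## Generative agents

Both structural agents hold an internal model: targets x̂ and weights w,
one per feature, in normalized feature units. Feature normalization to
[0, 1] is min-max, fitted once per world on random states drawn at every
scheduled state size, so x̂ lives in a stable space across months.

To select a concept, the agent computes the feature matrix A of every
candidate-augmented state, scores s = −|A − x̂·1ᵀ|·w, standardizes the
scores within the candidate set, and samples from softmax(z/T) with
T = 5·10⁻². Two choices here were genuinely open:

- the deviation is **absolute**, not signed: under a signed deviation the
  score differs across candidates only by a constant in x̂, the softmax is
  then exactly independent of x̂, and the targets could never be learned —
  the absolute form is the only reading under which the "weighted distance
  from the target values" does what it says;
- "normalized scores" before the softmax means **standardization** to zero
  mean and unit variance within the candidate set, which makes the fixed
  temperature meaningful across worlds of different scales.

The candidate set keeps all acquired concepts and refills to 300 uniformly
from the unacquired remainder; for smaller vocabularies the candidate set
(300), held-out concept sets (59 each) and probe slates (750 pairs) scale
proportionally to vocabulary/418, with small floors. Generative
trajectories are seeded with two uniformly drawn concepts (state features
need ≥ 3 members including the hypothetical addition); the model drives
every later selection.

**AoA-Matched loss.** At each month's end the model's inclusion
probability vector (1 for acquired concepts, the current selection
probability for unacquired candidates, 0 for table concepts outside the
candidate set) is compared by total MSE against bootstrapped
acquisition tables: B = 1000 bootstraps by default, each the inclusion
proportion over 300 simulated AoA sequences, split 70/30 into training and
validation sets. Training uses Adam at learning rate 0.003.

**Task-Optimized (soft alignment) loss.** Each month the remaining
concepts are segmented into candidate set and held-out train/validation
sets; 750 probe pairs are sampled from each held-out set. For each pair,
the concatenated probe columns over the candidate set are rank-transformed
and correlated with a *weighted* Pearson correlation, each entry weighted
by the corresponding concept's inclusion probability (the outer-product
weighting restricted to probe-vs-candidate entries; probe items carry unit
weight). The raw loss is the mean margin s_incorrect − s_correct, bounded
in [−2, 2]. Training uses Adam at learning rate 0.01.

Losses are z-normalized per month (μ, σ estimated from 5000 by default
random-selection samples per month, matching each loss's construction)
and shifted by the z-score of the theoretical floor (0 for the MSE, −2
for the margin) so normalized losses are nonnegative. Since
z(raw) − z(floor) = (raw − floor)/σ, only σ affects optimization; μ is
retained for reporting. A degenerate σ = 0 raises.

**Gradients** are analytic reverse-mode chain rules in numpy (no autograd
dependency): both losses are differentiable in the selection
probabilities; gradients flow through the softmax, the score
standardization (whose shift-invariance makes the gradient of any feature
whose target lies outside the candidate range exactly zero), and the
absolute-deviation score. The feature matrix A and the distance ranks are
treated as constants at each step — the loss is linear in the
probability weights, so this is the exact gradient of the weighted
estimator given the step's ranks; a soft-rank variant is out of scope.
Discrete monthly sampling is handled by the expected-loss reading: the
month-end probability vector, not the sampled path, enters the loss.
Finite-difference agreement at relative tolerance 1e-4 is part of the
acceptance suite. Weights are unconstrained: a preference for high feature
values can be expressed either as (high target, positive weight) or (low
target, negative weight), so |w| is the importance magnitude. A
nonnegativity projection was tried and rejected: a weight clamped at zero
receives no target gradient and the feature dies permanently.

Training runs R = 5 restarts × 150 epochs by default (each epoch simulates
the schedule, backpropagating at each month's end); the restart with the
lowest validation loss averaged over the final 5 epochs is returned.
Sequence generation freezes the model and reruns the selection loop
without gradients; a greedy mode gives the zero-temperature limit.

## Synthetic worlds

The generator realizes the premise the analysis rests on — mirrored
similarity structure across modalities — with controllable violations:

- Latent concept positions are drawn from balanced Gaussian clusters
  (equal sizes, so density is a within-cluster property, not a cluster-size
  artifact), with a per-concept radial scale in [0.3, 2.2]: every cluster
  has a tight prototypical core and a sparser periphery.
- Each modality observes the latents through its own random orthonormal
  map (an isometry: with zero noise the two systems are exactly
  second-order isomorphic and the true mapping scores ρ_s = 1), plus
  Gaussian noise whose per-coordinate scale is σ·√(latent dim/embedding
  dim), so the expected distance perturbation is the same in the 10-d
  visual and 50-d linguistic spaces.
- Noise is coupled to density: a concept's noise scale is multiplied by
  1 + c·(1 − density rank/n). This emulates the empirical observation that
  long-range interconcept relations are less stable across embedding
  initializations than short-range ones — the property that makes dense
  neighborhoods valuable for alignment. c = 0 gives homogeneous noise.
- The acquisition table covers a configurable AoA subset of the
  vocabulary, drawn with log-odds increasing in β·z(density) (a
  Gumbel-max sample, uniform at β = 0); within the subset, onsets are
  density-ordered with logistic jitter and spread from just below month 16
  to beyond month 24, and each cumulative curve is a logistic ramp (width
  1.5 months). β = 0 removes every density effect.

Registered fixtures (bitwise stable, regenerated from seeds at test time):
`mirror10` (10 concepts, zero noise), `noisy30` (30 concepts, moderate
coupled noise), `planted60` (60 concepts, 4 clusters, noise 0.6 with
strong density coupling, β = 5). The planted60 onset margin is set so the
schedule acquires ~15 of 60 concepts — the same ~20–25% depletion of the
vocabulary as the empirical schedule (83 of 418) — because at desk scale
a schedule that consumes most of the AoA set empties the probe pools and
the experiment measures probe composition rather than knowledge-state
quality.

For the generative-vs-control comparison the package supports a held-out
**probe reserve**: a fixed, density-stratified concept set excluded from
every agent's acquisition and used as the sole probe pool, so all agent
types face an identical probe distribution. This matters only in small
vocabularies; at empirical scale the remaining-concepts pools are large
enough that the distinction is negligible.

What the synthetic worlds do **not** model: real lexical statistics
(frequency, phonology), category semantics, reporting noise in parental
inventories, or embedding-training artifacts. Passing the directional
tests shows the pipeline detects the planted structure it is pointed at —
it does not certify effect sizes on real embeddings.

## Problem sizes in the bundled runs

The test suite and the acceptance script run entirely on synthetic worlds
of 6–250 concepts, with 30-agent populations, 25–30 probes per month,
bootstrap sets of 4–20 tables, 100–800 normalizer samples, and generative
training of 40–100 epochs × 1–5 restarts. These sizes are the package's
chosen desk-scale study conditions; every default above (B = 1000, 5000
samples, 150 epochs, 100 agents) remains available for full-scale runs.

## Known limitations

- The probe-column shortcut is checked empirically, not proven, against
  the full score; rare rank-tie configurations can make the two disagree.
- The weighted-Spearman gradient treats ranks as locally constant; at rank
  crossings the loss is only piecewise smooth.
- `mean_dim_coverage` is an interpretation (span ratio); other readings of
  "dimension coverage" exist.
- Multiword vocabulary items are dropped on intersection unless an alias
  map is supplied.
- With highly collinear feature sets, largest-|w| attribution in the
  internal model reflects the optimization path as much as the data;
  parameter-recovery experiments use a low-collinearity feature set.
- The min-max feature normalization is fitted at the scheduled state
  sizes; feature values of states far outside that range are
  extrapolations, and the absolute-deviation score can behave
  unexpectedly there. Trained models are therefore evaluated at states
  drawn from the acquisition process they were trained on.
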