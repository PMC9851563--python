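# Methods

## The task

Two binary accept/reject categorisation tasks are defined over a shared
two-dimensional stimulus space. Stimuli are grayscale images of isotropic
Gaussian "blobs" whose peak varies in five discrete steps along x and y,
coded as feature levels {−2, −1, 0, 1, 2}. Accepting a stimulus yields a
signed reward equal to the level of the task-relevant dimension — x in
task 1, y in task 2 — so level 0 is the category boundary and its decisions
are arbitrary. A trial is *congruent* when both dimensions share a sign
(the correct response is the same under both rules), *incongruent* when the
signs differ, and a *boundary* trial when either level is 0; boundary trials
are excluded from all accuracy statistics and congruency contrasts.

The network input is the flattened 25-pixel image concatenated with a 2-unit
contextual cue ([1, 0] for task 1, [0, 1] for task 2 at test), giving 27
inputs. The full test set is the 50-condition grid (2 tasks × 5 × 5), in a
fixed task-major, x-then-y order used by every analysis.

### Stimulus rendering

The rendering pipeline behind the 25-pixel code is under-determined (an
image "flattened and downscaled" to 5×5, with unstated patch size and
Gaussian width). We evaluate the Gaussian directly on the 5×5 feature
lattice with σ = 1 lattice unit and unit peak amplitude; σ is a config
knob. This gives partial overlap of adjacent blobs, so the input code
carries metric structure (unlike a one-hot code). The qualitative phenomena
(convergence, forgetting, rescue by gating) are insensitive to σ in
[0.5, 2]; tests assert the rendering invariants across that range.

### Curricula

Within each task, the 25 feature combinations are cycled in seeded shuffled
order, so coverage is balanced at any trial count (this matters in the
200-trial human-scale regime). *Blocked* curricula present all task-1 trials
then all task-2 trials; *interleaved* curricula are a seeded uniform shuffle
of the union. Both contain identical trial multisets. Defaults are 5,000
trials per task (200 in the human-scale presets).

## The network and baseline training

A single-hidden-layer MLP: 27 inputs → 100 ReLU units → 1 sigmoid output
f(x, θ) read as an accept probability. Input-to-hidden weights are drawn
from N(0, 0.01) (std 0.1, small enough for the "rich" feature-learning
regime; the scale is config-exposed), readout weights from N(0, 1/n_hidden),
biases start at 0.

Training is strictly online SGD (one trial per update) on the reward loss

    J(θ) = −f(x, θ) · R,      R ∈ {−2, …, 2},

with learning rate ε (0.2 interleaved / 0.03 blocked at full scale).
Accuracy over a trial set is the fraction of non-boundary trials on which
the decoded decision matches the reward sign; a tie at f = 0.5 carries no
decision and counts as incorrect. This tie convention is what makes the
shared diagonal policy "accept iff x + y > 0" score exactly 14/20 = 70% per
task on the 5×5 grid (the four x + y = 0 ties are unscoreable); under the
naive rule 1[f > 0.5] == (R > 0) it would score 80%, because a tie decodes
as "reject" and is sometimes accidentally right. For trained networks the
two conventions coincide almost surely.

## Motif 1: sluggish task signals

The contextual cue is smoothed with an exponentially moving average

    s_t = x_t                       (t = 1)
    s_t = (1 − α) x_t + α s_{t−1}   (t > 1),

with carry-over α ∈ [0, 1). α = 0 recovers the baseline exactly (bit-for-bit
in the training loop, which tests assert). Under blocked curricula the cue
is constant within a block, so the EMA converges to the veridical cue and
sluggishness is nearly free; under interleaved curricula the smoothed cue is
a mixture of both contexts, which degrades credit assignment to the correct
context and produces the interleaving cost: accuracy falls with α, the
congruency effect grows, and the learned solution moves from a factorised
(one boundary per task) to a linear (single diagonal boundary) policy.

**Evaluation cues.** The 50-condition test grid is always evaluated with
veridical (non-sluggish) one-hot cues, because choice matrices require a
deterministic input per condition and no test-time smoothing rule is
defined for a randomly ordered test phase. A sequential "sluggish test"
can be emulated by passing explicit cue mixtures to `network_input`.

## Motif 2: Hebbian (Oja-rule) context gating

After every SGD step, the 2-column task-weight block W_task (task units →
hidden layer) receives an Oja update, per hidden unit j:

    w_j ← w_j + η y_j (x − w_j y_j),

where y_j is the unit's full pre-activation on that trial (before the ReLU)
and x is the 2-entry task signal. On zero-mean inputs Oja's rule converges
to the unit-norm leading principal component; with two alternating context
codes that component is the context *contrast*, so per-unit task weights
with opposing signs emerge. Passed through the ReLU, these anti-correlated
weights act as an additive gate: each hidden unit is pushed into its active
range in one context and below threshold in the other, partitioning the
layer into task-specific subnetworks. Units serving task 1 are silenced
during task-2 training, receive no gradient, and are thereby protected —
this is what rescues blocked training from catastrophic forgetting.

**Task-signal coding.** Oja's rule needs (approximately) zero-mean inputs.
To avoid leaking knowledge of the unseen second task into the first block,
the first task keeps its one-hot cue [1, 0] and the second task uses the
mean-centred task contrast [−1, 1] ("do task 2 while suppressing task 1").
We use the unit-magnitude contrast rather than the halved code [−0.5, 0.5]:
the effective Oja rate scales with the squared signal, so the halved code
forms the gate a factor ~4 more slowly, too slowly to protect the first
task within a block at the reference rates (ε = 0.0377, η = 0.00021,
5,000-trial blocks). A fully symmetric scheme ([1, −1] / [−1, 1]) is
available via `centring_scheme="symmetric"` and behaves equivalently.

**Order within a trial:** forward pass → SGD update → Oja update, with y_j
taken from the forward pass. The Hebbian step touches only the task-weight
block; applying it to the full input matrix is out of scope (it is unstable
on richer inputs).

**Manual gating control.** The hand-crafted counterpart sets the
task-weight block to [+1, −1] for odd-numbered hidden units and [−1, +1]
for even-numbered ones, freezes the block, and trains the rest by SGD
(ε = 0.01). It serves as the ceiling reference for what gating can achieve.

**Block-length sensitivity.** With rates held fixed, retention degrades as
blocks grow (the Oja decay term slowly erodes the gate during the second
block) but remains above the no-Hebbian baseline even at double length;
`block_length_sweep` reproduces this.

## Human-scale regime and decision noise

For comparisons with behaviour-sized experiments, runs use 200 trials per
task and the reference rates ε = 0.0905 / η = 0.0026 (blocked) and
ε = 0.0926 / η = 0.000327 (interleaved), combined with sluggishness
(`sluggish_hebbian` variant). Residual (non-ceiling) performance is
modelled at test by a temperature on the logit, p = logistic(logit / T),
from which choices are sampled (10,000 Bernoulli draws per condition by
default). `grid_search_behaviour_fit` fits (α, T) to a target choice matrix
by minimising the mean squared discrepancy between 2×5×5 choice matrices —
the discrepancy measure is our choice; nothing finer is specified.

## Analysis suite

**Choice matrices** are the per-condition accept probabilities (or sampled
choice fractions), shaped (2, 5, 5).

**Sigmoid fits** average choices across tasks within the five bins of the
relevant (or irrelevant) dimension and fit the lapse-bounded logistic
σ(x) = L + (1 − 2L)/(1 + e^{−k(x − x0)}) by bounded least squares
(L ∈ [0, 0.5], k ≥ 0); the standard logistic is the only sigmoid used
anywhere in the package. Constant bins
(e.g. the irrelevant dimension of a perfect agent) return a flagged flat fit.

**Factorised/linear choice models**: model matrices with entries 1 / 0.5 / 0
for rewarded / boundary / punished conditions under per-task rules
(factorised) or the shared diagonal rule (linear). Each 50-vector yields a
50×50 RDM of absolute differences; the empirical choice RDM's z-scored
lower triangle is regressed jointly on both model RDMs plus an intercept.

**Psychophysical model**: five parameters (θ_a, θ_b, L, k, x0). Stimulus
coordinates are projected onto the boundary normal of each task
(X · [cos θ, sin θ]ᵀ) and passed through the lapse-logistic transducer; the
loss J = −Σ log(1 − |y − ŷ|) is minimised by L-BFGS-B with bounds
θ ∈ [0, 359]°, k ∈ [0, 20], x0 ∈ [−1, 1], L ∈ [0, 0.5]. Predictions are
clipped away from {0, 1} by 1e−6 to keep the loss finite. The loss is
multimodal in the angles, so the optimiser is restarted from the best 8
cells of an 8×8 coarse angle grid. The reported *angular bias* is the mean
absolute deviation of (θ_a, θ_b) from the true normals (0°, 90°), folded to
[0°, 90°] (θ and θ + 180° describe the same boundary); signed per-task
deviations are also exported.

**Task selectivity**: per hidden unit, post-ReLU test-grid activity is
regressed on four predictors (relevant/irrelevant level per task, zeroed
outside the task). A unit is task-k selective iff it is active in task k
(mean activity above 5% of the layer's grand-mean activity), near-silent in
the other task (below that floor), and |β_relevant| strictly exceeds
|β_irrelevant| with |β_relevant| above a small magnitude floor (0.01).
The thresholds are genuinely open — no exact operationalisation is fixed by
the definition — so all three are config-exposed
(`SelectivityThresholds`); the defaults are the plainest reading of the
verbal definition and are exact on noise-free constructed units. The
resulting selective fraction (~19% after full-scale interleaved baseline
training) is threshold-sensitive, which the wide acceptance band reflects.

**Hidden-layer RSA**: 50×50 Euclidean-distance RDMs over post-ReLU
patterns, regressed (z-scored lower triangles, with intercept) on three
model RDMs built from the coordinate rows (t, x, y), t ∈ {0, 1}:
*grid* (all coordinates), *orthogonal* (each task keeps the task coordinate
and its own relevant dimension: task 1 keeps (t, x), task 2 keeps (t, y)),
*diagonal* (both tasks keep (t, (x + y)/√2)). Group inference uses one-sample t-tests
of run-level betas against zero; two-group contrasts use Welch's t.

**Classical MDS** is Torgerson's method (eigendecomposition of the
double-centred squared-distance matrix), eigenvalue-ordered, with no manual
rotation; strongly negative eigenvalues raise an error.

## Synthetic choice agents

`make_synthetic_agent` provides the fixtures that stand in for behavioural
data: *factorised* (perfect per-task step policies), *diagonal* (accept iff
x + y > 0; exactly 70% correct per task), and *noisy* (a policy passed
through a lapse-logistic with chosen L, k, x0 and binomial sampling at a
chosen n). These exercise the fitting stack end-to-end; they emulate the
structure of real choice data (bounded fractions, binomial noise, lapses)
but not sequential effects, learning within the test phase, or individual
differences — passing recovery tests therefore validates the estimators,
not any claim about human participants.

## Problem sizes and defaults

Suites default to 20 runs per cell (the full-scale reference is 50, one
flag away); the sluggishness sweep uses the 20-point α grid [0, 0.95] at 10
seeds per point; recovery suites use 50 synthetic datasets at 10,000
choices per condition. Experiment presets: fig2 (baseline blocked vs
interleaved), fig3 (α sweep), fig4 (manual gating), fig5 (Hebbian blocked),
fig6 (human-scale model comparison), fig8 (high-α sluggish-Hebbian blocked
vs interleaved, α = 0.9 as a representative "very sluggish" value),
s1 (block-length sweep).

## Known limitations

* The Hebbian mechanism requires the context signal to dominate the
  mean-centred input variance seen by the Oja step; it is applied only to
  the task-weight block here, and the full-input variant is out of scope.
* Gate stability is rate- and block-length-sensitive; the defaults are
  calibrated for 5,000-trial blocks.
* Selectivity fractions depend on classifier thresholds (see above).
* The RGB tree-image simulations, RNN extensions and re-analysis of the
  original human dataset are out of scope; synthetic agents replace the
  latter.
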