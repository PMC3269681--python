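# Methods

## Model

Every node — gene transcript, imaging-derived morphology parameter, or
exposure dose — carries positive values whose natural logs are jointly
modelled by a linear Gaussian structural equation on a directed acyclic
graph: the conditional mean of `log G_j` is `Σ_i I_ij β_ij log g_i`
over its parents, with conditional variance `σ_j²`. There is no
intercept: the model assumes values are normalized so that a node with
no parents has log-mean zero. All node kinds are treated identically by
the likelihood; "gene → phenotype" directionality is learned, not
imposed.

Assumptions worth stating plainly: samples are i.i.d. within a
condition; dependencies are linear in log space with additive Gaussian
noise; no latent confounders; each condition is fit independently
(condition-to-condition similarity enters only at the classification
step).

## Priors and their defaults

The study protocol this reproduces reports sweep counts and thresholds
but no prior hyperparameters, so the package uses standard weakly
informative proper conjugate choices, all overridable in
`SamplerConfig`:

| parameter | meaning | default | why |
|---|---|---|---|
| `edge_prior` π | prior edge inclusion probability | 0.1 | sparse prior; ~0.1·P(P−1) expected edges keeps 28-node graphs interpretable |
| `beta_prior_var` τ² | scale of `β | σ² ~ N(0, τ²σ²)` | 1 | coefficients of order 1 on log-normalized data |
| `ig_shape`, `ig_scale` | InvGamma prior on σ² | 2, 1 | proper, prior mean 1, weak (2 pseudo-observations) |
| `max_parents` | in-degree cap | 4 | computational guard; biologically few direct regulators dominate |
| `n_iterations` / `n_burn_in` | Gibbs sweeps / discarded | 40,000 / 15,000 | inside the protocol's reported 33,000–48,000 total and 18,000–26,000 retained |
| `n_chains` | independent pooled chains | 1 | raise to 2–4 for large node counts (see mixing note) |

The β prior is deliberately scaled by σ_j² (normal–inverse-gamma
coupling) rather than fixed at τ²: this is what makes every per-node
marginal likelihood closed-form, which the collapsed structure moves,
the blocked parameter draws, and the enumeration oracle all rely on.

One consequence of `τ² = 1` with a no-intercept model deserves a
warning: if the data vary on a scale far below 1 in log space, `ZᵀZ`
is small against the prior precision and coefficients are shrunk hard,
so even a deterministic dependency can receive a modest linkage
probability. This is correct Bayesian behaviour under that prior, not a
bug — but it means data should reach the learner on roughly unit log
scale, or τ² should be widened to match.

## Sampler

One sweep is:

1. **Structure.** For each unordered node pair `{i, j}`, in an order
   re-permuted every sweep, the joint state of the two indicators
   `(I_ij, I_ji)` is resampled from its exact full conditional over the
   admissible states {no edge, i→j, j→i}, with both nodes' `(β, σ²)`
   integrated out analytically. States that would create a directed
   cycle, or push a node past `max_parents`, get probability zero —
   equivalent to a structure prior with zero mass there. The pairwise
   block matters: one-indicator-at-a-time flips cannot cross between
   the two orientations of a well-supported edge, because the
   intermediate no-edge state can be astronomically improbable; with
   the block, orientation is a single move and measured agreement with
   the exact oracle tightens from ~1.0 to ~0.01 in edge probability.
2. **Parent blocks.** Per node, a randomly chosen (state-independently)
   subset of four candidate parents has its edge indicators resampled
   *jointly* from their exact conditional, enumerating all admissible
   combinations. This is the move that crosses between "parent
   substitution" modes — two highly correlated ancestors explaining a
   node about equally well — which pairwise moves alone traverse so
   rarely that independent chains disagree for thousands of sweeps.
3. **Parameters.** Per node, `(σ_j², β_j)` is drawn exactly from its
   joint conditional given the structure: `σ_j²` from its collapsed
   inverse-gamma, then `β_j | σ_j²` from its normal. Draws are
   conditionally independent across sweeps, so with a fixed structure
   the β chain is i.i.d. from the true posterior.

Acyclicity is maintained via an incrementally updated transitive
closure and independently re-checked in the tests with networkx.
Chains start from the empty graph; with `n_chains > 1`, independent
chains (sub-seeded deterministically from `seed`) are pooled, which
further smooths over any residual mode-stickiness at larger node
counts. All randomness flows from a
single integer seed; identical seed and inputs give bit-identical
summaries.

`exact_posterior_small` enumerates all labelled DAGs (3 / 25 / 543 /
29,281 for P = 2–5), weighs each by its closed-form marginal likelihood
times the structure prior, and returns exact edge marginals plus
mixture summaries of the coefficient posteriors (Student-t per parent
set). It exists purely as an oracle: the sampler never consults it.

## Network extraction and thresholds

An ordered pair becomes a *down* edge when `edge_prob ≥ 0.47` and the
posterior probability that its coefficient is negative is ≥ 0.5, and an
*up* edge when `edge_prob ≥ 0.995` and the negative-sign probability is
< 0.5. The asymmetric defaults reproduce the source protocol, which
states ranges (0.995–1.0 up, 0.47–1.0 down) without a tuning rule; both
thresholds and the sign cut are therefore plain parameters. Sign
assignment by sign-probability rather than by the sign of the mean
coefficient is a package choice (the protocol does not say); the mean
coefficient is exported alongside every edge so either convention can
be audited. Note the consequence of the asymmetry: an edge whose
orientation the data genuinely cannot decide (posterior split ~0.5/0.5)
can still be reported as a down edge but never as an up edge.

## Classification

Per condition, the `P(P−1)` off-diagonal linkage probabilities (fixed
row-major pair order) form one row of a condition-by-pair table; the
table is column-centered (scaling optional — probabilities already
share a scale) and decomposed by SVD. Scores, loadings and explained-
variance ratios are reported with a deterministic sign convention
(largest-|loading| entry of each component made positive), so results
are bit-reproducible without any RNG. Distance from the named control
condition is Euclidean in the retained component space. An exact
k-medoids grouping is provided as a labelled convenience; the source
study grouped conditions by eye on the score plot.

## Synthetic studies

The generator emulates the study design, not its biology: a
ground-truth DAG over 18 gene nodes (the autism gene panel) plus the 10
imaging parameters; per-condition perturbations (edge additions,
removals, coefficient sign flips, log-mean shifts) standing in for
chemicals; log-linear Gaussian data drawn in topological order and
exponentiated. The "paper-like" preset has a control plus 12 conditions
in three 4-condition mechanism motifs sharing structural perturbations,
with a small condition-specific mean shift each — built so that
classification *should* group motifs, which is exactly what the
acceptance tests verify.

Default generation parameters: 50 samples per condition (150 for the
structure-recovery benchmark), noise SD 0.2 on every node's log scale,
coefficient magnitudes ±Uniform(0.8, 1.5), base density 0.12, and
ground-truth in-degree capped at 3. The last choice is deliberate
benchmark hygiene: with the truth sitting exactly at the learner's
4-parent capacity, correlated ancestors substitute for true parents and
edge identity becomes genuinely unidentifiable — the exact posterior
itself prefers the substituted sets — so a recovery benchmark must keep
the truth strictly inside the learner's support.

What the generator does **not** emulate: probe-level measurement error,
normalization artefacts, non-linear saturation, latent confounding,
unequal replicate counts (available only as an explicit
aggregate-to-condition-means mode), and real regulatory biology.
Passing tests therefore demonstrate that the inference machinery is
correct and well-calibrated under its own assumptions — not that those
assumptions hold for any particular assay.

## Problem sizes and numerical choices

Tests and the acceptance script run reduced problem sizes chosen to
exercise the full pipeline: oracle comparisons at P = 3–4 with 20,000
retained sweeps; structure recovery at 28 nodes with 4 pooled chains of
5,000 retained sweeps each (20,000 pooled, inside the production
retained range); the 13-condition classification with 2 pooled chains of
1,200 sweeps per condition. Production-scale defaults (40,000 sweeps)
remain the config defaults. Other numerical details: values below a
floor (default 1e-6) are clipped before the log transform and counted;
quadratic forms are guarded against tiny negative round-off;
explained-variance ratios are defined as zero when total variance is
numerically zero; ties in hub scoring break lexicographically.

## Known limitations

* Single-condition fits ignore shared structure across conditions; a
  hierarchical variant would borrow strength but is out of scope.
* Edge orientation for covered pairs (no v-structure context) is only
  weakly identified — through the equal-variance asymmetry of the
  marginal likelihood — and with modest n the posterior rightly splits
  across orientations; the stringent up-threshold then drops such
  edges.
* Dose can be included as a node, but the package does not model
  dose–response shape.
* The enumeration oracle is exponential and hard-capped at 5 nodes.
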