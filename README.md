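# gpinet

Bayesian network analysis linking early gene-expression changes to later
neuronal phenotypes under chemical exposure — the multi-parametric
profiling approach used in developmental neurotoxicity screening with
mouse embryonic stem cells.

## Who this is for

Toxicologists and systems biologists who profile a differentiation assay
two ways — transcript levels early (microarray/RNA panels) and
high-content imaging morphology late (neurite length, branch points,
neurosphere geometry, ...) — and want a single directed network per
exposure condition connecting both layers, plus a low-dimensional map
that groups chemicals by how they rewire that network.

## The model

For nodes `G_1 … G_P` (gene, phenotype, and optionally dose nodes) with
positive observed values, each node's natural log is conditionally
Gaussian given its parents in a directed acyclic graph:

```
E[log G_j] = Σ_{i≠j} I_ij · β_ij · log g_i ,   log G_j ~ N(·, σ_j²)
```

`I_ij ∈ {0,1}` indicates a directed edge `G_i → G_j`. Priors are
conjugate per node — Bernoulli(π) edge indicators truncated to acyclic
graphs with at most `max_parents` parents, `σ_j² ~ InvGamma(a₀, b₀)`,
and `β_ij | σ_j² ~ N(0, τ²σ_j²)` — so structures carry closed-form
marginal likelihoods. A collapsed Gibbs sampler (blocked over the two
orientations of each node pair, node parameters integrated out) yields
the **posterior linkage probability** of every directed edge: the
fraction of retained sweeps in which the edge is present.

Downstream:

* **Network extraction** — an edge enters the reported gene–phenotype
  interaction network as *up*-regulating when its linkage probability
  passes a stringent threshold (default 0.995) with a predominantly
  positive coefficient, or as *down*-regulating past a separate
  threshold (default 0.47) with a predominantly negative one.
* **Condition classification** — each condition's off-diagonal linkage
  probabilities form a `P(P−1)`-vector; PCA over the condition-by-vector
  table places conditions in a score map where chemicals with similar
  network effects cluster and distance from the control (e.g. DMSO)
  measures effect strength.

A synthetic-data module generates ground-truth DAGs and
chemical-like perturbed conditions with exactly the statistical
structure the model assumes, so the full pipeline is testable with no
external data. An exact posterior by whole-DAG enumeration (≤ 5 nodes)
serves as an independent oracle for the sampler.

## Worked example

```bash
gpinet run-all --preset tiny --iterations 2000 --burn-in 500 \
    --seed 7 --outdir demo
```

prints

```
wrote 3 condition matrices to demo/scenario
wrote 3 posterior summaries to demo/posteriors
wrote 3 networks to demo/networks
wrote PCA tables and score plot to demo/classification
pipeline complete under demo
```

`demo/scenario` holds one matrix per condition (control plus two
perturbed conditions over 4 gene + 4 morphology nodes) and the
ground-truth edge lists that generated them. `demo/posteriors/control/
edge_prob.tsv` is the 8×8 posterior linkage-probability matrix —
entries near 1 are edges the sampler considers certain.
`demo/networks/control.edges.tsv` lists the thresholded signed edges,
and `diff_condA_vs_control.txt` summarizes edges gained, lost, and
sign-flipped relative to control, plus nodes disconnected in either
network — at these short-chain demo settings the stringent up-threshold
keeps the extracted networks deliberately sparse and conservative.
`demo/classification/scores.tsv` holds one PC-score row per
condition, with `condition_map.tsv` ranking conditions by distance from
control in the score space and `scores.png` the PC1–PC2 scatter. Every
output directory contains a `manifest.json` with the seed and a SHA-256
hash per file; re-running with the same seed reproduces every hash.

The full-scale study analogue is `--preset paper-like`: a control plus
twelve chemical-like conditions over 18 autism-panel gene nodes and the
10 imaging parameters, with three perturbation motifs shared by
condition subsets (the classification map should, and in tests does,
group them).

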