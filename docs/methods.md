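# Methods

## Model

Transcription of each gene is described by the linear splicing system
du/dt = α(t) − βu, ds/dt = βu − γs, with transcription rate α(t),
splicing rate β and degradation rate γ. Instead of specifying α(t)
and integrating forward, the spliced mean is modelled directly as a
radial basis function of latent time,

    s_g(t) = h_g exp(−a_g (t − τ_g)²) + o_g,

and the unspliced mean follows by rearranging the second ODE:
u_g(t) = (s_g′(t) + γ_g s_g(t)) / β_g + i_g. Velocity is the exact
derivative of the spliced mean, (s_g(t) − o_g)(−2a_g(t − τ_g)) — the
constant offset drops out of the derivative. A variant that
multiplies the full s_g(t) (offset included) is available via
`velocity(..., include_offset=True)` for compatibility with
conventions that define it that way; the two agree when o = 0.

A single RBF family covers the three kinetic regimes seen along a
differentiation window rescaled to [0, 1]: a peak before the window
(τ ≤ 0) leaves only decay (repressed), a peak after it (τ ≥ 1) only
rise (induction), and an interior peak gives rise-then-fall
(transient). This classification is read directly off the fitted τ.

Observation noise is isotropic Gaussian in the (u, s) plane with
per-gene precision b = 1/(√(2π)σ); the negative log-likelihood per
gene is π b² Σᵢ |xᵢ − x̂ᵢ(t)|² − log b. One b is shared between the u
and s residual dimensions; since σ enters only through b, a poor fit
simply drives the fitted b down.

## Inference

Parameters and times are inferred by alternating optimization:

* **Gradient phase.** Adam (lr 0.01, β₁ 0.9, β₂ 0.999) updates all
  eight per-gene parameters against the summed loss at fixed times.
  Gradients are analytic and vectorized over cells × genes; h, a, γ,
  β, b are optimized in log space to stay positive.
* **Assignment phase.** Every 10 iterations, each cell is re-assigned
  per gene to the time on an even 100-point grid in [0, 1] minimizing
  the squared (u, s) distance to the trajectory; ties take the
  smallest candidate. In unified mode the per-gene matrix t_ng is
  pooled into one time per cell by averaging per-gene fractional
  ranks ((rank − 0.5)/N, ties averaged), with an optional SVD denoise
  (top 50 singular vectors, active when more than 100 genes are
  fitted), then min–max rescaled to [0, 1]. In independent mode t_ng
  is used directly and (τ, o, i) are frozen at (0.5, 0, 0).

Initialization: τ = 0.5 for every gene (non-informative: assumes both
induction and repression were experienced), h from the observed
spliced range, o and i from the layer minima, rates at 1, and the
initial cell ordering from the rank of total smoothed spliced
expression.

Two scheduling details matter and are deliberate design choices:

* **Warmup (default 300 steps).** The first time re-assignment is
  delayed so the portraits can adapt to the initial ordering first.
  Re-assigning immediately — when every gene still peaks at τ = 0.5 —
  maps both ends of the trajectory onto similar positions and folds
  the ordering irrecoverably.
* **Orientation pilot.** The model family is nearly symmetric under
  time reversal (t → 1 − t, τ → 1 − τ); only the unspliced channel
  breaks the tie, because nascent transcription leads splicing.
  Unified-mode fitting therefore runs warmup + 100 steps from both
  orientations of the initial ordering and continues the one with the
  lower loss. On the reference simulation the correct orientation
  wins by a wide margin (loss 1061 vs 1935), and with it gene classes
  and velocity signs are recovered; without it the optimizer can
  settle in the reversed basin.

Convergence: the run stops when the proportional change of the total
loss between consecutive re-assignment events falls below 10⁻⁴, or at
`max_iters` (default 12,000). The cycle-level check is intentional: a
per-iteration check fires on transient Adam plateaus long before the
portraits settle. A loss exceeding 10× its initial value aborts with
diagnostics. Optimizer state persists across re-assignments.

## Preprocessing

Genes need ≥ 20 cells with both spliced and unspliced counts; both
layers are size-normalized per cell to the median total (each layer
by its own size factors, preserving within-cell proportions). Up to
2,000 highly variable genes are kept by mean-binned normalized
dispersion. PCA (30 components) on log1p spliced values defines a
Euclidean KNN graph (30 neighbors, self included — including the cell
stabilizes small neighborhoods and makes k = 1 the identity); Ms/Mu
are neighborhood means of the normalized layers. Velocity genes are
HVGs whose zero-intercept regression of Mu on Ms (the steady-state γ
estimator) has slope > 0.01 and R² > 0.01, with sd(u)/sd(s) in
[0.03, 3]; σ-ratio and regression use the smoothed layers. An
optional expansion (`agenes_r2`) adds excluded HVGs whose spliced
profile regresses on the interim unified time with R² above the
threshold, followed by a refit; it is a no-op in independent mode.
HVG selection runs after the coverage filter.

## Mode selection

Unified time is the default. `choose_mode` recommends independent
mode when either trigger fires: more than half of the S-phase or
G2M-phase marker list appears among the HVGs (cell-cycle structure
breaks a single shared ordering), or strictly more than 2 clusters
have mean within-cluster KNN purity above 95% (disconnected
manifolds). Purity is aggregated as the mean over member cells. The
shipped marker lists are the standard curated human S/G2M symbol
sets; both files are user-replaceable, and the count trigger,
cluster-count and purity thresholds are parameters.

## Evaluation

Per-gene R² = 1 − MSE/Var of the smoothed spliced layer at the
assigned times (negative for fits worse than the gene mean). For
direction metrics, gene-space velocities are projected onto a 2-D
embedding by the standard transition-probability scheme: per cell,
cosine similarities between its velocity and expression displacements
to KNN neighbors are softmax-weighted (temperature 1/mean|cos| per
cell) and applied to embedding displacements. Cells with zero
velocity project to zero. CBDir averages, over boundary cells of a
source cluster (cells with ≥ 1 neighbor in the target cluster), the
mean cosine between the projected velocity and displacements to
target-cluster neighbors; pairs without boundary cells are reported
missing, not zero. Both the unweighted per-pair mean and the
boundary-cell-weighted mean are exposed. ICCoh is the mean cosine of
a cell's velocity with same-cluster neighbors; it is invariant to
global negation of the low-dimensional field (not to re-projection of
negated gene-space velocities, which changes the softmax weights).

## Down-sampling

`stratified_downsample` keeps max(min_per_cluster, frac · size) cells
per cluster (default minimum 50), so every cluster stays represented.
Held-out cells are projected onto the frozen trajectories with the
training grid search; per gene, each held-out time is mapped through
the mid-rank empirical CDF of the training assignments and the
quantiles averaged, keeping held-out unified times on the training
[0, 1] scale.

## Synthetic data

The generator forward-simulates the model: cell times uniform (or
Beta) on [0, 1]; per-gene portraits drawn by class — induction
τ ∈ (1.05, 1.5), repression τ ∈ (−0.5, −0.05), transient
τ ∈ (0.3, 0.7), mix 35/35/30 — with h ∈ (1, 5), a ∈ (1, 4),
γ ∈ (0.5, 2), β ∈ (2, 6), o = i = 0. The kinetic ranges are set so
unspliced magnitudes are a modest fraction of spliced ones, matching
real normalized layers (the regime the γ/R²/σ-ratio filters
presuppose). Gaussian noise with sd = 10% of each gene's amplitude is
truncated at zero for count realism. Cells are binned along true time
into ordered cluster labels whose consecutive pairs serve as
ground-truth transitions. An optional MURK-like stressor multiplies
late-time (t > 0.7) expression of a subset of induction genes by up
to 3×, emulating transcriptional boosting.

What the simulation does not emulate: count-level sampling
(Poisson/NB capture, dropout), batch structure, doublets, branching
trajectories, or gene-gene correlation beyond the shared time.
Passing recovery tests therefore demonstrates correctness of the
estimator under its own generative assumptions, not robustness to
every real-data pathology.

## Problem sizes and numerical choices

The reference recovery experiment uses 500 cells × 200 genes at 10%
noise with a 3,000-iteration budget; the down-sampling experiment
uses 5,000 cells × 100 genes with 1,200 iterations — both comfortably
past the loss plateau for these sizes. Degenerate inputs: constant
genes get amplitude floored at 10⁻³ and are flagged; zero-variance
genes are excluded from filters (undefined ratios) and reported
missing in R²; empty held-out sets return empty outputs; unified
times collapse to 0.5 when all cells tie. Grid-search ties resolve to
the smallest time; quantile transforms average ties.

## Known limitations

Direction identification relies on the unspliced channel; datasets
where nearly all selected genes are transient and symmetric about
τ = 0.5 give the pilot little signal. The unified ordering assumes
one global trajectory — cyclic or strongly branched topologies
violate it, which is exactly what `choose_mode` screens for.
Down-sampled prediction is validated on densely populated simulated
manifolds; accuracy on rare-population-heavy data is not claimed.
Loom input is not supported; convert to `.h5ad` or MTX triplets.
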