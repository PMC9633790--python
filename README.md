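# rbfvelo

RNA velocity estimation for single-cell transcriptomics with a
spliced-RNA-oriented model: each gene's spliced abundance is a radial
basis function (RBF) of a latent differentiation time shared by all
genes, and velocity is the closed-form derivative of that fit.

## Who this is for

Researchers quantifying the direction and speed of cell-state change
from spliced/unspliced count layers (10x + velocyto/kallisto-style
output). Classical steady-state and dynamical velocity models
parameterize transcription rates first and derive expression; they
struggle with genes whose phase portraits are distorted by late
transcriptional boosting (multiple rate kinetics) and with datasets
where most genes change monotonically. This package inverts the
design: it models spliced expression directly as a function of time
and derives the unspliced profile through the splicing ODE.

## Model

For gene *g* with parameters θ_g = (h, a, τ, γ, β, b, o, i) and cell
time t ∈ (0, 1):

```
s_g(t) = h · exp(−a (t − τ)²) + o                 spliced mean
u_g(t) = (s_g′(t) + γ s_g(t)) / β + i             unspliced mean (from ds/dt = βu − γs)
velocity_g(t) = ds_g/dt = (s_g(t) − o) · (−2a (t − τ))
```

Residuals in the (u, s) plane are Gaussian with per-gene precision
b = 1/(√(2π)σ), giving the per-gene loss
`π b² Σᵢ |xᵢ − x̂ᵢ(t)|² − log b`. Fitting alternates Adam gradient
steps on θ_g (analytic gradients, positivity by log-parameterization)
with periodic grid-search re-assignment of cell times by projection
onto the current phase trajectories. In **unified-time mode** the
per-gene assignments are pooled into one shared time per cell by
quantile averaging (`t_n = (1/G) Σ_g Q[t_ng]`, optional SVD denoise);
in **independent mode** each gene keeps its own time and (τ, o, i)
stay fixed at (0.5, 0, 0). The peak time classifies each gene:
repressed (τ ≤ 0), induction (τ ≥ 1), transient (0 < τ < 1).

Model quality is reported as per-gene R² of the spliced fit, and
trajectory direction as CBDir (cross-boundary direction correctness
against user-supplied cluster transitions) and ICCoh (in-cluster
velocity coherence).

## Worked example

`examples/01_simulate_and_fit.py` simulates 300 cells × 100 genes from
the generative model (10% amplitude noise), preprocesses, fits, and
compares with the simulation truth:

```
velocity genes selected: 62 / 99
final loss: 294.0 after 2000 iterations
Spearman(inferred latent time, true time) = 0.998
gene-class accuracy (repressed/induction/transient by peak time): 98.39%
```

The Spearman correlation says the inferred shared cell ordering
reproduces the simulated differentiation axis (sign included — the
unspliced channel identifies the arrow of time); the class accuracy
says the fitted peak times sort genes into the correct kinetic
regimes. The other scripts in `examples/` cover phase-portrait
inspection, mode selection, direction metrics, and down-sampled
fitting with held-out prediction.

The same pipeline runs from the shell:

```bash
rbfvelo simulate --output sim.h5ad --n-cells 500 --n-genes 200 --seed 1
rbfvelo run --input sim.h5ad --mode auto --seed 1
```

Inputs are `.h5ad` files or MTX-triplet directories with `spliced` /
`unspliced` layers and a cluster column; outputs are written back as
`.h5ad` with a `velocity` layer, `latent_time` per cell, and per-gene
fit annotations.

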