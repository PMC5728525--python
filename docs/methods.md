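# Methods

## The search problem

A multilayer perceptron maps 3 inputs to 6 outputs through *k* hidden
layers. Its structure is parameterised by the number of hidden layers
(1–3), the neuron count of each hidden layer (NHL, levels 3–27 in steps of
3), and the activation function of each weight stage (AF ∈ {tan-sig,
log-sig, linear}, coded 1/2/3). Each stage ℓ computes
`act_ℓ(W_ℓ x + b_ℓ)`; there are k + 1 stages, the last being the output
layer, which is why a k-hidden-layer group carries k + 1 AF factors.

The method is an exhaustive designed experiment: every combination of
factor levels is a treatment, evaluated exactly once (a full factorial
without repetition). Group sizes are 9·3² = 81, 9²·3³ = 2 187 and
9³·3⁴ = 59 049. For the single-hidden-layer group a reduced 7-level preset
(NHL ∈ {3..21}, 63 treatments) is provided as well; the published analysis
of that group used 63 treatments and 6 NHL degrees of freedom, which is
consistent with 7 levels rather than the 9-level grid, and the contiguous
choice 3..21 is the natural reading. Both layouts are exposed; neither is
silently merged into the other.

Enumeration order is mixed-radix with the rightmost factor varying fastest
(factor order NHL1..NHLk, AF1..AF(k+1)). The order itself is a free choice
— the original combinations were produced by an external statistics
package whose ordering is not documented — but fixing it buys exact
reproducibility: row indices are stable identifiers, seeds can be derived
from them, and serialized tables are byte-identical across runs.

## Training and scoring

The evaluation loop for one treatment: build the network, train it on the
training partition, score SSE on the evaluation partition.

- **Objective.** SSE summed over samples and output variables. With
  normalisation on (default), inputs and targets are min-max scaled to
  [−1, 1] and SSE is computed and reported on that scale, which makes the
  six outputs (whose raw ranges differ by two orders of magnitude)
  commensurable. Normalisation bounds are estimated from the training
  partition and stored on the network, so raw-scale prediction remains
  available through the inverse map.
- **Optimiser.** Full-batch gradient descent with classical momentum
  (defaults: learning rate 0.01, momentum 0.9, max 500 epochs, stop early
  when training SSE ≤ 1e−4). The reference implementation this mirrors
  delegated training to a toolbox whose settings are not documented; plain
  momentum descent is chosen as the simplest deterministic, dependency-free
  trainer, and the optimiser slot in `TrainConfig` is an identifier so
  alternatives can be registered. The gradient is *averaged over samples*
  (the objective is still the summed SSE); this decouples the stable
  learning-rate range from the dataset size, so one default works from
  10-sample tests to the 252-sample study scale.
- **Initialisation.** Default "small-random": weights and biases uniform in
  [−0.5, 0.5], seeded by (master seed, design row index) only. A "zero"
  scheme is also provided because the source procedure states parameters
  were initialised to zero; under gradient training zero initialisation
  provably keeps all hidden units of a layer identical (their incoming
  gradients coincide), a pathology the test suite documents, so it is not
  the default.
- **Split.** 70 % training / 30 % validation by a permutation derived only
  from the master seed — identical for every treatment, so validation SSE
  is comparable across the sweep. Whether the original scores were computed
  on training, validation or all data is not stated; held-out scoring is
  the defensible default and `eval_on="training"` is available.
- **Divergence.** A non-finite training SSE aborts that treatment only: the
  result records SSE = NaN with a failure flag, the sweep continues, and
  failed rows are excluded (with a logged count) before analysis. A sweep
  of tens of thousands of treatments should not die at row 40 000.

## Parallel execution

Static balanced partitioning: N treatments over n workers in contiguous
chunks of size ⌈N/n⌉ or ⌊N/n⌋ (earlier workers take the larger chunks),
mirroring a master that "divides the work equally". No dynamic
work-stealing — treatments are cheap and uniform enough that the ≤ 1
imbalance is immaterial, and static chunks keep the execution plan
deterministic. Because seeding never involves worker identity, the merged
results are bit-identical for any worker count; this is asserted for 1 vs
4 workers. Speedup and efficiency are S = T₀/Tₙ and η = S/n with wall time
measured around the sweep only (excluding enumeration and I/O). Absolute
times are hardware-dependent and never asserted.

## ANOVA and selection

One observation per cell forces a main-effects-only model: factor
SS = Σ_levels n_level (ȳ_level − ȳ)², residual = total − Σ factors (i.e. all
interaction variation pooled), df = L − 1 per factor, N − 1 total. On a
complete balanced design the main-effect projections are orthogonal, so
Type I/II/III sums of squares coincide and no type option is exposed. The
implementation also accepts equal replication r ≥ 1 per cell, which the
single-factor oracle tests use. F = MS_factor / MS_residual with
p = P(F(df₁, df₂) ≥ F) via the regularised incomplete beta function; a zero
residual mean square (constant response) reports F = 0, p = 1 with a
warning rather than infinity. P-values are reported at full precision.
No multiple-testing correction is applied; significance statements are
reporting-only. Correctness is cross-checked against an independent
statsmodels OLS/ANOVA fit on random balanced designs (≤ 1e−6 relative).

Selection is the argmin of finite SSE, ties broken by the lowest row
index (well-defined thanks to the fixed enumeration order).

## Synthetic data

The generator emulates the milk dataset's published per-variable summaries
(252 samples; Dn 1.026–1.03 g/ml, mean 1.028, σ 0.001; …). Inputs are drawn
from truncated normals with the printed mean/σ restricted to the printed
[min, max]. Outputs are a *fixed seeded smooth map* of the standardised
inputs — linear + quadratic + tanh mixing, squashed to (−1, 1) and affinely
rescaled into each output's printed range — plus gaussian noise of
`noise_sd` × the output's σ (default 0.1), re-clipped to the range.

What this does and does not emulate: marginals have the right support and
approximately the right location/scale, and the input→output coupling is a
smooth deterministic surface an MLP can learn; the *joint* correlation
structure of real milk composition is not reproduced, so absolute SSE
magnitudes from synthetic sweeps are not comparable to those measured on
the real data, and no test asserts them. Two printed anomalies are kept
verbatim and documented rather than repaired: the minerals row (mean 0.70
inside [0.41, 0.71]) places the mean essentially at the range edge, so the
realised truncated mean necessarily sits below 0.70 — the distributional
tests therefore check sample moments against the *analytic* truncated-normal
moments, not the printed mean; and the pH row's printed σ (0.637) is large
relative to its range, so its truncation is strongly asymmetric.

The planted-truth generator draws a random network of a chosen
architecture, uniform [−1, 1] inputs, and targets = network outputs + noise.
At noise 0 the truth network scores SSE 0 on its own data; with 5 % noise a
group-1 sweep selects an architecture whose validation SSE is required to be
within 1.5× the planted architecture's own trained SSE (the planted row
participates in the sweep, so the winner can only be at least as good —
the check guards the whole build/train/score/select chain).

## Problem sizes and numerical choices

Sweep-level tests and the acceptance script use the study-scale group-1
designs (63–81 treatments, 120–252 samples, 50–500 epochs); the 2 187- and
59 049-treatment designs are exercised through enumeration and ANOVA (df
layouts are response-independent), not through full training sweeps, which
is where the method's combinatorial facts live. Gradient checks use central
differences with step 1e−6 against tolerance 1e−5; the linear-limit check
trains an all-linear network for 4 000 epochs and compares against the
closed-form least-squares SSE within 1e−6. Seeds below 2³¹ everywhere;
substream tags keep split/init/synthetic randomness independent.

## Known limitations

- Second-order trainers (e.g. Levenberg-Marquardt) are out of scope; with
  plain momentum descent the absolute SSE levels reached in 500 epochs are
  higher than a quasi-Newton toolbox would reach, which affects magnitudes
  but not the methodology (enumeration, decomposition, selection).
- GPU and multi-machine execution are out of scope; the worker pool is
  process-based on one host.
- The ANOVA requires a complete balanced table; if diverged runs leave
  holes, the analysis stage reports a balance error rather than silently
  switching to an unbalanced estimator.
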