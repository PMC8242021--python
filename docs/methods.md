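# Methods

## The mechanism

`privgrad` trains neural networks with DP-SGD. One training step on a
minibatch of B samples is the subsampled Gaussian mechanism: per-sample
gradients g_i are clipped to L2 norm C, summed, perturbed with
N(0, σ²C²·I), and (by default) divided by the *nominal* batch size B:

    g̃ = ( Σ_i g_i · min(1, C/max(‖g_i‖, 10⁻¹²)) + N(0, σ²C²·I) ) / B

Design choices in this step:

- **Global clipping.** One L2 norm over each sample's full flattened
  gradient, not per-layer norms: the clipped quantity is exactly the
  per-record sensitivity the accountant assumes.
- **Noise before normalisation.** Noise is added once to the clipped sum
  and then divided, giving per-coordinate std σC/B; summation without the
  divide is available (`reduction="sum"`).
- **Nominal batch size under Poisson sampling.** The mean divides by the
  expected batch size B = qn, not the realised size. The realised size is
  itself data-dependent, so normalising by it would leak; the nominal
  divisor keeps the mechanism's sensitivity analysis exact at the cost of
  slightly noisier small batches.
- **Zero-gradient rows** pass through clipping unchanged via the
  max(‖·‖, 10⁻¹²) guard.

## Per-sample gradients by weight-sharing replicas

The engine wraps a model as B replica views over a single parameter
store (the views alias the same arrays; replication allocates no
parameter memory — the tests check storage identity by object identity
and byte count). Execution is one batched forward/backward pass whose
backward keeps the batch axis, so `grads[name]` has shape
(B, *param.shape) for every layer and flattening gives the (B, P)
per-sample gradient matrix. Parallelism is a *contract* — the result
equals a serial one-sample-at-a-time loop (the test oracle) and is
independent of scheduling — not a prescribed thread layout; a batched
single dispatch satisfies it.

This requires that sample i's output depend on sample i alone, which is
the surgery module's job to certify (below). The underlying layer set
(`privgrad.nn`) is a compact batched NumPy engine — dense, 2-D
convolution, average pooling, nearest-neighbour upsampling, ReLU,
sigmoid, batch/group normalisation — written so that per-sample weight
gradients are native. It is small but complete for the CNN and
encoder–decoder models used here, and the DP machinery makes no
assumption beyond the layer API.

## Privacy accounting

**Gaussian DP (primary).** The composed privacy of T steps of the
Poisson-subsampled Gaussian mechanism at sample rate q = B/n is
summarised, in the central-limit regime, by

    μ_poisson = q · sqrt( T · (e^(1/σ²) − 1) )

and for uniform (shuffled) subsampling by

    μ_uniform = q · sqrt(T) · sqrt( e^(1/σ²)·Φ(1.5/σ) + 3·Φ(−0.5/σ) − 2 ).

μ converts to the (ε, δ) vocabulary through the Gaussian trade-off dual

    δ(ε; μ) = Φ(−ε/μ + μ/2) − e^ε · Φ(−ε/μ − μ/2),

inverted for ε by Brent root-finding on [0, 10⁴] with tolerance 10⁻⁹
(contract: 10⁻⁶). The e^ε·Φ(·) product is evaluated through the normal
log-CDF so large ε cannot overflow. Degenerate cases: μ = 0 means no
privacy loss (δ = 0, ε = 0); if δ(0; μ) ≤ δ_target, ε = 0.

**Rényi DP (comparison).** The per-step bound at integer order α ≥ 2 is
the binomial sum

    ε(α) = log( Σ_{k=0..α} C(α,k)(1−q)^(α−k) q^k e^(k(k−1)/(2σ²)) ) / (α−1)

evaluated termwise in log-space (gammaln + logsumexp; exact at q ∈ {0,1}),
composed linearly over T steps, and converted by
ε = min_α [T·ε(α) + log(1/δ)/(α−1)] over the integer grid 2..256. The
grid covers the minimiser for every schedule with σ ∈ [0.5, 10] at
realistic sample rates; the integer-order bound is exact (no quadrature)
and is checked against an exact-arithmetic brute-force sum in the tests.
On both reference schedules GDP certifies a strictly smaller ε than this
RDP bound, which is why GDP-Poisson is the default accounting mode.

**Step counting.** T = E × ⌈n/B⌉: every epoch covers the data once, the
last short batch included. The accounting mode (Poisson vs. uniform vs.
RDP) is always recorded in the output, since the sampler actually used
must match the accountant's assumption.

**Watchdog.** The private loop asks the accountant for the ε that step
t+1 *would* certify before executing it and halts on the first step that
would exceed the budget (prospective accounting). ε along a trace is
therefore non-decreasing and never exceeds the budget; the halting step
equals the analytic inversion of the accountant, which the tests verify
on several schedules. Empty Poisson batches execute as noise-only steps
and are charged like any other, matching the mechanism being accounted.

## Model surgery

Batch normalisation breaks per-sample semantics twice over: running
mean/variance accumulate non-private cross-sample state, and training
statistics couple batchmates. The default repair keeps the layer but
switches it to **per-sample statistics**: each sample is normalised by
its own per-channel spatial moments in training and evaluation alike
(for one sample this coincides with instance normalisation), running
buffers are dropped, and the learnable affine parameters are preserved —
so parameter counts never change and checkpoints stay compatible. An
opt-in alternative substitutes single-group group normalisation with the
affine parameters transplanted.

Evaluation-mode semantics at batch size 1 are the same per-sample
statistics — **a sample is always normalised by its own moments**, never
by an assumed zero mean; this is deliberately documented because a
statistics-free batch-norm at batch size 1 is otherwise ambiguous.

Layers outside the certified-per-sample allowlist fail closed with an
error naming the layer: a privacy guarantee silently voided by an exotic
layer is worse than a refusal.

## Secure noise

DP noise must be unpredictable to an adversary, so the default source
draws from the OS CSPRNG (`os.urandom`) and maps 64-bit uniforms to
normals with Box–Muller (exact, needs only uniforms). A seeded PCG64
mode exists for tests and is refused by private training; likewise a
*global seed* combined with the secure source is refused, because it
would promise a reproducibility the secure noise cannot deliver.

## Data handling

- **Split**: half-up rounding on the training share (85% of 5163 →
  4389/774). When subject identifiers are present, whole subjects are
  assigned to one side, so no subject spans splits.
- **Class weighting**: weight 1 − count/total per class (weights sum to
  k−1), applied inside the per-sample loss so DP clipping bounds the
  weighted gradient.
- **Occurrence counting**: every presentation of a record counts against
  the budget, augmented or not; the log of (step, indices) pairs must be
  gapless, and the step total reported to the accountant is the number
  of logged steps.

## Synthetic fixtures

The generators emulate the *statistical shape* of the two reference
tasks, not their content. Classification: smoothed-noise backgrounds
(noise level 0.25 on [0,1], mid-grey mean); positives add 1–3 soft
elliptical bright opacities of amplitude 0.30–0.55 — well above the
background noise, so the signal is detectable by construction. Default
class counts 1339/3824 mirror the reference imbalance. Segmentation:
one smooth star-convex blob (radius 18–38% of the frame, four Fourier
harmonics of the boundary) at contrast 0.30–0.45 over textured
background; the mask is exactly the blob support. Augmentation uses the
task-appropriate affine families (classification: rotation ±15°, scale
0.9–1.1, translation ±10%, shear ±10°; segmentation: rotation,
translation, scale, flip plus additive Gaussian image noise), with
bilinear image and nearest-neighbour mask resampling so masks stay
binary; right-angle rotations are performed exactly on the grid. The
parameter ranges are package defaults chosen to be mild and
label-preserving, not values taken from any particular study.

A fixed seed yields byte-identical datasets. What passing tests on these
fixtures shows: the mechanism (per-sample gradients, clipping, noising,
accounting, watchdog) is correct and private training retains utility on
an easy, high-contrast task. What it does not show: performance on real
radiographs or CT slices, where signal is subtler, resolution higher and
models far larger.

## Problem sizes

Desk-scale defaults keep the full suite and the reproduction script fast
on one CPU: test fixtures use 32×32 images (500 classification images,
96 segmentation pairs), tiny CNNs (10³–10⁵ parameters), and ≤ 5 epochs;
the accounting computations always use the full-size reference schedules
(n = 4389 and 5184, thousands of steps), since they need no pixel data.
The utility smoke run (σ = 1, C = 1, 5 epochs, SGD at learning rate 0.2)
reliably exceeds ROC-AUC 0.8 on the held-out split of the classification
fixture.

## Known limitations

- Image-level privacy units: a patient contributing many images enjoys
  only the per-image guarantee.
- The CLT-based GDP formulas are asymptotic in T; at very small step
  counts they can be optimistic relative to exact f-DP composition,
  which is out of scope here.
- The RDP accountant is restricted to integer orders; fractional-order
  optima (rare at these σ) would be missed by at most the grid gap.
- The mean reduction divides by the nominal batch size under Poisson
  sampling (see above); realised-size normalisation is deliberately not
  offered.
- The NumPy engine targets clarity and correctness on small models;
  it does not implement GPU execution, transposed convolutions or
  attention layers.
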