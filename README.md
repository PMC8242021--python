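# privgrad

Differentially private deep learning for medical-image analysis, built
around per-sample gradients, tight Gaussian-DP privacy accounting, and
automatic DP-compatibility model surgery.

## The problem

Training a diagnostic model on patient images must not let the trained
model leak any individual patient's data. *Differential privacy* (DP)
gives that guarantee formally: an algorithm is (ε, δ)-DP when adding or
removing any single record changes its output distribution by at most a
factor e^ε, except with probability δ. For deep networks the standard
route is **DP-SGD**: at every step, compute the gradient of each sample's
loss *individually*, clip each per-sample gradient to L2 norm C, average,
and add Gaussian noise with standard deviation σC:

    g̃ = ( Σᵢ gᵢ · min(1, C/‖gᵢ‖₂) + 𝒩(0, σ²C² I) ) / B

The obstacle in practice is the *per-sample* gradient: reverse-mode
autodiff sums over the minibatch inside the backward pass. `privgrad`
solves this with weight-sharing model replicas — one zero-copy view of
the parameters per minibatch sample — executed as a single batched
forward/backward pass whose backward keeps the batch axis, so per-sample
gradients fall out natively for any layer type.

Around that engine the package provides:

- **Privacy accounting** under *Gaussian DP* (GDP, primary) and *Rényi DP*
  (RDP, comparison). GDP collapses T Poisson-subsampled Gaussian steps
  into one parameter μ = q·√(T·(e^(1/σ²)−1)) and converts to (ε, δ) via
  the Gaussian trade-off dual; RDP composes the integer-order binomial
  bound and converts by minimising over orders. GDP is tighter on
  realistic schedules.
- **A budget watchdog**: the training loop asks the accountant for the ε
  of the *next* step before executing it and halts when the budget would
  be exceeded, so a run can never overshoot.
- **Model surgery**: batch-normalisation layers keep non-private
  cross-sample state; surgery detects them, disables their running
  statistics and switches them to per-sample statistics (or substitutes
  group normalisation), preserving the learnable parameters. Unknown
  stateful layers fail closed.
- **Secure noise**: the DP noise is drawn from the operating system's
  CSPRNG via Box–Muller; a seeded mode exists for tests only and private
  training refuses it.
- **Privacy-aware data handling**: uniform and Poisson minibatch
  samplers (empty Poisson batches become noise-only steps and are still
  charged), class weighting `1 − count/total` for imbalanced data, and
  occurrence counting in which augmented presentations cost the same as
  raw ones.
- **Synthetic fixtures**: seeded generators for an imbalanced
  "opacity vs. normal" grayscale classification set (default counts
  1339/3824, split 85/15) and an "organ blob" binary segmentation set,
  so every pipeline is testable offline.

The whole stack runs on a compact batched NumPy neural-network engine
(`privgrad.nn`) whose layers expose per-sample parameter gradients by
construction.

## Worked example

Certify the privacy cost of a classification schedule — 4389 training
images, batch size 32, 20 epochs, noise multiplier σ = 3.0, δ = 10⁻⁵ —
under both accountants:

```bash
$ privgrad audit --n 4389 --batch 32 --epochs 20 --sigma 3.0 --delta 1e-5 --mode gdp-poisson
mu      = 0.131309
epsilon = 0.458363
delta   = 1e-05
steps   = 2760  (mode gdp-poisson)

$ privgrad audit --n 4389 --batch 32 --epochs 20 --sigma 3.0 --delta 1e-5 --mode rdp
epsilon = 0.649017
delta   = 1e-05
steps   = 2760  (mode rdp)
best Renyi order = 36
```

The 2760 steps are 20 × ⌈4389/32⌉. GDP certifies ε ≈ 0.46 — a strong
guarantee (ε < 1) — while RDP certifies ε ≈ 0.65 for the *same*
mechanism: the GDP analysis is tighter, which is why it is the default.

The same from Python, plus a private training run on the synthetic
fixture:

```python
import privgrad as pg

sched = pg.TrainingSchedule(n=4389, batch_size=32, noise_multiplier=3.0,
                            delta=1e-5, epochs=20, clip_norm=1.0)
pg.audit(sched).epsilon                 # 0.4583...

spec = pg.GeneratorSpec(task="classification", image_size=32,
                        class_counts=(150, 350), seed=7)
manifest = pg.generate_classification(spec, "data/cls")

model, report = pg.fix(pg.tiny_cnn_bn(32, seed=3))   # DP surgery
run = pg.RunConfig(task="classification", model=model,
                   schedule=pg.TrainingSchedule(n=425, batch_size=32,
                                                noise_multiplier=1.0,
                                                delta=1e-5, epochs=5),
                   learning_rate=0.2, epsilon_budget=5.0)
trace = pg.train_private(run, manifest)
trace.final_privacy.epsilon, trace.final_metrics
```

A run like this completes its 70 steps (`trace.halt_reason ==
"completed"`), spends ε ≈ 3.5 at δ = 10⁻⁵, and reaches a held-out
ROC-AUC above 0.8 on the synthetic task — private training with a tiny
CNN on desk-scale data.

## Scope

The package certifies image-level privacy (each image is one privacy
unit); subject-level accounting, individual accounting, and
exact f-DP composition beyond the central-limit regime are out of scope,
as are GPU execution and second-order training methods.
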