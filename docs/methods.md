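# Methods

`atomflow` generates all-atom 3D small molecules (coordinates, element
types, formal charges, kekulized bond orders, explicit hydrogens) with a
single multi-modal flow-matching model.  This note records the model
definition, the numerical choices, and the scope of the bundled fixtures.

## Data model

A molecule is a fully-connected graph over `N` atoms:

- `coords` — Cartesian positions, float64, zero-centroid on import;
- `atom_types` — one token per atom over a configurable element list plus
  one *fake atom* class;
- `charges` — one token per atom over a configurable integer charge list
  (must contain 0);
- `bonds` — one token per unordered pair in condensed upper-triangle order
  over `{none, single, double, triple}`.  Aromatic systems are kekulized on
  input, so no aromatic bond state exists.

Every categorical modality carries one extra **mask** token, always the
final index; logits never cover it.  The fake-atom class is a *data* state
of the atom-type modality: it is a legal terminal state during generation
and is stripped before any chemistry is evaluated.

## Continuous flow (coordinates)

Conditional path: straight line `X_t = (1-t) X_0 + t X_1` with Gaussian
prior `X_0`.  The network predicts the endpoint `X1_hat`; the learned
velocity is `(X1_hat - X_t)/(1-t)` (endpoint parameterization).  The
coordinate loss is `w(t) * MSE(X1_hat, X_1)` with
`w(t) = min(max(0.005, t/(1-t)), 1.5)` — the clamp keeps early-time noise
from dominating and late-time weights bounded.

### Coupling

Per molecule, the prior cloud is matched to the target by alternating
Kabsch superposition (proper rotations only, so chirality is never
silently mirrored) and linear assignment on squared distances.  Kabsch
under a *fixed* assignment is rotation-invariant, which means a single
alternating run has one basin of attraction per initial assignment and
frequently misses the global optimum.  We therefore run a multi-start
search: each start applies a Haar-random rotation to the prior, computes
the induced assignment first, then alternates to a fixed point; the
lowest-cost result wins.  For small clouds (`N <= 8`) 128 starts are
empirically exhaustive (0 failures in 100 random trials against brute
force over all permutations, max gap 5e-15); for larger molecules 4
starts recover most of the cost reduction over plain Kabsch at ~4 ms per
20-atom molecule, which keeps the training step cheap.  Every start is at
least as good as plain Kabsch, so the procedure can only shorten the
transport paths.

## Discrete flow (types, charges, bonds)

All categorical tokens start in the mask state.  The conditional path puts
probability `t` on the final state and `1-t` on mask.  The generative CTMC
unmasks at rate `(1 + eta*t)/(1-t)` toward the predicted data-state
distribution and, for `eta > 0`, re-masks unmasked tokens at rate `eta`
(`eta = 0`, the default, is pure progressive unmasking).  Training
minimizes cross-entropy of the endpoint logits over currently-masked
tokens only.

## Sampling

`K` uniform steps (default 250).  Coordinates use the exact Euler
coefficient `1/(K-k)`, so with an oracle endpoint the state lands exactly
on `X1_hat` at the final step; the discrete final step has unmask
probability exactly 1 after clamping and renormalization.  Any token still
masked after the last step decodes from the final prediction's argmax.
Fake atoms are stripped at the end.  Each sampled molecule's atom capacity
is a size drawn from the training-set histogram plus uniform fake-atom
head-room, mirroring the training-time law.

## Self-correction features

- **Self-conditioning** — in half of the training steps the denoiser runs
  twice: the first (gradient-free) prediction enters the second pass as a
  residual embedding built from the displacement to the current state,
  predicted class probabilities, and predicted-geometry distances.  At
  sampling time the previous step's prediction is fed back from the second
  step onward.  With no previous prediction the residual is exactly zero.
- **Fake atoms** — `k ~ U{0..floor(0.3 N)}` extra atoms are appended to
  each training molecule at Gaussian offsets (sigma 1 Å) from random
  anchor atoms, typed fake, neutral, unbonded.  This gives the sampler a
  mechanism to shed unneeded capacity.
- **Geometry distortion** — for `t >= 0.5`, a Bernoulli(0.2) subset of
  atoms is displaced by `N(0, 0.5^2 I)` Å after interpolation, so the
  denoiser learns to repair off-path geometries instead of only ever
  seeing exact interpolants.

## Network

An SE(3)-equivariant graph network over the fully-connected molecular
graph.  Nodes carry invariant scalars and equivariant vector channels;
edges carry invariant scalars.  The core layer is a geometric vector
perceptron whose vector path is augmented with channel-wise **cross
products** of linearly mixed input vectors.  Cross products of true
vectors are pseudovectors, so mixing them in deliberately breaks mirror
symmetry: the network is equivariant to rotations and translations but not
to reflections, and can therefore distinguish stereoisomers.  Each of the
`n_blocks` update blocks runs message passing (node feature update), a
position update (a gate-free GVP head so zero vectors map exactly to
zero), and an edge update from the refreshed geometry.  Bond logits are
symmetrized by averaging the two directed-edge outputs.  Distances enter
through a Gaussian radial basis (16 centers on [0, 10] Å).

Batches are processed as one block-diagonal graph (edges only within
molecules), so batched training and sampling need no padding and exactly
reproduce per-molecule outputs.

All computation is NumPy float64 under a small reverse-mode autodiff
engine included in the package (no external deep-learning framework is
required).  Training uses Adam.

## Default parameters

| Parameter | Default | Why |
| --- | --- | --- |
| `n_blocks` | 4 | enough rounds of message passing for ~20-atom graphs |
| `ds`, `dv`, `de` | 64, 16, 32 | balanced capacity at desk scale |
| `n_rbf`, `rbf_max` | 16, 10 Å | covers bonded through long-range distances |
| coord clamp | (0.005, 1.5) | bounded time weighting of the MSE |
| fake-atom `p` | 0.3 | up to 30% capacity head-room |
| distortion | p=0.2, t>=0.5, sigma=0.5 Å | late-stage geometry repair signal |
| `eta` | 0 | progressive unmasking; >0 enables re-masking correction |
| sampling `K` | 250 | fine CTMC/Euler grid |

## Fixtures

`make_toy_dataset` builds small reference molecules from a bundled pool of
30 drug-like SMILES (up to 12 heavy atoms), embedding each with ETKDGv3
and explicit hydrogens; embedding seeds derive deterministically from the
dataset seed.  The fixtures emulate *chemically valid, low-strain 3D
structures with realistic functional groups* for testing the training,
sampling and metric machinery at desk scale.  They do **not** emulate the
size, conformational diversity, or chemical coverage of a real training
corpus such as a large drug-like conformer database; nothing trained on
them is expected to generalize beyond them.

## Metrics

- **Validity** — fraction of sampled molecules whose decoded chemistry
  sanitizes (valence and aromaticity checks).
- **Functional-group deviation** — L1 distance between per-pattern
  instance frequencies (matches per molecule) of sample and reference over
  a structural-alert SMARTS collection; curated subsets of the public
  Dundee and Glaxo Wellcome alert sets ship with the package, and the
  pattern file is pluggable.
- **OOD ring rate** — ring atoms are grouped into fused/spiro systems;
  each system is identified by the canonical SMILES of its induced
  subgraph (substituents truncated).  The rate is the fraction of
  ring-system *occurrences* absent from a reference identifier table.
  Identifiers are only comparable to tables generated with this package's
  own canonicalizer.
- **Additive effects** — ordinary least squares (with intercept, per time
  point) of per-model response series on binary feature flags; the
  relative effect is coefficient/intercept.

## Limitations

- Desk-scale only: the bundled network sizes and fixture datasets are for
  correctness and small-scale studies, not for competitive generation
  quality; CPU-only NumPy autodiff is orders of magnitude slower than a
  GPU framework.
- At desk scale, sampling validity is limited by inference-time
  distribution drift: models trained for minutes are near-perfect on the
  conditional path (bond/type accuracy > 0.95 at `t >= 0.5`) but their
  endpoint predictions degrade from drifted states, and committed CTMC
  tokens disagree with the final prediction on 5–10% of bonds/types.
  Invalidity is almost entirely over-valence.  The self-correction
  features narrow but do not close this gap without substantially more
  training compute; the sampler deliberately applies no valence-masking
  constraints at decode time.
- Physical-plausibility (pose-quality) checking and relaxation-energy
  metrics are out of scope.
- The Euler/CTMC integrator uses a uniform time grid; no adaptive stepping.
- Ring-system identifiers and alert subsets are package-specific choices;
  cross-implementation metric equality is not guaranteed.
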