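# Methods

## The model

`rkseg` implements a family of semantic-segmentation networks whose entire
forward pass is a single time step of an s-stage Runge–Kutta (RK)
integrator.  The usual encoder/decoder split and hand-placed skip
connections are replaced by the structure of the integrator itself:

    y1 = y0 + Σ_{i=1..s} U(e_i)

* `y0` — the initial state: the image mapped to `k` feature channels at
  full resolution by a pre-processor (one two-convolution node, no
  down-sampling).
* `e_i` — the increment of stage `i`, a `k`-channel tensor computed by a
  two-convolution node at its own spatial scale (divisor `2^j` for the
  j-th node).  The RK coefficients (step size, stage weights) are not
  represented explicitly; they are absorbed into the learned weights of
  the stage nodes.
* `U` — parameter-free interpolation of each increment back to full
  resolution.  (Parameter-count bookkeeping forces `U` to be
  parameter-free: any learned up-sampling would change the totals.)
* The final state `y1` is decoded into class logits by a post-processor
  (`3×3,k → 3×3,k → 1×1,c`).

Three stage-wiring schemes ("backbones") are provided:

* **E (explicit)** — `e_i = E_i(D(y0), e_1, …, e_{i-1})`; stage `i`'s node
  consumes `k·i` channels.  `s = d` (one node per scale).
* **I (implicit)** — slope nodes first, `x_i = X_i(D(y0), x_1, …, x_{i-1})`
  (width `k·i`), then increment nodes
  `e_i = I_i(D(y0), e_1, …, e_{i-1}, x_{i+1}, …, x_s)` — always `s`
  tensors, width `k·s`.  Each stage spends two nodes, so the scale depth
  `d` must be even, `s = d/2`, and the alternating update needs `s ≥ 2`.
* **R (reduced implicit)** — `e_i = R_i(D(y0), x_1, …, x_{i-1}, x_{i+1}, …,
  x_s)`; same width arithmetic as I.

Two orientations assign nodes to scales: **L** runs stages from large
scale to small (node `j` at divisor `2^j`), **R** reverses the list.  For
I/R backbones the slope (X) nodes occupy the first `s` positions of the
schedule and the increment (I/R) nodes the remaining `s`; the reverse
assignment would change no parameter counts, only geometry.  Every tensor
entering a node is resampled to the node's scale — 2×2 max pooling (`D`)
when coming from a finer scale (always the case for `y0`), bilinear
interpolation (`V`) when coming from a coarser one.  `y0` is always
resampled directly from full resolution in one operator call, not
cascaded through intermediate stages.  Only one time step is computed;
stacking several would accumulate truncation error.

Evaluation order for I/R is a two-phase sweep: all `x_i` in index order,
then all `e_i` in index order — the increment equations reference
`x_{i+1}…x_s`, so slope computation must complete first.

## Node design and parameter counting

Every node is `3×3,k → 3×3,k` with a per-channel instance normalization
(learnable affine) and leaky ReLU (slope 0.01) after each convolution.
The width `k` is constant across scales — unlike U-Net-style models, depth
does not widen the network, which is why the family is small (0.1–0.35 M
parameters at `k = 32`).

Trainable scalars of a node with input width `a`:

    node(a→k) = 9·a·k + 9·k² + 2k (conv biases) + 4k (norm affine)

Pre-processor: `node(in→k)`.  Post-processor: `node(k→k) + k·c + c`.
Backbone E total: `node(in→k) + Σ_{i=1..s} node(k·i→k) + node(k→k) + k·c + c`;
backbones I/R add `s·node(k·s→k)` for the increment nodes.  Orientation
never changes the count.  The convention counts conv weights, conv biases
and normalization affine pairs; running statistics are not parameters.
The closed form (`rkseg.params`) is checked to the scalar against a
brute-force enumeration of every instantiated array across the whole
family in the test suite.

A consequence worth knowing: a conv bias that feeds an instance norm is an
invariant (dead) parameter — the norm subtracts the per-channel mean, so
its gradient is identically zero.  The biases are retained anyway because
the family's published parameter totals include them; the gradient-flow
test asserts non-zero gradients for every *live* parameter and ~0 for the
norm-shadowed biases.

Depth per task follows the published totals: brain `d=5` (4 channels, 4
classes), heart `d=6` (1, 2), hippocampus `d=3` (1, 3), liver `d=7`
(1, 3).  These depths are inferred from the parameter arithmetic — they
are the unique small depths reproducing every printed total — not stated
directly by the tables.

## Compute backend

No GPU tensor framework is used; the package carries its own small
reverse-mode autodiff engine over numpy (`rkseg.nn`): same-padded 3×3 and
1×1 convolution via im2col, instance norm, leaky ReLU, 2×2 max pooling,
matrix-based bilinear/nearest up-sampling (half-pixel-centres
convention), concatenation and addition.  The input gradient of a 3×3
correlation is computed as a correlation with the flipped,
channel-transposed kernel; all gradients are validated against central
finite differences in float64, and the full forward pass against an
independent loop-level trace.  Default arithmetic is float32.

## Training recipe

SGD with Nesterov momentum (`lr0 = 0.01`, `momentum = 0.99` — the
configuration this family was designed to train under), polynomial decay
`lr0·(1 − epoch/epochs)^0.9` (constant-LR option available), Dice +
cross-entropy loss.  The soft-Dice term uses softmax probabilities,
batch-aggregated per class, smoothing `ε = 1e-5` in numerator and
denominator, and averages over foreground classes only; the loss is
reported as `CE + (1 − Dice)` so perfect predictions drive it to ~0.  No
data augmentation and no deep supervision (auxiliary losses at
intermediate scales have no interpretation in the RK view).  Weight init
is He-normal; a `residual_init` flag zeroes each stage's final
convolution so training starts from the identity time step (off by
default — on step one it also zeroes the gradient of each stage's first
convolution).

Evaluation: argmax over logits; per-class Dice similarity coefficient
`DSC = 2|A∩B|/(|A|+|B|)` computed per case, averaged over cases, then
over foreground classes (each case weighted equally).  Both-empty pairs
score 1.  The published benchmark's exact aggregation across validation
cases is unstated; this convention is the package's own and is
documented, not asserted as theirs.

Odd input sizes are symmetrically zero-padded to the next multiple of
`2^d` and the logits cropped back (`pad_policy="pad_and_crop"`, default)
or rejected (`"reject"`).

## Synthetic data

`rkseg.synth` generates deterministic 2-D multi-class tasks: compact
foreground objects (rotated ellipses, or blobs whose disk boundary is
wobbled by Gaussian-smoothed noise) on a background, each class rendered
at intensity `contrast·class` and corrupted by i.i.d. Gaussian noise
(`σ = 0.1` by default against a contrast of 0.5 — an easily learnable but
non-trivial contrast-to-noise ratio).  Multi-channel images emulate
modalities by per-channel gain only.  Each case contains at least one
object of every foreground class.  Defaults: 200 cases of 64×64, one
channel, two classes — the desk-scale study condition used by the
learning-capability test, which trains the smallest explicit variant
(`d=3, k=8`, 160/40 split, 20 epochs, ~1 minute on one CPU) and checks
held-out mean foreground DSC ≥ 0.90; the threshold was fixed after three
independent-seed pilot runs (0.993, 0.985, 0.985).

What the generator does *not* emulate: MRI/CT physics, anisotropic
spacing, 3-D context, class imbalance of real organs, inter-case
registration.  Passing the synthetic tests therefore demonstrates that
the architecture, loss and optimizer are implemented correctly and can
fit a segmentation task — not that the model reaches any particular
accuracy on clinical data.

Datasets round-trip through an MSD-style NIfTI layout
(`imagesTr`/`labelsTr`, nnU-Net-style `_0000` channel suffixes,
`dataset.json` with `modality`/`labels`/`numTraining`) and through an
8-bit paired-PNG dialect (images quantized to [0, 255]; labels stored
raw, which is lossless for ≤ 4 classes).  Labels are uint8.

## Numerical choices and limitations

* Interpolation is bilinear with half-pixel centres (non-aligned
  corners); nearest is available.  Down-sampling is max pooling only —
  strided convolutions would add parameters and break the count
  arithmetic.
* Max-pool ties take the first maximum; instance norm uses `ε = 1e-5`.
* 2-D single-time-step networks only; no 3-D convolutions, no deep
  supervision, no multi-GPU, no cross-validation orchestration.
* The alternating backbones require an even depth and at least two
  stages (`d ≥ 4`); the explicit backbone works at any `d ≥ 1`.
* Training at realistic clinical resolutions is out of scope for the
  numpy backend; problem sizes in the tests (≤ 64×64, `k ≤ 32`) were
  chosen so the full suite runs in a few minutes on one CPU.
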