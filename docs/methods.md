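# Methods

This note documents the model implemented by `tracenet`, its parameters and
defaults, the scope of the synthetic stimulus generators, the numerical
choices made in the analysis code, and known limitations.

## 1. Model

### 1.1 V1 front end

Images are grayscale, on a uniform background of exactly gray 127. The input
stage convolves the contrast image (pixel value − 127) with a bank of Gabor
filters:

- 4 orientations (0°, 45°, 90°, 135°), spatial frequencies 0.35, 0.25 and
  0.125 cycles/pixel, 2 phases (0°, 90°), Gaussian envelope σ = 0.5 / f.
- Each kernel is DC-corrected to zero mean (uniform input drives no response)
  and scaled to unit L2 norm.
- Filter outputs are sampled on a square grid (stride 8 at 64 px → 8 × 8
  positions) and half-wave rectified into separate positive- and
  negative-polarity channels, giving non-negative "firing rates".
- Each image's full encoding vector is normalized to unit Euclidean norm
  (firing-rate normalization). Without this, encoding norms of several
  hundred swamp the unit-norm weight dynamics of the competitive layers and
  learning freezes.

### 1.2 Competitive hierarchy

Four layers of rate neurons, each a square grid (default 24 × 24 = 576 cells
per layer). Layer *n* receives convergent connections from a random sample of
cells within a Gaussian-disc neighborhood of the topographically corresponding
position in layer *n−1* (layer 1 samples the Gabor encoding):

- fan-in: 100 synapses per layer-1 neuron, 60 per upper-layer neuron,
  sampled without replacement within the convergence radius;
- convergence radii grow with depth (0.28·grid for layer 1 in input-grid
  units; 0.56, 0.69, 0.88·grid for layers 2–4), so layer-4 receptive fields
  cover the whole input;
- initial weights uniform random, each neuron's weight vector normalized to
  unit L2 norm (weights are non-negative throughout).

Activation within a layer, per stimulus:

1. linear response `a_i = w_i · x_(connectivity_i)`;
2. lateral inhibition: convolution with a difference kernel
   `δ − strength · G_σ` (unit-mass Gaussian surround, center excluded;
   defaults σ = 1.5 cells, strength = 0.9, kernel radius 3σ, zero padding);
3. contrast-enhancing sigmoid: activations are scaled by the layer maximum,
   thresholded at the (100 − sparseness) percentile (default sparseness:
   top 10% of cells above threshold) and passed through a logistic with
   slope 30, giving rates in [0, 1]. A silent layer stays silent.

### 1.3 Learning rules

Trace rule (default): each neuron keeps an exponentially decaying average of
its recent rates,

    trace(t) = (1 − η) · y(t) + η · trace(t−1),        η = 0.8
    Δw_ij    = α · trace_i(t) · x_j,                   α = 0.3

followed by renormalization of each neuron's weight vector to unit L2 norm
(competitive learning). The Hebbian control replaces the trace with the
instantaneous rate y(t); it is exactly the η = 0 special case.

Training is layer-sequential: layer 1 trains for all its epochs (default 50
per layer), is then frozen, and its outputs become the next layer's inputs.
Within an epoch, the schedule's groups are presented in fixed order; the
images inside a group are re-permuted every epoch, and the trace is reset to
zero at every group boundary so temporal binding cannot leak between groups.

### 1.4 Presentation schedules: the experimental manipulation

Both training modes present the *identical multiset of images* per epoch;
only the temporal grouping differs:

- **object mode** — one group per identity, containing all its
  deformation × view images: the trace binds transforms of one identity, so
  layer-4 cells become identity-selective and deformation/view invariant;
- **deformation mode** — one group per deformation (pose or windspeed),
  containing all identity × view images: cells become deformation-selective
  and identity/view invariant.

### 1.5 Information measures

Single-cell stimulus-specific information: each cell's rates are quantized
into 8 equal-width bins over the cell's own observed range; with equal class
priors, `I(s, R) = Σ_r P(r|s) log2(P(r|s) / P(r))` is computed per class and
the maximum over classes reported. A constant-rate cell carries 0 bits.

Multiple-cell information: the 5 highest-information cells per class (ties
broken by lower cell index) form a population vector. Decoding is
leave-one-transform-out: class mean vectors are computed from all other
transforms, and the held-out response is assigned to the class with the
highest cosine similarity (normalized dot product; ties resolve to the
lowest class index). The mutual information of the resulting
(actual × decoded) confusion matrix is computed by direct summation and
reported with percent correct.

### 1.6 Pattern-associator readout

For cross-validated generalization, a one-layer associator is trained on the
selected cells' rates: each class's weight vector is the unit-normalized sum
of its training vectors; classification is the argmax of dot products.
A delta-rule option exists but is off by default.

## 2. Experiments

- **Invariance** (both stimulus families, both modes): train at defaults,
  report max single-cell information, multiple-cell information, percent
  correct and the confusion matrix.
- **Capacity**: from a 28-flag procedural pool, draw seeded random subsets of
  4, 8, 10, 15 and 20 flags (20 trials per size; 60 epochs per layer), train
  object-mode networks per trial and report mean ± sd percent correct.
  The full pool is encoded once and trials index into it.
- **Cross-validation**: 6 synthetic individuals × 3 poses × 12 views;
  leave-one-identity-out. For each split, train deformation mode on 5
  individuals, select the 5 best cells per pose (15 readout cells), train the
  associator on their responses, and classify all 36 images of the held-out
  individual. Pooled accuracy over 6 × 36 = 216 classifications is tested
  against 1/3 chance with an exact upper-tail binomial test. The
  untrained-network control repeats the pipeline with initial weights.

## 3. Synthetic stimulus generators: scope

Rather than depending on rendered photographic stimuli (cloth-simulated
flags, articulated human models), the package generates procedural stand-ins
that preserve the experimental *structure* — a factorial identity ×
deformation × view design where deformation and view transforms are shared
across identities — not photographic appearance:

- **Flags** (identity = country pattern, deformation = windspeed 0–200,
  view = front/mirrored back): a library of 28 stripe/cross/canton patterns
  with per-seed tone assignment. Wind is rendered as a vertical droop
  displacement field that grows nonlinearly toward the fly end
  (shift ∝ wind^1 · |u|^1.5 plus a small ripple), anti-aliased by 2×
  supersampling. The back view is an exact horizontal mirror. The droop field
  depends only on windspeed, so deformation is identical across countries.
- **Figures** (identity = individual, deformation = pose, view = 12 azimuth
  steps): articulated capsule silhouettes. A pose is a joint-angle template
  (standing, sitting, walking) shared by all individuals; an individual is a
  set of limb proportions plus three gray tones (head/torso/limbs), shared
  across all its poses and views. Views modulate limb widths by
  0.55 + 0.45·|cos(azimuth)| with mirroring for rear views, so pose remains
  legible at every view.

Both generators are deterministic given a seed, and reference conditions are
tone-normalized so mean foreground contrast is matched at the undeformed
front view.

## 4. Numerical choices

- All randomness uses `numpy.random.default_rng` with explicit seeds;
  per-identity parameters use seed sequences `[seed, constant, identity]` so
  adding identities never changes existing ones.
- Gabor encoding uses FFT convolution (`scipy.signal.fftconvolve`) sampled at
  grid positions; unit tests verify exact agreement with a direct nested-loop
  correlation oracle.
- Lateral inhibition uses `scipy.ndimage.convolve` with zero padding, tested
  against a brute-force convolution oracle.
- Information quantities are computed by direct summation (no estimators or
  bias corrections); `0 log 0 = 0`. The confusion-matrix mutual information
  is verified against the `H(S) + H(D) − H(S,D)` decomposition.
- The exact binomial test is `scipy.stats.binomtest(..., alternative=
  "greater")`.
- During layer-sequential training the frozen lower layers' outputs are
  cached per image, so each presentation costs one layer update rather than
  a full forward pass.

## 5. Defaults and why

| Parameter | Default | Rationale |
| --- | --- | --- |
| image size | 64 px | smallest size at which wind droop and pose geometry stay legible |
| Gabor frequencies | 0.35/0.25/0.125 | coarse-to-fine coverage at 64 px; calibrated in pilot sweeps |
| grid stride | 8 | 8×8 sampling positions; receptive fields tile the image |
| layer grid | 24×24 | robust across network seeds (16×16 was seed-fragile); ~2× cheaper than 32×32 |
| fan-in | 100 / 60 | dense enough for feature conjunctions within the convergence disc |
| sparseness | 10% | sparser (5%) degrades deformation-mode accuracy |
| sigmoid slope | 30 | sharper competition keeps Hebbian-trained cells transform-specific, as in full-scale simulations |
| η (trace) | 0.8 | ~5-presentation memory, matching group sizes of 10–36 images |
| α | 0.3 | with slope 30, converges within 50 epochs per layer and sharpens competition |
| epochs/layer | 50 | performance plateaus; 60 used for capacity runs |
| decoding cells | 5 per class | standard choice in VisNet-style information analyses |
| bins | 8 | single-cell quantization; ceilings ≤ log2(8) = 3 bits cover all class counts used |

Network-architecture and front-end parameters are configuration, not
scientific claims: defaults were calibrated in pilot sweeps for robustness
across network seeds before the headline analyses were run.

## 6. Limitations

- Desk scale: 24×24-cell layers and 64 px images versus the 32×32 layers and
  richer rendered stimuli of full-scale VisNet simulations. Quantities that
  depend on scale (absolute information of intermediate cells, capacity at
  large set sizes, cross-validated accuracy on held-out identities) reproduce
  trends and contrasts, not exact full-scale values: the capacity curve stays
  near ceiling through 8 flags but declines more steeply at 15–20, and
  held-out pose accuracy is reliably above chance (exact binomial p ≪ 10⁻³)
  at a lower absolute level than a full-scale network reaches.
- An untrained (random-weight) network is not a blank control for a linear
  readout: with 10% sparseness, raw silhouette pose information leaks through
  random connectivity, so the untrained pattern-associator control can sit
  roughly 10 points above chance rather than at it. The trained-vs-untrained
  gap remains large.
- The stand-in stimuli are silhouettes/flat patterns without texture,
  lighting or occlusion; identity cues are geometric proportions and tone.
  Static tone cues make identity partially decodable without temporal
  binding, which mainly affects the Hebbian-control baseline.
- Single-cell information uses equal-width binning over each cell's observed
  range with no bias correction; values for near-silent cells are noisy but
  such cells are never selected for decoding.
- The leave-one-transform-out decoder is a nearest-mean cosine classifier,
  chosen for determinism; it is not an optimal (Bayesian) decoder, so
  multiple-cell information is a lower bound.
- Stochastic experiments (criteria involving trained networks) vary by a few
  percentage points across network seeds; acceptance values are computed at
  a caller-supplied seed.
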