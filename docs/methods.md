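# Methods

## Model overview

`sparsev1` simulates a patch of primary visual cortex as two populations of
current-based leaky integrate-and-fire (LIF) neurons — N_E excitatory and
N_I = N_E/4 inhibitory cells — driven by N_X = 2·p² thalamic (LGN) units, one
ON and one OFF unit per pixel of a p×p image patch.  All feedforward and
lateral connections are all-to-all (no self-connections laterally) and all are
plastic.  The six weight matrices W^{AB} (post × pre, A∈{E,I}, B∈{X,E,I}) are
stored nonnegative; inhibitory terms enter the current sum with a negative
sign, so Dale's law is a pure nonnegativity invariant.

### LGN front-end

Grayscale images in [0,1] are filtered with a divisively normalized
difference of Gaussians,

    F = (G_{σc} * I − G_{σs} * I) / (G_{σd} * I),

with σc = 1, σs = σd = 1.5 pixels, then normalized to unit standard deviation
per image.  Patches of p×p pixels are sampled uniformly.  Rectification maps a
filtered pixel value v to Poisson rates

    on = min(cr·max(v,0), 100 Hz),   off = min(cr·max(−v,0), 100 Hz),

with cr = 70, so at every pixel at most one channel is active.  Spikes are
drawn per 1 ms step as Bernoulli events with probability rate·dt (exact to
O((rate·dt)²); rate·dt ≤ 0.1 under the cap).

Numerical choices: Gaussian kernels are the sampled, unit-sum kernels
truncated at 4σ (truncation error < 1e-4); convolution uses reflect padding
to avoid border artifacts on small images; the unit-SD normalization leaves
the mean untouched (the filter output is already near zero mean).  An
all-zero image makes the divisive field vanish and is rejected as degenerate.

### Membrane dynamics

Per 1 ms step, in this order: (1) LGN spikes are drawn; (2) synaptic currents
are computed from the spikes of the **previous** step (a one-step synaptic
delay, which makes the disynaptic E→I→E inhibition lag structurally
expressible); fresh Gaussian noise ξ ~ N(0, 1) is added per neuron per step;
(3) forward-Euler update v ← v + dt·(v_rest − v)/τm + I with τm = 10 ms,
then the lower clamp v ← max(v, −10); (4) threshold test v ≥ θ (a neuron at
exactly threshold spikes — deterministic tie-break) and reset to v_rest = 0;
(5) plasticity.  Membrane capacitance is absorbed into the weights; voltages
and currents share model units.  There is no refractory period beyond the
reset.

### Plasticity

Synaptic traces are exponentially filtered spike trains
U(t) = Σ_i exp(−(t−t_i)/τ).  Within a step the order is: decay all traces,
compute **all** weight changes from the pre-increment trace values, apply
them, then add the step's spikes to the traces.  This implements the
"weight change before trace update" convention; simultaneous pre/post spikes
trigger both rule branches with traces that exclude the simultaneous spikes.

*Triplet STDP* (X→E, E→E): at a postsynaptic spike
ΔW = η·A_p·U_p,pre·U_a,post with τ_p = 20 ms and the slow rate trace
τ_a = 50 ms; at a presynaptic spike ΔW = −η·A_d·U_d,post with τ_d = 20 ms.
The rule is a spike-based BCM rule with fixed threshold
φ = A_d·τ_d/(A_p·τ_p·τ_a); with A_p = 1, A_d = 0.1 this gives φ = 2 Hz, the
excitatory target rate, so uncorrelated pre/post firing at the target rate
produces zero mean drift.  The depression trace uses τ_d for its kernel (the
natural reading of the trace family).  Depression can drive single weights
negative between normalizations; they are clipped to zero immediately.

*Symmetric STDP* (I→E, X→I, E→I, I→I): at any spike on either side,
ΔW = η·A_sym·U_sym of the opposite side (τ_sym = 20 ms, A_sym = 0.5).  Both
branches potentiate, so the rule depends only on |Δt| and is Hebbian in
rates (mean drift ∝ rate product).

*L1 normalization*: each row (a neuron's afferent weights from one
population) has an upper bound on its L1 norm.  When exceeded: subtract the
uniform excess (‖w‖₁ − l1)/N_pre, clip negatives to zero, rescale
multiplicatively to the bound exactly.  Checked once per presentation (after
the 400 ms window); within-presentation drift is of order η and the O(N²)
cost amortizes.

*Adaptive threshold*: once per presentation,
Δθ = clip(η_θ·(count/T − ρ), ±4), with ρ_E = 2 Hz, ρ_I = 4 Hz, η_θ = 0.1.
The cap value is a design choice: it must bound single-presentation jumps
(here to well under half the initial threshold) **without rate-limiting the
homeostat while plasticity reshapes a neuron's drive**.  A cap of one unit
per presentation — the smallest obvious choice — lets receptive-field
sharpening outrun threshold tracking at scaled-up learning rates; the
resulting sustained rate overshoot puts every excitatory neuron deep in the
triplet rule's potentiation regime and collapses the whole population onto
the stimulus ensemble's dominant feature.  At 4 units the threshold tracks
any transient the learning rules can produce, while the equilibrium noise
scale of the update (η_θ times the rate-estimate SD, ≈ 0.2–0.5 units) is
far below the cap, so it never binds in steady state.

### Balance configuration

L1 bounds (100, 10, 120, 80, 240, 120 for EX, EE, EI, IX, IE, II) are chosen
so the mean-weight chain  w̄^EX/w̄^IX > w̄^EI/w̄^II > w̄^EE/w̄^EI  holds
strictly (1.25 > 1.0 > 1/48 with the defaults, mean weights estimated as
l1/N_pre).  `check_balance_condition` reports the ratios; a violated chain
warns rather than aborts, since the homeostatic mechanisms often still
stabilize the run.

### Training protocol

Weights are initialized sparsely — each entry is b ~ N(1, 0.5) with
probability p = 0.2 and 0.01·b otherwise, clipped at zero — and every row is
scaled multiplicatively onto its L1 bound.  Warm-up (100 batches at full
scale) runs threshold adaptation with weight plasticity off.  Training then
presents N_n = 1200 batches of N_b = 100 patches for T = 400 ms each; all
learning and homeostatic rates are halved at 0.3·N_n and 0.6·N_n.  Patches
are drawn from the pool with replacement, fresh each presentation.  One
global seed expands into named streams (init / pool / presentation order /
dynamics) so robustness sweeps can vary one source of randomness at a time;
checkpoints capture weights, state, traces and both RNG streams, making an
interrupted-and-resumed run bit-identical to an uninterrupted one.

## Synthetic stimuli

No photographic corpus is packaged.  The generator synthesizes grayscale
images with an approximately 1/f² radially averaged power spectrum (white
Gaussian Fourier coefficients shaped by a 1/f amplitude envelope, min-max
rescaled to [0,1]).  This reproduces the second-order statistic that the
center-surround whitening front-end is matched to, which is what drives the
emergence of localized oriented receptive fields here.  It does **not**
reproduce the higher-order structure of natural scenes (edges, occlusions,
heavy-tailed filter responses), so quantitative endpoints obtained on these
stimuli (sparseness values, well-fit fractions) characterize the code for
Gaussian 1/f images, not for photographs; passing tests demonstrate the
mechanism, not equivalence to natural-scene training.

White-noise stimuli for receptive-field mapping go through the same filter
pipeline: unit-variance spatial noise n is mapped to pixels 50n + 100
clipped to [0,255], rescaled by 1/255, DoG-filtered, normalized to unit SD
per stimulus (a flat field passes through as zeros rather than raising), and
rectified with scale 2·cr.  The ON and OFF channel means are not exactly
equal under this construction — the pixel mapping clips asymmetrically and
the divisive field couples to local luminance — the residual asymmetry is a
few percent and is documented in the test suite.

## Analysis

* **STA**: receptive fields are the rate-weighted average of the *raw* noise
  fields, F = Σ r_i n_i / Σ r_i.  Rates are counted over the full
  presentation window (200 ms per noise stimulus at desk scale); membranes
  are reset between stimuli, plasticity off, thresholds as trained.  Neurons
  with no spikes in the whole assay are flagged unresponsive and excluded
  from downstream summaries.  Bilinear upsampling exists for display only.
* **Gabor fits**: nonlinear least squares of
  A·exp(−x'²/2σx² − y'²/2σy²)·cos(2πf_s x' + φ) with the modulation axis x'
  at orientation θ.  The objective is multimodal in θ and φ, so the optimizer
  restarts on an 8×2 orientation × phase grid, with a final polish at
  perturbed f_s (the f_s/envelope trade-off is the main residual ambiguity).
  Bounds: σ ∈ (0.3, 16) px, f_s ∈ (0.02, 0.5) cycles/px.  fit_error =
  SSR/Σ(RF²); "well fit" means fit_error < 0.10.  Shape descriptors:
  n_x = σx·f_s, n_y = σy·f_s.
* **Sparseness**: Treves–Rolls ς = 1 − (mean r)²/mean(r²) per neuron across
  images (temporal) or per image across neurons (population); all-zero
  response vectors are flagged and excluded from means.
* **Correlations**: Pearson, across images for rates (constant-rate units
  excluded with a flag) and across flattened maps for receptive fields;
  weight-versus-RF-correlation profiles use bins of width 0.02 with empty
  bins reported as count 0.
* **Balance probes**: the probed neuron's threshold and clamp are removed
  and its voltage integrated under all inputs, excitation only (X and E
  afferents), or inhibition only; the rest of the network runs normally and
  the probed neuron never spikes, so the trajectory is identical across
  modes and, at σξ = 0, the full trace is exactly the sum of the split
  traces.  Loose balance ranks a 1000-patch pool by the Pearson correlation
  of the filtered patch with the neuron's STA map and probes the most
  anti-correlated, nearest-zero and most correlated patches.  Tight balance
  is the lagged Pearson correlation between the excitation-only trace and
  the *magnitude* of the inhibition-only trace, computed after discarding
  the first 100 ms (onset transient), lags up to ±50 ms; a positive peak at
  positive lag means inhibition follows excitation.

## Desk-scale preset

The scaled-down study conditions are 8×8 patches (N_X = 128), N_E = 64,
N_I = 16, 150 batches of 50 presentations with 15 warm-up batches.  Two
derived scalings keep this run a faithful miniature of the full protocol:

1. **L1 bounds scale with the presynaptic population** (l1 ∝ N_pre), leaving
   every mean weight l1/N_pre — and hence the balance ratios — unchanged.
2. **STDP learning rates are multiplied by twice the presentation-count
   ratio**, 2·(1200·100)/(150·50) = 32.  The relative L1 drift per
   postsynaptic spike is η·A·U̅·N_pre·r·τ/l1; with l1 ∝ N_pre the
   population-size factors cancel, so multiplying η by the presentation
   ratio (16) preserves cumulative drift relative to the bound.  Drift
   parity alone, however, leaves the short schedule short of the learning
   dynamics' fixed point: weight reorganization and receptive-field
   structure are still maturing when the 150 batches end.  Doubling the
   multiplier brings the reorganization to saturation — a sweep over
   multipliers 16/24/32/48 shows receptive-field quality rising to a
   plateau at ≈32 with rates, decorrelation and stability unaffected — so
   32 is used.  The homeostatic rate η_θ stays at 0.1: raising it
   proportionally only injects threshold noise (its equilibrium fluctuation
   grows with √η_θ) and in diagnostics destabilized the run; what homeostasis
   needs at higher η is headroom in the per-presentation cap (above), not a
   faster gain.

Receptive-field mapping at this scale uses N_w = 2·10⁴ white-noise stimuli
of 200 ms (scaled from the 10⁵ full-scale assay; split-half reliability of
the resulting maps is ≈0.97, so they are signal- not noise-limited).

## Robustness protocols

* **L1 jitter**: each postsynaptic neuron's bound is scaled by an
  independent U(1−c, 1+c) factor and the corresponding learning rate by the
  same factor (keeping relative drift invariant); c ≥ 1 is rejected since a
  bound could reach zero.
* **Target-rate override**: ρ_E ∈ {1, 2, 5, 10, 20} Hz with ρ_I = 2ρ_E,
  A_d = ρ_E·τ_a (so φ tracks the target), and learning rates rescaled by one
  factor ρ_old/ρ_new per synapse terminal whose target rate changed
  (EX: post only; EE, EI, IE, II: both; IX: post only), keeping mean drift
  per presentation invariant.
* **Size multiplier**: integer c_n scales all three populations; c_n ON and
  OFF units per pixel (the rate vector is tiled per pixel copy).  L1 bounds
  scale linearly with N by default (a √N convention is available as
  `size_l1_scaling="sqrt"`), and learning rates follow the bounds.

## Known limitations

* Current-based synapses; no conductances, no refractory period, no axonal
  delays beyond the uniform one-step convention.
* Static images only; no temporal receptive fields, color, or multi-scale
  LGN channels; no topographic connectivity, hence no orientation maps.
* The synthetic-stimulus generator captures only second-order natural-image
  statistics (above).
* The balance inequality is evaluated on the uniform-row mean-weight
  estimate; after learning the weights are structured and the mean-field
  premises no longer hold exactly.
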