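# sparsev1

A biologically grounded spiking network model of primary visual cortex (V1)
for studying how **sparse coding, excitatory/inhibitory balance and
decorrelation emerge from local learning rules** — rather than being imposed
by an objective function.

The package is for computational neuroscientists who want a compact,
fully-tested reference implementation of this class of model: LGN-like ON/OFF
Poisson input, current-based leaky integrate-and-fire (LIF) excitatory and
inhibitory populations, spike-timing-dependent plasticity on every synapse,
and the analysis stack used to quantify the emergent code (spike-triggered
averages, Gabor fits, Treves–Rolls sparseness, correlation structure, and
loose/tight balance measurements).

## Model

Images are filtered with a divisively normalized difference of Gaussians
(σ_c = 1, σ_s = σ_d = 1.5 px), normalized to unit SD, and rectified into
ON/OFF Poisson rates `min(c_r·[±v]_+, 100 Hz)` with c_r = 70.  N_X = 512 LGN
units drive N_E = 400 excitatory and N_I = 100 inhibitory LIF neurons
(τ_m = 10 ms, 1 ms steps, reset to 0, clamp at −10, per-step N(0,1) current
noise; capacitance absorbed into the weights):

    v ← v + dt·(v_rest − v)/τ_m + Σ_B Σ_i W^{AB}_{ji} s_i^B + ξ

Synapses onto excitatory neurons from excitatory sources (X→E, E→E) learn by
**minimal triplet STDP** — potentiation `A_p·U_p,i·U_a,j` at post spikes,
depression `A_d·U_d,j` at pre spikes, with traces U_α = exponentially
filtered spike trains (τ_p = τ_d = 20 ms, τ_a = 50 ms).  This is a
spike-based BCM rule whose potentiation/depression threshold

    φ = A_d·τ_d / (A_p·τ_p·τ_a)  =  2 Hz   (A_p = 1, A_d = 0.1)

is fixed at the excitatory target rate.  All synapses with an inhibitory
terminal learn by **symmetric STDP** (`A_sym·U_sym` of the opposite side at
every spike; Hebbian in rates).  Homeostasis comes from per-row **L1 weight
normalization** (subtractive, clip, multiplicative; bounds 100/10/120 for
X/E/I→E and 80/240/120 for X/E/I→I) and an **adaptive spiking threshold**
driven at η_θ = 0.1 toward ρ_E = 2 Hz / ρ_I = 4 Hz.  The bounds satisfy the
balanced-network chain `w̄^EX/w̄^IX > w̄^EI/w̄^II > w̄^EE/w̄^EI`
(1.25 > 1.0 > 0.0208).

Training presents 16×16 patches of filtered images for 400 ms each, 1200
batches of 100 after a 100-batch threshold-only warm-up, halving all rates at
30 % and 60 % of the schedule.  Because no photographic corpus is packaged, a
generator synthesizes grayscale images with 1/f² spatial power spectra as a
stand-in for natural scenes (see `docs/methods.md` for what this does and
does not emulate).

## Worked example

```python
import sparsev1 as s

# analytic closures of the plasticity constants
cfg = s.RunConfig().validate()
phi = s.compute_phi(s.TripletParams.from_run_config(cfg))
print(f"triplet threshold phi = {phi:.1f} Hz (target rate {cfg.rho_e:.1f} Hz)")

from sparsev1.plasticity import NormalizationBounds
rep = s.check_balance_condition(NormalizationBounds.from_run_config(cfg),
                                s.Topology.from_run_config(cfg))
print("balance ratios: %.4f > %.4f > %.4f  satisfied=%s" % (*rep.ratios,
                                                            rep.satisfied))

# train the desk-scale network (64 E / 16 I, 8x8 patches; a few minutes)
coder = s.SpikingV1Coder(random_state=0)
coder.fit()
log = coder.log_[coder.log_.phase == "train"]
print("final mean E rate: %.2f Hz" % log.tail(10).mean_rate_e.mean())

rates = coder.transform(coder.trainer_.pool.patches[:100])
from sparsev1.analysis import population_sparseness
print("population sparseness: %.2f" % population_sparseness(rates.T).mean)
```

prints (seed 0):

```
triplet threshold phi = 2.0 Hz (target rate 2.0 Hz)
balance ratios: 1.2500 > 1.0000 > 0.0208  satisfied=True
final mean E rate: 2.05 Hz
population sparseness: 0.84
```

`phi` equal to the target rate means uncorrelated pre/post firing at the
homeostatic set point produces zero mean weight drift — the rate equilibrium
of the triplet rule.  The satisfied balance chain means the configured mean
weights admit a stable balanced state.  The final excitatory rate sitting at
the 2 Hz target shows threshold homeostasis converged, and a population
sparseness well above zero indicates that only a minority of neurons respond
strongly to any given patch.

The same model is scriptable from the shell:

```bash
sparsev1 train --desk-scale --seed 0 --out runs/desk
sparsev1 analyze --checkpoint runs/desk/checkpoint_final.h5 --out runs/desk/analysis
sparsev1 sweep --vary rate --values 1,2,5 --out runs/rates
```

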