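"""Current-based LIF network of excitatory and inhibitory populations.

The network advances in fixed 1 ms steps.  Per step, in this order:

1. LGN Poisson spikes are drawn from the stimulus rates.
2. Synaptic currents are computed from the spikes of the *previous* step
   (a one-step synaptic delay), with inhibitory terms entering negatively and
   fresh Gaussian noise added per neuron.
3. Forward-Euler membrane update ``v += dt*(v_rest - v)/tau_m + I`` followed
   by the lower clamp at ``v_min``.
4. Threshold test (``v >= theta`` spikes, deterministic tie-break) and reset
   to ``v_rest``.
5. Plasticity: traces decay, all weight changes are computed and applied from
   the pre-increment traces, then this step's spikes are added to the traces.

Membrane capacitance is absorbed into the weights, so currents and voltages
share the same model units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .config import RunConfig
from .errors import (ConfigurationError, NumericalInstabilityError, StateError)
from .plasticity import (HomeostasisParams, SymmetricParams, TraceSet,
                         TripletParams, apply_symmetric_inplace,
                         apply_triplet_inplace)

__all__ = [
    "NeuronParams", "Topology", "WeightMatrices", "NetworkState",
    "PresentationRecord", "ProbeTraces", "synaptic_current", "step_membrane",
    "run_presentation", "free_membrane_probe", "PROBE_MODES",
]

PROBE_MODES = ("full", "excitation_only", "inhibition_only")


@dataclass
class NeuronParams:
    """LIF membrane constants (times in ms, voltages in model units)."""

    tau_m: float = 10.0
    v_rest: float = 0.0
    v_min: float = -10.0
    theta_init: float = 10.0
    dt: float = 1.0
    mu_xi: float = 0.0
    sigma_xi: float = 1.0

    def __post_init__(self):
        if self.tau_m <= 0 or self.dt <= 0:
            raise ConfigurationError("tau_m and dt must be > 0")
        if not (self.v_min < self.theta_init):
            raise ConfigurationError("v_min must be < theta_init")

    @classmethod
    def from_run_config(cls, cfg: RunConfig) -> "NeuronParams":
        return cls(cfg.tau_m, cfg.v_rest, cfg.v_min, cfg.theta_init,
                   cfg.dt, cfg.mu_xi, cfg.sigma_xi)


@dataclass
class Topology:
    """Population sizes; lateral connectivity is all-to-all without self-connections."""

    n_x: int
    n_e: int
    n_i: int

    def __post_init__(self):
        if min(self.n_x, self.n_e, self.n_i) < 1:
            raise ConfigurationError("population sizes must be >= 1")

    @classmethod
    def from_run_config(cls, cfg: RunConfig) -> "Topology":
        return cls(cfg.n_x, cfg.n_e, cfg.n_i)


@dataclass
class WeightMatrices:
    """The six nonnegative weight matrices, post x pre.

    Inhibitory weights (``w_ei``, ``w_ii``) are stored nonnegative and enter
    the current sum with a negative sign, so Dale's law is a pure
    nonnegativity invariant.  Lateral within-population matrices have zero
    diagonals.
    """

    w_ex: np.ndarray  # X -> E
    w_ee: np.ndarray  # E -> E (zero diagonal)
    w_ei: np.ndarray  # I -> E (subtracted)
    w_ix: np.ndarray  # X -> I
    w_ie: np.ndarray  # E -> I
    w_ii: np.ndarray  # I -> I (zero diagonal, subtracted)

    GROUPS = ("ex", "ee", "ei", "ix", "ie", "ii")

    def get(self, group: str) -> np.ndarray:
        return getattr(self, f"w_{group.lower()}")

    def copy(self) -> "WeightMatrices":
        return WeightMatrices(*(self.get(g).copy() for g in self.GROUPS))

    def validate(self, topology: Topology | None = None,
                 bounds=None, tol: float = 1e-9) -> None:
        for g in self.GROUPS:
            w = self.get(g)
            if np.any(w < 0):
                raise StateError(f"negative entries in w_{g} violate Dale's law")
        for g in ("ee", "ii"):
            if np.any(np.diag(self.get(g)) != 0):
                raise StateError(f"w_{g} has nonzero self-connections")
        if topology is not None:
            shapes = {
                "ex": (topology.n_e, topology.n_x),
                "ee": (topology.n_e, topology.n_e),
                "ei": (topology.n_e, topology.n_i),
                "ix": (topology.n_i, topology.n_x),
                "ie": (topology.n_i, topology.n_e),
                "ii": (topology.n_i, topology.n_i),
            }
            for g, s in shapes.items():
                if self.get(g).shape != s:
                    raise StateError(f"w_{g} has shape {self.get(g).shape}, expected {s}")
        if bounds is not None:
            for g in self.GROUPS:
                norms = self.get(g).sum(axis=1)
                cap = np.broadcast_to(np.atleast_1d(bounds.get(g)), norms.shape)
                if np.any(norms > cap + tol):
                    raise StateError(f"w_{g} row L1 norm exceeds its bound")


@dataclass
class NetworkState:
    """Mutable simulation state: membranes, thresholds, traces, last spikes."""

    v_e: np.ndarray
    v_i: np.ndarray
    theta_e: np.ndarray
    theta_i: np.ndarray
    traces: TraceSet
    prev_x: np.ndarray = None  # last step's spike indicators (float 0/1)
    prev_e: np.ndarray = None
    prev_i: np.ndarray = None
    step: int = 0

    def __post_init__(self):
        if self.prev_x is None:
            self.prev_x = np.zeros_like(self.traces.up_x)
        if self.prev_e is None:
            self.prev_e = np.zeros(self.v_e.size)
        if self.prev_i is None:
            self.prev_i = np.zeros(self.v_i.size)

    @classmethod
    def initial(cls, topology: Topology, params: NeuronParams,
                triplet: TripletParams, symmetric: SymmetricParams) -> "NetworkState":
        traces = TraceSet(topology.n_x, topology.n_e, topology.n_i,
                          triplet, symmetric, dt=params.dt)
        return cls(
            v_e=np.full(topology.n_e, params.v_rest),
            v_i=np.full(topology.n_i, params.v_rest),
            theta_e=np.full(topology.n_e, params.theta_init),
            theta_i=np.full(topology.n_i, params.theta_init),
            traces=traces,
        )

    def reset_membranes(self, params: NeuronParams) -> None:
        self.v_e[:] = params.v_rest
        self.v_i[:] = params.v_rest
        self.prev_x[:] = 0.0
        self.prev_e[:] = 0.0
        self.prev_i[:] = 0.0


@dataclass
class PresentationRecord:
    """Per-presentation results: spike counts and optional rasters/traces."""

    counts_x: np.ndarray
    counts_e: np.ndarray
    counts_i: np.ndarray
    duration_ms: float
    spikes_e: list = None   # [(step, neuron), ...] if recorded
    spikes_i: list = None
    spikes_x: list = None
    v_trace_e: np.ndarray = None  # (n_steps, n_recorded) if requested
    probe: "ProbeTraces" = None   # set when a neuron is probed


@dataclass
class ProbeTraces:
    """Threshold-free voltage traces of one probed neuron under input splits."""

    full: np.ndarray
    excitation_only: np.ndarray
    inhibition_only: np.ndarray
    dt: float


def synaptic_current(weights: WeightMatrices, spikes: dict,
                     noise_e: np.ndarray | float = 0.0,
                     noise_i: np.ndarray | float = 0.0):
    """Instantaneous currents to (E, I) from 0/1 spike indicator vectors.

    ``spikes`` maps population tags "X", "E", "I" to indicator vectors of the
    *previous* step.  Inhibitory terms enter negatively.
    """
    sx, se, si = (np.asarray(spikes[k], dtype=float) for k in ("X", "E", "I"))
    if (sx.size != weights.w_ex.shape[1] or se.size != weights.w_ee.shape[1]
            or si.size != weights.w_ei.shape[1]):
        raise StateError("spike vector lengths do not match weight shapes")
    i_e = weights.w_ex @ sx + weights.w_ee @ se - weights.w_ei @ si + noise_e
    i_i = weights.w_ix @ sx + weights.w_ie @ se - weights.w_ii @ si + noise_i
    return i_e, i_i


def step_membrane(v: np.ndarray, current: np.ndarray, theta: np.ndarray,
                  params: NeuronParams):
    """One Euler step with clamp, threshold and reset.

    Returns (v_new, spike indicator).  A neuron at exactly v == theta spikes.
    """
    v = v + params.dt * (params.v_rest - v) / params.tau_m + current
    if not np.all(np.isfinite(v)):
        raise NumericalInstabilityError(
            "non-finite membrane potential after Euler update")
    np.maximum(v, params.v_min, out=v)
    spikes = v >= theta
    v[spikes] = params.v_rest
    return v, spikes.astype(float)


def _step_currents(weights, state, noise_e, noise_i):
    """Indexed current computation (fast path; equals synaptic_current)."""
    xs = np.flatnonzero(state.prev_x)
    es = np.flatnonzero(state.prev_e)
    is_ = np.flatnonzero(state.prev_i)
    i_e = np.array(noise_e, dtype=float, copy=True)
    i_i = np.array(noise_i, dtype=float, copy=True)
    if xs.size:
        i_e += weights.w_ex[:, xs].sum(axis=1)
        i_i += weights.w_ix[:, xs].sum(axis=1)
    if es.size:
        i_e += weights.w_ee[:, es].sum(axis=1)
        i_i += weights.w_ie[:, es].sum(axis=1)
    if is_.size:
        i_e -= weights.w_ei[:, is_].sum(axis=1)
        i_i -= weights.w_ii[:, is_].sum(axis=1)
    return i_e, i_i


def run_presentation(state: NetworkState, weights: WeightMatrices,
                     rates: np.ndarray, duration_ms: float,
                     params: NeuronParams, rng: np.random.Generator,
                     triplet: TripletParams | None = None,
                     symmetric: SymmetricParams | None = None,
                     plasticity_enabled: bool = False,
                     eta_scale: float = 1.0,
                     record_spikes: bool = False,
                     record_v_e: np.ndarray | None = None,
                     probe_e: int | None = None) -> PresentationRecord:
    """Advance the network for one stimulus presentation.

    ``rates`` is the concatenated [ON, OFF] LGN rate vector in Hz.  Weight and
    trace updates happen only with ``plasticity_enabled``; threshold
    homeostasis and L1 normalization are applied by the caller between
    presentations.  ``eta_scale`` implements the annealing schedule.
    ``probe_e`` designates one excitatory neuron whose threshold and clamp are
    removed and whose split input traces are recorded (loose/tight balance
    probes); the probed neuron never spikes.
    """
    n_steps_f = duration_ms / params.dt
    n_steps = int(round(n_steps_f))
    if abs(n_steps_f - n_steps) > 1e-9 or n_steps < 1:
        raise ConfigurationError("duration must be a positive multiple of dt")
    rates = np.asarray(rates, dtype=float)
    if rates.size != state.traces.up_x.size:
        raise StateError("stimulus rate vector does not match the X population")
    p_x = rates * params.dt / 1000.0
    if np.any(p_x > 1.0):
        raise ConfigurationError("stimulus rate exceeds one spike per step")

    n_x, n_e, n_i = rates.size, state.v_e.size, state.v_i.size
    counts_x = np.zeros(n_x)
    counts_e = np.zeros(n_e)
    counts_i = np.zeros(n_i)
    spk_e = [] if record_spikes else None
    spk_i = [] if record_spikes else None
    spk_x = [] if record_spikes else None
    v_rec = None
    if record_v_e is not None:
        record_v_e = np.asarray(record_v_e, dtype=int)
        v_rec = np.empty((n_steps, record_v_e.size))
    probe = None
    if probe_e is not None:
        probe = ProbeTraces(np.empty(n_steps), np.empty(n_steps),
                            np.empty(n_steps), dt=params.dt)
        pv_full = pv_exc = pv_inh = params.v_rest
        # the probed neuron must not fire through the normal path
        saved_theta = state.theta_e[probe_e]
        state.theta_e[probe_e] = np.inf

    leak = params.dt / params.tau_m
    do_plast = plasticity_enabled and triplet is not None and symmetric is not None
    tr = state.traces
    if do_plast:
        # scheduled learning-rate vectors, broadcast once per presentation
        def _ev(eta, n):
            return np.broadcast_to(np.atleast_1d(eta), (n,)).astype(float) * eta_scale
        eta_ex = _ev(triplet.eta_ex, n_e)
        eta_ee = _ev(triplet.eta_ee, n_e)
        eta_ei = _ev(symmetric.eta_ei, n_e)
        eta_ix = _ev(symmetric.eta_ix, n_i)
        eta_ie = _ev(symmetric.eta_ie, n_i)
        eta_ii = _ev(symmetric.eta_ii, n_i)

    v_e, v_i = state.v_e, state.v_i
    theta_e, theta_i = state.theta_e, state.theta_i
    w_ex, w_ee, w_ei = weights.w_ex, weights.w_ee, weights.w_ei
    w_ix, w_ie, w_ii = weights.w_ix, weights.w_ie, weights.w_ii
    xs_idx = np.flatnonzero(state.prev_x)
    es_idx = np.flatnonzero(state.prev_e)
    is_idx = np.flatnonzero(state.prev_i)
    sigma, mu = params.sigma_xi, params.mu_xi
    v_rest, v_min = params.v_rest, params.v_min

    for t in range(n_steps):
        sx = (rng.random(n_x) < p_x).astype(float)
        if sigma > 0:
            noise_e = mu + sigma * rng.standard_normal(n_e)
            noise_i = mu + sigma * rng.standard_normal(n_i)
        else:
            noise_e = np.full(n_e, mu)
            noise_i = np.full(n_i, mu)

        # currents from the previous step's spikes (one-step synaptic delay)
        i_e = noise_e
        i_i = noise_i
        if xs_idx.size:
            i_e = i_e + w_ex[:, xs_idx].sum(axis=1)
            i_i = i_i + w_ix[:, xs_idx].sum(axis=1)
        if es_idx.size:
            i_e = i_e + w_ee[:, es_idx].sum(axis=1)
            i_i = i_i + w_ie[:, es_idx].sum(axis=1)
        if is_idx.size:
            i_e = i_e - w_ei[:, is_idx].sum(axis=1)
            i_i = i_i - w_ii[:, is_idx].sum(axis=1)

        if probe_e is not None:
            exc = 0.0
            if xs_idx.size:
                exc += w_ex[probe_e, xs_idx].sum()
            if es_idx.size:
                exc += w_ee[probe_e, es_idx].sum()
            inh = -w_ei[probe_e, is_idx].sum() if is_idx.size else 0.0
            pv_full = pv_full + leak * (v_rest - pv_full) + exc + inh \
                + noise_e[probe_e]
            pv_exc = pv_exc + leak * (v_rest - pv_exc) + exc
            pv_inh = pv_inh + leak * (v_rest - pv_inh) + inh
            probe.full[t] = pv_full
            probe.excitation_only[t] = pv_exc
            probe.inhibition_only[t] = pv_inh

        # Euler update, clamp, threshold, reset (inline of step_membrane)
        v_e = v_e + leak * (v_rest - v_e) + i_e
        v_i = v_i + leak * (v_rest - v_i) + i_i
        if not (math.isfinite(v_e.sum()) and math.isfinite(v_i.sum())):
            raise NumericalInstabilityError(
                f"non-finite membrane potential at step {state.step}")
        np.maximum(v_e, v_min, out=v_e)
        np.maximum(v_i, v_min, out=v_i)
        se_b = v_e >= theta_e
        si_b = v_i >= theta_i
        es_new = np.flatnonzero(se_b)
        is_new = np.flatnonzero(si_b)
        v_e[es_new] = v_rest
        v_i[is_new] = v_rest
        se = se_b.astype(float)
        si = si_b.astype(float)
        xs_new = np.flatnonzero(sx)

        if do_plast:
            tr.decay()
            apply_triplet_inplace(w_ex, xs_new, es_new, tr.up_x,
                                  tr.ud_e, tr.ua_e, triplet, eta_ex)
            apply_triplet_inplace(w_ee, es_new, es_new, tr.up_e,
                                  tr.ud_e, tr.ua_e, triplet, eta_ee,
                                  zero_diagonal=True)
            apply_symmetric_inplace(w_ei, is_new, es_new, tr.sym_i,
                                    tr.sym_e, symmetric, eta_ei)
            apply_symmetric_inplace(w_ix, xs_new, is_new, tr.sym_x,
                                    tr.sym_i, symmetric, eta_ix)
            apply_symmetric_inplace(w_ie, es_new, is_new, tr.sym_e,
                                    tr.sym_i, symmetric, eta_ie)
            apply_symmetric_inplace(w_ii, is_new, is_new, tr.sym_i,
                                    tr.sym_i, symmetric, eta_ii,
                                    zero_diagonal=True)
            tr.accumulate(sx, se, si)

        counts_x += sx
        counts_e += se
        counts_i += si
        if record_spikes:
            for lst, vec in ((spk_x, xs_new), (spk_e, es_new), (spk_i, is_new)):
                for idx in vec:
                    lst.append((t, int(idx)))
        if v_rec is not None:
            v_rec[t] = v_e[record_v_e]

        state.prev_x, state.prev_e, state.prev_i = sx, se, si
        xs_idx, es_idx, is_idx = xs_new, es_new, is_new
        state.step += 1

    state.v_e, state.v_i = v_e, v_i

    rec = PresentationRecord(counts_x, counts_e, counts_i, duration_ms,
                             spikes_e=spk_e, spikes_i=spk_i, spikes_x=spk_x,
                             v_trace_e=v_rec)
    if probe_e is not None:
        state.theta_e[probe_e] = saved_theta
        rec.probe = probe
    return rec


def free_membrane_probe(state: NetworkState, weights: WeightMatrices,
                        rates: np.ndarray, duration_ms: float,
                        params: NeuronParams, neuron: int,
                        mode: str = "full", seed: int = 0) -> np.ndarray:
    """Threshold-free voltage trace of one excitatory neuron.

    ``mode`` selects the afferent set: "full" (all inputs plus membrane
    noise), "excitation_only" (X and E afferents), or "inhibition_only"
    (I afferents).  The rest of the network runs normally; the probed neuron
    does not spike, so the network trajectory is identical across modes for a
    fixed seed, and with sigma_xi = 0 the full trace is exactly the sum of the
    two split traces (linearity of the threshold-free Euler recursion).
    The probe is side-effect free: state and weights are copied.
    """
    if mode not in PROBE_MODES:
        raise ConfigurationError(f"unknown probe mode {mode!r}; use {PROBE_MODES}")
    work = NetworkState(state.v_e.copy(), state.v_i.copy(),
                        state.theta_e.copy(), state.theta_i.copy(),
                        state.traces, state.prev_x.copy(),
                        state.prev_e.copy(), state.prev_i.copy())
    rng = np.random.default_rng(seed)
    rec = run_presentation(work, weights, rates, duration_ms, params, rng,
                           plasticity_enabled=False, probe_e=neuron)
    return getattr(rec.probe, mode)
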