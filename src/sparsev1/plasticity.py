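"""Synaptic plasticity and homeostasis.

Four mechanisms act on the six weight matrices W^{AB} (post x pre, all
nonnegative under Dale's law):

* **Triplet STDP** on excitatory-target groups (X->E, E->E).  Potentiation at a
  postsynaptic spike is A_p * U_p,i * U_a,j where U_p is a fast presynaptic
  trace (tau_p) and U_a a slow postsynaptic rate trace (tau_a); depression at a
  presynaptic spike is A_d * U_d,j (tau_d).  The rule is equivalent to a BCM
  rate rule with a fixed potentiation/depression threshold
  phi = A_d tau_d / (A_p tau_p tau_a), set equal to the excitatory target rate.
* **Symmetric STDP** on all inhibitory-terminal groups (I->E, X->I, E->I,
  I->I): potentiation A_sym * U_sym of the opposite side at every spike,
  regardless of order (Hebbian in rates).
* **Three-stage L1 row normalization**: subtractive when a row exceeds its
  bound, clip negatives to zero, then multiplicative rescale to the bound.
* **Adaptive spiking threshold** driven per presentation toward a target rate,
  with a cap on the per-presentation change.

Trace reads follow the "weight change before trace update" convention: within
a step traces are decayed, all weight changes are computed and applied from the
pre-increment trace values, and only then are this step's spikes added to the
traces.  A spike pair landing in the same step therefore triggers both rule
branches with traces that exclude the simultaneous spikes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import RunConfig
from .errors import ConfigurationError, ContractError

__all__ = [
    "TripletParams", "SymmetricParams", "HomeostasisParams",
    "NormalizationBounds", "TraceSet", "decay_and_accumulate",
    "triplet_update", "symmetric_update", "compute_phi",
    "normalize_row", "normalize_rows", "update_threshold",
    "TRIPLET_GROUPS", "SYMMETRIC_GROUPS",
]

TRIPLET_GROUPS = ("EX", "EE")
SYMMETRIC_GROUPS = ("EI", "IX", "IE", "II")


@dataclass
class TripletParams:
    """Constants of the minimal triplet rule (time constants in ms)."""

    tau_p: float = 20.0
    tau_d: float = 20.0
    tau_a: float = 50.0
    a_p: float = 1.0
    a_d: float = 0.1
    eta_ex: float | np.ndarray = 2e-4
    eta_ee: float | np.ndarray = 1e-4

    def __post_init__(self):
        if min(self.tau_p, self.tau_d, self.tau_a, self.a_p, self.a_d) <= 0:
            raise ConfigurationError("triplet constants must be > 0")
        if self.tau_a <= self.tau_p:
            raise ConfigurationError("tau_a must exceed tau_p")

    @classmethod
    def from_run_config(cls, cfg: RunConfig) -> "TripletParams":
        return cls(cfg.tau_p, cfg.tau_d, cfg.tau_a, cfg.a_p, cfg.a_d,
                   cfg.eta_ex, cfg.eta_ee)


@dataclass
class SymmetricParams:
    tau_sym: float = 20.0
    a_sym: float = 0.5
    eta_ei: float | np.ndarray = 9e-2
    eta_ix: float | np.ndarray = 3e-3
    eta_ie: float | np.ndarray = 4e-2
    eta_ii: float | np.ndarray = 6e-2

    def __post_init__(self):
        if self.tau_sym <= 0 or self.a_sym <= 0:
            raise ConfigurationError("tau_sym and a_sym must be > 0")

    @classmethod
    def from_run_config(cls, cfg: RunConfig) -> "SymmetricParams":
        return cls(cfg.tau_sym, cfg.a_sym, cfg.eta_ei, cfg.eta_ix,
                   cfg.eta_ie, cfg.eta_ii)


@dataclass
class HomeostasisParams:
    rho_e: float = 2.0
    rho_i: float = 4.0
    eta_theta_e: float = 0.1
    eta_theta_i: float = 0.1
    delta_theta_cap: float = 4.0

    def __post_init__(self):
        if self.delta_theta_cap <= 0:
            raise ConfigurationError("delta_theta_cap must be > 0")

    @classmethod
    def from_run_config(cls, cfg: RunConfig) -> "HomeostasisParams":
        return cls(cfg.rho_e, cfg.rho_i, cfg.eta_theta_e, cfg.eta_theta_i,
                   cfg.delta_theta_cap)


@dataclass
class NormalizationBounds:
    """Per-row L1 caps for the six weight groups (scalar or per-neuron)."""

    l1_ex: float | np.ndarray = 100.0
    l1_ee: float | np.ndarray = 10.0
    l1_ei: float | np.ndarray = 120.0
    l1_ix: float | np.ndarray = 80.0
    l1_ie: float | np.ndarray = 240.0
    l1_ii: float | np.ndarray = 120.0

    def __post_init__(self):
        for g in ("ex", "ee", "ei", "ix", "ie", "ii"):
            if not np.all(np.asarray(getattr(self, f"l1_{g}")) > 0):
                raise ConfigurationError(f"l1_{g} must be > 0")

    @classmethod
    def from_run_config(cls, cfg: RunConfig) -> "NormalizationBounds":
        return cls(cfg.l1_ex, cfg.l1_ee, cfg.l1_ei, cfg.l1_ix,
                   cfg.l1_ie, cfg.l1_ii)

    def get(self, group: str):
        return getattr(self, f"l1_{group.lower()}")


class TraceSet:
    """Exponentially filtered spike-train traces for all populations.

    Holds, per neuron: the triplet presynaptic traces ``up_x`` / ``up_e``
    (tau_p), the postsynaptic depression and rate traces ``ud_e`` (tau_d) and
    ``ua_e`` (tau_a), and symmetric-STDP traces ``sym_x`` / ``sym_e`` /
    ``sym_i`` (tau_sym).  ``decay()`` multiplies every trace by its per-step
    factor; ``accumulate()`` adds this step's spikes.
    """

    _FIELDS = ("up_x", "up_e", "ud_e", "ua_e", "sym_x", "sym_e", "sym_i")

    def __init__(self, n_x: int, n_e: int, n_i: int,
                 triplet: TripletParams, symmetric: SymmetricParams,
                 dt: float = 1.0):
        self.dt = dt
        self.up_x = np.zeros(n_x)
        self.up_e = np.zeros(n_e)
        self.ud_e = np.zeros(n_e)
        self.ua_e = np.zeros(n_e)
        self.sym_x = np.zeros(n_x)
        self.sym_e = np.zeros(n_e)
        self.sym_i = np.zeros(n_i)
        self._decay = {
            "up_x": np.exp(-dt / triplet.tau_p),
            "up_e": np.exp(-dt / triplet.tau_p),
            "ud_e": np.exp(-dt / triplet.tau_d),
            "ua_e": np.exp(-dt / triplet.tau_a),
            "sym_x": np.exp(-dt / symmetric.tau_sym),
            "sym_e": np.exp(-dt / symmetric.tau_sym),
            "sym_i": np.exp(-dt / symmetric.tau_sym),
        }

    def decay(self) -> None:
        for name in self._FIELDS:
            getattr(self, name).__imul__(self._decay[name])

    def accumulate(self, spikes_x: np.ndarray, spikes_e: np.ndarray,
                   spikes_i: np.ndarray) -> None:
        self.up_x += spikes_x
        self.sym_x += spikes_x
        self.up_e += spikes_e
        self.ud_e += spikes_e
        self.ua_e += spikes_e
        self.sym_e += spikes_e
        self.sym_i += spikes_i

    def state_arrays(self) -> dict:
        return {name: getattr(self, name) for name in self._FIELDS}


def decay_and_accumulate(trace: np.ndarray, spikes: np.ndarray, tau: float,
                         dt: float) -> np.ndarray:
    """One incremental step of Eq-style trace filtering on a single array.

    Returns trace * exp(-dt/tau) + spikes; the pre-increment (post-decay)
    value is what plasticity reads within the same step.
    """
    if dt <= 0 or tau <= 0:
        raise ConfigurationError("dt and tau must be > 0")
    return trace * np.exp(-dt / tau) + spikes


def compute_phi(params: TripletParams) -> float:
    """Potentiation/depression threshold of the triplet rule, in Hz.

    phi = A_d * tau_d / (A_p * tau_p * tau_a) with time constants in seconds;
    with the default constants this equals the excitatory target rate.
    """
    tau_p = params.tau_p / 1000.0
    tau_d = params.tau_d / 1000.0
    tau_a = params.tau_a / 1000.0
    return params.a_d * tau_d / (params.a_p * tau_p * tau_a)


def _check_group(group: str, allowed, rule: str) -> str:
    g = group.upper()
    if g not in allowed:
        raise ContractError(
            f"{rule} STDP does not govern weight group {group!r}; "
            f"allowed: {allowed}")
    return g


def triplet_update(group: str, pre_spikes: np.ndarray, post_spikes: np.ndarray,
                   u_p_pre: np.ndarray, u_d_post: np.ndarray,
                   u_a_post: np.ndarray, params: TripletParams,
                   eta: float | np.ndarray = 1.0) -> np.ndarray:
    """Dense weight-change matrix of the triplet rule for one step.

    ``pre_spikes`` / ``post_spikes`` are 0/1 indicators for this step; the
    traces are the pre-increment values.  Returns dW of shape
    (n_post, n_pre):  +eta*A_p*U_p,i*U_a,j at post spikes,
    -eta*A_d*U_d,j at pre spikes.
    """
    _check_group(group, TRIPLET_GROUPS, "triplet")
    pre = np.asarray(pre_spikes, dtype=float)
    post = np.asarray(post_spikes, dtype=float)
    eta_col = np.broadcast_to(np.atleast_1d(eta), post.shape) \
        if np.ndim(eta) else np.full(post.shape, float(eta))
    pot = (eta_col * params.a_p * post * u_a_post)[:, None] * u_p_pre[None, :]
    dep = -(eta_col * params.a_d * u_d_post)[:, None] * pre[None, :]
    return pot + dep


def symmetric_update(group: str, pre_spikes: np.ndarray,
                     post_spikes: np.ndarray, u_sym_pre: np.ndarray,
                     u_sym_post: np.ndarray, params: SymmetricParams,
                     eta: float | np.ndarray = 1.0) -> np.ndarray:
    """Dense weight-change matrix of the symmetric rule for one step.

    +eta*A_sym*U_sym,pre at post spikes and +eta*A_sym*U_sym,post at pre
    spikes; both branches potentiate, so the rule depends only on |dt|.
    """
    _check_group(group, SYMMETRIC_GROUPS, "symmetric")
    pre = np.asarray(pre_spikes, dtype=float)
    post = np.asarray(post_spikes, dtype=float)
    eta_col = np.broadcast_to(np.atleast_1d(eta), post.shape) \
        if np.ndim(eta) else np.full(post.shape, float(eta))
    at_post = (eta_col * params.a_sym * post)[:, None] * u_sym_pre[None, :]
    at_pre = (eta_col * params.a_sym * u_sym_post)[:, None] * pre[None, :]
    return at_post + at_pre


# -- fast in-place variants used by the simulation loop ----------------------

def _eta_vec(eta, n_post: int) -> np.ndarray:
    if isinstance(eta, np.ndarray) and eta.shape == (n_post,):
        return eta
    return np.broadcast_to(np.atleast_1d(eta), (n_post,))


def apply_triplet_inplace(w: np.ndarray, pre_idx: np.ndarray,
                          post_idx: np.ndarray, u_p_pre: np.ndarray,
                          u_d_post: np.ndarray, u_a_post: np.ndarray,
                          params: TripletParams, eta: float | np.ndarray,
                          zero_diagonal: bool = False) -> None:
    """Indexed rank-1 application of the triplet rule (equivalent to the
    dense form; spikes are given as index arrays).  Negative entries produced
    by depression are clipped to zero immediately (Dale's law)."""
    eta_vec = _eta_vec(eta, w.shape[0])
    if post_idx.size:
        gain = eta_vec[post_idx] * params.a_p * u_a_post[post_idx]
        w[post_idx, :] += gain[:, None] * u_p_pre[None, :]
    if pre_idx.size:
        drop = eta_vec * params.a_d * u_d_post
        block = w[:, pre_idx]
        block -= drop[:, None]
        np.maximum(block, 0.0, out=block)
        w[:, pre_idx] = block
    if zero_diagonal:
        np.fill_diagonal(w, 0.0)


def apply_symmetric_inplace(w: np.ndarray, pre_idx: np.ndarray,
                            post_idx: np.ndarray, u_sym_pre: np.ndarray,
                            u_sym_post: np.ndarray, params: SymmetricParams,
                            eta: float | np.ndarray,
                            zero_diagonal: bool = False) -> None:
    eta_vec = _eta_vec(eta, w.shape[0])
    if post_idx.size:
        gain = eta_vec[post_idx] * params.a_sym
        w[post_idx, :] += gain[:, None] * u_sym_pre[None, :]
    if pre_idx.size:
        w[:, pre_idx] += (eta_vec * params.a_sym * u_sym_post)[:, None]
    if zero_diagonal:
        np.fill_diagonal(w, 0.0)


# -- normalization and homeostasis -------------------------------------------

def normalize_row(row: np.ndarray, l1_bound: float, n_pre: int | None = None) -> np.ndarray:
    """Three-stage L1 normalization of one weight row.

    If the row's L1 norm is within the bound it is returned unchanged.
    Otherwise: subtract the uniform excess (||row||_1 - bound)/n_pre from every
    entry, clip negatives to zero, and rescale multiplicatively so the norm
    equals the bound exactly.
    """
    if l1_bound <= 0:
        raise ConfigurationError("l1_bound must be > 0")
    row = np.asarray(row, dtype=float)
    n_pre = row.size if n_pre is None else n_pre
    norm = row.sum()  # rows are nonnegative on entry
    if norm <= l1_bound:
        return row
    out = row - (norm - l1_bound) / n_pre
    np.maximum(out, 0.0, out=out)
    s = out.sum()
    if s > 0:
        out *= l1_bound / s
    return out


def normalize_rows(w: np.ndarray, l1_bound: float | np.ndarray) -> None:
    """In-place three-stage L1 normalization of every row of a weight matrix."""
    bounds = np.broadcast_to(np.atleast_1d(l1_bound), (w.shape[0],))
    norms = w.sum(axis=1)
    over = np.flatnonzero(norms > bounds)
    if over.size == 0:
        return
    n_pre = w.shape[1]
    block = w[over, :]
    block -= ((norms[over] - bounds[over]) / n_pre)[:, None]
    np.maximum(block, 0.0, out=block)
    s = block.sum(axis=1)
    nz = s > 0
    block[nz] *= (bounds[over][nz] / s[nz])[:, None]
    w[over, :] = block


def update_threshold(theta: np.ndarray, spike_count: np.ndarray,
                     duration_s: float, rho: float, eta_theta: float,
                     delta_cap: float) -> np.ndarray:
    """Adaptive-threshold step: theta += clip(eta*(rate - rho), +-cap).

    ``duration_s`` is the presentation length in seconds; applied once per
    presentation.
    """
    if duration_s <= 0:
        raise ConfigurationError("duration must be > 0")
    rate = np.asarray(spike_count, dtype=float) / duration_s
    delta = np.clip(eta_theta * (rate - rho), -delta_cap, delta_cap)
    return theta + delta
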