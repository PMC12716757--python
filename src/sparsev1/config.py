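"""Run configuration: parameter schema, defaults, validation and (de)serialization.

The default :class:`RunConfig` is the reference simulation parameter set
for the full-size network (512 LGN inputs, 400 excitatory and 100 inhibitory
cells).  Scaled-down presets for desk-scale experiments are derived from it by
:func:`desk_scale_config` so that mean synaptic weights and cumulative plasticity
are preserved (see docs/methods.md).

L1 weight bounds and learning rates may be scalars or per-postsynaptic-neuron
vectors; the vector form is produced by the robustness jitter protocol.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import yaml

from .errors import ConfigurationError

__all__ = ["RunConfig", "desk_scale_config", "load_config", "save_config", "config_hash"]

#: weight groups, post/pre convention: "ei" caps/learns I -> E synapses.
WEIGHT_GROUPS = ("ex", "ee", "ei", "ix", "ie", "ii")


def _as_float_or_array(x):
    if np.ndim(x) == 0:
        return float(x)
    return np.asarray(x, dtype=float)


@dataclass
class RunConfig:
    """Complete parameter set for one simulation run.

    Defaults are the full-size network values; time constants are in ms,
    rates in Hz, membrane quantities in model voltage units (the membrane
    capacitance is absorbed into the weights).
    """

    # -- populations -------------------------------------------------------
    n_x: int = 512          # ON+OFF LGN input neurons (2 per pixel)
    n_e: int = 400          # excitatory cortical neurons
    n_i: int = 100          # inhibitory cortical neurons (n_e / 4)

    # -- LGN front-end ------------------------------------------------------
    sigma_c: float = 1.0    # center Gaussian SD (pixels)
    sigma_s: float = 1.5    # surround Gaussian SD (pixels)
    sigma_d: float = 1.5    # divisive-normalization Gaussian SD (pixels)
    cr: float = 70.0        # rate scaling constant (Hz per filtered-luminance unit)
    rate_cap: float = 100.0  # LGN Poisson rate saturation (Hz)
    patch_size: int = 16    # image patch side (pixels)
    mean_target_rate: float = 20.0  # diagnostic only: intended mean LGN rate (Hz)

    # -- neuron model -------------------------------------------------------
    tau_m: float = 10.0     # membrane time constant (ms)
    v_rest: float = 0.0     # resting / reset potential
    v_min: float = -10.0    # lower bound on membrane potential
    theta_init: float = 10.0  # initial adaptive spiking threshold
    dt: float = 1.0         # simulation step (ms)
    mu_xi: float = 0.0      # mean of per-step membrane current noise
    sigma_xi: float = 1.0   # SD of per-step membrane current noise

    # -- L1 weight-norm upper bounds (per postsynaptic row) ------------------
    l1_ex: float | np.ndarray = 100.0
    l1_ee: float | np.ndarray = 10.0
    l1_ei: float | np.ndarray = 120.0
    l1_ix: float | np.ndarray = 80.0
    l1_ie: float | np.ndarray = 240.0
    l1_ii: float | np.ndarray = 120.0

    # -- plasticity ---------------------------------------------------------
    rho_e: float = 2.0      # target excitatory rate (Hz)
    rho_i: float = 4.0      # target inhibitory rate (Hz), 2 * rho_e
    tau_p: float = 20.0     # triplet potentiation trace time constant (ms)
    tau_d: float = 20.0     # triplet depression trace time constant (ms)
    tau_a: float = 50.0     # slow postsynaptic (rate) trace time constant (ms)
    a_p: float = 1.0        # triplet potentiation amplitude
    a_d: float = 0.1        # triplet depression amplitude, rho_e * tau_a (s)
    tau_sym: float = 20.0   # symmetric STDP trace time constant (ms)
    a_sym: float = 0.5      # symmetric STDP amplitude
    eta_ex: float | np.ndarray = 2e-4
    eta_ee: float | np.ndarray = 1e-4
    eta_ei: float | np.ndarray = 9e-2
    eta_ix: float | np.ndarray = 3e-3
    eta_ie: float | np.ndarray = 4e-2
    eta_ii: float | np.ndarray = 6e-2
    eta_theta_e: float = 0.1
    eta_theta_i: float = 0.1
    delta_theta_cap: float = 4.0  # max |threshold change| per presentation

    # -- schedule -----------------------------------------------------------
    n_batches: int = 1200
    batch_size: int = 100
    presentation_ms: float = 400.0
    warmup_batches: int = 100
    anneal_points: tuple = (0.3, 0.6)  # fractions of n_batches where rates halve

    # -- weight initialization ----------------------------------------------
    strong_prob: float = 0.2
    strong_mean: float = 1.0
    strong_sd: float = 0.5
    weak_factor: float = 0.01

    # -- stimulus pool ------------------------------------------------------
    n_images: int = 100      # synthetic natural images generated when none are given
    image_size: int = 64     # side of the synthetic images (pixels)
    pool_size: int = 1000    # sampled patch pool for training

    # -- bookkeeping --------------------------------------------------------
    checkpoint_every: int = 50  # batches between checkpoints
    size_l1_scaling: str = "linear"  # how L1 bounds scale with network size

    def __post_init__(self):
        for g in WEIGHT_GROUPS:
            setattr(self, f"l1_{g}", _as_float_or_array(getattr(self, f"l1_{g}")))
            setattr(self, f"eta_{g}", _as_float_or_array(getattr(self, f"eta_{g}")))
        self.anneal_points = tuple(float(a) for a in self.anneal_points)

    # -- validation ---------------------------------------------------------
    def validate(self, strict: bool = True) -> "RunConfig":
        """Check hard invariants; warn on violated derived relations.

        Raises :class:`ConfigurationError` listing every hard failure.
        """
        errs = []
        positive = [
            "tau_m", "dt", "cr", "rate_cap", "rho_e", "rho_i", "tau_p", "tau_d",
            "tau_a", "a_p", "a_d", "tau_sym", "a_sym", "eta_theta_e",
            "eta_theta_i", "delta_theta_cap", "presentation_ms", "sigma_c",
            "sigma_s", "sigma_d",
        ]
        for name in positive:
            if not np.all(np.asarray(getattr(self, name)) > 0):
                errs.append(f"{name} must be > 0")
        for g in WEIGHT_GROUPS:
            if not np.all(np.asarray(getattr(self, f"l1_{g}")) > 0):
                errs.append(f"l1_{g} must be > 0")
            if not np.all(np.asarray(getattr(self, f"eta_{g}")) >= 0):
                errs.append(f"eta_{g} must be >= 0")
        if self.patch_size < 2:
            errs.append("patch_size must be >= 2")
        if not (self.sigma_c < self.sigma_s):
            errs.append("sigma_c must be < sigma_s")
        if self.n_x % (2 * self.patch_size ** 2) != 0 or self.n_x < 2 * self.patch_size ** 2:
            errs.append("n_x must be a positive multiple of 2 * patch_size**2 "
                        "(c_n ON and OFF units per pixel)")
        if min(self.n_e, self.n_i) < 1:
            errs.append("n_e and n_i must be >= 1")
        if not (self.v_min < self.theta_init):
            errs.append("v_min must be < theta_init")
        if self.tau_a <= self.tau_p:
            errs.append("tau_a must be > tau_p (slow rate trace)")
        if self.warmup_batches < 0 or self.n_batches < 1 or self.batch_size < 1:
            errs.append("schedule sizes must be positive (warmup_batches >= 0)")
        pts = self.anneal_points
        if any(not (0 < a < 1) for a in pts) or list(pts) != sorted(set(pts)):
            errs.append("anneal_points must be strictly increasing fractions in (0, 1)")
        if not (0 <= self.strong_prob <= 1):
            errs.append("strong_prob must lie in [0, 1]")
        if self.sigma_xi < 0:
            errs.append("sigma_xi must be >= 0")
        if self.rate_cap * self.dt / 1000.0 > 1:
            errs.append("rate_cap * dt must not exceed one spike per step")
        if self.size_l1_scaling not in ("linear", "sqrt"):
            errs.append("size_l1_scaling must be 'linear' or 'sqrt'")
        if errs:
            raise ConfigurationError("invalid configuration: " + "; ".join(errs))

        if strict:
            # derived relations: warn, do not fail
            a_d_expected = self.rho_e * self.tau_a / 1000.0
            if not np.isclose(self.a_d, a_d_expected, rtol=1e-6):
                warnings.warn(
                    f"a_d={self.a_d} != rho_e*tau_a={a_d_expected}; the triplet "
                    "threshold phi will not equal the excitatory target rate",
                    stacklevel=2,
                )
            if not np.isclose(self.rho_i, 2 * self.rho_e, rtol=1e-6):
                warnings.warn("rho_i != 2 * rho_e", stacklevel=2)
        return self

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        d = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, np.ndarray):
                v = v.tolist()
            elif isinstance(v, tuple):
                v = list(v)
            d[f.name] = v
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**d)

    def replace(self, **kw) -> "RunConfig":
        return dataclasses.replace(self, **kw)


def desk_scale_config(**overrides) -> RunConfig:
    """Scaled-down preset: 8x8 patches, 64 E / 16 I neurons, 150 batches of 50.

    L1 bounds scale in proportion to the presynaptic population size (mean
    weights unchanged) and STDP learning rates are multiplied by twice the
    presentation-count ratio of the full schedule to this one: parity in
    cumulative weight drift alone leaves the short schedule well short of the
    learning fixed point, and doubling it brings weight reorganization to
    saturation while threshold homeostasis holds rates at target throughout
    (derivation and diagnostics in docs/methods.md).
    """
    full = RunConfig()
    patch = 8
    n_e, n_i = 64, 16
    n_x = 2 * patch ** 2
    size_ratio = {"x": n_x / full.n_x, "e": n_e / full.n_e, "i": n_i / full.n_i}
    pre_of = {"ex": "x", "ee": "e", "ei": "i", "ix": "x", "ie": "e", "ii": "i"}
    n_batches, batch_size = 150, 50
    eta_mult = 2 * (full.n_batches * full.batch_size) / (n_batches * batch_size)
    kw = dict(
        patch_size=patch, n_x=n_x, n_e=n_e, n_i=n_i,
        n_batches=n_batches, batch_size=batch_size, warmup_batches=15,
        image_size=32, n_images=100, pool_size=1000, checkpoint_every=50,
    )
    for g in WEIGHT_GROUPS:
        kw[f"l1_{g}"] = getattr(full, f"l1_{g}") * size_ratio[pre_of[g]]
        kw[f"eta_{g}"] = getattr(full, f"eta_{g}") * eta_mult
    kw.update(overrides)
    return RunConfig(**kw).validate()


def load_config(path) -> RunConfig:
    """Read a YAML config file; missing keys fall back to the defaults."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigurationError(f"config file {path} does not contain a mapping")
    cfg = RunConfig.from_dict(data)
    cfg.validate()
    return cfg


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)


def config_hash(cfg: RunConfig) -> str:
    """Stable hash of the full parameter set (used in run manifests)."""
    blob = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()
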