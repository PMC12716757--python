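"""Training protocol: initialization, balance check, schedule, robustness.

A run proceeds in two phases.  During warm-up only the adaptive spiking
threshold is active, letting thresholds settle under the initial weights.
Training then presents batches of image patches (each for T = 400 ms by
default) with full plasticity; per presentation the thresholds are updated
and every weight row is re-normalized to its L1 bound.  Learning and
homeostatic rates are halved at 0.3 and 0.6 of the training batches.

The robustness protocols transform a configuration: per-neuron jitter of the
L1 bounds (with learning rates rescaled in proportion), target-rate overrides
(which move the triplet threshold phi with the target rate and rescale
learning rates to keep drift per presentation invariant), and integer network
size multipliers.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import WEIGHT_GROUPS, RunConfig
from .errors import ConfigurationError, NumericalInstabilityError
from .network import (NetworkState, NeuronParams, Topology, WeightMatrices,
                      run_presentation)
from .plasticity import (HomeostasisParams, NormalizationBounds,
                         SymmetricParams, TripletParams, normalize_rows,
                         update_threshold)
from .stimuli import (LgnConfig, StimulusBatch, encode_on_off,
                      generate_synthetic_images, normalize_filtered,
                      dog_filter, sample_patches)

__all__ = [
    "InitSpec", "TrainingSchedule", "RobustnessSpec", "BalanceReport",
    "init_weights", "check_balance_condition", "Trainer", "train",
    "apply_l1_jitter", "apply_rate_override", "apply_size_multiplier",
    "weights_hash", "build_patch_pool",
]

_POST_POP = {"ex": "e", "ee": "e", "ei": "e", "ix": "i", "ie": "i", "ii": "i"}
_PRE_POP = {"ex": "x", "ee": "e", "ei": "i", "ix": "x", "ie": "e", "ii": "i"}


@dataclass
class InitSpec:
    """Sparse random initialization: strong entries with probability p."""

    strong_prob: float = 0.2
    strong_mean: float = 1.0
    strong_sd: float = 0.5
    weak_factor: float = 0.01

    def __post_init__(self):
        if not (0 <= self.strong_prob <= 1):
            raise ConfigurationError("strong_prob must lie in [0, 1]")

    @classmethod
    def from_run_config(cls, cfg: RunConfig) -> "InitSpec":
        return cls(cfg.strong_prob, cfg.strong_mean, cfg.strong_sd,
                   cfg.weak_factor)


@dataclass
class TrainingSchedule:
    n_batches: int = 1200
    batch_size: int = 100
    presentation_ms: float = 400.0
    warmup_batches: int = 100
    anneal_points: tuple = (0.3, 0.6)

    def __post_init__(self):
        if self.warmup_batches < 0:
            raise ConfigurationError("warmup_batches must be >= 0")
        pts = tuple(self.anneal_points)
        if any(not (0 < a < 1) for a in pts) or list(pts) != sorted(set(pts)):
            raise ConfigurationError(
                "anneal_points must be strictly increasing in (0, 1)")

    @classmethod
    def from_run_config(cls, cfg: RunConfig) -> "TrainingSchedule":
        return cls(cfg.n_batches, cfg.batch_size, cfg.presentation_ms,
                   cfg.warmup_batches, cfg.anneal_points)

    def anneal_batches(self):
        return [int(round(a * self.n_batches)) for a in self.anneal_points]

    def eta_scale(self, batch: int) -> float:
        """Learning-rate multiplier in force during training batch ``batch``."""
        return 0.5 ** sum(batch >= ab for ab in self.anneal_batches())


@dataclass
class RobustnessSpec:
    """Drivers of the three robustness sweeps."""

    jitter_amplitude: float = 0.0       # c in [0, 1)
    size_multiplier: int = 1            # c_n
    target_rate_override: float | None = None  # rho_e replacement (Hz)

    def __post_init__(self):
        if not (0 <= self.jitter_amplitude < 1):
            raise ConfigurationError("jitter amplitude must lie in [0, 1)")
        if self.size_multiplier < 1:
            raise ConfigurationError("size multiplier must be >= 1")


@dataclass
class BalanceReport:
    ratio_feedforward: float   # mean(W^EX) / mean(W^IX)
    ratio_inhibitory: float    # mean(W^EI) / mean(W^II)
    ratio_recurrent: float     # mean(W^EE) / mean(W^EI)
    satisfied: bool

    @property
    def ratios(self):
        return (self.ratio_feedforward, self.ratio_inhibitory,
                self.ratio_recurrent)


def check_balance_condition(bounds: NormalizationBounds,
                            topology: Topology) -> BalanceReport:
    """Check the balanced-network inequality chain on the L1 bounds.

    Mean weights are estimated as l1^{AB} / N_B (uniform-row construction);
    stability requires  w_EX/w_IX > w_EI/w_II > w_EE/w_EI  strictly.
    """
    n_pre = {"x": topology.n_x, "e": topology.n_e, "i": topology.n_i}
    mean_w = {}
    for g in WEIGHT_GROUPS:
        mean_w[g] = float(np.mean(bounds.get(g))) / n_pre[_PRE_POP[g]]
    for denom in ("ix", "ii", "ei"):
        if mean_w[denom] == 0:
            raise ConfigurationError(f"mean weight of group {denom} is zero")
    r1 = mean_w["ex"] / mean_w["ix"]
    r2 = mean_w["ei"] / mean_w["ii"]
    r3 = mean_w["ee"] / mean_w["ei"]
    return BalanceReport(r1, r2, r3, bool(r1 > r2 > r3))


def init_weights(topology: Topology, spec: InitSpec,
                 bounds: NormalizationBounds,
                 rng: np.random.Generator) -> WeightMatrices:
    """Sparse random weights, each row scaled exactly to its L1 bound.

    Entries are b with probability p and 0.01*b otherwise, b ~ N(1, 0.5) drawn
    per entry and clipped at zero; lateral diagonals are zeroed before the
    multiplicative row scaling.
    """
    n = {"x": topology.n_x, "e": topology.n_e, "i": topology.n_i}
    mats = {}
    for g in WEIGHT_GROUPS:
        shape = (n[_POST_POP[g]], n[_PRE_POP[g]])
        strong = rng.random(shape) < spec.strong_prob
        b = spec.strong_mean + spec.strong_sd * rng.standard_normal(shape)
        w = np.where(strong, b, spec.weak_factor * b)
        np.maximum(w, 0.0, out=w)
        if g in ("ee", "ii"):
            np.fill_diagonal(w, 0.0)
        bound = np.broadcast_to(np.atleast_1d(bounds.get(g)), (shape[0],))
        sums = w.sum(axis=1)
        dead = sums <= 0
        if np.any(dead):  # pathological all-zero row: fall back to uniform
            w[dead] = 1.0
            if g in ("ee", "ii"):
                np.fill_diagonal(w, 0.0)
            sums = w.sum(axis=1)
        w *= (bound / sums)[:, None]
        mats[g] = w
    return WeightMatrices(**{f"w_{g}": mats[g] for g in WEIGHT_GROUPS})


def build_patch_pool(cfg: RunConfig, seed_seq: np.random.SeedSequence) -> StimulusBatch:
    """Deterministic training patch pool from synthetic 1/f images.

    Images are generated, center-surround filtered, normalized to unit SD, and
    ``cfg.pool_size`` patches are sampled and rectified into ON/OFF rates.
    The pool is a pure function of (config, seed), so checkpoints do not need
    to store it.
    """
    img_seed, patch_seed = [int(s.generate_state(1)[0] % (2 ** 31))
                            for s in seed_seq.spawn(2)]
    lgn = LgnConfig.from_run_config(cfg)
    images = generate_synthetic_images(cfg.n_images, cfg.image_size, img_seed,
                                       patch_size=cfg.patch_size)
    processed = np.stack([
        normalize_filtered(dog_filter(img, lgn)) for img in images])
    patches = sample_patches(processed, cfg.pool_size, cfg.patch_size,
                             patch_seed)
    return encode_on_off(patches, lgn)


def weights_hash(weights: WeightMatrices) -> str:
    h = hashlib.sha256()
    for g in WEIGHT_GROUPS:
        h.update(np.ascontiguousarray(weights.get(g)).tobytes())
    return h.hexdigest()


class Trainer:
    """Stateful training run; resumable from a checkpoint.

    The global seed expands into named independent streams (weight init,
    patch pool, presentation order, membrane/LGN dynamics) so robustness
    sweeps can vary one source of randomness at a time.
    """

    def __init__(self, config: RunConfig, seed: int,
                 patch_pool: StimulusBatch | None = None):
        config.validate()
        self.config = config
        self.seed = int(seed)
        ss = np.random.SeedSequence(self.seed)
        init_ss, pool_ss, stim_ss, dyn_ss = ss.spawn(4)
        self.stim_rng = np.random.default_rng(stim_ss)
        self.dyn_rng = np.random.default_rng(dyn_ss)

        self.topology = Topology.from_run_config(config)
        self.params = NeuronParams.from_run_config(config)
        self.triplet = TripletParams.from_run_config(config)
        self.symmetric = SymmetricParams.from_run_config(config)
        self.homeo = HomeostasisParams.from_run_config(config)
        self.bounds = NormalizationBounds.from_run_config(config)
        self.schedule = TrainingSchedule.from_run_config(config)

        self.pool = patch_pool if patch_pool is not None \
            else build_patch_pool(config, pool_ss)
        pool_rates = self.pool.rates
        m, rem = divmod(self.topology.n_x, pool_rates.shape[1])
        if rem:
            raise ConfigurationError(
                "n_x is not a multiple of the pool's ON+OFF vector length")
        # size-multiplied networks replicate the ON/OFF vector per pixel copy
        self._pool_rates = np.tile(pool_rates, m) if m > 1 else pool_rates

        self.weights = init_weights(self.topology,
                                    InitSpec.from_run_config(config),
                                    self.bounds,
                                    np.random.default_rng(init_ss))
        self.state = NetworkState.initial(self.topology, self.params,
                                          self.triplet, self.symmetric)
        self.warmup_done = 0
        self.batches_done = 0
        self.log_rows: list[dict] = []

    # -- bookkeeping --------------------------------------------------------
    @property
    def log(self) -> pd.DataFrame:
        return pd.DataFrame(self.log_rows)

    @property
    def finished(self) -> bool:
        return (self.warmup_done >= self.schedule.warmup_batches
                and self.batches_done >= self.schedule.n_batches)

    def _check_finite(self, where: str) -> None:
        ok = all(np.all(np.isfinite(self.weights.get(g)))
                 for g in WEIGHT_GROUPS)
        ok = ok and np.all(np.isfinite(self.state.v_e)) \
            and np.all(np.isfinite(self.state.theta_e))
        if not ok:
            raise NumericalInstabilityError(f"non-finite state after {where}")

    def _run_batch(self, plasticity: bool, eta_scale: float) -> dict:
        cfg = self.config
        dur_s = cfg.presentation_ms / 1000.0
        sum_e = 0.0
        sum_i = 0.0
        for _ in range(cfg.batch_size):
            idx = int(self.stim_rng.integers(len(self.pool)))
            rec = run_presentation(
                self.state, self.weights, self._pool_rates[idx],
                cfg.presentation_ms, self.params, self.dyn_rng,
                triplet=self.triplet, symmetric=self.symmetric,
                plasticity_enabled=plasticity, eta_scale=eta_scale)
            self.state.theta_e = update_threshold(
                self.state.theta_e, rec.counts_e, dur_s, self.homeo.rho_e,
                self.homeo.eta_theta_e * eta_scale, self.homeo.delta_theta_cap)
            self.state.theta_i = update_threshold(
                self.state.theta_i, rec.counts_i, dur_s, self.homeo.rho_i,
                self.homeo.eta_theta_i * eta_scale, self.homeo.delta_theta_cap)
            if plasticity:
                for g in WEIGHT_GROUPS:
                    normalize_rows(self.weights.get(g), self.bounds.get(g))
            sum_e += rec.counts_e.mean()
            sum_i += rec.counts_i.mean()
        row = {
            "mean_rate_e": sum_e / (cfg.batch_size * dur_s),
            "mean_rate_i": sum_i / (cfg.batch_size * dur_s),
            "mean_theta_e": float(self.state.theta_e.mean()),
            "mean_theta_i": float(self.state.theta_i.mean()),
            "eta_scale": eta_scale,
            "eta_ex": float(np.mean(self.triplet.eta_ex) * eta_scale),
        }
        for g in WEIGHT_GROUPS:
            norms = self.weights.get(g).sum(axis=1)
            cap = np.broadcast_to(np.atleast_1d(self.bounds.get(g)),
                                  norms.shape)
            row[f"sat_{g}"] = float(np.mean(norms >= cap - 1e-6))
        return row

    def run(self, n_batches: int | None = None,
            checkpoint_dir=None, progress: bool = False) -> "Trainer":
        """Advance the run by ``n_batches`` (default: to completion).

        Warm-up batches (threshold adaptation only, no weight plasticity) are
        consumed first; checkpoints are written every ``checkpoint_every``
        batches and at the anneal points when ``checkpoint_dir`` is given.
        """
        remaining = n_batches
        anneals = set(self.schedule.anneal_batches())
        while not self.finished and (remaining is None or remaining > 0):
            if self.warmup_done < self.schedule.warmup_batches:
                row = self._run_batch(plasticity=False, eta_scale=1.0)
                self.warmup_done += 1
                row.update(phase="warmup", batch=self.warmup_done)
            else:
                scale = self.schedule.eta_scale(self.batches_done)
                row = self._run_batch(plasticity=True, eta_scale=scale)
                self.batches_done += 1
                row.update(phase="train", batch=self.batches_done)
                if checkpoint_dir is not None and (
                        self.batches_done % self.config.checkpoint_every == 0
                        or self.batches_done in anneals):
                    self.checkpoint(checkpoint_dir)
            self.log_rows.append(row)
            if remaining is not None:
                remaining -= 1
            try:
                self._check_finite(f"batch {row['phase']}:{row['batch']}")
            except NumericalInstabilityError:
                if checkpoint_dir is not None:
                    self.checkpoint(checkpoint_dir, tag="diagnostic")
                raise
            if progress:  # pragma: no cover - cosmetic
                print(f"{row['phase']} batch {row['batch']}: "
                      f"E {row['mean_rate_e']:.2f} Hz, "
                      f"I {row['mean_rate_i']:.2f} Hz")
        return self

    def checkpoint(self, directory, tag: str | None = None):
        from . import io as _io
        import pathlib
        directory = pathlib.Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        name = tag or f"batch{self.batches_done:05d}"
        path = directory / f"checkpoint_{name}.h5"
        _io.save_checkpoint(path, self)
        return path

    # -- convenience views used by the analysis layer -----------------------
    @property
    def lgn(self) -> LgnConfig:
        return LgnConfig.from_run_config(self.config)


def train(config: RunConfig, seed: int,
          patch_pool: StimulusBatch | None = None,
          checkpoint_dir=None, progress: bool = False) -> Trainer:
    """Run the full protocol (warm-up + all batches); returns the Trainer.

    A warning-level balance check is performed first: a violated inequality
    chain does not abort the run but is reported.
    """
    report = check_balance_condition(NormalizationBounds.from_run_config(config),
                                     Topology.from_run_config(config))
    if not report.satisfied:
        import warnings
        warnings.warn(
            f"balance condition violated: ratios {report.ratios}", stacklevel=2)
    trainer = Trainer(config, seed, patch_pool=patch_pool)
    return trainer.run(checkpoint_dir=checkpoint_dir, progress=progress)


# -- robustness transforms ---------------------------------------------------

def apply_l1_jitter(config: RunConfig, c: float, seed: int) -> RunConfig:
    """Per-postsynaptic-neuron jitter of the L1 bounds by U(1-c, 1+c).

    Learning rates are rescaled by the same per-neuron factor so that relative
    weight drift per presentation is unchanged.
    """
    if not (0 <= c < 1):
        raise ConfigurationError("jitter amplitude c must lie in [0, 1)")
    if c == 0:
        return config.replace()
    rng = np.random.default_rng(seed)
    n_post = {"e": config.n_e, "i": config.n_i}
    kw = {}
    for g in WEIGHT_GROUPS:
        factors = rng.uniform(1.0 - c, 1.0 + c, size=n_post[_POST_POP[g]])
        kw[f"l1_{g}"] = np.asarray(getattr(config, f"l1_{g}")) * factors
        kw[f"eta_{g}"] = np.asarray(getattr(config, f"eta_{g}")) * factors
    return config.replace(**kw)


def apply_rate_override(config: RunConfig, rho_e_new: float) -> RunConfig:
    """Retarget the excitatory rate; inhibitory target stays at twice it.

    The triplet depression amplitude follows A_d = rho_e * tau_a so the
    potentiation/depression threshold phi moves with the target rate, and
    learning rates are rescaled by one factor rho_old/rho_new per synapse
    terminal whose target rate changed (X terminals are unchanged).
    """
    if rho_e_new <= 0:
        raise ConfigurationError("rho_e must be > 0")
    if rho_e_new == config.rho_e:
        return config.replace()
    k = config.rho_e / rho_e_new  # = rho_old / rho_new
    return config.replace(
        rho_e=rho_e_new,
        rho_i=2.0 * rho_e_new,
        a_d=rho_e_new * config.tau_a / 1000.0,
        eta_ex=np.asarray(config.eta_ex) * k,
        eta_ee=np.asarray(config.eta_ee) * k ** 2,
        eta_ei=np.asarray(config.eta_ei) * k ** 2,
        eta_ix=np.asarray(config.eta_ix) * k,
        eta_ie=np.asarray(config.eta_ie) * k ** 2,
        eta_ii=np.asarray(config.eta_ii) * k ** 2,
    )


def apply_size_multiplier(config: RunConfig, c_n: int) -> RunConfig:
    """Scale all population sizes by an integer factor.

    There are c_n ON and OFF units per pixel.  L1 bounds scale in proportion
    to the presynaptic population (or its square root with the
    ``size_l1_scaling='sqrt'`` convention) and learning rates follow the
    bounds, so the balance ratios are unchanged.
    """
    if int(c_n) != c_n or c_n < 1:
        raise ConfigurationError("size multiplier c_n must be an integer >= 1")
    c_n = int(c_n)
    if c_n == 1:
        return config.replace()
    factor = float(c_n) if config.size_l1_scaling == "linear" else float(np.sqrt(c_n))
    kw = dict(n_x=config.n_x * c_n, n_e=config.n_e * c_n,
              n_i=config.n_i * c_n)
    for g in WEIGHT_GROUPS:
        kw[f"l1_{g}"] = np.asarray(getattr(config, f"l1_{g}")) * factor
        kw[f"eta_{g}"] = np.asarray(getattr(config, f"eta_{g}")) * factor
    return config.replace(**kw)
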