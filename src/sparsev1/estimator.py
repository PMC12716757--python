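"""Scikit-learn-style front end to the spiking V1 network.

`SpikingV1Coder` treats the network as an unsupervised transformer: ``fit``
trains the synaptic weights and thresholds on a set of filtered image
patches via STDP and homeostasis; ``transform`` maps patches to evoked
excitatory firing-rate vectors of the trained network.  It composes with
sklearn pipelines and model selection (``get_params`` / ``set_params`` /
``clone`` follow the estimator contract).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .analysis import estimate_sta, measure_rates
from .config import RunConfig, desk_scale_config
from .errors import ConfigurationError
from .network import Topology
from .plasticity import NormalizationBounds
from .stimuli import LgnConfig, encode_on_off
from .training import Trainer, check_balance_condition

__all__ = ["SpikingV1Coder"]


class SpikingV1Coder(BaseEstimator, TransformerMixin):
    """Spiking sparse-coding model of V1 as an unsupervised transformer.

    Parameters
    ----------
    patch_size : side of the square input patches in pixels.
    n_excitatory, n_inhibitory : output population sizes.
    rho_e : target excitatory firing rate (Hz); the inhibitory target is
        twice it and the triplet-STDP threshold phi is tied to it.
    n_batches, batch_size, presentation_ms, warmup_batches : schedule.
    desk_scale : when True (default) the remaining parameters default to the
        scaled-down preset rather than the full-size reference network.
    config : a fully specified :class:`RunConfig`; overrides everything else.
    random_state : seed for all streams (init, stimuli, dynamics).

    Attributes (after ``fit``)
    --------------------------
    trainer_ : the underlying :class:`Trainer` (weights, state, log).
    weights_ : the six learned weight matrices.
    theta_e_, theta_i_ : adapted spiking thresholds.
    log_ : per-batch training log (DataFrame).
    """

    def __init__(self, patch_size=8, n_excitatory=64, n_inhibitory=16,
                 rho_e=2.0, n_batches=150, batch_size=50,
                 presentation_ms=400.0, warmup_batches=15,
                 desk_scale=True, config=None, random_state=None):
        self.patch_size = patch_size
        self.n_excitatory = n_excitatory
        self.n_inhibitory = n_inhibitory
        self.rho_e = rho_e
        self.n_batches = n_batches
        self.batch_size = batch_size
        self.presentation_ms = presentation_ms
        self.warmup_batches = warmup_batches
        self.desk_scale = desk_scale
        self.config = config
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _build_config(self) -> RunConfig:
        if self.config is not None:
            return self.config
        base = desk_scale_config() if self.desk_scale else RunConfig()
        kw = dict(
            patch_size=self.patch_size,
            n_x=2 * self.patch_size ** 2,
            n_e=self.n_excitatory, n_i=self.n_inhibitory,
            n_batches=self.n_batches, batch_size=self.batch_size,
            presentation_ms=self.presentation_ms,
            warmup_batches=self.warmup_batches,
        )
        cfg = base.replace(**kw)
        if self.rho_e != cfg.rho_e:
            from .training import apply_rate_override
            cfg = apply_rate_override(cfg, self.rho_e)
        return cfg.validate()

    def _patch_batch(self, X, cfg):
        X = np.asarray(X, dtype=float)
        p = cfg.patch_size
        if X.ndim == 2:
            if X.shape[1] != p * p:
                raise ConfigurationError(
                    f"flat patches must have {p * p} columns")
            X = X.reshape(-1, p, p)
        elif X.ndim != 3 or X.shape[1:] != (p, p):
            raise ConfigurationError(f"patches must be (n, {p}, {p})")
        return encode_on_off(X, LgnConfig.from_run_config(cfg))

    # ------------------------------------------------------------------
    def fit(self, X=None, y=None):
        """Train on filtered patches ``X`` (n, p, p); synthetic 1/f stimuli
        are generated when ``X`` is None."""
        cfg = self._build_config()
        seed = 0 if self.random_state is None else int(self.random_state)
        pool = None if X is None else self._patch_batch(X, cfg)
        self.balance_report_ = check_balance_condition(
            NormalizationBounds.from_run_config(cfg),
            Topology.from_run_config(cfg))
        self.trainer_ = Trainer(cfg, seed, patch_pool=pool).run()
        self.weights_ = self.trainer_.weights
        self.theta_e_ = self.trainer_.state.theta_e
        self.theta_i_ = self.trainer_.state.theta_i
        self.log_ = self.trainer_.log
        self.config_ = cfg
        return self

    def transform(self, X):
        """Evoked excitatory firing rates (Hz), shape (n_samples, n_e)."""
        if not hasattr(self, "trainer_"):
            raise ConfigurationError("estimator is not fitted")
        batch = self._patch_batch(X, self.config_)
        rates = measure_rates(self.trainer_, batch.rates,
                              self.config_.presentation_ms,
                              seed=0 if self.random_state is None
                              else int(self.random_state) + 1)
        return rates["E"].T

    def receptive_fields(self, n_stimuli=10_000, duration_ms=200.0,
                         population="E", seed=None):
        """Spike-triggered-average receptive fields of the fitted network."""
        if not hasattr(self, "trainer_"):
            raise ConfigurationError("estimator is not fitted")
        s = (0 if self.random_state is None else int(self.random_state)) + 2
        return estimate_sta(self.trainer_, n_stimuli,
                            seed=s if seed is None else seed,
                            duration_ms=duration_ms, population=population)
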