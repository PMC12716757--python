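"""Post-hoc quantification of a trained network.

* **Receptive fields** by spike-triggered averaging of Gaussian white-noise
  stimuli: F = sum_i r_i n_i / sum_i r_i over the raw noise fields.
* **Gabor fits** of the STA maps (sinusoidal plane wave times a 2D Gaussian
  envelope), with the fit error defined as SSR / sum(RF^2); a receptive field
  is "well fit" below 10 % error.  The shape descriptors n_x = sigma_x * f_s
  and n_y = sigma_y * f_s express envelope width/length in cycles.
* **Treves-Rolls sparseness**, temporal (per neuron over images) and
  population (per image over neurons):  s = 1 - (mean r)^2 / mean(r^2).
* **Correlation structure** of firing rates and of receptive-field maps, and
  the weight-versus-RF-correlation profiles that expose the decorrelation
  mechanism.
* **Excitatory/inhibitory balance**: threshold-free voltage probes under
  excitation-only / inhibition-only / full input (loose balance across
  stimulus drive levels; tight balance as the lagged cross-correlation of the
  excitatory trace with the magnitude of the inhibitory trace).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize, stats

from .errors import ConfigurationError, DegenerateInputError
from .network import ProbeTraces, run_presentation, NetworkState
from .stimuli import white_noise_batch

__all__ = [
    "ReceptiveFieldSet", "GaborFit", "SparsenessResult", "Correlogram",
    "LooseBalanceResult", "WeightCorrelationProfile",
    "estimate_sta", "measure_rates", "fit_gabor", "upsample_rf",
    "temporal_sparseness", "population_sparseness", "sorted_tuning_curves",
    "rate_correlation_matrix", "rf_correlation_matrix",
    "weight_vs_rf_correlation", "probe_neuron", "probe_loose_balance",
    "tight_balance_xcorr",
]

BALANCE_CATEGORIES = ("anti_correlated", "uncorrelated", "correlated")


# ---------------------------------------------------------------------------
# spike-triggered averages
# ---------------------------------------------------------------------------

@dataclass
class ReceptiveFieldSet:
    """Per-neuron STA maps (n_neurons, p, p) with a responsiveness mask."""

    maps: np.ndarray
    responsive: np.ndarray
    population: str
    n_stimuli: int

    def __len__(self):
        return self.maps.shape[0]


def _fresh_probe_state(trainer) -> NetworkState:
    st = trainer.state
    return NetworkState(st.v_e.copy(), st.v_i.copy(), st.theta_e.copy(),
                        st.theta_i.copy(), st.traces)


def measure_rates(trainer, rates_matrix: np.ndarray, duration_ms: float,
                  seed: int = 0) -> dict:
    """Evoked firing rates (Hz) of X, E and I for each stimulus row.

    Each stimulus is presented independently (membranes reset between
    presentations) with plasticity off and thresholds as trained.
    """
    state = _fresh_probe_state(trainer)
    rng = np.random.default_rng(seed)
    m = trainer.topology.n_x // rates_matrix.shape[1]
    dur_s = duration_ms / 1000.0
    out = {"X": [], "E": [], "I": []}
    for row in rates_matrix:
        full = np.tile(row, m) if m > 1 else row
        state.reset_membranes(trainer.params)
        rec = run_presentation(state, trainer.weights, full, duration_ms,
                               trainer.params, rng)
        out["X"].append(rec.counts_x / dur_s)
        out["E"].append(rec.counts_e / dur_s)
        out["I"].append(rec.counts_i / dur_s)
    return {k: np.array(v).T for k, v in out.items()}  # neurons x stimuli


def estimate_sta(trainer, n_stimuli: int, seed: int = 0,
                 duration_ms: float = 200.0, population: str = "E",
                 chunk: int = 1000) -> ReceptiveFieldSet:
    """Receptive fields as response-weighted averages of white-noise fields.

    Presents ``n_stimuli`` Gaussian white-noise stimuli (generated in chunks),
    records each neuron's spike rate, and averages the *raw* noise fields
    weighted by rate.  Neurons that never spike are flagged unresponsive and
    get an undefined (zero) map.
    """
    if n_stimuli < 1:
        raise ConfigurationError("n_stimuli must be >= 1")
    if population not in ("E", "I"):
        raise ConfigurationError("population must be 'E' or 'I'")
    lgn = trainer.lgn
    p = lgn.patch_size
    n_out = trainer.topology.n_e if population == "E" else trainer.topology.n_i
    m = trainer.topology.n_x // (2 * p * p)
    state = _fresh_probe_state(trainer)
    ss = np.random.SeedSequence(seed)
    noise_seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                   for s in ss.spawn((n_stimuli + chunk - 1) // chunk + 1)]
    rng = np.random.default_rng(noise_seeds[-1])
    dur_s = duration_ms / 1000.0
    weighted = np.zeros((n_out, p, p))
    total_rate = np.zeros(n_out)
    done = 0
    ci = 0
    while done < n_stimuli:
        n = min(chunk, n_stimuli - done)
        batch = white_noise_batch(n, lgn, noise_seeds[ci])
        ci += 1
        rates = batch.rates
        for k in range(n):
            full = np.tile(rates[k], m) if m > 1 else rates[k]
            state.reset_membranes(trainer.params)
            rec = run_presentation(state, trainer.weights, full, duration_ms,
                                   trainer.params, rng)
            counts = rec.counts_e if population == "E" else rec.counts_i
            r = counts / dur_s
            total_rate += r
            weighted += r[:, None, None] * batch.noise[k][None, :, :]
        done += n
    responsive = total_rate > 0
    maps = np.zeros_like(weighted)
    maps[responsive] = weighted[responsive] / total_rate[responsive, None, None]
    return ReceptiveFieldSet(maps=maps, responsive=responsive,
                             population=population, n_stimuli=n_stimuli)


def upsample_rf(rf_map: np.ndarray, factor: int = 10) -> np.ndarray:
    """Bilinear upsampling for display (the analysis always uses raw maps)."""
    return ndimage.zoom(np.asarray(rf_map, dtype=float), factor, order=1)


# ---------------------------------------------------------------------------
# Gabor fitting
# ---------------------------------------------------------------------------

@dataclass
class GaborFit:
    """Least-squares 2D Gabor description of a receptive-field map."""

    x0: float = np.nan
    y0: float = np.nan
    orientation: float = np.nan   # radians
    spatial_frequency: float = np.nan  # cycles / pixel
    sigma_x: float = np.nan       # envelope SD along the modulation axis
    sigma_y: float = np.nan
    phase: float = np.nan
    amplitude: float = np.nan
    fit_error: float = np.inf     # SSR / sum(RF^2)
    failed: bool = False

    @property
    def n_x(self) -> float:
        return self.sigma_x * self.spatial_frequency

    @property
    def n_y(self) -> float:
        return self.sigma_y * self.spatial_frequency

    @property
    def well_fit(self) -> bool:
        return (not self.failed) and self.fit_error < 0.10


def _gabor(theta_vec, X, Y):
    x0, y0, ori, fs, sx, sy, phase, amp = theta_vec
    dx, dy = X - x0, Y - y0
    xr = dx * np.cos(ori) + dy * np.sin(ori)
    yr = -dx * np.sin(ori) + dy * np.cos(ori)
    env = np.exp(-(xr ** 2 / (2 * sx ** 2) + yr ** 2 / (2 * sy ** 2)))
    return amp * env * np.cos(2 * np.pi * fs * xr + phase)


def _dominant_frequency(rf: np.ndarray) -> float:
    spec = np.abs(np.fft.fft2(rf))
    spec[0, 0] = 0.0
    f = np.fft.fftfreq(rf.shape[0])
    fr = np.hypot(f[:, None], f[None, :])
    return float(fr.flat[int(np.argmax(spec))])


def fit_gabor(rf_map: np.ndarray, n_orientations: int = 8) -> GaborFit:
    """Multi-start nonlinear least-squares Gabor fit of one STA map.

    The objective is multimodal in orientation and phase, so the optimizer is
    restarted on an orientation x phase grid (8 x 2 by default).  Envelope SDs
    are bounded to (0.3, 16) pixels and the spatial frequency to
    (0.02, 0.5) cycles/pixel.  A flat map is flagged as a failed fit.
    """
    rf = np.asarray(rf_map, dtype=float)
    total = float(np.sum(rf ** 2))
    if not np.all(np.isfinite(rf)) or total < 1e-20 or rf.std() < 1e-12:
        return GaborFit(failed=True)
    p = rf.shape[0]
    Y, X = np.mgrid[0:p, 0:p].astype(float)
    w = rf ** 2
    x0 = float((X * w).sum() / w.sum())
    y0 = float((Y * w).sum() / w.sum())
    amp0 = float(np.abs(rf).max())
    fs0 = float(np.clip(_dominant_frequency(rf), 0.03, 0.45))
    sig0 = max(p / 5.0, 0.5)
    lb = [-2.0, -2.0, -np.pi, 0.02, 0.3, 0.3, -2 * np.pi, 1e-6 * amp0]
    ub = [p + 1.0, p + 1.0, 2 * np.pi, 0.5, 16.0, 16.0, 2 * np.pi, 4.0 * amp0]

    def residuals(t):
        return (_gabor(t, X, Y) - rf).ravel()

    best = None
    for ori in np.linspace(0, np.pi, n_orientations, endpoint=False):
        for phase in (0.0, np.pi / 2):
            t0 = [x0, y0, ori, fs0, sig0, sig0, phase, amp0]
            t0 = np.clip(t0, lb, ub)
            try:
                sol = optimize.least_squares(residuals, t0, bounds=(lb, ub),
                                             max_nfev=400)
            except Exception:  # pragma: no cover - optimizer edge cases
                continue
            ssr = float(np.sum(sol.fun ** 2))
            if best is None or ssr < best[0]:
                best = (ssr, sol.x)
    if best is None:  # pragma: no cover
        return GaborFit(failed=True)
    # polish around the winner with perturbed spatial frequency (the fs /
    # envelope trade-off is the main residual ambiguity)
    for fs_scale in (0.75, 1.25):
        t0 = best[1].copy()
        t0[3] = np.clip(t0[3] * fs_scale, lb[3], ub[3])
        try:
            sol = optimize.least_squares(residuals, t0, bounds=(lb, ub),
                                         max_nfev=400)
        except Exception:  # pragma: no cover
            continue
        ssr = float(np.sum(sol.fun ** 2))
        if ssr < best[0]:
            best = (ssr, sol.x)
    ssr, t = best
    return GaborFit(x0=t[0], y0=t[1], orientation=t[2],
                    spatial_frequency=t[3], sigma_x=t[4], sigma_y=t[5],
                    phase=t[6], amplitude=t[7], fit_error=ssr / total)


# ---------------------------------------------------------------------------
# sparseness
# ---------------------------------------------------------------------------

@dataclass
class SparsenessResult:
    """Per-unit Treves-Rolls sparseness with undefined entries flagged."""

    values: np.ndarray        # NaN where undefined (all-zero response vector)
    axis: str                 # "temporal" or "population"
    mean: float
    n_excluded: int


def _treves_rolls(rows: np.ndarray, axis_tag: str) -> SparsenessResult:
    rows = np.asarray(rows, dtype=float)
    if rows.ndim != 2:
        raise ConfigurationError("rates must be a 2-D matrix")
    if np.any(rows < 0):
        raise ConfigurationError("rates must be non-negative")
    mean_sq = (rows ** 2).mean(axis=1)
    defined = mean_sq > 0
    values = np.full(rows.shape[0], np.nan)
    values[defined] = 1.0 - rows[defined].mean(axis=1) ** 2 / mean_sq[defined]
    mean = float(np.nanmean(values)) if defined.any() else np.nan
    return SparsenessResult(values=values, axis=axis_tag, mean=mean,
                            n_excluded=int((~defined).sum()))


def temporal_sparseness(rates: np.ndarray) -> SparsenessResult:
    """Lifetime sparseness: one value per neuron over its image responses."""
    return _treves_rolls(rates, "temporal")


def population_sparseness(rates: np.ndarray) -> SparsenessResult:
    """Population sparseness: one value per image over the population."""
    return _treves_rolls(np.asarray(rates).T, "population")


def sorted_tuning_curves(rates: np.ndarray, axis: str = "temporal") -> dict:
    """Mean sorted-response curve (each row or column sorted ascending).

    Returns the averaged curve plus a [0, 1]-normalized position axis so
    curves from populations of different size can be compared.
    """
    rates = np.asarray(rates, dtype=float)
    rows = rates if axis == "temporal" else rates.T
    curve = np.sort(rows, axis=1).mean(axis=0)
    n = curve.size
    position = np.linspace(0, 1, n) if n > 1 else np.zeros(1)
    return {"curve": curve, "position": position, "axis": axis}


# ---------------------------------------------------------------------------
# correlation structure
# ---------------------------------------------------------------------------

@dataclass
class RateCorrelation:
    matrix: np.ndarray
    valid: np.ndarray          # False for constant-rate neurons (excluded)
    offdiag: np.ndarray        # valid off-diagonal values
    mean_offdiag: float


def rate_correlation_matrix(rates: np.ndarray) -> RateCorrelation:
    """Pairwise Pearson correlation of firing rates across images."""
    rates = np.asarray(rates, dtype=float)
    if rates.ndim != 2 or rates.shape[1] < 2:
        raise DegenerateInputError("need at least 2 images to correlate rates")
    sd = rates.std(axis=1)
    valid = sd > 0
    n = rates.shape[0]
    matrix = np.full((n, n), np.nan)
    idx = np.flatnonzero(valid)
    if idx.size:
        sub = np.corrcoef(rates[idx])
        sub = np.atleast_2d(sub)
        matrix[np.ix_(idx, idx)] = sub
    iu = np.triu_indices(n, k=1)
    vals = matrix[iu]
    offdiag = vals[np.isfinite(vals)]
    mean = float(offdiag.mean()) if offdiag.size else np.nan
    return RateCorrelation(matrix=matrix, valid=valid, offdiag=offdiag,
                           mean_offdiag=mean)


def rf_correlation_matrix(rfs_a: np.ndarray, rfs_b: np.ndarray) -> np.ndarray:
    """Pearson correlation of flattened RF maps for every cross pair."""
    a = np.asarray(rfs_a, dtype=float)
    b = np.asarray(rfs_b, dtype=float)
    if a.ndim == 2:
        a = a[None]
    if b.ndim == 2:
        b = b[None]
    if a.shape[1:] != b.shape[1:]:
        raise DegenerateInputError(
            f"RF map shapes differ: {a.shape[1:]} vs {b.shape[1:]}")
    az = a.reshape(a.shape[0], -1)
    bz = b.reshape(b.shape[0], -1)

    def zscore(m):
        m = m - m.mean(axis=1, keepdims=True)
        sd = m.std(axis=1, keepdims=True)
        sd[sd == 0] = np.nan
        return m / sd

    az, bz = zscore(az), zscore(bz)
    return az @ bz.T / az.shape[1]


@dataclass
class WeightCorrelationProfile:
    rf_correlation: np.ndarray   # one value per synapse
    weight: np.ndarray
    bin_edges: np.ndarray
    bin_means: np.ndarray        # NaN where a bin is empty
    bin_counts: np.ndarray


def weight_vs_rf_correlation(w: np.ndarray, rf_corr: np.ndarray,
                             bin_width: float = 0.02) -> WeightCorrelationProfile:
    """(RF correlation, synaptic weight) pairs with binned mean weights."""
    w = np.asarray(w, dtype=float)
    rf_corr = np.asarray(rf_corr, dtype=float)
    if w.shape != rf_corr.shape:
        raise DegenerateInputError("weight and RF-correlation shapes differ")
    x = rf_corr.ravel()
    y = w.ravel()
    keep = np.isfinite(x)
    x, y = x[keep], y[keep]
    edges = np.arange(-1.0, 1.0 + bin_width / 2, bin_width)
    counts, _ = np.histogram(x, bins=edges)
    sums, _ = np.histogram(x, bins=edges, weights=y)
    means = np.full(counts.size, np.nan)
    nz = counts > 0
    means[nz] = sums[nz] / counts[nz]
    return WeightCorrelationProfile(rf_correlation=x, weight=y,
                                    bin_edges=edges, bin_means=means,
                                    bin_counts=counts)


# ---------------------------------------------------------------------------
# balance probes
# ---------------------------------------------------------------------------

def probe_neuron(trainer, rates: np.ndarray, neuron: int,
                 duration_ms: float = 400.0, seed: int = 0) -> ProbeTraces:
    """All three threshold-free voltage traces of one E neuron in one run."""
    state = _fresh_probe_state(trainer)
    state.reset_membranes(trainer.params)
    m = trainer.topology.n_x // rates.size
    full = np.tile(rates, m) if m > 1 else rates
    rng = np.random.default_rng(seed)
    rec = run_presentation(state, trainer.weights, full, duration_ms,
                           trainer.params, rng, probe_e=neuron)
    return rec.probe


@dataclass
class LooseBalanceResult:
    """Mean threshold-free voltages per stimulus category and probed neuron.

    Arrays have shape (3 categories, n_neurons); the categories are the
    pool patches most anti-correlated, nearest-zero-correlated and most
    correlated with each neuron's receptive field.
    """

    neurons: np.ndarray
    patch_index: np.ndarray     # (3, n) chosen pool patches
    mean_full: np.ndarray
    mean_exc: np.ndarray
    mean_inh: np.ndarray
    slope_exc_vs_inh: float     # excitation vs |inhibition| regression slope
    slope_total_vs_inh: float
    categories: tuple = BALANCE_CATEGORIES


def probe_loose_balance(trainer, pool_batch, rfs: ReceptiveFieldSet,
                        n_neurons: int = 40, seed: int = 0,
                        duration_ms: float = 400.0,
                        transient_ms: float = 100.0) -> LooseBalanceResult:
    """Loose-balance assay over anti-correlated/uncorrelated/correlated patches.

    For each probed neuron the patch pool is ranked by the Pearson correlation
    between the patch's filtered pixels and the neuron's STA map; the minimum,
    nearest-zero and maximum patches are presented while the neuron's
    threshold and clamp are removed, and the time-mean of the total,
    excitation-only and inhibition-only voltages (after the initial transient)
    is reported, together with excitation-versus-|inhibition| regressions.
    """
    patches = pool_batch.patches
    if patches.shape[0] < 3:
        raise DegenerateInputError("patch pool must contain at least 3 patches")
    rng = np.random.default_rng(seed)
    candidates = np.flatnonzero(rfs.responsive)
    if candidates.size == 0:
        raise DegenerateInputError("no responsive neurons to probe")
    n_neurons = min(n_neurons, candidates.size)
    neurons = np.sort(rng.choice(candidates, size=n_neurons, replace=False))

    corr = rf_correlation_matrix(rfs.maps[neurons], patches)  # (n, n_pool)
    sel = np.stack([np.nanargmin(corr, axis=1),
                    np.nanargmin(np.abs(corr), axis=1),
                    np.nanargmax(corr, axis=1)])  # (3, n)

    excl = int(round(transient_ms / trainer.params.dt))
    shape = (3, n_neurons)
    mean_full = np.empty(shape)
    mean_exc = np.empty(shape)
    mean_inh = np.empty(shape)
    rates = pool_batch.rates
    for c in range(3):
        for k, j in enumerate(neurons):
            probe_seed = int(rng.integers(2 ** 31))
            tr = probe_neuron(trainer, rates[sel[c, k]], int(j),
                              duration_ms, probe_seed)
            mean_full[c, k] = tr.full[excl:].mean()
            mean_exc[c, k] = tr.excitation_only[excl:].mean()
            mean_inh[c, k] = tr.inhibition_only[excl:].mean()
    exc_flat = mean_exc.ravel()
    inh_mag = np.abs(mean_inh.ravel())
    if np.ptp(inh_mag) > 0:
        slope_exc = float(stats.linregress(inh_mag, exc_flat).slope)
        slope_tot = float(stats.linregress(inh_mag, mean_full.ravel()).slope)
    else:  # degenerate: no inhibition at all
        slope_exc = slope_tot = np.nan
    return LooseBalanceResult(neurons=neurons, patch_index=sel,
                              mean_full=mean_full, mean_exc=mean_exc,
                              mean_inh=mean_inh,
                              slope_exc_vs_inh=slope_exc,
                              slope_total_vs_inh=slope_tot)


def plot_rf_mosaic(rfs: ReceptiveFieldSet, path, n_cols: int = 8,
                   upsample: int = 4) -> None:
    """Save a red/blue mosaic of receptive-field maps as PNG (display only)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    n = len(rfs)
    n_rows = int(np.ceil(n / n_cols))
    fig, axes = plt.subplots(n_rows, n_cols,
                             figsize=(1.2 * n_cols, 1.2 * n_rows))
    for ax, rf in zip(np.atleast_1d(axes).ravel(), rfs.maps):
        m = upsample_rf(rf, upsample)
        lim = np.abs(m).max() or 1.0
        ax.imshow(m, cmap="RdBu_r", vmin=-lim, vmax=lim)
    for ax in np.atleast_1d(axes).ravel():
        ax.set_xticks([])
        ax.set_yticks([])
    fig.tight_layout(pad=0.2)
    fig.savefig(path, dpi=120)
    plt.close(fig)


@dataclass
class Correlogram:
    lags_ms: np.ndarray
    values: np.ndarray
    peak_lag_ms: float
    peak_value: float


def tight_balance_xcorr(excitation: np.ndarray, inhibition: np.ndarray,
                        dt: float = 1.0, exclude_initial_ms: float = 100.0,
                        max_lag_ms: float = 50.0) -> Correlogram:
    """Lagged Pearson correlation of excitatory and |inhibitory| input traces.

    The first ``exclude_initial_ms`` are dropped to avoid the onset transient.
    The inhibition-only voltage is non-positive by construction, so its
    magnitude is used: balance then appears as a *positive* correlation, and a
    positive peak lag means inhibition follows excitation.
    """
    x = np.asarray(excitation, dtype=float)
    y = np.abs(np.asarray(inhibition, dtype=float))
    if x.shape != y.shape or x.ndim != 1:
        raise DegenerateInputError("traces must be 1-D and of equal length")
    excl = int(round(exclude_initial_ms / dt))
    lag_steps = int(round(max_lag_ms / dt))
    if x.size <= excl + 2 * lag_steps:
        raise DegenerateInputError(
            "trace too short for the requested exclusion window and max lag")
    x = x[excl:]
    y = y[excl:]
    n = x.size
    lags = np.arange(-lag_steps, lag_steps + 1)
    values = np.empty(lags.size)
    for li, k in enumerate(lags):
        if k >= 0:
            a, b = x[:n - k], y[k:]
        else:
            a, b = x[-k:], y[:n + k]
        if a.std() == 0 or b.std() == 0:
            values[li] = 0.0
        else:
            values[li] = float(np.corrcoef(a, b)[0, 1])
    peak = int(np.argmax(values))
    return Correlogram(lags_ms=lags * dt, values=values,
                       peak_lag_ms=float(lags[peak] * dt),
                       peak_value=float(values[peak]))
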