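"""HDF5/TSV persistence: checkpoints, rasters, stimulus batches, reports.

Checkpoints capture the complete simulation state — weights, thresholds,
membranes, synaptic traces, last-step spikes, both RNG streams and the batch
counters — so an interrupted run resumed from file is bit-identical to an
uninterrupted one (the training patch pool is a pure function of config and
seed and is rebuilt on load).
"""

from __future__ import annotations

import json
import pathlib

import h5py
import numpy as np
import pandas as pd

from .config import RunConfig, config_hash
from .stimuli import SpikeRaster, StimulusBatch

__all__ = [
    "save_checkpoint", "load_checkpoint", "save_raster", "load_raster",
    "save_stimulus_batch", "load_stimulus_batch", "write_manifest",
    "save_analysis_report",
]


def _dump_rng(gen: np.random.Generator) -> str:
    return json.dumps(gen.bit_generator.state)


def _load_rng(blob: str) -> np.random.Generator:
    state = json.loads(blob)
    gen = np.random.default_rng()
    gen.bit_generator.state = state
    return gen


def save_checkpoint(path, trainer) -> None:
    from .training import Trainer  # noqa: F401 (type only)
    with h5py.File(path, "w") as f:
        f.attrs["config_json"] = json.dumps(trainer.config.to_dict())
        f.attrs["seed"] = trainer.seed
        f.attrs["warmup_done"] = trainer.warmup_done
        f.attrs["batches_done"] = trainer.batches_done
        f.attrs["stim_rng"] = _dump_rng(trainer.stim_rng)
        f.attrs["dyn_rng"] = _dump_rng(trainer.dyn_rng)
        wg = f.create_group("weights")
        for g in trainer.weights.GROUPS:
            wg.create_dataset(g, data=trainer.weights.get(g))
        sg = f.create_group("state")
        st = trainer.state
        for name, arr in (("v_e", st.v_e), ("v_i", st.v_i),
                          ("theta_e", st.theta_e), ("theta_i", st.theta_i),
                          ("prev_x", st.prev_x), ("prev_e", st.prev_e),
                          ("prev_i", st.prev_i)):
            sg.create_dataset(name, data=arr)
        sg.attrs["step"] = st.step
        tg = f.create_group("traces")
        for name, arr in st.traces.state_arrays().items():
            tg.create_dataset(name, data=arr)
        if trainer.log_rows:
            f.create_dataset("log_rows", data=json.dumps(trainer.log_rows),
                             dtype=h5py.string_dtype())


def load_checkpoint(path):
    """Rebuild a Trainer exactly as it was when checkpointed."""
    from .training import Trainer
    with h5py.File(path, "r") as f:
        cfg = RunConfig.from_dict(json.loads(f.attrs["config_json"]))
        trainer = Trainer(cfg, int(f.attrs["seed"]))
        trainer.warmup_done = int(f.attrs["warmup_done"])
        trainer.batches_done = int(f.attrs["batches_done"])
        trainer.stim_rng = _load_rng(f.attrs["stim_rng"])
        trainer.dyn_rng = _load_rng(f.attrs["dyn_rng"])
        for g in trainer.weights.GROUPS:
            trainer.weights.get(g)[...] = f["weights"][g][...]
        st = trainer.state
        st.v_e[...] = f["state"]["v_e"][...]
        st.v_i[...] = f["state"]["v_i"][...]
        st.theta_e[...] = f["state"]["theta_e"][...]
        st.theta_i[...] = f["state"]["theta_i"][...]
        st.prev_x[...] = f["state"]["prev_x"][...]
        st.prev_e[...] = f["state"]["prev_e"][...]
        st.prev_i[...] = f["state"]["prev_i"][...]
        st.step = int(f["state"].attrs["step"])
        for name, arr in st.traces.state_arrays().items():
            arr[...] = f["traces"][name][...]
        if "log_rows" in f:
            trainer.log_rows = json.loads(f["log_rows"][()].decode())
    return trainer


def save_raster(path, raster: SpikeRaster, text: bool = False) -> None:
    """Spike raster as HDF5 (neuron_index uint32, time_ms float64) or TSV."""
    if text:
        with open(path, "w") as fh:
            fh.write("# neuron_index\ttime_ms\n")
            for i, t in zip(raster.neuron_index, raster.time_ms):
                fh.write(f"{i}\t{t}\n")
        return
    with h5py.File(path, "w") as f:
        f.create_dataset("neuron_index", data=raster.neuron_index,
                         dtype=np.uint32)
        f.create_dataset("time_ms", data=raster.time_ms, dtype=np.float64)
        f.attrs["duration_ms"] = raster.duration_ms
        f.attrs["n_neurons"] = raster.n_neurons


def load_raster(path) -> SpikeRaster:
    with h5py.File(path, "r") as f:
        return SpikeRaster(f["neuron_index"][...], f["time_ms"][...],
                           float(f.attrs["duration_ms"]),
                           int(f.attrs["n_neurons"]))


def save_stimulus_batch(path, batch: StimulusBatch) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("patches", data=batch.patches)
        if batch.on_rates is not None:
            f.create_dataset("on_rates", data=batch.on_rates)
            f.create_dataset("off_rates", data=batch.off_rates)
        if batch.noise is not None:
            f.create_dataset("noise", data=batch.noise)


def load_stimulus_batch(path) -> StimulusBatch:
    with h5py.File(path, "r") as f:
        return StimulusBatch(
            patches=f["patches"][...],
            on_rates=f["on_rates"][...] if "on_rates" in f else None,
            off_rates=f["off_rates"][...] if "off_rates" in f else None,
            noise=f["noise"][...] if "noise" in f else None,
        )


def write_manifest(path, cfg: RunConfig, seed: int, checkpoints=(),
                   log_path=None, extra=None) -> None:
    from importlib.metadata import version, PackageNotFoundError
    try:
        ver = version("sparsev1")
    except PackageNotFoundError:  # pragma: no cover
        ver = "unknown"
    manifest = {
        "config_hash": config_hash(cfg),
        "code_version": ver,
        "seed": int(seed),
        "checkpoints": [str(p) for p in checkpoints],
        "log_path": str(log_path) if log_path else None,
    }
    if extra:
        manifest.update(extra)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)


def save_analysis_report(h5_path, tsv_path, rfs, fits, temporal, population,
                         extras=None) -> None:
    """One HDF5 container (maps, fits, sparseness) + flat per-neuron TSV."""
    with h5py.File(h5_path, "w") as f:
        f.create_dataset("rf_maps", data=rfs.maps)
        f.create_dataset("responsive", data=rfs.responsive)
        f.create_dataset("sparseness_temporal", data=temporal.values)
        f.create_dataset("sparseness_population", data=population.values)
        fit_cols = np.array([[g.fit_error, g.n_x, g.n_y, g.orientation,
                              g.spatial_frequency, g.sigma_x, g.sigma_y]
                             for g in fits])
        f.create_dataset("gabor_fits", data=fit_cols)
        if extras:
            for key, val in extras.items():
                f.create_dataset(key, data=val)
    rows = []
    for j, g in enumerate(fits):
        rows.append({
            "neuron": j,
            "sparseness_temporal": temporal.values[j]
            if j < temporal.values.size else np.nan,
            "fit_error": g.fit_error,
            "n_x": g.n_x,
            "n_y": g.n_y,
            "well_fit": bool(g.well_fit),
        })
    pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)
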