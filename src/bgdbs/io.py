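"""Serialization: run configs (YAML/JSON), spike data (HDF5 / plain text)
and run manifests."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import yaml

from .engine import SimulationSpec, SpikeData
from .network import Network, NetworkConfig
from .stimulation import DBSProtocol

__all__ = [
    "load_config", "save_spikes_hdf5", "load_spikes_hdf5",
    "save_spikes_text", "load_spikes_text", "save_network_hdf5",
    "write_manifest",
]


def load_config(path) -> dict:
    """Read a YAML/JSON run config into (NetworkConfig, DBSProtocol,
    SimulationSpec) plus any extra keys, returned as a dict."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text) or {}
    out = dict(raw)
    out["network"] = NetworkConfig(**raw.get("network", {}))
    proto = dict(raw.get("dbs", {}))
    if "frequency_hz" in proto:
        proto["t_dbs"] = 1000.0 / proto.pop("frequency_hz")
        proto.setdefault("mode", "regular")
    out["dbs"] = DBSProtocol(**proto)
    out["simulation"] = SimulationSpec(**raw.get("simulation", {}))
    return out


def save_spikes_hdf5(path, spikes: SpikeData) -> None:
    import h5py

    with h5py.File(path, "w") as h:
        h.create_dataset("neuron", data=spikes.neuron, compression="gzip")
        h.create_dataset("time", data=spikes.time, compression="gzip")
        h.attrs["duration"] = spikes.duration
        for name, sl in spikes.pop_slices.items():
            h.attrs[f"pop_{name}"] = (sl.start, sl.stop)
        h.attrs["meta"] = json.dumps(_jsonable(spikes.meta))


def load_spikes_hdf5(path) -> SpikeData:
    import h5py

    with h5py.File(path, "r") as h:
        slices = {k[4:]: slice(int(v[0]), int(v[1]))
                  for k, v in h.attrs.items() if k.startswith("pop_")}
        return SpikeData(
            neuron=h["neuron"][:], time=h["time"][:], pop_slices=slices,
            duration=float(h.attrs["duration"]),
            meta=json.loads(h.attrs.get("meta", "{}")))


def save_spikes_text(path, spikes: SpikeData) -> None:
    """Two-column plain text: global neuron index, spike time (ms)."""
    np.savetxt(path, np.column_stack([spikes.neuron, spikes.time]),
               fmt=["%d", "%.4f"], header="neuron time_ms")


def load_spikes_text(path, pop_slices: dict, duration: float) -> SpikeData:
    arr = np.loadtxt(path, ndmin=2)
    return SpikeData(neuron=arr[:, 0].astype(np.int64), time=arr[:, 1],
                     pop_slices=pop_slices, duration=duration)


def save_network_hdf5(path, network: Network) -> None:
    """Persist a realized network (populations, synapse arrays, seeds)."""
    import h5py

    with h5py.File(path, "w") as h:
        g = h.create_group("synapses")
        for name in ("syn_pre", "syn_post", "syn_weight", "syn_delay",
                     "syn_chan", "syn_stp_class"):
            g.create_dataset(name, data=getattr(network, name),
                             compression="gzip")
        g = h.create_group("neurons")
        for name, arr in network.neuron_params.items():
            g.create_dataset(name, data=arr, compression="gzip")
        g.create_dataset("ext_rate", data=network.ext_rate)
        g.create_dataset("ext_weight", data=network.ext_weight)
        for name, sl in network.pop_slices.items():
            h.attrs[f"pop_{name}"] = (sl.start, sl.stop)
        h.attrs["config"] = json.dumps(_jsonable(
            dataclasses.asdict(network.config)))


def write_manifest(path, **entries) -> None:
    """JSON manifest of a run: config, seeds, package version."""
    from . import __version__

    payload = {"bgdbs_version": __version__}
    payload.update({k: _jsonable(v) for k, v in entries.items()})
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, slice):
        return [obj.start, obj.stop]
    return obj
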