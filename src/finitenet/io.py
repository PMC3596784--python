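"""Plain-text readers and writers for rasters, traces, graphs and events.

Formats
-------
* raster: TSV ``neuron<TAB>time_ms`` with a header line, sorted by time
* graph: edge-list TSV ``pre<TAB>post<TAB>weight`` plus a JSON sidecar
* fluorescence: CSV (rows = neurons, columns = frames) with a JSON sidecar
  carrying ``frame_rate_hz`` and optional ``gaba_flags``
* events: TSV ``neuron<TAB>onset_s<TAB>offset_s``
* simulation config: JSON (see :func:`load_config`)
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .calcium_events import CalciumEvent, FluorescenceRecording
from .sim_core import NoiseParameters, SimulationConfig, SpikeRaster
from .topology import ConnectivityGraph, SynapticMatrix

__all__ = [
    "write_raster", "read_raster",
    "write_graph", "read_graph",
    "write_traces", "read_traces",
    "write_events", "read_events",
    "load_config",
]


def write_raster(raster: SpikeRaster, path) -> None:
    df = pd.DataFrame({"neuron": raster.neuron_ids, "time_ms": raster.times})
    df = df.sort_values(["time_ms", "neuron"], kind="stable")
    df.to_csv(path, sep="\t", index=False)


def read_raster(path, n_neurons: int | None = None, duration: float | None = None) -> SpikeRaster:
    df = pd.read_csv(path, sep="\t")
    ids = df["neuron"].to_numpy(dtype=np.int64)
    t = df["time_ms"].to_numpy(dtype=np.float64)
    order = np.argsort(t, kind="stable")
    ids, t = ids[order], t[order]
    if n_neurons is None:
        n_neurons = int(ids.max()) + 1 if ids.size else 0
    if duration is None:
        duration = float(t.max()) if t.size else 0.0
    return SpikeRaster(ids, t, n_neurons=n_neurons, duration=duration)


def write_graph(weights: SynapticMatrix, path, meta: dict | None = None) -> None:
    post, pre = np.nonzero(weights.s)
    df = pd.DataFrame({"pre": pre, "post": post, "weight": weights.s[post, pre]})
    df.to_csv(path, sep="\t", index=False)
    sidecar = dict(meta or {})
    sidecar.setdefault("n", int(weights.s.shape[0]))
    sidecar["inhibitory_ids"] = sorted(int(i) for i in weights.inhibitory_ids)
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))


def read_graph(path) -> SynapticMatrix:
    df = pd.read_csv(path, sep="\t")
    sidecar = json.loads(Path(str(path) + ".json").read_text())
    n = int(sidecar["n"])
    s = np.zeros((n, n))
    s[df["post"].to_numpy(), df["pre"].to_numpy()] = df["weight"].to_numpy()
    return SynapticMatrix(s=s, inhibitory_ids=frozenset(sidecar.get("inhibitory_ids", [])))


def write_traces(rec: FluorescenceRecording, path) -> None:
    pd.DataFrame(rec.F).to_csv(path, index=False, header=False)
    meta = {"frame_rate_hz": rec.frame_rate}
    if rec.gaba_flags is not None:
        meta["gaba_flags"] = [bool(g) for g in rec.gaba_flags]
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=1))


def read_traces(path, meta_path=None) -> FluorescenceRecording:
    F = pd.read_csv(path, header=None).to_numpy(dtype=np.float64)
    meta_path = meta_path or str(path) + ".json"
    meta = json.loads(Path(meta_path).read_text())
    flags = meta.get("gaba_flags")
    return FluorescenceRecording(
        F=F,
        frame_rate=float(meta["frame_rate_hz"]),
        gaba_flags=np.asarray(flags, dtype=bool) if flags is not None else None,
    )


def write_events(events, path) -> None:
    df = pd.DataFrame(
        {
            "neuron": [e.neuron_id for e in events],
            "onset_s": [e.onset for e in events],
            "offset_s": [e.offset for e in events],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_events(path) -> list[CalciumEvent]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, row in df.iterrows():
        out.append(
            CalciumEvent(
                neuron_id=int(row["neuron"]),
                onset=float(row["onset_s"]),
                offset=float(row["offset_s"]),
                window=(0, 0),
                sigmoid_params=(np.nan, np.nan, np.nan, np.nan),
            )
        )
    return out


def load_config(path) -> tuple[SimulationConfig, dict]:
    """Read a simulation config JSON.

    Keys: ``n_neurons``, ``frac_inhibitory``, ``duration_ms``, ``dt_ms``,
    ``v_peak``, ``seed``, ``noise_gain``, ``noise{tau_ms, mean, sd}``,
    ``topology{m, weight_mean, weight_sd}``.  Returns the config and the
    topology sub-dict.
    """
    raw = json.loads(Path(path).read_text())
    noise = raw.get("noise", {})
    kwargs = dict(
        n_neurons=int(raw["n_neurons"]),
        frac_inhibitory=float(raw.get("frac_inhibitory", 0.25)),
        duration=float(raw.get("duration_ms", 600_000.0)),
        dt=float(raw.get("dt_ms", 0.1)),
        v_peak=float(raw.get("v_peak", 40.0)),
        seed=int(raw.get("seed", 0)),
        noise=NoiseParameters(
            tau_I=float(noise.get("tau_ms", 1.0)),
            m_I=float(noise.get("mean", 25.0)),
            s_I=float(noise.get("sd", 9.0)),
        ),
    )
    if "noise_gain" in raw:
        kwargs["noise_gain"] = float(raw["noise_gain"])
    cfg = SimulationConfig(**kwargs)
    return cfg, raw.get("topology", {})
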