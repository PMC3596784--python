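"""Network-wide synchronisation (burst) detection and rate/size regression.

The population instantaneous firing rate (IFR) is the spike-count histogram
over fixed bins (default 100 ms), accompanied by the fraction of neurons
active in each bin.  A network event is a maximal run of bins whose active
fraction reaches a threshold; runs separated by short gaps are merged.  Event
frequency is then regressed on population size with ordinary least squares;
for comparison against cell counts that include glia, simulated neuron
numbers are mapped to total cells with a 2:1 neuron-to-glia ratio
(total = 1.5 x neurons).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .sim_core import SpikeRaster

__all__ = [
    "IFRProfile",
    "NetworkEvent",
    "RateSizeRegression",
    "population_ifr",
    "detect_network_events",
    "event_rate",
    "rate_size_regression",
    "GLIA_FACTOR",
    "DEFAULT_TRANSIENT_MS",
]

#: total cells per simulated neuron (2:1 neuron/glia ratio -> 1.5x neurons)
GLIA_FACTOR = 1.5

#: initial span discarded from rate statistics (settling of the random
#: initial condition), in ms
DEFAULT_TRANSIENT_MS = 5_000.0


@dataclass(frozen=True)
class IFRProfile:
    bin_size: float  # ms
    counts: np.ndarray  # spikes per bin
    fraction_active: np.ndarray  # neurons with >=1 spike in the bin / n
    n_neurons: int
    duration: float  # ms


@dataclass(frozen=True)
class NetworkEvent:
    start: float  # ms
    end: float  # ms
    participating_fraction: float  # peak fraction of neurons active per bin
    peak_rate: float  # max spikes/s within the event

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError("event must have start < end")


@dataclass(frozen=True)
class RateSizeRegression:
    points: tuple  # ((total_cells, rate_hz), ...)
    slope: float  # Hz per cell
    intercept: float  # Hz
    pearson_r: float
    degenerate: bool = False


def population_ifr(raster: SpikeRaster, bin_size: float = 100.0) -> IFRProfile:
    """Bin all spikes of the raster into the population IFR profile."""
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    n_bins = int(np.ceil(raster.duration / bin_size))
    edges = np.arange(n_bins + 1) * bin_size
    counts, _ = np.histogram(raster.times, bins=edges)
    frac = np.zeros(n_bins)
    if raster.n_spikes:
        bin_idx = np.minimum((raster.times / bin_size).astype(np.int64), n_bins - 1)
        pairs = np.unique(np.stack([bin_idx, raster.neuron_ids], axis=1), axis=0)
        active_per_bin = np.bincount(pairs[:, 0], minlength=n_bins)
        frac = active_per_bin / raster.n_neurons
    return IFRProfile(
        bin_size=float(bin_size),
        counts=counts.astype(np.int64),
        fraction_active=frac,
        n_neurons=raster.n_neurons,
        duration=raster.duration,
    )


def detect_network_events(
    ifr: IFRProfile,
    threshold_fraction: float = 0.2,
    min_separation: float = 200.0,
) -> list[NetworkEvent]:
    """Find maximal runs of bins with active fraction >= threshold.

    Runs whose gap is shorter than ``min_separation`` are merged into one
    event.  Returns ordered, non-overlapping events; an empty list is a
    valid outcome.
    """
    if not 0.0 < threshold_fraction <= 1.0:
        raise ValueError("threshold_fraction must lie in (0, 1]")
    above = ifr.fraction_active >= threshold_fraction
    if not np.any(above):
        return []
    padded = np.concatenate([[False], above, [False]]).astype(np.int8)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)  # exclusive bin index

    # merge runs separated by gaps shorter than min_separation
    merged = [[starts[0], ends[0]]]
    for s, e in zip(starts[1:], ends[1:]):
        if (s - merged[-1][1]) * ifr.bin_size < min_separation:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    rate_scale = 1000.0 / ifr.bin_size  # spikes/bin -> spikes/s
    events = []
    for s, e in merged:
        events.append(
            NetworkEvent(
                start=s * ifr.bin_size,
                end=e * ifr.bin_size,
                participating_fraction=float(ifr.fraction_active[s:e].max()),
                peak_rate=float(ifr.counts[s:e].max() * rate_scale),
            )
        )
    return events


def event_rate(
    events,
    duration: float,
    transient_ms: float = DEFAULT_TRANSIENT_MS,
) -> float:
    """Event frequency in Hz, ignoring events starting in the initial transient."""
    if duration <= transient_ms:
        raise ValueError("duration must exceed the discarded transient")
    kept = [ev for ev in events if ev.start >= transient_ms]
    return len(kept) / ((duration - transient_ms) / 1000.0)


def rate_size_regression(points) -> RateSizeRegression:
    """Ordinary least squares of event rate (Hz) on total cell count."""
    pts = [(float(x), float(y)) for x, y in points]
    if len(pts) < 3:
        raise ValueError("need at least 3 (cells, rate) points")
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    if np.ptp(y) == 0 or np.ptp(x) == 0:
        return RateSizeRegression(
            points=tuple(pts), slope=0.0, intercept=float(y.mean()),
            pearson_r=0.0, degenerate=True,
        )
    res = stats.linregress(x, y)
    return RateSizeRegression(
        points=tuple(pts),
        slope=float(res.slope),
        intercept=float(res.intercept),
        pearson_r=float(res.rvalue),
    )
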