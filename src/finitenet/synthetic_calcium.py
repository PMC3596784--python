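"""Ground-truthed synthetic fluorescence recordings and onset series.

Every analysis stage in the package can be exercised without real data:
``spikes_to_fluorescence`` renders event times into noisy calcium traces
(double-exponential transients, linear superposition, white frame noise at a
59-Hz default frame rate), and ``make_chain_population`` builds repeated
feed-forward activation sweeps with a known directed-edge ground truth for
the connectivity inference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calcium_events import FluorescenceRecording
from .sim_core import SpikeRaster

__all__ = [
    "CalciumKernelParams",
    "GroundTruth",
    "kernel_peak_time",
    "spikes_to_fluorescence",
    "make_chain_population",
    "make_poisson_onsets",
]


@dataclass(frozen=True)
class CalciumKernelParams:
    """Double-exponential transient: amp * (exp(-t/decay) - exp(-t/rise)).

    Defaults (50-ms rise, 1-s decay) emulate somatic OGB-1/Fluo-4 transients.
    The kernel is normalised so its peak equals ``amplitude``.
    """

    rise_tau: float = 0.05  # s
    decay_tau: float = 1.0  # s
    amplitude: float = 1.0  # fluorescence units above baseline
    baseline: float = 100.0
    noise_sd: float = 0.0
    frame_rate: float = 59.0  # Hz
    #: optional slow baseline drift (fluorescence units per second); a
    #: stress mode for the detector's baseline-shift tolerance
    drift_per_s: float = 0.0

    def __post_init__(self):
        if not 0 < self.rise_tau < self.decay_tau:
            raise ValueError("need 0 < rise_tau < decay_tau")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @classmethod
    def for_peak_snr(cls, snr: float, amplitude: float = 1.0, **kw) -> "CalciumKernelParams":
        """Parameters whose detection-statistic peak SNR equals ``snr``.

        The 1-s sliding first-difference sum turns a transient of height
        ``amplitude`` into a processed peak of the same height, with noise SD
        ``sqrt(2)`` times the frame noise; ``noise_sd`` is set accordingly.
        """
        if snr <= 0:
            raise ValueError("snr must be positive")
        return cls(amplitude=amplitude, noise_sd=amplitude / (np.sqrt(2.0) * snr), **kw)


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually put into a synthetic recording."""

    onsets: tuple  # per-neuron tuple of onset times (s)
    edges: tuple = ()  # directed (pre, post) pairs when a known graph exists
    gaba_flags: tuple = ()
    duration_s: float = 0.0


def kernel_peak_time(params: CalciumKernelParams) -> float:
    """Analytic peak time of the double exponential after onset."""
    r, d = params.rise_tau, params.decay_tau
    return np.log(d / r) * (d * r) / (d - r)


def _kernel(t: np.ndarray, params: CalciumKernelParams) -> np.ndarray:
    r, d = params.rise_tau, params.decay_tau
    tt = np.maximum(t, 0.0)
    raw = np.exp(-tt / d) - np.exp(-tt / r)
    peak = np.exp(-kernel_peak_time(params) / d) - np.exp(-kernel_peak_time(params) / r)
    return params.amplitude * np.where(t >= 0, raw / peak, 0.0)


def _onsets_per_neuron(events, n_neurons: int) -> list[np.ndarray]:
    if isinstance(events, SpikeRaster):
        return [events.spikes_of(i) / 1000.0 for i in range(events.n_neurons)]
    return [np.asarray(o, dtype=np.float64) for o in events]


def spikes_to_fluorescence(
    events,
    params: CalciumKernelParams = CalciumKernelParams(),
    duration_s: float | None = None,
    seed: int = 0,
    gaba_flags=None,
    edges=(),
) -> tuple[FluorescenceRecording, GroundTruth]:
    """Render event times into a noisy fluorescence recording.

    ``events`` is a :class:`SpikeRaster` (times in ms) or a list of
    per-neuron onset arrays in seconds.  Each event adds one peak-normalised
    double-exponential transient; i.i.d. Gaussian noise is added per frame.
    """
    if isinstance(events, SpikeRaster):
        n = events.n_neurons
        dur = duration_s if duration_s is not None else events.duration / 1000.0
    else:
        n = len(events)
        if duration_s is None:
            raise ValueError("duration_s is required for plain onset lists")
        dur = float(duration_s)
    onsets = _onsets_per_neuron(events, n)
    n_frames = int(round(dur * params.frame_rate))
    if n_frames < 1:
        raise ValueError("duration too short for one frame")
    t = np.arange(n_frames) / params.frame_rate
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xCA]))
    F = np.full((n, n_frames), float(params.baseline))
    if params.drift_per_s:
        F += params.drift_per_s * t
    for i, ons in enumerate(onsets):
        for t0 in ons:
            F[i] += _kernel(t - t0, params)
    if params.noise_sd > 0:
        F += rng.normal(0.0, params.noise_sd, size=F.shape)
    rec = FluorescenceRecording(
        F=F,
        frame_rate=params.frame_rate,
        gaba_flags=np.asarray(gaba_flags, dtype=bool) if gaba_flags is not None else None,
    )
    truth = GroundTruth(
        onsets=tuple(tuple(float(x) for x in o) for o in onsets),
        edges=tuple(edges),
        gaba_flags=tuple(bool(g) for g in gaba_flags) if gaba_flags is not None else (),
        duration_s=dur,
    )
    return rec, truth


def make_chain_population(
    n_stages: int,
    delay_ms: float = 120.0,
    jitter_ms: float = 10.0,
    n_repetitions: int = 50,
    seed: int = 0,
    inter_sweep_s: float = 10.0,
) -> tuple[list[np.ndarray], GroundTruth]:
    """Feed-forward activation sweeps with fixed inter-stage delay.

    Stage ``k`` of sweep ``s`` activates at ``s * inter_sweep_s + k * delay
    + jitter``; the true directed graph is the chain 0 -> 1 -> ... .
    Returns per-neuron onset arrays (s) and the ground truth.
    """
    if n_stages < 2:
        raise ValueError("a chain needs at least 2 stages")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xC8]))
    # sweeps centred inside the span so jitter cannot spill past the edges
    sweep_starts = (np.arange(n_repetitions) + 0.5) * inter_sweep_s
    onsets = []
    for k in range(n_stages):
        jit = rng.normal(0.0, jitter_ms / 1000.0, size=n_repetitions) if jitter_ms > 0 else 0.0
        times = sweep_starts + k * delay_ms / 1000.0 + jit
        onsets.append(np.sort(times))
    edges = tuple((k, k + 1) for k in range(n_stages - 1))
    duration = float(n_repetitions * inter_sweep_s)
    truth = GroundTruth(
        onsets=tuple(tuple(float(x) for x in o) for o in onsets),
        edges=edges,
        duration_s=duration,
    )
    return onsets, truth


def make_poisson_onsets(
    n_neurons: int,
    rate_hz: float,
    duration_s: float,
    seed: int = 0,
) -> list[np.ndarray]:
    """Independent homogeneous Poisson onset trains (null fixture)."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xB0]))
    out = []
    for _ in range(n_neurons):
        n_ev = rng.poisson(rate_hz * duration_s)
        out.append(np.sort(rng.uniform(0.0, duration_s, size=n_ev)))
    return out
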