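"""Pulse-coupled Izhikevich network simulator with Ornstein-Uhlenbeck noise.

Each neuron follows the two-variable quadratic integrate-and-reset dynamics

    dv/dt = 0.04 v^2 + 5 v + 140 - u + I_syn + I_noise
    du/dt = a (b v - u)

with the after-spike reset ``v >= v_peak -> v <- c, u <- u + d``.  Synaptic
transmission is pulse coupling: a spike of presynaptic neuron ``j`` adds the
weight ``s_ij`` directly to the membrane potential of every postsynaptic
neuron ``i`` at the following integration step.  The background drive
``I_noise`` is a per-neuron Ornstein-Uhlenbeck process integrated with the
Euler-Maruyama scheme

    I <- I - (I / tau_I) dt + (m_I / tau_I) dt + s_I sqrt(2 dt / tau_I) xi.

Two interchangeable integration engines are provided: a numba-compiled
kernel (default) and a plain NumPy reference path; both consume identical
per-neuron noise streams and produce bit-identical rasters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "NeuronParameters",
    "NoiseParameters",
    "SimulationConfig",
    "NetworkState",
    "SpikeRaster",
    "NumericalDivergenceError",
    "make_neuron_population",
    "ou_noise_step",
    "step_network",
    "run_simulation",
]


class NumericalDivergenceError(RuntimeError):
    """Raised when the membrane potential of some neuron leaves the sane range."""

    def __init__(self, neuron: int, time_ms: float):
        self.neuron = int(neuron)
        self.time_ms = float(time_ms)
        super().__init__(
            f"integration diverged: neuron {neuron} at t = {time_ms:.3f} ms"
        )


# Membrane potentials beyond this magnitude signal a broken integration
# rather than a spike overshoot (reset overshoots stay well below 10^3 mV).
_DIVERGENCE_LIMIT_MV = 1.0e3

#: calibrated noise-current coupling (see SimulationConfig.noise_gain and
#: scripts/calibrate.py)
DEFAULT_NOISE_GAIN = 0.0795


@dataclass(frozen=True)
class NeuronParameters:
    """Izhikevich parameters of a single neuron.

    The regular-spiking (excitatory) and fast-spiking (inhibitory) families
    are parameterised by a uniform heterogeneity draw ``r`` in [0, 1]:

    * excitatory: a = 0.02, b = 0.2,  c = -65 + 15 r^2, d = 8 - 6 r^2
    * inhibitory: a = 0.02 + 0.08 r, b = 0.25 - 0.05 r, c = -65, d = 2
    """

    a: float
    b: float
    c: float
    d: float
    is_inhibitory: bool
    r: float

    def __post_init__(self):
        if not 0.0 <= self.r <= 1.0:
            raise ValueError(f"heterogeneity draw r must lie in [0, 1], got {self.r}")


@dataclass(frozen=True)
class NoiseParameters:
    """Stationary OU-noise parameters (correlation length, mean, SD)."""

    tau_I: float = 1.0  # ms
    m_I: float = 25.0  # pA (model units)
    s_I: float = 9.0  # pA (model units)

    def __post_init__(self):
        if self.tau_I <= 0:
            raise ValueError("tau_I must be positive")
        if self.s_I < 0:
            raise ValueError("s_I must be nonnegative")


@dataclass(frozen=True)
class SimulationConfig:
    n_neurons: int
    frac_inhibitory: float = 0.25
    duration: float = 600_000.0  # ms
    dt: float = 0.1  # ms (10-kHz sampling)
    v_peak: float = 40.0  # mV spike cut-off, as used by the network model
    seed: int = 0
    noise: NoiseParameters = field(default_factory=NoiseParameters)
    #: dimensionless coupling of the OU noise current into dv/dt.  The OU
    #: process itself keeps its stated pA moments; the gain maps pA onto the
    #: voltage-equation's current scale (a capacitance-like conversion) and
    #: is calibrated so that networks burst on the observed scale.
    noise_gain: float = DEFAULT_NOISE_GAIN
    #: optional per-neuron ids keying the noise streams; defaults to 0..n-1.
    #: Passing a sublist reproduces exactly the noise a neuron would receive
    #: inside a larger network with the same seed (decoupling checks).
    noise_stream_ids: tuple[int, ...] | None = None

    def __post_init__(self):
        if self.n_neurons < 1:
            raise ValueError("n_neurons must be >= 1")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.duration < self.dt:
            raise ValueError("duration must be at least one step")
        if not 0.0 <= self.frac_inhibitory <= 1.0:
            raise ValueError("frac_inhibitory must lie in [0, 1]")


@dataclass
class NetworkState:
    """Instantaneous state of the integrated network."""

    v: np.ndarray  # membrane potentials, mV
    u: np.ndarray  # recovery variables
    I_noise: np.ndarray  # OU noise currents
    t: float  # elapsed time, ms
    #: synaptic increments accumulated from spikes of the previous step,
    #: applied to v at the start of the next step (pulse coupling).
    pending: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        n = len(self.v)
        if self.pending is None:
            self.pending = np.zeros(n)
        if not (len(self.u) == len(self.I_noise) == len(self.pending) == n):
            raise ValueError("state vectors must share one length")


@dataclass(frozen=True)
class SpikeRaster:
    """Ordered (neuron, time) spike events over a fixed observation span."""

    neuron_ids: np.ndarray  # int array
    times: np.ndarray  # ms, nondecreasing
    n_neurons: int
    duration: float  # ms

    def __post_init__(self):
        ids = np.asarray(self.neuron_ids, dtype=np.int64)
        t = np.asarray(self.times, dtype=np.float64)
        if ids.shape != t.shape:
            raise ValueError("neuron_ids and times must have equal length")
        object.__setattr__(self, "neuron_ids", ids)
        object.__setattr__(self, "times", t)
        if t.size:
            if t.min() <= 0 or t.max() > self.duration:
                raise ValueError("spike times must lie strictly within (0, duration]")
            if np.any(ids < 0) or np.any(ids >= self.n_neurons):
                raise ValueError("neuron ids out of range")
            if np.any(np.diff(t) < 0):
                raise ValueError("spike times must be nondecreasing")

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)

    def spikes_of(self, neuron: int) -> np.ndarray:
        return self.times[self.neuron_ids == neuron]

    def subset(self, neurons: Iterable[int], renumber: bool = False) -> "SpikeRaster":
        neurons = list(neurons)
        mask = np.isin(self.neuron_ids, neurons)
        ids = self.neuron_ids[mask]
        if renumber:
            remap = {old: new for new, old in enumerate(neurons)}
            ids = np.array([remap[i] for i in ids], dtype=np.int64)
            n = len(neurons)
        else:
            n = self.n_neurons
        return SpikeRaster(ids, self.times[mask], n, self.duration)


def make_neuron_population(
    n: int, frac_inhibitory: float = 0.25, rng_seed: int = 0
) -> list[NeuronParameters]:
    """Draw a heterogeneous population of RS (excitatory) / FS (inhibitory) neurons.

    Exactly ``round(n * frac_inhibitory)`` neurons are inhibitory; their
    positions within the population are a seeded random subset.  Each neuron
    receives an independent uniform heterogeneity draw ``r``.
    """
    if n < 1:
        raise ValueError("population size must be >= 1")
    if not 0.0 <= frac_inhibitory <= 1.0:
        raise ValueError("frac_inhibitory must lie in [0, 1]")
    rng = np.random.default_rng(rng_seed)
    n_inh = int(round(n * frac_inhibitory))
    inhibitory = np.zeros(n, dtype=bool)
    inhibitory[rng.choice(n, size=n_inh, replace=False)] = True
    r = rng.uniform(0.0, 1.0, size=n)
    pop = []
    for i in range(n):
        if inhibitory[i]:
            pop.append(
                NeuronParameters(
                    a=0.02 + 0.08 * r[i],
                    b=0.25 - 0.05 * r[i],
                    c=-65.0,
                    d=2.0,
                    is_inhibitory=True,
                    r=r[i],
                )
            )
        else:
            pop.append(
                NeuronParameters(
                    a=0.02,
                    b=0.2,
                    c=-65.0 + 15.0 * r[i] ** 2,
                    d=8.0 - 6.0 * r[i] ** 2,
                    is_inhibitory=False,
                    r=r[i],
                )
            )
    return pop


def ou_noise_step(I: float, params: NoiseParameters, dt: float, xi: float) -> float:
    """One Euler-Maruyama step of the OU noise current.

    Returns ``I - (I/tau_I) dt + (m_I/tau_I) dt + s_I sqrt(2 dt / tau_I) xi``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    tau = params.tau_I
    return I - (I / tau) * dt + (params.m_I / tau) * dt + params.s_I * np.sqrt(
        2.0 * dt / tau
    ) * xi


def _params_arrays(params: Sequence[NeuronParameters]):
    a = np.array([p.a for p in params])
    b = np.array([p.b for p in params])
    c = np.array([p.c for p in params])
    d = np.array([p.d for p in params])
    return a, b, c, d


def step_network(
    state: NetworkState,
    params: Sequence[NeuronParameters],
    weights: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[NetworkState, set]:
    """Advance the network by one forward-Euler step of length ``config.dt``.

    ``weights`` is the signed synaptic matrix with ``weights[i, j]`` the pulse
    that a spike of presynaptic ``j`` adds to postsynaptic ``i``.  Pulses from
    neurons reported as fired are delivered at the *next* step.  The noise
    draws come from ``rng`` (one standard normal per neuron per step).
    """
    n = len(state.v)
    if len(params) != n or np.shape(weights) != (n, n):
        raise ValueError("state, params and weights dimensions disagree")
    a, b, c, d = _params_arrays(params)
    dt = config.dt
    noise = config.noise

    v = state.v + state.pending
    u = state.u.copy()
    I = state.I_noise
    v_new = v + dt * (0.04 * v * v + 5.0 * v + 140.0 - u + config.noise_gain * I)
    u_new = u + dt * (a * (b * v - u))
    xi = rng.standard_normal(n)
    I_new = I + dt * (noise.m_I - I) / noise.tau_I + noise.s_I * np.sqrt(
        2.0 * dt / noise.tau_I
    ) * xi

    t_new = state.t + dt
    bad = ~np.isfinite(v_new) | (np.abs(v_new) > _DIVERGENCE_LIMIT_MV)
    if np.any(bad):
        raise NumericalDivergenceError(int(np.flatnonzero(bad)[0]), t_new)
    fired = np.flatnonzero(v_new >= config.v_peak)
    u_new[fired] += d[fired]
    v_new[fired] = c[fired]

    pending = np.zeros(n)
    for j in fired:  # sequential adds keep engines bit-identical
        pending += weights[:, j]
    new_state = NetworkState(v=v_new, u=u_new, I_noise=I_new, t=t_new, pending=pending)
    return new_state, set(int(i) for i in fired)


def initial_state(
    params: Sequence[NeuronParameters], config: SimulationConfig
) -> NetworkState:
    """Draw the initial condition: v ~ U[c, -60] mV, u = b v, I = m_I.

    Randomising v avoids a synchronisation artifact at t = 0; statistics
    downstream additionally discard an initial transient.  Each neuron's
    draw comes from its own stream (keyed like the noise streams), so a
    sub-population started alone reproduces its in-network trajectory
    exactly.
    """
    a, b, c, d = _params_arrays(params)
    ids = config.noise_stream_ids or tuple(range(len(params)))
    v0 = np.array(
        [
            np.random.default_rng(
                np.random.SeedSequence([int(config.seed), 2, int(i)])
            ).uniform(c[k], max(c[k], -60.0))
            for k, i in enumerate(ids)
        ]
    )
    u0 = b * v0
    return NetworkState(
        v=v0,
        u=u0,
        I_noise=np.full(len(params), config.noise.m_I),
        t=0.0,
    )


def _noise_generators(config: SimulationConfig, n: int) -> list[np.random.Generator]:
    ids = config.noise_stream_ids
    if ids is None:
        ids = tuple(range(n))
    if len(ids) != n:
        raise ValueError("noise_stream_ids length must equal n_neurons")
    return [
        np.random.default_rng(np.random.SeedSequence([int(config.seed), 1, int(i)]))
        for i in ids
    ]


_NUMBA_KERNEL = None


def _get_kernel():
    global _NUMBA_KERNEL
    if _NUMBA_KERNEL is None:
        import numba

        @numba.njit(cache=True)
        def kernel(v, u, inoise, pend, a, b, c, d, wt, xi, dt, v_peak, tau, mI, amp, gain, spk_step, spk_id):  # pragma: no cover - compiled
            n = v.shape[0]
            K = xi.shape[1]
            cnt = 0
            for k in range(K):
                for i in range(n):
                    v[i] = v[i] + pend[i]
                    pend[i] = 0.0
                for i in range(n):
                    vv = v[i]
                    v[i] = vv + dt * (0.04 * vv * vv + 5.0 * vv + 140.0 - u[i] + gain * inoise[i])
                    u[i] = u[i] + dt * (a[i] * (b[i] * vv - u[i]))
                    inoise[i] = inoise[i] + dt * (mI - inoise[i]) / tau + amp * xi[i, k]
                    if not np.isfinite(v[i]) or (abs(v[i]) > 1.0e3 and not (v_peak <= v[i] <= 1.0e3)):
                        return cnt, i, k
                for i in range(n):
                    if v[i] >= v_peak:
                        spk_step[cnt] = k
                        spk_id[cnt] = i
                        cnt += 1
                        v[i] = c[i]
                        u[i] = u[i] + d[i]
                        for p in range(n):
                            pend[p] += wt[i, p]
            return cnt, -1, -1

        _NUMBA_KERNEL = kernel
    return _NUMBA_KERNEL


def _run_chunk_numpy(v, u, inoise, pend, a, b, c, d, wt, xi, dt, v_peak, tau, mI, amp, gain):
    """NumPy reference of the compiled kernel; same operation order."""
    n = v.shape[0]
    K = xi.shape[1]
    steps = []
    ids = []
    for k in range(K):
        v += pend
        pend[:] = 0.0
        vv = v.copy()
        v[:] = vv + dt * (0.04 * vv * vv + 5.0 * vv + 140.0 - u + gain * inoise)
        u[:] = u + dt * (a * (b * vv - u))
        inoise[:] = inoise + dt * (mI - inoise) / tau + amp * xi[:, k]
        bad = ~np.isfinite(v) | (np.abs(v) > _DIVERGENCE_LIMIT_MV)
        if np.any(bad):
            return steps, ids, int(np.flatnonzero(bad)[0]), k
        fired = np.flatnonzero(v >= v_peak)
        for i in fired:
            steps.append(k)
            ids.append(i)
            v[i] = c[i]
            u[i] += d[i]
            pend += wt[i]
    return steps, ids, -1, -1


def run_simulation(
    config: SimulationConfig,
    params: Sequence[NeuronParameters],
    weights: np.ndarray,
    engine: str = "numba",
    chunk_steps: int = 20_000,
    log: list | None = None,
) -> SpikeRaster:
    """Integrate the full network over ``config.duration`` and return the raster.

    The run is bit-identical across repetitions with the same seed and across
    the two engines.  Noise is drawn from one independent stream per neuron
    (keyed by ``config.seed`` and the neuron's stream id), so a zero-weight
    network decomposes exactly into independent single-neuron runs.
    """
    n = config.n_neurons
    if len(params) != n or np.shape(weights) != (n, n):
        raise ValueError("params / weights dimensions disagree with config")
    if engine not in ("numba", "numpy"):
        raise ValueError("engine must be 'numba' or 'numpy'")

    a, b, c, d = _params_arrays(params)
    wt = np.ascontiguousarray(np.asarray(weights, dtype=np.float64).T)  # wt[pre, post]
    state = initial_state(params, config)
    v, u, inoise, pend = state.v, state.u, state.I_noise, state.pending
    gens = _noise_generators(config, n)

    dt = config.dt
    noise = config.noise
    amp = noise.s_I * np.sqrt(2.0 * dt / noise.tau_I)
    total_steps = int(round(config.duration / dt))

    all_steps: list[np.ndarray] = []
    all_ids: list[np.ndarray] = []
    if engine == "numba":
        kernel = _get_kernel()
        spk_step = np.empty(n * chunk_steps, dtype=np.int64)
        spk_id = np.empty(n * chunk_steps, dtype=np.int64)

    done = 0
    while done < total_steps:
        K = min(chunk_steps, total_steps - done)
        xi = np.empty((n, K))
        for i, g in enumerate(gens):
            xi[i] = g.standard_normal(K)
        if engine == "numba":
            cnt, bad_i, bad_k = kernel(
                v, u, inoise, pend, a, b, c, d, wt, xi, dt, config.v_peak,
                noise.tau_I, noise.m_I, amp, config.noise_gain, spk_step, spk_id,
            )
            if bad_i >= 0:
                raise NumericalDivergenceError(bad_i, (done + bad_k + 1) * dt)
            all_steps.append(spk_step[:cnt] + done)
            all_ids.append(spk_id[:cnt].copy())
        else:
            steps, ids, bad_i, bad_k = _run_chunk_numpy(
                v, u, inoise, pend, a, b, c, d, wt, xi, dt, config.v_peak,
                noise.tau_I, noise.m_I, amp, config.noise_gain,
            )
            if bad_i >= 0:
                raise NumericalDivergenceError(bad_i, (done + bad_k + 1) * dt)
            all_steps.append(np.asarray(steps, dtype=np.int64) + done)
            all_ids.append(np.asarray(ids, dtype=np.int64))
        done += K

    steps_arr = np.concatenate(all_steps) if all_steps else np.empty(0, dtype=np.int64)
    ids_arr = np.concatenate(all_ids) if all_ids else np.empty(0, dtype=np.int64)
    times = (steps_arr + 1) * dt
    raster = SpikeRaster(ids_arr, times, n_neurons=n, duration=config.duration)
    if log is not None:
        n_inh = sum(p.is_inhibitory for p in params)
        log.append(
            {
                "n_neurons": n,
                "n_inhibitory": int(n_inh),
                "n_edges": int(np.count_nonzero(weights)),
                "mean_abs_weight": float(np.abs(weights[weights != 0]).mean())
                if np.any(weights)
                else 0.0,
                "n_spikes": raster.n_spikes,
                "duration_ms": config.duration,
            }
        )
    return raster
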