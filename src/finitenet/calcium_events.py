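"""Calcium-fluorescence event detection.

Pipeline, per neuron trace F (fluorescence vs frame at ``frame_rate`` Hz,
default 59):

1. first difference dF[j] = F[j+1] - F[j];
2. sliding 1-s sums of dF (window = round(frame_rate) frames), giving the
   processed signal I — baseline-shift invariant by construction;
3. a zero-centred Gaussian is fitted to the histogram of I to estimate the
   per-neuron noise SD sigma;
4. candidate events are maximal runs of at least 5 consecutive samples of I
   above 3 sigma;
5. onset/offset are read from a four-parameter sigmoid (logistic) fitted to
   F over the candidate window, at 5% and 95% of the fitted plateau.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

__all__ = [
    "FluorescenceRecording",
    "ProcessedSignal",
    "CalciumEvent",
    "derivative_integral",
    "estimate_noise_sigma",
    "detect_events",
    "fit_onset_offset",
    "detect_all_events",
]

MIN_CONSECUTIVE = 5
SIGMA_MULTIPLIER = 3.0


@dataclass(frozen=True)
class FluorescenceRecording:
    """Trace matrix (neurons x frames) with acquisition metadata."""

    F: np.ndarray
    frame_rate: float = 59.0
    gaba_flags: np.ndarray | None = None  # optional per-neuron GABAergic flag

    def __post_init__(self):
        F = np.atleast_2d(np.asarray(self.F, dtype=np.float64))
        object.__setattr__(self, "F", F)
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if F.shape[1] <= self.frame_rate:
            raise ValueError("recording must be longer than 1 s")

    @property
    def n_neurons(self) -> int:
        return self.F.shape[0]

    @property
    def n_frames(self) -> int:
        return self.F.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate


@dataclass(frozen=True)
class ProcessedSignal:
    """Windowed first-difference sums and per-neuron noise SDs."""

    I: np.ndarray  # (neurons, n_frames - window)
    sigma: np.ndarray
    window: int  # frames per 1-s window
    frame_rate: float
    degenerate: np.ndarray = None  # type: ignore[assignment]  # per-neuron flag


@dataclass(frozen=True)
class CalciumEvent:
    neuron_id: int
    onset: float  # s from recording start
    offset: float  # s
    window: tuple[int, int]  # frame span of the suprathreshold run (in I)
    sigmoid_params: tuple[float, float, float, float]  # base, amplitude, t0, tau

    def __post_init__(self):
        if not self.onset < self.offset:
            raise ValueError("onset must precede offset")


def derivative_integral(rec: FluorescenceRecording) -> ProcessedSignal:
    """First difference of F summed over overlapping 1-s sliding windows.

    ``I[i, j] = sum_{j <= n < j + window} dF[i, n]``, which telescopes to
    ``F[i, j + window] - F[i, j]``; the telescoped form is used directly.
    """
    window = int(round(rec.frame_rate))
    if rec.n_frames < window + 2:
        raise ValueError("recording shorter than one integration window")
    F = rec.F
    I = F[:, window:] - F[:, :-window]
    sigma = np.empty(rec.n_neurons)
    degenerate = np.zeros(rec.n_neurons, dtype=bool)
    for i in range(rec.n_neurons):
        sigma[i], degenerate[i] = estimate_noise_sigma(I[i])
    return ProcessedSignal(
        I=I, sigma=sigma, window=window, frame_rate=rec.frame_rate,
        degenerate=degenerate,
    )


def _freedman_diaconis_bins(x: np.ndarray) -> int:
    q75, q25 = np.percentile(x, [75, 25])
    iqr = q75 - q25
    if iqr <= 0:
        return 10
    h = 2.0 * iqr / len(x) ** (1.0 / 3.0)
    return max(int(np.ceil((x.max() - x.min()) / h)), 5)


def estimate_noise_sigma(I_row: np.ndarray) -> tuple[float, bool]:
    """Noise SD of a processed trace from a zero-centred Gaussian histogram fit.

    The histogram (Freedman-Diaconis bins) is built over the central 95% of
    the values so that sparse large transients do not widen the noise
    estimate; the fitted model is ``amp * exp(-x^2 / (2 sigma^2))``.
    Returns ``(sigma, degenerate_flag)``; an all-constant signal yields
    ``(0.0, True)``.
    """
    x = np.asarray(I_row, dtype=np.float64)
    if len(x) < 200:
        raise ValueError("need at least 200 samples for the noise fit")
    lo, hi = np.percentile(x, [2.5, 97.5])
    core = x[(x >= lo) & (x <= hi)]
    if np.ptp(core) <= 1e-9 * (np.abs(np.median(core)) + 1.0):
        return 0.0, True
    counts, edges = np.histogram(core, bins=_freedman_diaconis_bins(core))
    centers = 0.5 * (edges[:-1] + edges[1:])
    sigma0 = core.std() or 1.0

    def model(xx, amp, sigma):
        return amp * np.exp(-(xx**2) / (2.0 * sigma**2))

    try:
        popt, _ = optimize.curve_fit(
            model, centers, counts, p0=[counts.max(), sigma0],
            bounds=([0.0, 1e-12 * max(sigma0, 1.0)], [np.inf, np.inf]),
            maxfev=10_000,
        )
        return float(abs(popt[1])), False
    except RuntimeError:
        return float(sigma0), False


def detect_events(
    I_row: np.ndarray,
    sigma: float,
    sigma_multiplier: float = SIGMA_MULTIPLIER,
    min_consecutive: int = MIN_CONSECUTIVE,
) -> list[tuple[int, int]]:
    """Maximal runs of at least 5 consecutive samples above 3 sigma.

    Returns half-open frame spans ``(start, stop)`` into the processed
    signal; shorter runs are discarded.  Runs touching the edges count if
    they contain enough samples.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive (degenerate traces carry no events)")
    above = np.asarray(I_row) > sigma_multiplier * sigma
    padded = np.concatenate([[False], above, [False]]).astype(np.int8)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    return [(int(s), int(e)) for s, e in zip(starts, stops) if e - s >= min_consecutive]


def _logistic(t, base, amplitude, t0, tau):
    return base + amplitude / (1.0 + np.exp(-(t - t0) / tau))


# ln(19): the logistic reaches 5% of its plateau at t0 - tau*ln(19) and
# 95% at t0 + tau*ln(19)
_LN19 = np.log(19.0)


def fit_onset_offset(
    F_row: np.ndarray,
    window: tuple[int, int],
    frame_rate: float,
    neuron_id: int = 0,
    pad_s: float = 0.5,
) -> CalciumEvent | None:
    """Fit a four-parameter sigmoid to F over a candidate window.

    The window (frame span in the processed signal) is padded by ``pad_s``
    on each side where available.  Onset and offset are the times at which
    the fitted curve crosses 5% and 95% of its plateau.  Returns ``None``
    when the fit does not converge or is degenerate (callers count these in
    a QC log).
    """
    F_row = np.asarray(F_row, dtype=np.float64)
    pad = int(round(pad_s * frame_rate))
    lo = max(window[0] - pad, 0)
    hi = min(window[1] + int(round(frame_rate)) + pad, len(F_row))
    seg = F_row[lo:hi]
    t = (lo + np.arange(len(seg))) / frame_rate
    if len(seg) < 6 or np.ptp(seg) == 0:
        return None
    base0 = float(np.percentile(seg, 10))
    amp0 = float(np.percentile(seg, 90) - base0) or np.ptp(seg)
    t00 = float(t[int(np.argmax(np.diff(seg)))]) if len(seg) > 1 else float(t.mean())
    tau0 = max(0.05, 2.0 / frame_rate)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = optimize.curve_fit(
                _logistic, t, seg, p0=[base0, amp0, t00, tau0],
                bounds=(
                    [-np.inf, 1e-12, t[0] - 1.0, 1e-4],
                    [np.inf, np.inf, t[-1] + 1.0, 10.0],
                ),
                maxfev=10_000,
            )
    except (RuntimeError, ValueError):
        return None
    base, amplitude, t0, tau = (float(p) for p in popt)
    onset = t0 - tau * _LN19
    offset = t0 + tau * _LN19
    if not np.isfinite(onset) or not np.isfinite(offset) or onset >= offset:
        return None
    return CalciumEvent(
        neuron_id=neuron_id,
        onset=onset,
        offset=offset,
        window=(int(window[0]), int(window[1])),
        sigmoid_params=(base, amplitude, t0, tau),
    )


def _merge_windows(windows: list[tuple[int, int]], gap: int) -> list[tuple[int, int]]:
    """Collapse runs separated by less than ``gap`` samples into one span."""
    merged: list[list[int]] = []
    for s, e in windows:
        if merged and s - merged[-1][1] < gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def detect_all_events(
    rec: FluorescenceRecording,
    sigma_multiplier: float = SIGMA_MULTIPLIER,
    qc: dict | None = None,
) -> list[CalciumEvent]:
    """Full per-neuron pipeline: process, threshold, fit onsets.

    One fluorescence transient can split into several qualifying runs when
    the processed signal dips briefly below threshold, so runs of the same
    neuron closer than one integration window are merged into a single
    candidate before the sigmoid fit.  ``qc`` (optional dict) collects
    counts of candidate windows, merges, converged fits and dropped fits.
    """
    proc = derivative_integral(rec)
    events: list[CalciumEvent] = []
    n_candidates = n_dropped = n_merged = 0
    for i in range(rec.n_neurons):
        if proc.degenerate[i] or proc.sigma[i] <= 0:
            continue
        raw = detect_events(proc.I[i], proc.sigma[i], sigma_multiplier)
        wins = _merge_windows(raw, gap=proc.window)
        n_merged += len(raw) - len(wins)
        for win in wins:
            n_candidates += 1
            ev = fit_onset_offset(rec.F[i], win, rec.frame_rate, neuron_id=i)
            if ev is None:
                n_dropped += 1
                warnings.warn(
                    f"sigmoid fit dropped for neuron {i} window {win}",
                    stacklevel=2,
                )
                continue
            events.append(ev)
    if qc is not None:
        qc.update(
            candidates=n_candidates,
            merged_runs=n_merged,
            fitted=n_candidates - n_dropped,
            dropped=n_dropped,
        )
    events.sort(key=lambda e: (e.neuron_id, e.onset))
    return events
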