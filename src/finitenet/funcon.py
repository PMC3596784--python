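"""Directed functional connectivity from event-onset series.

A directed edge j -> k is declared when the onsets of k repeatedly follow
the onsets of j: for every onset of j the nearest onset of k within a
+-500 ms lag window contributes one signed lag, and the lag sample must be
inconsistent BOTH with a zero-mean Gaussian (one-sample t-test) AND with a
uniform distribution on the lag window (Kolmogorov-Smirnov test), each at a
5% confidence level.  The sign of the mean lag sets the direction.

Normalised cross-correlograms of binarised onset series give each neuron a
summary pair (<CC_max>, <tau_max>) over its positively correlated partners:
the average peak correlation and the average lag of the peak.  Under the
package's sign convention a positive ``tau_max`` means the reference neuron
leads its partner.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "OnsetSeries",
    "FunctionalEdge",
    "DirectedFunctionalGraph",
    "CorrelationSummary",
    "pairwise_lags",
    "test_direction",
    "build_functional_graph",
    "rank_nodes",
    "cross_correlation",
    "summarize_correlations",
]

MAX_LAG_MS = 500.0
MIN_LAGS = 5  # minimum evidence before a pair is tested
ALPHA = 0.05


@dataclass(frozen=True)
class OnsetSeries:
    """Per-neuron ordered event-onset times over a common span."""

    onsets: tuple  # tuple of per-neuron float arrays (s)
    duration: float  # s
    sampling_period: float = 1.0 / 59.0  # s; bin width used by Eq.-style CCs

    def __post_init__(self):
        ons = tuple(np.asarray(o, dtype=np.float64) for o in self.onsets)
        for o in ons:
            if o.size and (o.min() < 0 or o.max() > self.duration):
                raise ValueError("onsets must lie within [0, duration]")
            if np.any(np.diff(o) < 0):
                raise ValueError("per-neuron onsets must be ordered")
        object.__setattr__(self, "onsets", ons)

    @property
    def n_neurons(self) -> int:
        return len(self.onsets)

    def binarize(self, neuron: int) -> np.ndarray:
        """0/1 series at the sampling period (>=1 onset in bin -> 1)."""
        n_bins = int(np.ceil(self.duration / self.sampling_period))
        out = np.zeros(n_bins)
        idx = np.minimum(
            (self.onsets[neuron] / self.sampling_period).astype(np.int64), n_bins - 1
        )
        out[idx] = 1.0
        return out


@dataclass(frozen=True)
class FunctionalEdge:
    source: int
    target: int
    mean_lag_ms: float
    n_lags: int
    t_p: float
    ks_p: float


@dataclass(frozen=True)
class DirectedFunctionalGraph:
    n_neurons: int
    edges: tuple  # FunctionalEdge, at most one per unordered pair

    def in_degree(self) -> np.ndarray:
        d = np.zeros(self.n_neurons, dtype=np.int64)
        for e in self.edges:
            d[e.target] += 1
        return d

    def out_degree(self) -> np.ndarray:
        d = np.zeros(self.n_neurons, dtype=np.int64)
        for e in self.edges:
            d[e.source] += 1
        return d

    def edge_set(self) -> set:
        return {(e.source, e.target) for e in self.edges}


@dataclass(frozen=True)
class CorrelationSummary:
    cc_max: np.ndarray  # per-neuron <CC_max> (NaN when no positive partner)
    tau_max: np.ndarray  # per-neuron <tau_max> (s)
    n_partners: np.ndarray
    excluded: np.ndarray  # True when the neuron had no positive-CC partner


def pairwise_lags(onsets_j, onsets_k, max_lag_ms: float = MAX_LAG_MS) -> np.ndarray:
    """Signed lags (ms): nearest onset of k within +-max_lag of each onset of j.

    Positive lag means k fired after j.  Onsets of j with no k onset in the
    window contribute nothing.
    """
    oj = np.asarray(onsets_j, dtype=np.float64)
    ok = np.asarray(onsets_k, dtype=np.float64)
    if oj.size == 0 or ok.size == 0:
        return np.empty(0)
    pos = np.searchsorted(ok, oj)
    lags = []
    for t, p in zip(oj, pos):
        best = np.inf
        if p < len(ok):
            best = ok[p] - t
        if p > 0 and abs(ok[p - 1] - t) < abs(best):
            best = ok[p - 1] - t
        lag_ms = best * 1000.0
        if abs(lag_ms) <= max_lag_ms:
            lags.append(lag_ms)
    return np.asarray(lags)


def test_direction(
    lags: np.ndarray,
    alpha: float = ALPHA,
    max_lag_ms: float = MAX_LAG_MS,
    min_lags: int = MIN_LAGS,
) -> tuple[str, float, float]:
    """Dual statistical gate on a lag sample.

    Returns ``(decision, t_p, ks_p)`` where decision is ``"none"``,
    ``"forward"`` (j -> k, positive mean lag) or ``"backward"``.  An edge
    requires rejecting BOTH the zero-mean Gaussian (t-test) and the uniform
    lag distribution (KS test) at ``alpha``; fewer than ``min_lags`` samples
    yield ``"none"`` with NaN p-values (insufficient data).
    """
    lags = np.asarray(lags, dtype=np.float64)
    if lags.size < min_lags:
        return "none", np.nan, np.nan
    if np.ptp(lags) == 0:
        # all identical: maximal evidence unless exactly zero
        if lags[0] == 0:
            return "none", 1.0, 0.0
        return ("forward" if lags[0] > 0 else "backward"), 0.0, 0.0
    t_p = float(stats.ttest_1samp(lags, 0.0).pvalue)
    ks_p = float(
        stats.kstest(lags, stats.uniform(loc=-max_lag_ms, scale=2 * max_lag_ms).cdf).pvalue
    )
    if t_p < alpha and ks_p < alpha:
        return ("forward" if lags.mean() > 0 else "backward"), t_p, ks_p
    return "none", t_p, ks_p


def build_functional_graph(
    series: OnsetSeries,
    alpha: float = ALPHA,
    max_lag_ms: float = MAX_LAG_MS,
    min_lags: int = MIN_LAGS,
    fdr: bool = False,
) -> DirectedFunctionalGraph:
    """Evaluate every neuron pair once and keep the significant directions.

    Each unordered pair {j, k} (j < k) is scored from the lags of k's onsets
    around j's onsets, so at most one direction survives per pair.  No
    correction across pairs is applied by default; ``fdr=True`` switches to
    a Benjamini-Hochberg gate on the per-pair p-value (the larger of the two
    test p-values, since an edge needs both rejections).
    """
    n = series.n_neurons
    if n < 2:
        raise ValueError("need at least 2 neurons")
    candidates = []
    for j in range(n):
        for k in range(j + 1, n):
            lags = pairwise_lags(series.onsets[j], series.onsets[k], max_lag_ms)
            decision, t_p, ks_p = test_direction(
                lags, alpha if not fdr else 1.0, max_lag_ms, min_lags
            )
            if decision == "none":
                continue
            src, tgt = (j, k) if decision == "forward" else (k, j)
            candidates.append(
                FunctionalEdge(
                    source=src, target=tgt,
                    mean_lag_ms=float(abs(np.mean(lags))),
                    n_lags=int(lags.size), t_p=t_p, ks_p=ks_p,
                )
            )
    if fdr and candidates:
        pair_p = np.array([max(e.t_p, e.ks_p) for e in candidates])
        order = np.argsort(pair_p)
        m = len(pair_p)
        keep = np.zeros(m, dtype=bool)
        max_i = -1
        for rank, idx in enumerate(order, start=1):
            if pair_p[idx] <= alpha * rank / m:
                max_i = rank
        if max_i > 0:
            keep[order[:max_i]] = True
        candidates = [e for e, k_ in zip(candidates, keep) if k_]
    return DirectedFunctionalGraph(n_neurons=n, edges=tuple(candidates))


def rank_nodes(graph: DirectedFunctionalGraph, mode: str, top_n: int = 10) -> list[int]:
    """Top nodes by in-degree (mode='input') or out-degree (mode='output').

    Ties break toward the smaller node id.  Nodes of zero degree are not
    listed.
    """
    if mode == "input":
        deg = graph.in_degree()
    elif mode == "output":
        deg = graph.out_degree()
    else:
        raise ValueError("mode must be 'input' or 'output'")
    order = sorted(range(graph.n_neurons), key=lambda i: (-deg[i], i))
    return [i for i in order if deg[i] > 0][:top_n]


def cross_correlation(
    a: np.ndarray,
    b: np.ndarray,
    max_lag_samples: int,
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Normalised cross-correlogram of two equal-length binned series.

    ``CC_ab(tau) = (1/N_overlap) sum_t (a_t - <a>)(b_{t+tau} - <b>) / (sigma_a sigma_b)``

    so the autocorrelation at lag zero equals 1 exactly.  Positive ``tau``
    at the maximum means ``a`` leads ``b``.  Returns
    ``(lags, curve, cc_max, tau_max)`` with lags in samples.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("series must be 1-D and equal length")
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        raise ValueError("undefined correlation: zero-variance series")
    am, bm = a - a.mean(), b - b.mean()
    n = len(a)
    max_lag_samples = int(min(max_lag_samples, n - 1))
    lags = np.arange(-max_lag_samples, max_lag_samples + 1)
    curve = np.empty(lags.shape)
    norm = sa * sb  # commutative, so swapping arguments reuses it exactly
    for idx, tau in enumerate(lags):
        if tau >= 0:
            prod = am[: n - tau] * bm[tau:]
        else:
            prod = am[-tau:] * bm[: n + tau]
        curve[idx] = prod.sum() / ((n - abs(tau)) * norm)
    imax = int(np.argmax(curve))
    return lags, curve, float(curve[imax]), float(lags[imax])


def summarize_correlations(
    series: OnsetSeries,
    max_lag_s: float = 1.0,
) -> CorrelationSummary:
    """Per-neuron mean peak correlation and mean peak lag over partners.

    For each ordered pair the peak of the normalised cross-correlogram
    within ``|tau| <= max_lag_s`` is located; neuron i averages ``CC_max``
    and ``tau_max`` over the partners whose peak correlation is positive.
    Neurons with no positive partner (or an empty/constant series) are
    flagged as excluded.
    """
    n = series.n_neurons
    if n < 2:
        raise ValueError("need at least 2 neurons")
    binned = [series.binarize(i) for i in range(n)]
    max_lag = int(round(max_lag_s / series.sampling_period))
    cc = np.full((n, n), np.nan)
    tau = np.full((n, n), np.nan)
    usable = [bool(b.std() > 0) for b in binned]
    for i in range(n):
        for j in range(i + 1, n):
            if not (usable[i] and usable[j]):
                continue
            _, _, cmax, tmax = cross_correlation(binned[i], binned[j], max_lag)
            cc[i, j] = cc[j, i] = cmax
            tau[i, j] = tmax * series.sampling_period
            tau[j, i] = -tau[i, j]
    cc_mean = np.full(n, np.nan)
    tau_mean = np.full(n, np.nan)
    n_partners = np.zeros(n, dtype=np.int64)
    excluded = np.ones(n, dtype=bool)
    for i in range(n):
        mask = np.zeros(n, dtype=bool)
        for j in range(n):
            if j != i and np.isfinite(cc[i, j]) and cc[i, j] > 0:
                mask[j] = True
        if mask.any():
            cc_mean[i] = cc[i, mask].mean()
            tau_mean[i] = tau[i, mask].mean()
            n_partners[i] = int(mask.sum())
            excluded[i] = False
    return CorrelationSummary(
        cc_max=cc_mean, tau_max=tau_mean, n_partners=n_partners, excluded=excluded
    )
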