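"""Photon-by-photon two-state hidden Markov inference (H2MM) with fixed state
efficiencies, plus the validation analyses built on it.

The observation sequence of a burst is its donor-excitation photons: arrival
times and colors (donor / acceptor).  The hidden state is the molecule's
conformation, switching between state 1 (low FRET, efficiency E1) and state 2
(high FRET, E2) as a continuous-time Markov chain with rates k12 and k21.  The
transition matrix between consecutive photons is the exact two-state matrix
exponential for the inter-photon interval, so no clock-tick discretization is
needed; the emission probability of an acceptor photon in state i is E_i.

Fitting maximizes the exact total log-likelihood over (k12, k21) with E1, E2
held fixed, from many random restarts (log-uniform initial rates).  The fit
surface is the likelihood itself; the maximizer is a derivative-free simplex
search in log-rate space, whose accepted-likelihood trace is monotone
non-decreasing within each restart.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from ._kernels import forward_loglik, recolor_kernel, viterbi_kernel
from .bursts import Burst, fret_histogram_values
from .errors import DataError, InvalidParameterError

RATE_GUESS_RANGE = (1e2, 1e6)  # s^-1, log-uniform restart initialization


@dataclass
class TwoStateModel:
    """lambda = (Pi, A, B) of the two-state photon HMM.

    ``pi`` defaults to the stationary distribution of (k12, k21): bursts sample
    molecules at equilibrium.
    """

    k12: float
    k21: float
    E1: float
    E2: float
    pi: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.k12 <= 0 or self.k21 <= 0:
            raise InvalidParameterError("rates must be positive")
        if not (0 <= self.E1 <= 1 and 0 <= self.E2 <= 1):
            raise InvalidParameterError("efficiencies must lie in [0, 1]")
        if self.pi is None:
            k = self.k12 + self.k21
            self.pi = np.array([self.k21 / k, self.k12 / k])
        else:
            self.pi = np.asarray(self.pi, dtype=float)
            if self.pi.shape != (2,) or abs(self.pi.sum() - 1) > 1e-9 or np.any(self.pi < 0):
                raise InvalidParameterError("pi must be a length-2 probability vector")

    @property
    def P1(self) -> float:
        """Equilibrium population of state 1."""
        return self.k21 / (self.k12 + self.k21)

    @property
    def P2(self) -> float:
        return self.k12 / (self.k12 + self.k21)


@dataclass
class H2MMFit:
    """Result of a multi-restart likelihood maximization."""

    model: TwoStateModel
    loglik: float
    n_restarts: int
    converged: bool
    restart_logliks: np.ndarray
    traces: list[np.ndarray]  # accepted (monotone) likelihood trace per restart
    n_photons: int
    n_bursts: int

    @property
    def P1(self) -> float:
        return self.model.P1

    @property
    def P2(self) -> float:
        return self.model.P2


@dataclass
class ViterbiPath:
    """Most probable per-photon state sequence for one burst."""

    states: np.ndarray  # 1 or 2 per donor-excitation photon
    times: np.ndarray  # seconds, same length
    n_transitions: int


@dataclass
class DwellSummary:
    """Complete (uncensored) Viterbi dwell durations and exponential-MLE exit rates."""

    dwells_state1: np.ndarray  # seconds
    dwells_state2: np.ndarray
    n_censored: int
    exit_rate_1: float  # s^-1, 1 / mean complete dwell in state 1 (nan if none)
    exit_rate_2: float


def transition_matrix(k12: float, k21: float, dt: float) -> np.ndarray:
    """Exact two-state transition matrix over an interval ``dt`` seconds.

    With k = k12 + k21 and stationary probabilities pi1 = k21/k, pi2 = k12/k:
    P11 = pi1 + pi2 e^{-k dt}, P12 = pi2 (1 - e^{-k dt}), and symmetrically.
    """
    if dt < 0:
        raise InvalidParameterError("dt must be nonnegative")
    if k12 <= 0 or k21 <= 0:
        raise InvalidParameterError("rates must be positive")
    k = k12 + k21
    p1, p2 = k21 / k, k12 / k
    e = np.exp(-k * dt)
    return np.array([[p1 + p2 * e, p2 * (1 - e)], [p1 * (1 - e), p2 + p1 * e]])


def _observation_arrays(bursts: list[Burst]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Concatenate donor-excitation photon times/colors with burst offsets."""
    times_parts, color_parts = [], []
    for b in bursts:
        t, c = b.dex_photons()
        if t.size == 0:
            raise DataError("a burst has no donor-excitation photons")
        times_parts.append(t)
        color_parts.append(c)
    starts = np.zeros(len(bursts) + 1, dtype=np.int64)
    starts[1:] = np.cumsum([t.size for t in times_parts])
    return (
        np.concatenate(times_parts),
        np.concatenate(color_parts).astype(np.uint8),
        starts,
    )


def burst_loglik(model: TwoStateModel, burst: Burst) -> float:
    """Log-likelihood (nats) of one burst's donor-excitation photon sequence."""
    times, colors, starts = _observation_arrays([burst])
    return float(
        forward_loglik(
            times, colors, starts, model.k12, model.k21, model.E1, model.E2,
            model.pi[0], model.pi[1],
        )
    )


def total_loglik(model: TwoStateModel, bursts: list[Burst]) -> float:
    """Summed log-likelihood over a burst list."""
    times, colors, starts = _observation_arrays(bursts)
    return float(
        forward_loglik(
            times, colors, starts, model.k12, model.k21, model.E1, model.E2,
            model.pi[0], model.pi[1],
        )
    )


def fit_h2mm(
    bursts: list[Burst],
    E1: float,
    E2: float,
    n_restarts: int = 50,
    seed: int | None = None,
    max_iter: int = 3000,
    rel_tol: float = 1e-9,
    stationary_pi: bool = True,
) -> H2MMFit:
    """Maximum-likelihood rates of the fixed-efficiency two-state photon HMM.

    Each restart starts from rates drawn log-uniformly on [1e2, 1e6] s^-1 and
    maximizes the exact likelihood by Nelder-Mead simplex search over
    (ln k12, ln k21); the best restart is returned.  Convergence is declared at
    relative log-likelihood change below ``rel_tol`` (or ``max_iter``
    iterations, flagged as unconverged).
    """
    if not bursts:
        raise DataError("need at least one burst")
    if E1 == E2:
        raise InvalidParameterError("E1 and E2 must differ for a two-state fit")
    times, colors, starts = _observation_arrays(bursts)
    if colors.min() == colors.max():
        import warnings

        warnings.warn("all photons share one color; rates are at a likelihood boundary")

    def neg_loglik(log_rates: np.ndarray) -> float:
        k12, k21 = np.exp(np.clip(log_rates, -5, 20))
        if stationary_pi:
            k = k12 + k21
            pi1, pi2 = k21 / k, k12 / k
        else:
            pi1 = pi2 = 0.5
        return -forward_loglik(times, colors, starts, k12, k21, E1, E2, pi1, pi2)

    rng = np.random.default_rng(seed)
    lo, hi = np.log(RATE_GUESS_RANGE[0]), np.log(RATE_GUESS_RANGE[1])
    best = None
    restart_lls, traces, convs = [], [], []
    for _ in range(n_restarts):
        x0 = rng.uniform(lo, hi, size=2)
        trace: list[float] = []

        def record(xk):
            trace.append(-neg_loglik(xk))

        f0 = neg_loglik(x0)
        res = minimize(
            neg_loglik,
            x0,
            method="Nelder-Mead",
            callback=record,
            options={
                "maxiter": max_iter,
                "xatol": 1e-7,
                "fatol": rel_tol * max(abs(f0), 1.0),
                "adaptive": False,
            },
        )
        ll = -res.fun
        restart_lls.append(ll)
        # accepted-likelihood trace is monotone by construction
        traces.append(np.maximum.accumulate(np.array(trace if trace else [ll])))
        convs.append(bool(res.success))
        if best is None or ll > best[0]:
            best = (ll, res.x, bool(res.success))
    ll, x, conv = best
    k12, k21 = np.exp(x)
    model = TwoStateModel(k12=float(k12), k21=float(k21), E1=E1, E2=E2,
                          pi=None if stationary_pi else np.array([0.5, 0.5]))
    return H2MMFit(
        model=model,
        loglik=float(ll),
        n_restarts=n_restarts,
        converged=conv,
        restart_logliks=np.array(restart_lls),
        traces=traces,
        n_photons=int(times.size),
        n_bursts=len(bursts),
    )


def viterbi_path(model: TwoStateModel, burst: Burst) -> ViterbiPath:
    """Most probable state sequence of one burst (log-space DP; ties to state 1)."""
    times, colors, starts = _observation_arrays([burst])
    out = np.zeros(times.size, dtype=np.int8)
    viterbi_kernel(
        times, colors, starts, model.k12, model.k21, model.E1, model.E2,
        model.pi[0], model.pi[1], out,
    )
    states = out.astype(int)
    return ViterbiPath(states=states, times=times, n_transitions=int(np.sum(np.diff(states) != 0)))


def viterbi_paths(model: TwoStateModel, bursts: list[Burst]) -> list[ViterbiPath]:
    """Viterbi decoding of every burst (single kernel call)."""
    times, colors, starts = _observation_arrays(bursts)
    out = np.zeros(times.size, dtype=np.int8)
    viterbi_kernel(
        times, colors, starts, model.k12, model.k21, model.E1, model.E2,
        model.pi[0], model.pi[1], out,
    )
    paths = []
    for i in range(len(bursts)):
        lo, hi = starts[i], starts[i + 1]
        st = out[lo:hi].astype(int)
        paths.append(ViterbiPath(states=st, times=times[lo:hi], n_transitions=int(np.sum(np.diff(st) != 0))))
    return paths


@dataclass
class RecoloringResult:
    """Posterior-predictive (recoloring) check of a fitted model."""

    data_hist: np.ndarray
    replica_mean_hist: np.ndarray
    replica_hists: np.ndarray  # (n_replicas, n_bins)
    discrepancy: float  # sum of squared bin differences, data vs replica mean
    replica_discrepancies: np.ndarray  # leave-one-out: each replica vs mean of the others
    edges: np.ndarray

    @property
    def within_envelope(self) -> bool:
        """Data histogram within the 95th percentile of replica-replica discrepancies."""
        return self.discrepancy <= np.percentile(self.replica_discrepancies, 95)


def recolor_dataset(
    model: TwoStateModel,
    bursts: list[Burst],
    n_replicas: int = 10,
    seed: int | None = None,
    n_bins: int = 35,
) -> RecoloringResult:
    """Redraw photon colors from the fitted model, keeping arrival times.

    For each replica, per-burst state paths are re-sampled from the model at
    the recorded photon times, colors re-drawn from the emission probabilities,
    per-burst E recomputed and histogrammed with the same binning as the data.
    The discrepancy statistic is the sum of squared bin-mass differences.
    """
    if n_replicas < 1:
        raise InvalidParameterError("n_replicas must be >= 1")
    times, colors, starts = _observation_arrays(bursts)
    data_e = np.array(
        [colors[starts[i]:starts[i + 1]].mean() for i in range(len(bursts))]
    )
    edges, data_hist = fret_histogram_values(data_e, n_bins=n_bins)
    rng = np.random.default_rng(seed)
    rep_hists = np.empty((n_replicas, n_bins))
    for r in range(n_replicas):
        out = np.zeros(times.size, dtype=np.uint8)
        recolor_kernel(
            times, starts, model.k12, model.k21, model.E1, model.E2,
            model.pi[0], model.pi[1],
            rng.random(len(bursts)), rng.random(times.size), rng.random(times.size),
            out,
        )
        rep_e = np.array([out[starts[i]:starts[i + 1]].mean() for i in range(len(bursts))])
        _, rep_hists[r] = fret_histogram_values(rep_e, n_bins=n_bins)
    mean_hist = rep_hists.mean(axis=0)
    discrepancy = float(np.sum((data_hist - mean_hist) ** 2))
    loo = np.empty(n_replicas)
    for r in range(n_replicas):
        others = np.delete(rep_hists, r, axis=0).mean(axis=0)
        loo[r] = np.sum((rep_hists[r] - others) ** 2)
    return RecoloringResult(
        data_hist=data_hist,
        replica_mean_hist=mean_hist,
        replica_hists=rep_hists,
        discrepancy=discrepancy,
        replica_discrepancies=loo,
        edges=edges,
    )


def segment_bursts(
    model: TwoStateModel,
    bursts: list[Burst],
    min_segment_photons: int = 5,
    n_bins: int = 35,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Viterbi segmentation check: per-segment acceptor fraction histogram.

    Bursts are split at Viterbi state changes; for every segment with at least
    ``min_segment_photons`` photons the segment E (acceptor fraction) is
    recorded.  Returns ``(segment_E, edges, masses)``.
    """
    times, colors, starts = _observation_arrays(bursts)
    paths = viterbi_paths(model, bursts)
    seg_e = []
    for i, p in enumerate(paths):
        c = colors[starts[i]:starts[i + 1]]
        bounds = np.concatenate(([0], np.flatnonzero(np.diff(p.states) != 0) + 1, [p.states.size]))
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            if hi - lo >= min_segment_photons:
                seg_e.append(c[lo:hi].mean())
    seg_e = np.array(seg_e)
    if seg_e.size == 0:
        return seg_e, np.linspace(0, 1, n_bins + 1), np.zeros(n_bins)
    edges, masses = fret_histogram_values(seg_e, n_bins=n_bins)
    return seg_e, edges, masses


def dwell_times(paths: list[ViterbiPath]) -> DwellSummary:
    """Dwell-time analysis of Viterbi paths.

    A dwell runs from the first photon of a state run to the first photon of
    the next run.  The first and last run of every burst are censored by the
    burst edges and excluded from the exponential MLE; the exit rate of a state
    is the reciprocal mean of its complete dwells.
    """
    d1, d2 = [], []
    n_censored = 0
    for p in paths:
        bounds = np.concatenate(([0], np.flatnonzero(np.diff(p.states) != 0) + 1))
        run_starts = p.times[bounds]
        run_states = p.states[bounds]
        n_runs = bounds.size
        n_censored += min(n_runs, 2)
        # complete dwells: runs 2 .. n_runs-1 (1-based), i.e. indices 1..n_runs-2
        for j in range(1, n_runs - 1):
            dur = run_starts[j + 1] - run_starts[j]
            (d1 if run_states[j] == 1 else d2).append(dur)
    d1 = np.array(d1)
    d2 = np.array(d2)
    rate1 = float(1.0 / d1.mean()) if d1.size else float("nan")
    rate2 = float(1.0 / d2.mean()) if d2.size else float("nan")
    return DwellSummary(
        dwells_state1=d1,
        dwells_state2=d2,
        n_censored=n_censored,
        exit_rate_1=rate1,
        exit_rate_2=rate2,
    )
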