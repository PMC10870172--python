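"""Photon-level HMM: transition matrices, likelihood and Viterbi against
exhaustive enumeration, fitting behavior, recoloring, segmentation, dwells."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.linalg import expm

from fretpaths import bursts as bp
from fretpaths import h2mm, simulate
from fretpaths.errors import InvalidParameterError


def make_dex_burst(times_s, colors, clock=1e-9):
    """Burst of donor-excitation photons at the given times/acceptor flags."""
    ticks = np.round(np.asarray(times_s) / clock).astype(np.int64)
    return bp.Burst(
        timestamps=ticks,
        channels=np.asarray(colors, dtype=np.uint8),
        excitations=np.zeros(len(colors), dtype=np.uint8),
        clock_period=clock,
    )


def exhaustive_loglik(model, times, colors):
    """Brute-force sum over all 2^n state sequences; A via the matrix exponential."""
    n = len(times)
    Q = np.array([[-model.k12, model.k12], [model.k21, -model.k21]])
    As = [expm(Q * dt) for dt in np.diff(times)]
    B = np.array([[1 - model.E1, model.E1], [1 - model.E2, model.E2]])
    total = 0.0
    for seq in itertools.product((0, 1), repeat=n):
        p = model.pi[seq[0]] * B[seq[0], colors[0]]
        for i in range(1, n):
            p *= As[i - 1][seq[i - 1], seq[i]] * B[seq[i], colors[i]]
        total += p
    return np.log(total)


def exhaustive_viterbi(model, times, colors):
    """Argmax over all 2^n paths (first in lexicographic order wins ties)."""
    n = len(times)
    Q = np.array([[-model.k12, model.k12], [model.k21, -model.k21]])
    As = [expm(Q * dt) for dt in np.diff(times)]
    B = np.array([[1 - model.E1, model.E1], [1 - model.E2, model.E2]])
    best, best_p = None, -1.0
    for seq in itertools.product((0, 1), repeat=n):
        p = model.pi[seq[0]] * B[seq[0], colors[0]]
        for i in range(1, n):
            p *= As[i - 1][seq[i - 1], seq[i]] * B[seq[i], colors[i]]
        if p > best_p:
            best, best_p = seq, p
    return np.array(best) + 1


class TestTransitionMatrix:
    def test_zero_interval_is_identity(self):
        assert np.allclose(h2mm.transition_matrix(4e4, 2e4, 0.0), np.eye(2))

    def test_long_interval_reaches_stationarity(self):
        A = h2mm.transition_matrix(44_400.0, 20_600.0, 1.0)
        pi = np.array([20_600.0, 44_400.0]) / 65_000.0
        assert np.allclose(A[0], pi, atol=1e-12)
        assert np.allclose(A[1], pi, atol=1e-12)

    def test_matches_matrix_exponential(self):
        k12, k21, dt = 44_400.0, 20_600.0, 1e-5
        Q = np.array([[-k12, k12], [k21, -k21]])
        assert np.allclose(h2mm.transition_matrix(k12, k21, dt), expm(Q * dt), atol=1e-10)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.floats(1.0, 1e6), st.floats(1.0, 1e6), st.floats(0.0, 1e-2))
    def test_rows_sum_to_one(self, k12, k21, dt):
        A = h2mm.transition_matrix(k12, k21, dt)
        assert np.allclose(A.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(A >= 0)

    def test_negative_interval_rejected(self):
        with pytest.raises(InvalidParameterError):
            h2mm.transition_matrix(1e4, 1e4, -1e-6)


class TestBurstLoglik:
    def test_single_donor_photon(self):
        model = h2mm.TwoStateModel(k12=1e4, k21=1e4, E1=0.25, E2=0.8, pi=np.array([1.0, 0.0]))
        b = make_dex_burst([0.0], [0])
        assert h2mm.burst_loglik(model, b) == pytest.approx(np.log(0.75), abs=1e-12)

    def test_equal_efficiencies_make_rates_irrelevant(self):
        rng = np.random.default_rng(0)
        times = np.sort(rng.uniform(0, 1e-3, 30))
        colors = rng.integers(0, 2, 30)
        b = make_dex_burst(times, colors)
        lls = [
            h2mm.burst_loglik(h2mm.TwoStateModel(k12=k, k21=2 * k, E1=0.6, E2=0.6), b)
            for k in (1e3, 1e4, 1e5)
        ]
        assert np.ptp(lls) < 1e-9

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            n = rng.integers(1, 11)
            times = np.sort(rng.uniform(0, 2e-4, n))
            colors = rng.integers(0, 2, n)
            model = h2mm.TwoStateModel(
                k12=float(np.exp(rng.uniform(np.log(1e3), np.log(1e5)))),
                k21=float(np.exp(rng.uniform(np.log(1e3), np.log(1e5)))),
                E1=float(rng.uniform(0.05, 0.45)),
                E2=float(rng.uniform(0.55, 0.95)),
            )
            b = make_dex_burst(times, colors)
            t, c = b.dex_photons()
            assert h2mm.burst_loglik(model, b) == pytest.approx(
                exhaustive_loglik(model, t, c), abs=1e-9
            )

    def test_label_symmetry(self):
        """Swapping (state1 <-> state2, E1 <-> E2, k12 <-> k21) preserves the likelihood."""
        rng = np.random.default_rng(2)
        times = np.sort(rng.uniform(0, 1e-3, 50))
        colors = rng.integers(0, 2, 50)
        b = make_dex_burst(times, colors)
        m = h2mm.TwoStateModel(k12=3e4, k21=1.2e4, E1=0.3, E2=0.85)
        m_swapped = h2mm.TwoStateModel(k12=1.2e4, k21=3e4, E1=0.85, E2=0.3)
        assert h2mm.burst_loglik(m, b) == pytest.approx(h2mm.burst_loglik(m_swapped, b), abs=1e-9)


class TestViterbi:
    def test_deterministic_emission_follows_colors(self):
        model = h2mm.TwoStateModel(k12=1e4, k21=1e4, E1=0.0, E2=1.0)
        colors = np.array([0, 1, 0, 1, 1, 0])
        b = make_dex_burst(np.arange(6) * 1e-5, colors)
        path = h2mm.viterbi_path(model, b)
        assert np.array_equal(path.states, colors + 1)
        assert path.n_transitions == 4

    def test_matches_exhaustive_argmax(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = rng.integers(2, 11)
            times = np.sort(rng.uniform(0, 2e-4, n))
            colors = rng.integers(0, 2, n)
            model = h2mm.TwoStateModel(
                k12=float(np.exp(rng.uniform(np.log(1e3), np.log(1e5)))),
                k21=float(np.exp(rng.uniform(np.log(1e3), np.log(1e5)))),
                E1=float(rng.uniform(0.05, 0.45)),
                E2=float(rng.uniform(0.55, 0.95)),
            )
            b = make_dex_burst(times, colors)
            t, c = b.dex_photons()
            assert np.array_equal(h2mm.viterbi_path(model, b).states, exhaustive_viterbi(model, t, c))

    def test_slow_exchange_state_accuracy(self):
        m = simulate.GeneratorModel(k12=100.0, k21=100.0, leak=0.0, direct=0.0,
                                    bg_rate_d=0.0, bg_rate_a=0.0, aex_fraction=0.0,
                                    f_donor_only=0.0, f_acceptor_only=0.0)
        model = h2mm.TwoStateModel(k12=100.0, k21=100.0, E1=0.4, E2=0.8)
        correct = total = 0
        for s in range(100):
            sb = simulate.simulate_burst_photons(m, 1e-3, seed=s, species="double")
            b = bp.Burst(sb.timestamps, sb.channels, sb.excitations, sb.clock_period)
            truth = sb.path.states_at(sb.timestamps * m.clock_period)
            pred = h2mm.viterbi_path(model, b).states
            correct += int(np.sum(pred == truth))
            total += truth.size
        assert correct / total >= 0.95


class TestFit:
    def test_round_trip_symmetric_rates(self):
        m = simulate.GeneratorModel(k12=30_000.0, k21=30_000.0, leak=0.0, direct=0.0,
                                    bg_rate_d=0.0, bg_rate_a=0.0,
                                    f_donor_only=0.0, f_acceptor_only=0.0)
        ds = simulate.simulate_dataset(m, 800, seed=5)
        found = bp.find_bursts(ds.stream())
        metrics = bp.compute_metrics(found)
        sel, _ = bp.select_double_labeled(found, metrics)
        fit = h2mm.fit_h2mm(sel, E1=0.4, E2=0.8, n_restarts=5, seed=6)
        assert fit.model.k12 == pytest.approx(30_000.0, rel=0.10)
        assert fit.model.k21 == pytest.approx(30_000.0, rel=0.10)
        # maximizer property: fitted likelihood at least the truth's
        truth = h2mm.TwoStateModel(k12=30_000.0, k21=30_000.0, E1=0.4, E2=0.8)
        assert fit.loglik >= h2mm.total_loglik(truth, sel) - 1e-3

    def test_traces_are_monotone(self, pl1_fit):
        for trace in pl1_fit["fit"].traces:
            assert np.all(np.diff(trace) >= 0)

    def test_best_restart_reported(self, pl1_fit):
        fit = pl1_fit["fit"]
        assert fit.loglik == pytest.approx(fit.restart_logliks.max())
        assert fit.P1 + fit.P2 == pytest.approx(1.0, abs=1e-12)

    def test_equal_fixed_efficiencies_rejected(self, counts_burst):
        with pytest.raises(InvalidParameterError):
            h2mm.fit_h2mm([counts_burst(10, 10, 0)], E1=0.5, E2=0.5)


class TestRecoloring:
    def test_zero_replicas_rejected(self, counts_burst):
        model = h2mm.TwoStateModel(k12=1e4, k21=1e4, E1=0.4, E2=0.8)
        with pytest.raises(InvalidParameterError):
            h2mm.recolor_dataset(model, [counts_burst(10, 10, 0)], n_replicas=0)

    def test_single_state_recoloring_is_binomial(self):
        """With E1 = E2 = E, replica burst E values follow Binomial(n, E)/n."""
        model = h2mm.TwoStateModel(k12=1e4, k21=1e4, E1=0.6, E2=0.6)
        rng = np.random.default_rng(7)
        bursts = [
            make_dex_burst(np.sort(rng.uniform(0, 1e-3, 100)), rng.integers(0, 2, 100))
            for _ in range(300)
        ]
        res = h2mm.recolor_dataset(model, bursts, n_replicas=5, seed=8)
        centers = (res.edges[:-1] + res.edges[1:]) / 2
        mean_e = float(np.sum(centers * res.replica_mean_hist))
        assert mean_e == pytest.approx(0.6, abs=0.02)
        var_e = float(np.sum((centers - mean_e) ** 2 * res.replica_mean_hist))
        assert var_e == pytest.approx(0.6 * 0.4 / 100, rel=0.35)


class TestSegmentation:
    def test_single_state_burst_is_one_segment(self):
        model = h2mm.TwoStateModel(k12=100.0, k21=100.0, E1=0.1, E2=0.9)
        rng = np.random.default_rng(9)
        colors = (rng.random(80) < 0.9).astype(int)
        b = make_dex_burst(np.sort(rng.uniform(0, 1e-3, 80)), colors)
        seg_e, edges, mass = h2mm.segment_bursts(model, [b])
        assert seg_e.size == 1
        assert seg_e[0] == pytest.approx(0.9, abs=0.1)

    def test_threshold_above_burst_size_drops_burst(self):
        model = h2mm.TwoStateModel(k12=1e4, k21=1e4, E1=0.1, E2=0.9)
        b = make_dex_burst(np.arange(4) * 1e-5, [1, 1, 1, 1])
        seg_e, _, mass = h2mm.segment_bursts(model, [b], min_segment_photons=5)
        assert seg_e.size == 0

    def test_well_separated_states_give_bimodal_segments(self):
        m = simulate.GeneratorModel(k12=2_000.0, k21=2_000.0, E1=0.2, E2=0.9,
                                    leak=0.0, direct=0.0, bg_rate_d=0.0, bg_rate_a=0.0,
                                    aex_fraction=0.0, f_donor_only=0.0, f_acceptor_only=0.0)
        ds = simulate.simulate_dataset(m, 300, seed=10)
        found = bp.find_bursts(ds.stream())
        model = h2mm.TwoStateModel(k12=2_000.0, k21=2_000.0, E1=0.2, E2=0.9)
        seg_e, edges, mass = h2mm.segment_bursts(model, found, min_segment_photons=10)
        centers = (edges[:-1] + edges[1:]) / 2
        lo = mass[np.abs(centers - 0.2) < 0.1].sum()
        hi = mass[np.abs(centers - 0.9) < 0.1].sum()
        assert lo > 0.25 and hi > 0.25


class TestDwellTimes:
    def test_hand_built_path(self):
        # photons at 0,10,20,30,40 us, states 1,1,2,2,1:
        # one complete state-2 dwell from t=20 to t=40 us
        path = h2mm.ViterbiPath(
            states=np.array([1, 1, 2, 2, 1]),
            times=np.array([0, 10, 20, 30, 40]) * 1e-6,
            n_transitions=2,
        )
        summary = h2mm.dwell_times([path])
        assert summary.dwells_state1.size == 0
        assert summary.dwells_state2.size == 1
        assert summary.dwells_state2[0] == pytest.approx(20e-6)
        assert summary.exit_rate_2 == pytest.approx(1.0 / 20e-6)

    def test_single_state_burst_fully_censored(self):
        path = h2mm.ViterbiPath(states=np.ones(50, dtype=int), times=np.arange(50) * 1e-6, n_transitions=0)
        summary = h2mm.dwell_times([path])
        assert summary.dwells_state1.size == 0 and summary.dwells_state2.size == 0
        assert np.isnan(summary.exit_rate_1)
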