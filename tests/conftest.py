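"""Shared fixtures: synthetic datasets and fits reused across test modules.

The heavy fixtures are session-scoped so that the parameter-recovery, dwell
and recoloring checks all share one simulation + fit per condition.
"""

from __future__ import annotations

import numpy as np
import pytest

from fretpaths import bursts as bp
from fretpaths import h2mm, simulate

# Generating conditions for the fast-switching (PL1-like, no substrate) system:
# k12 = 44,400 s^-1, k21 = 20,600 s^-1, detection 300 kHz, E = 0.4 / 0.8.
PL1_RATES = (44_400.0, 20_600.0)
# Low-equilibrium condition: population ratio k21/k12 = 0.24 at total rate 60,000 s^-1.
K024_RATES = (60_000.0 / 1.24, 60_000.0 * 0.24 / 1.24)


def _simulate_and_fit(k12, k21, n_bursts, seed, photon_rate=300_000.0, n_restarts=10,
                      burst_duration=1e-3, E1=0.4, E2=0.8):
    model = simulate.GeneratorModel(k12=k12, k21=k21, photon_rate=photon_rate, E1=E1, E2=E2)
    dataset = simulate.simulate_dataset(model, n_bursts, seed=seed, burst_duration=burst_duration)
    found = bp.find_bursts(dataset.stream())
    cf = bp.estimate_corrections(found)
    metrics = bp.compute_metrics(found, cf)
    selected, sel_metrics = bp.select_double_labeled(found, metrics)
    e1, e2 = simulate.apparent_efficiencies(model)
    fit = h2mm.fit_h2mm(selected, E1=e1, E2=e2, n_restarts=n_restarts, seed=seed + 1)
    return {
        "model": model,
        "dataset": dataset,
        "found": found,
        "selected": selected,
        "metrics": sel_metrics,
        "corrections": cf,
        "fit": fit,
    }


@pytest.fixture(scope="session")
def pl1_fit():
    """7000-burst dataset at the fast-switching rates, full pipeline + 10-restart fit."""
    return _simulate_and_fit(*PL1_RATES, n_bursts=7000, seed=11)


@pytest.fixture(scope="session")
def k024_fit():
    """7000-burst dataset at equilibrium coefficient 0.24, full pipeline + fit."""
    return _simulate_and_fit(*K024_RATES, n_bursts=7000, seed=23)


@pytest.fixture(scope="session")
def dwell_fit():
    """Dataset in the dwell-resolvable regime for dwell-time validation.

    Dwell analysis reads state durations off the Viterbi path, so dwells must
    span many photons (photon spacing << dwell) yet fit inside bursts
    (dwell << burst length), and the states must be well separated.  Rates
    10,000 / 4,640 s^-1 (population ratio 0.464) at 500 kHz detection in 2 ms
    bursts with E = 0.1 / 0.9 satisfy all three; outside this regime Viterbi
    dwell estimates are biased low (merged short dwells) or high (burst-window
    truncation).
    """
    return _simulate_and_fit(10_000.0, 4_640.0, n_bursts=1200, seed=37,
                             photon_rate=500_000.0, burst_duration=2e-3,
                             E1=0.1, E2=0.9)


def make_burst(f_dd=0, f_da=0, f_aa=0, clock_period=1e-9, gap_ticks=1000):
    """Construct a Burst with the requested photon counts (times 1 us apart)."""
    n = f_dd + f_da + f_aa
    channels = np.array([bp.DONOR] * f_dd + [bp.ACCEPTOR] * f_da + [bp.ACCEPTOR] * f_aa, dtype=np.uint8)
    excit = np.array([bp.DEX] * (f_dd + f_da) + [bp.AEX] * f_aa, dtype=np.uint8)
    return bp.Burst(
        timestamps=np.arange(n, dtype=np.int64) * gap_ticks,
        channels=channels,
        excitations=excit,
        clock_period=clock_period,
    )


@pytest.fixture
def counts_burst():
    return make_burst
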