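"""Synthetic photon datasets and coordinate ensembles with known ground truth.

The photon generator emulates diffusion-based smFRET bursts from a molecule
whose FRET efficiency switches between two conformational states as a
continuous-time Markov chain (rates ``k12``, ``k21`` of order 1e4-1e5 s^-1).
During a burst, detected photons form a renewal stream whose mean rate is the
requested detection rate but whose gaps never reach the burst-search cutoff,
so that every simulated burst is recoverable by the inter-photon gap rule.
The photon-level HMM conditions on arrival times, so this gap construction
does not perturb the color statistics it infers from.

Photon colors follow the state at the photon's arrival time: an emission
photon is detected in the acceptor channel with probability E_state, donor
photons leak into the acceptor channel with probability ``leak``, direct
excitation of the acceptor by the donor laser adds acceptor-channel photons at
rate ``direct * photon_rate``, and uncorrelated background photons are mixed
in per channel.  Acceptor-excitation (PIE) photons are interleaved at rate
``aex_fraction * photon_rate``.  Donor-only and acceptor-only contaminant
species are produced at the requested fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

from .bursts import ACCEPTOR, AEX, DEX, DONOR, PhotonStream
from .errors import InvalidParameterError, PathDegeneracyError

SPECIES_DOUBLE = "double"
SPECIES_DONOR_ONLY = "donor_only"
SPECIES_ACCEPTOR_ONLY = "acceptor_only"


@dataclass
class GeneratorModel:
    """Parameters of the two-state photon generator.

    Defaults correspond to a fast-switching pore-loop-like system: transition
    rates of a few 1e4 s^-1, detection at 300 kHz during a burst, leak 0.05,
    direct excitation 0.02, ~1 kHz background per channel and realistic
    donor-only / acceptor-only contaminant fractions.
    """

    k12: float = 44_400.0  # state1 -> state2 rate, s^-1
    k21: float = 20_600.0  # state2 -> state1 rate, s^-1
    E1: float = 0.4  # apparent FRET efficiency of state 1 (low)
    E2: float = 0.8  # apparent FRET efficiency of state 2 (high)
    photon_rate: float = 300_000.0  # mean detected photons s^-1 during a burst
    aex_fraction: float = 1.0  # acceptor-excitation photons per donor-excitation emission
    leak: float = 0.05
    direct: float = 0.02
    bg_rate_d: float = 1_000.0  # background, donor channel, s^-1
    bg_rate_a: float = 1_000.0  # background, acceptor channel, s^-1
    f_donor_only: float = 0.15
    f_acceptor_only: float = 0.10
    clock_period: float = 1e-9  # seconds per tick
    max_intra_gap: float = 4.5e-6  # supremum of intra-burst photon gaps, seconds
    rate_multiplier_state2: float = 1.0  # optional per-state brightness ratio

    def __post_init__(self) -> None:
        if self.k12 < 0 or self.k21 < 0:
            raise InvalidParameterError("rates must be nonnegative")
        if not (0 <= self.E1 < self.E2 <= 1):
            raise InvalidParameterError("need 0 <= E1 < E2 <= 1")
        for name in ("leak", "direct", "f_donor_only", "f_acceptor_only", "aex_fraction"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise InvalidParameterError(f"{name} must lie in [0, 1]")
        if self.f_donor_only + self.f_acceptor_only > 1:
            raise InvalidParameterError("contaminant fractions must sum to <= 1")
        if self.photon_rate <= 0 or self.bg_rate_d < 0 or self.bg_rate_a < 0:
            raise InvalidParameterError("photon rates must be positive (background nonnegative)")
        if self.clock_period <= 0 or self.max_intra_gap <= 0:
            raise InvalidParameterError("clock_period and max_intra_gap must be positive")

    @property
    def stationary_p1(self) -> float:
        """Stationary probability of state 1, k21 / (k12 + k21)."""
        return self.k21 / (self.k12 + self.k21)


@dataclass
class StateTrajectory:
    """Latent two-state path: ordered switch times within [0, duration]."""

    switch_times: np.ndarray
    initial_state: int
    duration: float

    def __post_init__(self) -> None:
        self.switch_times = np.asarray(self.switch_times, dtype=float)
        if self.initial_state not in (1, 2):
            raise InvalidParameterError("initial_state must be 1 or 2")
        if self.switch_times.size:
            if np.any(np.diff(self.switch_times) <= 0):
                raise InvalidParameterError("switch_times must be strictly increasing")
            if self.switch_times[0] < 0 or self.switch_times[-1] > self.duration:
                raise InvalidParameterError("switch_times must lie within [0, duration]")

    def states_at(self, times: np.ndarray) -> np.ndarray:
        """State (1 or 2) occupied at each query time."""
        n_switches = np.searchsorted(self.switch_times, np.asarray(times, dtype=float), side="right")
        other = 3 - self.initial_state
        return np.where(n_switches % 2 == 0, self.initial_state, other).astype(np.int8)

    def occupancy(self, state: int = 1) -> float:
        """Fraction of [0, duration] spent in ``state``."""
        bounds = np.concatenate(([0.0], self.switch_times, [self.duration]))
        segment = np.diff(bounds)
        seg_state = np.where(np.arange(segment.size) % 2 == 0, self.initial_state, 3 - self.initial_state)
        return float(segment[seg_state == state].sum() / self.duration)


@dataclass
class SimulatedBurst:
    """One generated burst plus its ground truth."""

    timestamps: np.ndarray  # integer ticks, strictly increasing
    channels: np.ndarray
    excitations: np.ndarray
    species: str
    path: StateTrajectory | None
    clock_period: float


@dataclass
class PhotonDataset:
    """A full synthetic dataset: a photon stream plus per-burst ground truth."""

    timestamps: np.ndarray
    channels: np.ndarray
    excitations: np.ndarray
    burst_ids: np.ndarray  # ground-truth burst index per photon
    species: list[str]  # per ground-truth burst
    paths: list[StateTrajectory | None]
    model: GeneratorModel
    clock_period: float

    @property
    def n_bursts(self) -> int:
        return len(self.species)

    def stream(self) -> PhotonStream:
        return PhotonStream(
            timestamps=self.timestamps,
            channels=self.channels,
            excitations=self.excitations,
            clock_period=self.clock_period,
        )


def simulate_two_state_path(
    model: GeneratorModel,
    duration: float,
    seed: int | np.random.Generator,
    initial_state: int | None = None,
) -> StateTrajectory:
    """Gillespie draw of the latent two-state chain.

    Holding times are exponential with mean 1/k12 in state 1 and 1/k21 in
    state 2; the initial state is drawn from the stationary distribution
    unless given.
    """
    if duration <= 0:
        raise InvalidParameterError("duration must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if initial_state is None:
        initial_state = 1 if rng.random() < model.stationary_p1 else 2
    rates = {1: model.k12, 2: model.k21}
    t = 0.0
    state = initial_state
    switches = []
    while True:
        rate = rates[state]
        if rate == 0:
            break
        t += rng.exponential(1.0 / rate)
        if t >= duration:
            break
        switches.append(t)
        state = 3 - state
    return StateTrajectory(np.array(switches), initial_state, duration)


def _truncated_exp_log_rate(target_mean: float, cutoff: float) -> float:
    """Rate lambda such that a density proportional to exp(-lambda * g) on (0, cutoff)
    has the requested mean.  lambda may be negative (mean above cutoff/2)."""
    if not (0 < target_mean < cutoff):
        raise InvalidParameterError("target mean gap must lie in (0, cutoff)")

    def mean_of(lam: float) -> float:
        if abs(lam * cutoff) < 1e-9:
            return cutoff / 2.0
        return 1.0 / lam - cutoff / np.expm1(lam * cutoff)

    lo, hi = -1.0 / cutoff, 1.0 / cutoff
    while mean_of(lo) < target_mean:
        lo *= 2.0
    while mean_of(hi) > target_mean:
        hi *= 2.0
    return brentq(lambda lam: mean_of(lam) - target_mean, lo, hi, xtol=1e-6 / cutoff)


def _sample_gaps(rng: np.random.Generator, n: int, lam: float, cutoff: float) -> np.ndarray:
    """Inverse-CDF draws from the truncated-exponential gap law."""
    u = rng.random(n)
    if abs(lam * cutoff) < 1e-9:
        return u * cutoff
    return -np.log1p(-u * -np.expm1(-lam * cutoff)) / lam


def _strictify(ticks: np.ndarray) -> np.ndarray:
    """Make integer timestamps strictly increasing, resolving ties by +1 tick."""
    ticks = np.maximum.accumulate(ticks)
    while True:
        d = np.diff(ticks)
        bad = d <= 0
        if not bad.any():
            return ticks
        ticks = ticks.copy()
        ticks[1:][bad] = ticks[:-1][bad] + 1
        ticks = np.maximum.accumulate(ticks)


def apparent_efficiencies(model: GeneratorModel) -> tuple[float, float]:
    """Per-state acceptor probability of a donor-excitation photon, after leak,
    direct excitation and background mixing.

    These are the emission probabilities the photon-level HMM sees, hence the
    values at which its fixed state efficiencies should be pinned when fitting
    data from this generator.
    """
    rho, delta = model.photon_rate, model.direct * model.photon_rate
    bd, ba = model.bg_rate_d, model.bg_rate_a
    out = []
    for e in (model.E1, model.E2):
        acc = e + (1.0 - e) * model.leak
        out.append((rho * acc + delta + ba) / (rho + delta + bd + ba))
    return out[0], out[1]


def simulate_burst_photons(
    model: GeneratorModel,
    duration: float,
    seed: int | np.random.Generator,
    species: str | None = None,
) -> SimulatedBurst:
    """Generate the photons of one burst.

    The species (double-labeled molecule, donor-only or acceptor-only
    contaminant) is drawn from the model's contaminant fractions unless given.
    """
    if duration <= 0:
        raise InvalidParameterError("duration must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if species is None:
        u = rng.random()
        if u < model.f_donor_only:
            species = SPECIES_DONOR_ONLY
        elif u < model.f_donor_only + model.f_acceptor_only:
            species = SPECIES_ACCEPTOR_ONLY
        else:
            species = SPECIES_DOUBLE

    # component rates of the merged photon stream, by species
    em = model.photon_rate if species != SPECIES_ACCEPTOR_ONLY else 0.0
    direct = model.direct * model.photon_rate if species != SPECIES_DONOR_ONLY else 0.0
    aex = model.aex_fraction * model.photon_rate if species != SPECIES_DONOR_ONLY else 0.0
    rates = np.array([em, direct, model.bg_rate_d, model.bg_rate_a, aex])
    total = rates.sum()
    if total <= 0:
        raise InvalidParameterError("no photon source has a positive rate")

    lam = _truncated_exp_log_rate(1.0 / total, model.max_intra_gap)
    n_guess = int(total * duration * 1.5 + 30)
    gaps = _sample_gaps(rng, n_guess, lam, model.max_intra_gap)
    times = np.cumsum(gaps)
    while times[-1] < duration:
        extra = _sample_gaps(rng, n_guess, lam, model.max_intra_gap)
        times = np.concatenate([times, times[-1] + np.cumsum(extra)])
    times = times[times < duration]

    kinds = rng.choice(5, size=times.size, p=rates / total)
    channels = np.empty(times.size, dtype=np.uint8)
    excit = np.full(times.size, DEX, dtype=np.uint8)

    path: StateTrajectory | None = None
    em_mask = kinds == 0
    if em_mask.any():
        if species == SPECIES_DONOR_ONLY:
            acc_prob = np.full(em_mask.sum(), 0.0)
        else:
            path = simulate_two_state_path(model, duration, rng)
            states = path.states_at(times[em_mask])
            acc_prob = np.where(states == 1, model.E1, model.E2)
        acc = rng.random(em_mask.sum()) < acc_prob
        # donor photons leak into the acceptor channel with probability leak
        leak_flip = (~acc) & (rng.random(em_mask.sum()) < model.leak)
        channels[em_mask] = np.where(acc | leak_flip, ACCEPTOR, DONOR)
    channels[kinds == 1] = ACCEPTOR  # direct excitation
    channels[kinds == 2] = DONOR  # donor-channel background
    channels[kinds == 3] = ACCEPTOR  # acceptor-channel background
    channels[kinds == 4] = ACCEPTOR  # PIE acceptor-excitation check photons
    excit[kinds == 4] = AEX

    ticks = _strictify(np.round(times / model.clock_period).astype(np.int64))
    return SimulatedBurst(
        timestamps=ticks,
        channels=channels,
        excitations=excit,
        species=species,
        path=path,
        clock_period=model.clock_period,
    )


def simulate_dataset(
    model: GeneratorModel,
    n_bursts: int,
    seed: int,
    burst_duration: float = 1e-3,
    duration_law: str = "fixed",
    inter_burst_gap: float = 1e-4,
) -> PhotonDataset:
    """Generate a dataset of well-separated bursts with ground truth.

    Bursts are separated by gaps much larger than the burst-search cutoff
    (default 100 us >> 5 us), so burst recovery is unambiguous.  ``duration_law``
    is ``"fixed"`` or ``"exponential"`` (mean ``burst_duration``).
    """
    if n_bursts < 1:
        raise InvalidParameterError("n_bursts must be >= 1")
    if duration_law not in ("fixed", "exponential"):
        raise InvalidParameterError("duration_law must be 'fixed' or 'exponential'")
    root = np.random.SeedSequence(seed)
    children = root.spawn(n_bursts)
    gap_ticks = int(round(inter_burst_gap / model.clock_period))

    ts_parts, ch_parts, ex_parts, id_parts = [], [], [], []
    species, paths = [], []
    offset = 0
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        dur = burst_duration if duration_law == "fixed" else float(rng.exponential(burst_duration))
        dur = max(dur, 10.0 / model.photon_rate)  # avoid empty degenerate bursts
        b = simulate_burst_photons(model, dur, rng)
        ts_parts.append(b.timestamps + offset)
        ch_parts.append(b.channels)
        ex_parts.append(b.excitations)
        id_parts.append(np.full(b.timestamps.size, i, dtype=np.int64))
        species.append(b.species)
        paths.append(b.path)
        offset += int(round(dur / model.clock_period)) + gap_ticks
    return PhotonDataset(
        timestamps=np.concatenate(ts_parts),
        channels=np.concatenate(ch_parts),
        excitations=np.concatenate(ex_parts),
        burst_ids=np.concatenate(id_parts),
        species=species,
        paths=paths,
        model=model,
        clock_period=model.clock_period,
    )


# ---------------------------------------------------------------------------
# coordinate ensembles and planted correlation networks
# ---------------------------------------------------------------------------


@dataclass
class EnsembleSpec:
    """Planted low-rank Gaussian ensemble: frames = mean + sum_m z_m sqrt(ev_m) mode_m."""

    n_atoms: int
    modes: np.ndarray  # (n_modes, 3 * n_atoms), orthonormal rows
    eigenvalues: np.ndarray  # variances, A^2, per mode
    mean_structure: np.ndarray  # (3 * n_atoms,)
    n_frames: int
    seed: int

    def __post_init__(self) -> None:
        self.modes = np.atleast_2d(np.asarray(self.modes, dtype=float))
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        self.mean_structure = np.asarray(self.mean_structure, dtype=float).ravel()
        if self.modes.shape[1] != 3 * self.n_atoms or self.mean_structure.size != 3 * self.n_atoms:
            raise InvalidParameterError("modes and mean_structure must have length 3 * n_atoms")
        if np.any(self.eigenvalues < 0):
            raise InvalidParameterError("eigenvalues must be nonnegative")
        gram = self.modes @ self.modes.T
        if not np.allclose(gram, np.eye(self.modes.shape[0]), atol=1e-8):
            raise InvalidParameterError("modes must be mutually orthonormal (tolerance 1e-8)")
        if self.eigenvalues.size != self.modes.shape[0]:
            raise InvalidParameterError("one eigenvalue per mode required")


def simulate_ensemble(spec: EnsembleSpec):
    """Draw a Gaussian coordinate ensemble with planted covariance structure."""
    from .allostery import CoordinateEnsemble

    rng = np.random.default_rng(spec.seed)
    z = rng.standard_normal((spec.n_frames, spec.modes.shape[0]))
    flat = spec.mean_structure + (z * np.sqrt(spec.eigenvalues)) @ spec.modes
    frames = flat.reshape(spec.n_frames, spec.n_atoms, 3)
    return CoordinateEnsemble(
        frames=frames,
        residue_ids=np.arange(1, spec.n_atoms + 1),
        chain_ids=np.array(["A"] * spec.n_atoms),
    )


def planted_correlation_network(
    n_nodes: int,
    backbone: list[int],
    backbone_corr: float,
    off_corr: float,
) -> tuple[np.ndarray, list[int], float]:
    """Correlation matrix whose unique -ln|C| shortest path between the backbone
    endpoints is the backbone chain.

    Returns ``(C, expected_path, expected_length)``.  Raises
    :class:`PathDegeneracyError` when off-backbone shortcuts tie or beat the
    backbone (``off_corr >= backbone_corr ** (len(backbone) - 1)``).
    """
    backbone = list(backbone)
    if len(set(backbone)) != len(backbone):
        raise InvalidParameterError("backbone nodes must be distinct")
    if not (0 < off_corr < backbone_corr < 1):
        raise InvalidParameterError("need 0 < off_corr < backbone_corr < 1")
    n_hops = len(backbone) - 1
    if n_hops >= 1 and off_corr >= backbone_corr**n_hops:
        raise PathDegeneracyError(
            "off-backbone correlation admits a shortcut at least as short as the backbone"
        )
    C = np.full((n_nodes, n_nodes), off_corr)
    np.fill_diagonal(C, 1.0)
    for a, b in zip(backbone[:-1], backbone[1:]):
        C[a, b] = C[b, a] = backbone_corr
    expected_length = n_hops * -np.log(backbone_corr)
    return C, backbone, float(expected_length)
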