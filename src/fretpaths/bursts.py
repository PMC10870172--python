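"""Burst search, FRET/stoichiometry metrics and burst selection for smFRET photon streams.

Photons are recorded with an integer macrotime (clock ticks), a detection
channel (donor or acceptor) and an excitation label (donor laser, ``Dex``, or
acceptor laser, ``Aex``, in a PIE/ALEX scheme).  Bursts are maximal runs of
photons whose inter-photon gaps all fall below a cutoff; per-burst raw and
corrected FRET efficiency E and stoichiometry S are computed from the three
photon counts

    F_Dex_D  donor-channel photons under donor excitation
    F_Dex_A  acceptor-channel photons under donor excitation
    F_Aex_A  acceptor-channel photons under acceptor excitation

following the standard ALEX conventions.  Leak (donor signal bleeding into the
acceptor channel) and direct excitation (acceptor excited by the donor laser)
are estimated from the donor-only and acceptor-only contaminant populations and
subtracted from the acceptor signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError, EstimationError, InvalidParameterError

# channel / excitation codes used throughout the package
DONOR = 0
ACCEPTOR = 1
DEX = 0
AEX = 1

CHANNEL_NAMES = {DONOR: "D", ACCEPTOR: "A"}
EXCITATION_NAMES = {DEX: "Dex", AEX: "Aex"}


@dataclass
class PhotonStream:
    """Time-ordered photon records.

    Parameters
    ----------
    timestamps : integer clock ticks, nondecreasing
    channels : per-photon detection channel, ``DONOR``/``ACCEPTOR``
    excitations : per-photon excitation label, ``DEX``/``AEX``
    clock_period : seconds per clock tick
    """

    timestamps: np.ndarray
    channels: np.ndarray
    excitations: np.ndarray
    clock_period: float = 1e-9

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=np.int64)
        self.channels = np.asarray(self.channels, dtype=np.uint8)
        self.excitations = np.asarray(self.excitations, dtype=np.uint8)
        n = len(self.timestamps)
        if len(self.channels) != n or len(self.excitations) != n:
            raise DataError("timestamps, channels and excitations must have equal length")
        if n > 1 and np.any(np.diff(self.timestamps) < 0):
            raise DataError("timestamps must be nondecreasing")
        if self.clock_period <= 0:
            raise InvalidParameterError("clock_period must be positive")

    def __len__(self) -> int:
        return len(self.timestamps)


@dataclass
class Burst:
    """A contiguous photon slice of a :class:`PhotonStream`."""

    timestamps: np.ndarray
    channels: np.ndarray
    excitations: np.ndarray
    clock_period: float
    start_index: int = 0

    def __len__(self) -> int:
        return len(self.timestamps)

    @property
    def start(self) -> int:
        return int(self.timestamps[0])

    @property
    def end(self) -> int:
        return int(self.timestamps[-1])

    @property
    def duration(self) -> float:
        """Burst duration in seconds (first to last photon)."""
        return (self.end - self.start) * self.clock_period

    @property
    def n_photons(self) -> int:
        return len(self.timestamps)

    @property
    def F_Dex_D(self) -> int:
        return int(np.sum((self.excitations == DEX) & (self.channels == DONOR)))

    @property
    def F_Dex_A(self) -> int:
        return int(np.sum((self.excitations == DEX) & (self.channels == ACCEPTOR)))

    @property
    def F_Aex_A(self) -> int:
        return int(np.sum((self.excitations == AEX) & (self.channels == ACCEPTOR)))

    def dex_photons(self) -> tuple[np.ndarray, np.ndarray]:
        """Donor-excitation photons only: (times in seconds, acceptor flags).

        This is the observation sequence used by the photon-level HMM;
        acceptor-excitation photons never enter it.
        """
        mask = self.excitations == DEX
        times = self.timestamps[mask].astype(np.float64) * self.clock_period
        colors = (self.channels[mask] == ACCEPTOR).astype(np.uint8)
        return times, colors


@dataclass
class CorrectionFactors:
    """Leak and direct-excitation correction factors (both unitless, in [0, 1))."""

    leak: float = 0.0
    direct: float = 0.0

    def __post_init__(self) -> None:
        if not (0 <= self.leak < 1 and 0 <= self.direct < 1):
            raise InvalidParameterError("leak and direct must lie in [0, 1)")


@dataclass
class BurstMetrics:
    """Raw and corrected E/S for one burst."""

    n_photons: int
    E_raw: float
    S_raw: float
    E_corr: float
    S_corr: float
    valid: bool = True
    burst_id: int = -1


def find_bursts(
    stream: PhotonStream,
    max_gap: float = 5e-6,
    min_photons: int = 2,
) -> list[Burst]:
    """Split a photon stream into bursts with the inter-photon gap rule.

    A gap of ``max_gap`` seconds or more between consecutive photons terminates
    a burst; runs with fewer than ``min_photons`` photons are discarded.
    """
    if max_gap < 0:
        raise InvalidParameterError("max_gap must be nonnegative")
    if len(stream) == 0:
        return []
    gaps = np.diff(stream.timestamps) * stream.clock_period
    breaks = np.flatnonzero(gaps >= max_gap) + 1
    bounds = np.concatenate(([0], breaks, [len(stream)]))
    bursts = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        if hi - lo >= min_photons:
            bursts.append(
                Burst(
                    timestamps=stream.timestamps[lo:hi],
                    channels=stream.channels[lo:hi],
                    excitations=stream.excitations[lo:hi],
                    clock_period=stream.clock_period,
                    start_index=int(lo),
                )
            )
    return bursts


def raw_E_S(burst: Burst) -> tuple[float, float]:
    """Raw FRET efficiency and raw stoichiometry from uncorrected counts.

    E_raw = F_Dex_A / (F_Dex_D + F_Dex_A);
    S_raw = (F_Dex_D + F_Dex_A) / (F_Dex_D + F_Dex_A + F_Aex_A).
    Returns ``(nan, nan)`` when the burst has no donor-excitation photons.
    """
    f_dd, f_da, f_aa = burst.F_Dex_D, burst.F_Dex_A, burst.F_Aex_A
    dex = f_dd + f_da
    if dex == 0:
        return float("nan"), float("nan")
    e_raw = f_da / dex
    s_raw = dex / (dex + f_aa)
    return e_raw, s_raw


def corrected_E_S(burst: Burst, cf: CorrectionFactors) -> BurstMetrics:
    """Leak/direct-corrected E and S for one burst.

    The corrected acceptor signal is
    ``F_A_corr = F_Dex_A - leak * F_Dex_D - direct * F_Aex_A``; E and S are
    recomputed from it.  Values may fall slightly outside [0, 1]; they are kept
    uncorrected for statistics and only clipped at histogram display.
    """
    f_dd, f_da, f_aa = burst.F_Dex_D, burst.F_Dex_A, burst.F_Aex_A
    e_raw, s_raw = raw_E_S(burst)
    f_a_corr = f_da - cf.leak * f_dd - cf.direct * f_aa
    denom = f_a_corr + f_dd
    valid = np.isfinite(e_raw) and denom > 0
    if valid:
        e_corr = f_a_corr / denom
        s_corr = denom / (denom + f_aa)
    else:
        e_corr = float("nan")
        s_corr = float("nan")
    return BurstMetrics(
        n_photons=burst.n_photons,
        E_raw=e_raw,
        S_raw=s_raw,
        E_corr=e_corr,
        S_corr=s_corr,
        valid=bool(valid),
    )


def compute_metrics(bursts: list[Burst], cf: CorrectionFactors | None = None) -> list[BurstMetrics]:
    """Per-burst metrics for a list of bursts (identity correction if ``cf`` is None)."""
    cf = cf or CorrectionFactors()
    out = []
    for i, b in enumerate(bursts):
        m = corrected_E_S(b, cf)
        m.burst_id = i
        out.append(m)
    return out


def estimate_corrections(
    bursts: list[Burst],
    donor_only_S_min: float = 0.8,
    acceptor_only_S_max: float = 0.2,
    min_population: int = 20,
) -> CorrectionFactors:
    """Estimate leak and direct-excitation factors from contaminant species.

    Leak is the mean raw E of donor-only bursts (raw S above
    ``donor_only_S_min``): any acceptor signal there is crosstalk.  Direct
    excitation is the mean F_Dex_A / F_Aex_A over acceptor-only bursts (raw S
    below ``acceptor_only_S_max``): their donor-excitation acceptor photons
    come from direct excitation alone.
    """
    donor_only_E = []
    acceptor_only_ratio = []
    for b in bursts:
        e_raw, s_raw = raw_E_S(b)
        if not np.isfinite(s_raw):
            # no Dex photons at all: acceptor-only signature
            if b.F_Aex_A > 0:
                acceptor_only_ratio.append(0.0)
            continue
        if s_raw >= donor_only_S_min:
            donor_only_E.append(e_raw)
        elif s_raw <= acceptor_only_S_max and b.F_Aex_A > 0:
            acceptor_only_ratio.append(b.F_Dex_A / b.F_Aex_A)
    if len(donor_only_E) < min_population:
        raise EstimationError(
            f"only {len(donor_only_E)} donor-only bursts (need >= {min_population}) "
            "to estimate the leak factor"
        )
    if len(acceptor_only_ratio) < min_population:
        raise EstimationError(
            f"only {len(acceptor_only_ratio)} acceptor-only bursts (need >= {min_population}) "
            "to estimate the direct-excitation factor"
        )
    return CorrectionFactors(
        leak=float(np.mean(donor_only_E)),
        direct=float(np.mean(acceptor_only_ratio)),
    )


def select_double_labeled(
    bursts: list[Burst],
    metrics: list[BurstMetrics],
    S_window: tuple[float, float] = (0.3, 0.7),
    min_photons: int = 30,
) -> tuple[list[Burst], list[BurstMetrics]]:
    """Keep bursts from double-labeled molecules: S inside the window, enough photons."""
    if len(bursts) != len(metrics):
        raise DataError("bursts and metrics must align")
    lo, hi = S_window
    sel_b, sel_m = [], []
    for b, m in zip(bursts, metrics):
        if m.valid and lo <= m.S_corr <= hi and m.n_photons >= min_photons:
            sel_b.append(b)
            sel_m.append(m)
    return sel_b, sel_m


def fret_histogram(metrics: list[BurstMetrics], n_bins: int = 35, corrected: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Normalized per-burst FRET efficiency histogram on [0, 1].

    Returns ``(edges, masses)`` with ``len(edges) == n_bins + 1`` and bin
    masses summing to 1.  E values outside [0, 1] are clipped into the edge
    bins.
    """
    if not metrics:
        raise DataError("cannot histogram an empty metric list")
    e = np.array([m.E_corr if corrected else m.E_raw for m in metrics], dtype=float)
    e = e[np.isfinite(e)]
    if e.size == 0:
        raise DataError("no finite E values to histogram")
    return fret_histogram_values(e, n_bins=n_bins)


def fret_histogram_values(e_values: np.ndarray, n_bins: int = 35) -> tuple[np.ndarray, np.ndarray]:
    """Histogram raw E values (clipped to [0, 1]) into ``n_bins`` uniform bins, mass-normalized."""
    e_values = np.asarray(e_values, dtype=float)
    if e_values.size == 0:
        raise DataError("no E values to histogram")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    counts, _ = np.histogram(np.clip(e_values, 0.0, 1.0), bins=edges)
    return edges, counts / counts.sum()


def metrics_frame(metrics: list[BurstMetrics], selected: set[int] | None = None) -> pd.DataFrame:
    """Tabulate per-burst metrics; ``selected`` marks burst ids that passed selection."""
    selected = selected or set()
    return pd.DataFrame(
        {
            "burst_id": [m.burst_id for m in metrics],
            "n_photons": [m.n_photons for m in metrics],
            "E_raw": [m.E_raw for m in metrics],
            "S_raw": [m.S_raw for m in metrics],
            "E_corr": [m.E_corr for m in metrics],
            "S_corr": [m.S_corr for m in metrics],
            "selected": [m.burst_id in selected for m in metrics],
        }
    )
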