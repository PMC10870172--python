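"""Equilibrium coefficients, labeling statistics, binding isotherms and
double-mutant-cycle energetics downstream of the photon-level HMM.

The effective equilibrium coefficient of a two-state system is
K = k21 / k12 = P1 / P2, the population ratio of the low-FRET (state 1) to the
high-FRET (state 2) conformation.  Free energies follow as dG = -R T ln K
(R = 8.314 J mol^-1 K^-1, T = 295.15 K by default); double-mutant cycles over
the wild type, two single Walker-B mutants and the double mutant quantify
thermodynamic coupling between the two ATPase sites as the difference of
opposite cycle edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .errors import DataError, InvalidParameterError

R_GAS = 8.314  # J mol^-1 K^-1
T_DEFAULT = 295.15  # K


@dataclass
class KineticsRecord:
    """Per-construct kinetic summary."""

    label: str
    k12: float
    k21: float
    K: float
    se_K: float = float("nan")
    P1: float = float("nan")
    P2: float = float("nan")


@dataclass
class DMCResult:
    """Double-mutant-cycle free energies (J mol^-1).

    Edges are the mutation free-energy changes ddG(X -> Y) = dG(X) - dG(Y); the
    coupling energy is the difference of opposite edges, identically equal to
    -R T ln[(K_wt * K_bb) / (K_b1 * K_b2)].
    """

    dG: dict[str, float]
    edges: dict[str, float]
    coupling: float
    se_edges: dict[str, float]
    se_coupling: float
    temperature: float


@dataclass
class TitrationFit:
    """Single-site binding-isotherm fit R(c) = 1 + A c^h / (Kd^h + c^h)."""

    concentrations: np.ndarray
    ratios: np.ndarray
    Kd: float
    amplitude: float
    hill: float
    residuals: np.ndarray
    rss: float
    converged: bool
    flagged: str | None = None


def equilibrium_coefficient(k12: float, k21: float, P1: float | None = None, P2: float | None = None) -> float:
    """K = k21 / k12 (checked against P1 / P2 when populations are supplied)."""
    if k12 <= 0 or k21 <= 0:
        raise InvalidParameterError("rates must be positive")
    K = k21 / k12
    if P1 is not None and P2 is not None and P2 > 0:
        if abs(K - P1 / P2) > 1e-9 * max(K, P1 / P2):
            raise DataError("populations inconsistent with rates: K != P1/P2")
    return K


def labeling_statistics(labeled_to_unlabeled_ratio: float, n_subunits: int = 6) -> np.ndarray:
    """Probability of exactly m labeled protomers in an n-mer, m = 0..n.

    A hexamer assembled from a 1:ratio mix of labeled to unlabeled protomers
    incorporates each labeled protomer with probability p = 1 / (1 + ratio);
    the count of labeled protomers is Binomial(n, p).
    """
    if labeled_to_unlabeled_ratio <= 0:
        raise InvalidParameterError("ratio must be positive")
    p = 1.0 / (1.0 + labeled_to_unlabeled_ratio)
    return stats.binom.pmf(np.arange(n_subunits + 1), n_subunits, p)


def state1_ratio_curve(concentrations, P1_values) -> tuple[np.ndarray, np.ndarray]:
    """Ratio of state-1 population at each ligand concentration to the 0-concentration reference.

    ``concentrations`` must include 0; ratio(0) = 1 exactly.
    """
    conc = np.asarray(concentrations, dtype=float)
    p1 = np.asarray(P1_values, dtype=float)
    if conc.shape != p1.shape:
        raise DataError("concentrations and P1 values must align")
    zero = np.flatnonzero(conc == 0)
    if zero.size == 0:
        raise DataError("the zero-concentration reference point is required")
    p1_0 = p1[zero[0]]
    if p1_0 <= 0:
        raise DataError("reference state-1 population must be positive")
    order = np.argsort(conc)
    return conc[order], (p1 / p1_0)[order]


def fit_binding_isotherm(concentrations, ratios, hill: float = 1.0) -> TitrationFit:
    """Least-squares fit of R(c) = 1 + A c^h / (Kd^h + c^h), A >= 0, Kd > 0.

    The curve is anchored at R(0) = 1.  Flat data pin A at 0 with Kd flagged as
    unidentifiable.
    """
    conc = np.asarray(concentrations, dtype=float)
    ratios = np.asarray(ratios, dtype=float)
    if np.unique(conc).size < 3:
        raise DataError("need at least 3 distinct concentrations")

    def model(c, A, Kd):
        ch = np.power(c, hill)
        return 1.0 + A * ch / (Kd**hill + ch)

    span = ratios.max() - 1.0
    if span <= 0:
        resid = ratios - 1.0
        return TitrationFit(conc, ratios, float("nan"), 0.0, hill, resid,
                            float(np.sum(resid**2)), True, flagged="amplitude pinned at 0; Kd unidentifiable")
    pos = conc[conc > 0]
    p0 = (span, float(np.median(pos)))
    try:
        popt, _ = optimize.curve_fit(
            model, conc, ratios, p0=p0,
            bounds=([0.0, 1e-12], [np.inf, np.inf]), maxfev=20000,
        )
        converged = True
        flagged = None
    except RuntimeError:
        popt = p0
        converged = False
        flagged = "non-convergence; initial guess returned"
    resid = ratios - model(conc, *popt)
    return TitrationFit(conc, ratios, float(popt[1]), float(popt[0]), hill,
                        resid, float(np.sum(resid**2)), converged, flagged)


def free_energy(K: float, T: float = T_DEFAULT) -> float:
    """dG = -R T ln K in J mol^-1."""
    if K <= 0:
        raise InvalidParameterError("K must be positive")
    return -R_GAS * T * np.log(K)


def free_energy_se(K: float, se_K: float, T: float = T_DEFAULT) -> float:
    """First-order (delta-method) standard error of dG: R T se_K / K."""
    if K <= 0 or se_K < 0:
        raise InvalidParameterError("K must be positive, se_K nonnegative")
    return R_GAS * T * se_K / K


def double_mutant_cycle(
    K_wt: float,
    K_B1: float,
    K_B2: float,
    K_BB: float,
    ses: tuple[float, float, float, float] | None = None,
    T: float = T_DEFAULT,
) -> DMCResult:
    """Double-mutant-cycle energetics from four equilibrium coefficients.

    Edges: ddG(WT->B1) = dG_WT - dG_B1, ddG(WT->B2) = dG_WT - dG_B2,
    ddG(B1->BB) = dG_B1 - dG_BB, ddG(B2->BB) = dG_B2 - dG_BB.
    Coupling = ddG(WT->B2) - ddG(B1->BB) = ddG(WT->B1) - ddG(B2->BB).
    Standard errors propagate from se_K by the delta method in quadrature.
    """
    Ks = {"wt": K_wt, "B1": K_B1, "B2": K_B2, "BB": K_BB}
    dG = {name: free_energy(K, T) for name, K in Ks.items()}
    edges = {
        "WT->B1": dG["wt"] - dG["B1"],
        "WT->B2": dG["wt"] - dG["B2"],
        "B1->BB": dG["B1"] - dG["BB"],
        "B2->BB": dG["B2"] - dG["BB"],
    }
    coupling = edges["WT->B2"] - edges["B1->BB"]
    alt = edges["WT->B1"] - edges["B2->BB"]
    assert abs(coupling - alt) < 1e-9 * max(1.0, abs(coupling)), "cycle identity violated"
    se_dG = {name: 0.0 for name in Ks}
    if ses is not None:
        se_dG = {
            name: free_energy_se(Ks[name], se, T)
            for name, se in zip(("wt", "B1", "B2", "BB"), ses)
        }
    se_edges = {
        "WT->B1": float(np.hypot(se_dG["wt"], se_dG["B1"])),
        "WT->B2": float(np.hypot(se_dG["wt"], se_dG["B2"])),
        "B1->BB": float(np.hypot(se_dG["B1"], se_dG["BB"])),
        "B2->BB": float(np.hypot(se_dG["B2"], se_dG["BB"])),
    }
    se_coupling = float(np.sqrt(sum(se_dG[n] ** 2 for n in se_dG)))
    return DMCResult(dG=dG, edges=edges, coupling=float(coupling),
                     se_edges=se_edges, se_coupling=se_coupling, temperature=T)
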