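"""Essential-dynamics PCA, subspace overlaps and correlation-weighted
allosteric path networks on coordinate ensembles.

An ensemble is a stack of frames of Calpha coordinates.  After least-squares
superposition, the covariance matrix of atomic fluctuations is diagonalized;
eigenvalues measure fluctuation amplitudes and eigenvectors the orthogonal
directions of maximal variance (essential dynamics).  Subspace similarity is
quantified by mode overlaps, cumulative overlaps and the root-mean-square
inner product (RMSIP) over the top modes.  Residue-residue cross-correlations
of displacement vectors define a network whose edges (between residues in
persistent contact) have length -ln|C_ij|, so that shortest paths trace the
strongest allosteric coupling routes; path-length distributions of the optimal
and suboptimal paths are compared between systems with an overlap coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import islice

import networkx as nx
import numpy as np

from .errors import DataError, InvalidParameterError


@dataclass
class CoordinateEnsemble:
    """Frames of Calpha coordinates with residue metadata.

    frames : (n_frames, n_atoms, 3) array, Angstrom
    residue_ids, chain_ids : per-atom metadata used by selections
    """

    frames: np.ndarray
    residue_ids: np.ndarray
    chain_ids: np.ndarray

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise DataError("frames must have shape (n_frames, n_atoms, 3)")
        if not np.all(np.isfinite(self.frames)):
            raise DataError("coordinates must be finite")
        n = self.frames.shape[1]
        self.residue_ids = np.asarray(self.residue_ids)
        self.chain_ids = np.asarray(self.chain_ids)
        if self.residue_ids.size != n or self.chain_ids.size != n:
            raise DataError("metadata must have one entry per atom")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    def select(self, chain: str | None = None, residues=None) -> np.ndarray:
        """Boolean atom mask for a chain and/or residue-id collection."""
        mask = np.ones(self.n_atoms, dtype=bool)
        if chain is not None:
            mask &= self.chain_ids == chain
        if residues is not None:
            mask &= np.isin(self.residue_ids, np.asarray(list(residues)))
        return mask


@dataclass
class PCAResult:
    """Eigenvalues (descending, A^2), orthonormal eigenvectors (rows), variance fractions."""

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # (n_modes, 3 * n_sel)
    variance_fractions: np.ndarray
    mean_structure: np.ndarray  # (n_sel, 3)

    def top_variance_fraction(self, k: int = 10) -> float:
        """Cumulative variance fraction of the top k modes."""
        return float(self.variance_fractions[:k].sum())


@dataclass
class AllostericNetwork:
    """Residue graph with edge length -ln|C_ij| between contacting residues."""

    graph: nx.Graph
    node_labels: np.ndarray
    contact_cutoff: float
    occupancy: float
    eps: float


@dataclass
class PathSet:
    """Up to k shortest simple paths between two residues, lengths nondecreasing."""

    source: int
    target: int
    paths: list[list[int]]
    lengths: np.ndarray
    k_requested: int
    connected: bool = True

    @property
    def optimal(self) -> list[int] | None:
        return self.paths[0] if self.paths else None


@dataclass
class PathDistributionComparison:
    """Overlap coefficient between two path-length distributions."""

    grid: np.ndarray
    density_a: np.ndarray
    density_b: np.ndarray
    oc: float


def _kabsch(mobile: np.ndarray, ref: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Optimal rotation/translation of ``mobile`` onto ``ref`` (both (n, 3))."""
    mc = mobile.mean(axis=0)
    rc = ref.mean(axis=0)
    h = (mobile - mc).T @ (ref - rc)
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    rot = u @ np.diag([1.0, 1.0, d]) @ vt
    return rot, mc, rc


def superpose(ensemble: CoordinateEnsemble, selection: np.ndarray | None = None) -> CoordinateEnsemble:
    """Least-squares rigid-body fit of every frame onto the ensemble mean.

    The fit is computed on the selected atoms and applied to all atoms; the
    mean is recomputed once and the fit repeated (two passes), after which the
    residual mean drift is negligible for analysis purposes.
    """
    if ensemble.n_frames < 2:
        raise DataError("need at least 2 frames to superpose")
    sel = np.ones(ensemble.n_atoms, dtype=bool) if selection is None else np.asarray(selection, dtype=bool)
    if sel.sum() < 3:
        raise DataError("selection must contain at least 3 atoms")
    frames = ensemble.frames.copy()
    if np.linalg.matrix_rank(frames[0][sel] - frames[0][sel].mean(axis=0)) < 2:
        raise DataError("degenerate (collinear) selection")
    for _ in range(2):
        ref = frames[:, sel].mean(axis=0)
        for f in range(frames.shape[0]):
            rot, mc, rc = _kabsch(frames[f][sel], ref)
            frames[f] = (frames[f] - mc) @ rot + rc
    return CoordinateEnsemble(frames=frames, residue_ids=ensemble.residue_ids, chain_ids=ensemble.chain_ids)


def covariance_pca(ensemble: CoordinateEnsemble, selection: np.ndarray | None = None) -> PCAResult:
    """Diagonalize the covariance matrix of selected-atom fluctuations."""
    sel = np.ones(ensemble.n_atoms, dtype=bool) if selection is None else np.asarray(selection, dtype=bool)
    x = ensemble.frames[:, sel].reshape(ensemble.n_frames, -1)
    if ensemble.n_frames < 2:
        raise DataError("a single frame has zero covariance")
    if ensemble.n_frames <= x.shape[1]:
        import warnings

        warnings.warn("fewer frames than coordinate dimensions; covariance is rank-deficient")
    mean = x.mean(axis=0)
    xc = x - mean
    cov = xc.T @ xc / (x.shape[0] - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order].T
    total = evals.sum()
    fractions = evals / total if total > 0 else np.zeros_like(evals)
    return PCAResult(
        eigenvalues=evals,
        eigenvectors=evecs,
        variance_fractions=fractions,
        mean_structure=mean.reshape(-1, 3),
    )


def mode_overlap(u: np.ndarray, v: np.ndarray) -> float:
    """|u . v| for unit-normalized mode vectors (normalized defensively)."""
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise InvalidParameterError("zero vector has no direction")
    if u.size != v.size:
        raise DataError("vectors must have equal length")
    return float(abs(u @ v) / (nu * nv))


def _check_orthonormal(basis: np.ndarray, tol: float = 1e-6) -> np.ndarray:
    basis = np.atleast_2d(np.asarray(basis, dtype=float))
    gram = basis @ basis.T
    if not np.allclose(gram, np.eye(basis.shape[0]), atol=tol):
        raise InvalidParameterError("basis must be orthonormal")
    return basis


def cumulative_overlap(u: np.ndarray, basis) -> float:
    """sqrt(sum_j (u . v_j)^2): magnitude of u's projection onto the mode set."""
    basis = _check_orthonormal(np.array([np.asarray(b, dtype=float).ravel() for b in basis]))
    u = np.asarray(u, dtype=float).ravel()
    n = np.linalg.norm(u)
    if n == 0:
        raise InvalidParameterError("zero vector has no direction")
    return float(np.sqrt(np.sum((basis @ (u / n)) ** 2)))


def rmsip(set_a, set_b) -> float:
    """Root-mean-square inner product between two orthonormal mode sets.

    RMSIP = sqrt((1/n) sum_i sum_j (a_i . b_j)^2) with n the size of set A;
    1 for identical essential subspaces, 0 for mutually orthogonal ones.
    """
    a = _check_orthonormal(np.array([np.asarray(v, dtype=float).ravel() for v in set_a]))
    b = _check_orthonormal(np.array([np.asarray(v, dtype=float).ravel() for v in set_b]))
    if a.shape[1] != b.shape[1]:
        raise DataError("mode sets live in different dimensions")
    return float(np.sqrt(np.sum((a @ b.T) ** 2) / a.shape[0]))


def cross_correlation(ensemble: CoordinateEnsemble, selection: np.ndarray | None = None) -> np.ndarray:
    """Normalized covariance of residue displacement vectors.

    C_ij = <dr_i . dr_j> / sqrt(<|dr_i|^2> <|dr_j|^2>) over frames, computed on
    the (already superposed) ensemble; the diagonal is exactly 1.
    """
    sel = np.ones(ensemble.n_atoms, dtype=bool) if selection is None else np.asarray(selection, dtype=bool)
    x = ensemble.frames[:, sel]
    dx = x - x.mean(axis=0)
    inner = np.einsum("fia,fja->ij", dx, dx) / x.shape[0]
    var = np.diag(inner)
    if np.any(var <= 0):
        raise DataError("zero-variance residue: correlation undefined")
    c = inner / np.sqrt(np.outer(var, var))
    np.fill_diagonal(c, 1.0)
    return c


def contact_map(ensemble: CoordinateEnsemble, selection: np.ndarray | None = None,
                cutoff: float = 8.0, occupancy: float = 0.75) -> np.ndarray:
    """Boolean matrix: residue pairs within ``cutoff`` Angstrom in >= ``occupancy`` of frames."""
    sel = np.ones(ensemble.n_atoms, dtype=bool) if selection is None else np.asarray(selection, dtype=bool)
    x = ensemble.frames[:, sel]
    n = x.shape[1]
    frac = np.zeros((n, n))
    for f in range(x.shape[0]):
        d = np.linalg.norm(x[f][:, None, :] - x[f][None, :, :], axis=-1)
        frac += d <= cutoff
    frac /= x.shape[0]
    contacts = frac >= occupancy
    np.fill_diagonal(contacts, False)
    return contacts


def network_from_correlation(C: np.ndarray, contacts: np.ndarray | None = None,
                             eps: float = 1e-6, node_labels=None) -> AllostericNetwork:
    """Build the -ln|C| weighted residue graph, optionally masked by contacts."""
    C = np.asarray(C, dtype=float)
    n = C.shape[0]
    if C.shape != (n, n) or not np.allclose(C, C.T, atol=1e-9):
        raise DataError("correlation matrix must be square and symmetric")
    labels = np.arange(n) if node_labels is None else np.asarray(node_labels)
    g = nx.Graph()
    g.add_nodes_from(int(v) for v in labels)
    for i in range(n):
        for j in range(i + 1, n):
            if contacts is not None and not contacts[i, j]:
                continue
            c = abs(C[i, j])
            w = -np.log(np.clip(c, eps, 1.0 - eps))
            g.add_edge(int(labels[i]), int(labels[j]), weight=float(w), correlation=float(C[i, j]))
    return AllostericNetwork(graph=g, node_labels=labels, contact_cutoff=float("nan"),
                             occupancy=float("nan"), eps=eps)


def build_network(
    ensemble: CoordinateEnsemble,
    C: np.ndarray,
    selection: np.ndarray | None = None,
    contact_cutoff: float = 8.0,
    occupancy: float = 0.75,
    eps: float = 1e-6,
) -> AllostericNetwork:
    """Allosteric network: residues in persistent Calpha contact, edge length -ln|C_ij|."""
    sel = np.ones(ensemble.n_atoms, dtype=bool) if selection is None else np.asarray(selection, dtype=bool)
    if C.shape[0] != sel.sum():
        raise DataError("correlation matrix does not match the selection size")
    contacts = contact_map(ensemble, sel, cutoff=contact_cutoff, occupancy=occupancy)
    labels = ensemble.residue_ids[sel]
    net = network_from_correlation(C, contacts=contacts, eps=eps, node_labels=labels)
    net.contact_cutoff = contact_cutoff
    net.occupancy = occupancy
    return net


def shortest_paths(network: AllostericNetwork, source: int, target: int, k: int = 200) -> PathSet:
    """Optimal and suboptimal (k-shortest simple) paths between two residues.

    Path 1 is the Dijkstra-optimal path; paths 2..k follow in nondecreasing
    length (Yen's algorithm); equal-length ties are ordered lexicographically
    by node sequence.  A disconnected pair yields an empty, flagged PathSet.
    """
    g = network.graph
    if source not in g or target not in g:
        raise DataError("source/target not in network")
    try:
        gen = nx.shortest_simple_paths(g, source, target, weight="weight")
        raw = list(islice(gen, k))
    except nx.NetworkXNoPath:
        return PathSet(source, target, [], np.array([]), k, connected=False)

    def plen(path):
        return sum(g[a][b]["weight"] for a, b in zip(path[:-1], path[1:]))

    decorated = sorted(((plen(p), tuple(p)) for p in raw), key=lambda t: (round(t[0], 10), t[1]))
    paths = [list(p) for _, p in decorated]
    lengths = np.array([l for l, _ in decorated])
    return PathSet(source, target, paths, lengths, k, connected=True)


def path_length_overlap(lengths_a, lengths_b, n_bins: int = 30) -> PathDistributionComparison:
    """Overlap coefficient between two path-length distributions.

    Both samples are histogrammed as densities on a common uniform grid
    spanning the pooled range; OC = sum_b min(p_b, q_b) * db, in [0, 1]
    (1 = identical distributions, 0 = disjoint supports).
    """
    a = np.asarray(lengths_a, dtype=float)
    b = np.asarray(lengths_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise DataError("both path-length lists must be nonempty")
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    if hi == lo:
        hi = lo + 1e-12
    grid = np.linspace(lo, hi, n_bins + 1)
    pa, _ = np.histogram(a, bins=grid, density=True)
    pb, _ = np.histogram(b, bins=grid, density=True)
    db = grid[1] - grid[0]
    oc = float(np.sum(np.minimum(pa, pb)) * db)
    return PathDistributionComparison(grid=grid, density_a=pa, density_b=pb, oc=min(oc, 1.0))


def mean_overlap_coefficient(pairs: list[tuple[np.ndarray, np.ndarray]], n_bins: int = 30) -> tuple[float, float, np.ndarray]:
    """Average OC over per-protomer path-length pairs: (mean, SD, per-pair values)."""
    ocs = np.array([path_length_overlap(a, b, n_bins=n_bins).oc for a, b in pairs])
    return float(ocs.mean()), float(ocs.std(ddof=1)) if ocs.size > 1 else 0.0, ocs
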