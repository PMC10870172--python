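"""Readers and writers: photon TSV/HDF5 dialects, multi-model PDB ensembles,
and tabular analysis reports.

The canonical photon interchange format is a TSV with columns
``burst_id, timestamp_ticks, channel, excitation`` (channel ``D``/``A``,
excitation ``Dex``/``Aex``); the bulk option is an HDF5 container with one
group per burst holding ``timestamps`` and ``detectors`` datasets, mirroring
the photon-HDF5 layout.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .bursts import ACCEPTOR, AEX, CHANNEL_NAMES, DEX, DONOR, EXCITATION_NAMES, PhotonStream
from .errors import DataError
from .simulate import GeneratorModel, PhotonDataset, StateTrajectory

_CHANNEL_CODES = {"D": DONOR, "A": ACCEPTOR}
_EXCITATION_CODES = {"Dex": DEX, "Aex": AEX}


def write_photon_tsv(dataset: PhotonDataset, path, header_comment: str | None = None) -> None:
    """Write a dataset to the TSV dialect (one photon per row)."""
    df = pd.DataFrame(
        {
            "burst_id": dataset.burst_ids,
            "timestamp_ticks": dataset.timestamps,
            "channel": [CHANNEL_NAMES[c] for c in dataset.channels],
            "excitation": [EXCITATION_NAMES[e] for e in dataset.excitations],
        }
    )
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write(f"# clock_period={dataset.clock_period!r}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_photon_tsv(path) -> tuple[PhotonStream, np.ndarray]:
    """Read the TSV dialect back: (stream, ground-truth burst ids)."""
    clock_period = 1e-9
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            if "clock_period=" in line:
                clock_period = float(line.split("clock_period=")[1])
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t")
    required = {"burst_id", "timestamp_ticks", "channel", "excitation"}
    if not required.issubset(df.columns):
        raise DataError(f"photon TSV missing columns {required - set(df.columns)}")
    try:
        channels = df["channel"].map(_CHANNEL_CODES).to_numpy(dtype=np.uint8)
        excitations = df["excitation"].map(_EXCITATION_CODES).to_numpy(dtype=np.uint8)
    except (ValueError, TypeError) as exc:
        raise DataError(f"unrecognized channel/excitation label: {exc}") from exc
    stream = PhotonStream(
        timestamps=df["timestamp_ticks"].to_numpy(np.int64),
        channels=channels,
        excitations=excitations,
        clock_period=clock_period,
    )
    return stream, df["burst_id"].to_numpy(np.int64)


def write_photon_hdf5(dataset: PhotonDataset, path) -> None:
    """Write one HDF5 group per burst with ``timestamps`` and ``detectors`` datasets.

    ``detectors`` encodes channel + excitation: 0 = Dex donor, 1 = Dex acceptor,
    2 = Aex acceptor.
    """
    with h5py.File(path, "w") as fh:
        fh.attrs["clock_period"] = dataset.clock_period
        fh.attrs["n_bursts"] = dataset.n_bursts
        for i in range(dataset.n_bursts):
            mask = dataset.burst_ids == i
            grp = fh.create_group(f"burst_{i:06d}")
            grp.create_dataset("timestamps", data=dataset.timestamps[mask])
            det = np.where(
                dataset.excitations[mask] == AEX, 2, dataset.channels[mask]
            ).astype(np.uint8)
            grp.create_dataset("detectors", data=det)
            grp.attrs["species"] = dataset.species[i]


def read_photon_hdf5(path) -> tuple[PhotonStream, np.ndarray]:
    """Read the HDF5 dialect back: (stream, burst ids)."""
    ts_parts, det_parts, id_parts = [], [], []
    with h5py.File(path, "r") as fh:
        clock_period = float(fh.attrs["clock_period"])
        names = sorted(k for k in fh.keys() if k.startswith("burst_"))
        for i, name in enumerate(names):
            ts = fh[name]["timestamps"][...]
            det = fh[name]["detectors"][...]
            ts_parts.append(ts)
            det_parts.append(det)
            id_parts.append(np.full(ts.size, i, dtype=np.int64))
    det = np.concatenate(det_parts)
    stream = PhotonStream(
        timestamps=np.concatenate(ts_parts),
        channels=np.where(det == 2, ACCEPTOR, det).astype(np.uint8),
        excitations=np.where(det == 2, AEX, DEX).astype(np.uint8),
        clock_period=clock_period,
    )
    return stream, np.concatenate(id_parts)


def write_ground_truth_tsv(dataset: PhotonDataset, path) -> None:
    """Sidecar TSV of per-burst ground truth (species, initial state, switch times)."""
    rows = []
    for i, (sp, p) in enumerate(zip(dataset.species, dataset.paths)):
        rows.append(
            {
                "burst_id": i,
                "species": sp,
                "initial_state": p.initial_state if p is not None else "",
                "duration_s": p.duration if p is not None else "",
                "switch_times_s": ";".join(f"{t:.9f}" for t in p.switch_times) if p is not None else "",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_ensemble_pdb(path):
    """Parse a multi-model PDB file into a :class:`CoordinateEnsemble` (Calpha atoms).

    Every MODEL must contain the same atoms in the same order.
    """
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    from .allostery import CoordinateEnsemble

    pdb_file = pdb.PDBFile.read(str(path))
    stack = pdb_file.get_structure()
    if stack.stack_depth() == 0:
        raise DataError(f"{path}: no MODEL records found")
    ca = stack[:, stack.atom_name == "CA"]
    if ca.array_length() == 0:
        raise DataError(f"{path}: no CA atoms found")
    return CoordinateEnsemble(
        frames=ca.coord,
        residue_ids=ca.res_id[:],
        chain_ids=ca.chain_id[:],
    )


def read_ensemble_xyz(path, n_atoms: int):
    """Plain whitespace table: one row per frame, 3*n_atoms columns (x y z per atom)."""
    from .allostery import CoordinateEnsemble

    data = np.loadtxt(path, ndmin=2)
    if data.shape[1] != 3 * n_atoms:
        raise DataError(f"{path}: expected {3 * n_atoms} columns, found {data.shape[1]}")
    return CoordinateEnsemble(
        frames=data.reshape(data.shape[0], n_atoms, 3),
        residue_ids=np.arange(1, n_atoms + 1),
        chain_ids=np.array(["A"] * n_atoms),
    )


def write_fit_report(fit, path, extra: dict | None = None) -> None:
    """JSON fit report: rates, populations, K, log-likelihood, restarts."""
    report = {
        "k12": fit.model.k12,
        "k21": fit.model.k21,
        "E1": fit.model.E1,
        "E2": fit.model.E2,
        "P1": fit.P1,
        "P2": fit.P2,
        "K": fit.model.k21 / fit.model.k12,
        "loglik": fit.loglik,
        "n_restarts": fit.n_restarts,
        "converged": fit.converged,
        "n_bursts": fit.n_bursts,
        "n_photons": fit.n_photons,
    }
    if extra:
        report.update(extra)
    Path(path).write_text(json.dumps(report, indent=2) + "\n")


def write_histogram_tsv(edges: np.ndarray, masses: np.ndarray, path) -> None:
    pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "mass": masses}
    ).to_csv(path, sep="\t", index=False)


def write_dwell_tsv(summary, path) -> None:
    """Per-dwell table (state, duration in seconds) plus exit-rate footer comment."""
    rows = [{"state": 1, "duration_s": d} for d in summary.dwells_state1]
    rows += [{"state": 2, "duration_s": d} for d in summary.dwells_state2]
    with open(path, "w") as fh:
        fh.write(f"# exit_rate_1={summary.exit_rate_1!r} exit_rate_2={summary.exit_rate_2!r} "
                 f"n_censored={summary.n_censored}\n")
        pd.DataFrame(rows, columns=["state", "duration_s"]).to_csv(fh, sep="\t", index=False)


def write_viterbi_tsv(paths, path) -> None:
    """Per-photon Viterbi states: burst_id, time_s, state."""
    rows = []
    for i, p in enumerate(paths):
        for t, s in zip(p.times, p.states):
            rows.append({"burst_id": i, "time_s": t, "state": int(s)})
    pd.DataFrame(rows, columns=["burst_id", "time_s", "state"]).to_csv(path, sep="\t", index=False)


def write_edge_list_tsv(network, path) -> None:
    rows = [
        {"i": a, "j": b, "abs_correlation": abs(d["correlation"]), "weight": d["weight"]}
        for a, b, d in network.graph.edges(data=True)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_paths_tsv(pathset, path) -> None:
    rows = [
        {"rank": r + 1, "length": l, "nodes": "-".join(map(str, p))}
        for r, (l, p) in enumerate(zip(pathset.lengths, pathset.paths))
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
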