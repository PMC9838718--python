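"""File I/O for connectome stacks, phenotypes and partitions.

Three stack layouts are supported:

* a directory of per-subject square matrices as comma- or tab-delimited text
  (one file per subject, sorted by filename);
* a single HDF5 container with datasets ``/values`` (subjects x E),
  ``/n_nodes`` and optionally ``/subject_ids``;
* a single subjects-by-edges delimited table whose header row lists the
  0-based edge indices.

Partitions are two-column delimited text (component index, network id) with a
header line ``# kind=node|edge n=<count>``; phenotypes are two-column text
(subject id, value).
"""

from __future__ import annotations

import os
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .core import (
    ConnectomeStack,
    EdgePartition,
    NodePartition,
    Phenotype,
    n_edges_for,
    vectorize,
    devectorize,
)

__all__ = [
    "load_stack",
    "save_stack_hdf5",
    "save_stack_table",
    "save_stack_matrices",
    "load_phenotype",
    "save_phenotype",
    "load_partition",
    "save_partition",
]


def _read_delimited(path: Path) -> np.ndarray:
    """Read a numeric text matrix, accepting comma or whitespace delimiters."""
    with open(path) as fh:
        first = fh.readline()
    delim = "," if "," in first else None
    return np.loadtxt(path, delimiter=delim, ndmin=2)


def load_stack(path: str | os.PathLike) -> ConnectomeStack:
    """Load a connectome stack from any supported layout (auto-detected)."""
    path = Path(path)
    if path.is_dir():
        return _load_stack_dir(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        return _load_stack_hdf5(path)
    return _load_stack_table(path)


def _load_stack_dir(path: Path) -> ConnectomeStack:
    files = sorted(p for p in path.iterdir() if p.is_file())
    if not files:
        raise ValueError(f"stack directory {path} contains no files")
    rows = []
    for f in files:
        m = _read_delimited(f)
        rows.append(vectorize(m))
    n_nodes = _read_delimited(files[0]).shape[0]
    return ConnectomeStack(np.vstack(rows), n_nodes, [f.stem for f in files])


def _load_stack_hdf5(path: Path) -> ConnectomeStack:
    with h5py.File(path, "r") as h5:
        values = np.asarray(h5["/values"])
        n_nodes = int(np.asarray(h5["/n_nodes"]).item())
        subject_ids = None
        if "subject_ids" in h5:
            subject_ids = [
                s.decode() if isinstance(s, bytes) else str(s) for s in h5["/subject_ids"][()]
            ]
    return ConnectomeStack(values, n_nodes, subject_ids)


def _load_stack_table(path: Path) -> ConnectomeStack:
    df = pd.read_csv(path, sep=None, engine="python")
    values = df.to_numpy(dtype=float)
    E = values.shape[1]
    # solve E = n(n-1)/2 for n
    n_nodes = int(round((1 + np.sqrt(1 + 8 * E)) / 2))
    if n_edges_for(n_nodes) != E:
        raise ValueError(f"table has {E} edge columns, not a triangular number")
    return ConnectomeStack(values, n_nodes)


def save_stack_hdf5(stack: ConnectomeStack, path: str | os.PathLike) -> None:
    with h5py.File(path, "w") as h5:
        h5.create_dataset("values", data=stack.values)
        h5.create_dataset("n_nodes", data=stack.n_nodes)
        if stack.subject_ids is not None:
            h5.create_dataset(
                "subject_ids", data=np.array(stack.subject_ids, dtype="S")
            )


def save_stack_table(stack: ConnectomeStack, path: str | os.PathLike) -> None:
    """Write the subjects-by-edges table with a header row of edge indices."""
    df = pd.DataFrame(stack.values, columns=[str(k) for k in range(stack.n_edges)])
    df.to_csv(path, sep="\t", index=False)


def save_stack_matrices(stack: ConnectomeStack, directory: str | os.PathLike) -> None:
    """Write one square matrix file per subject into ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    width = len(str(stack.n_subjects - 1))
    for s in range(stack.n_subjects):
        name = (
            stack.subject_ids[s]
            if stack.subject_ids is not None
            else f"subject_{s:0{width}d}"
        )
        m = devectorize(stack.values[s], stack.n_nodes)
        np.savetxt(directory / f"{name}.txt", m, delimiter=",")


def load_phenotype(path: str | os.PathLike, kind: str) -> Phenotype:
    """Load a two-column (subject id, value) phenotype file."""
    df = pd.read_csv(path, sep=None, engine="python", header=None, comment="#")
    if df.shape[1] != 2:
        raise ValueError(f"phenotype file must have 2 columns, found {df.shape[1]}")
    values = df.iloc[:, 1].to_numpy()
    if kind == "continuous":
        values = values.astype(float)
    return Phenotype(values, kind)  # type: ignore[arg-type]


def save_phenotype(
    phenotype: Phenotype, path: str | os.PathLike, subject_ids=None
) -> None:
    n = phenotype.n_subjects
    ids = subject_ids if subject_ids is not None else [f"subject_{i}" for i in range(n)]
    pd.DataFrame({"subject_id": ids, "value": phenotype.values}).to_csv(
        path, sep="\t", index=False, header=False
    )


def load_partition(path: str | os.PathLike) -> NodePartition | EdgePartition:
    """Load a partition file; returns node or edge partition per its header."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip()
    if not header.startswith("#"):
        raise ValueError(f"partition file {path} is missing its '# kind=... n=...' header")
    fields = dict(
        tok.split("=", 1) for tok in header.lstrip("#").split() if "=" in tok
    )
    kind = fields.get("kind")
    if kind not in ("node", "edge"):
        raise ValueError(f"partition header must declare kind=node|edge, got {header!r}")
    n = int(fields["n"])
    data = np.loadtxt(path, comments="#", dtype=int, ndmin=2)
    if data.shape[1] != 2:
        raise ValueError("partition file must have two columns (index, network id)")
    order = np.argsort(data[:, 0])
    idx, labels = data[order, 0], data[order, 1]
    if not np.array_equal(idx, np.arange(n)):
        raise ValueError(f"partition must label every component 0..{n - 1} exactly once")
    if kind == "node":
        return NodePartition(labels)
    return EdgePartition(labels)


def save_partition(
    partition: NodePartition | EdgePartition, path: str | os.PathLike
) -> None:
    if isinstance(partition, NodePartition):
        kind, n = "node", partition.n_nodes
    else:
        kind, n = "edge", partition.n_edges
    with open(path, "w") as fh:
        fh.write(f"# kind={kind} n={n}\n")
        for i, lab in enumerate(partition.labels):
            fh.write(f"{i}\t{int(lab)}\n")
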