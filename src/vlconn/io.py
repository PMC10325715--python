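"""Readers and writers for the package's on-disk formats.

Conventions (enforced once, here): CSV is UTF-8 with a mandatory header
row; coordinates are in µm; voxel indices are 0-based; volumes in µm³;
voxel sizes in nm.  Graphs go to GraphML and skeletons to SWC so outputs
open in standard graph/neuroanatomy tools; label volumes are HDF5
(dataset ``labels`` with a ``voxel_size_nm`` attribute) or multipage TIFF.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import h5py
import networkx as nx
import numpy as np
import pandas as pd
import tifffile

from .skeleton import Skeleton
from .tables import NEURON_COLUMNS, SYNAPSE_COLUMNS, ConnectomeError, ConnectomeTable
from .wiring import WiringDiagram

logger = logging.getLogger("vlconn")


class SchemaError(ConnectomeError):
    """A file does not match its declared column schema."""


def _check_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}; found {list(df.columns)}")


# ---------------------------------------------------------------------------
# Connectome tables
# ---------------------------------------------------------------------------

def write_connectome(table: ConnectomeTable, neurons_path, synapses_path) -> None:
    table.neurons[NEURON_COLUMNS].to_csv(neurons_path, index=False)
    table.synapses[SYNAPSE_COLUMNS].to_csv(synapses_path, index=False)


def read_connectome(neurons_path, synapses_path, allow_autapse: bool = False) -> ConnectomeTable:
    """Read and validate a neuron/synapse CSV pair."""
    neurons = pd.read_csv(neurons_path)
    synapses = pd.read_csv(synapses_path)
    _check_columns(neurons, NEURON_COLUMNS, neurons_path)
    _check_columns(synapses, [c for c in SYNAPSE_COLUMNS if c != "compartment"], synapses_path)
    if "compartment" in synapses.columns:
        synapses["compartment"] = synapses["compartment"].fillna("")
    table = ConnectomeTable(
        neurons=neurons[NEURON_COLUMNS],
        synapses=synapses[[c for c in SYNAPSE_COLUMNS if c in synapses.columns]],
        allow_autapse=allow_autapse,
    )
    return table.validate()


def write_graphml(w: WiringDiagram, path) -> None:
    nx.write_graphml(w.to_networkx(), path)


# ---------------------------------------------------------------------------
# Label volumes
# ---------------------------------------------------------------------------

def write_label_volume(volume: np.ndarray, voxel_size_nm, path) -> None:
    """Write a labeled volume; format chosen by extension (.h5/.hdf5 or .tif)."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            ds = f.create_dataset("labels", data=np.asarray(volume, dtype=np.uint32))
            ds.attrs["voxel_size_nm"] = np.asarray(voxel_size_nm, dtype=float)
    elif path.suffix in (".tif", ".tiff"):
        tifffile.imwrite(
            path,
            np.asarray(volume, dtype=np.uint32),
            photometric="minisblack",
            metadata={"voxel_size_nm": list(map(float, voxel_size_nm))},
        )
    else:
        raise ValueError(f"unsupported volume extension {path.suffix!r} (use .h5 or .tif)")


def read_label_volume(path, voxel_size_nm=None) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read a labeled volume plus its voxel size.

    HDF5 files must carry a ``voxel_size_nm`` attribute on the ``labels``
    dataset unless the caller supplies one explicitly.
    """
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            if "labels" not in f:
                raise SchemaError(f"{path}: expected dataset 'labels'")
            ds = f["labels"]
            vol = ds[()]
            if voxel_size_nm is None:
                if "voxel_size_nm" not in ds.attrs:
                    raise SchemaError(
                        f"{path}: dataset 'labels' lacks the voxel_size_nm attribute; "
                        "supply voxel_size_nm explicitly"
                    )
                voxel_size_nm = tuple(float(v) for v in ds.attrs["voxel_size_nm"])
    elif path.suffix in (".tif", ".tiff"):
        vol = tifffile.imread(path)
        if voxel_size_nm is None:
            raise SchemaError(f"{path}: supply voxel_size_nm for TIFF volumes")
    else:
        raise ValueError(f"unsupported volume extension {path.suffix!r}")
    return np.asarray(vol), tuple(float(v) for v in voxel_size_nm)


# ---------------------------------------------------------------------------
# Skeletons (SWC)
# ---------------------------------------------------------------------------

def write_swc(skel: Skeleton, path, radius_um: float = 0.5) -> None:
    """Write a skeleton as SWC (1-based ids, parent -1 for roots).

    SWC encodes trees; for skeletons with cycles one edge per independent
    cycle is necessarily dropped from the parent relation (noted in the
    header).
    """
    g = skel.to_networkx()
    coords = skel.coords_um()
    parent = {}
    dropped = 0
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        tree = nx.minimum_spanning_tree(sub)
        dropped += sub.number_of_edges() - tree.number_of_edges()
        root = min(comp)
        for child, par in nx.bfs_predecessors(tree, root):
            parent[child] = par
        parent.setdefault(root, -1)
    with open(path, "w") as f:
        f.write(f"# SWC export, label {skel.label}\n")
        if dropped:
            f.write(f"# {dropped} cycle-closing edge(s) omitted from parent relation\n")
        for i in range(skel.n_voxels):
            x, y, z = coords[i]
            par = parent.get(i, -1)
            f.write(f"{i + 1} 0 {x:.4f} {y:.4f} {z:.4f} {radius_um:.3f} "
                    f"{par + 1 if par != -1 else -1}\n")


def read_swc(path, voxel_size_nm=(1000.0, 1000.0, 1000.0)) -> Skeleton:
    """Read an SWC file back into a skeleton graph (coordinates in µm)."""
    rows = []
    with open(path) as f:
        for line in f:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            rows.append((int(parts[0]), float(parts[2]), float(parts[3]), float(parts[4]),
                         int(parts[6])))
    vx = np.asarray(voxel_size_nm) / 1000.0
    ids = {r[0]: k for k, r in enumerate(rows)}
    voxels = np.array([[round(r[1] / vx[0]), round(r[2] / vx[1]), round(r[3] / vx[2])]
                       for r in rows], dtype=np.int64)
    edges, weights = [], []
    for r in rows:
        if r[4] != -1:
            i, j = ids[r[0]], ids[r[4]]
            edges.append((min(i, j), max(i, j)))
            weights.append(float(np.linalg.norm(voxels[i] * vx - voxels[j] * vx)))
    return Skeleton(
        voxels=voxels,
        edges=np.array(edges, dtype=np.int64).reshape(-1, 2),
        weights_um=np.array(weights),
        voxel_size_nm=tuple(voxel_size_nm),
    )


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def write_report(results: dict, path) -> None:
    """Write an analysis result dict as JSON (numpy types coerced)."""

    def coerce(obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        raise TypeError(f"not JSON serializable: {type(obj)}")

    with open(path, "w") as f:
        json.dump(results, f, indent=2, sort_keys=True, default=coerce)
        f.write("\n")
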