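"""HDF5 and TSV serialization for pipeline inputs and outputs.

HDF5 layout (one file may hold any subset):

    /head/sensor_positions, /head/sensor_orientations,
    /head/dipole_positions, /head/dipole_orientations,
    /head/neighbor_indices, /head/neighbor_indptr, /head/sphere_center
    /leadfield/matrix
    /recording/data          (attrs: fs, kind, seed)
    /inverse/filters         (attrs: algorithm, lambda2, snr_db)
    /atlas/dipole_roi, /atlas/roi_cluster, /atlas/roi_adjacency

Atlas label tables are also exchanged as TSV with columns
``dipole_id, roi_id, cluster_id``.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .datatypes import Atlas, HeadModel, InverseOperator, Leadfield, Recording


def save_head(f: h5py.File, head: HeadModel) -> None:
    g = f.require_group("head")
    for name in ("sensor_positions", "sensor_orientations", "dipole_positions", "dipole_orientations", "sphere_center"):
        g.create_dataset(name, data=getattr(head, name))
    csr = head.neighbor_graph.tocsr()
    g.create_dataset("neighbor_indices", data=csr.indices)
    g.create_dataset("neighbor_indptr", data=csr.indptr)


def load_head(f: h5py.File) -> HeadModel:
    g = f["head"]
    n = g["dipole_positions"].shape[0]
    indices = g["neighbor_indices"][()]
    indptr = g["neighbor_indptr"][()]
    graph = sp.csr_matrix((np.ones(indices.size), indices, indptr), shape=(n, n))
    return HeadModel(
        sensor_positions=g["sensor_positions"][()],
        sensor_orientations=g["sensor_orientations"][()],
        dipole_positions=g["dipole_positions"][()],
        dipole_orientations=g["dipole_orientations"][()],
        neighbor_graph=graph,
        sphere_center=g["sphere_center"][()],
    )


def save_leadfield(f: h5py.File, leadfield: Leadfield) -> None:
    f.require_group("leadfield").create_dataset("matrix", data=leadfield.matrix)


def load_leadfield(f: h5py.File) -> Leadfield:
    return Leadfield(f["leadfield/matrix"][()])


def save_recording(f: h5py.File, rec: Recording, name: str = "recording") -> None:
    g = f.require_group(name)
    d = g.create_dataset("data", data=rec.data)
    d.attrs["fs"] = rec.fs
    d.attrs["kind"] = rec.kind.value
    if rec.seed is not None:
        d.attrs["seed"] = rec.seed


def load_recording(f: h5py.File, name: str = "recording") -> Recording:
    d = f[f"{name}/data"]
    return Recording(
        data=d[()],
        fs=float(d.attrs["fs"]),
        kind=d.attrs["kind"],
        seed=int(d.attrs["seed"]) if "seed" in d.attrs else None,
    )


def save_inverse(f: h5py.File, op: InverseOperator) -> None:
    g = f.require_group("inverse")
    d = g.create_dataset("filters", data=op.filters)
    d.attrs["algorithm"] = op.algorithm.value
    d.attrs["lambda2"] = op.lambda2
    d.attrs["snr_db"] = op.snr_db


def load_inverse(f: h5py.File) -> InverseOperator:
    d = f["inverse/filters"]
    return InverseOperator(
        filters=d[()],
        algorithm=d.attrs["algorithm"],
        lambda2=float(d.attrs["lambda2"]),
        snr_db=float(d.attrs["snr_db"]),
    )


def save_atlas(f: h5py.File, atlas: Atlas) -> None:
    g = f.require_group("atlas")
    g.create_dataset("dipole_roi", data=atlas.dipole_roi)
    g.create_dataset("roi_cluster", data=atlas.roi_cluster)
    adjacency = np.array(sorted(atlas.roi_adjacency), dtype=int).reshape(-1, 2)
    g.create_dataset("roi_adjacency", data=adjacency)


def load_atlas(f: h5py.File) -> Atlas:
    g = f["atlas"]
    adjacency = {tuple(int(x) for x in row) for row in g["roi_adjacency"][()]}
    return Atlas(dipole_roi=g["dipole_roi"][()], roi_cluster=g["roi_cluster"][()], roi_adjacency=adjacency)


def atlas_to_tsv(atlas: Atlas, path: str | Path) -> None:
    """Label table: dipole_id, roi_id, cluster_id."""
    df = pd.DataFrame(
        {
            "dipole_id": np.arange(atlas.n_dipoles),
            "roi_id": atlas.dipole_roi,
            "cluster_id": atlas.roi_cluster[atlas.dipole_roi - 1],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def atlas_from_tsv(path: str | Path, roi_adjacency: set | None = None) -> Atlas:
    df = pd.read_csv(path, sep="\t")
    required = {"dipole_id", "roi_id", "cluster_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"atlas TSV missing columns: {sorted(missing)}")
    df = df.sort_values("dipole_id")
    dipole_roi = df["roi_id"].to_numpy()
    n_rois = int(dipole_roi.max())
    roi_cluster = np.empty(n_rois, dtype=int)
    for roi, cluster in zip(df["roi_id"], df["cluster_id"]):
        roi_cluster[roi - 1] = cluster
    return Atlas(dipole_roi=dipole_roi, roi_cluster=roi_cluster, roi_adjacency=roi_adjacency or set())
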