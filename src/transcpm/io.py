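"""Readers and writers for connectomes, phenotype tables and network maps.

Formats are deliberately plain:

* connectome set — a directory holding one whitespace-delimited square matrix
  file per subject and task (``<subject>__<task>.txt``) plus a
  ``manifest.json`` declaring subjects, tasks and node count; or a single
  packed ``.npz`` with a JSON sidecar.
* phenotype table — CSV with a header row: ``subject_id``, ``group``,
  ``motion_grand_mean``, one ``motion_<task>`` column per task, remaining
  columns are behavioral measures.
* network map — CSV with columns ``node`` (1-based) and ``network``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import CANONICAL_NETWORKS, NetworkMap, PhenotypeTable, TaskConnectomeSet
from .edges import restore_matrix, vectorize_edges

MOTION_PREFIX = "motion_"
GRAND_MEAN_COL = "motion_grand_mean"


# ---------------------------------------------------------------- connectomes

def write_connectomes(conn: TaskConnectomeSet, path: str | Path) -> None:
    """Write one matrix file per subject/task plus a manifest."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {
        "subject_ids": conn.subject_ids,
        "task_names": conn.task_names,
        "n_nodes": conn.n_nodes,
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=1))
    for si, sid in enumerate(conn.subject_ids):
        for ti, task in enumerate(conn.task_names):
            mat = restore_matrix(conn.edges[si, ti], conn.n_nodes)
            np.savetxt(path / f"{sid}__{task}.txt", mat, fmt="%.17g")


def read_connectomes(path: str | Path) -> TaskConnectomeSet:
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    subs, tasks, n_nodes = manifest["subject_ids"], manifest["task_names"], manifest["n_nodes"]
    edges = np.empty((len(subs), len(tasks), n_nodes * (n_nodes - 1) // 2))
    for si, sid in enumerate(subs):
        for ti, task in enumerate(tasks):
            f = path / f"{sid}__{task}.txt"
            try:
                mat = np.loadtxt(f)
            except ValueError as e:  # ragged rows etc.
                raise ValueError(f"{f}: cannot parse matrix ({e})") from e
            if mat.shape != (n_nodes, n_nodes):
                raise ValueError(f"{f}: expected {n_nodes}x{n_nodes}, got {mat.shape}")
            edges[si, ti] = vectorize_edges(mat)
    return TaskConnectomeSet(subject_ids=subs, task_names=tasks, n_nodes=n_nodes, edges=edges)


def write_connectomes_packed(conn: TaskConnectomeSet, path: str | Path) -> None:
    """Single packed array file (``.npz``) with a JSON metadata sidecar."""
    path = Path(path)
    np.savez_compressed(path, edges=conn.edges)
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps({
        "subject_ids": conn.subject_ids,
        "task_names": conn.task_names,
        "n_nodes": conn.n_nodes,
    }))


def read_connectomes_packed(path: str | Path) -> TaskConnectomeSet:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    meta = json.loads(path.with_suffix(".json").read_text())
    with np.load(path) as z:
        edges = z["edges"]
    return TaskConnectomeSet(edges=edges, **meta)


# ----------------------------------------------------------------- phenotypes

def write_phenotypes(table: PhenotypeTable, path: str | Path) -> None:
    df = pd.DataFrame({"subject_id": table.subject_ids})
    df["group"] = table.group.to_numpy()
    df[GRAND_MEAN_COL] = table.motion_grand_mean.to_numpy()
    for task in table.motion_per_task.columns:
        df[MOTION_PREFIX + str(task)] = table.motion_per_task[task].to_numpy()
    for m in table.measures.columns:
        df[str(m)] = table.measures[m].to_numpy()
    df.to_csv(path, index=False)


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    path = Path(path)
    df = pd.read_csv(path)
    required = {"subject_id", "group", GRAND_MEAN_COL}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    ids = df["subject_id"].astype(str)
    dup = ids[ids.duplicated()]
    if len(dup) > 0:
        line = int(dup.index[0]) + 2  # header + 1-based
        raise ValueError(f"{path}:{line}: duplicate subject ID {dup.iloc[0]!r}")
    motion_cols = [c for c in df.columns if c.startswith(MOTION_PREFIX) and c != GRAND_MEAN_COL]
    measure_cols = [
        c for c in df.columns
        if c not in required and c not in motion_cols
    ]
    df = df.set_index(ids.rename("subject_id"))
    motion = df[motion_cols].astype(float)
    motion.columns = [c[len(MOTION_PREFIX):] for c in motion_cols]
    return PhenotypeTable(
        subject_ids=list(ids),
        group=df["group"].astype(str),
        motion_grand_mean=df[GRAND_MEAN_COL].astype(float),
        motion_per_task=motion,
        measures=df[measure_cols].astype(float),
    )


# ---------------------------------------------------------------- network map

def write_network_map(netmap: NetworkMap, path: str | Path) -> None:
    pd.DataFrame({
        "node": np.arange(1, netmap.n_nodes + 1),  # 1-based in files/reports
        "network": netmap.labels,
    }).to_csv(path, index=False)


def read_network_map(path: str | Path, label_set: tuple[str, ...] = CANONICAL_NETWORKS) -> NetworkMap:
    path = Path(path)
    df = pd.read_csv(path)
    if not {"node", "network"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns 'node' and 'network'")
    nodes = df["node"].astype(int).to_numpy()
    n = nodes.max() if len(nodes) else 0
    expected = set(range(1, n + 1))
    got = set(nodes.tolist())
    if got != expected or len(nodes) != n:
        missing = sorted(expected - got)
        raise ValueError(f"{path}: node column must cover 1..{n} exactly once (missing {missing[:5]})")
    labels = np.empty(n, dtype=object)
    labels[nodes - 1] = df["network"].astype(str).to_numpy()
    unknown = sorted(set(labels) - set(label_set))
    if unknown:
        rows = df.index[df["network"].isin(unknown)]
        line = int(rows[0]) + 2
        raise ValueError(f"{path}:{line}: unknown network labels {unknown}")
    return NetworkMap(labels=labels, label_set=label_set)
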