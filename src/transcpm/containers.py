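"""Typed containers for multi-task connectomes, phenotypes and network maps."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .edges import edge_count

#: Canonical 10-network parcellation labels: medial frontal, frontoparietal,
#: default mode, motor, visual A, visual B, visual association, salience,
#: subcortical, cerebellum.
CANONICAL_NETWORKS = ("MF", "FP", "DMN", "Mot", "VI", "VII", "VAs", "SAL", "SC", "CBL")


@dataclass
class TaskConnectomeSet:
    """Fisher-z edge vectors for every subject and task.

    ``edges`` is indexed (subject, task, edge); the edge axis holds the strict
    upper triangle of the symmetric node-by-node matrix in row-major order
    (see :mod:`transcpm.edges`).
    """

    subject_ids: list[str]
    task_names: list[str]
    n_nodes: int
    edges: np.ndarray

    def __post_init__(self) -> None:
        self.subject_ids = [str(s) for s in self.subject_ids]
        self.task_names = [str(t) for t in self.task_names]
        self.edges = np.asarray(self.edges, dtype=float)
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise ValueError("duplicate subject IDs")
        expected = (len(self.subject_ids), len(self.task_names), edge_count(self.n_nodes))
        if self.edges.shape != expected:
            raise ValueError(
                f"edges shape {self.edges.shape} != (subjects, tasks, edges) {expected}"
            )
        if not np.all(np.isfinite(self.edges)):
            raise ValueError("edges contain non-finite values")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_tasks(self) -> int:
        return len(self.task_names)

    @property
    def n_edges(self) -> int:
        return self.edges.shape[2]

    def subject_index(self, ids: list[str]) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.subject_ids)}
        missing = [s for s in ids if s not in pos]
        if missing:
            raise KeyError(f"unknown subject IDs: {missing[:5]}")
        return np.array([pos[s] for s in ids], dtype=int)

    def select_subjects(self, ids: list[str]) -> "TaskConnectomeSet":
        idx = self.subject_index(ids)
        return TaskConnectomeSet(
            subject_ids=[self.subject_ids[i] for i in idx],
            task_names=list(self.task_names),
            n_nodes=self.n_nodes,
            edges=self.edges[idx],
        )


@dataclass
class PhenotypeTable:
    """Per-subject diagnostic group, motion summaries and behavioral measures.

    ``motion_per_task`` columns are task names; ``measures`` columns are
    behavioral measure names.  Motion is mean frame-to-frame displacement in
    millimeters.  Missing motion is allowed (such subjects are excluded by
    QC); missing measures are allowed only if dropped before modeling.
    """

    subject_ids: list[str]
    group: pd.Series
    motion_grand_mean: pd.Series
    motion_per_task: pd.DataFrame
    measures: pd.DataFrame

    def __post_init__(self) -> None:
        self.subject_ids = [str(s) for s in self.subject_ids]
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise ValueError("duplicate subject IDs")
        idx = pd.Index(self.subject_ids, name="subject_id")
        for name in ("group", "motion_grand_mean"):
            s = getattr(self, name)
            if not isinstance(s, pd.Series):
                s = pd.Series(np.asarray(s), index=idx, name=name)
            else:
                s = s.reindex(idx)
            setattr(self, name, s)
        for name in ("motion_per_task", "measures"):
            df = getattr(self, name)
            if not isinstance(df, pd.DataFrame):
                raise TypeError(f"{name} must be a DataFrame")
            setattr(self, name, df.reindex(idx))
        if self.group.isna().any():
            bad = list(self.group.index[self.group.isna()])[:5]
            raise ValueError(f"subjects without group label: {bad}")
        for name in ("motion_grand_mean", "motion_per_task"):
            vals = getattr(self, name).to_numpy(dtype=float)
            if np.nanmin(vals, initial=np.inf) < 0:
                raise ValueError(f"{name} contains negative motion values")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def groups(self) -> np.ndarray:
        return self.group.to_numpy()

    def select_subjects(self, ids: list[str]) -> "PhenotypeTable":
        missing = set(ids) - set(self.subject_ids)
        if missing:
            raise KeyError(f"unknown subject IDs: {sorted(missing)[:5]}")
        return PhenotypeTable(
            subject_ids=list(ids),
            group=self.group.loc[list(ids)],
            motion_grand_mean=self.motion_grand_mean.loc[list(ids)],
            motion_per_task=self.motion_per_task.loc[list(ids)],
            measures=self.measures.loc[list(ids)],
        )


@dataclass
class NetworkMap:
    """Assignment of every node to exactly one canonical functional network."""

    labels: np.ndarray  # length n_nodes, dtype str
    label_set: tuple[str, ...] = field(default=CANONICAL_NETWORKS)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        unknown = sorted(set(self.labels) - set(self.label_set))
        if unknown:
            raise ValueError(f"unknown network labels: {unknown}")

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @property
    def networks(self) -> list[str]:
        """Networks present, in canonical label-set order."""
        present = set(self.labels)
        return [n for n in self.label_set if n in present]

    def label_indices(self) -> np.ndarray:
        """Per-node integer index into :attr:`networks`."""
        order = {n: i for i, n in enumerate(self.networks)}
        return np.array([order[l] for l in self.labels], dtype=int)

    def members(self, network: str) -> np.ndarray:
        return np.flatnonzero(self.labels == network)
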