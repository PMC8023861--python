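"""Functional connectivity from node time series.

A task connectome is the matrix of pairwise Pearson correlations between
regional (node) activity time courses, Fisher z-transformed
(``z = atanh(r)``) to stabilize variance.  ``general_fc`` builds a single
connectome from several task runs by z-scoring each run per node and
concatenating along frames before correlating — the general functional
connectivity approach for combining disparate task data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

#: correlations are clipped to +/-(1 - R_CLIP) before atanh to keep z finite
R_CLIP = 1e-7


@dataclass
class NodeTimeseries:
    """Frames x nodes activity matrix for one task run."""

    data: np.ndarray
    task: str = ""
    tr: float | None = None  # repetition time, seconds

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("time series must be 2-D (frames x nodes)")
        if self.data.shape[0] < 2:
            raise ValueError("need at least 2 frames")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.data.shape[1]


def compute_fc(ts: NodeTimeseries | np.ndarray, return_flagged: bool = False):
    """Fisher-z connectivity matrix from one run of node time series.

    Pearson r for every node pair, clipped to ``+/-(1 - 1e-7)``, then
    ``z = atanh(r)``; diagonal set to 0.  Zero-variance nodes get zero on
    all their edges and are reported in the flagged list (also emitted as a
    warning).

    Returns the symmetric n x n matrix, plus the flagged node list when
    ``return_flagged`` is true.
    """
    if not isinstance(ts, NodeTimeseries):
        ts = NodeTimeseries(np.asarray(ts))
    if ts.n_frames < 3:
        raise ValueError("need at least 3 frames for a correlation estimate")
    x = ts.data
    sd = x.std(axis=0)
    flagged = np.flatnonzero(sd == 0).tolist()
    if flagged:
        warnings.warn(f"zero-variance nodes {flagged}: their edges set to 0", stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x, rowvar=False)
    r = np.nan_to_num(r, nan=0.0)
    r = np.clip(r, -(1 - R_CLIP), 1 - R_CLIP)
    z = np.arctanh(r)
    np.fill_diagonal(z, 0.0)
    if flagged:
        z[flagged, :] = 0.0
        z[:, flagged] = 0.0
    z = (z + z.T) / 2  # enforce exact symmetry against fp round-off
    return (z, flagged) if return_flagged else z


def general_fc(ts_list: list[NodeTimeseries | np.ndarray], return_flagged: bool = False):
    """Single Fisher-z connectome from several runs via frame concatenation.

    Each run is z-scored per node (so runs with different scales or offsets
    contribute equally), the runs are concatenated along frames, and
    :func:`compute_fc` is applied to the result.
    """
    if not ts_list:
        raise ValueError("need at least one time series")
    arrays = []
    n_nodes = None
    for ts in ts_list:
        if not isinstance(ts, NodeTimeseries):
            ts = NodeTimeseries(np.asarray(ts))
        if n_nodes is None:
            n_nodes = ts.n_nodes
        elif ts.n_nodes != n_nodes:
            raise ValueError(f"node-count mismatch: {ts.n_nodes} != {n_nodes}")
        x = ts.data
        sd = x.std(axis=0)
        sd_safe = np.where(sd == 0, 1.0, sd)
        arrays.append((x - x.mean(axis=0)) / sd_safe)
    cat = np.concatenate(arrays, axis=0)
    return compute_fc(NodeTimeseries(cat, task="general"), return_flagged=return_flagged)
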