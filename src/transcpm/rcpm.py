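"""Ridge-regularized connectome-based predictive modeling (rCPM).

The model has two stages, both fit on training subjects only:

1. **Edge selection.**  For every task and edge, the Pearson correlation
   between edge strength and the phenotype across training subjects is
   tested at a two-sided significance threshold ``alpha`` (default 0.01).
   Positively and negatively correlated edges are pooled into one mask.
   When a per-subject motion summary is supplied, partial correlation is
   used instead: edge and phenotype are each residualized on motion and the
   residuals correlated, with ``n - 3`` degrees of freedom — so edges that
   merely track head motion are not selected.

2. **Ridge fit.**  Selected edges from *all* tasks enter a single ridge
   regression (task connectomes are strongly dependent; one joint
   penalized fit handles those dependencies rather than per-task models).
   Features are z-scored with training statistics, the intercept is the
   (unpenalized) training mean, and the penalty is chosen by inner k-fold
   cross-validation over a log-spaced grid.  The whole penalty path is
   evaluated from a single SVD per inner fold.

Prediction applies the stored training scalings and weights to new
subjects; the test phenotype is never touched.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .containers import TaskConnectomeSet

DEFAULT_LAMBDA_GRID = np.logspace(-3, 3, 13)


def _edges_array(edges) -> tuple[np.ndarray, list[str]]:
    if isinstance(edges, TaskConnectomeSet):
        return edges.edges, list(edges.task_names)
    arr = np.asarray(edges, dtype=float)
    if arr.ndim != 3:
        raise ValueError("edges must be (subjects, tasks, edges)")
    return arr, [f"task{t}" for t in range(arr.shape[1])]


def _residualize(x: np.ndarray, covariate: np.ndarray) -> np.ndarray:
    """Residuals of columns of ``x`` after simple regression on covariate."""
    c = covariate - covariate.mean()
    var = c @ c
    if var == 0:
        return x - x.mean(axis=0)
    xc = x - x.mean(axis=0)
    beta = (c @ xc) / var
    return xc - np.outer(c, beta)


def _edge_corr(
    arr: np.ndarray, phenotype: np.ndarray, motion: np.ndarray | None
) -> tuple[np.ndarray, np.ndarray, int]:
    """(Partial) correlation of every task/edge with the phenotype.

    Returns ``(r, valid, df)`` with r shaped (n_tasks, n_edges); ``valid``
    is False for zero-variance edges (r forced to 0).
    """
    n, n_tasks, n_edges = arr.shape
    y = np.asarray(phenotype, dtype=float)
    if y.shape != (n,):
        raise ValueError(f"phenotype length {y.shape} != n subjects {n}")
    if not np.all(np.isfinite(y)):
        raise ValueError("phenotype contains non-finite values")
    x = arr.reshape(n, n_tasks * n_edges)
    if motion is not None:
        motion = np.asarray(motion, dtype=float)
        if motion.shape != (n,):
            raise ValueError("motion length mismatch")
        x = _residualize(x, motion)
        yc = _residualize(y[:, None], motion)[:, 0]
        df = n - 3
    else:
        x = x - x.mean(axis=0)
        yc = y - y.mean()
        df = n - 2
    if df < 1:
        raise ValueError("too few subjects for edge selection")
    sx = np.sqrt(np.einsum("ij,ij->j", x, x))
    sy = np.sqrt(yc @ yc)
    denom = sx * sy
    valid = denom > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(valid, (yc @ x) / np.where(valid, denom, 1.0), 0.0)
    r = np.clip(r, -1.0, 1.0)
    return r.reshape(n_tasks, n_edges), valid.reshape(n_tasks, n_edges), df


def edge_phenotype_correlation(
    edges, phenotype: np.ndarray, motion: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-task, per-edge (partial) correlation with the phenotype and p-value.

    Returns ``(r, p)`` each shaped (n_tasks, n_edges).  Two-sided p from the
    t transform ``t = r * sqrt(df / (1 - r^2))`` with ``df = n - 2``
    (``n - 3`` under motion partial correlation).  Zero-variance edges get
    r = 0, p = 1.
    """
    arr, _ = _edges_array(edges)
    r, valid, df = _edge_corr(arr, phenotype, motion)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt(df / np.maximum(1 - r**2, 1e-300))
    p = 2 * stats.t.sf(np.abs(t), df)
    p = np.where(valid, p, 1.0)
    return r, p


def select_edges(
    train_edges,
    phenotype: np.ndarray,
    motion: np.ndarray | None = None,
    alpha: float = 0.01,
    return_stats: bool = False,
):
    """Boolean (n_tasks, n_edges) mask of edges correlated with the phenotype.

    Both signs are pooled; selection is ``p < alpha`` two-sided.  Requires at
    least 10 training subjects.
    """
    arr, _ = _edges_array(train_edges)
    if arr.shape[0] < 10:
        raise ValueError(f"need >= 10 training subjects, got {arr.shape[0]}")
    if return_stats:
        r, p = edge_phenotype_correlation(arr, phenotype, motion)
        return p < alpha, r, p
    # p < alpha  <=>  |t| > t_crit  <=>  |r| > r_crit; avoids a survival-
    # function evaluation per edge
    r, valid, df = _edge_corr(arr, phenotype, motion)
    t_crit = stats.t.isf(alpha / 2, df)
    r_crit = t_crit / np.sqrt(df + t_crit**2)
    return (np.abs(r) > r_crit) & valid


@dataclass
class PredictiveModel:
    """Fitted rCPM: per-task selection mask, ridge weights, train scalings.

    Selected features are ordered task-major (all selected edges of task 0,
    then task 1, ...); ``feat_task``/``feat_edge`` give each feature's task
    and edge index.  ``feature_stds`` are the training standard deviations
    std(E_k(:,m)) used both for z-scoring and for contribution scores.
    """

    task_names: list[str]
    n_edges: int
    mask: np.ndarray               # (n_tasks, n_edges) bool
    feat_task: np.ndarray          # (n_features,) int
    feat_edge: np.ndarray          # (n_features,) int
    weights: np.ndarray            # (n_features,) ridge coefficients on z-scored features
    feature_means: np.ndarray
    feature_stds: np.ndarray
    lam: float
    intercept: float
    alpha: float
    n_train: int
    is_null: bool = False          # no edges selected; predicts the train mean

    @property
    def n_features(self) -> int:
        return len(self.weights)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "task_names": self.task_names,
            "n_edges": self.n_edges,
            "mask": self.mask.astype(int).tolist(),
            "feat_task": self.feat_task.tolist(),
            "feat_edge": self.feat_edge.tolist(),
            "weights": self.weights.tolist(),
            "feature_means": self.feature_means.tolist(),
            "feature_stds": self.feature_stds.tolist(),
            "lam": self.lam,
            "intercept": self.intercept,
            "alpha": self.alpha,
            "n_train": self.n_train,
            "is_null": self.is_null,
        }))

    @classmethod
    def from_json(cls, path: str | Path) -> "PredictiveModel":
        d = json.loads(Path(path).read_text())
        return cls(
            task_names=d["task_names"],
            n_edges=d["n_edges"],
            mask=np.array(d["mask"], dtype=bool),
            feat_task=np.array(d["feat_task"], dtype=int),
            feat_edge=np.array(d["feat_edge"], dtype=int),
            weights=np.array(d["weights"]),
            feature_means=np.array(d["feature_means"]),
            feature_stds=np.array(d["feature_stds"]),
            lam=d["lam"],
            intercept=d["intercept"],
            alpha=d["alpha"],
            n_train=d["n_train"],
            is_null=d["is_null"],
        )


def _ridge_path_beta(x: np.ndarray, y: np.ndarray, lambdas: np.ndarray) -> np.ndarray:
    """Ridge coefficients for every penalty from one SVD; (n_lambda, p)."""
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    uty = u.T @ y
    shrink = s[None, :] / (s[None, :] ** 2 + lambdas[:, None])  # (L, r)
    return (shrink * uty[None, :]) @ vt


def fit_rcpm(
    train_edges,
    masks: np.ndarray,
    phenotype: np.ndarray,
    lambda_grid: np.ndarray | None = None,
    inner_folds: int = 5,
    seed: int = 0,
) -> PredictiveModel:
    """Single ridge regression over the pooled selected edges of all tasks.

    The penalty minimizing inner-CV mean squared error is kept (smallest
    penalty on ties); with fewer than ``2 * inner_folds`` training subjects
    or a single-point grid, the first grid value is used directly.
    """
    arr, task_names = _edges_array(train_edges)
    n, n_tasks, n_edges = arr.shape
    y = np.asarray(phenotype, dtype=float)
    masks = np.asarray(masks, dtype=bool)
    if masks.shape != (n_tasks, n_edges):
        raise ValueError(f"mask shape {masks.shape} != (tasks, edges) {(n_tasks, n_edges)}")
    if lambda_grid is None:
        lambda_grid = DEFAULT_LAMBDA_GRID
    lambda_grid = np.atleast_1d(np.asarray(lambda_grid, dtype=float))

    feat_task, feat_edge = np.nonzero(masks)
    intercept = float(y.mean())
    if len(feat_task) == 0:
        return PredictiveModel(
            task_names=task_names, n_edges=n_edges, mask=masks,
            feat_task=feat_task, feat_edge=feat_edge,
            weights=np.empty(0), feature_means=np.empty(0), feature_stds=np.empty(0),
            lam=float(lambda_grid[0]), intercept=intercept, alpha=np.nan,
            n_train=n, is_null=True,
        )
    x = arr[:, feat_task, feat_edge]  # (n, F) task-major feature order
    means = x.mean(axis=0)
    stds = x.std(axis=0, ddof=1)
    if np.any(stds == 0):
        raise ValueError("selected feature with zero training variance")
    xz = (x - means) / stds
    yc = y - intercept

    if len(lambda_grid) > 1 and n >= 2 * inner_folds:
        rng = np.random.default_rng(seed)
        order = rng.permutation(n)
        folds = np.array_split(order, inner_folds)
        sse = np.zeros(len(lambda_grid))
        for fi, test_idx in enumerate(folds):
            tr = np.concatenate([f for fj, f in enumerate(folds) if fj != fi])
            betas = _ridge_path_beta(xz[tr], yc[tr], lambda_grid)  # (L, F)
            pred = betas @ xz[test_idx].T                          # (L, n_test)
            sse += ((pred - yc[test_idx][None, :]) ** 2).sum(axis=1)
        lam = float(lambda_grid[int(np.argmin(sse))])
    else:
        lam = float(lambda_grid[0])

    beta = _ridge_path_beta(xz, yc, np.array([lam]))[0]
    return PredictiveModel(
        task_names=task_names, n_edges=n_edges, mask=masks,
        feat_task=feat_task, feat_edge=feat_edge,
        weights=beta, feature_means=means, feature_stds=stds,
        lam=lam, intercept=intercept, alpha=np.nan, n_train=n,
    )


def predict_rcpm(model: PredictiveModel, test_edges) -> np.ndarray:
    """Predicted phenotype for new subjects from stored scalings and weights."""
    arr, task_names = _edges_array(test_edges)
    if isinstance(test_edges, TaskConnectomeSet) and task_names != model.task_names:
        raise ValueError(f"task mismatch: {task_names} != {model.task_names}")
    if arr.shape[1] != len(model.task_names) or arr.shape[2] != model.n_edges:
        raise ValueError(
            f"test edges shape {arr.shape[1:]} != (tasks, edges) "
            f"{(len(model.task_names), model.n_edges)}"
        )
    if model.is_null:
        return np.full(arr.shape[0], model.intercept)
    x = arr[:, model.feat_task, model.feat_edge]
    xz = (x - model.feature_means) / model.feature_stds
    return xz @ model.weights + model.intercept
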