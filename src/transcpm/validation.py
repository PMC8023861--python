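"""Cross-validation harnesses, performance metrics and permutation nulls.

Three validation schemes are provided, each answering a different question:

* **10-fold cross-validation** (:func:`kfold_cv`) — does the model predict
  held-out subjects at all?  The sample is split into k near-equal folds
  regardless of diagnostic group; per fold, the latent construct, edge
  selection and ridge fit are all restricted to the training subjects, and
  out-of-fold predictions are pooled into one cross-validated R² (q²) per
  division.  The median over many random divisions is the headline
  statistic.
* **Leave-one-group-out** (:func:`leave_group_out`) — does a model trained
  without a diagnostic category generalize to it?  One exhaustive split per
  group; performance is the Pearson r between actual and predicted scores
  in the left-out group.
* **External validation** (:func:`external_validate`) — does a model
  transfer between independently collected datasets?  Each dataset gets its
  own latent construct over all of its subjects; the model trains on one
  dataset in full and is scored on the other.

Significance comes from permutation: shuffling the behavior-connectome
correspondence for the k-fold statistic, and shuffling group membership
(sizes preserved) for the leave-group-out comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import TaskConnectomeSet
from .edges import edge_node_indices, nodes_from_edge_count
from .latent import apply_latent, fit_latent
from .rcpm import _edges_array, fit_rcpm, predict_rcpm, select_edges


# --------------------------------------------------------------------- metric

def r2_cv(actual, predicted) -> tuple[float, float]:
    """Cross-validated R² (q²) and its square root.

    ``q² = 1 - SS_res / SS_tot`` with the total sum of squares taken around
    the mean of ``actual``.  q² can be negative out of sample (the model
    does worse than predicting the mean); the root is then undefined and
    returned as NaN rather than clamped.
    """
    y = np.asarray(actual, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1:
        raise ValueError("actual and predicted must be equal-length 1-D arrays")
    if len(y) < 3:
        raise ValueError("need at least 3 observations")
    ss_tot = ((y - y.mean()) ** 2).sum()
    if ss_tot == 0:
        raise ValueError("actual values are constant; q2 undefined")
    q2 = 1 - ((y - yhat) ** 2).sum() / ss_tot
    root = float(np.sqrt(q2)) if q2 >= 0 else float("nan")
    return float(q2), root


# ----------------------------------------------------------------- fold logic

def _measures_frame(measures) -> pd.DataFrame:
    if isinstance(measures, pd.DataFrame):
        return measures
    x = np.asarray(measures, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    return pd.DataFrame(x, columns=[f"m{i}" for i in range(x.shape[1])])


def _fit_and_predict_fold(
    edges_arr: np.ndarray,
    measures: np.ndarray,
    motion: np.ndarray | None,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    alpha: float,
    lambda_grid,
    inner_folds: int,
    inner_seed: int,
):
    """Fit latent + selection + ridge on train rows, predict test rows.

    Returns (actual test scores, predicted, per-task mask, null-fold flag).
    The test rows never enter any fitting statistic.
    """
    assert len(np.intersect1d(train_idx, test_idx)) == 0
    lat = fit_latent(measures[train_idx])
    y_train = apply_latent(lat, measures[train_idx])
    y_test = apply_latent(lat, measures[test_idx])
    mot = motion[train_idx] if motion is not None else None
    mask = select_edges(edges_arr[train_idx], y_train, motion=mot, alpha=alpha)
    model = fit_rcpm(
        edges_arr[train_idx], mask, y_train,
        lambda_grid=lambda_grid, inner_folds=inner_folds, seed=inner_seed,
    )
    pred = predict_rcpm(model, edges_arr[test_idx])
    return y_test, pred, mask, model.is_null


@dataclass
class CVResult:
    """Pooled predictions and q² per random k-fold division."""

    q2: np.ndarray                 # (iterations,)
    root: np.ndarray               # sqrt(q2), NaN where q2 < 0
    actual: np.ndarray             # (iterations, n) pooled out-of-fold actual scores
    predicted: np.ndarray          # (iterations, n)
    mask_history: np.ndarray       # (iterations, n_edges) union over tasks and folds
    fold_assignments: np.ndarray   # (iterations, n) fold id per subject
    null_fold_count: int           # folds where no edge was selected
    seed: int = 0

    @property
    def median_q2(self) -> float:
        return float(np.median(self.q2))

    @property
    def median_root(self) -> float:
        m = self.median_q2
        return float(np.sqrt(m)) if m >= 0 else float("nan")


def kfold_cv(
    edges,
    measures,
    groups=None,
    motion: np.ndarray | None = None,
    k: int = 10,
    iterations: int = 1000,
    seed: int = 0,
    alpha: float = 0.01,
    lambda_grid=None,
    inner_folds: int = 5,
) -> CVResult:
    """Repeated random k-fold cross-validation of the full pipeline.

    Folds are drawn regardless of diagnostic group (``groups`` is accepted
    for API parity and ignored).  Within every training fold the latent
    construct is re-fit, edges re-selected and the ridge re-trained; the
    excluded fold is predicted with those training parameters only.  One
    pooled q² per division; fold sizes differ by at most one.
    """
    arr, _ = _edges_array(edges)
    meas = _measures_frame(measures).to_numpy(dtype=float)
    n = arr.shape[0]
    if len(meas) != n:
        raise ValueError("measures rows != subjects")
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    if n < 2 * k:
        raise ValueError(f"need n >= 2k (n={n}, k={k})")
    rng = np.random.default_rng(seed)
    q2s = np.empty(iterations)
    actual = np.empty((iterations, n))
    predicted = np.empty((iterations, n))
    mask_hist = np.zeros((iterations, arr.shape[2]), dtype=bool)
    assignments = np.empty((iterations, n), dtype=int)
    null_folds = 0
    for it in range(iterations):
        order = rng.permutation(n)
        folds = np.array_split(order, k)
        ys, yhats, pos = [], [], []
        for fi, test_idx in enumerate(folds):
            train_idx = np.concatenate([f for fj, f in enumerate(folds) if fj != fi])
            inner_seed = int(rng.integers(2**31 - 1))
            y_test, pred, mask, is_null = _fit_and_predict_fold(
                arr, meas, motion, train_idx, test_idx,
                alpha, lambda_grid, inner_folds, inner_seed,
            )
            null_folds += is_null
            ys.append(y_test)
            yhats.append(pred)
            pos.append(test_idx)
            mask_hist[it] |= mask.any(axis=0)
            assignments[it, test_idx] = fi
        pos = np.concatenate(pos)
        y_pool = np.empty(n)
        yh_pool = np.empty(n)
        y_pool[pos] = np.concatenate(ys)
        yh_pool[pos] = np.concatenate(yhats)
        q2s[it], _ = r2_cv(y_pool, yh_pool)
        actual[it] = y_pool
        predicted[it] = yh_pool
    root = np.where(q2s >= 0, np.sqrt(np.abs(q2s)), np.nan)
    return CVResult(
        q2=q2s, root=root, actual=actual, predicted=predicted,
        mask_history=mask_hist, fold_assignments=assignments,
        null_fold_count=null_folds, seed=seed,
    )


# ----------------------------------------------------------------- permutation

@dataclass
class PermutationResult:
    observed: float
    null: np.ndarray
    p_value: float
    scheme: str

    @property
    def n_perm(self) -> int:
        return len(self.null)


def permutation_null_behavior(
    edges,
    measures,
    motion: np.ndarray | None = None,
    n_perm: int = 1000,
    iterations: int = 1,
    k: int = 10,
    seed: int = 0,
    alpha: float = 0.01,
    lambda_grid=None,
    observed: CVResult | None = None,
) -> PermutationResult:
    """Permutation test of k-fold prediction performance.

    The behavior-connectome correspondence is shuffled (measure rows are
    permuted; connectomes and motion stay together) and the whole pipeline
    re-run per permutation.  The statistic compared is the per-run median
    q² — a strictly monotone transform of the reported √q² wherever the
    root is defined, and totally ordered even when it is not.  One-tailed
    ``p = (#{null > observed} + 1) / (n_perm + 1)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    meas = _measures_frame(measures).to_numpy(dtype=float)
    if observed is None:
        observed = kfold_cv(
            edges, meas, motion=motion, k=k, iterations=iterations,
            seed=seed, alpha=alpha, lambda_grid=lambda_grid,
        )
    obs_stat = observed.median_q2
    rng = np.random.default_rng(seed + 1)
    null = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(len(meas))
        shuffled = meas[perm]
        res = kfold_cv(
            edges, shuffled, motion=motion, k=k, iterations=iterations,
            seed=int(rng.integers(2**31 - 1)), alpha=alpha, lambda_grid=lambda_grid,
        )
        null[b] = res.median_q2
    p = (np.sum(null > obs_stat) + 1) / (n_perm + 1)
    return PermutationResult(observed=obs_stat, null=null, p_value=float(p),
                             scheme="behavior-shuffle")


# ------------------------------------------------------------- leave-group-out

@dataclass
class LOGOResult:
    group_r: dict                   # group -> Pearson r in the left-out group
    group_n: dict
    actual: dict                    # group -> actual latent scores (test fold)
    predicted: dict


def leave_group_out(
    edges,
    measures,
    groups,
    motion: np.ndarray | None = None,
    alpha: float = 0.01,
    lambda_grid=None,
    inner_seed: int = 0,
) -> LOGOResult:
    """One exhaustive train/test split per diagnostic group (no iteration)."""
    arr, _ = _edges_array(edges)
    meas = _measures_frame(measures).to_numpy(dtype=float)
    groups = np.asarray(groups)
    labels = list(pd.unique(groups))
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    counts = {g: int(np.sum(groups == g)) for g in labels}
    small = [g for g, c in counts.items() if c < 3]
    if small:
        raise ValueError(f"groups with fewer than 3 subjects: {small}")
    out_r, out_n, out_y, out_yh = {}, {}, {}, {}
    for g in labels:
        test_idx = np.flatnonzero(groups == g)
        train_idx = np.flatnonzero(groups != g)
        y_test, pred, _, _ = _fit_and_predict_fold(
            arr, meas, motion, train_idx, test_idx,
            alpha, lambda_grid, 5, inner_seed,
        )
        r = float(stats.pearsonr(y_test, pred).statistic)
        out_r[g], out_n[g] = r, len(test_idx)
        out_y[g], out_yh[g] = y_test, pred
    return LOGOResult(group_r=out_r, group_n=out_n, actual=out_y, predicted=out_yh)


@dataclass
class GroupPermutationResult:
    observed: dict                  # group -> observed leave-group-out r
    null: dict                      # group -> (n_perm,) null r
    band: dict                      # group -> (low percentile, high percentile)
    p_two_sided: dict               # empirical two-sided p per group
    fdr_significant: dict           # BH-FDR at fdr_alpha
    classification: dict            # contributes / detracts / uninformative (FDR-gated)
    band_classification: dict       # same, band only (no FDR gate)


def group_permutation_test(
    edges,
    measures,
    groups,
    motion: np.ndarray | None = None,
    n_perm: int = 200,
    seed: int = 0,
    alpha: float = 0.01,
    lambda_grid=None,
    percentiles: tuple[float, float] = (2.5, 97.5),
    fdr_alpha: float = 0.001,
    observed: LOGOResult | None = None,
) -> GroupPermutationResult:
    """Does diagnostic category itself carry predictive information?

    Group membership is randomly permuted (group sizes preserved; the
    behavior-connectome pairing is left intact) and leave-group-out
    prediction re-run per permutation.  Observed performance above the
    97.5th / below the 2.5th percentile of a group's null suggests that the
    true diagnostic label detracts from / contributes to prediction; inside
    the band the label is uninformative.  Empirical two-sided p-values are
    corrected across groups by Benjamini-Hochberg FDR, and the final
    classification requires both the band excursion and FDR significance.
    """
    if n_perm < 40:
        warnings.warn(f"n_perm={n_perm} < 40: percentile band unstable", stacklevel=2)
    groups = np.asarray(groups)
    if observed is None:
        observed = leave_group_out(edges, measures, groups, motion,
                                   alpha=alpha, lambda_grid=lambda_grid)
    labels = list(observed.group_r)
    rng = np.random.default_rng(seed)
    null = {g: np.empty(n_perm) for g in labels}
    for b in range(n_perm):
        permuted = groups[rng.permutation(len(groups))]
        res = leave_group_out(edges, measures, permuted, motion,
                              alpha=alpha, lambda_grid=lambda_grid)
        for g in labels:
            null[g][b] = res.group_r[g]
    lo, hi = percentiles
    band = {g: (float(np.percentile(null[g], lo)), float(np.percentile(null[g], hi)))
            for g in labels}
    p_two = {}
    for g in labels:
        obs = observed.group_r[g]
        p_hi = (np.sum(null[g] >= obs) + 1) / (n_perm + 1)
        p_lo = (np.sum(null[g] <= obs) + 1) / (n_perm + 1)
        p_two[g] = float(min(1.0, 2 * min(p_hi, p_lo)))
    reject = multipletests([p_two[g] for g in labels], alpha=fdr_alpha,
                           method="fdr_bh")[0]
    fdr_sig = {g: bool(r) for g, r in zip(labels, reject)}

    def classify(g, gate: bool) -> str:
        obs = observed.group_r[g]
        if obs > band[g][1] and (not gate or fdr_sig[g]):
            return "detracts"
        if obs < band[g][0] and (not gate or fdr_sig[g]):
            return "contributes"
        return "uninformative"

    return GroupPermutationResult(
        observed=dict(observed.group_r),
        null=null,
        band=band,
        p_two_sided=p_two,
        fdr_significant=fdr_sig,
        classification={g: classify(g, True) for g in labels},
        band_classification={g: classify(g, False) for g in labels},
    )


# ------------------------------------------------------ selection consistency

@dataclass
class ConsistencyResult:
    consistent_mask: np.ndarray     # (n_edges,) bool
    node_degree: np.ndarray         # (n_nodes,)
    selection_fraction: np.ndarray  # (n_edges,)

    @property
    def n_consistent_edges(self) -> int:
        return int(self.consistent_mask.sum())


def consistency_degree(
    mask_history: np.ndarray,
    n_nodes: int | None = None,
    threshold: float = 0.95,
) -> ConsistencyResult:
    """Per-node degree of edges selected in >= ``threshold`` of iterations.

    ``mask_history`` is (iterations, n_edges) — or (iterations, tasks,
    n_edges), in which case selection by *any* task counts.  An edge is
    consistent when its selection fraction is at least ``threshold``; a
    node's degree is the number of consistent edges incident to it, so
    degrees sum to twice the consistent-edge count.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    hist = np.asarray(mask_history, dtype=bool)
    if hist.ndim == 3:
        hist = hist.any(axis=1)
    if hist.ndim != 2 or hist.shape[0] < 2:
        raise ValueError("need mask records from at least 2 iterations")
    frac = hist.mean(axis=0)
    consistent = frac >= threshold
    if n_nodes is None:
        n_nodes = nodes_from_edge_count(hist.shape[1])
    iu, ju = edge_node_indices(n_nodes)
    degree = (
        np.bincount(iu[consistent], minlength=n_nodes)
        + np.bincount(ju[consistent], minlength=n_nodes)
    )
    return ConsistencyResult(consistent_mask=consistent, node_degree=degree,
                             selection_fraction=frac)


# ------------------------------------------------------------------- external

@dataclass
class ExternalResult:
    r: float
    p_value: float
    actual: np.ndarray
    predicted: np.ndarray
    n_test: int


def _as_single_task(edges) -> np.ndarray:
    if isinstance(edges, TaskConnectomeSet):
        arr = edges.edges
    else:
        arr = np.asarray(edges, dtype=float)
    if arr.ndim == 2:
        arr = arr[:, None, :]
    if arr.ndim != 3:
        raise ValueError("expected (subjects, edges) or (subjects, tasks, edges)")
    return arr


def external_validate(
    train: tuple,
    test: tuple,
    motion_train: np.ndarray | None = None,
    alpha: float = 0.01,
    lambda_grid=None,
    inner_seed: int = 0,
) -> ExternalResult:
    """Train on one dataset in full, predict the other.

    ``train`` and ``test`` are ``(edges, measures)`` pairs; edges are the
    per-subject general-functional-connectivity vectors (one combined
    connectome per subject, built with :func:`transcpm.connectome.general_fc`
    when starting from time series).  A "general memory" construct is fit by
    PCA over *all* subjects of each dataset independently — the two datasets
    need not share instruments; they must share the node atlas.
    """
    tr_edges = _as_single_task(train[0])
    te_edges = _as_single_task(test[0])
    if tr_edges.shape[2] != te_edges.shape[2]:
        raise ValueError(
            f"edge-dimension mismatch between datasets: {tr_edges.shape[2]} "
            f"!= {te_edges.shape[2]} (different node atlases?)"
        )
    lat_tr = fit_latent(_measures_frame(train[1]))
    lat_te = fit_latent(_measures_frame(test[1]))
    y_train = apply_latent(lat_tr, _measures_frame(train[1]))
    y_test = apply_latent(lat_te, _measures_frame(test[1]))
    mask = select_edges(tr_edges, y_train, motion=motion_train, alpha=alpha)
    model = fit_rcpm(tr_edges, mask, y_train, lambda_grid=lambda_grid, seed=inner_seed)
    pred = predict_rcpm(model, te_edges)
    rr = stats.pearsonr(y_test, pred)
    return ExternalResult(r=float(rr.statistic), p_value=float(rr.pvalue),
                          actual=y_test, predicted=pred, n_test=len(y_test))
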