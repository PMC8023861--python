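"""Latent behavioral phenotypes via fold-restricted principal components.

A single behavioral instrument is a noisy, incomplete probe of the construct
it targets, so several instruments per construct are summarized into one
latent score per subject: measures are z-scored using training-set mean and
standard deviation, and the first principal component of the training
correlation structure defines a fixed loading vector.  Test subjects are
projected with the *training* centering, scaling and loadings — the test set
never influences the fit, which keeps cross-validation honest.

The component sign is fixed so the loading sum is non-negative; with
positively scored instruments, higher latent scores then mean better
performance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class LatentModel:
    """Train-fold PCA parameters producing one construct score per subject."""

    measure_names: list[str]
    means: np.ndarray
    stds: np.ndarray
    loadings: np.ndarray          # (n_measures, n_components), unit-norm columns
    explained_variance: np.ndarray  # fraction per component

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.stds = np.asarray(self.stds, dtype=float)
        self.loadings = np.atleast_2d(np.asarray(self.loadings, dtype=float))
        if self.loadings.shape[0] != len(self.measure_names):
            self.loadings = self.loadings.T
        self.explained_variance = np.atleast_1d(np.asarray(self.explained_variance, dtype=float))

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "measure_names": self.measure_names,
            "means": self.means.tolist(),
            "stds": self.stds.tolist(),
            "loadings": self.loadings.tolist(),
            "explained_variance": self.explained_variance.tolist(),
        }))

    @classmethod
    def from_json(cls, path: str | Path) -> "LatentModel":
        d = json.loads(Path(path).read_text())
        return cls(
            measure_names=d["measure_names"],
            means=np.array(d["means"]),
            stds=np.array(d["stds"]),
            loadings=np.array(d["loadings"]),
            explained_variance=np.array(d["explained_variance"]),
        )


def _as_matrix(measures) -> tuple[np.ndarray, list[str]]:
    if isinstance(measures, pd.DataFrame):
        return measures.to_numpy(dtype=float), [str(c) for c in measures.columns]
    x = np.asarray(measures, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    return x, [f"m{i}" for i in range(x.shape[1])]


def fit_latent(train_measures, n_components: int = 1) -> LatentModel:
    """Fit the latent construct on training subjects only.

    Parameters
    ----------
    train_measures
        Subjects x measures matrix or DataFrame; >= 3 subjects, no missing
        values.
    n_components
        Components retained (default 1 — one construct score per subject).
    """
    x, names = _as_matrix(train_measures)
    if x.shape[0] < 3:
        raise ValueError("need at least 3 training subjects")
    if x.shape[1] < 1:
        raise ValueError("need at least 1 measure")
    if not np.all(np.isfinite(x)):
        raise ValueError("missing or non-finite values in training measures")
    means = x.mean(axis=0)
    stds = x.std(axis=0, ddof=1)
    zero = np.flatnonzero(stds == 0)
    if len(zero):
        raise ValueError(f"zero-variance measure(s): {[names[i] for i in zero]}")
    z = (x - means) / stds
    # PCA of the correlation structure via SVD of the z-scored matrix
    _, s, vt = np.linalg.svd(z, full_matrices=False)
    n_components = min(n_components, vt.shape[0])
    loadings = vt[:n_components].T.copy()
    # sign convention: sum of loadings non-negative, per component
    for c in range(n_components):
        if loadings[:, c].sum() < 0:
            loadings[:, c] *= -1
    var = s**2 / (s**2).sum()
    return LatentModel(
        measure_names=names,
        means=means,
        stds=stds,
        loadings=loadings,
        explained_variance=var[:n_components],
    )


def apply_latent(model: LatentModel, measures) -> np.ndarray:
    """Project subjects into construct space using train statistics only."""
    if isinstance(measures, pd.DataFrame):
        missing = [m for m in model.measure_names if m not in measures.columns]
        if missing:
            raise KeyError(f"measures missing from input: {missing}")
        x = measures[model.measure_names].to_numpy(dtype=float)
    else:
        x = np.asarray(measures, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
        if x.shape[1] != len(model.measure_names):
            raise ValueError(
                f"expected {len(model.measure_names)} measures, got {x.shape[1]}"
            )
    if not np.all(np.isfinite(x)):
        raise ValueError("missing or non-finite measure values")
    z = (x - model.means) / model.stds
    scores = z @ model.loadings
    return scores[:, 0] if model.n_components == 1 else scores
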