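"""RBF-kernel SVM classification with leave-one-out cross-validation.

The classifier is a soft-margin support vector machine with the Gaussian
radial basis kernel

    k(x_i, x_j) = exp(-||x_i - x_j||^2 / (2 sigma^2)),

sigma = 2 and C = 0.01 by default. Performance is estimated by
leave-one-out cross-validation (LOOCV): each sample is held out once,
Kendall-tau feature selection is re-run on the remaining samples only
(the held-out sample never influences ranking or training), the SVM is
fit on the selected features, and the held-out sample is predicted.
With 25 subjects scanned pre and post, LOOCV has exactly 50 folds.

Metrics: generalization rate (GR) = overall proportion of held-out
samples predicted correctly; sensitivity = proportion of post-training
(+1) samples correct; specificity = proportion of pre-training (-1)
samples correct.

The dual problem is solved by scikit-learn's libsvm binding with the
kernel width mapped exactly (gamma = 1/(2 sigma^2)); kernel form and
parameters are this module's contract, the solver is standard machinery.
Features enter as-is (Fisher-z scale); per-fold standardization is
available behind a flag but off by default, and its state is logged.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from sklearn.svm import SVC

from .features import LabeledStudy, PairSignCache, top_k_by_power

__all__ = [
    "SvmConfig",
    "FoldRecord",
    "CVResult",
    "SweepResult",
    "rbf_kernel",
    "train_svm",
    "loocv",
    "sweep",
    "default_c_grid",
    "default_k_grid",
]


@dataclass(frozen=True)
class SvmConfig:
    """Classifier settings: kernel width sigma, penalty C, feature count k."""

    sigma: float = 2.0
    C: float = 0.01
    k: int = 160
    standardize: bool = False

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.C <= 0:
            raise ValueError("C must be positive")
        if self.k < 1:
            raise ValueError("k must be >= 1")

    @property
    def gamma(self) -> float:
        return 1.0 / (2.0 * self.sigma**2)


@dataclass(frozen=True)
class FoldRecord:
    """One LOOCV fold: who was held out, what was selected, what happened."""

    sample_id: object
    held_out_index: int
    selected: np.ndarray  # 1-based feature indices
    y_true: int
    y_pred: int
    decision_value: float


@dataclass(frozen=True)
class CVResult:
    """LOOCV outcome: per-fold records plus GR / sensitivity / specificity."""

    folds: tuple  # of FoldRecord
    gr: float
    sensitivity: float
    specificity: float

    @property
    def n_folds(self) -> int:
        return len(self.folds)

    @property
    def selections(self) -> list[np.ndarray]:
        return [f.selected for f in self.folds]

    @property
    def decision_values(self) -> np.ndarray:
        return np.array([f.decision_value for f in self.folds])


@dataclass(frozen=True)
class SweepResult:
    """GR surface over (k, C) grid points, and its argmax."""

    k_grid: np.ndarray
    c_grid: np.ndarray
    gr: np.ndarray  # (len(k_grid), len(c_grid))
    best_k: int
    best_c: float
    best_gr: float


def rbf_kernel(x1: np.ndarray, x2: np.ndarray, sigma: float = 2.0) -> float:
    """Gaussian kernel exp(-||x1-x2||^2 / (2 sigma^2)); 1 iff x1 == x2."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.shape != x2.shape:
        raise ValueError(f"vector length mismatch: {x1.shape} vs {x2.shape}")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    sq = float(np.dot(x1 - x2, x1 - x2))
    return float(np.exp(-sq / (2.0 * sigma**2)))


def train_svm(X: np.ndarray, y: np.ndarray, config: SvmConfig = SvmConfig()) -> SVC:
    """Fit the soft-margin RBF SVM f(x) = sum_j alpha_j y_j k(x_j, x) + b.

    Dual coefficients satisfy 0 <= alpha <= C; prediction is sign(f).
    """
    y = np.asarray(y, dtype=int)
    if np.unique(y).size < 2:
        raise ValueError("training labels contain a single class")
    model = SVC(kernel="rbf", gamma=config.gamma, C=config.C)
    model.fit(np.asarray(X, dtype=float), y)
    return model


def _metrics(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float, float, float]:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    post = y_true == 1
    pre = y_true == -1
    tp = int((y_pred[post] == 1).sum())
    tn = int((y_pred[pre] == -1).sum())
    gr = (tp + tn) / y_true.size
    sens = tp / post.sum()
    spec = tn / pre.sum()
    return gr, sens, spec


def loocv(
    study: LabeledStudy,
    config: SvmConfig = SvmConfig(),
    cache: PairSignCache | None = None,
) -> CVResult:
    """Leave-one-out cross-validation with feature selection inside each fold.

    For every sample: drop it, rank features by |tau| on the remaining
    samples, keep the top ``config.k``, fit the SVM on those features,
    predict the held-out sample. The held-out sample never touches the
    ranking or the fit.
    """
    n = study.n_samples
    if n < 4:
        raise ValueError("LOOCV needs at least 4 samples")
    if not 1 <= config.k <= study.n_features:
        raise ValueError(f"k={config.k} out of range [1, {study.n_features}]")
    if cache is None:
        cache = PairSignCache(study.X)
    folds = _run_folds(study.X, study.y, study.subject_ids, config, cache)
    gr, sens, spec = _metrics(study.y, np.array([f.y_pred for f in folds]))
    return CVResult(folds=tuple(folds), gr=gr, sensitivity=sens, specificity=spec)


def _run_folds(X, y, sample_ids, config: SvmConfig, cache: PairSignCache) -> list[FoldRecord]:
    n = X.shape[0]
    counts = np.bincount((np.asarray(y) == 1).astype(int), minlength=2)
    if counts.min() < 2:
        raise ValueError("a LOOCV training fold would lose one class entirely")
    _, tau_loo = cache.tau_full_and_loo(y)
    folds = []
    train_mask = np.ones(n, dtype=bool)
    for i in range(n):
        train_mask[:] = True
        train_mask[i] = False
        sel = top_k_by_power(tau_loo[i], config.k)
        Xtr = X[train_mask][:, sel - 1]
        Xte = X[i, sel - 1][None, :]
        if config.standardize:
            mu, sd = Xtr.mean(axis=0), Xtr.std(axis=0)
            sd[sd == 0] = 1.0
            Xtr = (Xtr - mu) / sd
            Xte = (Xte - mu) / sd
        model = SVC(kernel="rbf", gamma=config.gamma, C=config.C)
        model.fit(Xtr, y[train_mask])
        dec = float(model.decision_function(Xte)[0])
        pred = int(model.predict(Xte)[0])
        folds.append(
            FoldRecord(
                sample_id=sample_ids[i],
                held_out_index=i,
                selected=sel,
                y_true=int(y[i]),
                y_pred=pred,
                decision_value=dec,
            )
        )
    return folds


def default_k_grid(start: int = 40, stop: int = 300, step: int = 20) -> np.ndarray:
    """Feature-count grid 40..300 (default step 20)."""
    return np.arange(start, stop + 1, step)


def default_c_grid(start: float = 0.005, step: float = 0.05, stop: float = 2.0) -> np.ndarray:
    """Penalty grid in start:step:stop colon notation (largest point <= stop)."""
    n = int(np.floor((stop - start) / step + 1e-9)) + 1
    return start + step * np.arange(n)


def sweep(
    study: LabeledStudy,
    k_grid: np.ndarray | None = None,
    c_grid: np.ndarray | None = None,
    config: SvmConfig = SvmConfig(),
) -> SweepResult:
    """Full LOOCV at every (k, C) grid point; argmax GR, ties to the
    smallest k then smallest C. Deterministic: re-running on the same
    inputs reproduces the GR surface exactly."""
    k_grid = default_k_grid() if k_grid is None else np.asarray(k_grid, dtype=int)
    c_grid = default_c_grid() if c_grid is None else np.asarray(c_grid, dtype=float)
    if k_grid.size == 0 or c_grid.size == 0:
        raise ValueError("grids must be non-empty")
    cache = PairSignCache(study.X)
    gr = np.empty((k_grid.size, c_grid.size))
    for a, k in enumerate(k_grid):
        for b, C in enumerate(c_grid):
            res = loocv(study, replace(config, k=int(k), C=float(C)), cache=cache)
            gr[a, b] = res.gr
    flat = np.argmax(gr)  # first occurrence = smallest k then smallest C
    ia, ib = np.unravel_index(flat, gr.shape)
    return SweepResult(
        k_grid=k_grid,
        c_grid=c_grid,
        gr=gr,
        best_k=int(k_grid[ia]),
        best_c=float(c_grid[ib]),
        best_gr=float(gr[ia, ib]),
    )
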