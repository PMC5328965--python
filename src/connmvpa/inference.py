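"""Whole-pipeline permutation test of classifier significance.

The generalization rate (GR) from leave-one-out cross-validation is the
test statistic. For each of B label shuffles the ENTIRE classification
operation -- Kendall-tau feature selection inside every fold, SVM
training, LOOCV prediction -- is recomputed on the shuffled labels,
yielding a null GR. The p-value is the add-one permutation estimator

    p = (1 + #{GR* >= GR0}) / (1 + B),

so ties count against significance and p can never be 0. Two shuffle
schemes: ``free`` permutes all labels (the default), ``paired`` flips the
pre/post labels independently within each subject, respecting the paired
design.

Re-running feature selection inside every shuffle is what keeps the test
valid: freezing the selection made on the observed labels and only
shuffling afterwards lets the selection's overfitting leak into the null
and inflates significance. ``reselect_features=False`` deliberately
reproduces that broken variant for negative-control diagnostics; it must
never be used for inference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classify import CVResult, SvmConfig, loocv
from .features import LabeledStudy, PairSignCache, top_k_by_power

__all__ = ["PermutationResult", "permutation_test"]

SCHEMES = ("free", "paired")


@dataclass(frozen=True)
class PermutationResult:
    """Observed GR, the permutation null, and the add-one p-value."""

    gr0: float
    null_gr: np.ndarray  # (B,)
    p_value: float
    B: int
    scheme: str
    seed: int
    n_redrawn: int
    observed: CVResult

    def null_quantile(self, q: float) -> float:
        return float(np.quantile(self.null_gr, q))


def _draw_labels(y: np.ndarray, subject_ids: np.ndarray, scheme: str, rng) -> np.ndarray:
    if scheme == "free":
        return rng.permutation(y)
    # paired: flip the two sessions of a subject with probability 1/2
    y_new = y.copy()
    for s in np.unique(subject_ids):
        if rng.random() < 0.5:
            idx = subject_ids == s
            y_new[idx] = -y_new[idx]
    return y_new


def permutation_test(
    study: LabeledStudy,
    config: SvmConfig = SvmConfig(),
    B: int = 1000,
    scheme: str = "free",
    seed: int = 0,
    cache: PairSignCache | None = None,
    reselect_features: bool = True,
) -> PermutationResult:
    """Permutation p-value for the LOOCV generalization rate.

    Parameters
    ----------
    B : number of label shuffles (default 1000).
    scheme : "free" (permute all labels) or "paired" (within-subject flips).
    seed : seeds the shuffle sequence; same seed => identical p-value.
    reselect_features : when False, features are selected ONCE per fold on
        the observed labels and frozen across shuffles -- the invalid
        procedure kept only as a negative control.

    A shuffle that would leave a LOOCV training fold with a single class
    (a class with fewer than 2 members overall) is redrawn and counted in
    ``n_redrawn``, never silently skipped.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if scheme not in SCHEMES:
        raise ValueError(f"scheme must be one of {SCHEMES}")
    rng = np.random.default_rng(seed)
    if cache is None:
        cache = PairSignCache(study.X)

    observed = loocv(study, config, cache=cache)
    gr0 = observed.gr

    frozen_selections = None
    if not reselect_features:
        frozen_selections = observed.selections

    null_gr = np.empty(B)
    n_redrawn = 0
    for b in range(B):
        while True:
            y_perm = _draw_labels(study.y, study.subject_ids, scheme, rng)
            counts = np.bincount((y_perm == 1).astype(int), minlength=2)
            if counts.min() >= 2:
                break
            n_redrawn += 1
        null_gr[b] = _null_gr(study, y_perm, config, cache, frozen_selections)

    p = (1 + int((null_gr >= gr0).sum())) / (1 + B)
    return PermutationResult(
        gr0=gr0,
        null_gr=null_gr,
        p_value=p,
        B=B,
        scheme=scheme,
        seed=seed,
        n_redrawn=n_redrawn,
        observed=observed,
    )


def _null_gr(
    study: LabeledStudy,
    y_perm: np.ndarray,
    config: SvmConfig,
    cache: PairSignCache,
    frozen_selections,
) -> float:
    from sklearn.svm import SVC

    X = study.X
    n = X.shape[0]
    if frozen_selections is None:
        _, tau_loo = cache.tau_full_and_loo(y_perm)
    correct = 0
    train_mask = np.ones(n, dtype=bool)
    for i in range(n):
        train_mask[:] = True
        train_mask[i] = False
        if frozen_selections is None:
            sel = top_k_by_power(tau_loo[i], config.k)
        else:
            sel = frozen_selections[i]
        model = SVC(kernel="rbf", gamma=config.gamma, C=config.C)
        model.fit(X[train_mask][:, sel - 1], y_perm[train_mask])
        pred = int(model.predict(X[i, sel - 1][None, :])[0])
        correct += pred == int(y_perm[i])
    return correct / n
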