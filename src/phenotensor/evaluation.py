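"""Discrimination and distinction metrics with cross-validation.

Discrimination asks: do the learned patient memberships predict the outcome
on held-out patients?  The factorization is refit inside every fold (held-out
rows are updated with omega = 0, so no label leaks into their memberships),
then a fresh logistic regression on the training memberships scores the test
patients.  Distinction asks: are the phenotypes concise (relative length) and
non-overlapping (average pairwise cosine of the code factors)?
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .data import RunConfig
from .decomposition import TrainingSplit, _as_dense, fit_model
from .errors import DegenerateLabelsError, ParameterError

log = logging.getLogger(__name__)


def _mean_ci(values: np.ndarray) -> tuple[float, float]:
    """Mean and half-width of the 95% t-interval."""
    values = np.asarray(values, dtype=float)
    mean = float(values.mean())
    if values.size < 2 or np.allclose(values, mean):
        return mean, 0.0
    half = float(stats.t.ppf(0.975, values.size - 1) * values.std(ddof=1) / np.sqrt(values.size))
    return mean, half


@dataclass
class EvalReport:
    """Per-fold metric values plus mean and 95% CI summaries."""

    auc: tuple[float, float]
    sensitivity: tuple[float, float]
    specificity: tuple[float, float]
    per_fold: dict[str, list[float]] = field(default_factory=dict)
    relative_length: float | None = None
    avg_overlap: float | None = None
    rmse: float | None = None


def discrimination_cv(
    O,
    S_B,
    S_C,
    y: np.ndarray,
    cfg: RunConfig,
    folds: int = 10,
    repeats: int = 1,
    threshold: float = 0.5,
) -> EvalReport:
    """Repeated stratified k-fold evaluation of outcome discrimination.

    Within each fold the constrained factorization is refit with supervision
    restricted to the training patients; a binary logistic regression on the
    training memberships (A_bar rows) then scores the held-out patients.
    AUC is the rank statistic; sensitivity/specificity use the probability
    ``threshold``.  Means carry 95% t-intervals over folds x repeats.
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise DegenerateLabelsError("discrimination requires both outcome classes")
    per_fold: dict[str, list[float]] = {"auc": [], "sensitivity": [], "specificity": []}
    for rep in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=cfg.seed + rep)
        for fold, (train, test) in enumerate(skf.split(np.zeros(y.size), y)):
            if len(np.unique(y[train])) < 2 or len(np.unique(y[test])) < 2:
                raise DegenerateLabelsError(f"fold {fold} has a single outcome class")
            split = TrainingSplit(train_idx=train, test_idx=test)
            fold_cfg = cfg.replace(seed=cfg.seed + 1000 * rep + fold)
            model = fit_model(O, S_B, S_C, y, split=split, cfg=fold_cfg)
            clf = LogisticRegression(max_iter=2000)
            clf.fit(model.A_bar[train], y[train])
            prob = clf.predict_proba(model.A_bar[test])[:, list(clf.classes_).index(1)]
            per_fold["auc"].append(float(roc_auc_score(y[test], prob)))
            pred = np.where(prob >= threshold, 1, -1)
            pos = y[test] == 1
            per_fold["sensitivity"].append(float(np.mean(pred[pos] == 1)))
            per_fold["specificity"].append(float(np.mean(pred[~pos] == -1)))
    return EvalReport(
        auc=_mean_ci(np.array(per_fold["auc"])),
        sensitivity=_mean_ci(np.array(per_fold["sensitivity"])),
        specificity=_mean_ci(np.array(per_fold["specificity"])),
        per_fold=per_fold,
    )


def relative_length(model) -> float:
    """Mean over phenotypes of (nonzeros in B_bar_:r + C_bar_:r) / (J + K):
    the conciseness measure (smaller is more concise)."""
    if model.B_bar is None or model.C_bar is None:
        raise ParameterError("relative_length requires a normalized, thresholded model")
    j, _ = model.B_bar.shape
    k, _ = model.C_bar.shape
    counts = (model.B_bar > 0).sum(axis=0) + (model.C_bar > 0).sum(axis=0)
    return float(np.mean(counts / (j + k)))


def _cos_cols(mat: np.ndarray) -> np.ndarray:
    """Pairwise column cosines; columns of zero norm yield 0."""
    norms = np.linalg.norm(mat, axis=0)
    safe = np.where(norms > 0, norms, 1.0)
    unit = mat / safe
    cos = unit.T @ unit
    cos[norms == 0, :] = 0.0
    cos[:, norms == 0] = 0.0
    return cos


def average_overlap(model, use_thresholded: bool = True) -> float:
    """Average pairwise cosine between phenotype pairs over both code modes:

        sum_{r1 < r2} [cos(B_:r1, B_:r2) + cos(C_:r1, C_:r2)] / (R (R - 1)).

    Lower means more distinct phenotypes.  Uses the thresholded normalized
    factors by default (set ``use_thresholded=False`` for raw B, C).
    """
    if use_thresholded:
        if model.B_bar is None or model.C_bar is None:
            raise ParameterError("average_overlap requires a normalized model")
        b_mat, c_mat = model.B_bar, model.C_bar
    else:
        b_mat, c_mat = model.B, model.C
    r = b_mat.shape[1]
    if r < 2:
        raise ParameterError("average_overlap requires at least 2 phenotypes")
    iu = np.triu_indices(r, k=1)
    total = _cos_cols(b_mat)[iu].sum() + _cos_cols(c_mat)[iu].sum()
    return float(total / (r * (r - 1)))


def rmse(O, X) -> float:
    """Root-mean-square error over *all* tensor entries (zeros included)."""
    O = _as_dense(O)
    X = _as_dense(X)
    if O.shape != X.shape:
        raise ParameterError(f"shape mismatch {O.shape} vs {X.shape}")
    return float(np.sqrt(np.sum((O - X) ** 2) / O.size))
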