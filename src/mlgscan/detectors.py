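"""Raw anomaly scores: Mahalanobis distance, isolation forest, one-class SVM.

Three detectors applied to each of the two feature sets give the six
methods MD-M, MD-F, IF-M, IF-F, SVM-M, SVM-F.  MD emits squared
Mahalanobis distances (larger = more anomalous); IF and SVM emit signed
decision values in the library convention where LOWER = more anomalous.
Conversion of all three to p-values lives in :mod:`mlgscan.calibration`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve, LinAlgError

MD = "MD"
IF = "IF"
SVM = "SVM"
DETECTORS = (MD, IF, SVM)

#: Canonical method labels: detector x feature set.
METHODS = ("MD-M", "MD-F", "IF-M", "IF-F", "SVM-M", "SVM-F")


@dataclass
class MiniBatchPlan:
    """Systematic-sampling partition of N rows into m non-overlapping batches.

    Batch ``i`` (0-based) holds rows i, i+m, i+2m, ...; batches are disjoint
    and cover all rows.  Used to keep one-class SVM training tractable.
    """

    m_batches: int
    assignment: np.ndarray

    def batch_indices(self, i: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == i)


def mahalanobis_squared(X: np.ndarray, ridge: float = 0.0) -> np.ndarray:
    """Squared Mahalanobis distance of each row from the sample mean.

    D2_i = (x_i - xbar)^T C^{-1} (x_i - xbar) with xbar the column means
    and C the sample covariance (N-1 denominator).  Requires N > p and an
    invertible covariance; ``ridge`` > 0 adds ridge * mean(diag C) to the
    diagonal as a regularization escape hatch.  For feature matrices with
    structural collinearity use :func:`mahalanobis_squared_pinv`.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    N, p = X.shape
    if N <= p:
        raise ValueError(f"need more observations ({N}) than features ({p})")
    Xc = X - X.mean(axis=0)
    C = (Xc.T @ Xc) / (N - 1)
    if ridge > 0:
        C = C + ridge * float(np.mean(np.diag(C))) * np.eye(p)
    try:
        factor = cho_factor(C)
    except LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular sample covariance: prune constant/collinear features, "
            "pass ridge > 0, or use mahalanobis_squared_pinv"
        ) from exc
    return np.einsum("ij,ji->i", Xc, cho_solve(factor, Xc.T))


def mahalanobis_squared_pinv(
    X: np.ndarray, rtol: float = 1e-8
) -> tuple[np.ndarray, int]:
    """Mahalanobis distance within the support subspace of the data.

    Uses the Moore-Penrose pseudoinverse of the sample covariance:
    directions whose singular value falls below ``rtol`` times the
    largest are treated as degenerate (constant or exactly collinear
    features contribute nothing).  Returns (D2, effective rank); the
    effective rank is the degrees of freedom to use in the downstream
    F transform.  Coincides with :func:`mahalanobis_squared` when the
    covariance has full rank.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    N = X.shape[0]
    if N < 2:
        raise ValueError("need at least 2 observations")
    Xc = X - X.mean(axis=0)
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    keep = s > rtol * s[0] if s[0] > 0 else np.zeros_like(s, dtype=bool)
    rank = int(keep.sum())
    if rank == 0:
        raise np.linalg.LinAlgError("feature matrix has no variation")
    if N <= rank:
        raise ValueError(f"need more observations ({N}) than effective rank ({rank})")
    d2 = (N - 1) * np.sum(U[:, keep] ** 2, axis=1)
    return d2, rank


def isolation_forest_scores(
    X: np.ndarray,
    n_trees: int = 100,
    subsample: int = 256,
    seed: int | None = 0,
) -> np.ndarray:
    """Isolation-forest decision values (lower = more anomalous).

    An ensemble of randomly partitioned trees isolates rare, distinct
    observations in fewer splits; short average path lengths map to low
    decision values.  Deterministic given ``seed``.
    """
    from sklearn.ensemble import IsolationForest

    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] < 2:
        raise ValueError("need at least 2 observations")
    forest = IsolationForest(
        n_estimators=n_trees,
        max_samples=min(subsample, X.shape[0]),
        random_state=seed,
    )
    return forest.fit(X).decision_function(X)


def plan_minibatches(N: int, m_batches: int = 18) -> MiniBatchPlan:
    """Systematic-sampling batch plan: row r goes to batch r mod m."""
    if N < m_batches:
        raise ValueError(f"cannot form {m_batches} batches from {N} rows")
    return MiniBatchPlan(
        m_batches=m_batches, assignment=np.arange(N) % m_batches
    )


def ocsvm_scores(
    X: np.ndarray,
    plan: MiniBatchPlan | None = None,
    gamma: str | float = "auto",
    nu: float = 0.5,
    min_batch_size: int = 5,
    cross_score: str = "own",
) -> np.ndarray:
    """One-class SVM (RBF kernel) scores, mini-batch trained.

    One model is trained per batch of the plan; with ``cross_score="own"``
    (default) each row is scored by the model trained on its own batch,
    with ``"mean"`` by the mean over all batch models.  Scores are
    ``score_samples`` log-likelihood-like values, lower = more anomalous.
    Deterministic (the solver has no randomness for fixed input order).
    """
    from sklearn.svm import OneClassSVM

    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    N = X.shape[0]
    if plan is None:
        plan = MiniBatchPlan(m_batches=1, assignment=np.zeros(N, dtype=int))
    if len(plan.assignment) != N:
        raise ValueError("batch plan does not match number of rows")
    if cross_score not in ("own", "mean"):
        raise ValueError("cross_score must be 'own' or 'mean'")
    models = []
    for i in range(plan.m_batches):
        idx = plan.batch_indices(i)
        if len(idx) < min_batch_size:
            raise ValueError(
                f"batch {i} has {len(idx)} rows < minimum {min_batch_size}"
            )
        models.append(OneClassSVM(kernel="rbf", gamma=gamma, nu=nu).fit(X[idx]))
    scores = np.empty(N)
    if cross_score == "own":
        for i, model in enumerate(models):
            idx = plan.batch_indices(i)
            scores[idx] = model.score_samples(X[idx])
    else:
        scores[:] = np.mean([model.score_samples(X) for model in models], axis=0)
    return scores
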