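"""Semisupervised mapping-convergence (MC) classifier.

A positive-unlabeled learner for core-fucose identification. The tagged
FUT8-knockout vectors P are all genuine nCF (the "positive" class in PU
terms). Training has two phases:

mapping
    A one-class boundary learner (SVDD role; here a ν-one-class SVM with RBF
    kernel) is fit on P and applied to the untagged set U, splitting it into
    positives P0 (inside the nCF support) and negatives N0 (the initial
    identified-CF set N).

convergence
    Iteratively fit a binary maximum-margin classifier (SVM) on P vs N,
    reclassify the current positive remainder P_i, move its predicted
    negatives into N, and repeat until an iteration finds no new negatives.

The returned classifier h predicts nCF for positive decision values; N is the
accumulated set of untagged vectors identified as CF.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import clone
from sklearn.svm import SVC, OneClassSVM

from .labeling import CF, NCF

logger = logging.getLogger("corefucid")


@dataclass
class MCConfig:
    """Hyperparameters for mapping-convergence training.

    ``gamma=None`` selects the bandwidth heuristic 1 / (10 · mean per-feature
    variance of P ∪ U); ν and C default to standard mild settings since no
    values are prescribed for the original experiment.
    """

    nu: float = 0.05
    C: float = 1.0
    gamma: float | None = None
    max_iter: int = 100
    min_pos: int = 10
    balanced: bool = False  # optional class-weight rebalancing, off by default
    seed: int = 42


@dataclass
class MCModel:
    """Trained MC state: final classifier ``h`` plus bookkeeping."""

    h: object
    N_idx: np.ndarray  # indices into U identified as CF
    config: MCConfig
    n_iterations: int
    converged: bool
    used_one_class_only: bool = False
    history: list[int] = field(default_factory=list)  # |N| per iteration
    P_final_idx: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.intp))

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(self.h.decision_function(np.atleast_2d(X))).ravel()

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Vectorised CF/nCF prediction (nCF iff decision value > 0)."""
        d = self.decision_values(X)
        return np.where(d > 0, NCF, CF)


def _bandwidth(X: np.ndarray) -> float:
    v = float(X.var(axis=0, ddof=0).mean())
    if v <= 0:
        return 1.0
    return 1.0 / (10.0 * v)


def train_mc(P: np.ndarray, U: np.ndarray, config: MCConfig | None = None) -> MCModel:
    """Train the mapping-convergence model.

    Parameters
    ----------
    P : (n_p, 10) array
        Tagged nCF vectors (normalized).
    U : (n_u, 10) array
        Untagged vectors (normalized).

    Returns
    -------
    MCModel
        With ``h`` the final classifier and ``N_idx`` the indices of U
        identified as CF. If the mapping phase finds no negatives, the
        one-class boundary itself is returned with an empty N and a warning.
    """
    cfg = config or MCConfig()
    P = np.atleast_2d(np.asarray(P, dtype=np.float64))
    U = np.atleast_2d(np.asarray(U, dtype=np.float64)) if len(U) else np.empty((0, P.shape[1]))
    if len(P) < cfg.min_pos:
        raise ValueError(f"need at least {cfg.min_pos} tagged vectors, got {len(P)}")

    gamma = cfg.gamma if cfg.gamma is not None else _bandwidth(np.vstack([P, U]) if len(U) else P)

    # mapping phase: one-class boundary on P splits U
    h0 = OneClassSVM(kernel="rbf", nu=cfg.nu, gamma=gamma)
    h0.fit(P)
    if len(U) == 0:
        return MCModel(h=h0, N_idx=np.empty(0, dtype=np.intp), config=cfg,
                       n_iterations=0, converged=True, used_one_class_only=True)
    d0 = h0.decision_function(U).ravel()
    neg0 = d0 <= 0
    N_mask = neg0.copy()  # accumulated CF set, as a mask over U
    P_i = np.flatnonzero(~neg0)  # current positive remainder, indices into U
    if not N_mask.any():
        logger.warning("mapping phase found no negatives; returning one-class boundary")
        return MCModel(h=h0, N_idx=np.empty(0, dtype=np.intp), config=cfg,
                       n_iterations=0, converged=True, used_one_class_only=True,
                       P_final_idx=np.arange(len(U), dtype=np.intp))

    svm_template = SVC(
        kernel="rbf", C=cfg.C, gamma=gamma,
        class_weight="balanced" if cfg.balanced else None,
        random_state=cfg.seed,
    )

    h = h0
    history = [int(N_mask.sum())]
    converged = False
    iteration = 0
    for iteration in range(1, cfg.max_iter + 1):
        X_train = np.vstack([P, U[N_mask]])
        y_train = np.concatenate([np.ones(len(P)), -np.ones(int(N_mask.sum()))])
        h = clone(svm_template).fit(X_train, y_train)
        if len(P_i) == 0:
            converged = True
            break
        pred = h.predict(U[P_i])
        new_neg = P_i[pred < 0]
        if len(new_neg) == 0:
            converged = True
            break
        N_mask[new_neg] = True
        P_i = P_i[pred > 0]
        history.append(int(N_mask.sum()))
    else:
        logger.warning("mapping convergence did not terminate in %d iterations", cfg.max_iter)

    return MCModel(h=h, N_idx=np.flatnonzero(N_mask), config=cfg,
                   n_iterations=iteration, converged=converged, history=history,
                   P_final_idx=np.asarray(P_i, dtype=np.intp))


def mc_predict(model: MCModel, X: np.ndarray) -> str | np.ndarray:
    """Predict CF/nCF for one vector (returns str) or a matrix (returns array)."""
    X = np.asarray(X, dtype=np.float64)
    if X.ndim == 1:
        return str(model.predict(X[None, :])[0])
    return model.predict(X)
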