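"""Split protocols, metrics and the robustness-to-missing-ions experiment.

The two classifiers get deliberately different training fractions so their
training sets end up comparable in size: the mapping-convergence model trains
on 80% of the tagged *and* untagged data, the autoencoder on 95% of only the
tagged data; the remainders are the test pools. Train-set sizes use the floor
rule, which reproduces the published counts exactly (23,809 tagged → 19,047
at 80% and 22,618 at 95%; 20,072 untagged → 16,057 at 80%).

Only trustworthy rows of a test pool are ever scored (nCF via the FUT8-KO
rule, CF via the core-fucosylated-mannose rule); F1 uses CF as the positive
class — the minority detection target.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import floor
from typing import Sequence

import numpy as np
import pandas as pd

from .ae_model import AEConfig, ae_predict, train_ae
from .features import CIFeatureVector, feature_matrix, min_ci_filter, normalize
from .labeling import CF, NCF
from .mc_model import MCConfig, mc_predict, train_mc

logger = logging.getLogger("corefucid")


@dataclass(frozen=True)
class SplitSpec:
    mc_train_frac: float = 0.8
    ae_train_frac: float = 0.95
    seed: int = 42

    def __post_init__(self):
        for f in (self.mc_train_frac, self.ae_train_frac):
            if not 0 < f < 1:
                raise ValueError(f"train fraction must be in (0,1), got {f}")


@dataclass
class Splits:
    """Index-level output of split_datasets (indices into the input lists)."""

    mc_train_tagged: np.ndarray
    mc_test_tagged: np.ndarray
    mc_train_untagged: np.ndarray
    mc_test_untagged: np.ndarray
    ae_train_tagged: np.ndarray
    ae_test_tagged: np.ndarray
    ae_test_untagged: np.ndarray


def train_size(n: int, frac: float) -> int:
    """Floor rule for the train-set size."""
    return floor(frac * n)


def split_datasets(n_tagged: int, n_untagged: int, spec: SplitSpec | None = None) -> Splits:
    """Shuffle and split tagged/untagged index ranges per the two protocols.

    Tagged and untagged sets are split independently; the autoencoder's test
    pool is its remaining 5% of tagged data plus all untagged data not used
    for anything else (the untagged MC test split is reused there, keeping
    every untagged test spectrum out of AE training trivially — the AE never
    trains on untagged data).
    """
    if n_tagged <= 0:
        raise ValueError("need a nonempty tagged set")
    s = spec or SplitSpec()
    rng = np.random.default_rng(s.seed)
    tagged = rng.permutation(n_tagged)
    untagged = rng.permutation(n_untagged)
    k_mc_t = train_size(n_tagged, s.mc_train_frac)
    k_mc_u = train_size(n_untagged, s.mc_train_frac)
    k_ae_t = train_size(n_tagged, s.ae_train_frac)
    return Splits(
        mc_train_tagged=np.sort(tagged[:k_mc_t]),
        mc_test_tagged=np.sort(tagged[k_mc_t:]),
        mc_train_untagged=np.sort(untagged[:k_mc_u]),
        mc_test_untagged=np.sort(untagged[k_mc_u:]),
        ae_train_tagged=np.sort(tagged[:k_ae_t]),
        ae_test_tagged=np.sort(tagged[k_ae_t:]),
        ae_test_untagged=np.sort(untagged[k_mc_u:]),
    )


def build_test_prime(
    vectors: Sequence[CIFeatureVector],
    labels: Sequence[str],
) -> tuple[list[CIFeatureVector], np.ndarray]:
    """Keep only trustworthy-labeled test rows (CF or nCF); drop the rest.

    ``labels`` carries the trustworthy label per vector (CF, nCF or anything
    else meaning unlabeled). Emits a warning when no CF rows survive, since
    the evaluation then covers one class only.
    """
    kept, y = [], []
    for v, lab in zip(vectors, labels):
        if lab in (CF, NCF):
            kept.append(v)
            y.append(lab)
    y_arr = np.array(y)
    if len(y_arr) and not np.any(y_arr == CF):
        logger.warning("test-prime set has no trustworthy CF rows; nCF-only evaluation")
    return kept, y_arr


@dataclass
class Metrics:
    """Per-class recalls, overall accuracy and CF-positive F1."""

    tp: int  # predicted CF, truly CF
    fn: int
    fp: int
    tn: int
    n_undetermined: int = 0

    @property
    def cf_acc(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def ncf_acc(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else float("nan")

    @property
    def overall_acc(self) -> float:
        total = self.tp + self.fn + self.fp + self.tn
        return (self.tp + self.tn) / total if total else float("nan")

    @property
    def f1(self) -> float:
        denom = 2 * self.tp + self.fp + self.fn
        return 2 * self.tp / denom if denom else float("nan")

    def as_dict(self) -> dict:
        return {
            "cf_acc": self.cf_acc, "ncf_acc": self.ncf_acc,
            "overall_acc": self.overall_acc, "f1": self.f1,
            "tp": self.tp, "fn": self.fn, "fp": self.fp, "tn": self.tn,
            "n_undetermined": self.n_undetermined,
        }


def evaluate(predictions: Sequence[str], truth: Sequence[str]) -> Metrics:
    """Confusion-matrix metrics with CF as the positive class.

    UNDETERMINED predictions (the ratio baseline's sentinel) are excluded
    from the denominator and counted separately.
    """
    pred = np.asarray(predictions)
    y = np.asarray(truth)
    if pred.shape != y.shape:
        raise ValueError("predictions and truth differ in length")
    ok = (pred == CF) | (pred == NCF)
    n_und = int((~ok).sum())
    pred, y = pred[ok], y[ok]
    return Metrics(
        tp=int(np.sum((pred == CF) & (y == CF))),
        fn=int(np.sum((pred == NCF) & (y == CF))),
        fp=int(np.sum((pred == CF) & (y == NCF))),
        tn=int(np.sum((pred == NCF) & (y == NCF))),
        n_undetermined=n_und,
    )


def _renormalized_matrix(vectors: Sequence[CIFeatureVector], norm: str) -> np.ndarray:
    return np.stack([normalize(v.x, norm) for v in vectors])


def robustness_experiment(
    tagged: Sequence[CIFeatureVector],
    untagged: Sequence[CIFeatureVector],
    test_vectors: Sequence[CIFeatureVector],
    test_truth: Sequence[str],
    min_ci_values: Sequence[int] = (3, 4, 5, 6),
    norms: Sequence[str] = ("max", "sum"),
    k: float = 0.4,
    mc_config: MCConfig | None = None,
    ae_config: AEConfig | None = None,
) -> pd.DataFrame:
    """Retrain both models on nested min-matched-ion training subsets.

    For every (min_ci, norm) cell the training pools are filtered to spectra
    with at least ``min_ci`` matched ions, both models are retrained, and
    both are scored on the fixed test set. Returns a tidy table with one row
    per (min_ci, norm, model).
    """
    rows = []
    truth = np.asarray(test_truth)
    for norm in norms:
        X_test = _renormalized_matrix(test_vectors, norm)
        for mc in min_ci_values:
            P_vecs = [v for v in tagged if min_ci_filter(v, mc)]
            U_vecs = [v for v in untagged if min_ci_filter(v, mc)]
            P = _renormalized_matrix(P_vecs, norm)
            U = _renormalized_matrix(U_vecs, norm) if U_vecs else np.empty((0, 10))
            mc_model = train_mc(P, U, mc_config)
            m_mc = evaluate(mc_predict(mc_model, X_test), truth)
            ae = train_ae(P, k=k, config=ae_config)
            m_ae = evaluate(ae_predict(ae, X_test), truth)
            for model_name, m in (("MC", m_mc), ("AE", m_ae)):
                rows.append({"min_ci": mc, "norm": norm, "model": model_name,
                             "n_train_tagged": len(P_vecs),
                             "n_train_untagged": len(U_vecs), **m.as_dict()})
    return pd.DataFrame(rows)
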