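"""Distance-threshold family membership classification and its evaluation.

A query protein belongs to the receptor superfamily when its minimum
symmetrized distance to the base dataset is strictly below a threshold tau
(default 0.0009, the value that maximizes the F-measure of superfamily
identification on the reference dataset).  Queries at or above tau can be
re-examined with an iterative profile search (PSI-BLAST style, default 10
iterations) through a pluggable remote-homology provider: the provider's
minimum distance d' flags the query as *remotely related* when d' < tau,
but the verdict stays non-member — remote homology is evidence worth
surfacing, not a membership call.

Evaluation utilities build the ROC curve (score = -d_min: smaller distance
means more member-like), the trapezoidal AUC, and the F-measure sweep that
selects the optimal threshold.  Threshold candidates sit at geometric means
of consecutive distinct distances because E-values are log-scale
quantities; an arithmetic midpoint would be dominated by the larger value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .distance import QueryDistanceVector

DEFAULT_TAU = 0.0009
DEFAULT_REMOTE_ITERATIONS = 10

#: provider signature: query id -> QueryDistanceVector of remote distances
RemoteProvider = Callable[[str], QueryDistanceVector]


@dataclass(frozen=True)
class ClassifierConfig:
    tau: float = DEFAULT_TAU
    remote_iterations: int = DEFAULT_REMOTE_ITERATIONS
    remote_provider: RemoteProvider | None = None

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if self.remote_iterations < 1:
            raise ValueError("remote_iterations must be >= 1")


@dataclass(frozen=True)
class RemoteCheck:
    attempted: bool = False
    d_prime_min: float | None = None
    nearest: str | None = None
    remotely_related: bool = False
    error: str | None = None


@dataclass(frozen=True)
class ClassificationResult:
    query_id: str
    d_min: float
    nearest: str
    cluster: str | None
    verdict: str  # "member" | "non_member"
    remote: RemoteCheck = field(default_factory=RemoteCheck)

    @property
    def is_member(self) -> bool:
        return self.verdict == "member"


def classify(
    qd: QueryDistanceVector,
    config: ClassifierConfig | None = None,
    cluster_map: dict[str, object] | None = None,
    remote_provider: RemoteProvider | None = None,
) -> ClassificationResult:
    """Decide membership of one query from its base-distance vector.

    Membership requires the *strict* inequality d_min < tau; equality falls
    to the conservative non-member branch.  The assigned cluster is the
    cluster of the nearest base sequence.  When the verdict is non-member
    and a remote provider is configured, the provider's distances set the
    ``remotely_related`` flag (d' < tau) without changing the verdict.  A
    provider failure is recorded on the result rather than raised.
    """
    config = config or ClassifierConfig()
    provider = remote_provider or config.remote_provider
    member = qd.d_min < config.tau
    cluster = None
    if cluster_map is not None:
        label = cluster_map.get(qd.nearest)
        cluster = str(label) if label is not None else None
    remote = RemoteCheck()
    if not member and provider is not None:
        try:
            remote_qd = provider(qd.query_id)
            remote = RemoteCheck(
                attempted=True,
                d_prime_min=remote_qd.d_min,
                nearest=remote_qd.nearest,
                remotely_related=remote_qd.d_min < config.tau,
            )
        except Exception as exc:  # provider is external; stay diagnosable
            remote = RemoteCheck(attempted=True, error=str(exc))
    return ClassificationResult(
        query_id=qd.query_id,
        d_min=qd.d_min,
        nearest=qd.nearest,
        cluster=cluster,
        verdict="member" if member else "non_member",
        remote=remote,
    )


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def _as_bool_labels(labels) -> np.ndarray:
    arr = []
    for lab in labels:
        if isinstance(lab, str):
            if lab not in ("positive", "negative"):
                raise ValueError(f"unknown label {lab!r}")
            arr.append(lab == "positive")
        else:
            arr.append(bool(lab))
    out = np.asarray(arr, dtype=bool)
    if out.all() or not out.any():
        raise ValueError("need at least one positive and one negative label")
    return out


@dataclass(frozen=True)
class RocCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    table: pd.DataFrame  # per-threshold precision/recall/F-measure

    def __post_init__(self) -> None:
        fpr = np.asarray(self.fpr, dtype=float)
        tpr = np.asarray(self.tpr, dtype=float)
        object.__setattr__(self, "fpr", fpr)
        object.__setattr__(self, "tpr", tpr)
        if np.any(np.diff(fpr) < 0) or np.any(np.diff(tpr) < 0):
            raise ValueError("ROC points must be monotone non-decreasing")


def candidate_thresholds(d_mins) -> np.ndarray:
    """Geometric means of consecutive distinct distances, plus one above.

    A zero lower neighbor would collapse the geometric mean to 0 (which
    predicts nothing under the strict inequality), so it is replaced by
    half the upper neighbor.  The final candidate sits a decade above the
    maximum so the all-member prediction is always swept.
    """
    values = np.unique(np.asarray(d_mins, dtype=float))
    if np.any(values < 0):
        raise ValueError("distances must be nonnegative")
    cands = []
    for lo, hi in zip(values[:-1], values[1:]):
        cands.append(hi / 2.0 if lo == 0.0 else float(np.sqrt(lo * hi)))
    top = values[-1]
    cands.append(10.0 * top if top > 0 else 1.0)
    return np.array(cands)


def _precision_recall_f(d: np.ndarray, positive: np.ndarray,
                        tau: float) -> tuple[float, float, float]:
    predicted = d < tau
    tp = int(np.sum(predicted & positive))
    fp = int(np.sum(predicted & ~positive))
    fn = int(np.sum(~predicted & positive))
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    f = (
        2 * precision * recall / (precision + recall)
        if (precision + recall) > 0
        else 0.0
    )
    return precision, recall, f


def roc_curve(d_mins, labels) -> RocCurve:
    """ROC of the minimum-distance score over labeled queries.

    Ranking uses score = -d_min; thresholds sweep all distinct values with
    trapezoidal AUC, which handles tied scores by the midpoint
    (average-rank) convention.  Raises on single-class input.
    """
    d = np.asarray(d_mins, dtype=float)
    positive = _as_bool_labels(labels)
    if d.shape != positive.shape:
        raise ValueError("d_mins and labels differ in length")
    fpr, tpr, _ = _sk_roc_curve(positive.astype(int), -d)
    roc_auc = float(_trapezoid_auc(fpr, tpr))
    rows = []
    for tau in candidate_thresholds(d):
        precision, recall, f = _precision_recall_f(d, positive, tau)
        rows.append(
            {"threshold": float(tau), "precision": precision,
             "recall": recall, "f_measure": f}
        )
    return RocCurve(fpr=fpr, tpr=tpr, auc=roc_auc,
                    table=pd.DataFrame(rows))


def optimal_threshold_fmeasure(d_mins, labels) -> tuple[float, float]:
    """Sweep candidate thresholds, return (tau*, F*) maximizing F1.

    F-measure is the harmonic mean of precision and recall over the
    predictions d_min < tau.  Ties on F go to the smallest threshold.
    """
    d = np.asarray(d_mins, dtype=float)
    positive = _as_bool_labels(labels)
    if d.shape != positive.shape:
        raise ValueError("d_mins and labels differ in length")
    best_tau, best_f = None, -1.0
    for tau in candidate_thresholds(d):
        _, _, f = _precision_recall_f(d, positive, float(tau))
        if f > best_f:
            best_tau, best_f = float(tau), f
    return best_tau, best_f


# ---------------------------------------------------------------------------
# sklearn-style estimator
# ---------------------------------------------------------------------------

class MinDistanceMembershipClassifier(BaseEstimator, ClassifierMixin):
    """Membership by minimum distance to a reference set.

    Parameters
    ----------
    tau : float or None, default 0.0009
        Strict membership threshold on the minimum distance.  ``None``
        selects the threshold by F-measure sweep during :meth:`fit`
        (labels required).

    Attributes
    ----------
    tau_ : float
        Threshold in effect after fitting.
    f_measure_ : float
        F-measure achieved at ``tau_`` on the training distances (only when
        labels were supplied to :meth:`fit`).
    classes_ : ndarray
        ``["member", "non_member"]``.
    """

    def __init__(self, tau: float | None = DEFAULT_TAU):
        self.tau = tau

    def fit(self, X, y=None):
        d = np.asarray(X, dtype=float).reshape(-1)
        if np.any(d < 0):
            raise ValueError("distances must be nonnegative")
        if self.tau is None:
            if y is None:
                raise ValueError("tau=None requires labels to fit")
            self.tau_, self.f_measure_ = optimal_threshold_fmeasure(d, y)
        else:
            if self.tau <= 0:
                raise ValueError("tau must be > 0")
            self.tau_ = float(self.tau)
            if y is not None:
                _, _, self.f_measure_ = _precision_recall_f(
                    d, _as_bool_labels(y), self.tau_
                )
        self.classes_ = np.array(["member", "non_member"])
        return self

    def decision_function(self, X) -> np.ndarray:
        """Monotone membership score: tau - d_min (positive = member)."""
        d = np.asarray(X, dtype=float).reshape(-1)
        return self.tau_ - d

    def predict(self, X) -> np.ndarray:
        d = np.asarray(X, dtype=float).reshape(-1)
        return np.where(d < self.tau_, "member", "non_member")
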