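"""Standard discrimination metrics and the rank-sum rating of conditions.

Total sensitivity (TS) follows the Mahalanobis membership rule: a well
belongs to every class whose center is within D_M <= 4 of it (each class
using its own sample covariance); only wells matched uniquely to their own
class count as correct, wells matching several classes are flagged as
potentially misclassified, wells matching none are left unowned.  QDA and
SVM training-set sensitivities delegate to scikit-learn.  Conditions
(fluorophores) are compared by ranking each metric with its own polarity
and summing the places; the minimum rank sum wins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import QuadraticDiscriminantAnalysis
from sklearn.svm import SVC

from .errors import ComputationError, ValidationError
from .pca_core import ScoreCloud

#: D_M bound for class membership; corresponds to visual non-intersection
#: of the 80% confidence ellipses
DM_THRESHOLD_DEFAULT = 4.0

#: ranking polarity per metric column: +1 higher-is-better, -1 lower-is-better
METRIC_POLARITY = {
    "n_groups": +1,
    "crn": -1,
    "rp": +1,
    "ts_mah": +1,
    "ts_qda": +1,
    "ts_svm_linear": +1,
    "ts_svm_poly3": +1,
    "ts_svm_rbf": +1,
}

SVM_KERNELS = {"linear": dict(kernel="linear"),
               "poly3": dict(kernel="poly", degree=3),
               "rbf": dict(kernel="rbf")}


@dataclass
class MembershipTable:
    """Per-well Mahalanobis membership bookkeeping behind a TS value."""

    table: pd.DataFrame = field(repr=False)  # well_id, sample_id, n_classes, status
    distances: pd.DataFrame = field(repr=False)  # wells x classes D_M

    @property
    def statuses(self) -> pd.Series:
        return self.table["status"]


def _class_stats(points: np.ndarray, label: str):
    if points.shape[0] < 3:
        raise ValidationError(f"class {label!r} needs >= 3 wells, got {points.shape[0]}")
    cov = np.cov(points, rowvar=False, ddof=1)
    if np.linalg.eigvalsh(cov)[0] <= 1e-12 * max(np.trace(cov), 1e-300):
        raise ComputationError(f"singular covariance for class {label!r}")
    return points.mean(axis=0), np.linalg.inv(cov)


def total_sensitivity(
    cloud: ScoreCloud,
    threshold: float = DM_THRESHOLD_DEFAULT,
    leave_one_out: bool = False,
) -> tuple[float, MembershipTable]:
    """Training-set TS under the D_M <= threshold membership rule.

    With ``leave_one_out`` the evaluated well is excluded from its own
    class's center and covariance, giving an honest (lower) sensitivity;
    the default keeps it in, which is the training-set definition.
    """
    points, labels = cloud.labels()
    points = points[:, :2]
    classes = list(dict.fromkeys(labels))
    stats = {c: _class_stats(points[labels == c], c) for c in classes}

    n = len(points)
    dist = np.empty((n, len(classes)))
    for j, c in enumerate(classes):
        mean, prec = stats[c]
        d = points - mean
        dist[:, j] = np.sqrt(np.einsum("ij,jk,ik->i", d, prec, d))
    if leave_one_out:
        for i in range(n):
            c = labels[i]
            mask = (labels == c)
            mask_i = mask.copy()
            mask_i[i] = False
            own = points[mask_i]
            mean, prec = _class_stats(own, c)
            d = points[i] - mean
            dist[i, classes.index(c)] = np.sqrt(d @ prec @ d)

    member = dist <= threshold
    statuses = []
    for i in range(n):
        hits = [classes[j] for j in np.flatnonzero(member[i])]
        own = labels[i]
        if len(hits) == 1 and hits[0] == own:
            statuses.append("correct")
        elif len(hits) > 1:
            statuses.append("multi-class")
        elif len(hits) == 0:
            statuses.append("unowned")
        else:
            statuses.append("misassigned")
    meta = cloud.well_meta.loc[~cloud.well_meta["is_blank"]]
    table = pd.DataFrame({
        "well_id": meta["well_id"].to_numpy(),
        "sample_id": labels,
        "n_classes": member.sum(axis=1),
        "status": statuses,
    })
    distances = pd.DataFrame(dist, columns=classes, index=meta["well_id"].to_numpy())
    ts = float(np.mean([s == "correct" for s in statuses]))
    return ts, MembershipTable(table, distances)


def qda_sensitivity(cloud: ScoreCloud) -> float:
    """Training-set sensitivity of QDA with per-class covariances.

    Each well goes to the class minimizing the quadratic discriminant
    score (own-covariance Mahalanobis term plus log-determinant penalty);
    uniform priors, so the rule reduces to the Mahalanobis rule when all
    class covariances are equal.
    """
    points, labels = cloud.labels()
    points = points[:, :2]
    classes = list(dict.fromkeys(labels))
    for c in classes:  # surface singular classes with a clear error
        _class_stats(points[labels == c], c)
    # rank tolerance scaled to the data: sklearn's absolute default rejects
    # legitimately tight replicate clusters in small score units
    qda = QuadraticDiscriminantAnalysis(
        priors=np.full(len(classes), 1 / len(classes)),
        tol=1e-10 * float(points.var(axis=0).sum()),
    )
    qda.fit(points, labels)
    return float(np.mean(qda.predict(points) == labels))


def svm_sensitivity(cloud: ScoreCloud, kernel: str = "rbf") -> float:
    """Training-set sensitivity of a multi-class SVC with the named kernel
    (``linear``, ``poly3`` or ``rbf``); hyperparameters are library defaults."""
    if kernel not in SVM_KERNELS:
        raise ValidationError(
            f"unknown kernel {kernel!r}; choose from {sorted(SVM_KERNELS)}"
        )
    points, labels = cloud.labels()
    if len(set(labels)) < 2:
        raise ValidationError("SVM sensitivity needs >= 2 classes")
    clf = SVC(**SVM_KERNELS[kernel])
    clf.fit(points[:, :2], labels)
    return float(np.mean(clf.predict(points[:, :2]) == labels))


# --------------------------------------------------------------------------
# condition-level report
# --------------------------------------------------------------------------


def metric_correlations(report: pd.DataFrame, method: str = "pearson") -> pd.DataFrame:
    """Pairwise correlations between metric columns across conditions.

    Zero-variance columns yield undefined correlations and are reported as
    missing (NaN).  ``method`` may be ``pearson`` (default) or ``spearman``.
    """
    cols = [c for c in report.columns if c in METRIC_POLARITY]
    if len(report) < 3:
        raise ValidationError("need >= 3 conditions to correlate metrics")
    sub = report[cols].astype(float)
    if not np.isfinite(sub.to_numpy()).all():
        raise ValidationError("non-finite metric values in report")
    return sub.corr(method=method)


def overall_rating(report: pd.DataFrame) -> pd.DataFrame:
    """Rank conditions per metric and sum the places into an overall rating.

    Each metric column present in the report is ranked best-to-worst with
    its own polarity (crossing number: lower better; groups, RP and every
    sensitivity: higher better); ties share the mean rank.  The rating is
    the row sum of ranks — the condition with the minimum sum is the best —
    and the returned frame is sorted by rating (ties broken by condition
    name).
    """
    if len(report) < 2:
        raise ValidationError("need >= 2 conditions to rate")
    cols = [c for c in report.columns if c in METRIC_POLARITY]
    if not cols:
        raise ValidationError("no known metric columns to rate")
    out = report.copy()
    if "condition" not in out.columns:
        out = out.reset_index(names="condition")
    for c in cols:
        ascending = METRIC_POLARITY[c] < 0
        out[f"rank_{c}"] = out[c].astype(float).rank(
            ascending=ascending, method="average"
        )
    out["rating"] = out[[f"rank_{c}" for c in cols]].sum(axis=1)
    out = out.sort_values(["rating", "condition"], kind="mergesort")
    return out.reset_index(drop=True)


def evaluate_condition(
    cloud: ScoreCloud,
    level: float = 0.80,
    dm_threshold: float = DM_THRESHOLD_DEFAULT,
    svm_kernels: tuple[str, ...] = ("linear", "poly3", "rbf"),
    ellipse_mode: str = "coverage",
) -> dict[str, float]:
    """All separability metrics of one condition's score cloud."""
    from .ellipse_geometry import (count_groups, ellipses_from_cloud,
                                   total_crossing_number)
    from .rp_index import groups_from_cloud, rp_overall

    ellipses = ellipses_from_cloud(cloud, level=level, mode=ellipse_mode)
    row: dict[str, float] = {
        "n_groups": count_groups(ellipses),
        "crn": total_crossing_number(ellipses),
        "rp": rp_overall(groups_from_cloud(cloud)),
        "ts_mah": total_sensitivity(cloud, threshold=dm_threshold)[0],
        "ts_qda": qda_sensitivity(cloud),
    }
    for kern in svm_kernels:
        row[f"ts_svm_{kern}"] = svm_sensitivity(cloud, kern)
    return row
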