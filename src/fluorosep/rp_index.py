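"""The relative-position (RP) separability index.

Each sample's replicate points form a group with a center of mass C and a
convex-hull boundary.  For an ordered pair of groups (1, 2) the index is a
ratio of signed scalar projections onto the inter-center direction C1→C2:

    RP_12 = proj(C1→A2) / proj(C1→A1)

where A2 is the boundary point of group 2 nearest to group 1 along that
direction, and A1 the boundary point of group 1 farthest toward group 2
(formally: A_i minimizes the scalar projection of C_j→A_i on C_j→C_i for
the opposing group j).  The signs make the value interpretable against two
thresholds: RP > 1 means the hulls are separated along the center line,
0 < RP < 1 means they interpenetrate, and RP < 0 means the groups are
merged (each center lies beyond the other group's near boundary).  A
symmetric pair value takes min(RP_12, RP_21); the plot-level index averages
the pair minima over all unordered pairs — higher is better.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .errors import ComputationError, ValidationError

#: centers closer than this (relative to group extents) are "identical"
_CENTER_TOL = 1e-12


@dataclass(frozen=True)
class GroupGeometry:
    """One sample's score points, their mean center, and convex boundary."""

    sample_id: str
    points: np.ndarray
    center: np.ndarray
    hull: np.ndarray  # counter-clockwise hull vertices, subset of points


@dataclass(frozen=True)
class RPResult:
    sample_a: str
    sample_b: str
    rp_12: float
    rp_21: float
    rp_pair: float
    classification: str  # separated | intersecting | merged


def convex_hull(points: np.ndarray) -> np.ndarray:
    """Counter-clockwise convex-polygon boundary of a 2-D point set.

    Collinear sets degenerate to the two extreme points (a segment hull);
    fewer than two distinct points is an error.
    """
    pts = np.asarray(points, float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValidationError("points must be an (n, 2) array")
    distinct = np.unique(pts, axis=0)
    if distinct.shape[0] < 2:
        raise ValidationError("need >= 2 distinct points for a hull")
    try:
        h = ConvexHull(pts)
        return pts[h.vertices]  # scipy orders 2-D hull vertices CCW
    except QhullError:
        # collinear: return the two extreme points of the segment
        direction = distinct[-1] - distinct[0]
        proj = pts @ direction
        return pts[[int(np.argmin(proj)), int(np.argmax(proj))]]


def group_geometry(sample_id: str, points: np.ndarray) -> GroupGeometry:
    """Center of mass (mean of *all* points) plus convex boundary."""
    pts = np.asarray(points, float)
    return GroupGeometry(sample_id, pts, pts.mean(axis=0), convex_hull(pts))


def _boundary_point(group: GroupGeometry, origin: np.ndarray,
                    direction: np.ndarray) -> np.ndarray:
    """Hull vertex minimizing the scalar projection of origin→vertex on
    ``direction`` (ties broken by smallest vertex index)."""
    proj = (group.hull - origin) @ direction
    return group.hull[int(np.argmin(proj))]


def _rp_directed(g1: GroupGeometry, g2: GroupGeometry) -> float:
    """RP_12 per the projection-ratio formula."""
    u = g2.center - g1.center
    norm = np.linalg.norm(u)
    extent = max(
        np.abs(g1.points - g1.center).max(),
        np.abs(g2.points - g2.center).max(),
        1.0,
    )
    if norm <= _CENTER_TOL * extent:
        raise ComputationError(
            f"merged: identical centers for groups {g1.sample_id!r} and {g2.sample_id!r}"
        )
    u = u / norm
    # A1: boundary point of group 1 with smallest projection of C2->A1 on C2->C1
    a1 = _boundary_point(g1, g2.center, -u)
    # A2: boundary point of group 2 with smallest projection of C1->A2 on C1->C2
    a2 = _boundary_point(g2, g1.center, u)
    num = float((a2 - g1.center) @ u)
    den = float((a1 - g1.center) @ u)
    if abs(den) <= _CENTER_TOL * extent:
        raise ComputationError(
            f"zero denominator: group {g1.sample_id!r} has no extent toward "
            f"{g2.sample_id!r} along the center line"
        )
    return num / den


def classify_rp(rp_pair: float) -> str:
    """Map an RP value to its regime; the boundary values 1 and 0 resolve
    conservatively toward the worse regime (intersecting, merged)."""
    if rp_pair > 1.0:
        return "separated"
    if rp_pair > 0.0:
        return "intersecting"
    return "merged"


def rp_pairwise(g1: GroupGeometry, g2: GroupGeometry) -> RPResult:
    """Symmetric RP of two groups: both directed values and their minimum."""
    rp_12 = _rp_directed(g1, g2)
    rp_21 = _rp_directed(g2, g1)
    rp_pair = min(rp_12, rp_21)
    return RPResult(g1.sample_id, g2.sample_id, rp_12, rp_21, rp_pair,
                    classify_rp(rp_pair))


def rp_overall(groups: list[GroupGeometry], normalization: str = "mean") -> float:
    """Plot-level RP: aggregate of min(RP_ij, RP_ji) over unordered pairs.

    ``mean`` (default) averages over the N(N-1)/2 unordered pairs;
    ``printed`` divides the doubled sum by 0.5·N(N-1), i.e. exactly twice
    the mean, matching a normalization sometimes quoted with the doubled
    double-sum form of the index.
    """
    if len(groups) < 2:
        raise ValidationError("need >= 2 groups for an overall RP")
    if normalization not in ("mean", "printed"):
        raise ValidationError(f"unknown normalization {normalization!r}")
    vals = []
    for g1, g2 in combinations(groups, 2):
        try:
            vals.append(rp_pairwise(g1, g2).rp_pair)
        except ComputationError as exc:
            raise ComputationError(
                f"pair ({g1.sample_id!r}, {g2.sample_id!r}): {exc}"
            ) from exc
    mean = float(np.mean(vals))
    return 2.0 * mean if normalization == "printed" else mean


def groups_from_cloud(cloud) -> list[GroupGeometry]:
    """One group geometry per non-blank sample of a score cloud."""
    return [group_geometry(sid, pts) for sid, pts in cloud.sample_points().items()]
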