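"""Confidence ellipses in score space, their intersections, and the CrN index.

Each sample's replicate scores define an 80% confidence ellipse: center at
the replicate mean, shape from the sample covariance, boundary at squared
Mahalanobis radius t²(1 - α/2, n - 1) (Student coverage scaling; a
Hotelling-T² mean-region alternative is available).  Two boundaries are
intersected exactly by mapping one ellipse to the unit circle, rationally
parametrizing it, and solving the resulting quartic — every transversal
crossing is a real root.  The crossing number CrN of a scores plot is the
sum of pairwise crossing counts, with full containment of one ellipse in
another postulated as 4 crossings; fewer crossings mean better
discrimination.  Samples whose ellipses do not meet are "separated", and
the number of groups is the number of connected components of the
intersection graph.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .errors import ComputationError, ValidationError

#: relative tolerance below which a quartic root's imaginary part is noise
#: (double roots at tangency split as +-sqrt(eps), hence the loose value)
_IMAG_TOL = 1e-7
#: relative residual tolerance for accepting a candidate boundary point
_RESIDUAL_TOL = 1e-9


@dataclass(frozen=True)
class ConfidenceEllipse:
    """Elliptical confidence region { x : (x-c)' S^-1 (x-c) <= scale2 }."""

    center: np.ndarray
    covariance: np.ndarray
    scale2: float
    sample_id: str = ""
    n_points: int = 0

    def __post_init__(self):
        c = np.asarray(self.center, float).reshape(2)
        s = np.asarray(self.covariance, float).reshape(2, 2)
        object.__setattr__(self, "center", c)
        object.__setattr__(self, "covariance", s)
        if not np.allclose(s, s.T, rtol=1e-8, atol=1e-12):
            raise ValidationError("covariance must be symmetric")
        if np.linalg.eigvalsh(s)[0] <= 0:
            raise ComputationError(
                f"singular covariance for sample {self.sample_id!r}"
            )
        if self.scale2 <= 0:
            raise ValidationError("scale2 must be positive")

    def mahalanobis2(self, points: np.ndarray) -> np.ndarray:
        """Squared Mahalanobis distance of points from the center."""
        d = np.atleast_2d(points) - self.center
        sol = np.linalg.solve(self.covariance, d.T)
        return np.einsum("ij,ji->i", d, sol)

    def contains(self, point: np.ndarray) -> bool:
        """Strict interior test against the scaled boundary."""
        return bool(self.mahalanobis2(point)[0] < self.scale2)

    def boundary(self, n: int = 256) -> np.ndarray:
        """Points on the boundary (parametric, for plotting/oracles)."""
        theta = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
        circ = np.stack([np.cos(theta), np.sin(theta)])
        l = np.linalg.cholesky(self.covariance)
        return (self.center[:, None] + np.sqrt(self.scale2) * (l @ circ)).T


@dataclass(frozen=True)
class PairCrossing:
    """Crossing bookkeeping for one unordered ellipse pair."""

    sample_a: str
    sample_b: str
    n_boundary_points: int
    containment: bool
    crossing_number: int


def ellipse_scale2(n: int, level: float = 0.80, mode: str = "coverage") -> float:
    """Squared Mahalanobis radius of the confidence boundary.

    ``coverage`` (default): t²(1 - α/2, n-1) with α = 1 - level — a
    replicate-coverage region built on the two-sided Student quantile, which
    visibly encloses the replicate points.  ``hotelling``: the exact
    confidence region for the class mean, 2(n-1)/(n(n-2)) F(level; 2, n-2),
    which is tighter.
    """
    if not 0.0 < level < 1.0:
        raise ValidationError(f"confidence level must be in (0,1), got {level}")
    if mode == "coverage":
        if n < 2:
            raise ValidationError("coverage scaling needs n >= 2 replicates")
        return float(stats.t.ppf(1.0 - (1.0 - level) / 2.0, n - 1) ** 2)
    if mode == "hotelling":
        if n < 3:
            raise ValidationError("Hotelling scaling needs n >= 3 replicates")
        return float(2.0 * (n - 1) / (n * (n - 2)) * stats.f.ppf(level, 2, n - 2))
    raise ValidationError(f"unknown ellipse scaling mode {mode!r}")


def confidence_ellipse(
    points: np.ndarray,
    level: float = 0.80,
    sample_id: str = "",
    mode: str = "coverage",
) -> ConfidenceEllipse:
    """Confidence ellipse of one sample's replicate scores.

    Requires at least 3 non-collinear replicates so the 2-D sample
    covariance is positive definite.
    """
    pts = np.asarray(points, float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValidationError("points must be an (n, 2) array of scores")
    n = pts.shape[0]
    if n < 3:
        raise ValidationError(
            f"sample {sample_id!r}: need >= 3 replicate points, got {n}"
        )
    center = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False, ddof=1)
    if np.linalg.eigvalsh(cov)[0] <= max(1e-13 * np.trace(cov), 0.0):
        raise ComputationError(
            f"singular covariance (collinear replicates) for sample {sample_id!r}"
        )
    return ConfidenceEllipse(center, cov, ellipse_scale2(n, level, mode), sample_id, n)


def mahalanobis(point: np.ndarray, ellipse_or_class) -> float:
    """Mahalanobis distance D_M = sqrt((x-c)' S^-1 (x-c)).

    Accepts either a fitted :class:`ConfidenceEllipse` or a raw labeled
    point set (n x 2 array), in which case the class mean and sample
    covariance are estimated first.
    """
    if isinstance(ellipse_or_class, ConfidenceEllipse):
        ell = ellipse_or_class
    else:
        pts = np.asarray(ellipse_or_class, float)
        if pts.shape[0] < 3:
            raise ValidationError("class point set needs >= 3 points")
        cov = np.cov(pts, rowvar=False, ddof=1)
        if np.linalg.eigvalsh(cov)[0] <= 0:
            raise ComputationError("singular class covariance")
        ell = ConfidenceEllipse(pts.mean(axis=0), cov, 1.0)
    return float(np.sqrt(ell.mahalanobis2(np.asarray(point, float))[0]))


# --------------------------------------------------------------------------
# boundary intersection via quartic reduction
# --------------------------------------------------------------------------


def _quartic_coefficients(a: ConfidenceEllipse, b: ConfidenceEllipse):
    """Coefficients of the intersection quartic in the Weierstrass parameter.

    Boundary of ``a`` is x = c_a + K u with |u| = 1 and K = sqrt(scale2_a)·L
    (Cholesky).  Substituting u = ((1-t²)/(1+t²), 2t/(1+t²)) into b's
    boundary quadric G(x) = (x-c_b)' M_b (x-c_b) - scale2_b gives
    G = P(t)/(1+t²)² with P quartic; its real roots are the transversal
    boundary intersections (the parametrization's antipode u = (-1, 0) is
    the root at infinity, recovered when the quartic degenerates).
    """
    k = np.sqrt(a.scale2) * np.linalg.cholesky(a.covariance)
    m_b = np.linalg.inv(b.covariance)
    d = a.center - b.center
    q = k.T @ m_b @ k
    r = k.T @ m_b @ d
    w = float(d @ m_b @ d) - b.scale2
    c4 = q[0, 0] - 2 * r[0] + w
    c3 = -4 * q[0, 1] + 4 * r[1]
    c2 = -2 * q[0, 0] + 4 * q[1, 1] + 2 * w
    c1 = 4 * q[0, 1] + 4 * r[1]
    c0 = q[0, 0] + 2 * r[0] + w
    scale = max(abs(v) for v in
                (q[0, 0], q[0, 1], q[1, 1], r[0], r[1], w, b.scale2))
    return np.array([c4, c3, c2, c1, c0]), k, scale


def _form_residual(e: ConfidenceEllipse, pts: np.ndarray) -> np.ndarray:
    """|quadric value| at pts, normalized by the boundary level."""
    return np.abs(e.mahalanobis2(pts) - e.scale2) / e.scale2


def _newton_polish(a: ConfidenceEllipse, b: ConfidenceEllipse,
                   p: np.ndarray, iters: int = 3) -> np.ndarray:
    """Newton steps on the 2x2 system of boundary quadrics (skipped when the
    Jacobian is near-singular, e.g. at tangency points)."""
    ma = np.linalg.inv(a.covariance)
    mb = np.linalg.inv(b.covariance)
    for _ in range(iters):
        fa = float((p - a.center) @ ma @ (p - a.center)) - a.scale2
        fb = float((p - b.center) @ mb @ (p - b.center)) - b.scale2
        jac = np.stack([2 * ma @ (p - a.center), 2 * mb @ (p - b.center)])
        det = np.linalg.det(jac)
        norm = np.abs(jac).max()
        if abs(det) < 1e-10 * norm * norm:
            break
        p = p - np.linalg.solve(jac, np.array([fa, fb]))
    return p


def ellipse_intersection_points(
    a: ConfidenceEllipse, b: ConfidenceEllipse
) -> list[np.ndarray]:
    """All real transversal intersection points of the two boundaries (0-4).

    A tangency appears as a double root and is reported as two coincident
    points (counted as a crossing).  Coincident ellipses return no points
    and are classified as containment by :func:`pair_crossing_number`.
    """
    coeffs, k, scale = _quartic_coefficients(a, b)
    if scale <= 0 or np.max(np.abs(coeffs)) < 1e-12 * scale:
        return []  # coincident boundaries: identically zero quadric
    pts: list[np.ndarray] = []
    # root at infinity: antipodal point u = (-1, 0) when degree drops
    if abs(coeffs[0]) < 1e-12 * scale:
        pts.append(a.center + k @ np.array([-1.0, 0.0]))
        coeffs = coeffs.copy()
        coeffs[0] = 0.0  # keep np.roots from producing a huge spurious twin
    roots = np.roots(coeffs)
    for t in roots:
        if abs(t.imag) > _IMAG_TOL * (1.0 + abs(t.real)):
            continue
        tr = t.real
        denom = 1.0 + tr * tr
        u = np.array([(1.0 - tr * tr) / denom, 2.0 * tr / denom])
        pts.append(a.center + k @ u)
    out = []
    for p in pts:
        p = _newton_polish(a, b, p)
        if max(_form_residual(a, p[None, :])[0], _form_residual(b, p[None, :])[0]) < 1e-6:
            out.append(p)
    return out[:4]


def pair_crossing_number(a: ConfidenceEllipse, b: ConfidenceEllipse) -> PairCrossing:
    """Crossing count for one ellipse pair under the containment postulate.

    Transversal boundary intersections are counted directly; when the
    boundaries do not meet, one ellipse lying entirely inside the other is
    postulated to count as 4 crossings (maximal overlap), and disjoint
    ellipses count 0.  Coincident ellipses are treated as containment.
    """
    points = ellipse_intersection_points(a, b)
    n = len(points)
    if n == 0:
        contained = a.contains(b.center) or b.contains(a.center)
        return PairCrossing(a.sample_id, b.sample_id, 0, contained,
                            4 if contained else 0)
    return PairCrossing(a.sample_id, b.sample_id, n, False, n)


def total_crossing_number(ellipses: list[ConfidenceEllipse]) -> int:
    """CrN: the crossing number summed over every unordered ellipse pair.

    The headline separability index of a scores plot — lower is better.
    """
    if len(ellipses) < 2:
        raise ValidationError("need >= 2 ellipses for a crossing number")
    return sum(
        pair_crossing_number(a, b).crossing_number
        for a, b in combinations(ellipses, 2)
    )


def pairwise_crossings(ellipses: list[ConfidenceEllipse]) -> list[PairCrossing]:
    """All unordered pair crossings (the CrN decomposition)."""
    return [pair_crossing_number(a, b) for a, b in combinations(ellipses, 2)]


def count_groups(
    ellipses: list[ConfidenceEllipse],
    predicate: str = "intersection",
    dm_threshold: float = 4.0,
) -> int:
    """Number of separated groups in the scores plot.

    Builds a graph with an edge between two samples whenever they are *not*
    separated and returns its number of connected components, so chains of
    pairwise-overlapping samples merge transitively into one group.  Two
    separation predicates are offered: ``intersection`` (edge iff the
    confidence ellipses meet, i.e. pair crossing number > 0) and
    ``mahalanobis`` (edge iff the Mahalanobis distance between class
    centers under the pooled covariance is below ``dm_threshold``; the
    D_M = 4 rule corresponds to visual non-intersection of the ellipses).
    """
    if len(ellipses) < 1:
        raise ValidationError("need >= 1 ellipse")
    if predicate not in ("intersection", "mahalanobis"):
        raise ValidationError(f"unknown separation predicate {predicate!r}")
    n = len(ellipses)
    rows, cols = [], []
    for i, j in combinations(range(n), 2):
        a, b = ellipses[i], ellipses[j]
        if predicate == "intersection":
            linked = pair_crossing_number(a, b).crossing_number > 0
        elif predicate == "mahalanobis":
            linked = _center_mahalanobis(a, b) < dm_threshold
        else:
            raise ValidationError(f"unknown separation predicate {predicate!r}")
        if linked:
            rows += [i, j]
            cols += [j, i]
    graph = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    n_comp, _ = connected_components(graph, directed=False)
    return int(n_comp)


def _center_mahalanobis(a: ConfidenceEllipse, b: ConfidenceEllipse) -> float:
    """D_M between class centers under the pooled (df-weighted) covariance."""
    na = a.n_points if a.n_points >= 2 else 2
    nb = b.n_points if b.n_points >= 2 else 2
    pooled = ((na - 1) * a.covariance + (nb - 1) * b.covariance) / (na + nb - 2)
    d = a.center - b.center
    return float(np.sqrt(d @ np.linalg.solve(pooled, d)))


def ellipses_from_cloud(cloud, level: float = 0.80,
                        mode: str = "coverage") -> list[ConfidenceEllipse]:
    """One confidence ellipse per non-blank sample of a score cloud."""
    return [
        confidence_ellipse(pts, level=level, sample_id=sid, mode=mode)
        for sid, pts in cloud.sample_points().items()
    ]
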