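"""epsilon-recurrence networks and their global graph measures.

The network's vertices are embedded state vectors; two states are linked
when their maximum-norm distance is at most epsilon. Rather than fixing
epsilon, the recurrence rate RR (fraction of recurrent state pairs) is
fixed, which keeps edge counts comparable across analysis windows; epsilon
is then the RR-quantile of the off-diagonal pairwise distances.

Global clustering, transitivity and degree assortativity are computed
directly on the adjacency matrix with dense linear algebra; recurrence
networks from 2-s windows are small (a few hundred vertices), so O(N^3)
matrix products are cheap and exactly match naive triangle enumeration.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .embedding import EmbeddedSeries
from .io import ValidationError

RR_TOLERANCE = 0.005


class TieWarning(UserWarning):
    """Achieved recurrence rate drifted from the requested one (distance ties)."""


@dataclass
class RecurrenceNetwork:
    """Binary symmetric adjacency with its threshold and achieved edge density."""

    adjacency: np.ndarray      # (N, N) float 0/1, zero diagonal
    epsilon: float
    achieved_rr: float

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValidationError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise ValidationError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValidationError("adjacency diagonal must be zero")

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]

    @property
    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)


@dataclass
class NetworkMeasures:
    """Global clustering C, transitivity T and degree assortativity A."""

    clustering: float
    transitivity: float
    assortativity: float          # NaN when undefined
    assortativity_defined: bool
    degrees: np.ndarray


def _points_array(points) -> np.ndarray:
    if isinstance(points, EmbeddedSeries):
        points = points.vectors
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    return pts


def epsilon_for_rr(points, rr: float = 0.03) -> float:
    """Distance threshold whose edge density first reaches ``rr``.

    epsilon is the smallest pairwise maximum-norm distance d such that the
    fraction of off-diagonal pairs with distance <= d is >= rr
    (deterministic non-strict quantile, stable under ties). Heavy ties can
    push the achieved rate beyond rr +/- 0.005, which is flagged.
    """
    pts = _points_array(points)
    if pts.shape[0] < 2:
        raise ValidationError("need at least two points")
    if not 0 < rr < 1:
        raise ValidationError("recurrence rate must be in (0, 1)")
    d = pdist(pts, metric="chebyshev")
    if d.max() == 0:
        raise ValidationError("all points identical: epsilon undefined")
    d_sorted = np.sort(d)
    k = max(math.ceil(rr * d.size) - 1, 0)
    eps = float(d_sorted[k])
    achieved = float(np.count_nonzero(d <= eps)) / d.size
    if abs(achieved - rr) > RR_TOLERANCE:
        warnings.warn(
            f"distance ties: achieved RR {achieved:.4f} vs requested {rr:.4f}",
            TieWarning, stacklevel=2)
    return eps


def build_network(points, epsilon: float, theiler: int = 0) -> RecurrenceNetwork:
    """Adjacency A(i,j) = 1 iff max-norm distance <= epsilon and i != j.

    The boundary counts as recurrent (Heaviside step with theta(0) = 1).
    ``theiler`` optionally excludes temporally close pairs (|i-j| <= theiler);
    the analysis protocol applies none by default.
    """
    pts = _points_array(points)
    dmat = squareform(pdist(pts, metric="chebyshev"))
    adj = (dmat <= epsilon).astype(float)
    np.fill_diagonal(adj, 0.0)
    if theiler > 0:
        idx = np.arange(pts.shape[0])
        adj[np.abs(idx[:, None] - idx[None, :]) <= theiler] = 0.0
    n = pts.shape[0]
    achieved = adj.sum() / (n * (n - 1)) if n > 1 else 0.0
    return RecurrenceNetwork(adjacency=adj, epsilon=float(epsilon),
                             achieved_rr=float(achieved))


def _adjacency(net) -> np.ndarray:
    if isinstance(net, RecurrenceNetwork):
        return net.adjacency
    return np.asarray(net, dtype=float)


def global_clustering(net) -> float:
    """Mean local clustering coefficient over all N vertices.

    C_i is the fraction of a vertex's neighbour pairs that are themselves
    linked; vertices of degree < 2 contribute C_i = 0 and stay in the
    average (isolated states still dilute the mean).
    """
    a = _adjacency(net)
    if a.shape[0] == 0:
        return 0.0
    return _clustering_transitivity(a)[0]


def transitivity(net) -> float:
    """3 x triangles / connected triples; 0 when the graph has no triples."""
    a = _adjacency(net)
    return _clustering_transitivity(a)[1]


def _clustering_transitivity(a: np.ndarray) -> tuple[float, float]:
    """Both triangle-based measures from one matrix product."""
    k = a.sum(axis=1)
    closed = ((a @ a) * a).sum(axis=1)   # 2x triangles through each vertex
    denom = k * (k - 1)                  # ordered neighbour pairs per vertex
    with np.errstate(divide="ignore", invalid="ignore"):
        ci = np.where(denom > 0, closed / denom, 0.0)
    c = float(np.mean(ci)) if a.shape[0] else 0.0
    triples = float(denom.sum())
    t = float(closed.sum()) / triples if triples > 0 else 0.0
    return c, t


def assortativity(net) -> float:
    """Degree-degree Pearson correlation over edge endpoints (Newman's r).

    Each undirected edge contributes both orientations. Returns NaN when the
    endpoint degrees have zero variance (e.g. regular graphs), where the
    correlation is undefined.
    """
    a = _adjacency(net)
    k = a.sum(axis=1)
    ii, jj = np.nonzero(np.triu(a, 1))
    if ii.size == 0:
        return float("nan")
    x = np.concatenate([k[ii], k[jj]])
    y = np.concatenate([k[jj], k[ii]])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def network_measures(net) -> NetworkMeasures:
    """All three global measures of one network."""
    a = _adjacency(net)
    r = assortativity(a)
    c, t = _clustering_transitivity(a)
    return NetworkMeasures(
        clustering=c,
        transitivity=t,
        assortativity=r,
        assortativity_defined=not math.isnan(r),
        degrees=a.sum(axis=1),
    )


def measures_for_points(points, rr: float = 0.03,
                        theiler: int = 0) -> tuple[NetworkMeasures, RecurrenceNetwork]:
    """Shortcut: threshold selection, network build, all three measures."""
    eps = epsilon_for_rr(points, rr)
    net = build_network(points, eps, theiler=theiler)
    return network_measures(net), net
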