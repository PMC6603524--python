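"""Phase-space reconstruction by time-delay embedding.

The delay ``tau`` is chosen at the first local minimum of the auto-mutual
information of the series, the dimension ``m`` by the false-nearest-
neighbours criterion of Kennel et al.; both are selected once per recording
and held fixed across analysis windows so that the recurrence networks
remain comparable.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.stats import rankdata

from .io import ValidationError


class DegenerateSeriesWarning(UserWarning):
    """Emitted when a series carries no information (e.g. is constant)."""


class SelectionWarning(UserWarning):
    """Emitted when a parameter selection rule had to fall back."""


@dataclass(frozen=True)
class EmbeddingParams:
    """Delay-embedding parameters: delay ``tau`` and dimension ``m`` (samples)."""

    tau: int
    m: int

    def __post_init__(self) -> None:
        if self.tau < 1 or self.m < 1:
            raise ValidationError("tau and m must be positive integers")


@dataclass
class EmbeddedSeries:
    """Delay vectors x(k) = (u(k), u(k+tau), ..., u(k+(m-1)tau))."""

    vectors: np.ndarray        # shape (N - (m-1)*tau, m)
    source_indices: np.ndarray
    params: EmbeddingParams


def embed(x: np.ndarray, params: EmbeddingParams) -> EmbeddedSeries:
    """Delay-embed a scalar series; yields N - (m-1)*tau vectors."""
    x = np.asarray(x, dtype=float).ravel()
    tau, m = params.tau, params.m
    count = x.size - (m - 1) * tau
    if count < 1:
        raise ValidationError(
            f"series of {x.size} samples too short to embed with m={m}, tau={tau}")
    cols = [x[j * tau: j * tau + count] for j in range(m)]
    return EmbeddedSeries(vectors=np.column_stack(cols),
                          source_indices=np.arange(count), params=params)


def auto_mutual_information(x: np.ndarray, tau_max: int,
                            bins: int | None = None,
                            binning: str = "width") -> np.ndarray:
    """Auto-mutual information MI(tau) for tau = 0..tau_max (nats).

    Probabilities come from a histogram of the amplitude distribution with
    B = max(8, floor(N^(1/3))) bins. The default is the classic equal-width
    partition, which preserves the geometry of the lagged return map (a
    noiseless oscillation then shows the textbook quarter-period minimum);
    ``binning="quantile"`` uses equal-occupancy bins instead, which are
    invariant under monotone amplitude transforms but flatten exactly the
    structure the delay selection looks for. MI(0) equals the plug-in
    entropy of the binned marginal. A constant series has no information at
    any lag; it yields all zeros with a degenerate-input warning.
    """
    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    if n <= tau_max + 10:
        raise ValidationError(f"series of {n} samples too short for tau_max={tau_max}")
    if np.ptp(x) == 0:
        warnings.warn("constant series: MI is identically zero",
                      DegenerateSeriesWarning, stacklevel=2)
        return np.zeros(tau_max + 1)
    if binning not in ("width", "quantile"):
        raise ValidationError("binning must be 'width' or 'quantile'")
    b = bins if bins is not None else max(8, int(np.floor(n ** (1 / 3))))
    if binning == "quantile":
        # average ranks keep exactly tied samples in one bin
        ranks = rankdata(x, method="average") - 1.0
        codes = np.clip(np.floor(ranks * b / n), 0, b - 1).astype(np.int64)
    else:
        edges = np.linspace(x.min(), x.max(), b + 1)
        codes = np.clip(np.digitize(x, edges) - 1, 0, b - 1).astype(np.int64)
    out = np.empty(tau_max + 1)
    for tau in range(tau_max + 1):
        a = codes[: n - tau] if tau else codes
        c = codes[tau:] if tau else codes
        joint = np.bincount(a * b + c, minlength=b * b).astype(float)
        joint /= joint.sum()
        px = joint.reshape(b, b).sum(axis=1)
        py = joint.reshape(b, b).sum(axis=0)
        nz = joint > 0
        denom = np.outer(px, py).ravel()[nz]
        out[tau] = float(np.sum(joint[nz] * np.log(joint[nz] / denom)))
    return out


def select_tau(mi: np.ndarray) -> int:
    """First local minimum of MI(tau); ties on the left are allowed.

    tau is the smallest lag with MI(tau) <= MI(tau-1) and MI(tau) < MI(tau+1).
    If the curve has no interior minimum, fall back to the first lag where
    MI drops below MI(0)/e, else to the largest lag, with a warning.
    """
    mi = np.asarray(mi, dtype=float)
    if mi.size < 3:
        raise ValidationError("need at least 3 MI values to find a local minimum")
    for tau in range(1, mi.size - 1):
        if mi[tau] <= mi[tau - 1] and mi[tau] < mi[tau + 1]:
            return tau
    below = np.flatnonzero(mi < mi[0] / np.e)
    fallback = int(below[0]) if below.size and below[0] >= 1 else mi.size - 1
    warnings.warn(
        f"MI has no interior local minimum; falling back to tau={fallback}",
        SelectionWarning, stacklevel=2)
    return fallback


def false_nearest_neighbours(x: np.ndarray, tau: int, m_max: int,
                             r_tol: float = 10.0, a_tol: float = 2.0) -> np.ndarray:
    """Fraction of false nearest neighbours for m = 1..m_max.

    A neighbour pair at dimension m is false when adding the (m+1)-th delay
    coordinate stretches it by more than ``r_tol`` relative to its distance,
    or moves it beyond ``a_tol`` times the series' standard deviation
    (Kennel criteria, Euclidean norm). Points whose nearest neighbour is
    farther than one standard deviation are too lonely to be informative and
    are excluded.
    """
    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    sigma = float(np.std(x))
    if sigma == 0:
        warnings.warn("constant series: FNN undefined, returning zeros",
                      DegenerateSeriesWarning, stacklevel=2)
        return np.zeros(m_max)
    out = np.empty(m_max)
    for m in range(1, m_max + 1):
        count = n - m * tau  # points that still have an (m+1)-th coordinate
        if count < 2:
            raise ValidationError(
                f"series of {n} samples too short for FNN at m={m}, tau={tau}")
        pts = embed(x[: count + (m - 1) * tau], EmbeddingParams(tau=tau, m=m)).vectors
        tree = cKDTree(pts)
        dist, nbr = tree.query(pts, k=2)
        r_m = dist[:, 1]
        j = nbr[:, 1]
        i = np.arange(count)
        r_next = np.abs(x[i + m * tau] - x[j + m * tau])
        with np.errstate(divide="ignore", invalid="ignore"):
            stretch = np.where(r_m > 0, r_next / r_m,
                               np.where(r_next > 0, np.inf, 0.0))
        false = (stretch > r_tol) | (np.hypot(r_m, r_next) / sigma > a_tol)
        # a pair separated only by floating-point noise is a true neighbour
        false &= r_next > 1e-8 * sigma
        valid = r_m <= sigma
        if not np.any(valid):
            warnings.warn(f"no valid neighbours at m={m}; reporting FNN=1",
                          SelectionWarning, stacklevel=2)
            out[m - 1] = 1.0
        else:
            out[m - 1] = float(np.mean(false[valid]))
    return out


def select_m(fractions: np.ndarray, threshold: float = 0.01) -> int:
    """Smallest m whose FNN fraction is at or below ``threshold``."""
    fractions = np.asarray(fractions, dtype=float)
    ok = np.flatnonzero(fractions <= threshold)
    if ok.size:
        return int(ok[0]) + 1
    warnings.warn(
        f"FNN never fell below {threshold}; using m_max={fractions.size}",
        SelectionWarning, stacklevel=2)
    return int(fractions.size)


def select_embedding(x: np.ndarray, tau_max: int = 30, m_max: int = 10,
                     fnn_threshold: float = 0.01) -> EmbeddingParams:
    """Convenience: tau from the AMI minimum, then m from FNN at that tau."""
    tau = select_tau(auto_mutual_information(x, tau_max))
    fnn = false_nearest_neighbours(x, tau, m_max)
    return EmbeddingParams(tau=tau, m=select_m(fnn, fnn_threshold))
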