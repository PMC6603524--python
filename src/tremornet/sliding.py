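"""Moving-window recurrence-network analysis with significance bands.

Each analysis window is embedded, thresholded at fixed recurrence rate and
summarised by the three global network measures, assigned to the window's
mid-point. A centred moving median smooths each measure's time course; the
spread sigma of the raw values around that track, estimated over an
atremorous baseline, defines +/-2 sigma and +/-3 sigma significance bands
(labelled p<0.05 and p<0.01 under a Gaussian reading of the residuals).
A peak is a run of windows whose trigger-memory average exceeds a band.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .embedding import EmbeddingParams, embed
from .io import LabelTrack, ValidationError
from .network import epsilon_for_rr, build_network, network_measures
from .preprocess import WindowSet

MEASURES = ("C", "T", "A")


@dataclass
class MeasureSeries:
    """Per-window global network measures at window mid-points."""

    mid_times: np.ndarray
    C: np.ndarray
    T: np.ndarray
    A: np.ndarray               # NaN where assortativity is undefined
    params: EmbeddingParams
    rr: float

    def __post_init__(self) -> None:
        n = len(self.mid_times)
        if not (len(self.C) == len(self.T) == len(self.A) == n):
            raise ValidationError("measure arrays must have equal length")

    def values(self, measure: str) -> np.ndarray:
        if measure not in MEASURES:
            raise ValidationError(f"unknown measure {measure!r}")
        return getattr(self, measure)

    @property
    def n(self) -> int:
        return len(self.mid_times)


@dataclass
class SignificanceBands:
    """Moving-median track, subject-baseline center and residual scale sigma.

    The thresholds are horizontal: ``center + level * sigma``, where
    ``center`` is the median of the measure over the subject's atremorous
    baseline and ``sigma`` the spread of the raw values around the moving
    median there. The moving-median track itself is the smoothed summary
    signal, not the threshold reference.
    """

    median_track: np.ndarray
    sigma: float
    center: float = 0.0

    def upper(self, level: float) -> float:
        return self.center + level * self.sigma

    def lower(self, level: float) -> float:
        return self.center - level * self.sigma


@dataclass
class PeakEvent:
    """Onset of a significant excursion of one measure above a band."""

    time_s: float
    measure: str
    level: int                  # 2 or 3 (sigma multiples)
    state_at_peak: str | None = None


def moving_median(values: np.ndarray, n: int) -> np.ndarray:
    """Centred moving median of odd length ``n``; NaN-aware.

    Near the series ends the half-window shrinks instead of padding, so no
    values are fabricated.
    """
    if n < 1 or n % 2 == 0:
        raise ValidationError("median window length must be a positive odd integer")
    values = np.asarray(values, dtype=float)
    half = n // 2
    out = np.empty_like(values)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
        for i in range(values.size):
            lo = max(0, i - half)
            hi = min(values.size, i + half + 1)
            out[i] = np.nanmedian(values[lo:hi])
    return out


def measure_timecourse(windows: WindowSet, params: EmbeddingParams,
                       rr: float = 0.03, theiler: int = 0) -> MeasureSeries:
    """Embed each window, build its network, record C/T/A at the mid-point.

    Degenerate windows (constant signal, all embedded states identical)
    yield NaN for every measure rather than aborting the time course.
    """
    n = windows.n
    c = np.full(n, np.nan)
    t = np.full(n, np.nan)
    a = np.full(n, np.nan)
    for i in range(n):
        seg = windows.windows[i]
        try:
            pts = embed(seg, params)
            eps = epsilon_for_rr(pts, rr)
        except ValidationError:
            continue
        m = network_measures(build_network(pts, eps, theiler=theiler))
        c[i], t[i], a[i] = m.clustering, m.transitivity, m.assortativity
    return MeasureSeries(mid_times=windows.mid_times.copy(), C=c, T=t, A=a,
                         params=params, rr=rr)


def significance_bands(values: np.ndarray, median_window_n: int = 21,
                       baseline_n: int | None = None,
                       sigma_mode: str = "total") -> SignificanceBands:
    """Moving-median track, baseline center and spread sigma of one measure.

    ``center`` is the median of the raw values over the first ``baseline_n``
    windows (the subject's atremorous baseline); with ``baseline_n=None``
    the whole series is used. ``sigma`` measures the baseline variability of
    the measure: with ``sigma_mode="total"`` (default) it is the standard
    deviation of the raw baseline values, which includes their slow wander
    and is what keeps atremorous fluctuations below the 2-sigma band;
    ``sigma_mode="residual"`` uses only the deviations from the moving
    median (the fast component). NaN values (undefined assortativity,
    degenerate windows) are excluded, never interpolated.
    """
    values = np.asarray(values, dtype=float)
    if values.size < median_window_n:
        raise ValidationError("series shorter than the median window")
    if sigma_mode not in ("total", "residual"):
        raise ValidationError("sigma_mode must be 'total' or 'residual'")
    track = moving_median(values, median_window_n)
    spread = values - track if sigma_mode == "residual" else values
    base = values
    if baseline_n is not None:
        if baseline_n < 2:
            raise ValidationError("baseline must span at least 2 windows")
        spread = spread[:baseline_n]
        base = values[:baseline_n]
    spread = spread[np.isfinite(spread)]
    base = base[np.isfinite(base)]
    sigma = float(np.std(spread)) if spread.size else 0.0
    center = float(np.median(base)) if base.size else 0.0
    return SignificanceBands(median_track=track, sigma=sigma, center=center)


def memory_average(values: np.ndarray, memory_windows: int) -> np.ndarray:
    """Mean of each window with its ``memory_windows`` predecessors (NaN-aware)."""
    values = np.asarray(values, dtype=float)
    out = np.empty_like(values)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for i in range(values.size):
            out[i] = np.nanmean(values[max(0, i - memory_windows): i + 1])
    return out


def detect_peaks(values: np.ndarray, bands: SignificanceBands,
                 memory_windows: int = 4, mid_times: np.ndarray | None = None,
                 measure: str = "C", statistic: str = "smoothed") -> list[PeakEvent]:
    """Significant excursions of the smoothed measure above the bands.

    The tested statistic is the trigger-memory average of the moving-median
    track (``statistic="smoothed"``, the default: transients are judged on
    the median-filtered signal, which is robust to single-window spikes) or
    of the raw values (``statistic="raw"``). For each sigma level (2 then 3)
    every maximal run of windows where the statistic strictly exceeds the
    horizontal threshold ``center + level*sigma`` emits one event at the
    run's first window. A 3-sigma event therefore always sits inside a
    2-sigma run.
    """
    values = np.asarray(values, dtype=float)
    if statistic not in ("smoothed", "raw"):
        raise ValidationError("statistic must be 'smoothed' or 'raw'")
    if mid_times is None:
        mid_times = np.arange(values.size, dtype=float)
    base = bands.median_track if statistic == "smoothed" else values
    avg = memory_average(base, memory_windows)
    events: list[PeakEvent] = []
    for level in (2, 3):
        above = avg > bands.upper(level)
        above &= np.isfinite(avg)
        starts = np.flatnonzero(above & ~np.concatenate(([False], above[:-1])))
        for i in starts:
            events.append(PeakEvent(time_s=float(mid_times[i]), measure=measure,
                                    level=level))
    events.sort(key=lambda e: (e.time_s, e.level))
    return events


@dataclass
class PeakSummary:
    """Peak counts by (state, level) and lead times ahead of the T boundary."""

    counts: dict[tuple[str, int], int] = field(default_factory=dict)
    lead_times_s: list[float] = field(default_factory=list)

    @property
    def n_peaks(self) -> int:
        return sum(self.counts.values())

    def count(self, state: str, level: int | None = None) -> int:
        if level is not None:
            return self.counts.get((state, level), 0)
        return sum(v for (st, _), v in self.counts.items() if st == state)


def state_of_peaks(peaks: list[PeakEvent], labels: LabelTrack) -> PeakSummary:
    """Tag peaks with the movement state at their time and summarise.

    Lead times are reported for peaks inside TO, as seconds ahead of the
    TO -> T boundary (positive = anticipatory).
    """
    summary = PeakSummary()
    t_onset = labels.onset_of("T")
    for p in peaks:
        state = labels.state_at(p.time_s)
        p.state_at_peak = state
        if state is None:
            continue
        key = (state, p.level)
        summary.counts[key] = summary.counts.get(key, 0) + 1
        if state == "TO" and t_onset is not None:
            summary.lead_times_s.append(t_onset - p.time_s)
    return summary
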