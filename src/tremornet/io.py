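"""Domain types and file I/O.

Biosignals are exchanged either as EDF (read through :mod:`mne`, optional
dependency) or as plain tab-separated text; state labels and per-window
measure series are always tab-separated text with ``#``-prefixed header
lines, so every artefact the pipeline emits is diffable and parseable
without this package.
"""
from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

STATES = ("NT", "TO", "T")
ROLES = ("LFP", "EMG")


class FormatError(ValueError):
    """Raised when an on-disk artefact cannot be interpreted."""


class ValidationError(ValueError):
    """Raised when a domain object violates one of its invariants."""


@dataclass
class Recording:
    """A uniformly sampled single-channel biosignal.

    Parameters
    ----------
    samples : array-like
        Signal values in microvolts.
    rate : float
        Sampling rate in samples per second; must be positive.
    role : {"LFP", "EMG"}
        Which physiological channel the samples represent.
    start_time : float
        Time of the first sample in seconds (default 0).
    """

    samples: np.ndarray
    rate: float
    role: str = "LFP"
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.rate <= 0:
            raise ValidationError(f"rate must be positive, got {self.rate}")
        if self.role not in ROLES:
            raise ValidationError(f"role must be one of {ROLES}, got {self.role!r}")
        if self.samples.size < 1:
            raise ValidationError("a Recording needs at least one sample")
        if not np.all(np.isfinite(self.samples)):
            raise ValidationError("samples must be finite")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Length of the recording in seconds."""
        return self.n / self.rate

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n) / self.rate


@dataclass
class LabelTrack:
    """Ordered, non-overlapping movement-state intervals.

    Intervals are half-open ``[start, end)`` in seconds, each tagged with a
    clinical state: NT (atremorous rest), TO (tremor onset / transition) or
    T (overt resting tremor).
    """

    segments: list[tuple[float, float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        segs = [(float(s), float(e), str(st)) for s, e, st in self.segments]
        for s, e, st in segs:
            if st not in STATES:
                raise ValidationError(f"unknown state {st!r}; expected one of {STATES}")
            if not s < e:
                raise ValidationError(f"segment ({s}, {e}) must satisfy start < end")
        segs.sort(key=lambda t: t[0])
        for (s0, e0, _), (s1, _, _) in zip(segs, segs[1:]):
            if s1 < e0:
                raise ValidationError(f"segments overlap at t={s1}")
        self.segments = segs

    def state_at(self, t: float) -> str | None:
        """State covering time ``t`` (half-open intervals), or None."""
        for s, e, st in self.segments:
            if s <= t < e:
                return st
        return None

    def onset_of(self, state: str) -> float | None:
        """Earliest start time of ``state``, or None if absent."""
        for s, _, st in self.segments:
            if st == state:
                return s
        return None

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LabelTrack):
            return NotImplemented
        return self.segments == other.segments


@dataclass
class AnalysisConfig:
    """Tunable parameters of the moving-window recurrence-network pipeline.

    Defaults follow the analysis protocol: downsampling to 125 Hz, a
    500th-order 2-45 Hz FIR band-pass, 2-s windows with 90% overlap, a fixed
    recurrence rate of 0.03, a 21-window moving median, a 5-s atremorous
    baseline, a 2-sigma start trigger and a four-window trigger memory.
    """

    target_rate: float = 125.0
    band: tuple[float, float] = (2.0, 45.0)
    filter_order: int = 500
    window_s: float = 2.0
    overlap_frac: float = 0.90
    recurrence_rate: float = 0.03
    median_window_n: int = 21
    baseline_s: float = 5.0
    sigma_trigger: float = 2.0
    memory_windows: int = 4

    def __post_init__(self) -> None:
        if not 0 <= self.overlap_frac < 1:
            raise ValidationError("overlap_frac must be in [0, 1)")
        if not 0 < self.recurrence_rate < 1:
            raise ValidationError("recurrence_rate must be in (0, 1)")
        for name in ("target_rate", "window_s", "baseline_s"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        lo, hi = self.band
        if not 0 < lo < hi:
            raise ValidationError("band must satisfy 0 < low < high")
        if self.median_window_n < 1 or self.median_window_n % 2 == 0:
            raise ValidationError("median_window_n must be a positive odd integer")

    @classmethod
    def from_toml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        if "band" in raw:
            raw["band"] = tuple(raw["band"])
        return cls(**raw)

    def to_toml(self, path: str | Path) -> None:
        lines = []
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, tuple):
                lines.append(f"{f.name} = [{v[0]}, {v[1]}]")
            elif isinstance(v, bool):
                lines.append(f"{f.name} = {str(v).lower()}")
            else:
                lines.append(f"{f.name} = {v}")
        Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _parse_headers(path: Path) -> tuple[dict[str, str], list[str]]:
    meta: dict[str, str] = {}
    body: list[str] = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            stripped = line.lstrip("#").strip()
            if "=" in stripped:
                k, _, v = stripped.partition("=")
                meta[k.strip()] = v.strip()
        else:
            body.append(line)
    return meta, body


def read_recording(path: str | Path, role: str = "LFP") -> Recording:
    """Read a biosignal from EDF or delimited text.

    Text files carry either one value per line with a ``# rate=...`` header,
    or two columns (time, value) from which the rate is inferred; a gap in
    the time column larger than twice the sampling interval is a format
    error.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if path.suffix.lower() == ".edf":
        return _read_edf(path, role)
    meta, body = _parse_headers(path)
    rows = [line.replace(",", "\t").split() for line in body]
    ncol = len(rows[0]) if rows else 0
    if ncol == 1:
        if "rate" not in meta:
            raise FormatError(f"{path}: single-column file needs a '# rate=' header")
        rate = float(meta["rate"])
        samples = np.array([float(r[0]) for r in rows])
    elif ncol == 2:
        t = np.array([float(r[0]) for r in rows])
        samples = np.array([float(r[1]) for r in rows])
        dt = np.diff(t)
        if t.size < 2 or np.any(dt <= 0):
            raise FormatError(f"{path}: time column must be strictly increasing")
        step = np.median(dt)
        if np.any(dt > 2 * step):
            raise FormatError(f"{path}: gap in time column exceeds 2/rate")
        rate = 1.0 / step
    else:
        raise FormatError(f"{path}: expected 1 or 2 columns, found {ncol}")
    start = float(meta.get("start_time", 0.0))
    role = meta.get("role", role)
    return Recording(samples, rate=rate, role=role, start_time=start)


def _read_edf(path: Path, role: str) -> Recording:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - depends on optional extra
        raise FormatError("reading EDF requires the optional 'mne' dependency") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data(picks=[0])[0] * 1e6  # mne returns volts
    return Recording(data, rate=float(raw.info["sfreq"]), role=role)


def write_recording(path: str | Path, rec: Recording) -> None:
    """Write a Recording as single-column TSV with metadata headers."""
    lines = [
        f"# rate={rec.rate!r}",
        f"# role={rec.role}",
        f"# start_time={rec.start_time!r}",
    ]
    lines.extend(repr(float(v)) for v in rec.samples)
    Path(path).write_text("\n".join(lines) + "\n")


def read_labels(path: str | Path) -> LabelTrack:
    """Read a state-label track (TSV columns: start, end, state)."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    _, body = _parse_headers(path)
    segs = []
    for line in body:
        parts = line.split()
        if len(parts) != 3:
            raise FormatError(f"{path}: expected 3 columns, got {line!r}")
        segs.append((float(parts[0]), float(parts[1]), parts[2]))
    return LabelTrack(segs)


def write_labels(path: str | Path, labels: LabelTrack) -> None:
    lines = ["# start_s\tend_s\tstate"]
    for s, e, st in labels.segments:
        lines.append(f"{s!r}\t{e!r}\t{st}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_measures(path: str | Path, series, bands: dict | None = None) -> None:
    """Write a MeasureSeries (and optionally its significance bands) as TSV.

    Columns: time, C, T, A, then ``<measure>_median`` per banded measure;
    per-measure sigma values go into the header so the full band set can be
    reconstructed on read.
    """
    cols = ["time", "C", "T", "A"]
    data = [series.mid_times, series.C, series.T, series.A]
    lines = [
        f"# tau={series.params.tau}",
        f"# m={series.params.m}",
        f"# rr={series.rr!r}",
    ]
    if bands:
        for name, b in bands.items():
            cols.append(f"{name}_median")
            data.append(b.median_track)
            lines.append(f"# sigma_{name}={b.sigma!r}")
            lines.append(f"# center_{name}={b.center!r}")
    lines.append("# " + "\t".join(cols))
    for row in zip(*data):
        lines.append("\t".join(repr(float(v)) for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_measures(path: str | Path):
    """Inverse of :func:`write_measures`; returns (MeasureSeries, bands)."""
    from .embedding import EmbeddingParams
    from .sliding import MeasureSeries, SignificanceBands

    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    meta, body = _parse_headers(path)
    rows = np.array([[float(v) for v in line.split("\t")] for line in body])
    params = EmbeddingParams(tau=int(meta["tau"]), m=int(meta["m"]))
    series = MeasureSeries(
        mid_times=rows[:, 0], C=rows[:, 1], T=rows[:, 2], A=rows[:, 3],
        params=params, rr=float(meta["rr"]),
    )
    bands = {}
    col = 4
    for name in ("C", "T", "A"):
        key = f"sigma_{name}"
        if key in meta:
            bands[name] = SignificanceBands(
                median_track=rows[:, col], sigma=float(meta[key]),
                center=float(meta.get(f"center_{name}", 0.0)))
            col += 1
    return series, bands
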