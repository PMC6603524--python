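"""Closed-loop stimulation controller and the stop/onset classifiers.

While stimulation is off the controller watches one network measure
(clustering by default, the measure with the most abrupt pre-tremor peaks):
it averages the current window with its last ``memory_windows`` predecessors
and issues START when that average exceeds the subject's baseline by
``sigma_trigger`` standard deviations. While stimulation is on, a
per-patient support-vector classifier labels each incoming window and the
controller issues STOP on the first window classified NT. The trigger
memory only accumulates while stimulation is off and is cleared on STOP, so
a freshly re-armed trigger is not contaminated by tremor-era windows.

Classifier validity is reported as accuracy, sensitivity, specificity, FPR
and FNR from a pooled ten-fold cross-validated confusion matrix.
"""
from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .io import LabelTrack, ValidationError
from .sliding import MeasureSeries, SignificanceBands

Command = str  # "START" | "STOP" | "NONE"

# classify(time_s, features) -> state label; features is the (C, T, A) row
ClassifyFn = Callable[[float, np.ndarray], str]


@dataclass
class ValidityReport:
    """Percent accuracy, sensitivity, specificity, FPR and FNR."""

    acc: float
    sensitivity: float
    specificity: float
    fpr: float
    fnr: float

    @classmethod
    def from_confusion(cls, tp: int, fn: int, tn: int, fp: int) -> "ValidityReport":
        if tp + fn == 0 or tn + fp == 0:
            raise ValidationError("both classes must be present in the confusion matrix")
        sens = 100.0 * tp / (tp + fn)
        spec = 100.0 * tn / (tn + fp)
        acc = 100.0 * (tp + tn) / (tp + fn + tn + fp)
        return cls(acc=acc, sensitivity=sens, specificity=spec,
                   fpr=100.0 - spec, fnr=100.0 - sens)

    def as_row(self) -> dict[str, float]:
        return {"ACC": self.acc, "Sensitivity": self.sensitivity,
                "Specificity": self.specificity, "FPR": self.fpr, "FNR": self.fnr}


@dataclass
class ControllerState:
    """Mutable controller memory: stimulation flag, trigger buffer, baseline."""

    threshold: float                 # baseline median + sigma_trigger * sigma
    memory_windows: int = 4
    dbs_on: bool = False
    buffer: deque = field(default_factory=deque)

    def __post_init__(self) -> None:
        self.buffer = deque(self.buffer, maxlen=self.memory_windows)


@dataclass
class StimulationTrace:
    """Per-window controller log: (time_s, dbs_on, command)."""

    rows: list[tuple[float, bool, Command]] = field(default_factory=list)

    def append(self, time_s: float, dbs_on: bool, command: Command) -> None:
        if command == "START" and (self.commands() and self.commands()[-1] == "START"):
            raise ValidationError("START while already started")
        self.rows.append((time_s, dbs_on, command))

    def commands(self) -> list[Command]:
        return [c for _, _, c in self.rows if c != "NONE"]

    def command_times(self, command: Command) -> list[float]:
        return [t for t, _, c in self.rows if c == command]


def controller_step(state: ControllerState, value: float,
                    time_s: float = 0.0,
                    classify: ClassifyFn | None = None,
                    features: np.ndarray | None = None) -> Command:
    """Advance the controller by one window; mutates ``state``.

    Off: average the new value with the ``memory_windows`` buffered
    predecessors and START on a threshold crossing; the trigger stays armed
    only once the memory is full, so a freshly (re)started controller first
    gathers its four-window context. On: ask the classifier; STOP (and clear
    the trigger memory) when it answers NT.
    """
    if state.dbs_on:
        if classify is None:
            raise ValidationError("a stop classifier is required while DBS is on")
        label = classify(time_s, features if features is not None else np.array([value]))
        if label == "NT":
            state.dbs_on = False
            state.buffer.clear()
            return "STOP"
        return "NONE"
    armed = len(state.buffer) == state.memory_windows
    window = [v for v in (*state.buffer, value) if np.isfinite(v)]
    state.buffer.append(value)
    if armed and window and float(np.mean(window)) > state.threshold:
        state.dbs_on = True
        return "START"
    return "NONE"


def run_loop(series: MeasureSeries, bands: SignificanceBands,
             classify: ClassifyFn, measure: str = "C",
             sigma_trigger: float = 2.0, memory_windows: int = 4,
             smooth: bool = True) -> StimulationTrace:
    """Deterministic fold of :func:`controller_step` over the windows.

    The start threshold is the subject's horizontal significance band:
    baseline center + ``sigma_trigger`` times the bands' sigma. With
    ``smooth=True`` (default) the trigger consumes the median-filtered
    measure -- the same smoothed signal whose transients the significance
    analysis judges -- rather than the spiky per-window raw values; the stop
    classifier always sees the raw per-window features.
    """
    values = bands.median_track if smooth else series.values(measure)
    feats = np.column_stack([series.C, series.T, series.A])
    state = ControllerState(threshold=bands.center + sigma_trigger * bands.sigma,
                            memory_windows=memory_windows)
    trace = StimulationTrace()
    for i in range(series.n):
        cmd = controller_step(state, float(values[i]), time_s=float(series.mid_times[i]),
                              classify=classify, features=feats[i])
        trace.append(float(series.mid_times[i]), state.dbs_on, cmd)
    return trace


def oracle_classifier(labels: LabelTrack, margin_s: float = 1.0) -> ClassifyFn:
    """Label-reading stand-in for the SVM: answers NT only when the whole
    window (mid-time +/- ``margin_s``) lies inside an NT segment, else T.

    Used to exercise the control loop against construction-known ground
    truth, independent of any trained model.
    """

    def classify(time_s: float, features: np.ndarray) -> str:
        edges = (time_s - margin_s, time_s, time_s + margin_s - 1e-9)
        if all(labels.state_at(t) == "NT" for t in edges):
            return "NT"
        return "T"

    return classify


def sklearn_classifier(model, feature_builder=None) -> ClassifyFn:
    """Adapt a fitted sklearn estimator to the controller's classify protocol."""

    def classify(time_s: float, features: np.ndarray) -> str:
        x = np.asarray(features, dtype=float)[None, :]
        if feature_builder is not None:
            x = feature_builder(x)
        x = np.nan_to_num(x, nan=0.0)
        return str(model.predict(x)[0])

    return classify


# ---------------------------------------------------------------------------
# SVM training with cross-validated validity reporting
# ---------------------------------------------------------------------------

def build_features(series: MeasureSeries, memory_windows: int = 4) -> np.ndarray:
    """Per-window feature rows: (C, T, A) plus their trigger-memory means.

    NaNs (undefined assortativity, degenerate windows) are replaced by the
    column median so the SVM sees complete rows.
    """
    from .sliding import memory_average

    cols = [series.C, series.T, series.A]
    cols += [memory_average(c, memory_windows) for c in cols[:3]]
    x = np.column_stack(cols)
    med = np.nanmedian(x, axis=0)
    idx = np.where(np.isnan(x))
    x[idx] = np.take(med, idx[1])
    return x


def window_labels(mid_times: np.ndarray, labels: LabelTrack) -> np.ndarray:
    """State label of each window mid-time ('' outside any segment)."""
    return np.array([labels.state_at(t) or "" for t in mid_times])


def _train_classifier(x: np.ndarray, y: Sequence[str], positive: str,
                      n_folds: int = 10, seed: int = 0, kernel: str = "rbf",
                      cv: str = "stratified"):
    from .estimators import TremorStateClassifier

    clf = TremorStateClassifier(positive_class=positive, n_folds=n_folds,
                                random_state=seed, kernel=kernel, cv=cv)
    clf.fit(np.asarray(x, dtype=float), np.asarray(y))
    return clf, clf.report_


def train_stop_classifier(x: np.ndarray, y: Sequence[str], n_folds: int = 10,
                          seed: int = 0, kernel: str = "rbf",
                          cv: str = "stratified"):
    """NT-vs-T classifier for the stop decision; T is the positive class."""
    return _train_classifier(x, y, positive="T", n_folds=n_folds, seed=seed,
                             kernel=kernel, cv=cv)


def train_onset_classifier(x: np.ndarray, y: Sequence[str], n_folds: int = 10,
                           seed: int = 0, kernel: str = "rbf",
                           cv: str = "stratified"):
    """NT-vs-TO classifier for the (harder) start decision; NT is positive."""
    return _train_classifier(x, y, positive="NT", n_folds=n_folds, seed=seed,
                             kernel=kernel, cv=cv)
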