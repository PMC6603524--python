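"""scikit-learn style estimators wrapping the core pipeline stages.

`RecurrenceMeasureTransformer` turns an array of analysis windows into
per-window (C, T, A) network-measure features; `TremorStateClassifier` is
the per-patient support-vector classifier with its cross-validated validity
report. Both follow the sklearn estimator contract (get_params/set_params,
fitted attributes with trailing underscores), so they compose with sklearn
pipelines and model selection.
"""
from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.model_selection import GroupKFold, StratifiedKFold, cross_val_predict
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .embedding import EmbeddingParams, select_embedding
from .io import ValidationError
from .network import epsilon_for_rr, build_network, network_measures
from .decision import ValidityReport


class RecurrenceMeasureTransformer(TransformerMixin, BaseEstimator):
    """Window-wise recurrence-network features (clustering, transitivity,
    assortativity).

    Parameters
    ----------
    tau, m : int or "auto"
        Delay-embedding parameters. With "auto" they are selected during
        ``fit`` from the training windows (auto-mutual-information minimum
        and false-nearest-neighbours criterion) and then held fixed, which
        mirrors the once-per-recording selection of the analysis protocol.
    rr : float
        Recurrence rate fixing the edge density of every window's network.
    theiler : int
        Temporal-neighbour exclusion window (0 = none, the default protocol).
    select_n : int
        Number of leading training samples used for auto selection.

    Attributes
    ----------
    tau_, m_ : int
        The embedding parameters in effect after ``fit``.
    """

    def __init__(self, tau="auto", m="auto", rr=0.03, theiler=0,
                 tau_max=30, m_max=10, select_n=2000):
        self.tau = tau
        self.m = m
        self.rr = rr
        self.theiler = theiler
        self.tau_max = tau_max
        self.m_max = m_max
        self.select_n = select_n

    def fit(self, X, y=None):
        X = check_array(X)
        self.n_features_in_ = X.shape[1]
        if self.tau == "auto" or self.m == "auto":
            flat = X.ravel()[: self.select_n]
            params = select_embedding(flat, tau_max=self.tau_max, m_max=self.m_max)
            self.tau_ = params.tau if self.tau == "auto" else int(self.tau)
            self.m_ = params.m if self.m == "auto" else int(self.m)
        else:
            self.tau_, self.m_ = int(self.tau), int(self.m)
        return self

    def transform(self, X):
        check_is_fitted(self, "tau_")
        X = check_array(X)
        from .embedding import embed

        params = EmbeddingParams(tau=self.tau_, m=self.m_)
        out = np.full((X.shape[0], 3), np.nan)
        for i, row in enumerate(X):
            try:
                pts = embed(row, params)
                eps = epsilon_for_rr(pts, self.rr)
            except ValidationError:
                continue
            meas = network_measures(build_network(pts, eps, theiler=self.theiler))
            out[i] = (meas.clustering, meas.transitivity, meas.assortativity)
        return out

    def get_feature_names_out(self, input_features=None):
        return np.array(["clustering", "transitivity", "assortativity"])


class TremorStateClassifier(ClassifierMixin, BaseEstimator):
    """Per-patient RBF support-vector classifier of movement states.

    ``fit`` standardises the features, trains a class-balanced SVC and, when
    ``compute_report`` is set, aggregates ten-fold cross-validated
    predictions into a pooled confusion matrix reported as accuracy /
    sensitivity / specificity / FPR / FNR percentages (``report_``), with
    ``positive_class`` as the positive.

    ``cv="stratified"`` shuffles windows into stratified folds (the default
    protocol); ``cv="blocked"`` keeps temporally contiguous blocks together,
    which avoids leakage between heavily overlapping windows.
    """

    def __init__(self, positive_class="T", C=1.0, gamma="scale", kernel="rbf",
                 n_folds=10, cv="stratified", random_state=0, compute_report=True):
        self.positive_class = positive_class
        self.C = C
        self.gamma = gamma
        self.kernel = kernel
        self.n_folds = n_folds
        self.cv = cv
        self.random_state = random_state
        self.compute_report = compute_report

    def _make_pipeline(self):
        return Pipeline([
            ("scale", StandardScaler()),
            ("svc", SVC(C=self.C, gamma=self.gamma, kernel=self.kernel,
                        class_weight="balanced")),
        ])

    def fit(self, X, y):
        X, y = check_X_y(X, np.asarray(y, dtype=object))
        y = y.astype(str)
        self.classes_ = np.unique(y)
        if self.classes_.size < 2:
            raise ValidationError("training data must contain both classes")
        counts = {c: int(np.sum(y == c)) for c in self.classes_}
        if min(counts.values()) < self.n_folds:
            raise ValidationError(
                f"need at least {self.n_folds} samples per class, got {counts}")
        self.pipeline_ = self._make_pipeline().fit(X, y)
        if self.compute_report:
            self.report_ = self._cv_report(X, y)
        return self

    def _cv_report(self, X, y) -> ValidityReport:
        if self.cv == "blocked":
            groups = (np.arange(len(y)) * self.n_folds) // len(y)
            splitter = GroupKFold(n_splits=self.n_folds)
            pred = cross_val_predict(self._make_pipeline(), X, y,
                                     cv=splitter, groups=groups)
        else:
            splitter = StratifiedKFold(n_splits=self.n_folds, shuffle=True,
                                       random_state=self.random_state)
            pred = cross_val_predict(self._make_pipeline(), X, y, cv=splitter)
        pos = self.positive_class
        tp = int(np.sum((y == pos) & (pred == pos)))
        fn = int(np.sum((y == pos) & (pred != pos)))
        tn = int(np.sum((y != pos) & (pred != pos)))
        fp = int(np.sum((y != pos) & (pred == pos)))
        return ValidityReport.from_confusion(tp=tp, fn=fn, tn=tn, fp=fp)

    def predict(self, X):
        check_is_fitted(self, "pipeline_")
        return self.pipeline_.predict(check_array(X))

    def decision_function(self, X):
        check_is_fitted(self, "pipeline_")
        return self.pipeline_.decision_function(check_array(X))
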