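"""Classifiers used inside the selection loop and for evaluation.

Two small in-house learners are implemented because the selection loop calls
them tens of thousands of times and their tie behaviour must be exact:

* NBC  — Gaussian naive Bayes with class-frequency priors.
* NMSC — nearest mean classifier on features scaled by the pooled
  within-class standard deviation.

Support vector machines and random forests are deliberately thin adapters
over scikit-learn; the forest additionally exposes its out-of-bag error for
the peephole tie-break.

Ties everywhere break to the lower class code, and training accuracies are
exchanged as exact integer counts (:class:`AccuracyCount`) so that "same
highest accuracy" is an integer comparison, never a float one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from functools import total_ordering

import numpy as np

_LOG2PI = float(np.log(2.0 * np.pi))
_VALID_NAMES = ("nbc", "nmsc", "svm", "rf")


@dataclass(frozen=True)
class ClassifierSpec:
    """Named classifier + hyperparameters + seed (required for the forest)."""

    name: str = "nbc"
    hyperparameters: dict = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self):
        object.__setattr__(self, "name", self.name.lower())
        if self.name not in _VALID_NAMES:
            raise ValueError(f"unknown classifier {self.name!r}; expected one of {_VALID_NAMES}")
        if self.name == "rf" and self.seed is None:
            raise ValueError("the rf classifier is stochastic and requires a seed")


@total_ordering
@dataclass(frozen=True)
class AccuracyCount:
    """Exact accuracy as correct/total; compared by cross-multiplication."""

    correct: int
    total: int

    def __post_init__(self):
        if self.total <= 0:
            raise ValueError("total must be positive")
        if not 0 <= self.correct <= self.total:
            raise ValueError("correct must lie in [0, total]")

    @property
    def accuracy(self) -> float:
        return self.correct / self.total

    def as_fraction(self) -> Fraction:
        return Fraction(self.correct, self.total)

    def __eq__(self, other):
        if not isinstance(other, AccuracyCount):
            return NotImplemented
        return self.correct * other.total == other.correct * self.total

    def __lt__(self, other):
        if not isinstance(other, AccuracyCount):
            return NotImplemented
        return self.correct * other.total < other.correct * self.total

    def __hash__(self):
        return hash(self.as_fraction())


def default_var_floor(X) -> float:
    """Variance floor: 1e-9 × the mean per-feature variance of ``X``.

    Falls back to 1e-12 when the matrix is entirely constant, so that degenerate
    features never abort a fit.
    """
    X = np.asarray(X, dtype=float)
    v = float(X.var(axis=0, ddof=0).mean()) if X.size else 0.0
    return max(1e-9 * v, 1e-12)


# ---------------------------------------------------------------------------
# In-house predictors
# ---------------------------------------------------------------------------

class _GaussianNB:
    """Per-class, per-feature Gaussian model with frequency priors."""

    def __init__(self, classes, log_priors, means, variances):
        self.classes_ = classes          # ascending class codes present at fit
        self.log_priors_ = log_priors
        self.means_ = means              # (k, f)
        self.variances_ = variances      # (k, f), floored

    def log_joint(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = np.empty((X.shape[0], len(self.classes_)))
        for k in range(len(self.classes_)):
            ll = -0.5 * (_LOG2PI + np.log(self.variances_[k])
                         + (X - self.means_[k]) ** 2 / self.variances_[k])
            out[:, k] = self.log_priors_[k] + ll.sum(axis=1)
        return out

    def predict(self, X):
        scores = self.log_joint(X)
        return self.classes_[np.argmax(scores, axis=1)]  # argmax → lowest code on ties


class _NearestMeanScaled:
    """Nearest class mean in coordinates scaled by pooled within-class SD."""

    def __init__(self, classes, means, pooled_var):
        self.classes_ = classes
        self.means_ = means              # (k, f)
        self.pooled_var_ = pooled_var    # (f,), floored

    def distances(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = np.empty((X.shape[0], len(self.classes_)))
        for k in range(len(self.classes_)):
            out[:, k] = (((X - self.means_[k]) ** 2) / self.pooled_var_).sum(axis=1)
        return out

    def predict(self, X):
        return self.classes_[np.argmin(self.distances(X), axis=1)]


def fit_nbc(X, y, var_floor: float | None = None) -> _GaussianNB:
    """Fit the Gaussian naive Bayes model; variances are MLE, then floored."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=int)
    if X.shape[0] != len(y):
        raise ValueError("X rows and y length differ")
    if X.shape[0] == 0 or X.shape[1] == 0:
        raise ValueError("need at least one sample and one feature")
    if var_floor is None:
        var_floor = default_var_floor(X)
    classes = np.unique(y)
    n = len(y)
    means = np.empty((len(classes), X.shape[1]))
    variances = np.empty_like(means)
    log_priors = np.empty(len(classes))
    for k, c in enumerate(classes):
        Xc = X[y == c]
        means[k] = Xc.mean(axis=0)
        variances[k] = np.maximum(Xc.var(axis=0, ddof=0), var_floor)
        log_priors[k] = np.log(Xc.shape[0] / n)
    return _GaussianNB(classes, log_priors, means, variances)


def fit_nmsc(X, y, var_floor: float | None = None) -> _NearestMeanScaled:
    """Fit the nearest-mean-scaled model (pooled within-class variance)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=int)
    if X.shape[0] != len(y):
        raise ValueError("X rows and y length differ")
    if X.shape[0] == 0 or X.shape[1] == 0:
        raise ValueError("need at least one sample and one feature")
    if var_floor is None:
        var_floor = default_var_floor(X)
    classes = np.unique(y)
    means = np.empty((len(classes), X.shape[1]))
    ss = np.zeros(X.shape[1])
    for k, c in enumerate(classes):
        Xc = X[y == c]
        means[k] = Xc.mean(axis=0)
        ss += ((Xc - means[k]) ** 2).sum(axis=0)
    denom = max(len(y) - len(classes), 1)
    pooled = np.maximum(ss / denom, var_floor)
    return _NearestMeanScaled(classes, means, pooled)


def fit_classifier(spec: ClassifierSpec, X, y, var_floor: float | None = None):
    """Fit any supported classifier; returns an object with ``predict``."""
    if spec.name == "nbc":
        return fit_nbc(X, y, var_floor)
    if spec.name == "nmsc":
        return fit_nmsc(X, y, var_floor)
    if spec.name == "svm":
        from sklearn.svm import SVC
        hp = spec.hyperparameters
        model = SVC(kernel=hp.get("kernel", "linear"), C=hp.get("C", 1.0),
                    gamma=hp.get("gamma", "scale"))
        return model.fit(np.atleast_2d(X), y)
    if spec.name == "rf":
        model = _make_forest(spec)
        return model.fit(np.atleast_2d(X), y)
    raise AssertionError(spec.name)


def _make_forest(spec: ClassifierSpec, oob: bool = False):
    from sklearn.ensemble import RandomForestClassifier
    return RandomForestClassifier(
        n_estimators=int(spec.hyperparameters.get("n_trees", 500)),
        random_state=spec.seed,
        oob_score=oob,
        bootstrap=True,
        n_jobs=1,
    )


def rf_oob_error(X, y, spec: ClassifierSpec) -> float:
    """Out-of-bag error of a seeded random forest on ``(X, y)``."""
    if spec.name != "rf":
        raise ValueError("rf_oob_error requires an rf ClassifierSpec")
    model = _make_forest(spec, oob=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # tiny-n folds may leave a sample never OOB
        model.fit(np.atleast_2d(X), np.asarray(y))
    return 1.0 - float(model.oob_score_)


# ---------------------------------------------------------------------------
# Training accuracy (resubstitution / leave-one-out)
# ---------------------------------------------------------------------------

def training_accuracy(spec: ClassifierSpec, X, y,
                      mode: str = "loo",
                      var_floor: float | None = None) -> AccuracyCount:
    """Count training samples a classifier gets right.

    ``mode="loo"`` refits on each leave-one-out fold and scores the held-out
    sample; ``mode="resub"`` scores the fitted data.  A fold that empties a
    class is still evaluated — the model is fit on the remaining class only.
    The variance floor is derived once from the full matrix so every fold uses
    the same floor.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=int)
    if mode not in ("loo", "resub"):
        raise ValueError(f"mode must be 'loo' or 'resub', got {mode!r}")
    if X.shape[0] == 0:
        raise ValueError("empty sample matrix")
    if var_floor is None and spec.name in ("nbc", "nmsc"):
        var_floor = default_var_floor(X)
    n = X.shape[0]
    if mode == "resub":
        model = fit_classifier(spec, X, y, var_floor)
        correct = int((np.asarray(model.predict(X)) == y).sum())
        return AccuracyCount(correct, n)
    correct = 0
    idx = np.arange(n)
    for j in range(n):
        train = idx != j
        model = fit_classifier(spec, X[train], y[train], var_floor)
        if int(np.asarray(model.predict(X[j:j + 1]))[0]) == y[j]:
            correct += 1
    return AccuracyCount(correct, n)


# ---------------------------------------------------------------------------
# Vectorised per-candidate accuracy counts (the selection loop's hot path)
# ---------------------------------------------------------------------------

def _loo_class_stats(X, y, code):
    """Leave-one-out count/mean/variance of class ``code`` for every fold.

    Returns ``(cnt (s,), mean (s, f), var (s, f))`` where row j holds the
    class statistics with sample j removed (unchanged if j is not in the
    class).  Variances are MLE; empty-class folds yield cnt 0 and zeroed
    mean/variance (callers must mask them via cnt).
    """
    m = (np.asarray(y) == code)
    n_c = int(m.sum())
    contrib = np.where(m[:, None], X, 0.0)
    cnt = n_c - m.astype(int)
    loo_sum = X[m].sum(axis=0)[None, :] - contrib
    loo_sumsq = (X[m] ** 2).sum(axis=0)[None, :] - contrib ** 2
    safe = np.maximum(cnt, 1)[:, None]
    mean = loo_sum / safe
    var = np.maximum(loo_sumsq / safe - mean ** 2, 0.0)
    empty = (cnt == 0)[:, None]
    mean = np.where(empty, 0.0, mean)
    var = np.where(empty, 0.0, var)
    return cnt, mean, var


def _nbc_feature_ll(X, y, var_floor, mode):
    """Per-fold, per-feature, per-class Gaussian log density of each sample
    under the model it would be scored against, plus per-fold log priors."""
    s = X.shape[0]
    ll = {}
    log_prior = {}
    if mode == "resub":
        for c in (0, 1):
            Xc = X[y == c]
            mean = Xc.mean(axis=0)
            var = np.maximum(Xc.var(axis=0, ddof=0), var_floor)
            ll[c] = -0.5 * (_LOG2PI + np.log(var)[None, :] + (X - mean[None, :]) ** 2 / var[None, :])
            log_prior[c] = np.full(s, np.log(Xc.shape[0] / s))
        return ll, log_prior
    for c in (0, 1):
        cnt, mean, var = _loo_class_stats(X, y, c)
        var = np.maximum(var, var_floor)
        ll[c] = -0.5 * (_LOG2PI + np.log(var) + (X - mean) ** 2 / var)
        with np.errstate(divide="ignore"):
            log_prior[c] = np.where(cnt > 0, np.log(np.maximum(cnt, 1) / (s - 1)), -np.inf)
    return ll, log_prior


def _nmsc_feature_dist(X, y, var_floor, mode):
    """Per-fold, per-feature scaled squared distance of each sample to each
    class mean, with empty-class folds pushed to +inf."""
    s = X.shape[0]
    dist = {}
    if mode == "resub":
        means = {}
        ss = np.zeros(X.shape[1])
        for c in (0, 1):
            Xc = X[y == c]
            means[c] = Xc.mean(axis=0)
            ss += ((Xc - means[c][None, :]) ** 2).sum(axis=0)
        pooled = np.maximum(ss / max(s - 2, 1), var_floor)
        for c in (0, 1):
            dist[c] = (X - means[c][None, :]) ** 2 / pooled[None, :]
        return dist
    stats = {c: _loo_class_stats(X, y, c) for c in (0, 1)}
    cnt0, mean0, var0 = stats[0]
    cnt1, mean1, var1 = stats[1]
    ss_total = cnt0[:, None] * var0 + cnt1[:, None] * var1
    n_classes = (cnt0 > 0).astype(int) + (cnt1 > 0).astype(int)
    denom = np.maximum(cnt0 + cnt1 - n_classes, 1)[:, None]
    pooled = np.maximum(ss_total / denom, var_floor)
    for c, (cnt, mean, _) in stats.items():
        d = (X - mean) ** 2 / pooled
        dist[c] = np.where((cnt == 0)[:, None], np.inf, d)
    return dist


def candidate_accuracy_counts(X, y, prefix, candidates,
                              spec: ClassifierSpec,
                              mode: str = "loo",
                              var_floor: float | None = None) -> np.ndarray:
    """Training-accuracy correct counts for ``prefix + [g]`` for every ``g``.

    For NBC/NMSC this shares the prefix log-likelihood (or distance) across
    candidates, so one selection step costs O(samples × genes) instead of a
    refit per candidate; other classifiers fall back to a per-candidate loop.
    Returns an int array aligned with ``candidates`` (out of ``len(y)``).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=int)
    prefix = list(prefix)
    candidates = list(candidates)
    if mode not in ("loo", "resub"):
        raise ValueError(f"mode must be 'loo' or 'resub', got {mode!r}")
    if not candidates:
        return np.zeros(0, dtype=int)
    if spec.name not in ("nbc", "nmsc"):
        counts = [
            training_accuracy(spec, X[:, prefix + [g]], y, mode, var_floor).correct
            for g in candidates
        ]
        return np.asarray(counts, dtype=int)
    if var_floor is None:
        var_floor = default_var_floor(X)
    is_one = (y == 1)
    if spec.name == "nbc":
        ll, log_prior = _nbc_feature_ll(X, y, var_floor, mode)
        pre = {c: log_prior[c] + ll[c][:, prefix].sum(axis=1) for c in (0, 1)}
        score0 = pre[0][:, None] + ll[0][:, candidates]
        score1 = pre[1][:, None] + ll[1][:, candidates]
        pred_one = score1 > score0          # tie → class 0
    else:
        dist = _nmsc_feature_dist(X, y, var_floor, mode)
        pre = {c: dist[c][:, prefix].sum(axis=1) for c in (0, 1)}
        d0 = pre[0][:, None] + dist[0][:, candidates]
        d1 = pre[1][:, None] + dist[1][:, candidates]
        pred_one = d1 < d0                  # tie → class 0
    return (pred_one == is_one[:, None]).sum(axis=0).astype(int)
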