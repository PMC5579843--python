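"""Binary expertise classifiers: linear SVM, KNN, small neural network, LDA.

Labels are 1 = novice, 2 = expert.  Feature vectors hold the normalized
energy metrics — 4 for the instrument (WN, EP-N, ETK-N, ERK-N), 3 for
the arthroscope (EP-N, ETK-N, ERK-N), or all 7 concatenated.

Configurations mirror the reference pipeline: SVM with a linear kernel;
KNN with K = 3 and posterior Ki/K; a d->3->1 network (tanh hidden layer,
linear output regressed onto the {1, 2} targets, Levenberg-Marquardt
training with an internal 70/30 early-stopping split, outputs rounded to
the nearer target, ties at 1.5 to expert); and Fisher LDA with a
midpoint threshold between the projected class means.  Features are
z-scored with training statistics by default, since the normalized
metrics span two orders of magnitude.
"""

from __future__ import annotations

import enum
import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

__all__ = [
    "NOVICE_LABEL",
    "EXPERT_LABEL",
    "FeatureVector",
    "ClassifierKind",
    "ClassifierSpec",
    "TrainedModel",
    "fit",
    "predict",
]

logger = logging.getLogger(__name__)

NOVICE_LABEL = 1
EXPERT_LABEL = 2
VALID_FEATURE_COUNTS = (3, 4, 7)


class ClassifierKind(str, enum.Enum):
    SVM_LINEAR = "svm_linear"
    KNN = "knn"
    NN = "nn"
    LDA = "lda"


@dataclass(frozen=True)
class FeatureVector:
    """Per-subject classifier input: ordered normalized metrics plus label."""

    subject_id: str
    label: int  # 1 = novice, 2 = expert
    features: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "features", np.asarray(self.features, dtype=float))
        if self.label not in (NOVICE_LABEL, EXPERT_LABEL):
            raise ValueError(f"label must be 1 (novice) or 2 (expert), got {self.label}")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("features must be finite")


@dataclass(frozen=True)
class ClassifierSpec:
    kind: ClassifierKind = ClassifierKind.SVM_LINEAR
    k: int = 3  # KNN neighbor count; odd so binary votes cannot tie
    nn_hidden: int = 3
    nn_split: float = 0.7  # fraction of training data used for weight fitting
    svm_c: float = 1.0
    standardize: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", ClassifierKind(self.kind))
        if self.k < 1 or self.k % 2 == 0:
            raise ValueError("k must be odd and >= 1")
        if not 0 < self.nn_split < 1:
            raise ValueError("nn_split must lie in (0, 1)")
        if self.nn_hidden < 1:
            raise ValueError("nn_hidden must be >= 1")


@dataclass
class TrainedModel:
    spec: ClassifierSpec
    n_features: int
    mean: np.ndarray
    scale: np.ndarray
    _impl: object = field(repr=False, default=None)


def _stack(train: Sequence[FeatureVector]) -> tuple[np.ndarray, np.ndarray]:
    # classifier ops are dimension-agnostic; the {3, 4, 7} metric-set rule
    # is enforced where feature vectors are assembled from a cohort
    X = np.vstack([fv.features for fv in train])
    y = np.array([fv.label for fv in train])
    return X, y


# ---------------------------------------------------------------------------
# the d -> nn_hidden -> 1 network
# ---------------------------------------------------------------------------

class _TinyNet:
    """tanh hidden layer, linear output; squared-error fit onto targets {1, 2}.

    Trained by staged Levenberg-Marquardt: repeated damped-least-squares
    passes with a bounded evaluation budget per stage, keeping the weights
    with the lowest validation error on the held-out split (early
    stopping).  Small Tikhonov residuals keep the problem over-determined
    (LM needs at least as many residuals as parameters) and discourage
    runaway weights on separable data.
    """

    RIDGE = 1e-4
    STAGES = 25
    NFEV_PER_STAGE = 40
    PATIENCE = 5

    def __init__(self, d: int, hidden: int, split: float, seed: int):
        self.d = d
        self.hidden = hidden
        self.split = split
        self.seed = seed
        self.n_params = hidden * d + hidden + hidden + 1
        self.theta = np.zeros(self.n_params)

    def _unpack(self, theta):
        h, d = self.hidden, self.d
        w1 = theta[: h * d].reshape(h, d)
        b1 = theta[h * d : h * d + h]
        w2 = theta[h * d + h : h * d + 2 * h]
        b2 = theta[-1]
        return w1, b1, w2, b2

    def forward(self, X: np.ndarray, theta: Optional[np.ndarray] = None) -> np.ndarray:
        w1, b1, w2, b2 = self._unpack(self.theta if theta is None else theta)
        return np.tanh(X @ w1.T + b1) @ w2 + b2

    def fit(self, X: np.ndarray, y: np.ndarray) -> None:
        rng = np.random.default_rng(self.seed)
        n = X.shape[0]
        order = rng.permutation(n)
        n_fit = max(2, int(round(self.split * n)))
        fit_idx, val_idx = order[:n_fit], order[n_fit:]
        if len(val_idx) == 0:  # too few points for a holdout: train on all
            fit_idx, val_idx = order, order
        Xf, yf = X[fit_idx], y[fit_idx].astype(float)
        Xv, yv = X[val_idx], y[val_idx].astype(float)

        theta = rng.normal(0.0, 0.5, self.n_params)
        sqrt_ridge = np.sqrt(self.RIDGE)

        def residuals(th):
            return np.concatenate([self.forward(Xf, th) - yf, sqrt_ridge * th])

        best_theta = theta.copy()
        best_val = float(np.mean((self.forward(Xv, theta) - yv) ** 2))
        stale = 0
        for _ in range(self.STAGES):
            res = least_squares(
                residuals, theta, method="lm", max_nfev=self.NFEV_PER_STAGE
            )
            theta = res.x
            val = float(np.mean((self.forward(Xv, theta) - yv) ** 2))
            if val < best_val - 1e-12:
                best_val, best_theta, stale = val, theta.copy(), 0
            else:
                stale += 1
                if stale >= self.PATIENCE:
                    break
        self.theta = best_theta


# ---------------------------------------------------------------------------
# Fisher LDA with midpoint threshold
# ---------------------------------------------------------------------------

class _FisherLDA:
    """1-D Fisher projection w = Sw^-1 (mu_expert - mu_novice).

    The pooled within-class covariance is ridge-regularized by
    1e-6 * trace for singular cases; the decision boundary is the
    midpoint of the projected class means, so the classifier depends
    only on first and second moments.
    """

    def fit(self, X: np.ndarray, y: np.ndarray) -> None:
        Xn, Xe = X[y == NOVICE_LABEL], X[y == EXPERT_LABEL]
        mun, mue = Xn.mean(axis=0), Xe.mean(axis=0)
        scatter = np.zeros((X.shape[1], X.shape[1]))
        for Xc, mu in ((Xn, mun), (Xe, mue)):
            dev = Xc - mu
            scatter += dev.T @ dev
        sw = scatter / max(X.shape[0] - 2, 1)
        sw = sw + 1e-6 * np.trace(sw) * np.eye(X.shape[1])
        self.w = np.linalg.solve(sw, mue - mun)
        self.threshold = 0.5 * (mun @ self.w + mue @ self.w)
        # orient so that projections above threshold are expert
        if mue @ self.w < mun @ self.w:  # pragma: no cover - solve orients already
            self.w, self.threshold = -self.w, -self.threshold

    def score(self, X: np.ndarray) -> np.ndarray:
        return X @ self.w - self.threshold


# ---------------------------------------------------------------------------
# public fit / predict
# ---------------------------------------------------------------------------

def fit(spec: ClassifierSpec, train: Sequence[FeatureVector]) -> TrainedModel:
    """Train one classifier on per-subject feature vectors.

    Raises ``ValueError`` if only one class is present or, for KNN, if K
    exceeds the training size.
    """
    X, y = _stack(train)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training set contains a single class")
    if spec.standardize:
        mean = X.mean(axis=0)
        scale = X.std(axis=0)
        scale[scale == 0] = 1.0
    else:
        mean = np.zeros(X.shape[1])
        scale = np.ones(X.shape[1])
    Z = (X - mean) / scale

    kind = spec.kind
    if kind == ClassifierKind.SVM_LINEAR:
        impl = SVC(kernel="linear", C=spec.svm_c)
        impl.fit(Z, y)
    elif kind == ClassifierKind.KNN:
        if spec.k > len(train):
            raise ValueError(f"k={spec.k} exceeds training size {len(train)}")
        impl = KNeighborsClassifier(n_neighbors=spec.k)
        impl.fit(Z, y)
    elif kind == ClassifierKind.NN:
        max_hidden = X.shape[0] / X.shape[1]
        if spec.nn_hidden > max_hidden:
            msg = (
                f"nn_hidden={spec.nn_hidden} exceeds the N/d guideline "
                f"({X.shape[0]}/{X.shape[1]} = {max_hidden:.1f}); risk of overfitting"
            )
            logger.warning(msg)
            warnings.warn(msg, UserWarning, stacklevel=2)
        impl = _TinyNet(X.shape[1], spec.nn_hidden, spec.nn_split, spec.seed)
        impl.fit(Z, y)
    elif kind == ClassifierKind.LDA:
        impl = _FisherLDA()
        impl.fit(Z, y)
    else:  # pragma: no cover
        raise ValueError(f"unknown classifier kind {kind}")
    return TrainedModel(spec=spec, n_features=X.shape[1], mean=mean, scale=scale, _impl=impl)


def predict(model: TrainedModel, x: FeatureVector | np.ndarray) -> tuple[int, float]:
    """Predict the expertise label of one feature vector.

    Returns ``(label, score)`` where the score is classifier-specific:
    signed margin (SVM, positive toward expert), expert posterior Ki/K
    (KNN), the raw pre-rounding network output on the {1, 2} scale (NN),
    or the signed projected coordinate relative to the midpoint (LDA).
    """
    feats = x.features if isinstance(x, FeatureVector) else np.asarray(x, dtype=float)
    if feats.shape != (model.n_features,):
        raise ValueError(
            f"feature count {feats.shape} does not match training ({model.n_features},)"
        )
    z = (feats - model.mean) / model.scale
    kind = model.spec.kind
    if kind == ClassifierKind.SVM_LINEAR:
        margin = float(model._impl.decision_function(z[None, :])[0])
        # decision_function is positive for the larger label (expert = 2)
        label = EXPERT_LABEL if margin > 0 else NOVICE_LABEL
        return label, margin
    if kind == ClassifierKind.KNN:
        proba = model._impl.predict_proba(z[None, :])[0]
        expert_col = list(model._impl.classes_).index(EXPERT_LABEL)
        posterior = float(proba[expert_col])
        label = int(model._impl.predict(z[None, :])[0])
        return label, posterior
    if kind == ClassifierKind.NN:
        raw = float(np.clip(model._impl.forward(z[None, :])[0], 1.0, 2.0))
        label = EXPERT_LABEL if raw >= 1.5 else NOVICE_LABEL  # half-up: 1.5 -> expert
        return label, raw
    if kind == ClassifierKind.LDA:
        score = float(model._impl.score(z[None, :])[0])
        label = EXPERT_LABEL if score > 0 else NOVICE_LABEL
        return label, score
    raise ValueError(f"unknown classifier kind {kind}")  # pragma: no cover
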