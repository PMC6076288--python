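"""Linear decoders: soft-margin SVM and the flexible m-of-n (OR-of-ANDs) scheme.

The SVM separates target-odor population bins from distractor / baseline
bins at a fixed box constraint (C = 0.01 by default) and reports per-sample
functional margins and slacks.  The flexible decoder carries binary weights
(1 for solitary-target responders) and fires when the weighted activity
crosses a threshold: a raw spike-count sum against tau (analog) or a count
of co-active weighted neurons against m < n (digital) — equivalent to an
OR over all n-choose-m ANDs of weighted neurons.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from flexdecode.core import BinnedTensor
from flexdecode.characterize import Barcode

__all__ = [
    "SvmModel",
    "FlexDecoder",
    "ClassificationProbability",
    "train_svm",
    "svm_classify",
    "build_flex_weights",
    "flex_classify",
    "binarize_counts",
    "decide_bins",
    "classification_probability",
    "nearest_centroid_confusion",
]

DEFAULT_BOX_CONSTRAINT = 0.01


@dataclass(frozen=True)
class SvmModel:
    """Linear soft-margin SVM: decision is sign(weights . x + bias)."""

    weights: np.ndarray
    bias: float
    C: float
    margins: np.ndarray = field(default_factory=lambda: np.empty(0))
    slacks: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        object.__setattr__(self, "weights", np.asarray(self.weights, dtype=float).ravel())

    @property
    def n_features(self) -> int:
        return self.weights.size

    def score(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.shape[-1] != self.n_features:
            raise ValueError(
                f"expected vectors of length {self.n_features}, got {x.shape[-1]}"
            )
        return x @ self.weights + self.bias

    def objective(self) -> float:
        """Primal objective 0.5 ||w||^2 + C sum(slacks) at the stored solution."""
        return 0.5 * float(self.weights @ self.weights) + self.C * float(self.slacks.sum())

    def to_json(self) -> str:
        return json.dumps(
            {
                "weights": self.weights.tolist(),
                "bias": self.bias,
                "C": self.C,
                "margins": self.margins.tolist(),
                "slacks": self.slacks.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "SvmModel":
        d = json.loads(text)
        return cls(
            weights=np.array(d["weights"]),
            bias=float(d["bias"]),
            C=float(d["C"]),
            margins=np.array(d["margins"]),
            slacks=np.array(d["slacks"]),
        )


def train_svm(
    positive_bins: np.ndarray,
    negative_bins: np.ndarray,
    C: float = DEFAULT_BOX_CONSTRAINT,
    tol: float = 1e-8,
) -> SvmModel:
    """Fit the linear soft-margin SVM on per-bin population vectors.

    ``positive_bins`` / ``negative_bins`` are (n_samples, n_neurons) arrays
    (labels +1 / -1).  Deterministic given the data order.
    """
    pos = np.atleast_2d(np.asarray(positive_bins, dtype=float))
    neg = np.atleast_2d(np.asarray(negative_bins, dtype=float))
    if pos.shape[0] < 2 or neg.shape[0] < 2:
        raise ValueError("each class needs at least two samples")
    if pos.shape[1] != neg.shape[1]:
        raise ValueError("classes must share the feature dimension")
    X = np.vstack([pos, neg])
    y = np.concatenate([np.ones(pos.shape[0]), -np.ones(neg.shape[0])])
    clf = SVC(kernel="linear", C=C, tol=tol, shrinking=False)
    clf.fit(X, y)
    w = clf.coef_.ravel()
    b = float(clf.intercept_[0])
    margins = y * (X @ w + b)
    slacks = np.maximum(0.0, 1.0 - margins)
    return SvmModel(weights=w, bias=b, C=C, margins=margins, slacks=slacks)


def svm_classify(model: SvmModel, x: np.ndarray) -> bool:
    """Present iff the decision score is strictly positive (ties -> absent)."""
    return bool(model.score(np.asarray(x, dtype=float)) > 0)


@dataclass(frozen=True)
class FlexDecoder:
    """Binary weight vector plus a threshold: tau (analog) or m < n (digital)."""

    weights: np.ndarray
    m: int | None = None
    tau: float | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.weights)
        if not np.all(np.isin(w, (0, 1))):
            raise ValueError("flexible decoder weights must be binary")
        object.__setattr__(self, "weights", w.astype(np.int64))
        if self.n == 0:
            raise ValueError("no responsive neurons: weight vector is all zero")
        if self.m is not None and not 0 < self.m < self.n:
            raise ValueError(f"digital threshold m={self.m} must satisfy 0 < m < n={self.n}")

    @property
    def n(self) -> int:
        return int(self.weights.sum())

    def to_json(self) -> str:
        return json.dumps({"weights": self.weights.tolist(), "m": self.m, "tau": self.tau})

    @classmethod
    def from_json(cls, text: str) -> "FlexDecoder":
        d = json.loads(text)
        return cls(weights=np.array(d["weights"]), m=d["m"], tau=d["tau"])


def build_flex_weights(
    solitary_target_barcode: Barcode,
    m: int | None = None,
    tau: float | None = None,
) -> FlexDecoder:
    """Weights 1 for solitary-target responders, 0 otherwise; validates m < n."""
    return FlexDecoder(weights=solitary_target_barcode.labels.astype(int), m=m, tau=tau)


def default_analog_threshold(decoder: FlexDecoder, training_bins: np.ndarray, m: int) -> float:
    """tau = (m/n) * mean weighted score over solitary-target training bins."""
    scores = np.atleast_2d(np.asarray(training_bins, dtype=float)) @ decoder.weights
    return float(m / decoder.n * scores.mean())


def flex_classify(decoder: FlexDecoder, x: np.ndarray, mode: str = "analog") -> bool:
    """Threshold the weighted input: v.x >= tau (analog) or #active >= m (digital).

    In digital mode ``x`` is the per-bin binarized activity vector; the
    decision depends only on how many weight-1 neurons are active, never on
    which ones (the OR-of-ANDs property).
    """
    x = np.asarray(x, dtype=float)
    if x.shape != decoder.weights.shape:
        raise ValueError("input length must match the weight vector")
    if mode == "analog":
        if decoder.tau is None:
            raise ValueError("analog mode requires tau")
        return bool(decoder.weights @ x >= decoder.tau)
    if mode == "digital":
        if decoder.m is None:
            raise ValueError("digital mode requires m")
        if not np.all(np.isin(x, (0, 1))):
            raise ValueError("digital mode expects a binarized input vector")
        return bool(decoder.weights @ x >= decoder.m)
    raise ValueError(f"unknown mode {mode!r}")


def binarize_counts(tensor: BinnedTensor, thresholds: np.ndarray) -> np.ndarray:
    """Per-(neuron, trial, bin) activity: count strictly above the neuron's threshold.

    Thresholds come from the same mean + k*sd pre-stimulus criterion used
    for responder barcodes.
    """
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.shape != (tensor.n_neurons,):
        raise ValueError("one threshold per neuron required")
    return tensor.counts > thresholds[:, None, None]


def decide_bins(
    decoder: FlexDecoder,
    tensor: BinnedTensor,
    mode: str = "analog",
    thresholds: np.ndarray | None = None,
) -> np.ndarray:
    """(trial, bin) boolean decisions over a whole tensor."""
    if mode == "analog":
        if decoder.tau is None:
            raise ValueError("analog mode requires tau")
        scores = np.tensordot(decoder.weights, tensor.counts, axes=(0, 0))
        return scores >= decoder.tau
    if mode == "digital":
        if decoder.m is None:
            raise ValueError("digital mode requires m")
        if thresholds is None:
            raise ValueError("digital mode requires per-neuron binarization thresholds")
        active = binarize_counts(tensor, thresholds)
        n_active = np.tensordot(decoder.weights, active.astype(np.int64), axes=(0, 0))
        return n_active >= decoder.m
    raise ValueError(f"unknown mode {mode!r}")


def svm_decide_bins(model: SvmModel, tensor: BinnedTensor) -> np.ndarray:
    """(trial, bin) SVM decisions over a whole tensor."""
    scores = np.tensordot(model.weights, tensor.counts.astype(float), axes=(0, 0)) + model.bias
    return scores > 0


@dataclass(frozen=True)
class ClassificationProbability:
    """Per-bin fraction of trials classified 'present'."""

    probability: np.ndarray
    bin_starts: np.ndarray
    bin_width_s: float
    condition: str = ""
    n_trials: int = 0

    def __post_init__(self) -> None:
        p = np.asarray(self.probability, dtype=float)
        s = np.asarray(self.bin_starts, dtype=float)
        if p.shape != s.shape or p.ndim != 1:
            raise ValueError("probability and bin_starts must be matching 1-D arrays")
        if np.any((p < 0) | (p > 1)):
            raise ValueError("probabilities must lie in [0, 1]")
        object.__setattr__(self, "probability", p)
        object.__setattr__(self, "bin_starts", s)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "condition": self.condition,
                "bin_start_s": self.bin_starts,
                "probability": self.probability,
            }
        )


def classification_probability(
    decisions: np.ndarray,
    bin_starts: np.ndarray,
    bin_width_s: float,
    condition: str = "",
) -> ClassificationProbability:
    """Average (trial, bin) boolean decisions across trials."""
    d = np.asarray(decisions, dtype=bool)
    if d.ndim != 2 or d.shape[0] < 1:
        raise ValueError("decisions must be a non-empty (trial, bin) array")
    return ClassificationProbability(
        probability=d.mean(axis=0),
        bin_starts=np.asarray(bin_starts, dtype=float),
        bin_width_s=bin_width_s,
        condition=condition,
        n_trials=d.shape[0],
    )


def nearest_centroid_confusion(
    features: np.ndarray, labels: np.ndarray
) -> tuple[np.ndarray, pd.DataFrame]:
    """Leave-one-trial-out nearest-centroid classification, row-normalized.

    For each held-out trial the class centroids are recomputed from the
    remaining trials (of every class) and the trial is assigned to the
    nearest centroid in Euclidean distance.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if X.ndim != 2 or y.shape != (X.shape[0],):
        raise ValueError("features must be (n_trials, d) with one label each")
    classes = np.array(sorted(set(y.tolist())))
    for c in classes:
        if (y == c).sum() < 2:
            raise ValueError(f"class {c!r} needs at least two trials")
    counts = np.zeros((classes.size, classes.size), dtype=float)
    class_index = {c: i for i, c in enumerate(classes)}
    sums = {c: X[y == c].sum(axis=0) for c in classes}
    ns = {c: int((y == c).sum()) for c in classes}
    for i in range(X.shape[0]):
        dists = []
        for c in classes:
            s, n = sums[c], ns[c]
            if y[i] == c:
                centroid = (s - X[i]) / (n - 1)
            else:
                centroid = s / n
            dists.append(np.linalg.norm(X[i] - centroid))
        predicted = classes[int(np.argmin(dists))]
        counts[class_index[y[i]], class_index[predicted]] += 1
    fractions = counts / counts.sum(axis=1, keepdims=True)
    df = pd.DataFrame(fractions, index=classes, columns=classes)
    return fractions, df
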