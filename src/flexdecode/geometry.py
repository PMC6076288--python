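"""Population-trajectory geometry and contrast-enhancement statistics.

PCA operates on the neuron-dimension covariance of the concatenated
trial-averaged bins; each condition's trajectory has its first (pre-onset)
bin projection subtracted and is smoothed with a three-point moving
average.  Contrast enhancement is quantified with Pearson correlations of
1 s mean population vectors and paired t-tests across trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

from flexdecode.core import BinnedTensor, ResponseMatrix, split_conditions

__all__ = [
    "Trajectory",
    "CorrelationReport",
    "LdaResult",
    "moving_average3",
    "pca_trajectories",
    "lda_project",
    "ensemble_correlation",
    "matrix_correlation",
    "contrast_test",
    "linear_shift_prediction",
    "fit_shift_alpha",
    "temporal_pattern_correlation",
]


@dataclass(frozen=True)
class Trajectory:
    """Time-ordered low-dimensional coordinates of one condition's bins."""

    points: np.ndarray  # (n_bins, k)
    condition: str
    bin_starts: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        starts = np.asarray(self.bin_starts, dtype=float)
        if pts.ndim != 2 or starts.shape != (pts.shape[0],):
            raise ValueError("points must be (n_bins, k) with matching bin starts")
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "bin_starts", starts)

    def to_dataframe(self) -> pd.DataFrame:
        k = self.points.shape[1]
        df = pd.DataFrame(self.points, columns=[f"c{i + 1}" for i in range(k)])
        df.insert(0, "bin_start_s", self.bin_starts)
        df.insert(0, "condition", self.condition)
        return df


@dataclass(frozen=True)
class CorrelationReport:
    """Per-trial correlations between two conditions plus the paired test."""

    condition_a: str
    condition_b: str
    per_trial_r: np.ndarray
    mean_r: float
    sd_r: float
    p_value: float | None = None

    def to_dict(self) -> dict:
        return {
            "condition_a": self.condition_a,
            "condition_b": self.condition_b,
            "per_trial_r": self.per_trial_r.tolist(),
            "mean_r": self.mean_r,
            "sd_r": self.sd_r,
            "p_value": self.p_value,
        }


@dataclass(frozen=True)
class LdaResult:
    projections: np.ndarray  # (n_samples, k)
    directions: np.ndarray  # (n_features, k)
    eigenvalues: np.ndarray
    labels: np.ndarray
    degenerate: bool = False


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Make each column's largest-magnitude component positive (plot stability)."""
    out = vectors.copy()
    for j in range(out.shape[1]):
        i = np.argmax(np.abs(out[:, j]))
        if out[i, j] < 0:
            out[:, j] = -out[:, j]
    return out


def moving_average3(x: np.ndarray, axis: int = 0) -> np.ndarray:
    """Three-point moving average with shrinking windows at the ends.

    Linear in its input and point-count preserving.
    """
    x = np.asarray(x, dtype=float)
    x = np.moveaxis(x, axis, 0)
    n = x.shape[0]
    out = np.empty_like(x)
    for i in range(n):
        lo, hi = max(0, i - 1), min(n, i + 2)
        out[i] = x[lo:hi].mean(axis=0)
    return np.moveaxis(out, 0, axis)


def pca_trajectories(
    concatenated: ResponseMatrix,
    k: int = 3,
    baseline_subtract: bool = True,
    smooth: bool = True,
) -> list[Trajectory]:
    """Project concatenated bins on the top-k principal axes, per condition.

    The covariance is taken over all concatenated bins (mean-centred across
    bins); eigenvector signs are fixed for reproducibility.  Per condition
    the first bin's projection is subtracted and a three-point moving
    average applied.
    """
    if concatenated.n_bins < 2:
        raise ValueError("need at least two bins for a covariance")
    X = concatenated.values  # (n_neurons, n_bins)
    mean = X.mean(axis=1, keepdims=True)
    cov = np.cov(X)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1][:k]
    V = _fix_signs(evecs[:, order])  # (n_neurons, k)
    proj = (X - mean).T @ V  # (n_bins, k)

    trajectories = []
    cols = concatenated.block_columns()
    for block in concatenated.blocks:
        idx = cols[block.condition]
        pts = proj[idx]
        if baseline_subtract:
            pts = pts - pts[0]
        if smooth:
            pts = moving_average3(pts, axis=0)
        starts = block.window[0] + concatenated.bin_width_s * np.arange(block.n_bins)
        trajectories.append(
            Trajectory(points=pts, condition=block.condition, bin_starts=starts)
        )
    return trajectories


def pca_full(concatenated: ResponseMatrix) -> tuple[np.ndarray, np.ndarray]:
    """All eigenvalues / sign-fixed eigenvectors of the bin covariance (diagnostics)."""
    cov = np.cov(concatenated.values)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    return evals[order], _fix_signs(evecs[:, order])


def lda_project(
    samples: np.ndarray,
    labels: np.ndarray,
    k: int = 3,
    reg: float = 1e-6,
) -> LdaResult:
    """Fisher discriminant projection of labeled bin vectors.

    Solves the generalized eigenproblem of between- vs within-class scatter;
    a singular within-class scatter is ridge-regularized by
    ``reg * trace(Sw)/n`` on the diagonal.
    """
    X = np.asarray(samples, dtype=float)
    y = np.asarray(labels)
    if X.ndim != 2 or y.shape != (X.shape[0],):
        raise ValueError("samples must be (n_samples, n_features) with one label each")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("need at least two classes")
    n, d = X.shape
    overall = X.mean(axis=0)
    Sw = np.zeros((d, d))
    Sb = np.zeros((d, d))
    for c in classes:
        Xc = X[y == c]
        if Xc.shape[0] < 2:
            raise ValueError(f"class {c!r} needs at least two samples")
        mu = Xc.mean(axis=0)
        Sw += (Xc - mu).T @ (Xc - mu)
        Sb += Xc.shape[0] * np.outer(mu - overall, mu - overall)

    ridge = reg * np.trace(Sw) / d
    if ridge <= 0:
        ridge = reg
    try:
        evals, evecs = linalg.eigh(Sb, Sw)
    except linalg.LinAlgError:
        evals, evecs = linalg.eigh(Sb, Sw + ridge * np.eye(d))
    order = np.argsort(evals)[::-1][:k]
    W = _fix_signs(evecs[:, order])
    top = np.asarray(evals)[np.argsort(evals)[::-1][:k]]
    degenerate = bool(np.max(evals) < 1e-10)
    return LdaResult(
        projections=X @ W,
        directions=W,
        eigenvalues=top,
        labels=y,
        degenerate=degenerate,
    )


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return np.nan  # undefined for zero-variance vectors
    return float(np.corrcoef(a, b)[0, 1])


def ensemble_correlation(
    a: BinnedTensor,
    b: BinnedTensor,
    window_a: tuple[float, float] = (0.0, 1.0),
    window_b: tuple[float, float] | None = None,
    condition_a: str = "a",
    condition_b: str = "b",
) -> CorrelationReport:
    """Per-trial Pearson correlation of mean population vectors over a window.

    Trials are paired by index; the window defaults to the first second
    after onset for both tensors.
    """
    if a.neuron_ids != b.neuron_ids:
        raise ValueError("tensors must share neuron ids and order")
    if a.n_trials != b.n_trials:
        raise ValueError("per-trial correlation needs matched trial counts")
    if window_b is None:
        window_b = window_a
    ia, ib = a.bin_slice(window_a), b.bin_slice(window_b)
    if ia.size == 0 or ib.size == 0:
        raise ValueError("correlation window contains no bins")
    va = a.counts[:, :, ia].mean(axis=2)  # (neuron, trial)
    vb = b.counts[:, :, ib].mean(axis=2)
    rs = np.array([_pearson(va[:, t], vb[:, t]) for t in range(a.n_trials)])
    valid = rs[~np.isnan(rs)]
    return CorrelationReport(
        condition_a=condition_a,
        condition_b=condition_b,
        per_trial_r=rs,
        mean_r=float(valid.mean()) if valid.size else np.nan,
        sd_r=float(valid.std(ddof=1)) if valid.size > 1 else np.nan,
    )


def matrix_correlation(
    a: ResponseMatrix, b: ResponseMatrix, window: tuple[float, float] = (0.0, 1.0)
) -> float:
    """Pearson correlation of the trial-mean population vectors over a window."""
    if a.neuron_ids != b.neuron_ids:
        raise ValueError("matrices must share neuron ids and order")

    def mean_vec(m: ResponseMatrix) -> np.ndarray:
        (block,) = m.blocks
        starts = block.window[0] + m.bin_width_s * np.arange(block.n_bins)
        idx = np.flatnonzero((starts >= window[0] - 1e-9) & (starts < window[1] - 1e-9))
        return m.values[:, idx].mean(axis=1)

    return _pearson(mean_vec(a), mean_vec(b))


def contrast_test(solitary_rs: np.ndarray, sequential_rs: np.ndarray) -> float:
    """Two-sided paired t-test p-value on per-trial correlation values."""
    a = np.asarray(solitary_rs, dtype=float)
    b = np.asarray(sequential_rs, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be matching 1-D arrays")
    if a.size < 2:
        raise ValueError("need at least two pairs")
    diff = a - b
    if np.all(diff == diff[0]):
        # zero-variance difference: t is 0/0 (identical) or infinite (constant shift)
        return 1.0 if diff[0] == 0 else float(np.finfo(float).tiny)
    return float(stats.ttest_rel(a, b).pvalue)


def linear_shift_prediction(
    target: ResponseMatrix, distractor: ResponseMatrix, alpha: float
) -> ResponseMatrix:
    """Predicted sequential response: target + alpha * (target - distractor), >= 0."""
    if target.values.shape != distractor.values.shape:
        raise ValueError("matrices must share shapes")
    if target.neuron_ids != distractor.neuron_ids:
        raise ValueError("matrices must share neuron ids")
    pred = np.maximum(target.values + alpha * (target.values - distractor.values), 0.0)
    return ResponseMatrix(
        values=pred,
        neuron_ids=target.neuron_ids,
        bin_width_s=target.bin_width_s,
        blocks=target.blocks,
    )


def fit_shift_alpha(
    target: ResponseMatrix, distractor: ResponseMatrix, observed: ResponseMatrix
) -> float:
    """Least-squares alpha for the linear shift against an observed sequential matrix."""
    d = (target.values - distractor.values).ravel()
    r = (observed.values - target.values).ravel()
    denom = float(d @ d)
    if denom == 0:
        return 0.0
    return float(d @ r / denom)


def temporal_pattern_correlation(
    solitary: ResponseMatrix, sequential: ResponseMatrix
) -> tuple[np.ndarray, int]:
    """Per-neuron Pearson correlation between the two temporal response vectors.

    Returns (correlations with NaN for excluded zero-variance neurons,
    number excluded).
    """
    if solitary.values.shape != sequential.values.shape:
        raise ValueError("matrices must share shapes")
    if solitary.neuron_ids != sequential.neuron_ids:
        raise ValueError("matrices must share neuron ids")
    rs = np.array(
        [
            _pearson(solitary.values[i], sequential.values[i])
            for i in range(solitary.n_neurons)
        ]
    )
    return rs, int(np.isnan(rs).sum())
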