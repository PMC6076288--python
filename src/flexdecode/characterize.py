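"""Binary responsiveness / latency labeling and barcode set algebra.

A neuron is a responder when any trial-averaged 50 ms bin inside the
response window exceeds mean + k_sd * s.d. of its trial-averaged activity
in a 2 s pre-stimulus window (k_sd = 6.5 by default).  Latencies are the
first qualifying bin; "early" means the bin starts strictly before the
600 ms cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from flexdecode.core import BinnedTensor, ResponseMatrix

__all__ = [
    "Barcode",
    "LatencyVector",
    "responder_thresholds",
    "classify_responders",
    "compute_latency",
    "early_late",
    "consistent_set",
    "unique_consistent_set",
]

DEFAULT_K_SD = 6.5
DEFAULT_EARLY_CUTOFF_S = 0.6


@dataclass(frozen=True)
class Barcode:
    """Per-neuron boolean labels in the fixed neuron order."""

    labels: np.ndarray
    neuron_ids: tuple[str, ...]
    context: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=bool)
        if labels.ndim != 1 or labels.size != len(self.neuron_ids):
            raise ValueError("labels must be one boolean per neuron")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "neuron_ids", tuple(str(i) for i in self.neuron_ids))

    @property
    def n_neurons(self) -> int:
        return self.labels.size

    @property
    def count(self) -> int:
        return int(self.labels.sum())

    @property
    def fraction(self) -> float:
        return float(self.labels.mean())

    def members(self) -> frozenset[str]:
        return frozenset(np.array(self.neuron_ids)[self.labels])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"neuron_id": list(self.neuron_ids), "label": self.labels.astype(int)}
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, **context) -> "Barcode":
        df = pd.read_csv(path)
        return cls(
            labels=df["label"].to_numpy(bool),
            neuron_ids=tuple(df["neuron_id"].astype(str)),
            context=context,
        )


@dataclass(frozen=True)
class LatencyVector:
    """First qualifying bin per neuron; -1 / NaN mark never-qualifying neurons."""

    latency_bin: np.ndarray  # int, -1 = none
    latency_s: np.ndarray  # bin start time, NaN = none
    neuron_ids: tuple[str, ...]
    cutoff_s: float = DEFAULT_EARLY_CUTOFF_S

    def __post_init__(self) -> None:
        lb = np.asarray(self.latency_bin, dtype=int)
        ls = np.asarray(self.latency_s, dtype=float)
        if lb.shape != ls.shape or lb.ndim != 1 or lb.size != len(self.neuron_ids):
            raise ValueError("latency arrays must be one entry per neuron")
        if np.any((lb < 0) != np.isnan(ls)):
            raise ValueError("bin == -1 must coincide with time == NaN")
        object.__setattr__(self, "latency_bin", lb)
        object.__setattr__(self, "latency_s", ls)
        object.__setattr__(self, "neuron_ids", tuple(str(i) for i in self.neuron_ids))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "neuron_id": list(self.neuron_ids),
                "latency_bin": self.latency_bin,
                "latency_s": self.latency_s,
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _pre_stats(
    tensor: BinnedTensor, pre_window: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray]:
    """Mean and s.d. of the trial-averaged PSTH over the pre-stimulus bins."""
    idx = tensor.bin_slice(pre_window)
    if idx.size < 2:
        raise ValueError("pre-stimulus window must span at least two bins")
    psth = tensor.counts.mean(axis=1)[:, idx]
    return psth.mean(axis=1), psth.std(axis=1, ddof=1)


def responder_thresholds(
    tensor: BinnedTensor,
    pre_window: tuple[float, float],
    k_sd: float = DEFAULT_K_SD,
) -> np.ndarray:
    """Per-neuron threshold mean + k_sd * s.d. of pre-stimulus activity.

    A silent neuron (zero pre-stimulus s.d.) gets mean + 1/n_trials instead,
    so it must produce more than one evoked spike across trials in a bin.
    """
    mean, sd = _pre_stats(tensor, pre_window)
    eps = 1.0 / tensor.n_trials
    return np.where(sd > 0, mean + k_sd * sd, mean + eps)


def classify_responders(
    tensor: BinnedTensor,
    pre_window: tuple[float, float],
    response_window: tuple[float, float],
    k_sd: float = DEFAULT_K_SD,
    context: dict | None = None,
) -> Barcode:
    """Responsive iff any trial-averaged response-window bin exceeds the threshold."""
    thr = responder_thresholds(tensor, pre_window, k_sd)
    idx = tensor.bin_slice(response_window)
    if idx.size == 0:
        raise ValueError("response window contains no bins")
    psth = tensor.counts.mean(axis=1)[:, idx]
    labels = (psth > thr[:, None]).any(axis=1)
    ctx = {"criterion": f"mean+{k_sd}sd", "pre_window": pre_window, **(context or {})}
    return Barcode(labels=labels, neuron_ids=tensor.neuron_ids, context=ctx)


def compute_latency(
    matrix: ResponseMatrix,
    thresholds: np.ndarray,
    mode: str = "solitary",
    onset_s: float = 0.0,
    window_s: float = 4.0,
    cutoff_s: float = DEFAULT_EARLY_CUTOFF_S,
) -> LatencyVector:
    """First qualifying bin after ``onset_s`` within ``window_s``.

    ``solitary``: first bin whose trial-averaged count exceeds the neuron's
    threshold.  ``sequential``: first such bin at which, additionally, the
    first difference of the PSTH is positive.
    """
    if mode not in ("solitary", "sequential"):
        raise ValueError(f"unknown latency mode {mode!r}")
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.shape != (matrix.n_neurons,):
        raise ValueError("one threshold per neuron required")
    starts = None
    # bin start times of the (single-block) matrix
    if len(matrix.blocks) != 1:
        raise ValueError("latency expects a single-condition matrix")
    block = matrix.blocks[0]
    starts = block.window[0] + matrix.bin_width_s * np.arange(block.n_bins)
    in_win = (starts >= onset_s - 1e-9) & (starts < onset_s + window_s - 1e-9)
    idx = np.flatnonzero(in_win)
    if idx.size == 0:
        raise ValueError("no bins inside the latency window")

    psth = matrix.values
    above = psth[:, idx] > thresholds[:, None]
    if mode == "sequential":
        diff = np.diff(psth, axis=1, prepend=psth[:, :1])  # first bin has diff 0
        above &= diff[:, idx] > 0

    latency_bin = np.full(matrix.n_neurons, -1, dtype=int)
    latency_s = np.full(matrix.n_neurons, np.nan)
    any_hit = above.any(axis=1)
    first = above.argmax(axis=1)
    rel = first[any_hit]
    latency_bin[any_hit] = rel
    latency_s[any_hit] = starts[idx[rel]] - onset_s
    return LatencyVector(
        latency_bin=latency_bin,
        latency_s=latency_s,
        neuron_ids=matrix.neuron_ids,
        cutoff_s=cutoff_s,
    )


def early_late(latencies: LatencyVector, cutoff_s: float | None = None) -> Barcode:
    """Early iff a latency exists and its bin starts strictly before the cutoff."""
    cut = latencies.cutoff_s if cutoff_s is None else cutoff_s
    with np.errstate(invalid="ignore"):
        labels = (latencies.latency_bin >= 0) & (latencies.latency_s < cut)
    return Barcode(
        labels=labels, neuron_ids=latencies.neuron_ids, context={"cutoff_s": cut}
    )


def _check_aligned(barcodes: Sequence[Barcode]) -> None:
    if not barcodes:
        raise ValueError("need at least one barcode")
    ids = barcodes[0].neuron_ids
    for b in barcodes[1:]:
        if b.neuron_ids != ids:
            raise ValueError("barcodes must share the same neuron ids and order")


def consistent_set(barcodes: Sequence[Barcode]) -> Barcode:
    """Elementwise AND: neurons labeled in every barcode."""
    _check_aligned(barcodes)
    labels = np.logical_and.reduce([b.labels for b in barcodes])
    return Barcode(
        labels=labels, neuron_ids=barcodes[0].neuron_ids, context={"set": "consistent"}
    )


def unique_consistent_set(
    consistent: Barcode, distractor_barcodes: Sequence[Barcode]
) -> Barcode:
    """Consistent responders that respond to no distractor: AND NOT (OR of distractors)."""
    if distractor_barcodes:
        _check_aligned([consistent, *distractor_barcodes])
        distractor_any = np.logical_or.reduce([b.labels for b in distractor_barcodes])
        labels = consistent.labels & ~distractor_any
    else:
        labels = consistent.labels.copy()
    return Barcode(
        labels=labels,
        neuron_ids=consistent.neuron_ids,
        context={"set": "unique-consistent"},
    )
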