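"""Core data model: protocols, spike rasters, binned tensors, response matrices.

All spike times are in seconds relative to the protocol's alignment epoch
(t = 0 at that epoch's onset; pre-stimulus times are negative).  Bins are
half-open ``[left, right)`` so a 4 s window at 50 ms yields exactly 80
unambiguous bins.  Neuron ordering is the lexicographic order of the neuron
ids, fixed at construction, so barcodes and weight vectors are comparable
across stages.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Epoch",
    "StimulusProtocol",
    "SpikeRaster",
    "BinnedTensor",
    "ResponseMatrix",
    "Block",
    "bin_spikes",
    "trial_average",
    "concatenate_conditions",
    "split_conditions",
]

_TOL = 1e-9


@dataclass(frozen=True)
class Epoch:
    """One odor pulse: label plus onset/offset in seconds."""

    odor: str
    onset_s: float
    offset_s: float

    def __post_init__(self) -> None:
        if not self.offset_s > self.onset_s:
            raise ValueError(
                f"epoch {self.odor!r}: offset {self.offset_s} must exceed onset {self.onset_s}"
            )

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


@dataclass(frozen=True)
class StimulusProtocol:
    """Time-ordered, non-overlapping odor epochs plus trial count and alignment.

    ``alignment`` names the odor of the epoch whose onset defines t = 0;
    :meth:`aligned` returns a copy with all epoch times shifted accordingly.
    """

    epochs: tuple[Epoch, ...]
    trial_count: int
    alignment: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "epochs", tuple(self.epochs))
        if not self.epochs:
            raise ValueError("protocol must contain at least one epoch")
        if self.trial_count < 1:
            raise ValueError("trial_count must be a positive integer")
        for a, b in zip(self.epochs, self.epochs[1:]):
            if b.onset_s < a.offset_s:
                raise ValueError(
                    f"epochs must be time-ordered and non-overlapping: "
                    f"{a.odor!r} ends at {a.offset_s}, {b.odor!r} starts at {b.onset_s}"
                )
        if self.alignment not in {e.odor for e in self.epochs}:
            raise ValueError(f"alignment epoch {self.alignment!r} not present in protocol")

    @property
    def alignment_epoch(self) -> Epoch:
        for e in self.epochs:
            if e.odor == self.alignment:
                return e
        raise AssertionError("unreachable")  # __post_init__ guarantees presence

    def aligned(self) -> "StimulusProtocol":
        """Shift all epoch times so the alignment epoch's onset is t = 0."""
        t0 = self.alignment_epoch.onset_s
        if t0 == 0.0:
            return self
        shifted = tuple(
            Epoch(e.odor, e.onset_s - t0, e.offset_s - t0) for e in self.epochs
        )
        return replace(self, epochs=shifted)

    def to_json(self) -> str:
        return json.dumps(
            {
                "epochs": [
                    {"odor": e.odor, "onset_s": e.onset_s, "offset_s": e.offset_s}
                    for e in self.epochs
                ],
                "trial_count": self.trial_count,
                "alignment": self.alignment,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "StimulusProtocol":
        d = json.loads(text)
        epochs = tuple(Epoch(e["odor"], e["onset_s"], e["offset_s"]) for e in d["epochs"])
        return cls(epochs=epochs, trial_count=int(d["trial_count"]), alignment=d["alignment"])


def _order_ids(ids: Iterable[str]) -> tuple[str, ...]:
    return tuple(sorted({str(i) for i in ids}))


@dataclass(frozen=True)
class SpikeRaster:
    """Per-(neuron, trial) sorted spike times relative to the alignment onset.

    Trials are dense 1..trial_count.  Missing (neuron, trial) entries are
    treated as silent.
    """

    neuron_ids: tuple[str, ...]
    trial_count: int
    spikes: Mapping[tuple[str, int], np.ndarray]

    def __post_init__(self) -> None:
        object.__setattr__(self, "neuron_ids", _order_ids(self.neuron_ids))
        if self.trial_count < 1:
            raise ValueError("trial_count must be positive")
        clean: dict[tuple[str, int], np.ndarray] = {}
        known = set(self.neuron_ids)
        for (nid, trial), times in self.spikes.items():
            nid = str(nid)
            if nid not in known:
                raise ValueError(f"spike entry for unknown neuron {nid!r}")
            if not 1 <= trial <= self.trial_count:
                raise ValueError(f"trial index {trial} outside 1..{self.trial_count}")
            t = np.asarray(times, dtype=float)
            if t.ndim != 1:
                raise ValueError("spike times must be one-dimensional")
            if t.size > 1 and np.any(np.diff(t) < 0):
                raise ValueError(f"spike times for ({nid}, trial {trial}) are not sorted")
            clean[(nid, int(trial))] = t
        object.__setattr__(self, "spikes", clean)

    @property
    def n_neurons(self) -> int:
        return len(self.neuron_ids)

    def spike_times(self, neuron_id: str, trial: int) -> np.ndarray:
        return self.spikes.get((str(neuron_id), int(trial)), np.empty(0))

    def total_spikes(self) -> int:
        return int(sum(t.size for t in self.spikes.values()))

    # --- CSV interface: header `neuron_id,trial,spike_time_s` ---

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for nid in self.neuron_ids:
            for trial in range(1, self.trial_count + 1):
                for t in self.spike_times(nid, trial):
                    rows.append((nid, trial, t))
        return pd.DataFrame(rows, columns=["neuron_id", "trial", "spike_time_s"])

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        trial_count: int | None = None,
        neuron_ids: Sequence[str] | None = None,
    ) -> "SpikeRaster":
        required = {"neuron_id", "trial", "spike_time_s"}
        if not required.issubset(df.columns):
            raise ValueError(f"spike table must have columns {sorted(required)}")
        ids = _order_ids(neuron_ids if neuron_ids is not None else df["neuron_id"])
        n_trials = int(trial_count if trial_count is not None else df["trial"].max())
        spikes: dict[tuple[str, int], np.ndarray] = {}
        for (nid, trial), sub in df.groupby(["neuron_id", "trial"], sort=True):
            spikes[(str(nid), int(trial))] = np.sort(sub["spike_time_s"].to_numpy(float))
        return cls(neuron_ids=ids, trial_count=n_trials, spikes=spikes)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "SpikeRaster":
        return cls.from_dataframe(pd.read_csv(path), **kwargs)


def _n_bins(window: tuple[float, float], bin_width_s: float) -> int:
    start, end = window
    if not end > start:
        raise ValueError(f"window start {start} must precede end {end}")
    if bin_width_s <= 0:
        raise ValueError("bin width must be positive")
    length = end - start
    n = round(length / bin_width_s)
    if n < 1 or abs(n * bin_width_s - length) > _TOL * max(1.0, abs(length)):
        raise ValueError(
            f"bin width {bin_width_s} does not divide window length {length}"
        )
    return int(n)


@dataclass(frozen=True)
class BinnedTensor:
    """Spike counts indexed (neuron, trial, bin) over a half-open window."""

    counts: np.ndarray
    neuron_ids: tuple[str, ...]
    bin_width_s: float
    window: tuple[float, float]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 3:
            raise ValueError("counts must be (neuron, trial, bin)")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", counts.astype(np.int64))
        object.__setattr__(self, "neuron_ids", tuple(str(i) for i in self.neuron_ids))
        object.__setattr__(self, "window", (float(self.window[0]), float(self.window[1])))
        expected = _n_bins(self.window, self.bin_width_s)
        if counts.shape[0] != len(self.neuron_ids):
            raise ValueError("neuron axis does not match neuron_ids")
        if counts.shape[2] != expected:
            raise ValueError(f"expected {expected} bins, got {counts.shape[2]}")

    @property
    def n_neurons(self) -> int:
        return self.counts.shape[0]

    @property
    def n_trials(self) -> int:
        return self.counts.shape[1]

    @property
    def n_bins(self) -> int:
        return self.counts.shape[2]

    @property
    def bin_starts(self) -> np.ndarray:
        return self.window[0] + self.bin_width_s * np.arange(self.n_bins)

    def bin_slice(self, window: tuple[float, float]) -> np.ndarray:
        """Index array of the bins whose start falls inside ``window`` (half-open)."""
        starts = self.bin_starts
        lo, hi = window
        return np.flatnonzero((starts >= lo - _TOL) & (starts < hi - _TOL))


@dataclass(frozen=True)
class Block:
    """Provenance of one column block of a (possibly concatenated) matrix."""

    condition: str
    window: tuple[float, float]
    n_bins: int


@dataclass(frozen=True)
class ResponseMatrix:
    """Trial-averaged counts, (neuron, bin); provenance retained per column block."""

    values: np.ndarray
    neuron_ids: tuple[str, ...]
    bin_width_s: float
    blocks: tuple[Block, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError("values must be (neuron, bin)")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "neuron_ids", tuple(str(i) for i in self.neuron_ids))
        object.__setattr__(self, "blocks", tuple(self.blocks))
        if values.shape[0] != len(self.neuron_ids):
            raise ValueError("neuron axis does not match neuron_ids")
        if self.blocks and sum(b.n_bins for b in self.blocks) != values.shape[1]:
            raise ValueError("block bin counts do not sum to the column count")

    @property
    def n_neurons(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    @property
    def condition(self) -> str:
        return "+".join(b.condition for b in self.blocks)

    def block_columns(self) -> dict[str, np.ndarray]:
        """Column indices per block condition, in concatenation order."""
        out: dict[str, np.ndarray] = {}
        start = 0
        for b in self.blocks:
            out[b.condition] = np.arange(start, start + b.n_bins)
            start += b.n_bins
        return out

    def to_dataframe(self) -> pd.DataFrame:
        cols = []
        for b in self.blocks:
            starts = b.window[0] + self.bin_width_s * np.arange(b.n_bins)
            cols.extend(f"{b.condition}:{s:.3f}" for s in starts)
        return pd.DataFrame(self.values, index=list(self.neuron_ids), columns=cols)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index_label="neuron_id")


def bin_spikes(
    raster: SpikeRaster,
    bin_width_s: float = 0.05,
    window: tuple[float, float] = (0.0, 4.0),
) -> BinnedTensor:
    """Count spikes in half-open, non-overlapping bins of ``bin_width_s``.

    A spike at time t lands in bin k iff ``start + k*w <= t < start + (k+1)*w``;
    spikes outside the window are silently excluded.
    """
    n_bins = _n_bins(window, bin_width_s)
    start, end = window
    edges = start + bin_width_s * np.arange(n_bins + 1)
    edges[-1] = end  # guard the last edge against accumulation error
    counts = np.zeros((raster.n_neurons, raster.trial_count, n_bins), dtype=np.int64)
    for i, nid in enumerate(raster.neuron_ids):
        for trial in range(1, raster.trial_count + 1):
            t = raster.spike_times(nid, trial)
            if t.size == 0:
                continue
            t = t[(t >= start) & (t < end)]  # half-open window, end excluded
            if t.size == 0:
                continue
            idx = np.minimum(((t - start) / bin_width_s).astype(np.int64), n_bins - 1)
            # a spike numerically at an edge belongs to the right bin
            at_edge = t >= edges[np.minimum(idx + 1, n_bins)]
            idx = np.minimum(idx + at_edge, n_bins - 1)
            counts[i, trial - 1] = np.bincount(idx, minlength=n_bins)
    return BinnedTensor(
        counts=counts, neuron_ids=raster.neuron_ids, bin_width_s=bin_width_s, window=window
    )


def trial_average(tensor: BinnedTensor, condition: str = "") -> ResponseMatrix:
    """Arithmetic mean over trials; provenance recorded as a single block."""
    if tensor.n_trials < 1:
        raise ValueError("need at least one trial")
    values = tensor.counts.mean(axis=1)
    block = Block(condition=condition, window=tensor.window, n_bins=tensor.n_bins)
    return ResponseMatrix(
        values=values,
        neuron_ids=tensor.neuron_ids,
        bin_width_s=tensor.bin_width_s,
        blocks=(block,),
    )


def concatenate_conditions(matrices: Sequence[ResponseMatrix]) -> ResponseMatrix:
    """Stack response matrices along the time axis, keeping block provenance."""
    if not matrices:
        raise ValueError("nothing to concatenate")
    first = matrices[0]
    for m in matrices[1:]:
        if m.neuron_ids != first.neuron_ids:
            raise ValueError("all matrices must share the same neuron ids and order")
        if abs(m.bin_width_s - first.bin_width_s) > _TOL:
            raise ValueError("all matrices must share the same bin width")
    values = np.concatenate([m.values for m in matrices], axis=1)
    blocks = tuple(b for m in matrices for b in m.blocks)
    return ResponseMatrix(
        values=values,
        neuron_ids=first.neuron_ids,
        bin_width_s=first.bin_width_s,
        blocks=blocks,
    )


def split_conditions(matrix: ResponseMatrix) -> list[ResponseMatrix]:
    """Inverse of :func:`concatenate_conditions` via block provenance."""
    out = []
    start = 0
    for b in matrix.blocks:
        out.append(
            ResponseMatrix(
                values=matrix.values[:, start : start + b.n_bins],
                neuron_ids=matrix.neuron_ids,
                bin_width_s=matrix.bin_width_s,
                blocks=(b,),
            )
        )
        start += b.n_bins
    return out
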