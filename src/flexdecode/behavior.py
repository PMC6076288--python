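"""Palp-opening-response handling and the ON-OFF behavioral prediction model.

A trace counts as responsive when its in-stimulus peak exceeds baseline
mean + 6.5 s.d. and the trace stays above 20% of that peak for an
uninterrupted second.  Predicted PORs come from two flexible-decoder
probability traces: the ON probability drives palp opening, the OFF
probability drives closing; the rectified, thresholded difference is
low-pass filtered (first-order, causal) and clipped at zero.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from flexdecode.characterize import Barcode, DEFAULT_K_SD
from flexdecode.decoders import ClassificationProbability
from flexdecode.simulate import PORTrace

__all__ = [
    "PORTrace",
    "OnOffModelParams",
    "ParamLattice",
    "classify_por",
    "build_on_off_weights",
    "predict_por",
    "fit_on_off_params",
    "por_correlation",
    "resample_trace",
]


@dataclass(frozen=True)
class OnOffModelParams:
    """Binary ON/OFF templates plus the output-stage parameters."""

    theta_on: float
    theta_off: float
    gain: float
    tau_s: float
    v_on: np.ndarray | None = None
    v_off: np.ndarray | None = None
    overlap: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta_on <= 1.0 or not 0.0 <= self.theta_off <= 1.0:
            raise ValueError("probability thresholds must lie in [0, 1]")
        if self.gain < 0 or self.tau_s <= 0:
            raise ValueError("gain must be >= 0 and tau_s > 0")

    def to_json(self) -> str:
        return json.dumps(
            {
                "theta_on": self.theta_on,
                "theta_off": self.theta_off,
                "gain": self.gain,
                "tau_s": self.tau_s,
                "v_on": None if self.v_on is None else np.asarray(self.v_on).tolist(),
                "v_off": None if self.v_off is None else np.asarray(self.v_off).tolist(),
                "overlap": self.overlap,
            }
        )


@dataclass(frozen=True)
class ParamLattice:
    """Deterministic grid searched by :func:`fit_on_off_params`."""

    gains: np.ndarray = field(
        default_factory=lambda: np.geomspace(0.1, 10.0, 20)
    )
    thresholds: np.ndarray = field(
        default_factory=lambda: np.round(np.arange(0.0, 0.951, 0.05), 2)
    )
    taus: np.ndarray = field(default_factory=lambda: np.array([0.1, 0.25, 0.5, 1.0]))


def classify_por(
    trace: PORTrace,
    pre_window: tuple[float, float],
    stim_window: tuple[float, float],
    k_sd: float = DEFAULT_K_SD,
    sustain_fraction: float = 0.2,
    sustain_s: float = 1.0,
) -> bool:
    """Responsive iff peak > baseline mean + k_sd * s.d. AND the trace stays
    above ``sustain_fraction`` of that peak for an uninterrupted ``sustain_s``
    inside the stimulus window."""
    t, v = trace.times_s, trace.values
    base = v[(t >= pre_window[0]) & (t < pre_window[1])]
    if base.size < 2:
        raise ValueError("pre-stimulus baseline must span at least two samples")
    stim_mask = (t >= stim_window[0]) & (t < stim_window[1])
    stim = v[stim_mask]
    if stim.size == 0:
        raise ValueError("stimulus window contains no samples")
    peak = stim.max()
    if peak <= base.mean() + k_sd * base.std(ddof=1):
        return False
    above = stim > sustain_fraction * peak
    needed = int(np.ceil(sustain_s / trace.dt_s))
    longest = max(
        (len(list(g)) for val, g in itertools.groupby(above) if val), default=0
    )
    return longest >= needed


def build_on_off_weights(
    on_barcode: Barcode, off_barcode: Barcode
) -> tuple[np.ndarray, np.ndarray, float]:
    """Copy ON/OFF barcodes into binary weight vectors; report Jaccard overlap."""
    if on_barcode.neuron_ids != off_barcode.neuron_ids:
        raise ValueError("barcodes must share neuron ids and order")
    v_on = on_barcode.labels.astype(np.int64)
    v_off = off_barcode.labels.astype(np.int64)
    union = int(np.logical_or(v_on, v_off).sum())
    if union == 0:
        raise ValueError("both barcodes are empty")
    overlap = float(np.logical_and(v_on, v_off).sum() / union)
    return v_on, v_off, overlap


def _lowpass(drive: np.ndarray, dt_s: float, tau_s: float) -> np.ndarray:
    """Causal first-order low-pass: y[k] = a y[k-1] + (1-a) drive[k], a = exp(-dt/tau)."""
    a = np.exp(-dt_s / tau_s)
    return signal.lfilter([1.0 - a], [1.0, -a], drive)


def predict_por(
    p_on: ClassificationProbability,
    p_off: ClassificationProbability,
    params: OnOffModelParams,
) -> PORTrace:
    """ON-OFF model output: rectified thresholded probabilities, opened minus
    closed, low-pass filtered and clipped at zero."""
    if p_on.bin_starts.shape != p_off.bin_starts.shape or np.any(
        np.abs(p_on.bin_starts - p_off.bin_starts) > 1e-9
    ):
        raise ValueError("ON and OFF probabilities must share the same bin grid")
    drive = params.gain * (
        np.maximum(0.0, p_on.probability - params.theta_on)
        - np.maximum(0.0, p_off.probability - params.theta_off)
    )
    out = np.maximum(0.0, _lowpass(drive, p_on.bin_width_s, params.tau_s))
    return PORTrace(
        times_s=p_on.bin_starts,
        values=out,
        condition=p_on.condition or "predicted",
    )


def resample_trace(
    trace: PORTrace, bin_starts: np.ndarray, bin_width_s: float
) -> PORTrace:
    """Average trace samples within each decoder bin (bins past the trace end
    are held at the last available mean)."""
    bin_starts = np.asarray(bin_starts, dtype=float)
    out = np.empty(bin_starts.size)
    last = 0.0
    for i, s in enumerate(bin_starts):
        sel = (trace.times_s >= s - 1e-9) & (trace.times_s < s + bin_width_s - 1e-9)
        if sel.any():
            last = float(trace.values[sel].mean())
        out[i] = last
    return PORTrace(
        times_s=bin_starts, values=out, subject=trace.subject,
        trial=trace.trial, condition=trace.condition,
    )


def fit_on_off_params(
    observed: PORTrace,
    p_on: ClassificationProbability,
    p_off: ClassificationProbability,
    lattice: ParamLattice | None = None,
    v_on: np.ndarray | None = None,
    v_off: np.ndarray | None = None,
    overlap: float | None = None,
) -> OnOffModelParams:
    """Grid-search the lattice for the squared-error argmin against the mean
    observed solitary trained-odor POR.

    ``observed`` must already live on the decoder bin grid.  The search is
    deterministic; for each (theta_on, theta_off, tau) cell the gain axis is
    scanned exactly (clipping commutes with a positive gain).
    """
    if lattice is None:
        lattice = ParamLattice()
    if observed.times_s.shape != p_on.bin_starts.shape or np.any(
        np.abs(observed.times_s - p_on.bin_starts) > 1e-9
    ):
        raise ValueError("observed trace must be resampled to the probability bin grid")
    if np.allclose(observed.values, observed.values[0]):
        raise ValueError("observed POR is flat; nothing to fit")

    target = observed.values
    best: tuple[float, OnOffModelParams] | None = None
    for th_on in lattice.thresholds:
        on_part = np.maximum(0.0, p_on.probability - th_on)
        for th_off in lattice.thresholds:
            base_drive = on_part - np.maximum(0.0, p_off.probability - th_off)
            for tau in lattice.taus:
                z = np.maximum(0.0, _lowpass(base_drive, p_on.bin_width_s, tau))
                for g in lattice.gains:
                    sse = float(np.sum((target - g * z) ** 2))
                    if best is None or sse < best[0] - 1e-15:
                        best = (
                            sse,
                            OnOffModelParams(
                                theta_on=float(th_on),
                                theta_off=float(th_off),
                                gain=float(g),
                                tau_s=float(tau),
                                v_on=v_on,
                                v_off=v_off,
                                overlap=overlap,
                            ),
                        )
    assert best is not None
    return best[1]


def por_correlation(predicted: PORTrace, observed: PORTrace) -> float:
    """Pearson correlation over the common (identical) time grid; NaN when a
    trace has zero variance."""
    if predicted.times_s.shape != observed.times_s.shape or np.any(
        np.abs(predicted.times_s - observed.times_s) > 1e-9
    ):
        raise ValueError("traces must share the same time grid")
    a, b = predicted.values, observed.values
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])
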