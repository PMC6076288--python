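"""Seeded generator of projection-neuron ensembles with history cross-talk.

Stands in for undeposited recordings.  The latent structure per odor is an
ON set (transient-then-steady excitation), an inhibited set (firing pushed
below baseline) and an OFF set (elevated firing in a 4 s window starting
500 ms after offset, largely disjoint from the ON set).  In a two-odor
sequence the target-epoch response of a neuron is rescaled by
``suppression_factor`` when it also responds to the distractor, and by
``enhancement_factor`` when the distractor inhibits it — the cross-talk
rule the downstream contrast-enhancement analyses are built to detect.

Spiking is an inhomogeneous Poisson process sampled by thinning; a single
integer seed fixes every draw.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from typing import Mapping, Sequence

import numpy as np

from flexdecode.core import Epoch, SpikeRaster, StimulusProtocol

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "PORTrace",
    "sample_tuning",
    "apply_history_modulation",
    "simulate_trials",
    "simulate_por",
    "sequence_protocol",
]

OFF_DELAY_S = 0.5  # OFF window starts this long after stimulus offset
OFF_DURATION_S = 4.0


def _round_half_up(x: float) -> int:
    # round(0.30 * 85) must be 26 despite 0.30*85 == 25.4999...96 in floats
    return int(math.floor(x + 0.5 + 1e-9))


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic ensemble; every fraction lives in [0, 1]."""

    n_neurons: int = 85
    n_trials: int = 10
    odors: tuple[str, ...] = ("hex", "2oct", "iaa", "bzald", "cit", "app")
    baseline_rate_mean_hz: float = 3.0
    baseline_rate_sd_hz: float = 1.0
    responsive_fraction: float = 0.30
    inhibited_fraction: float = 0.10
    on_amplitude_hz: float = 20.0
    off_amplitude_hz: float = 15.0
    transient_duration_s: float = 1.25
    steady_fraction: float = 0.5
    off_fraction: float = 0.25
    off_overlap_with_on: float = 0.05
    inhibition_depth: float = 0.2
    suppression_factor: float = 0.4
    enhancement_factor: float = 1.5
    por_max: float = 1.0
    por_noise_sd: float = 0.02
    por_overlap_threshold: float = 0.05
    por_rise_tau_s: float = 0.5
    por_fall_tau_s: float = 0.15  # palps close fast (OFF-driven) after offset
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = {
            "responsive_fraction": self.responsive_fraction,
            "inhibited_fraction": self.inhibited_fraction,
            "off_fraction": self.off_fraction,
            "off_overlap_with_on": self.off_overlap_with_on,
            "inhibition_depth": self.inhibition_depth,
            "steady_fraction": self.steady_fraction,
        }
        for name, v in fracs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.responsive_fraction + self.inhibited_fraction > 1.0:
            raise ValueError("responsive_fraction + inhibited_fraction exceeds 1")
        if not 0.0 <= self.suppression_factor < 1.0:
            raise ValueError("suppression_factor must be in [0, 1)")
        if self.enhancement_factor <= 1.0:
            raise ValueError("enhancement_factor must exceed 1")
        for name in ("baseline_rate_mean_hz", "on_amplitude_hz", "off_amplitude_hz"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_neurons < 1 or self.n_trials < 1:
            raise ValueError("n_neurons and n_trials must be positive")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_mapping(cls, d: Mapping) -> "GeneratorConfig":
        d = dict(d)
        if "odors" in d:
            d["odors"] = tuple(d["odors"])
        return cls(**d)


@dataclass(frozen=True)
class GroundTruth:
    """Latent tuning exported for tests: per-odor ON/OFF/inhibited sets."""

    neuron_ids: tuple[str, ...]
    on_sets: Mapping[str, frozenset[str]]
    off_sets: Mapping[str, frozenset[str]]
    inhibited_sets: Mapping[str, frozenset[str]]
    baseline_rates_hz: Mapping[str, float]

    def on_mask(self, odor: str) -> np.ndarray:
        return np.array([n in self.on_sets[odor] for n in self.neuron_ids])

    def off_mask(self, odor: str) -> np.ndarray:
        return np.array([n in self.off_sets[odor] for n in self.neuron_ids])

    def inhibited_mask(self, odor: str) -> np.ndarray:
        return np.array([n in self.inhibited_sets[odor] for n in self.neuron_ids])

    def to_json(self) -> str:
        return json.dumps(
            {
                "neuron_ids": list(self.neuron_ids),
                "on_sets": {o: sorted(s) for o, s in self.on_sets.items()},
                "off_sets": {o: sorted(s) for o, s in self.off_sets.items()},
                "inhibited_sets": {o: sorted(s) for o, s in self.inhibited_sets.items()},
                "baseline_rates_hz": dict(self.baseline_rates_hz),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(
            neuron_ids=tuple(d["neuron_ids"]),
            on_sets={o: frozenset(s) for o, s in d["on_sets"].items()},
            off_sets={o: frozenset(s) for o, s in d["off_sets"].items()},
            inhibited_sets={o: frozenset(s) for o, s in d["inhibited_sets"].items()},
            baseline_rates_hz={n: float(r) for n, r in d["baseline_rates_hz"].items()},
        )


@dataclass(frozen=True)
class PORTrace:
    """Palp-distance (observed or predicted) versus time, uniformly sampled."""

    times_s: np.ndarray
    values: np.ndarray
    subject: str = ""
    trial: int = 0
    condition: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("times and values must be matching 1-D arrays")
        if t.size >= 2:
            dt = np.diff(t)
            if np.any(np.abs(dt - dt[0]) > 1e-9):
                raise ValueError("POR trace must be uniformly sampled")
        object.__setattr__(self, "times_s", t)
        object.__setattr__(self, "values", v)

    @property
    def dt_s(self) -> float:
        if self.times_s.size < 2:
            raise ValueError("trace too short to define a sampling step")
        return float(self.times_s[1] - self.times_s[0])


def _neuron_ids(n: int) -> tuple[str, ...]:
    width = max(3, len(str(n - 1)))
    return tuple(f"pn{i:0{width}d}" for i in range(n))


def sample_tuning(config: GeneratorConfig, rng: np.random.Generator | None = None) -> GroundTruth:
    """Draw per-odor ON / inhibited / OFF sets and per-neuron baseline rates.

    ON and inhibited sets are disjoint per odor; the OFF set respects the
    ``off_overlap_with_on`` cap (at most that fraction of the ON set may be
    shared).  Set sizes use round-half-up of fraction * n_neurons.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0]))
    ids = _neuron_ids(config.n_neurons)
    id_arr = np.array(ids)
    n = config.n_neurons

    n_on = _round_half_up(config.responsive_fraction * n)
    n_inh = _round_half_up(config.inhibited_fraction * n)
    n_off = _round_half_up(config.off_fraction * n)
    if n_on + n_inh > n:
        raise ValueError("responsive + inhibited fractions select more neurons than exist")

    # baseline rates: gamma matched to the configured mean / sd, floored at 0.1 Hz
    mean, sd = config.baseline_rate_mean_hz, config.baseline_rate_sd_hz
    if sd > 0:
        shape = (mean / sd) ** 2
        rates = rng.gamma(shape, scale=mean / shape, size=n)
    else:
        rates = np.full(n, mean)
    rates = np.maximum(rates, 0.1)

    on_sets: dict[str, frozenset[str]] = {}
    off_sets: dict[str, frozenset[str]] = {}
    inh_sets: dict[str, frozenset[str]] = {}
    for odor in config.odors:
        picked = rng.choice(n, size=n_on + n_inh, replace=False)
        on_idx = picked[:n_on]
        inh_idx = picked[n_on:]
        on_cap = int(math.floor(config.off_overlap_with_on * n_on + 1e-9))
        non_on = np.setdiff1d(np.arange(n), on_idx)
        n_from_on = max(0, n_off - non_on.size)
        if n_from_on > on_cap:
            raise ValueError("off_fraction too large to respect the ON-overlap cap")
        off_idx = rng.choice(non_on, size=n_off - n_from_on, replace=False)
        if n_from_on:
            off_idx = np.concatenate([off_idx, rng.choice(on_idx, size=n_from_on, replace=False)])
        on_sets[odor] = frozenset(id_arr[on_idx])
        inh_sets[odor] = frozenset(id_arr[inh_idx])
        off_sets[odor] = frozenset(id_arr[off_idx])

    return GroundTruth(
        neuron_ids=ids,
        on_sets=on_sets,
        off_sets=off_sets,
        inhibited_sets=inh_sets,
        baseline_rates_hz={nid: float(r) for nid, r in zip(ids, rates)},
    )


def apply_history_modulation(
    gt: GroundTruth, config: GeneratorConfig, sequence: tuple[str, str]
) -> dict[str, float]:
    """Per-neuron scale factor on the target-epoch evoked amplitude.

    Neurons responding to both odors are scaled by ``suppression_factor``;
    neurons the distractor inhibits but the target excites are scaled by
    ``enhancement_factor``; everything else is unchanged.
    """
    distractor, target = sequence
    for odor in sequence:
        if odor not in gt.on_sets:
            raise KeyError(f"odor {odor!r} has no tuning in the ground truth")
    factors: dict[str, float] = {}
    for nid in gt.neuron_ids:
        f = 1.0
        if nid in gt.on_sets[target]:
            if nid in gt.on_sets[distractor]:
                f = config.suppression_factor
            elif nid in gt.inhibited_sets[distractor]:
                f = config.enhancement_factor
        factors[nid] = f
    return factors


def sequence_protocol(
    target: str,
    distractor: str | None = None,
    pulse_s: float = 4.0,
    gap_s: float = OFF_DELAY_S,
    trial_count: int = 10,
) -> StimulusProtocol:
    """Solitary or distractor-then-target protocol aligned to the target onset."""
    epochs = []
    if distractor is not None:
        epochs.append(Epoch(distractor, -(pulse_s + gap_s), -gap_s))
    epochs.append(Epoch(target, 0.0, pulse_s))
    return StimulusProtocol(epochs=tuple(epochs), trial_count=trial_count, alignment=target)


def _rate_profile(
    gt: GroundTruth,
    config: GeneratorConfig,
    protocol: StimulusProtocol,
    nid: str,
    t: np.ndarray,
) -> np.ndarray:
    """Instantaneous firing rate (Hz) of one neuron over time points ``t``."""
    epochs = protocol.aligned().epochs
    base = gt.baseline_rates_hz[nid]
    rate = np.full(t.shape, base, dtype=float)
    prev_odor: str | None = None
    for ep in epochs:
        factor = 1.0
        if prev_odor is not None:
            factor = apply_history_modulation(gt, config, (prev_odor, ep.odor))[nid]
        in_ep = (t >= ep.onset_s) & (t < ep.offset_s)
        if nid in gt.inhibited_sets[ep.odor]:
            rate[in_ep] = base * config.inhibition_depth
        elif nid in gt.on_sets[ep.odor]:
            amp = config.on_amplitude_hz * factor
            sf, tau = config.steady_fraction, config.transient_duration_s
            decay = sf + (1.0 - sf) * np.exp(-(t[in_ep] - ep.onset_s) / tau)
            rate[in_ep] = base + amp * decay
        prev_odor = ep.odor
    # OFF ensembles are additive so they can bridge into a following epoch
    for ep in epochs:
        if nid in gt.off_sets[ep.odor]:
            lo = ep.offset_s + OFF_DELAY_S
            in_off = (t >= lo) & (t < lo + OFF_DURATION_S)
            rate[in_off] += config.off_amplitude_hz
    return np.maximum(rate, 0.0)


def _max_rate(gt: GroundTruth, config: GeneratorConfig, nid: str) -> float:
    base = gt.baseline_rates_hz[nid]
    return (
        base
        + config.on_amplitude_hz * config.enhancement_factor
        + config.off_amplitude_hz
    )


def simulate_trials(
    config: GeneratorConfig,
    protocol: StimulusProtocol,
    gt: GroundTruth | None = None,
    span: tuple[float, float] | None = None,
    stream: int = 1,
) -> tuple[SpikeRaster, GroundTruth]:
    """Inhomogeneous-Poisson spike trains for every neuron and trial.

    ``span`` is the simulated time range relative to the alignment onset;
    by default it runs from 2.5 s before the first epoch to 5 s after the
    last offset (covering the pre-stimulus baseline and the OFF window).
    ``stream`` decorrelates rasters simulated for different conditions under
    the same seed.
    """
    if gt is None:
        gt = sample_tuning(config)
    aligned = protocol.aligned()
    if span is None:
        span = (aligned.epochs[0].onset_s - 2.5, aligned.epochs[-1].offset_s + 5.0)
    t_lo, t_hi = span
    if t_lo > aligned.epochs[0].onset_s or t_hi < aligned.epochs[-1].offset_s:
        raise ValueError("protocol epochs must lie within the simulated span")
    duration = t_hi - t_lo

    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), int(stream)]))
    spikes: dict[tuple[str, int], np.ndarray] = {}
    for nid in gt.neuron_ids:
        lam = _max_rate(gt, config, nid)
        for trial in range(1, protocol.trial_count + 1):
            n_cand = rng.poisson(lam * duration)
            cand = np.sort(rng.uniform(t_lo, t_hi, size=n_cand))
            keep = rng.uniform(size=n_cand) * lam < _rate_profile(gt, config, aligned, nid, cand)
            spikes[(nid, trial)] = cand[keep]
    raster = SpikeRaster(
        neuron_ids=gt.neuron_ids, trial_count=protocol.trial_count, spikes=spikes
    )
    return raster, gt


def expected_rate(
    config: GeneratorConfig,
    protocol: StimulusProtocol,
    gt: GroundTruth,
    neuron_id: str,
    t: np.ndarray,
) -> np.ndarray:
    """Closed-form rate profile used by the sampler (exposed for oracle tests)."""
    return _rate_profile(gt, config, protocol.aligned(), str(neuron_id), np.asarray(t, float))


def simulate_por(
    gt: GroundTruth,
    config: GeneratorConfig,
    trained_odor: str,
    protocol: StimulusProtocol,
    presented_odor: str | None = None,
    dt_s: float = 0.05,
    span: tuple[float, float] | None = None,
    trial: int = 1,
    subject: str = "locust1",
    stream: int = 2,
) -> PORTrace:
    """Smooth synthetic palp-opening trace with seeded observation noise.

    The amplitude is ``por_max`` scaled by the fractional overlap of the
    presented odor's ON set with the trained odor's ON set, gated by
    ``por_overlap_threshold``; the rise after target onset is a saturating
    exponential with time constant ``por_rise_tau_s``.
    """
    if trained_odor not in gt.on_sets:
        raise KeyError(f"trained odor {trained_odor!r} has no tuning")
    aligned = protocol.aligned()
    if presented_odor is None:
        presented_odor = aligned.alignment
    if presented_odor not in gt.on_sets:
        raise KeyError(f"presented odor {presented_odor!r} has no tuning")
    if span is None:
        span = (aligned.epochs[0].onset_s - 2.5, aligned.epochs[-1].offset_s + 5.0)
    t = span[0] + dt_s * np.arange(int(round((span[1] - span[0]) / dt_s)))

    trained = gt.on_sets[trained_odor]
    presented = gt.on_sets[presented_odor]
    overlap = len(trained & presented) / len(trained) if trained else 0.0
    amp = config.por_max * overlap if overlap >= config.por_overlap_threshold else 0.0

    onset = aligned.alignment_epoch.onset_s
    offset = aligned.alignment_epoch.offset_s
    shape = np.zeros_like(t)
    rising = (t >= onset) & (t < offset)
    shape[rising] = 1.0 - np.exp(-(t[rising] - onset) / config.por_rise_tau_s)
    falling = t >= offset
    peak = 1.0 - np.exp(-(offset - onset) / config.por_rise_tau_s)
    shape[falling] = peak * np.exp(-(t[falling] - offset) / config.por_fall_tau_s)

    rng = np.random.default_rng(
        np.random.SeedSequence([int(config.seed), int(stream), int(trial)])
    )
    values = amp * shape + rng.normal(0.0, config.por_noise_sd, size=t.size)
    return PORTrace(
        times_s=t,
        values=values,
        subject=subject,
        trial=trial,
        condition=f"{presented_odor}|trained={trained_odor}",
    )
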