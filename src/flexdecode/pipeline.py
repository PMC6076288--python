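"""Configuration-driven end-to-end runs: simulate -> characterize ->
geometry -> decode -> behavior, with every stage artifact written to a run
directory.  A run is a pure function of (config, seed): rerunning with the
same config yields byte-identical numerical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from flexdecode import behavior, characterize, decoders, geometry
from flexdecode.core import (
    SpikeRaster,
    StimulusProtocol,
    bin_spikes,
    concatenate_conditions,
    trial_average,
)
from flexdecode.simulate import (
    OFF_DELAY_S,
    OFF_DURATION_S,
    GeneratorConfig,
    GroundTruth,
    sample_tuning,
    sequence_protocol,
    simulate_por,
    simulate_trials,
)

__all__ = ["RunConfig", "run_pipeline", "load_config"]

log = logging.getLogger("flexdecode")

PULSE_S = 4.0


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce a run: generator block + analysis knobs."""

    simulate: GeneratorConfig = dataclasses.field(default_factory=GeneratorConfig)
    target: str = "hex"
    distractors: tuple[str, ...] = ("2oct", "iaa", "bzald", "cit", "app")
    bin_width_s: float = 0.05
    k_sd: float = 6.5
    latency_cutoff_s: float = 0.6
    svm_C: float = 0.01
    flex_m: int = 4
    pca_k: int = 3

    def __post_init__(self) -> None:
        if self.target not in self.simulate.odors:
            raise ValueError(f"target {self.target!r} missing from simulated odors")
        missing = set(self.distractors) - set(self.simulate.odors)
        if missing:
            raise ValueError(f"distractors missing from simulated odors: {sorted(missing)}")
        n_on = round(self.simulate.responsive_fraction * self.simulate.n_neurons)
        if self.flex_m >= n_on:
            raise ValueError(
                f"decoder stage: digital threshold m={self.flex_m} must be below the "
                f"expected responsive-set size n={n_on}"
            )

    @classmethod
    def from_mapping(cls, d: Mapping) -> "RunConfig":
        d = dict(d)
        sim = d.pop("simulate", {})
        if "distractors" in d:
            d["distractors"] = tuple(d["distractors"])
        return cls(simulate=GeneratorConfig.from_mapping(sim), **d)

    def to_mapping(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulate"] = dataclasses.asdict(self.simulate)
        d["distractors"] = list(self.distractors)
        d["simulate"]["odors"] = list(self.simulate.odors)
        return d


def load_config(path, seed: int | None = None) -> RunConfig:
    """Read a YAML/JSON run config; an explicit ``seed`` overrides the file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if seed is not None:
        raw.setdefault("simulate", {})["seed"] = int(seed)
    return RunConfig.from_mapping(raw)


def _conditions(config: RunConfig) -> dict[str, StimulusProtocol]:
    """All simulated conditions keyed by label, aligned to the relevant onset."""
    n_trials = config.simulate.n_trials
    conds = {config.target: sequence_protocol(config.target, trial_count=n_trials)}
    for d in config.distractors:
        conds[d] = sequence_protocol(d, trial_count=n_trials)
        conds[f"{d}-{config.target}"] = sequence_protocol(
            config.target, distractor=d, trial_count=n_trials
        )
    return conds


def simulate_stage(config: RunConfig, outdir: Path) -> tuple[GroundTruth, dict[str, SpikeRaster]]:
    gt = sample_tuning(config.simulate)
    conds = _conditions(config)
    rasters: dict[str, SpikeRaster] = {}
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "ground_truth.json").write_text(gt.to_json())
    for stream, (label, protocol) in enumerate(sorted(conds.items()), start=10):
        raster, _ = simulate_trials(config.simulate, protocol, gt=gt, stream=stream)
        rasters[label] = raster
        raster.to_csv(outdir / f"raster_{label}.csv")
        (outdir / f"protocol_{label}.json").write_text(protocol.to_json())
        log.info("simulated condition %s: %d spikes", label, raster.total_spikes())
    return gt, rasters


def _pre_window(protocol: StimulusProtocol) -> tuple[float, float]:
    first = protocol.aligned().epochs[0].onset_s
    return (first - 2.0, first)


def _full_window(protocol: StimulusProtocol) -> tuple[float, float]:
    aligned = protocol.aligned()
    return (aligned.epochs[0].onset_s - 2.0, aligned.epochs[-1].offset_s + 5.0)


def characterize_stage(
    config: RunConfig, rasters: dict[str, SpikeRaster], outdir: Path
) -> dict:
    """Barcodes, latencies and set algebra for every condition."""
    outdir.mkdir(parents=True, exist_ok=True)
    conds = _conditions(config)
    target_conditions = [config.target] + [f"{d}-{config.target}" for d in config.distractors]
    barcodes: dict[str, characterize.Barcode] = {}
    latencies: dict[str, characterize.LatencyVector] = {}
    tensors: dict[str, object] = {}
    thresholds: dict[str, np.ndarray] = {}
    for label, protocol in conds.items():
        tensor = bin_spikes(rasters[label], config.bin_width_s, _full_window(protocol))
        tensors[label] = tensor
        pre = _pre_window(protocol)
        thr = characterize.responder_thresholds(tensor, pre, config.k_sd)
        thresholds[label] = thr
        barcodes[label] = characterize.classify_responders(
            tensor, pre, (0.0, PULSE_S), config.k_sd, context={"condition": label}
        )
        matrix = trial_average(tensor, label)
        mode = "sequential" if "-" in label else "solitary"
        latencies[label] = characterize.compute_latency(
            matrix, thr, mode=mode, onset_s=0.0, window_s=PULSE_S,
            cutoff_s=config.latency_cutoff_s,
        )
        barcodes[label].to_csv(outdir / f"barcode_{label}.csv")
        latencies[label].to_csv(outdir / f"latency_{label}.csv")
    consistent = characterize.consistent_set([barcodes[c] for c in target_conditions])
    unique = characterize.unique_consistent_set(
        consistent, [barcodes[d] for d in config.distractors]
    )
    consistent.to_csv(outdir / "barcode_consistent.csv")
    unique.to_csv(outdir / "barcode_unique_consistent.csv")
    log.info(
        "characterize: consistent=%d unique-consistent=%d (of %d neurons)",
        consistent.count, unique.count, consistent.n_neurons,
    )
    return {
        "barcodes": barcodes,
        "latencies": latencies,
        "tensors": tensors,
        "thresholds": thresholds,
        "consistent": consistent,
        "unique": unique,
        "target_conditions": target_conditions,
    }


def geometry_stage(config: RunConfig, state: dict, outdir: Path) -> dict:
    """PCA trajectories of the six target presentations + contrast statistics."""
    outdir.mkdir(parents=True, exist_ok=True)
    tensors = state["tensors"]
    target_conditions = state["target_conditions"]
    matrices = [
        _stim_matrix(tensors[c], c, config) for c in target_conditions
    ]
    concatenated = concatenate_conditions(matrices)
    trajectories = geometry.pca_trajectories(concatenated, k=config.pca_k)
    pd.concat([t.to_dataframe() for t in trajectories]).to_csv(
        outdir / "pca_trajectories.csv", index=False
    )

    reports = []
    for d in config.distractors:
        seq = f"{d}-{config.target}"
        sol = geometry.ensemble_correlation(
            tensors[d], tensors[config.target],
            condition_a=d, condition_b=config.target,
        )
        sequential = geometry.ensemble_correlation(
            tensors[d], tensors[seq], condition_a=d, condition_b=seq,
        )
        p = geometry.contrast_test(sol.per_trial_r, sequential.per_trial_r)
        reports.append(
            {
                "distractor": d,
                "r_solitary_mean": sol.mean_r,
                "r_solitary_sd": sol.sd_r,
                "r_sequential_mean": sequential.mean_r,
                "r_sequential_sd": sequential.sd_r,
                "p_paired_t": p,
            }
        )
        log.info(
            "contrast %s: r_sol=%.3f r_seq=%.3f p=%.2g",
            d, sol.mean_r, sequential.mean_r, p,
        )
    df = pd.DataFrame(reports)
    df.to_csv(outdir / "contrast_report.csv", index=False)
    return {"trajectories": trajectories, "contrast": df}


def _stim_matrix(tensor, condition: str, config: RunConfig):
    """Trial-averaged matrix restricted to the 4 s target window [0, 4)."""
    idx = tensor.bin_slice((0.0, PULSE_S))
    from flexdecode.core import BinnedTensor

    sub = BinnedTensor(
        counts=tensor.counts[:, :, idx],
        neuron_ids=tensor.neuron_ids,
        bin_width_s=tensor.bin_width_s,
        window=(0.0, PULSE_S),
    )
    return trial_average(sub, condition)


def _stim_tensor(tensor, window: tuple[float, float]):
    from flexdecode.core import BinnedTensor

    idx = tensor.bin_slice(window)
    return BinnedTensor(
        counts=tensor.counts[:, :, idx],
        neuron_ids=tensor.neuron_ids,
        bin_width_s=tensor.bin_width_s,
        window=window,
    )


def decode_stage(config: RunConfig, state: dict, outdir: Path) -> dict:
    """SVM and flexible decoders with per-bin classification probabilities."""
    outdir.mkdir(parents=True, exist_ok=True)
    tensors = state["tensors"]
    thresholds = state["thresholds"]

    # SVM training set: solitary target stimulus bins (+1) vs solitary
    # distractor stimulus bins plus equal-duration pre-stimulus bins (-1)
    def stim_bins(label: str, window=(0.0, PULSE_S)) -> np.ndarray:
        t = _stim_tensor(tensors[label], window)
        return t.counts.transpose(1, 2, 0).reshape(-1, t.n_neurons).astype(float)

    positives = stim_bins(config.target)
    neg_parts = [stim_bins(d) for d in config.distractors]
    neg_parts.append(stim_bins(config.target, (-2.0, 0.0)))  # baseline bins
    negatives = np.vstack(neg_parts)
    svm = decoders.train_svm(positives, negatives, C=config.svm_C)
    (outdir / "svm_model.json").write_text(svm.to_json())

    flex = decoders.build_flex_weights(state["barcodes"][config.target], m=config.flex_m)
    tau = decoders.default_analog_threshold(flex, positives, config.flex_m)
    flex = decoders.FlexDecoder(weights=flex.weights, m=config.flex_m, tau=tau)
    (outdir / "flex_model.json").write_text(flex.to_json())
    log.info("decoders: svm |w|=%.4f b=%.4f; flex n=%d m=%d tau=%.3f",
             float(np.linalg.norm(svm.weights)), svm.bias, flex.n, flex.m, tau)

    probs = []
    prob_traces: dict[str, dict[str, decoders.ClassificationProbability]] = {}
    for label in sorted(tensors):
        tensor = tensors[label]
        grids = dict(bin_starts=tensor.bin_starts, bin_width_s=tensor.bin_width_s)
        entry = {}
        entry["svm"] = decoders.classification_probability(
            decoders.svm_decide_bins(svm, tensor), condition=label, **grids
        )
        entry["flex_analog"] = decoders.classification_probability(
            decoders.decide_bins(flex, tensor, "analog"), condition=label, **grids
        )
        entry["flex_digital"] = decoders.classification_probability(
            decoders.decide_bins(flex, tensor, "digital", thresholds[label]),
            condition=label, **grids,
        )
        prob_traces[label] = entry
        for name, p in entry.items():
            df = p.to_dataframe()
            df.insert(0, "decoder", name)
            probs.append(df)
    pd.concat(probs).to_csv(outdir / "classification_probabilities.csv", index=False)
    return {"svm": svm, "flex": flex, "probabilities": prob_traces}


def behavior_stage(
    config: RunConfig, gt: GroundTruth, state: dict, decode_state: dict, outdir: Path
) -> dict:
    """ON-OFF weights, model fit on the solitary trained odor, predicted PORs."""
    outdir.mkdir(parents=True, exist_ok=True)
    tensors = state["tensors"]
    thresholds = state["thresholds"]
    target = config.target
    protocols = _conditions(config)

    off_window = (PULSE_S + OFF_DELAY_S, PULSE_S + OFF_DELAY_S + OFF_DURATION_S)
    off_barcode = characterize.classify_responders(
        tensors[target], _pre_window(protocols[target]), off_window, config.k_sd,
        context={"condition": target, "window": "off"},
    )
    v_on, v_off, overlap = behavior.build_on_off_weights(
        state["barcodes"][target], off_barcode
    )
    off_decoder = decoders.FlexDecoder(weights=v_off, m=min(config.flex_m, int(v_off.sum()) - 1) or 1)
    log.info("behavior: |V_on|=%d |V_off|=%d jaccard overlap=%.3f",
             int(v_on.sum()), int(v_off.sum()), overlap)

    flex = decode_state["flex"]
    p_on_traces, p_off_traces = {}, {}
    for label, tensor in tensors.items():
        grids = dict(bin_starts=tensor.bin_starts, bin_width_s=tensor.bin_width_s)
        p_on_traces[label] = decoders.classification_probability(
            decoders.decide_bins(flex, tensor, "digital", thresholds[label]),
            condition=label, **grids,
        )
        p_off_traces[label] = decoders.classification_probability(
            decoders.decide_bins(off_decoder, tensor, "digital", thresholds[label]),
            condition=label, **grids,
        )

    # observed PORs (synthetic), mean across trials on the decoder grid
    observed: dict[str, behavior.PORTrace] = {}
    for label, protocol in protocols.items():
        presented = protocol.alignment
        traces = [
            simulate_por(
                gt, config.simulate, target, protocol,
                presented_odor=presented, trial=t, stream=30 + len(observed),
            )
            for t in range(1, config.simulate.n_trials + 1)
        ]
        mean = behavior.PORTrace(
            times_s=traces[0].times_s,
            values=np.mean([tr.values for tr in traces], axis=0),
            condition=label,
        )
        observed[label] = behavior.resample_trace(
            mean, p_on_traces[label].bin_starts, config.bin_width_s
        )

    params = behavior.fit_on_off_params(
        observed[target], p_on_traces[target], p_off_traces[target],
        v_on=v_on, v_off=v_off, overlap=overlap,
    )
    (outdir / "on_off_params.json").write_text(params.to_json())

    rows = []
    predictions = {}
    for label in sorted(tensors):
        pred = behavior.predict_por(p_on_traces[label], p_off_traces[label], params)
        predictions[label] = pred
        r = behavior.por_correlation(pred, observed[label])
        rows.append(
            {
                "condition": label,
                "predicted_peak": float(pred.values.max()),
                "observed_peak": float(observed[label].values.max()),
                "r": r,
            }
        )
        df = pd.DataFrame(
            {
                "condition": label,
                "time_s": pred.times_s,
                "predicted": pred.values,
                "observed": observed[label].values,
            }
        )
        df.to_csv(outdir / f"por_{label}.csv", index=False)
        log.info("por %s: r=%.3f predicted peak %.3f", label, r, pred.values.max())
    pd.DataFrame(rows).to_csv(outdir / "por_report.csv", index=False)
    return {
        "params": params,
        "predictions": predictions,
        "observed": observed,
        "off_barcode": off_barcode,
        "overlap": overlap,
    }


def run_pipeline(config: RunConfig, outdir) -> Path:
    """Run every stage and write a summary; returns the run directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        log.info(
            "run config: bin=%.3fs k_sd=%.1f cutoff=%.1fs C=%g m=%d off_delay=%.1fs seed=%d",
            config.bin_width_s, config.k_sd, config.latency_cutoff_s,
            config.svm_C, config.flex_m, OFF_DELAY_S, config.simulate.seed,
        )
        (outdir / "config.yaml").write_text(yaml.safe_dump(config.to_mapping()))
        gt, rasters = simulate_stage(config, outdir / "simulate")
        state = characterize_stage(config, rasters, outdir / "characterize")
        geom = geometry_stage(config, state, outdir / "geometry")
        dec = decode_stage(config, state, outdir / "decode")
        beh = behavior_stage(config, gt, state, dec, outdir / "behavior")
        summary = {
            "seed": config.simulate.seed,
            "n_neurons": config.simulate.n_neurons,
            "n_trials": config.simulate.n_trials,
            "consistent_count": state["consistent"].count,
            "unique_consistent_count": state["unique"].count,
            "contrast_p_values": dict(
                zip(geom["contrast"]["distractor"], geom["contrast"]["p_paired_t"])
            ),
            "flex_n": dec["flex"].n,
            "flex_m": dec["flex"].m,
            "on_off_overlap": beh["overlap"],
            "por_r": {
                label: behavior.por_correlation(pred, beh["observed"][label])
                for label, pred in beh["predictions"].items()
            },
        }
        (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
        log.info("run complete")
    finally:
        log.removeHandler(handler)
        handler.close()
    return outdir
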