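"""File formats, run configuration, and the end-to-end pipeline.

Events use the BIDS ``events.tsv`` dialect (tab-separated onset /
duration / trial_type, seconds, time origin at recording start) with the
trial_type vocabulary ``rest, 0back, 1back, 2back, stim_target,
stim_nontarget, response``. Signals are written as a flat CSV of samples
with a JSON sidecar carrying the sampling rate; EDF recordings are read
through MNE. Burst events and ground truth are tab-separated tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .detect import BurstEvent, DetectionConfig, detect_bursts
from .simulate import BurstModel, make_nback_schedule, simulate_behavior, synthesize_eeg, synthesize_bold
from .stats import condition_rates, pmbr
from .tfr import ContinuousSignal

logger = logging.getLogger("betaburst")

EVENT_COLUMNS = ("onset", "duration", "trial_type")
KNOWN_TRIAL_TYPES = {
    "rest", "0back", "1back", "2back", "stim_target", "stim_nontarget", "response",
}


def read_events(path) -> pd.DataFrame:
    """Read a BIDS-style events.tsv; onsets returned sorted (a warning is
    logged if the file was out of order), unknown trial_type values are
    preserved but flagged in the log."""
    path = Path(path)
    ev = pd.read_csv(path, sep="\t")
    missing = [c for c in EVENT_COLUMNS if c not in ev.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    if not ev["onset"].is_monotonic_increasing:
        logger.warning("%s: onsets out of order; sorting", path)
        warnings.warn(f"{path}: onsets out of order; sorting", stacklevel=2)
    unknown = set(ev["trial_type"].unique()) - KNOWN_TRIAL_TYPES
    if unknown:
        logger.warning("%s: unknown trial_type values %s", path, sorted(unknown))
    return ev.sort_values("onset", kind="stable").reset_index(drop=True)


def write_events(events: pd.DataFrame, path):
    events.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_signal(path, fs: float = None) -> ContinuousSignal:
    """Read a continuous signal from EDF (sampling rate embedded) or from
    a CSV / .npy sample array with the rate in a JSON sidecar or given
    explicitly. NaN samples are rejected."""
    path = Path(path)
    if path.suffix.lower() == ".edf":
        import mne

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        samples = raw.get_data()[0]
        return ContinuousSignal(samples=samples, fs=float(raw.info["sfreq"]))
    if path.suffix.lower() == ".npy":
        samples = np.load(path)
    else:
        samples = pd.read_csv(path, header=None).to_numpy(dtype=float).ravel()
    if fs is None:
        sidecar = path.with_suffix(".json")
        if not sidecar.exists():
            raise ValueError(
                f"{path}: sampling rate not given and sidecar {sidecar.name} not found"
            )
        fs = float(json.loads(sidecar.read_text())["fs"])
    if np.any(np.isnan(samples)):
        raise ValueError(f"{path}: signal contains NaN samples")
    return ContinuousSignal(samples=samples, fs=float(fs))


def write_signal(signal: ContinuousSignal, path, meta: dict = None):
    """Write samples as one-column CSV plus a JSON sidecar with fs."""
    path = Path(path)
    np.savetxt(path, signal.samples, fmt="%.8g")
    sidecar = {"fs": signal.fs, "n_samples": int(signal.samples.size),
               "units": "uV"}
    if meta:
        sidecar.update(meta)
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1, sort_keys=True))


BURST_COLUMNS = ("time", "freq", "peak_power", "median_ratio")


def write_bursts(events, path):
    df = pd.DataFrame(
        [(e.time, e.freq, e.peak_power, e.median_ratio) for e in events],
        columns=BURST_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_bursts(path) -> list:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in BURST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    return [BurstEvent(**{c: float(r[c]) for c in BURST_COLUMNS})
            for _, r in df.iterrows()]


@dataclass
class RunConfig:
    """Declarative configuration for the end-to-end pipeline.

    Round-trips losslessly through JSON; every parameter carries the
    analysis-convention default where one exists (5-cycle wavelets, 1-Hz /
    6-ms smoothing SDs, 13-30 Hz band, 6x median threshold, PMBR windows
    0.5-1 s post and -3 to -1.5 s pre response).
    """

    runs: int = 1
    seed: int = 0
    fs: float = 250.0
    attenuation: float = 1.0
    hit_rate: float = 0.95
    noise_alpha: float = 1.0
    noise_amplitude: float = 1.0
    beta_band: tuple = (13.0, 30.0)
    threshold_factor: float = 6.0
    n_cycles: int = 5
    sd_f: float = 1.0
    sd_t: float = 0.006
    pmbr_post: tuple = (0.5, 1.0)
    pmbr_baseline: tuple = (-3.0, -1.5)
    tr: float = 2.0
    n_voxels: int = 20
    bold_noise_sd: float = 1.0
    bold_burst_beta: float = 0.5
    microtime_factor: int = 16

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        for key in ("beta_band", "pmbr_post", "pmbr_baseline"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def param_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Run simulate -> detect -> rates / PMBR -> BOLD GLM end to end.

    Writes signal.csv (+ sidecar), events.tsv, ground_truth.tsv,
    bursts.tsv, participant.csv (condition rates + PMBR), glm.csv (burst
    contrast over simulated voxels) and provenance.json into ``out_dir``.
    Outputs are a pure function of the configuration: re-running with the
    same config reproduces them byte for byte.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results = {}

    def _stage(name, fn):
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - annotate stage and re-raise
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    schedule = _stage("simulate", lambda: make_nback_schedule(config.runs, seed=config.seed))
    responses = _stage("simulate", lambda: simulate_behavior(
        schedule, hit_rate=config.hit_rate, seed=config.seed + 1))
    schedule = schedule.with_responses(responses)
    model = BurstModel(group_attenuation=config.attenuation)
    signal, truth = _stage("simulate", lambda: synthesize_eeg(
        schedule, model, fs=config.fs, noise_alpha=config.noise_alpha,
        noise_amplitude=config.noise_amplitude, seed=config.seed + 2))
    write_signal(signal, out / "signal.csv", meta={"param_hash": config.param_hash()})
    write_events(schedule.to_events(), out / "events.tsv")
    truth.to_frame().to_csv(out / "ground_truth.tsv", sep="\t", index=False,
                            float_format="%.6f")

    det_cfg = DetectionConfig(
        beta_band=config.beta_band, threshold_factor=config.threshold_factor,
        n_cycles=config.n_cycles, sd_f=config.sd_f, sd_t=config.sd_t,
    )
    bursts = _stage("detect", lambda: detect_bursts(signal, det_cfg))
    write_bursts(bursts, out / "bursts.tsv")
    burst_times = np.array([b.time for b in bursts])
    results["n_bursts"] = len(bursts)

    events = schedule.to_events()
    rates = _stage("rates", lambda: condition_rates(burst_times, events))
    resp_times = responses["onset"].to_numpy(float)
    pm = _stage("pmbr", lambda: pmbr(
        burst_times, resp_times, post=config.pmbr_post,
        baseline=config.pmbr_baseline, t_start=0.0, t_stop=schedule.duration))
    row = {**{f"rate_{k}": v for k, v in rates.items()},
           "pmbr": pm.pmbr, "post_rate": pm.post_rate,
           "baseline_rate": pm.baseline_rate, "n_responses": pm.n_responses}
    pd.DataFrame([row]).to_csv(out / "participant.csv", index=False,
                               float_format="%.6f")
    results.update(row)

    def _glm():
        from .glm import fit_glm

        true_betas = np.array([0.3, 0.3, 0.3, 0.4, config.bold_burst_beta, 0.0])
        Y, design, _ = synthesize_bold(
            truth.times, schedule, tr=config.tr, n_voxels=config.n_voxels,
            true_betas=true_betas, noise_sd=config.bold_noise_sd,
            seed=config.seed + 3)
        fit = fit_glm(Y, design)
        est, t, p = fit.contrast(design.contrast_vector("burst"))
        return pd.DataFrame({"voxel": np.arange(config.n_voxels),
                             "burst_beta": est, "t": t, "p": p})

    glm_df = _stage("glm", _glm)
    glm_df.to_csv(out / "glm.csv", index=False, float_format="%.6f")
    results["glm_mean_burst_beta"] = float(glm_df["burst_beta"].mean())

    import betaburst

    provenance = {
        "package": "betaburst",
        "version": betaburst.__version__,
        "config": json.loads(config.to_json()),
        "param_hash": config.param_hash(),
        "numpy": np.__version__,
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=1, sort_keys=True))
    return results
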