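"""End-to-end orchestration: experiment templates and the subject chain.

A template bundles the analysis parameters of one experimental design:

* ``experiment1`` — Go/NoGo task, MEG-like source analysis at 500 Hz
  (band-pass 1–245 Hz, notches at 49–55 / 99–101 / 149–151 / 199–201
  Hz, LCMV beamforming, four band features: β ERD, β ERS, slow-γ,
  mid-γ) plus pre-movement TMS (15 trials per protocol) and the
  sequence-learning task.
* ``experiment2`` — paced-press task, mid-γ only, visuomotor learning.
* ``experiment3`` — Go-only task analysed EEG-style: 250 Hz, band-pass
  1–95 Hz, notch 49–51 Hz, slow-γ only, channel-space peaks (no
  beamforming), rest TMS with 13 trials per condition.

The per-subject chain is: condition the continuous data → flag bad
segments → detect EMG movement onsets/offsets and exclude outlier
trials → (per band) band-filter, normalise coil types, beamform,
epoch, multitaper, baseline-correct and extract the band peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from gammaflow import bayescorr, behaviour, emgevents, sigprep, spectral, tmsmep
from gammaflow.beamform import (
    Leadfield,
    covariance,
    eigen_normalize,
    lcmv_weights,
    project,
    scale_leadfield,
)
from gammaflow.containers import BandPeak, Recording
from gammaflow.errors import ConfigError, InputError
from gammaflow.synthgen import (
    SICI_PAIRS,
    SimConfig,
    SubjectSim,
    simulate_mep_trials,
    simulate_population,
)

__all__ = ["BandSpec", "AnalysisParams", "TEMPLATES", "make_template",
           "analyze_recording", "run_experiment"]


@dataclass(frozen=True)
class BandSpec:
    """One band-feature definition."""

    name: str
    band: str  # key into containers.BANDS
    mode: str  # "max" (ERS) / "min" (ERD)
    lock: str  # epochs locked to movement "onset" or "offset"
    window: str  # "onset-offset" or "offset-plus-1s"
    baseline: tuple[float, float]


BETA_ERD = BandSpec("beta-erd", "beta", "min", "onset", "onset-offset", (-1.0, -0.5))
BETA_ERS = BandSpec("beta-ers", "beta", "max", "offset", "offset-plus-1s",
                    (-1.5, -1.0))
SLOW_GAMMA = BandSpec("slow-gamma", "slow-gamma", "max", "onset", "onset-offset",
                      (-1.0, -0.5))
MID_GAMMA = BandSpec("mid-gamma", "mid-gamma", "max", "onset", "onset-offset",
                     (-1.0, -0.5))


@dataclass
class AnalysisParams:
    """Tunable analysis-chain parameters with their design defaults."""

    resample_to: float | None = None
    bandpass: tuple[float, float] = (1.0, 245.0)
    notches: tuple[tuple[float, float], ...] = ((49.0, 51.0),)
    band_specs: tuple[BandSpec, ...] = (BETA_ERD, BETA_ERS, SLOW_GAMMA, MID_GAMMA)
    source_space: bool = True  # False -> channel-space peaks (EEG style)
    rank: int = 50
    epoch_pre_s: float = 2.0
    epoch_post_s: float = 2.0
    window_s: float = 1.6
    step_s: float = 0.2
    freq_step: float = 1.0
    half_bandwidth: float = 2.5
    gesd_alpha: float = 0.05
    gesd_max_fraction: float = 0.2
    roi_mask: np.ndarray | None = None


def make_template(name: str) -> tuple[SimConfig, AnalysisParams]:
    """Simulation + analysis presets for one experiment design."""
    if name == "experiment1":
        sim = SimConfig(task_id="MA1", sampling_rate=500.0)
        ana = AnalysisParams(
            bandpass=(1.0, 245.0),
            notches=((49.0, 55.0), (99.0, 101.0), (149.0, 151.0), (199.0, 201.0)),
        )
        return sim, ana
    if name == "experiment2":
        sim = SimConfig(task_id="MA2", sampling_rate=500.0,
                        mt_mean_s=0.35, mt_sd_s=0.05,
                        traits=("mid_gamma_amplitude", "ml2_asymptote_mt_s"))
        ana = AnalysisParams(
            bandpass=(1.0, 245.0), notches=((49.0, 51.0),),
            band_specs=(MID_GAMMA,),
            epoch_pre_s=2.0, epoch_post_s=2.0,
        )
        return sim, ana
    if name == "experiment3":
        sim = SimConfig(task_id="MA1-exp3", sampling_rate=500.0,
                        n_channels={"EEG": 12})
        ana = AnalysisParams(
            resample_to=250.0, bandpass=(1.0, 95.0), notches=((49.0, 51.0),),
            band_specs=(SLOW_GAMMA,), source_space=False,
        )
        return sim, ana
    raise ConfigError(f"unknown template {name!r}")


TEMPLATES = ("experiment1", "experiment2", "experiment3")


def _movement_marks(rec: Recording, params: AnalysisParams) -> pd.DataFrame:
    emg_rows = rec.channel_indices("EMG")
    if emg_rows.size != 1:
        raise InputError("expected exactly one EMG channel")
    go = rec.events.loc[rec.events["label"].isin(("go", "flash")), "sample"]
    marks = emgevents.mark_movements(rec.data[emg_rows[0]], go.to_numpy(),
                                     rec.sampling_rate)
    return emgevents.exclude_trials(marks, alpha=params.gesd_alpha)


def analyze_recording(
    rec: Recording,
    lead: Leadfield | None,
    params: AnalysisParams,
) -> dict:
    """Run the full sensor→feature chain on one continuous recording.

    Returns a dict with the band features (``features``: name →
    :class:`BandPeak`), the movement marks, the bad-segment mask and
    per-band retained-trial counts.
    """
    if params.resample_to is not None and params.resample_to < rec.sampling_rate:
        rec = sigprep.resample(rec, params.resample_to)
    fs = rec.sampling_rate
    broad = sigprep.filter_band(rec, *params.bandpass, notches=params.notches)
    mask = sigprep.detect_bad_segments(broad, alpha=params.gesd_alpha,
                                       max_fraction=params.gesd_max_fraction)
    bad = mask.sample_mask(broad.n_samples, fs)
    marks = _movement_marks(broad, params)
    retained = marks[~marks["excluded"]]
    if len(retained) < 3:
        raise InputError("fewer than 3 retained movement trials")

    features: dict[str, BandPeak] = {}
    n_used: dict[str, int] = {}
    from gammaflow.containers import BANDS

    for spec in params.band_specs:
        lo, hi = BANDS[spec.band]
        band_rec = sigprep.filter_band(broad, lo, hi)
        meg_rows = np.flatnonzero(band_rec.channel_groups != "EMG")
        data = band_rec.data[meg_rows]
        groups = band_rec.channel_groups[meg_rows]
        scales: dict[str, float] = {}
        if len(set(groups)) > 1 or params.source_space:
            data, scales = eigen_normalize(data, groups)
        if params.source_space:
            if lead is None:
                raise InputError("source-space analysis requires a leadfield")
            band_lead = scale_leadfield(lead, groups, scales)
            cov = covariance(data, bad_mask=bad)
            w = lcmv_weights(cov, band_lead,
                             rank=min(params.rank, len(meg_rows)))
            sensors = data
        else:
            w = None
            sensors = data

        lock_col = "onset_s" if spec.lock == "onset" else "offset_s"
        centers = (retained["go_sample"].to_numpy()
                   + np.round(retained[lock_col].to_numpy() * fs)).astype(int)
        epochs, kept = sigprep.epoch_data(sensors, fs, centers,
                                          params.epoch_pre_s, params.epoch_post_s,
                                          bad_mask=bad)
        if len(kept) < 3:
            raise InputError(f"fewer than 3 clean epochs for {spec.name}")
        # with an ROI, only the ROI sources are projected and transformed
        # (the peak search is confined to them anyway)
        roi = (None if params.roi_mask is None
               else np.flatnonzero(params.roi_mask))
        if w is not None:
            epochs = project(epochs, w if roi is None else w[roi])
        elif roi is not None:
            epochs = epochs[:, roi]
        tf = spectral.multitaper_tf(
            epochs, fs, t_start=-params.epoch_pre_s, fmin=lo, fmax=hi,
            window_s=params.window_s, step_s=params.step_s,
            freq_step=params.freq_step, half_bandwidth=params.half_bandwidth,
        )
        tf = spectral.baseline_correct(tf, spec.baseline)
        peak = spectral.extract_band_peak(
            tf, retained.iloc[kept], spec.band, mode=spec.mode,
            window=spec.window,
        )
        if roi is not None:
            peak = BandPeak(band=peak.band, power=peak.power,
                            peak_frequency=peak.peak_frequency,
                            peak_location=int(roi[peak.peak_location]),
                            window=peak.window, mode=peak.mode)
        features[spec.name] = peak
        n_used[spec.name] = int(len(kept))
    return {"features": features, "marks": marks, "segment_mask": mask,
            "n_epochs": n_used}


def _sici_summary(trials: pd.DataFrame) -> dict[str, float]:
    """Per-pair SICI ratios (after rejection) plus a pooled pre-movement value."""
    rejected = tmsmep.reject_trials(trials)
    out: dict[str, float] = {}
    for cond, uncond in SICI_PAIRS.items():
        if (rejected["protocol"] == cond).any() and \
           (rejected["protocol"] == uncond).any():
            out[cond] = tmsmep.sici(rejected, cond, uncond).ratio
    pre = [out[k] for k in ("SICI_early", "SICI_late") if k in out]
    if pre:
        out["SICI_pre"] = float(np.mean(pre))
    return out


def subject_features(sub: SubjectSim, params: AnalysisParams,
                     tms_protocols: tuple[str, ...] = (),
                     n_mep_trials: int = 15,
                     learning_task: str | None = None) -> dict:
    """Simulate one subject's raw inputs and run every analysis arm."""
    rec, lead, _ = sub.recording()
    result = analyze_recording(rec, lead if params.source_space else None, params)
    row: dict[str, float] = {"subject": sub.subject}
    for name, peak in result["features"].items():
        row[f"{name}_power"] = peak.power
        row[f"{name}_peak_hz"] = peak.peak_frequency
        row[f"{name}_peak_loc"] = peak.peak_location
    if tms_protocols:
        trials = pd.concat(
            [simulate_mep_trials(sub.config, p, n_mep_trials, seed=sub.seed)
             for p in tms_protocols], ignore_index=True)
        for key, ratio in _sici_summary(trials).items():
            row[f"sici_{key}"] = ratio
    if learning_task == "ml1":
        row["ml1_score_pct"] = behaviour.ml1_score(sub.ml1()).value
    elif learning_task == "ml2":
        score = behaviour.ml2_score(sub.ml2())
        row["ml2_delta_mt_s"] = score.value
        row["ml2_delta_error_deg"] = score.delta_error
    return row


#: correlation pairs evaluated per template: (x column, y column)
TEMPLATE_PAIRS = {
    "experiment1": (("sici_SICI_pre", "slow-gamma_peak_hz"),
                    ("ml1_score_pct", "mid-gamma_power")),
    "experiment2": (("ml2_delta_mt_s", "mid-gamma_power"),
                    ("ml2_delta_error_deg", "mid-gamma_power")),
    "experiment3": (("sici_SICI1ms", "slow-gamma_peak_hz"),
                    ("sici_SICI2.5ms", "slow-gamma_peak_hz")),
}

TEMPLATE_TMS = {
    "experiment1": (("spMEP_early", "spMEP_late", "SICI_early", "SICI_late"), 15),
    "experiment2": ((), 0),
    "experiment3": (("spMEP", "SICI1ms", "SICI2.5ms"), 13),
}

TEMPLATE_LEARNING = {"experiment1": "ml1", "experiment2": "ml2",
                     "experiment3": None}


def run_experiment(
    template: str,
    sim_config: SimConfig | None = None,
    params: AnalysisParams | None = None,
    outdir: str | Path | None = None,
    make_figures: bool = False,
) -> dict:
    """Simulate a population and run the template's full analysis.

    Returns a report dict with the subject feature table, the
    correlation results, the ground-truth table and the configuration
    echo; optionally writes CSV/JSON outputs under ``outdir``.
    """
    base_sim, base_params = make_template(template)
    sim = base_sim if sim_config is None else sim_config
    params = base_params if params is None else params
    truth, subjects = simulate_population(sim)
    protocols, n_mep = TEMPLATE_TMS[template]
    learning = TEMPLATE_LEARNING[template]
    rows = [subject_features(s, params, tms_protocols=protocols,
                             n_mep_trials=n_mep, learning_task=learning)
            for s in subjects]
    table = pd.DataFrame(rows)

    correlations = []
    for xcol, ycol in TEMPLATE_PAIRS[template]:
        if xcol not in table.columns or ycol not in table.columns:
            continue
        res = bayescorr.correlate(table[xcol].to_numpy(),
                                  table[ycol].to_numpy(), seed=sim.seed)
        correlations.append({
            "x": xcol, "y": ycol, "r": res.r, "n": res.n_used,
            "bf10": res.bf10, "category": res.category,
            "removed_ids": list(res.removed_ids),
        })
    report = {
        "template": template,
        "seed": sim.seed,
        "features": table,
        "correlations": pd.DataFrame(correlations),
        "truth": truth.table,
        "latent_r": truth.latent_r,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        table.to_csv(outdir / "features.csv", index=False)
        report["correlations"].to_csv(outdir / "correlations.csv", index=False)
        truth.table.to_csv(outdir / "ground_truth.csv", index=False)
        from gammaflow.io import save_json
        save_json(outdir / "run_log.json", {
            "template": template, "seed": sim.seed,
            "n_subjects": sim.n_subjects, "latent_r": truth.latent_r,
        })
        if make_figures:
            _write_figures(table, report["correlations"], params, outdir)
    return report


def _write_figures(table: pd.DataFrame, correlations: pd.DataFrame,
                   params: AnalysisParams, outdir: Path) -> None:
    """Peak-frequency histograms per band and correlation scatters."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from gammaflow.plots import plot_peak_histogram

    for spec in params.band_specs:
        col = f"{spec.name}_peak_hz"
        if col not in table.columns:
            continue
        ax = plot_peak_histogram(table[col], spec.name)
        ax.figure.savefig(outdir / f"peak_freqs_{spec.name}.png", dpi=100)
        plt.close(ax.figure)
    for _, row in correlations.iterrows():
        fig, ax = plt.subplots()
        ax.scatter(table[row["x"]], table[row["y"]])
        ax.set_xlabel(row["x"])
        ax.set_ylabel(row["y"])
        ax.set_title(f"r = {row['r']:.3f}, BF10 = {row['bf10']:.3g}")
        fig.savefig(outdir / f"corr_{row['x']}__{row['y']}.png", dpi=100)
        plt.close(fig)
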