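"""Population layer: correlated latent traits across synthetic subjects.

Latent trait pairs are drawn from a bivariate standard normal with the
configured correlation and mapped to generator parameters through
monotone affine maps clamped to plausible empirical ranges (slow-γ
peak frequency 35–57 Hz, SICI ratio within (0, 1.5), etc.), so the
population-level correlation survives into the quantities the analysis
chain recovers.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from gammaflow.errors import ConfigError
from gammaflow.synthgen.config import SimConfig
from gammaflow.synthgen.recording import make_movement_truth, simulate_recording
from gammaflow.synthgen.schedule import make_trial_schedule
from gammaflow.synthgen.mep import simulate_mep_trials
from gammaflow.synthgen import behaviour as bhv

__all__ = ["SubjectSim", "PopulationTruth", "simulate_population"]

#: latent z -> trait value: (intercept, slope, low clamp, high clamp)
TRAIT_MAPS = {
    "slow_gamma_peak_hz": (46.0, 5.0, 35.0, 57.0),
    "mid_gamma_peak_hz": (71.0, 4.0, 63.0, 80.0),
    "sici_ratio": (0.55, 0.15, 0.10, 1.40),
    "mid_gamma_amplitude": (1.0, 0.25, 0.30, 2.00),
    "ml1_score_pct": (-20.0, 6.0, -45.0, 5.0),
    "ml2_asymptote_mt_s": (8.0, 0.8, 5.5, 10.5),
}


def _map_trait(name: str, z: np.ndarray) -> np.ndarray:
    if name not in TRAIT_MAPS:
        raise ConfigError(f"unknown latent trait {name!r}; "
                          f"known: {sorted(TRAIT_MAPS)}")
    b0, b1, lo, hi = TRAIT_MAPS[name]
    return np.clip(b0 + b1 * np.asarray(z), lo, hi)


def _apply_trait(config: SimConfig, name: str, value: float) -> SimConfig:
    """Push a trait value into the subject's generator parameters."""
    if name == "slow_gamma_peak_hz":
        bt = dict(config.band_truth)
        bt["slow-gamma"] = replace(bt["slow-gamma"], center_hz=float(value))
        return config.with_updates(band_truth=bt)
    if name == "mid_gamma_peak_hz":
        bt = dict(config.band_truth)
        bt["mid-gamma"] = replace(bt["mid-gamma"], center_hz=float(value))
        return config.with_updates(band_truth=bt)
    if name == "mid_gamma_amplitude":
        bt = dict(config.band_truth)
        bt["mid-gamma"] = replace(bt["mid-gamma"], amplitude=float(value))
        return config.with_updates(band_truth=bt)
    if name == "sici_ratio":
        mm = replace(config.mep_model,
                     sici_ratio={k: float(value)
                                 for k in config.mep_model.sici_ratio})
        return config.with_updates(mep_model=mm)
    if name == "ml1_score_pct":
        lm = config.learning_model
        # choose the asymptote that makes the expected score equal `value`
        plateau_decay = np.mean([np.exp(-lm.ml1_rate * (b - 2))
                                 for b in range(10, 15)])
        target_plateau = lm.ml1_initial_ms * (1 + value / 100.0)
        asym = ((target_plateau - lm.ml1_initial_ms * plateau_decay)
                / (1 - plateau_decay))
        return config.with_updates(
            learning_model=replace(lm, ml1_asymptote_ms=float(asym)))
    if name == "ml2_asymptote_mt_s":
        lm = replace(config.learning_model, ml2_asymptote_mt_s=float(value))
        return config.with_updates(learning_model=lm)
    raise ConfigError(f"unknown latent trait {name!r}")


@dataclass
class SubjectSim:
    """Lazy per-subject input generator.

    Holds the subject-specific configuration and seed; the heavyweight
    raw inputs (continuous recording, MEP tables, behavioural sessions)
    are generated on demand so large populations need not be resident
    in memory at once.
    """

    subject: int
    seed: int
    config: SimConfig
    traits: dict[str, float]

    def schedule(self) -> pd.DataFrame:
        sched = make_trial_schedule(self.config.task_id, seed=self.seed)
        if self.config.n_trials is not None:
            sched = sched[sched["trial"] < self.config.n_trials].reset_index(
                drop=True)
        return sched

    def movement_truth(self, schedule: pd.DataFrame | None = None) -> pd.DataFrame:
        sched = self.schedule() if schedule is None else schedule
        return make_movement_truth(sched, self.config, seed=self.seed)

    def recording(self):
        sched = self.schedule()
        truth = self.movement_truth(sched)
        rec, lead = simulate_recording(self.config, sched, truth, seed=self.seed)
        return rec, lead, truth

    def mep_trials(self, protocols=("spMEP", "SICI2.5ms"),
                   n_trials: int = 15) -> pd.DataFrame:
        return pd.concat(
            [simulate_mep_trials(self.config, p, n_trials, seed=self.seed)
             for p in protocols],
            ignore_index=True,
        )

    def ml1(self) -> pd.DataFrame:
        return bhv.simulate_ml1(self.config, seed=self.seed)

    def ml2(self) -> pd.DataFrame:
        return bhv.simulate_ml2(self.config, seed=self.seed)


@dataclass
class PopulationTruth:
    """Ground-truth feature table plus the realised latent correlation."""

    table: pd.DataFrame
    latent_r: float


def simulate_population(config: SimConfig) -> tuple[PopulationTruth, list[SubjectSim]]:
    """Draw a correlated-subject population from the configuration.

    Latent pairs ``(z1, z2)`` come from a bivariate normal with
    correlation ``config.trait_corr``; each is mapped to the two named
    traits and pushed into a per-subject configuration.  Returns the
    ground-truth table (with the empirical latent correlation) and the
    lazy per-subject generators.
    """
    if config.n_subjects < 5:
        raise ConfigError("need at least 5 subjects for a population")
    if abs(config.trait_corr) > 1:
        raise ConfigError("|trait_corr| must not exceed 1")
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0xA11)))
    rho = config.trait_corr
    cov = np.array([[1.0, rho], [rho, 1.0]])
    z = rng.multivariate_normal([0.0, 0.0], cov, size=config.n_subjects,
                                method="cholesky")
    name1, name2 = config.traits
    v1 = _map_trait(name1, z[:, 0])
    v2 = _map_trait(name2, z[:, 1])
    latent_r = float(np.corrcoef(z[:, 0], z[:, 1])[0, 1])

    child_seeds = np.random.SeedSequence(config.seed).generate_state(
        config.n_subjects) % (2**31)
    subjects = []
    rows = []
    for i in range(config.n_subjects):
        sub_cfg = _apply_trait(config, name1, v1[i])
        sub_cfg = _apply_trait(sub_cfg, name2, v2[i])
        subjects.append(SubjectSim(subject=i, seed=int(child_seeds[i]),
                                   config=sub_cfg,
                                   traits={name1: float(v1[i]),
                                           name2: float(v2[i])}))
        rows.append((i, int(child_seeds[i]), z[i, 0], z[i, 1],
                     float(v1[i]), float(v2[i])))
    table = pd.DataFrame(rows, columns=["subject", "seed", "z1", "z2",
                                        name1, name2])
    return PopulationTruth(table=table, latent_r=latent_r), subjects
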