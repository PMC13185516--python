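"""Generative stop-signal-task simulator with known latent ground truth.

The simulator emulates an event-related stop-signal task (SST): a majority
of go trials and a minority of stop trials (default 60/40 over 132 trials,
guaranteeing at least 50 stop trials), uniformly jittered inter-stimulus
intervals rescaled to a fixed run length, uniform go reaction times and
stop-signal delays, and a fixed stop-signal reaction time (SSRT) that
decides stop success (a stop succeeds when the go process, at RT, would
finish after SSD + SSRT).

For each trial a first-order Markov chain over three latent cognitive
states runs across the D FIR delay bins; its initial distribution depends
on trial type and its stay probability on the transition regime (a *low*
transition regime means a *high* stay probability).  Observations are
generated directly in the FIR domain: each state has a fixed per-subject
node amplitude pattern (state 0 high positive, state 1 low positive,
state 2 mixed sign) plus i.i.d. Gaussian noise, z-scored per node — the
same representation the FIR module would produce from raw BOLD.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .fir import FirSeries

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_behavior",
    "simulate_state_sequence",
    "simulate_fir_bold",
    "simulate_subject",
    "simulate_cohort",
]

REGIMES = ("low", "medium", "high")
NOISE_LEVELS = ("low", "medium", "high", "very_high")
N_STATES = 3


def _default_stay_probs() -> dict[str, float]:
    # keyed by *transition* regime: low transition = high stay probability
    return {"low": 0.90, "medium": 0.70, "high": 0.50}


def _default_noise_sds() -> dict[str, float]:
    # multiples {0.5, 1, 1.5, 2} of the state-0 amplitude half-width (0.2)
    return {"low": 0.1, "medium": 0.2, "high": 0.3, "very_high": 0.4}


def _default_amplitude_ranges() -> dict[int, tuple[float, float]]:
    return {0: (0.8, 1.2), 1: (0.2, 0.5), 2: (-0.8, 0.8)}


def _default_initial_state_probs() -> dict[str, tuple[float, ...]]:
    # go trials favour the low-positive state 1, stop trials the salient state 0
    return {"go": (0.2, 0.6, 0.2), "stop": (0.6, 0.2, 0.2)}


@dataclass
class SimulationConfig:
    """Parameters of one simulated subject/run.

    Time quantities are in seconds.  ``noise_sd_by_level`` entries are the
    standard deviation of the Gaussian noise added per node, trial and delay
    before z-scoring.
    """

    n_subjects: int = 1
    n_trials: int = 132
    stop_proportion: float = 0.40
    n_delays: int = 5
    tr_s: float = 2.0
    n_nodes: int = 200
    isi_range_s: tuple[float, float] = (2.0, 6.0)
    rt_range_s: tuple[float, float] = (0.35, 0.65)
    ssd_range_s: tuple[float, float] = (0.10, 0.40)
    ssrt_s: float = 0.25
    transition_regime: str = "medium"
    stay_prob_by_regime: Mapping[str, float] = field(default_factory=_default_stay_probs)
    noise_level: str = "medium"
    noise_sd_by_level: Mapping[str, float] = field(default_factory=_default_noise_sds)
    state_amplitude_ranges: Mapping[int, tuple[float, float]] = field(
        default_factory=_default_amplitude_ranges)
    initial_state_probs: Mapping[str, Sequence[float]] = field(
        default_factory=_default_initial_state_probs)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_trials <= 0:
            raise ValueError("n_trials must be positive")
        if not 0.0 <= self.stop_proportion <= 1.0:
            raise ValueError("stop_proportion must lie in [0, 1]")
        if self.n_delays <= 0 or self.n_nodes <= 0 or self.n_subjects <= 0:
            raise ValueError("n_delays, n_nodes and n_subjects must be positive")
        for name in ("isi_range_s", "rt_range_s", "ssd_range_s"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} low must not exceed high")
        if self.transition_regime not in self.stay_prob_by_regime:
            raise ValueError(f"unknown transition regime {self.transition_regime!r}")
        if self.noise_level not in self.noise_sd_by_level:
            raise ValueError(f"unknown noise level {self.noise_level!r}")
        stays = [self.stay_prob_by_regime[r] for r in REGIMES
                 if r in self.stay_prob_by_regime]
        if any(not 0.0 < s <= 1.0 for s in stays):
            raise ValueError("stay probabilities must lie in (0, 1]")
        if stays != sorted(stays, reverse=True):
            raise ValueError("stay probabilities must decrease from regime 'low' to 'high'")
        if any(sd <= 0 for sd in self.noise_sd_by_level.values()):
            raise ValueError("noise sds must be positive")
        for probs in self.initial_state_probs.values():
            p = np.asarray(probs, dtype=float)
            if p.shape != (N_STATES,) or np.any(p < 0) or not np.isclose(p.sum(), 1.0):
                raise ValueError("initial state distributions must be length-3 simplices")

    @property
    def stay_prob(self) -> float:
        return float(self.stay_prob_by_regime[self.transition_regime])

    @property
    def noise_sd(self) -> float:
        return float(self.noise_sd_by_level[self.noise_level])

    @property
    def run_duration_s(self) -> float:
        """Target run length: the trial count times the mean nominal ISI."""
        return self.n_trials * float(np.mean(self.isi_range_s))

    def transition_matrix(self) -> np.ndarray:
        """The regime's 3x3 chain: stay on the diagonal, rest split equally."""
        stay = self.stay_prob
        off = (1.0 - stay) / (N_STATES - 1)
        return np.full((N_STATES, N_STATES), off) + np.eye(N_STATES) * (stay - off)


@dataclass
class GroundTruth:
    """Per-subject latent ground truth aligned with the FIR-domain frames."""

    state_seq: np.ndarray        # (K,) states in {0, 1, 2}
    trials: np.ndarray           # (K,) trial index per frame
    delays: np.ndarray           # (K,) delay index per frame
    regime: str
    noise_level: str

    @property
    def K(self) -> int:
        return len(self.state_seq)

    def transition_seq(self) -> tuple[np.ndarray, np.ndarray]:
        """Binary stay(0)/change(1) sequence and its validity mask.

        The indicator is undefined across trial boundaries (delay 0), where
        the mask is False.
        """
        change = np.zeros(self.K, dtype=int)
        change[1:] = self.state_seq[1:] != self.state_seq[:-1]
        valid = self.delays > 0
        return change, valid


def simulate_behavior(config: SimulationConfig,
                      rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Simulate one run of stop-signal-task behaviour.

    Returns a trial table with strictly increasing onsets; exactly
    ``round(n_trials * stop_proportion)`` stop trials in random order; ISIs
    sampled uniformly then rescaled so the total matches the run length; and
    outcomes from the fixed-SSRT race rule (stop succeeds iff RT > SSD + SSRT).
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = config.n_trials
    n_stop = int(round(n * config.stop_proportion))
    types = np.array(["go"] * (n - n_stop) + ["stop"] * n_stop)
    rng.shuffle(types)
    isis = rng.uniform(*config.isi_range_s, size=n)
    isis *= config.run_duration_s / isis.sum()
    onsets = np.cumsum(isis)
    rts = rng.uniform(*config.rt_range_s, size=n)
    ssds = np.where(types == "stop", rng.uniform(*config.ssd_range_s, size=n), np.nan)
    outcome = np.where(types == "go", "go_response",
                       np.where(rts > ssds + config.ssrt_s, "stop_success", "stop_fail"))
    return pd.DataFrame({
        "trial_id": np.arange(n),
        "onset_s": onsets,
        "trial_type": types,
        "rt_s": rts,
        "ssd_s": ssds,
        "outcome": outcome,
        "isi_s": isis,
    })


def simulate_state_sequence(trials: pd.DataFrame, config: SimulationConfig,
                            rng: np.random.Generator | None = None) -> GroundTruth:
    """Draw per-trial latent state chains over the D FIR delay bins.

    Each trial starts from a trial-type-conditioned initial distribution and
    evolves by the regime's stay/switch chain; chains never bridge trials.
    """
    if len(trials) == 0:
        raise ValueError("trial table is empty")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    D = config.n_delays
    A = config.transition_matrix()
    cum_A = np.cumsum(A, axis=1)
    R = len(trials)
    states = np.empty(R * D, dtype=np.intp)
    u = rng.random((R, D))
    for r, ttype in enumerate(trials["trial_type"].to_numpy()):
        init = np.cumsum(np.asarray(config.initial_state_probs[ttype], dtype=float))
        s = int(np.searchsorted(init, u[r, 0], side="right"))
        states[r * D] = s
        for d in range(1, D):
            s = int(np.searchsorted(cum_A[s], u[r, d], side="right"))
            states[r * D + d] = s
    return GroundTruth(
        state_seq=states,
        trials=np.repeat(np.arange(R), D),
        delays=np.tile(np.arange(D), R),
        regime=config.transition_regime,
        noise_level=config.noise_level,
    )


def simulate_fir_bold(truth: GroundTruth, config: SimulationConfig,
                      rng: np.random.Generator | None = None,
                      return_amplitudes: bool = False):
    """Generate the z-scored K x N FIR-amplitude matrix for one subject.

    Each (state, node) amplitude is drawn once per subject from its state's
    amplitude range; each frame's observation is that amplitude plus
    Gaussian noise, then every node column is z-scored across all K frames.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    expected = truth.trials.max() + 1
    if truth.K != expected * config.n_delays:
        raise ValueError("ground truth dimensions inconsistent with config")
    N = config.n_nodes
    amps = np.empty((N_STATES, N))
    for c in range(N_STATES):
        lo, hi = config.state_amplitude_ranges[c]
        amps[c] = rng.uniform(lo, hi, size=N)
    values = amps[truth.state_seq] + rng.normal(0.0, config.noise_sd, size=(truth.K, N))
    fir = FirSeries(values=values, trials=truth.trials.copy(),
                    delays=truth.delays.copy(), zscored=False).zscore()
    if return_amplitudes:
        return fir, amps
    return fir


def simulate_subject(config: SimulationConfig,
                     rng: np.random.Generator | None = None
                     ) -> tuple[pd.DataFrame, GroundTruth, FirSeries]:
    """Run the full generative chain for one subject with a single RNG stream."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    trials = simulate_behavior(config, rng)
    truth = simulate_state_sequence(trials, config, rng)
    fir = simulate_fir_bold(truth, config, rng)
    return trials, truth, fir


def simulate_cohort(n_subjects_per_cell: int, seed: int | None = None,
                    base_config: SimulationConfig | None = None,
                    regimes: Sequence[str] = REGIMES,
                    noise_levels: Sequence[str] = NOISE_LEVELS):
    """Simulate a cohort balanced over transition regimes x noise levels.

    Returns parallel lists ``(configs, trial_tables, truths, fir_series)``;
    subject order is regime-major, then noise level, then replicate.  Each
    subject gets an independent child seed spawned from ``seed``.
    """
    base = base_config if base_config is not None else SimulationConfig()
    root = np.random.SeedSequence(seed)
    configs, tabs, truths, firs = [], [], [], []
    cells = [(r, nz) for r in regimes for nz in noise_levels]
    children = root.spawn(len(cells) * n_subjects_per_cell)
    i = 0
    for regime, noise in cells:
        for _ in range(n_subjects_per_cell):
            cfg = replace(base, transition_regime=regime, noise_level=noise, seed=None)
            rng = np.random.default_rng(children[i])
            i += 1
            tab, truth, fir = simulate_subject(cfg, rng)
            configs.append(cfg)
            tabs.append(tab)
            truths.append(truth)
            firs.append(fir)
    return configs, tabs, truths, firs
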