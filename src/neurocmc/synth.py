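"""IAT design generation and fully synthetic behavioral + EEG data.

The implicit association test (IAT) probes cross-modal correspondences
(CMCs) between auditory pitch and a visual feature (size or elevation) with
unisensory trials: each block fixes a key–stimulus mapping that is either
congruent (e.g. high pitch and small circle on one key) or incongruent, and
participants classify one auditory or visual stimulus per trial.  Congruency
is therefore a block-level property of the mapping, not of the stimulus.

This module generates that design and simulates complete datasets with
known ground truth:

* behavior — per-trial drift-diffusion parameters are derived from planted
  single-trial EEG component amplitudes through the same linear links the
  inference module estimates (drift delta = a0 + a1*y_early + a2*y_late +
  a3*S, boundary theta = b0 + b1*y_early + b2*y_late, non-decision time
  tau = g0 + g1*y_early + g2*y_late), and (rt, correct) is drawn from the
  Wiener first-passage process with the start fixed at the midpoint;
* EEG — epochs are a sum of planted components (unit-norm spatial pattern
  x temporal envelope x signed per-trial amplitude) plus spatially mixed
  AR(1) noise.  Congruent trials carry positive planted amplitudes and
  incongruent trials negative ones, matching the discriminant sign
  convention used downstream.

Ground truth is returned alongside every dataset so that decoding and
hierarchical inference can be validated by parameter recovery.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd
import yaml

from .wfpt import simulate_wiener

__all__ = [
    "DesignConfig",
    "GroundTruth",
    "EpochSet",
    "generate_design",
    "default_ground_truth",
    "simulate_behavior",
    "simulate_epochs",
    "simulate_pseudo_trial_table",
    "synthesize_dataset",
    "read_trials_csv",
    "write_trials_csv",
    "read_epochs_h5",
    "write_epochs_h5",
]

STIMULI = {
    "size": ["high_pitch", "low_pitch", "small_circle", "large_circle"],
    "elevation": ["high_pitch", "low_pitch", "high_circle", "low_circle"],
}
#: stimulus -> modality
MODALITY = {
    "high_pitch": "auditory", "low_pitch": "auditory",
    "small_circle": "visual", "large_circle": "visual",
    "high_circle": "visual", "low_circle": "visual",
}
#: congruent pairings per CMC type: high pitch <-> small / high-elevation
_CONGRUENT_PARTNER = {
    "size": {"high_pitch": "small_circle", "low_pitch": "large_circle"},
    "elevation": {"high_pitch": "high_circle", "low_pitch": "low_circle"},
}

TRIAL_COLUMNS = [
    "participant_id", "block_index", "mapping_id", "congruency", "modality",
    "stimulus_feature", "correct_key", "response_key", "correct", "rt",
]


@dataclass
class DesignConfig:
    """Counterbalancing arithmetic of the IAT session (per participant).

    Defaults reproduce the full experiment: 16 blocks x 4 stimuli x 20
    repetitions = 1,280 trials, half of them under congruent mappings.
    """

    n_blocks: int = 16
    trials_per_stimulus_per_block: int = 20
    cmc_type: str = "size"
    n_participants: int = 1
    rng_seed: int = 0

    def validate(self) -> "DesignConfig":
        if self.n_blocks % 2 != 0 or self.n_blocks < 2:
            raise ValueError(
                f"n_blocks must be even and >= 2 (half congruent, half "
                f"incongruent mappings), got {self.n_blocks}")
        if self.trials_per_stimulus_per_block < 1:
            raise ValueError("trials_per_stimulus_per_block must be >= 1")
        if self.cmc_type not in STIMULI:
            raise ValueError(f"cmc_type must be one of {sorted(STIMULI)}")
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        return self


def _key_mappings(cmc_type: str) -> list[dict]:
    """The four key-stimulus mappings: congruency x key-side counterbalance.

    A mapping assigns one auditory and one visual stimulus to the left key
    and the complementary pair to the right key.
    """
    partner = _CONGRUENT_PARTNER[cmc_type]
    hi, lo = "high_pitch", "low_pitch"
    mappings = []
    for congruency in ("congruent", "incongruent"):
        vis_hi = partner[hi] if congruency == "congruent" else partner[lo]
        vis_lo = partner[lo] if congruency == "congruent" else partner[hi]
        for side in ("left", "right"):
            other = "right" if side == "left" else "left"
            key_of = {hi: side, vis_hi: side, lo: other, vis_lo: other}
            mappings.append({"congruency": congruency, "key_of": key_of})
    return mappings


def generate_design(config: DesignConfig) -> pd.DataFrame:
    """Generate the trial table of the IAT design.

    Blocks cycle deterministically through the four key-stimulus mappings
    (congruent/incongruent alternating so any even block count is split
    half/half); trial order within a block is randomized by the seed.
    Returns one row per trial with ``rt``/``correct`` unset.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    mappings = _key_mappings(config.cmc_type)
    stimuli = STIMULI[config.cmc_type]
    rows = []
    for p in range(config.n_participants):
        for b in range(config.n_blocks):
            # alternate congruency each block; alternate key-side every two
            m_id = (b % 2) * 2 + (b // 2) % 2
            mapping = mappings[m_id]
            block_stims = np.repeat(stimuli, config.trials_per_stimulus_per_block)
            rng.shuffle(block_stims)
            for stim in block_stims:
                rows.append((
                    p, b, m_id, mapping["congruency"], MODALITY[stim], stim,
                    mapping["key_of"][stim], pd.NA, pd.NA, np.nan,
                ))
    df = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    df["correct"] = df["correct"].astype("boolean")
    return df


# ---------------------------------------------------------------------------
# Ground truth


@dataclass
class GroundTruth:
    """Generating parameters of a synthetic dataset.

    ``alpha``/``beta``/``gamma`` hold the group-mean regression coefficients
    of the drift / boundary / non-decision-time links, one row per
    congruency condition (row 0 congruent, row 1 incongruent):
    alpha = (a0, a1, a2, a3), beta = (b0, b1, b2), gamma = (g0, g1, g2),
    where a1/b1/g1 weight the Early amplitude, a2/b2/g2 the Late amplitude
    and a3 the modality predictor S (0 = auditory, 1 = visual).
    ``coef_sd`` gives the between-participant SD of every coefficient
    (same shapes).  Spatial patterns are unit-norm channel vectors.
    """

    alpha: np.ndarray
    beta: np.ndarray
    gamma: np.ndarray
    alpha_sd: np.ndarray
    beta_sd: np.ndarray
    gamma_sd: np.ndarray
    amp_mean: float = 1.5
    amp_sd: float = 0.5
    patterns: np.ndarray | None = None          # (2, n_channels), unit norm
    component_windows: tuple = ((0.125, 0.300), (0.400, 0.600))
    noise_sd: float = 2.5
    noise_ar: float = 0.95
    n_channels: int = 64
    participant_coefs: dict | None = None       # filled by draw_participants

    conditions = ("congruent", "incongruent")

    def ensure_patterns(self, rng: np.random.Generator) -> np.ndarray:
        """Two orthonormal random channel patterns (Early, Late)."""
        if self.patterns is None:
            m = rng.standard_normal((self.n_channels, 2))
            q, _ = np.linalg.qr(m)
            self.patterns = np.ascontiguousarray(q[:, :2].T)
        return self.patterns

    def draw_participants(self, n_participants: int, rng: np.random.Generator) -> dict:
        """Draw participant-level coefficients around the group means."""
        coefs = {}
        for name in ("alpha", "beta", "gamma"):
            mu = getattr(self, name)
            sd = getattr(self, name + "_sd")
            coefs[name] = mu[None] + sd[None] * rng.standard_normal(
                (n_participants,) + mu.shape)
        self.participant_coefs = coefs
        return coefs

    def trial_params(self, participant, condition_idx, y_early, y_late, s):
        """Per-trial (delta, theta, tau) via the linear links."""
        c = self.participant_coefs
        a = c["alpha"][participant, condition_idx]
        b = c["beta"][participant, condition_idx]
        g = c["gamma"][participant, condition_idx]
        delta = a[0] + a[1] * y_early + a[2] * y_late + a[3] * s
        theta = b[0] + b[1] * y_early + b[2] * y_late
        tau = g[0] + g[1] * y_early + g[2] * y_late
        return delta, theta, tau


def default_ground_truth(n_channels: int = 64, rng_seed: int = 0) -> GroundTruth:
    """Study-condition defaults for the synthetic generator.

    The sign pattern mirrors the qualitative structure of the findings the
    pipeline is meant to recover: in congruent trials the Early amplitude
    raises the drift rate and the Late amplitude shortens non-decision
    time; in incongruent trials the Late amplitude lowers the drift rate;
    the visual modality raises the drift rate in both conditions; boundary
    slopes are zero.  Magnitudes are set so the simulated behavior lands in
    the realistic IAT regime (accuracy ~0.9-0.95, median RT ~0.5-0.7 s,
    congruent faster and more accurate).
    """
    gt = GroundTruth(
        alpha=np.array([[1.4, 0.35, 0.0, 0.5],
                        [1.6, 0.0, -0.3, 0.5]]),
        beta=np.array([[1.4, 0.0, 0.0],
                       [1.5, 0.0, 0.0]]),
        gamma=np.array([[0.28, 0.0, -0.03],
                        [0.32, 0.0, 0.0]]),
        alpha_sd=np.array([[0.15, 0.08, 0.08, 0.08],
                           [0.15, 0.08, 0.08, 0.08]]),
        beta_sd=np.array([[0.10, 0.03, 0.03],
                          [0.10, 0.03, 0.03]]),
        gamma_sd=np.array([[0.03, 0.008, 0.008],
                           [0.03, 0.008, 0.008]]),
        n_channels=n_channels,
    )
    gt.ensure_patterns(np.random.default_rng(rng_seed))
    return gt


# ---------------------------------------------------------------------------
# Behavioral simulation


def simulate_behavior(design: pd.DataFrame, truth: GroundTruth,
                      rng_seed: int = 0) -> pd.DataFrame:
    """Fill rt / correct / response_key by simulating the diffusion process.

    Per-trial diffusion parameters come from the ground-truth links applied
    to planted single-trial component amplitudes (stored in the returned
    table as ``y_early`` / ``y_late``, unsigned) and the modality predictor
    S (0 = auditory, 1 = visual).  Accuracy coding: an upper-boundary
    passage is a correct response.
    """
    rng = np.random.default_rng(rng_seed)
    df = design.copy().reset_index(drop=True)
    n = len(df)
    if truth.participant_coefs is None:
        truth.draw_participants(int(df["participant_id"].max()) + 1, rng)
    # planted unsigned amplitudes (truncated normal, strictly positive)
    y_early = _trunc_normal(rng, truth.amp_mean, truth.amp_sd, n)
    y_late = _trunc_normal(rng, truth.amp_mean, truth.amp_sd, n)
    s = (df["modality"] == "visual").to_numpy().astype(float)
    cond = (df["congruency"] == "incongruent").to_numpy().astype(int)
    part = df["participant_id"].to_numpy()

    delta = np.empty(n)
    theta = np.empty(n)
    tau = np.empty(n)
    for p in np.unique(part):
        for c in (0, 1):
            m = (part == p) & (cond == c)
            delta[m], theta[m], tau[m] = truth.trial_params(
                p, c, y_early[m], y_late[m], s[m])
    if np.any(theta <= 0) or np.any(tau <= 0):
        raise ValueError("ground truth produced non-positive theta or tau")
    rt, upper = simulate_wiener(delta, theta, tau,
                                rng_seed=int(rng.integers(2**31 - 1)))
    df["rt"] = rt
    df["correct"] = pd.array(upper, dtype="boolean")
    other = {"left": "right", "right": "left"}
    df["response_key"] = np.where(
        upper, df["correct_key"], df["correct_key"].map(other))
    df["y_early"] = y_early
    df["y_late"] = y_late
    df["S"] = s
    return df


def _trunc_normal(rng, mean, sd, n):
    x = mean + sd * rng.standard_normal(n)
    bad = x <= 0
    while np.any(bad):  # redraw; negligible mass for default mean/sd
        x[bad] = mean + sd * rng.standard_normal(bad.sum())
        bad = x <= 0
    return x


# ---------------------------------------------------------------------------
# EEG epochs


@dataclass
class EpochSet:
    """Epoched multichannel signal: trial x channel x time.

    ``times`` holds sample times in seconds relative to the alignment
    event (stimulus onset or response).
    """

    data: np.ndarray
    sampling_rate: float
    times: np.ndarray
    alignment: str = "stimulus"
    channel_names: Sequence[str] = ()
    trial_index: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be trial x channel x time")
        if self.data.shape[2] != self.times.size:
            raise ValueError("time axis mismatch between data and times")
        if not self.channel_names:
            self.channel_names = [f"ch{i:02d}" for i in range(self.data.shape[1])]
        if self.trial_index is None:
            self.trial_index = np.arange(self.data.shape[0])

    @property
    def epoch_window(self) -> tuple[float, float]:
        return float(self.times[0]), float(self.times[-1])

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]


def simulate_epochs(trials: pd.DataFrame, truth: GroundTruth,
                    epoch_window: tuple[float, float] = (-0.3, 0.7),
                    sampling_rate: float = 200.0,
                    rng_seed: int = 0) -> EpochSet:
    """Synthesize stimulus-locked epochs with planted components.

    epoch = sum_k pattern_k * envelope_k(t) * amplitude_k(trial) + noise,
    where the signed amplitude is the trial's planted y (positive for
    congruent, negative for incongruent trials) and the noise is AR(1) in
    time, mixed across channels by a random orthogonal matrix with a
    decaying spectrum (spatially correlated, pink-ish in time).
    """
    rng = np.random.default_rng(rng_seed)
    n_trials = len(trials)
    if "y_early" not in trials.columns:
        raise ValueError("trials must carry planted amplitudes; run simulate_behavior first")
    dt = 1.0 / sampling_rate
    times = np.arange(round((epoch_window[1] - epoch_window[0]) * sampling_rate)) \
        * dt + epoch_window[0]
    patterns = truth.ensure_patterns(rng)
    D = patterns.shape[1]

    envs = []
    for (t0, t1) in truth.component_windows:
        if t0 < times[0] or t1 > times[-1] + dt:
            raise ValueError(
                f"component window ({t0}, {t1}) outside epoch window {epoch_window}")
        env = np.zeros_like(times)
        inside = (times >= t0) & (times <= t1)
        # Hann bump over the latency window
        env[inside] = np.sin(np.pi * (times[inside] - t0) / (t1 - t0)) ** 2
        envs.append(env)
    envs = np.asarray(envs)  # (2, T)

    sign = np.where(trials["congruency"].to_numpy() == "congruent", 1.0, -1.0)
    amps = np.stack([sign * trials["y_early"].to_numpy(),
                     sign * trials["y_late"].to_numpy()])  # (2, n)

    # signal: (n, D, T)
    data = np.einsum('kn,kd,kt->ndt', amps, patterns, envs).astype(np.float32)
    data += _spatially_mixed_ar1_noise(
        rng, n_trials, D, times.size, truth.noise_ar, truth.noise_sd)
    return EpochSet(data=data, sampling_rate=sampling_rate, times=times,
                    alignment="stimulus", trial_index=trials.index.to_numpy())


def _spatially_mixed_ar1_noise(rng, n_trials, n_channels, n_times, phi, sd):
    """AR(1)-in-time innovations mixed through a random orthogonal matrix
    with a decaying spectrum, giving correlated channels."""
    if sd <= 0:
        return np.zeros((n_trials, n_channels, n_times), dtype=np.float32)
    innov_sd = sd * np.sqrt(1.0 - phi ** 2)
    x = rng.standard_normal((n_trials, n_channels, n_times)).astype(np.float32)
    x[..., 0] *= sd / innov_sd
    x *= innov_sd
    # AR(1) recursion along time
    for t in range(1, n_times):
        x[..., t] += phi * x[..., t - 1]
    q, _ = np.linalg.qr(rng.standard_normal((n_channels, n_channels)))
    spectrum = np.linspace(1.5, 0.5, n_channels)
    mix = (q * spectrum[None, :]) @ q.T
    return np.einsum('dc,nct->ndt', mix.astype(np.float32), x)


# ---------------------------------------------------------------------------
# Direct pseudo-trial table simulation (for inference-stage recovery tests)


def simulate_pseudo_trial_table(truth: GroundTruth, n_participants: int = 8,
                                n_pseudo_per_participant: int = 400,
                                rng_seed: int = 0) -> pd.DataFrame:
    """Simulate the regressor table the hierarchical model consumes.

    Each row is a pseudo-trial with congruency-normalized (unsigned)
    amplitudes ``y_early_max`` / ``y_late_max``, modality predictor ``S``
    and a single (rt, correct) draw from the per-row diffusion parameters.
    This bypasses the EEG stage so inference can be validated directly
    against known coefficients.
    """
    rng = np.random.default_rng(rng_seed)
    truth.draw_participants(n_participants, rng)
    rows = []
    for p in range(n_participants):
        n = n_pseudo_per_participant
        cond = np.arange(n) % 2  # half congruent, half incongruent
        y1 = _trunc_normal(rng, truth.amp_mean, truth.amp_sd, n)
        y2 = _trunc_normal(rng, truth.amp_mean, truth.amp_sd, n)
        s = rng.integers(0, 2, n).astype(float)
        delta = np.empty(n)
        theta = np.empty(n)
        tau = np.empty(n)
        for c in (0, 1):
            m = cond == c
            delta[m], theta[m], tau[m] = truth.trial_params(p, c, y1[m], y2[m], s[m])
        rt, upper = simulate_wiener(delta, theta, tau,
                                    rng_seed=int(rng.integers(2**31 - 1)))
        rows.append(pd.DataFrame({
            "participant_id": p,
            "congruency": np.where(cond == 0, "congruent", "incongruent"),
            "S": s, "y_early_max": y1, "y_late_max": y2,
            "rt": rt, "correct": upper,
        }))
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# One-call dataset synthesis


def synthesize_dataset(n_participants: int = 8, n_blocks: int = 4,
                       trials_per_stimulus_per_block: int = 20,
                       cmc_type: str = "size", n_channels: int = 64,
                       rng_seed: int = 0, truth: GroundTruth | None = None):
    """Generate a complete desk-scale dataset: trials, epochs, ground truth.

    Defaults: 8 participants x 4 blocks x 20 repetitions (320 trials per
    participant); the full experimental scale (16 blocks) is available via
    the arguments.
    """
    cfg = DesignConfig(n_blocks=n_blocks,
                       trials_per_stimulus_per_block=trials_per_stimulus_per_block,
                       cmc_type=cmc_type, n_participants=n_participants,
                       rng_seed=rng_seed)
    if truth is None:
        truth = default_ground_truth(n_channels=n_channels, rng_seed=rng_seed + 1)
    design = generate_design(cfg)
    trials = simulate_behavior(design, truth, rng_seed=rng_seed + 2)
    epochs = simulate_epochs(trials, truth, rng_seed=rng_seed + 3)
    return trials, epochs, truth


# ---------------------------------------------------------------------------
# File formats: behavioral CSV, epoch HDF5, config YAML


def write_trials_csv(trials: pd.DataFrame, path) -> None:
    trials.to_csv(path, index=False)


def read_trials_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "correct" in df.columns:
        df["correct"] = df["correct"].astype("boolean")
    return df


def write_epochs_h5(epochs: EpochSet, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data.astype(np.float32))
        f.create_dataset("time", data=epochs.times)
        f.create_dataset("channels",
                         data=np.array(list(epochs.channel_names), dtype="S"))
        f.create_dataset("trial_index", data=epochs.trial_index)
        f.attrs["sampling_rate"] = epochs.sampling_rate
        f.attrs["alignment"] = epochs.alignment


def read_epochs_h5(path) -> EpochSet:
    with h5py.File(path, "r") as f:
        return EpochSet(
            data=f["data"][()],
            times=f["time"][()],
            channel_names=[c.decode() for c in f["channels"][()]],
            trial_index=f["trial_index"][()],
            sampling_rate=float(f.attrs["sampling_rate"]),
            alignment=str(f.attrs["alignment"]),
        )


def write_design_config(config: DesignConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(dataclasses.asdict(config)))


def read_design_config(path) -> DesignConfig:
    return DesignConfig(**yaml.safe_load(Path(path).read_text()))


def ground_truth_to_json(truth: GroundTruth) -> str:
    d = dataclasses.asdict(truth)
    for k, v in d.items():
        if isinstance(v, np.ndarray):
            d[k] = v.tolist()
    if d.get("participant_coefs"):
        d["participant_coefs"] = {k: np.asarray(v).tolist()
                                  for k, v in d["participant_coefs"].items()}
    return json.dumps(d)


def ground_truth_from_json(s: str) -> GroundTruth:
    d = json.loads(s)
    for k in ("alpha", "beta", "gamma", "alpha_sd", "beta_sd", "gamma_sd", "patterns"):
        if d.get(k) is not None:
            d[k] = np.asarray(d[k])
    if d.get("participant_coefs"):
        d["participant_coefs"] = {k: np.asarray(v)
                                  for k, v in d["participant_coefs"].items()}
    d["component_windows"] = tuple(tuple(w) for w in d["component_windows"])
    return GroundTruth(**d)
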