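"""Single-trial multivariate EEG analysis.

The decoding chain: epochs are low-pass filtered and baseline corrected;
same-condition trials are averaged into pseudo-trials to raise the
single-trial signal-to-noise ratio; a shrinkage-regularized linear
discriminant is fit in a sliding window (60 ms, stepped by 5 ms, data
averaged over time within the window), giving per-window spatial filters
``w`` and one-dimensional projections y(t) = w^T x(t); classifier
performance is the ROC AUC from Monte-Carlo stratified cross-validation;
group-level significance uses a max-statistic label-randomization
threshold (the percentile of the distribution of the maximum
group-averaged AUC over time controls the family-wise error rate over
windows); forward-model topographies a = X^T y / (y^T y) express each
discriminant component in channel space and are clustered over time with
k-means (k chosen by silhouette) to delineate components; per-participant
peak discriminant amplitudes inside the Early/Late component windows feed
the hierarchical drift-diffusion model as neural regressors.

Sign convention throughout: projections are oriented (and centered at the
midpoint between class means) so that the congruent / positive class mean
is >= 0 — larger positive amplitudes mean more evidence for the congruent
class, larger negative amplitudes more evidence for the incongruent class.

Covariance regularization is Ledoit-Wolf analytic shrinkage toward a
scaled identity, computed here in batched form across all sliding windows
at once (the shrinkage intensity is the standard optimal-ratio estimate,
evaluated per window).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.stats import rankdata
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score
from sklearn.model_selection import StratifiedShuffleSplit

from .synth import EpochSet

__all__ = [
    "SlidingWindowConfig",
    "PseudoTrialSet",
    "DecodingResult",
    "ClusterSolution",
    "SEARCH_WINDOW_PRESETS",
    "epoch_preprocess",
    "build_pseudo_trials",
    "fit_window_lda",
    "crossval_auc",
    "decode_participant",
    "bootstrap_threshold",
    "forward_model",
    "forward_model_series",
    "temporal_clustering",
    "extract_peak_amplitudes",
    "realign_to_response",
]

#: Early/Late component search windows (seconds, window-onset convention),
#: per CMC type.  Two variants are in internal use for the Early bound and
#: the Late onset; "default" is the component definition adopted for the
#: reported analyses, "alternate" the regressor-extraction variant.
SEARCH_WINDOW_PRESETS = {
    "default": {
        "size": {"early": (0.125, 0.300), "late": (0.400, 0.600)},
        "elevation": {"early": (0.125, 0.350), "late": (0.400, 0.600)},
    },
    "alternate": {
        "size": {"early": (0.125, 0.350), "late": (0.450, 0.600)},
        "elevation": {"early": (0.125, 0.300), "late": (0.450, 0.600)},
    },
}


@dataclass(frozen=True)
class SlidingWindowConfig:
    """Sliding-window segmentation; timestamps refer to the window ONSET."""

    window_length: float = 0.060
    step: float = 0.005

    def validate(self):
        if not (self.window_length > self.step > 0):
            raise ValueError("require window_length > step > 0")
        return self


@dataclass
class PseudoTrialSet:
    """Condition-averaged pseudo-trials: data (n, channels, time)."""

    data: np.ndarray
    labels: np.ndarray
    info: pd.DataFrame            # per pseudo-trial: label, congruency, rt, ...
    times: np.ndarray
    sampling_rate: float
    membership: list = field(default_factory=list)  # source-trial row groups
    _window_cache: dict = field(default_factory=dict, repr=False)

    @property
    def n_pseudo(self) -> int:
        return self.data.shape[0]

    def windowed(self, cfg: "SlidingWindowConfig"):
        """Cached sliding-window averages (n, D, W) and window onsets."""
        key = (cfg.window_length, cfg.step)
        if key not in self._window_cache:
            self._window_cache[key] = window_average(self.data, self.times, cfg)
        return self._window_cache[key]


@dataclass
class DecodingResult:
    """Per-window discriminant output for one participant."""

    onsets: np.ndarray            # window-onset times (s)
    filters: np.ndarray           # (n_windows, channels) spatial filters w
    projections: np.ndarray       # (n_pseudo, n_windows) y(t)
    auc: np.ndarray               # (n_windows,) cross-validated AUC
    info: pd.DataFrame
    significance_threshold: float | None = None


@dataclass
class ClusterSolution:
    k: int
    assignments: np.ndarray
    silhouette: float
    time_ranges: list            # (cluster_id, t_start, t_end) dominant ranges


# ---------------------------------------------------------------------------
# Epoch preprocessing (already-epoched data only)


def epoch_preprocess(epochs: EpochSet, lowpass_hz: float = 30.0,
                     baseline: tuple[float, float] = (-0.3, 0.0)) -> EpochSet:
    """Zero-phase low-pass filter per channel, then baseline correction.

    The baseline interval must lie inside the epoch window; the per-epoch,
    per-channel mean over it is subtracted.
    """
    fs = epochs.sampling_rate
    data = np.asarray(epochs.data, dtype=np.float64)
    if lowpass_hz is not None:
        if lowpass_hz >= fs / 2:
            raise ValueError(
                f"low-pass cutoff {lowpass_hz} Hz must be below Nyquist {fs / 2} Hz")
        sos = sps.butter(4, lowpass_hz, btype="low", fs=fs, output="sos")
        data = sps.sosfiltfilt(sos, data, axis=-1)
    if baseline is not None:
        t = epochs.times
        m = (t >= baseline[0]) & (t <= baseline[1])
        if not m.any() or baseline[0] < t[0] - 1e-9:
            raise ValueError(f"baseline {baseline} outside epoch window "
                             f"{epochs.epoch_window}")
        data = data - data[:, :, m].mean(axis=-1, keepdims=True)
    return EpochSet(data=data.astype(np.float32), sampling_rate=fs,
                    times=epochs.times, alignment=epochs.alignment,
                    channel_names=epochs.channel_names,
                    trial_index=epochs.trial_index)


# ---------------------------------------------------------------------------
# Pseudo-trials


def build_pseudo_trials(epochs: EpochSet, trials: pd.DataFrame,
                        group_size: int = 4, rng_seed: int = 0,
                        label_column: str = "congruency",
                        condition_keys: Sequence[str] = ("congruency",
                                                         "modality", "correct"),
                        ) -> PseudoTrialSet:
    """Average randomly grouped same-condition trials into pseudo-trials.

    Within each condition cell (by default congruency x modality x
    correctness) trials are randomly partitioned into groups of
    ``group_size``; incomplete remainder groups are discarded; the epoch
    data are averaged within each group and the pseudo-trial RT is the
    mean member RT.  Cells with fewer than ``group_size`` trials yield no
    pseudo-trials (warned).
    """
    if group_size < 1:
        raise ValueError("group_size must be >= 1")
    trials = trials.reset_index(drop=True)
    if len(trials) != epochs.data.shape[0]:
        raise ValueError("trial table and epochs must align one-to-one")
    rng = np.random.default_rng(rng_seed)
    data_rows, info_rows, membership = [], [], []
    for cell, idx in trials.groupby(list(condition_keys), observed=True).indices.items():
        if idx.size < group_size:
            warnings.warn(f"condition cell {cell}: {idx.size} trials "
                          f"< group_size {group_size}, no pseudo-trials")
            continue
        idx = rng.permutation(idx)
        n_groups = idx.size // group_size
        for g in range(n_groups):
            members = np.sort(idx[g * group_size:(g + 1) * group_size])
            data_rows.append(epochs.data[members].mean(axis=0))
            row = {k: trials.iloc[members[0]][k] for k in condition_keys}
            row["label"] = trials.iloc[members[0]][label_column]
            row["rt"] = float(trials.iloc[members]["rt"].mean())
            info_rows.append(row)
            membership.append(members)
    if not info_rows:
        raise ValueError("no condition cell had enough trials for a pseudo-trial")
    info = pd.DataFrame(info_rows)
    return PseudoTrialSet(
        data=np.asarray(data_rows, dtype=np.float32),
        labels=info["label"].to_numpy(), info=info,
        times=epochs.times, sampling_rate=epochs.sampling_rate,
        membership=membership)


# ---------------------------------------------------------------------------
# Batched shrinkage LDA over sliding windows


def window_average(data: np.ndarray, times: np.ndarray,
                   cfg: SlidingWindowConfig):
    """Average (n, D, T) data inside each sliding window -> (n, D, W), onsets."""
    cfg.validate()
    dt = float(times[1] - times[0])
    wlen = max(1, int(round(cfg.window_length / dt)))
    step = max(1, int(round(cfg.step / dt)))
    starts = np.arange(0, times.size - wlen + 1, step)
    cs = np.cumsum(np.asarray(data, dtype=np.float64), axis=-1)
    cs = np.concatenate([np.zeros(cs.shape[:-1] + (1,)), cs], axis=-1)
    out = (cs[..., starts + wlen] - cs[..., starts]) / wlen
    # float32 keeps the batched covariance/solve hot path fast; shrinkage
    # regularization makes the reduced precision immaterial
    return out.astype(np.float32), times[starts]


def _class_split(labels):
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError(f"exactly two classes required, got {classes.tolist()}")
    # orient so that "congruent" (if present) is the positive class
    if "congruent" in classes.tolist():
        classes = np.array([c for c in classes if c != "congruent"] + ["congruent"],
                           dtype=classes.dtype)
    return classes


def _batched_lda_filters(Xw: np.ndarray, y01: np.ndarray,
                         shrinkage: float | None = None):
    """Shrinkage-LDA filters for every window of Xw (n, D, W).

    Returns (w (W, D), mid (W,)) with w = Sigma_shrunk^-1 (mu1 - mu0),
    oriented so the positive-class mean projection exceeds the negative,
    and mid the projection midpoint between class means (used to center).
    """
    n, D, W = Xw.shape
    Xw = np.asarray(Xw, dtype=np.float32)
    m1 = Xw[y01 == 1].mean(axis=0)            # (D, W)
    m0 = Xw[y01 == 0].mean(axis=0)
    Xc = Xw.copy()
    Xc[y01 == 1] -= m1[None]
    Xc[y01 == 0] -= m0[None]
    Xt = np.ascontiguousarray(Xc.transpose(2, 0, 1))      # (W, n, D)
    S = Xt.transpose(0, 2, 1) @ Xt / n                    # MLE pooled covariance
    tr = np.trace(S, axis1=1, axis2=2)
    mu = tr / D                                           # (W,)
    eye = np.eye(D, dtype=S.dtype)
    frob_S = np.einsum('wde,wde->w', S, S)
    d2 = frob_S - 2.0 * mu * tr + D * mu ** 2             # ||S - mu I||_F^2
    if shrinkage is None:
        sq = np.einsum('wnd,wnd->wn', Xt, Xt)             # ||x_i||^2 per window
        b2 = ((sq ** 2).sum(axis=1) - n * frob_S) / n ** 2
        rho = np.where(d2 > 1e-30, np.minimum(b2, d2) / np.maximum(d2, 1e-30), 1.0)
    else:
        rho = np.full(W, float(shrinkage))
    S_sh = (1.0 - rho)[:, None, None] * S \
        + (rho * np.maximum(mu, 1e-12))[:, None, None] * eye[None]
    diff = (m1 - m0).T                                    # (W, D)
    w = np.linalg.solve(S_sh.astype(np.float32),
                        diff[..., None].astype(np.float32))[..., 0].astype(np.float64)
    # orientation: positive class mean projection >= negative class
    sep = np.einsum('wd,dw->w', w, m1 - m0)
    w[sep < 0] *= -1.0
    mid = 0.5 * np.einsum('wd,dw->w', w, m1 + m0)
    return w, mid


def _project(Xw: np.ndarray, w: np.ndarray, mid: np.ndarray) -> np.ndarray:
    """Centered projections y = w^T x - mid, shape (n, W)."""
    return np.einsum('ndw,wd->nw', Xw, w, optimize=True) - mid[None]


def fit_window_lda(pseudo_trials: PseudoTrialSet, window: tuple[float, float],
                   shrinkage: float | None = None):
    """Fit the regularized LDA on one time window.

    Data are averaged over the window's samples before fitting.  Returns
    (w, projections) with the projection sign convention enforced
    (congruent / positive class mean >= 0).
    """
    t = pseudo_trials.times
    m = (t >= window[0] - 1e-9) & (t < window[1] - 1e-9)
    if not m.any():
        raise ValueError(f"window {window} contains no samples")
    Xw = np.asarray(pseudo_trials.data, dtype=np.float64)[:, :, m].mean(
        axis=-1)[..., None]
    classes = _class_split(pseudo_trials.labels)
    y01 = (pseudo_trials.labels == classes[1]).astype(int)
    w, mid = _batched_lda_filters(Xw, y01, shrinkage)
    return w[0], _project(Xw, w, mid)[:, 0]


def _auc_columns(scores: np.ndarray, y01: np.ndarray) -> np.ndarray:
    """ROC AUC of every column of scores (n, W) via the rank-sum identity."""
    n1 = int(y01.sum())
    n0 = y01.size - n1
    ranks = rankdata(scores, axis=0)
    return (ranks[y01 == 1].sum(axis=0) - n1 * (n1 + 1) / 2) / (n1 * n0)


def crossval_auc(pseudo_trials: PseudoTrialSet,
                 cfg: SlidingWindowConfig = SlidingWindowConfig(),
                 n_splits: int = 20, test_fraction: float = 0.2,
                 rng_seed: int = 0, shrinkage: float | None = None,
                 labels: np.ndarray | None = None):
    """Monte-Carlo stratified cross-validated AUC time course.

    For each of ``n_splits`` random stratified train/test splits the LDA is
    refit per window on the training pseudo-trials and the test-set ROC
    AUC computed; the returned curve is the mean over splits.  Returns
    (auc (W,), onsets (W,)).
    """
    if labels is None:
        labels = pseudo_trials.labels
    classes = _class_split(labels)
    y01 = (labels == classes[1]).astype(int)
    if min(y01.sum(), (1 - y01).sum()) < 2:
        raise ValueError("need at least 2 pseudo-trials per class")
    Xw, onsets = pseudo_trials.windowed(cfg)
    sss = StratifiedShuffleSplit(n_splits=n_splits, test_size=test_fraction,
                                 random_state=rng_seed)
    auc = np.zeros(onsets.size)
    for tr_idx, te_idx in sss.split(Xw[:, 0, 0], y01):
        if len(np.unique(y01[te_idx])) < 2:  # unreachable under stratification
            raise RuntimeError("test split lost a class")
        w, mid = _batched_lda_filters(Xw[tr_idx], y01[tr_idx], shrinkage)
        auc += _auc_columns(_project(Xw[te_idx], w, mid), y01[te_idx])
    return auc / n_splits, onsets


def decode_participant(pseudo_trials: PseudoTrialSet,
                       cfg: SlidingWindowConfig = SlidingWindowConfig(),
                       n_splits: int = 20, rng_seed: int = 0,
                       shrinkage: float | None = None) -> DecodingResult:
    """Full single-participant decoding: filters, projections, CV AUC."""
    classes = _class_split(pseudo_trials.labels)
    y01 = (pseudo_trials.labels == classes[1]).astype(int)
    Xw, onsets = pseudo_trials.windowed(cfg)
    w, mid = _batched_lda_filters(Xw, y01, shrinkage)
    proj = _project(Xw, w, mid)
    auc, _ = crossval_auc(pseudo_trials, cfg, n_splits=n_splits,
                          rng_seed=rng_seed, shrinkage=shrinkage)
    return DecodingResult(onsets=onsets, filters=w, projections=proj,
                          auc=auc, info=pseudo_trials.info)


def bootstrap_threshold(pseudo_trial_sets: Sequence[PseudoTrialSet],
                        cfg: SlidingWindowConfig = SlidingWindowConfig(),
                        n_randomizations: int = 1000, percentile: float = 99.0,
                        n_splits: int = 20, rng_seed: int = 0,
                        shrinkage: float | None = None) -> float:
    """Group max-statistic significance threshold for the AUC time course.

    For each randomization the class labels are permuted within every
    participant, the cross-validated AUC time course recomputed, averaged
    across participants, and its maximum over windows recorded; the
    threshold is the requested percentile of that max distribution (the
    max operation makes exceeding it family-wise-error controlled over
    windows at 1 - percentile/100).
    """
    if n_randomizations < 100 and percentile >= 99:
        warnings.warn(f"{n_randomizations} randomizations give an unstable "
                      f"{percentile}th-percentile tail estimate")
    rng = np.random.default_rng(rng_seed)
    maxima = np.empty(n_randomizations)
    for r in range(n_randomizations):
        group = None
        for pset in pseudo_trial_sets:
            perm = rng.permutation(pset.labels)
            auc, _ = crossval_auc(
                pset, cfg, n_splits=n_splits, labels=perm,
                rng_seed=int(rng.integers(2**31 - 1)), shrinkage=shrinkage)
            group = auc if group is None else group + auc
        maxima[r] = (group / len(pseudo_trial_sets)).max()
    return float(np.percentile(maxima, percentile))


# ---------------------------------------------------------------------------
# Forward models and temporal clustering


def forward_model(projections: np.ndarray, windowed_data: np.ndarray,
                  normalize: bool = True) -> np.ndarray:
    """Forward-model topography a = X^T y / (y^T y) for one window.

    ``windowed_data``: (n_pseudo, channels) window-averaged EEG;
    ``projections``: (n_pseudo,) discriminant amplitudes.  The topography
    expresses the correlation of the discriminant component with each
    channel; it is unit-normalized for comparison/clustering.
    """
    y = np.asarray(projections, dtype=float)
    X = np.asarray(windowed_data, dtype=float)
    denom = float(y @ y)
    if denom <= 0 or np.isclose(y.std(), 0):
        raise ValueError("zero-variance projections: forward model undefined")
    a = X.T @ y / denom
    if normalize:
        nrm = np.linalg.norm(a)
        if nrm < 1e-12:
            warnings.warn("projections orthogonal to all channels; "
                          "returning zero topography")
            return a
        a = a / nrm
    return a


def forward_model_series(result: DecodingResult, pseudo_trials: PseudoTrialSet,
                         cfg: SlidingWindowConfig = SlidingWindowConfig()):
    """Unit-norm topography per sliding window, (n_windows, channels)."""
    Xw, onsets = pseudo_trials.windowed(cfg)
    topos = np.empty((onsets.size, Xw.shape[1]))
    for j in range(onsets.size):
        topos[j] = forward_model(result.projections[:, j], Xw[:, :, j])
    return topos, onsets


def temporal_clustering(topographies: np.ndarray, onsets: np.ndarray,
                        k_range: Sequence[int] = (1, 2, 3, 4, 5),
                        n_restarts: int = 50, rng_seed: int = 0) -> ClusterSolution:
    """Cluster topographies over time with k-means; pick k by silhouette.

    Topographies are expected unit-normalized (polarity retained — opposite
    polarity is a different component).  Returns assignments over windows
    and the dominant contiguous time range of each cluster.  If all
    topographies coincide the silhouette is undefined for k >= 2 and k = 1
    is returned.
    """
    A = np.asarray(topographies, dtype=float)
    n = A.shape[0]
    if n < 2:
        raise ValueError("need at least 2 windows to cluster")
    k_range = sorted(set(int(k) for k in k_range))
    if max(k_range) >= n:
        warnings.warn(f"fewer windows ({n}) than max k; shrinking k_range")
        k_range = [k for k in k_range if k < n] or [1]
    if np.allclose(A, A[0], atol=1e-10):
        return ClusterSolution(k=1, assignments=np.zeros(n, dtype=int),
                               silhouette=np.nan,
                               time_ranges=_dominant_ranges(np.zeros(n, int), onsets))
    best = None
    for k in k_range:
        if k < 2:
            continue
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=rng_seed)
        lab = km.fit_predict(A)
        if len(np.unique(lab)) < 2:
            continue
        sil = silhouette_score(A, lab, metric="euclidean")
        if best is None or sil > best[0]:
            best = (sil, k, lab)
    if best is None:
        return ClusterSolution(k=1, assignments=np.zeros(n, dtype=int),
                               silhouette=np.nan,
                               time_ranges=_dominant_ranges(np.zeros(n, int), onsets))
    sil, k, lab = best
    return ClusterSolution(k=k, assignments=lab, silhouette=float(sil),
                           time_ranges=_dominant_ranges(lab, onsets))


def _dominant_ranges(assignments, onsets):
    """Longest contiguous run of each cluster id, as (id, t_start, t_end)."""
    ranges = []
    for c in np.unique(assignments):
        best_len, best_start, cur_len, cur_start = 0, 0, 0, 0
        for i, a in enumerate(assignments):
            if a == c:
                if cur_len == 0:
                    cur_start = i
                cur_len += 1
                if cur_len > best_len:
                    best_len, best_start = cur_len, cur_start
            else:
                cur_len = 0
        ranges.append((int(c), float(onsets[best_start]),
                       float(onsets[best_start + best_len - 1])))
    return ranges


# ---------------------------------------------------------------------------
# Peak amplitudes for the neural regressors


def extract_peak_amplitudes(result: DecodingResult,
                            early_window: tuple[float, float],
                            late_window: tuple[float, float]) -> pd.DataFrame:
    """Per-pseudo-trial peak discriminant amplitudes for one participant.

    The peak is taken at the window of maximal cross-validated AUC inside
    each search range (window-onset convention).  Amplitudes are
    congruency-normalized: incongruent pseudo-trials carry negative
    projections by the sign convention, so their sign is flipped — after
    normalization a larger value always means more neural evidence for
    the trial's own condition.
    """
    out = result.info.copy()
    for name, win in (("early", early_window), ("late", late_window)):
        m = (result.onsets >= win[0] - 1e-9) & (result.onsets <= win[1] + 1e-9)
        if not m.any():
            raise ValueError(f"{name} search window {win} outside decoded "
                             f"range ({result.onsets[0]}, {result.onsets[-1]})")
        j = np.flatnonzero(m)[np.argmax(result.auc[m])]
        amps = result.projections[:, j].copy()
        if "congruency" in out.columns:
            amps[out["congruency"].to_numpy() == "incongruent"] *= -1.0
        out[f"y_{name}_max"] = amps
        out[f"{name}_peak_latency"] = float(result.onsets[j])
        out[f"{name}_peak_auc"] = float(result.auc[j])
    return out


# ---------------------------------------------------------------------------
# Response-locked realignment


def realign_to_response(epochs: EpochSet, trials: pd.DataFrame,
                        window: tuple[float, float] = (-0.4, 0.1)) -> EpochSet:
    """Re-cut stimulus-locked epochs relative to each trial's response.

    The sample at stimulus time ``rt`` becomes response time 0.  Trials
    whose response window falls outside the source epoch are dropped with
    a warning.
    """
    trials = trials.reset_index(drop=True)
    if len(trials) != epochs.data.shape[0]:
        raise ValueError("trial table and epochs must align one-to-one")
    fs = epochs.sampling_rate
    n_out = int(round((window[1] - window[0]) * fs))
    new_times = np.arange(n_out) / fs + window[0]
    rts = trials["rt"].to_numpy(dtype=float)
    start = np.round((rts + window[0] - epochs.times[0]) * fs).astype(int)
    ok = (start >= 0) & (start + n_out <= epochs.times.size) & np.isfinite(rts)
    if not ok.all():
        warnings.warn(f"dropping {int((~ok).sum())} trials whose response "
                      "window exceeds the source epoch")
    if not ok.any():
        raise ValueError("no trial admits the requested response window")
    idx = np.flatnonzero(ok)
    data = np.stack([epochs.data[i, :, start[i]:start[i] + n_out] for i in idx])
    return EpochSet(data=data, sampling_rate=fs, times=new_times,
                    alignment="response", channel_names=epochs.channel_names,
                    trial_index=np.asarray(epochs.trial_index)[idx])
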