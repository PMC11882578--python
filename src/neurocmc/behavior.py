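"""Behavioral preprocessing and statistics.

RT outliers are removed with a fixed lower bound (250 ms, anticipatory
responses) and a robust per-participant upper bound anchored at the median:
rt > median + 3 * 1.4826 * MAD, where MAD is the raw median absolute
deviation (1.4826 * MAD estimates the SD under normality).  Condition
contrasts of participant-level medians/means use paired sign-flip
permutation tests, with Cliff's delta as the non-parametric effect size for
RTs and the paired-differences Cohen's d for accuracy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

__all__ = [
    "reject_outliers",
    "paired_permutation_test",
    "cliffs_delta",
    "cohens_d_paired",
    "behavior_summary",
    "congruency_stats",
    "StatResult",
]

MAD_SCALE = 1.4826
RT_LOWER_S = 0.250


@dataclass(frozen=True)
class StatResult:
    p_value: float
    effect_size: float
    effect_type: str
    n_permutations: int
    statistic: float = np.nan


def reject_outliers(trials: pd.DataFrame, rt_lower: float = RT_LOWER_S,
                    n_mads: float = 3.0):
    """Remove RT outliers per participant; return (retained, report).

    Rejects rt < ``rt_lower`` and rt > median + ``n_mads`` * 1.4826 * MAD
    (MAD taken raw, on each participant's trials).  The MAD rule is
    upper-tail only; the lower tail is the fixed absolute bound.  With
    fewer than 3 trials for a participant the MAD is unreliable, so only
    the lower bound is applied (with a warning).  The report gives counts
    and rejected fractions both per participant and pooled.
    """
    if trials["rt"].isna().any():
        raise ValueError("all trials must have an rt before outlier rejection")
    keep = np.ones(len(trials), dtype=bool)
    per_participant = {}
    rts = trials["rt"].to_numpy(dtype=float)
    for p, idx in trials.groupby("participant_id").indices.items():
        r = rts[idx]
        low = r < rt_lower
        if idx.size < 3:
            warnings.warn(
                f"participant {p}: fewer than 3 trials, MAD undefined; "
                "applying only the lower RT bound")
            rej = low
            cutoff = np.inf
        else:
            med = np.median(r)
            mad = np.median(np.abs(r - med))
            cutoff = med + n_mads * MAD_SCALE * mad
            rej = low | (r > cutoff)
        keep[idx[rej]] = False
        per_participant[str(p)] = {
            "n": int(idx.size), "n_rejected": int(rej.sum()),
            "fraction_rejected": float(rej.mean()), "upper_cutoff": float(cutoff),
        }
    report = {
        "per_participant": per_participant,
        "n_total": int(len(trials)),
        "n_rejected": int((~keep).sum()),
        "fraction_rejected_pooled": float((~keep).mean()),
        "fraction_rejected_mean_over_participants": float(np.mean(
            [v["fraction_rejected"] for v in per_participant.values()])),
    }
    return trials.loc[keep], report


def paired_permutation_test(values_a, values_b, n_permutations: int = 10_000,
                            rng_seed: int = 0, effect: str = "cliffs_delta",
                            exhaustive_limit: int = 20_000) -> StatResult:
    """Two-sided paired sign-flip permutation test on the mean difference.

    Enumerates all 2^n sign patterns when that is at most
    ``exhaustive_limit`` (p = #{|stat*| >= |stat|} / 2^n, the identity
    flip included); otherwise Monte-Carlo with the add-one estimator
    p = (#extreme + 1) / (n_permutations + 1).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be equal-length 1-d vectors")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    stat = d.mean()
    if np.all(d == 0):
        p = 1.0
        n_used = 0
    elif 2 ** n <= exhaustive_limit:
        signs = np.array(list(product([1.0, -1.0], repeat=n)))
        null = signs @ d / n
        p = float(np.mean(np.abs(null) >= abs(stat) - 1e-12))
        n_used = 2 ** n
    else:
        rng = np.random.default_rng(rng_seed)
        signs = rng.choice([1.0, -1.0], size=(n_permutations, n))
        null = signs @ d / n
        extreme = int(np.sum(np.abs(null) >= abs(stat) - 1e-12))
        p = (extreme + 1) / (n_permutations + 1)
        n_used = n_permutations
    if effect == "cliffs_delta":
        es = cliffs_delta(a, b)
    elif effect == "cohens_d":
        es = cohens_d_paired(a, b)
    else:
        raise ValueError(f"unknown effect type {effect!r}")
    return StatResult(p_value=float(p), effect_size=es, effect_type=effect,
                      n_permutations=n_used, statistic=float(stat))


def cliffs_delta(x, y) -> float:
    """Cliff's delta: (#{x_i > y_j} - #{x_i < y_j}) / (n_x * n_y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("samples must be nonempty")
    diff = x[:, None] - y[None, :]
    return float((np.sum(diff > 0) - np.sum(diff < 0)) / (x.size * y.size))


def cohens_d_paired(x, y) -> float:
    """Cohen's d for paired samples: mean(x - y) / sd(x - y), sd with n-1.

    Raises when the differences have zero variance (d undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("need paired 1-d samples with n >= 2")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        raise ZeroDivisionError(
            "paired Cohen's d undefined: zero variance of differences")
    return float(d.mean() / sd)


def behavior_summary(trials: pd.DataFrame, by_modality: bool = False) -> pd.DataFrame:
    """Median RT and mean accuracy per participant x congruency (x modality)."""
    keys = ["participant_id", "congruency"] + (["modality"] if by_modality else [])
    g = trials.groupby(keys)
    out = pd.DataFrame({
        "median_rt": g["rt"].median(),
        "mean_accuracy": g["correct"].mean().astype(float),
        "n_trials": g.size(),
    }).reset_index()
    return out


def congruency_stats(trials: pd.DataFrame, n_permutations: int = 10_000,
                     rng_seed: int = 0) -> pd.DataFrame:
    """Congruent-vs-incongruent tests on median RT and mean accuracy.

    One tidy row per test: paired permutation p, Cliff's delta for RTs,
    paired Cohen's d for accuracy.
    """
    summ = behavior_summary(trials).pivot(
        index="participant_id", columns="congruency",
        values=["median_rt", "mean_accuracy"])
    rows = []
    for measure, effect in (("median_rt", "cliffs_delta"),
                            ("mean_accuracy", "cohens_d")):
        cong = summ[(measure, "congruent")].to_numpy(dtype=float)
        inc = summ[(measure, "incongruent")].to_numpy(dtype=float)
        try:
            res = paired_permutation_test(cong, inc, n_permutations,
                                          rng_seed=rng_seed, effect=effect)
        except ZeroDivisionError:
            res = StatResult(np.nan, np.nan, effect, 0)
        rows.append({
            "measure": measure, "contrast": "congruent_vs_incongruent",
            "n_participants": cong.size, "statistic": res.statistic,
            "p_value": res.p_value, "effect_size": res.effect_size,
            "effect_type": res.effect_type, "n_permutations": res.n_permutations,
        })
    return pd.DataFrame(rows)
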