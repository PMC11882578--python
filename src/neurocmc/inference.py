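"""Neurally informed hierarchical drift-diffusion model.

Each pseudo-trial's diffusion parameters are linear functions of its
EEG-derived discriminant peak amplitudes (congruency-normalized, so larger
always means more neural evidence for the trial's own condition) and the
stimulus-modality predictor S (0 = auditory, 1 = visual):

    delta = a0 + a1 * y_early_max + a2 * y_late_max + a3 * S
    theta = b0 + b1 * y_early_max + b2 * y_late_max
    tau   = g0 + g1 * y_early_max + g2 * y_late_max

with the starting point fixed at the unbiased midpoint (z = 0.5) and a
separate coefficient set per congruency condition.  Participant-level
coefficients are exchangeable draws from group-level normal distributions
whose means and variances are inferred jointly (the hierarchy improves
participant estimates when trials are few).  Boundary and non-decision
time pass through a smooth softplus floor so the linear links stay linear
while theta, tau remain positive.

Priors are weakly informative: group means normal(0, 5^2) for all slopes
and the drift intercept, positive-truncated normal(1.5, 1^2) for the
boundary intercept and positive-truncated normal(0.3, 0.2^2) for the
non-decision intercept (typical DDM values), half-normal(0, 1) for all
group SDs.

Sampling is adaptive Metropolis-within-Gibbs: random-walk Metropolis on
each participant's drift / boundary / non-decision coefficient blocks and
on each group log-SD, conjugate Gibbs for the group means; proposal
scales adapt toward standard acceptance targets during burn-in and are
frozen afterwards.  Convergence is monitored with the Gelman-Rubin R-hat,
model comparison uses the DIC, and hypotheses about group-level
coefficients are tested with posterior log-odds: the logit of the
posterior probability that a coefficient satisfies a directional claim,
compared against logit(threshold_p).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .wfpt import WFPT_ERR, _fpt_density_lower, simulate_wiener

__all__ = [
    "HierarchicalModel",
    "PosteriorSamples",
    "LogOddsResult",
    "build_model",
    "sample_posterior",
    "gelman_rubin",
    "dic",
    "posterior_predictive",
    "log_odds_test",
    "default_hypotheses",
    "log_odds_table",
]

CONDITIONS = ("congruent", "incongruent")
COEF_NAMES = ("alpha0", "alpha1", "alpha2", "alpha3",
              "beta0", "beta1", "beta2", "gamma0", "gamma1", "gamma2")
N_COEF = len(COEF_NAMES)
_INTERCEPTS = (0, 4, 7)

# prior on group means: normal(mu0, s0^2); beta0/gamma0 truncated positive
_PRIOR_MU0 = np.array([0, 0, 0, 0, 1.5, 0, 0, 0.3, 0, 0], dtype=float)
_PRIOR_S0 = np.array([5, 5, 5, 5, 1.0, 5, 5, 0.2, 5, 5], dtype=float)
_TRUNCATED = np.zeros(N_COEF, dtype=bool)
_TRUNCATED[[4, 7]] = True
_SIGMA_PRIOR_SCALE = 1.0  # half-normal scale on group SDs

_SOFT_FLOOR = 1e-3
_SOFT_SCALE = 0.05


@njit(cache=True)
def _softfloor(x):
    """Smooth positive floor: ~identity above the floor, > _SOFT_FLOOR always."""
    u = (x - _SOFT_FLOOR) / _SOFT_SCALE
    if u > 30.0:
        return x
    return _SOFT_FLOOR + _SOFT_SCALE * math.log1p(math.exp(u))


@njit(cache=True)
def _cond_loglik(coefs, y1, y2, s, rt, correct, err):
    """Log-likelihood of one participant-condition cell under one
    coefficient vector (layout: COEF_NAMES)."""
    total = 0.0
    for i in range(rt.shape[0]):
        delta = coefs[0] + coefs[1] * y1[i] + coefs[2] * y2[i] + coefs[3] * s[i]
        th = _softfloor(coefs[4] + coefs[5] * y1[i] + coefs[6] * y2[i])
        ta = _softfloor(coefs[7] + coefs[8] * y1[i] + coefs[9] * y2[i])
        t = rt[i] - ta
        if t <= 1e-5:
            total += -20.0 - 100.0 * (1e-5 - t)
            continue
        if correct[i]:
            d = _fpt_density_lower(t, -delta, th, 0.5, err)
        else:
            d = _fpt_density_lower(t, delta, th, 0.5, err)
        if d < 1e-300:
            total += -690.0
        else:
            total += math.log(d)
    return total


@dataclass
class HierarchicalModel:
    """Data + structure of the hierarchical neurally informed DDM."""

    cells: dict                      # (participant, cond_idx) -> arrays
    participants: np.ndarray
    active: np.ndarray               # (N_COEF,) sampled-coefficient mask
    table: pd.DataFrame
    cells_rows: dict = field(default_factory=dict)  # (p, c) -> table row idx

    @property
    def n_participants(self) -> int:
        return self.participants.size

    def cell_loglik(self, p: int, c: int, coefs: np.ndarray) -> float:
        y1, y2, s, rt, corr = self.cells[(p, c)]
        return _cond_loglik(coefs, y1, y2, s, rt, corr, WFPT_ERR)

    def total_loglik(self, coefs: np.ndarray) -> float:
        """coefs: (P, 2, N_COEF) participant-level coefficients."""
        total = 0.0
        for (p, c) in self.cells:
            pi = int(np.searchsorted(self.participants, p))
            total += self.cell_loglik(p, c, coefs[pi, c])
        return total

    def trial_params(self, coefs: np.ndarray):
        """Per-row (delta, theta, tau) of the table under participant coefs."""
        delta = np.empty(len(self.table))
        theta = np.empty(len(self.table))
        tau = np.empty(len(self.table))
        for (p, c), (y1, y2, s, rt, corr) in self.cells.items():
            pi = int(np.searchsorted(self.participants, p))
            k = self.cells_rows[(p, c)]
            cf = coefs[pi, c]
            delta[k] = cf[0] + cf[1] * y1 + cf[2] * y2 + cf[3] * s
            th = cf[4] + cf[5] * y1 + cf[6] * y2
            ta = cf[7] + cf[8] * y1 + cf[9] * y2
            theta[k] = np.array([_softfloor(v) for v in th])
            tau[k] = np.array([_softfloor(v) for v in ta])
        return delta, theta, tau


REQUIRED_COLUMNS = ("participant_id", "congruency", "S",
                    "y_early_max", "y_late_max", "rt", "correct")


def build_model(table: pd.DataFrame, include_slopes: bool = True) -> HierarchicalModel:
    """Assemble the hierarchical model from a pseudo-trial regressor table.

    The table needs one row per pseudo-trial with congruency-normalized
    amplitude regressors (columns ``y_early_max``, ``y_late_max``), the
    modality predictor ``S``, and (rt, correct).  ``include_slopes=False``
    builds the intercept-only comparison model (slope coefficients fixed
    at zero, not sampled).
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"regressor table missing columns: {missing}")
    bad = ~table["congruency"].isin(CONDITIONS)
    if bad.any():
        raise ValueError(f"unknown congruency labels: "
                         f"{table.loc[bad, 'congruency'].unique().tolist()}")
    participants = np.sort(table["participant_id"].unique())
    cells, rows = {}, {}
    for (p, cond), sub in table.groupby(["participant_id", "congruency"]):
        c = CONDITIONS.index(cond)
        cells[(p, c)] = tuple(
            np.ascontiguousarray(sub[col].to_numpy(dtype=dt))
            for col, dt in (("y_early_max", np.float64), ("y_late_max", np.float64),
                            ("S", np.float64), ("rt", np.float64),
                            ("correct", np.bool_)))
        rows[(p, c)] = sub.index.to_numpy()
    active = np.ones(N_COEF, dtype=bool)
    if not include_slopes:
        active[:] = False
        active[list(_INTERCEPTS)] = True
    model = HierarchicalModel(cells=cells, participants=participants,
                              active=active, table=table.reset_index(drop=True))
    model.cells_rows = {k: np.asarray(v) for k, v in rows.items()}
    return model


# ---------------------------------------------------------------------------
# Posterior container


@dataclass
class PosteriorSamples:
    """Thinned post-burn-in MCMC draws.

    group_mu / group_sigma: (chains, draws, 2, N_COEF);
    participant: (chains, draws, P, 2, N_COEF);
    loglik: (chains, draws) total data log-likelihood per stored draw.
    """

    group_mu: np.ndarray
    group_sigma: np.ndarray
    participant: np.ndarray
    loglik: np.ndarray
    active: np.ndarray
    participants: np.ndarray
    n_samples: int
    burn_in: int
    thin: int

    @property
    def n_chains(self) -> int:
        return self.group_mu.shape[0]

    def parameter_names(self) -> list[str]:
        return [f"mu_{n}_{cond}" for cond in CONDITIONS
                for j, n in enumerate(COEF_NAMES) if self.active[j]] + \
               [f"sigma_{n}_{cond}" for cond in CONDITIONS
                for j, n in enumerate(COEF_NAMES) if self.active[j]]

    def group_level(self) -> dict[str, np.ndarray]:
        """Name -> (chains, draws) array for every sampled group parameter."""
        out = {}
        for ci, cond in enumerate(CONDITIONS):
            for j, n in enumerate(COEF_NAMES):
                if self.active[j]:
                    out[f"mu_{n}_{cond}"] = self.group_mu[:, :, ci, j]
                    out[f"sigma_{n}_{cond}"] = self.group_sigma[:, :, ci, j]
        return out

    def pooled(self, name: str) -> np.ndarray:
        """Pooled draws of one group parameter across chains."""
        groups = self.group_level()
        if name not in groups:
            raise KeyError(f"unknown parameter {name!r}; known: "
                           f"{sorted(groups)}")
        return groups[name].ravel()


# ---------------------------------------------------------------------------
# Sampler


def _init_state(model: HierarchicalModel, rng: np.random.Generator):
    """Data-informed, chain-jittered starting values."""
    P = model.n_participants
    coefs = np.zeros((P, 2, N_COEF))
    for pi, p in enumerate(model.participants):
        for c in (0, 1):
            if (p, c) not in model.cells:
                continue
            rt = model.cells[(p, c)][3]
            coefs[pi, c, 0] = 1.0 + 0.5 * rng.standard_normal()      # alpha0
            coefs[pi, c, 4] = max(0.8, 1.5 + 0.3 * rng.standard_normal())
            coefs[pi, c, 7] = max(0.05, 0.5 * float(np.min(rt))
                                  + 0.02 * rng.standard_normal())
            for j in range(N_COEF):
                if model.active[j] and j not in _INTERCEPTS:
                    coefs[pi, c, j] = 0.1 * rng.standard_normal()
    mu = coefs.mean(axis=0)
    sigma = np.full((2, N_COEF), 0.3)
    sigma[:, 7:] = 0.05  # non-decision scale
    return coefs, mu, sigma


_BLOCKS = {"drift": np.array([0, 1, 2, 3]),
           "boundary": np.array([4, 5, 6]),
           "ndt": np.array([7, 8, 9])}


@njit(cache=True)
def _cell_ll_slice(coefs_vec, y1, y2, sv, rt, corr, a, b, err):
    return _cond_loglik(coefs_vec, y1[a:b], y2[a:b], sv[a:b], rt[a:b],
                        corr[a:b], err)


@njit(cache=True)
def _chol10(a, out):
    """In-place lower Cholesky of a small SPD matrix; returns success."""
    n = a.shape[0]
    for i in range(n):
        for j in range(i + 1):
            s = a[i, j]
            for k in range(j):
                s -= out[i, k] * out[j, k]
            if i == j:
                if s <= 0.0:
                    return False
                out[i, i] = math.sqrt(s)
            else:
                out[i, j] = s / out[j, j]
        for j in range(i + 1, n):
            out[i, j] = 0.0
    return True


@njit(cache=True)
def _run_chain(seed, n_samples, burn_in, thin, inner,
               coefs, mu, sigma,
               cell_pi, cell_c, cell_start, cell_end,
               y1, y2, sv, rt, corr,
               active_idx, blocks_flat, block_start,
               trunc, prior_mu0, prior_s0, sigma_prior_scale, err,
               out_mu, out_sigma, out_part, out_ll):
    """One MCMC chain; all state arrays are chain-local and modified in place.

    Move set per iteration (x ``inner``): random-walk Metropolis on each
    cell's coefficient blocks, 3 adaptive-Metropolis full-vector moves per
    cell (empirical-covariance proposal, burn-in adapted), conjugate Gibbs
    for group means (rejection-truncated where the prior is), Metropolis on
    log group SDs; then group translation moves (mean + all participant
    coefficients shifted together).  Scales adapt during burn-in only.
    """
    np.random.seed(seed)
    n_cells = cell_pi.shape[0]
    n_blocks = block_start.shape[0] - 1
    d_act = active_idx.shape[0]
    n_coef = mu.shape[1]

    cell_ll = np.empty(n_cells)
    for k in range(n_cells):
        cell_ll[k] = _cell_ll_slice(coefs[cell_pi[k], cell_c[k]], y1, y2, sv,
                                    rt, corr, cell_start[k], cell_end[k], err)

    # per-condition participant counts (cells present)
    n_in_cond = np.zeros(2, np.int64)
    for k in range(n_cells):
        n_in_cond[cell_c[k]] += 1

    step = np.full((n_cells, n_blocks), math.log(0.05))
    am_scale = np.zeros(n_cells)
    sig_step = np.full((2, n_coef), math.log(0.3))
    tr_step = np.full((2, n_coef), math.log(0.02))
    sc_step = np.full((2, n_coef), math.log(0.1))
    acc = np.zeros((n_cells, n_blocks))
    tries = np.zeros((n_cells, n_blocks))
    am_acc = np.zeros(n_cells)
    am_tries = np.zeros(n_cells)
    sig_acc = np.zeros((2, n_coef))
    sig_tries = np.zeros((2, n_coef))
    tr_acc = np.zeros((2, n_coef))
    tr_tries = np.zeros((2, n_coef))
    sc_acc = np.zeros((2, n_coef))
    sc_tries = np.zeros((2, n_coef))

    hist_n = 0
    hist_mean = np.zeros((n_cells, d_act))
    hist_m2 = np.zeros((n_cells, d_act, d_act))
    am_chol = np.zeros((n_cells, d_act, d_act))
    am_ok = np.zeros(n_cells, np.bool_)
    am_start = max(100, burn_in // 5)
    mu_hist_mean = np.zeros((2, d_act))
    mu_hist_m2 = np.zeros((2, d_act, d_act))
    mu_chol = np.zeros((2, d_act, d_act))
    mu_ok = np.zeros(2, np.bool_)
    mu_tr_scale = np.zeros(2)
    mu_tr_acc = np.zeros(2)
    mu_tr_tries = np.zeros(2)
    eta = np.empty(d_act)

    prop = np.empty(n_coef)
    noise = np.empty(d_act)
    delta1 = np.empty(d_act)
    delta2 = np.empty(d_act)
    covtmp = np.empty((d_act, d_act))
    kept = 0
    for it in range(n_samples):
        adapting = it < burn_in
        for _inner in range(inner):
            # --- participant-level moves
            for k in range(n_cells):
                pi = cell_pi[k]
                c = cell_c[k]
                for bi in range(n_blocks):
                    lo = block_start[bi]
                    hi = block_start[bi + 1]
                    if hi == lo:
                        continue
                    for j in range(n_coef):
                        prop[j] = coefs[pi, c, j]
                    s = math.exp(step[k, bi])
                    lp = 0.0
                    for q in range(lo, hi):
                        j = blocks_flat[q]
                        nj = prop[j] + s * np.random.standard_normal()
                        lp += ((coefs[pi, c, j] - mu[c, j]) ** 2
                               - (nj - mu[c, j]) ** 2) / (2.0 * sigma[c, j] ** 2)
                        prop[j] = nj
                    ll_new = _cell_ll_slice(prop, y1, y2, sv, rt, corr,
                                            cell_start[k], cell_end[k], err)
                    lp += ll_new - cell_ll[k]
                    tries[k, bi] += 1
                    if np.isfinite(ll_new) and math.log(np.random.random()) < lp:
                        for j in range(n_coef):
                            coefs[pi, c, j] = prop[j]
                        cell_ll[k] = ll_new
                        acc[k, bi] += 1
                if am_ok[k]:
                    for _rep in range(2):
                        for j in range(n_coef):
                            prop[j] = coefs[pi, c, j]
                        lam = math.exp(am_scale[k])
                        for q in range(d_act):
                            noise[q] = np.random.standard_normal()
                        lp = 0.0
                        for q in range(d_act):
                            j = active_idx[q]
                            dq = 0.0
                            for r in range(q + 1):
                                dq += am_chol[k, q, r] * noise[r]
                            nj = prop[j] + lam * dq
                            lp += ((coefs[pi, c, j] - mu[c, j]) ** 2
                                   - (nj - mu[c, j]) ** 2) / (2.0 * sigma[c, j] ** 2)
                            prop[j] = nj
                        ll_new = _cell_ll_slice(prop, y1, y2, sv, rt, corr,
                                                cell_start[k], cell_end[k], err)
                        lp += ll_new - cell_ll[k]
                        am_tries[k] += 1
                        if np.isfinite(ll_new) and math.log(np.random.random()) < lp:
                            for j in range(n_coef):
                                coefs[pi, c, j] = prop[j]
                            cell_ll[k] = ll_new
                            am_acc[k] += 1
            # --- group means: conjugate Gibbs over participants present
            for c in range(2):
                for q in range(d_act):
                    j = active_idx[q]
                    tot = 0.0
                    cnt = 0
                    for k in range(n_cells):
                        if cell_c[k] == c:
                            tot += coefs[cell_pi[k], c, j]
                            cnt += 1
                    var = 1.0 / (cnt / sigma[c, j] ** 2 + 1.0 / prior_s0[j] ** 2)
                    mean = var * (tot / sigma[c, j] ** 2
                                  + prior_mu0[j] / prior_s0[j] ** 2)
                    draw = mean + math.sqrt(var) * np.random.standard_normal()
                    if trunc[j]:
                        guard = 0
                        while draw <= 0.0 and guard < 100:
                            draw = mean + math.sqrt(var) * np.random.standard_normal()
                            guard += 1
                        if draw <= 0.0:
                            draw = 1e-3
                    mu[c, j] = draw
            # --- group SDs: Metropolis on log sigma
            for c in range(2):
                for q in range(d_act):
                    j = active_idx[q]
                    cur = sigma[c, j]
                    cand = cur * math.exp(math.exp(sig_step[c, j])
                                          * np.random.standard_normal())
                    ssq = 0.0
                    cnt = 0
                    for k in range(n_cells):
                        if cell_c[k] == c:
                            ssq += (coefs[cell_pi[k], c, j] - mu[c, j]) ** 2
                            cnt += 1
                    lp_cur = (-cnt * math.log(cur) - ssq / (2 * cur * cur)
                              - cur * cur / (2 * sigma_prior_scale ** 2)
                              + math.log(cur))
                    lp_new = (-cnt * math.log(cand) - ssq / (2 * cand * cand)
                              - cand * cand / (2 * sigma_prior_scale ** 2)
                              + math.log(cand))
                    sig_tries[c, j] += 1
                    if math.log(np.random.random()) < lp_new - lp_cur:
                        sigma[c, j] = cand
                        sig_acc[c, j] += 1
        # --- joint group-mean translation: shift ALL of a condition's group
        #     means (empirical-covariance proposal) together with every
        #     participant's coefficients; one full-likelihood pass moves the
        #     whole group-mean vector, which dominates group-level mixing
        for c in range(2):
            if not mu_ok[c]:
                continue
            for _rep in range(8):
                lam = math.exp(mu_tr_scale[c])
                for q in range(d_act):
                    noise[q] = np.random.standard_normal()
                bad = False
                lp = 0.0
                for q in range(d_act):
                    e = 0.0
                    for r in range(q + 1):
                        e += mu_chol[c, q, r] * noise[r]
                    eta[q] = lam * e
                    j = active_idx[q]
                    nm = mu[c, j] + eta[q]
                    if trunc[j] and nm <= 0.0:
                        bad = True
                    lp += ((mu[c, j] - prior_mu0[j]) ** 2
                           - (nm - prior_mu0[j]) ** 2) / (2 * prior_s0[j] ** 2)
                mu_tr_tries[c] += 1
                if bad:
                    continue
                new_ll = np.empty(n_cells)
                ok = True
                for k in range(n_cells):
                    if cell_c[k] != c:
                        continue
                    for jj in range(n_coef):
                        prop[jj] = coefs[cell_pi[k], c, jj]
                    for q in range(d_act):
                        prop[active_idx[q]] += eta[q]
                    ll = _cell_ll_slice(prop, y1, y2, sv, rt, corr,
                                        cell_start[k], cell_end[k], err)
                    if not np.isfinite(ll):
                        ok = False
                        break
                    new_ll[k] = ll
                    lp += ll - cell_ll[k]
                if ok and math.log(np.random.random()) < lp:
                    for q in range(d_act):
                        mu[c, active_idx[q]] += eta[q]
                    for k in range(n_cells):
                        if cell_c[k] == c:
                            for q in range(d_act):
                                coefs[cell_pi[k], c, active_idx[q]] += eta[q]
                            cell_ll[k] = new_ll[k]
                    mu_tr_acc[c] += 1
        # --- scalar group translation moves (fallback / complement)
        for c in range(2):
            if mu_ok[c]:
                continue
            for q in range(d_act):
                j = active_idx[q]
                eps = math.exp(tr_step[c, j]) * np.random.standard_normal()
                new_mu = mu[c, j] + eps
                tr_tries[c, j] += 1
                if trunc[j] and new_mu <= 0.0:
                    continue
                lp = ((mu[c, j] - prior_mu0[j]) ** 2
                      - (new_mu - prior_mu0[j]) ** 2) / (2 * prior_s0[j] ** 2)
                new_ll = np.empty(n_cells)
                ok = True
                for k in range(n_cells):
                    if cell_c[k] != c:
                        continue
                    for jj in range(n_coef):
                        prop[jj] = coefs[cell_pi[k], c, jj]
                    prop[j] += eps
                    ll = _cell_ll_slice(prop, y1, y2, sv, rt, corr,
                                        cell_start[k], cell_end[k], err)
                    if not np.isfinite(ll):
                        ok = False
                        break
                    new_ll[k] = ll
                    lp += ll - cell_ll[k]
                if ok and math.log(np.random.random()) < lp:
                    mu[c, j] = new_mu
                    for k in range(n_cells):
                        if cell_c[k] == c:
                            coefs[cell_pi[k], c, j] += eps
                            cell_ll[k] = new_ll[k]
                    tr_acc[c, j] += 1
        # --- group scale moves: rescale a group SD together with every
        #     participant's deviation from the mean (breaks the funnel
        #     coupling that throttles group-SD mixing);
        #     log-acceptance = dloglik + dlogprior(sigma) + log(kappa)
        for c in range(2):
            for q in range(d_act):
                j = active_idx[q]
                logk = math.exp(sc_step[c, j]) * np.random.standard_normal()
                kappa = math.exp(logk)
                new_sd = sigma[c, j] * kappa
                sc_tries[c, j] += 1
                lp = (logk + (sigma[c, j] ** 2 - new_sd ** 2)
                      / (2 * sigma_prior_scale ** 2))
                new_ll = np.empty(n_cells)
                ok = True
                for k in range(n_cells):
                    if cell_c[k] != c:
                        continue
                    for jj in range(n_coef):
                        prop[jj] = coefs[cell_pi[k], c, jj]
                    prop[j] = mu[c, j] + kappa * (prop[j] - mu[c, j])
                    ll = _cell_ll_slice(prop, y1, y2, sv, rt, corr,
                                        cell_start[k], cell_end[k], err)
                    if not np.isfinite(ll):
                        ok = False
                        break
                    new_ll[k] = ll
                    lp += ll - cell_ll[k]
                if ok and math.log(np.random.random()) < lp:
                    sigma[c, j] = new_sd
                    for k in range(n_cells):
                        if cell_c[k] == c:
                            coefs[cell_pi[k], c, j] = (
                                mu[c, j] + kappa
                                * (coefs[cell_pi[k], c, j] - mu[c, j]))
                            cell_ll[k] = new_ll[k]
                    sc_acc[c, j] += 1
        # --- empirical covariance accumulation (burn-in only, Welford)
        if adapting:
            hist_n += 1
            for c in range(2):
                for q in range(d_act):
                    noise[q] = mu[c, active_idx[q]]
                for q in range(d_act):
                    d1 = noise[q] - mu_hist_mean[c, q]
                    mu_hist_mean[c, q] += d1 / hist_n
                    delta1[q] = d1
                    delta2[q] = noise[q] - mu_hist_mean[c, q]
                for q in range(d_act):
                    for r in range(d_act):
                        mu_hist_m2[c, q, r] += delta1[q] * delta2[r]
            for k in range(n_cells):
                for q in range(d_act):
                    noise[q] = coefs[cell_pi[k], cell_c[k], active_idx[q]]
                for q in range(d_act):
                    d1 = noise[q] - hist_mean[k, q]
                    hist_mean[k, q] += d1 / hist_n
                    delta1[q] = d1
                    delta2[q] = noise[q] - hist_mean[k, q]
                for q in range(d_act):
                    for r in range(d_act):
                        hist_m2[k, q, r] += delta1[q] * delta2[r]
            if (it + 1) % 100 == 0 and it + 1 >= am_start and hist_n > 2 * d_act:
                for k in range(n_cells):
                    for q in range(d_act):
                        for r in range(d_act):
                            covtmp[q, r] = (hist_m2[k, q, r] / (hist_n - 1)
                                            * (2.38 ** 2 / d_act))
                        covtmp[q, q] += 1e-9
                    am_ok[k] = _chol10(covtmp, am_chol[k])
                for c in range(2):
                    for q in range(d_act):
                        for r in range(d_act):
                            covtmp[q, r] = (mu_hist_m2[c, q, r] / (hist_n - 1)
                                            * (2.38 ** 2 / d_act))
                        covtmp[q, q] += 1e-12
                    mu_ok[c] = _chol10(covtmp, mu_chol[c])
        if adapting and (it + 1) % 25 == 0:
            rate = 1.0 / math.sqrt(1.0 + it / 25.0)
            for k in range(n_cells):
                for bi in range(n_blocks):
                    if tries[k, bi] > 0:
                        step[k, bi] += rate * (acc[k, bi] / tries[k, bi] - 0.30)
                    acc[k, bi] = 0.0
                    tries[k, bi] = 0.0
                if am_tries[k] > 0:
                    am_scale[k] += rate * (am_acc[k] / am_tries[k] - 0.23)
                am_acc[k] = 0.0
                am_tries[k] = 0.0
            for c in range(2):
                if mu_tr_tries[c] > 0:
                    mu_tr_scale[c] += rate * (mu_tr_acc[c] / mu_tr_tries[c]
                                              - 0.23)
                mu_tr_acc[c] = 0.0
                mu_tr_tries[c] = 0.0
            for c in range(2):
                for q in range(d_act):
                    j = active_idx[q]
                    if sig_tries[c, j] > 0:
                        sig_step[c, j] += rate * (sig_acc[c, j] / sig_tries[c, j]
                                                  - 0.44)
                    sig_acc[c, j] = 0.0
                    sig_tries[c, j] = 0.0
                    if tr_tries[c, j] > 0:
                        tr_step[c, j] += rate * (tr_acc[c, j] / tr_tries[c, j]
                                                 - 0.30)
                    tr_acc[c, j] = 0.0
                    tr_tries[c, j] = 0.0
                    if sc_tries[c, j] > 0:
                        sc_step[c, j] += rate * (sc_acc[c, j] / sc_tries[c, j]
                                                 - 0.30)
                    sc_acc[c, j] = 0.0
                    sc_tries[c, j] = 0.0
        # --- record
        if it >= burn_in and (it - burn_in) % thin == 0:
            for c in range(2):
                for j in range(n_coef):
                    out_mu[kept, c, j] = mu[c, j]
                    out_sigma[kept, c, j] = sigma[c, j]
            out_part[kept] = coefs
            tot = 0.0
            for k in range(n_cells):
                tot += cell_ll[k]
            out_ll[kept] = tot
            kept += 1
    return kept


def sample_posterior(model: HierarchicalModel, n_samples: int = 11_000,
                     burn_in: int = 5_000, thin: int = 20, chains: int = 4,
                     rng_seed: int = 0, inner_updates: int = 2) -> PosteriorSamples:
    """Run the adaptive Metropolis-within-Gibbs sampler.

    ``n_samples`` iterations per chain; the first ``burn_in`` are
    discarded and the remainder thinned by ``thin``.  Any correct MCMC
    scheme satisfies the model contract; this one repeats, per iteration,
    ``inner_updates`` rounds of participant-level moves — random-walk
    Metropolis on the drift/boundary/non-decision coefficient blocks plus
    a full-vector adaptive-Metropolis move whose proposal covariance is
    the empirical posterior covariance accumulated during burn-in (this
    handles the strong drift/boundary/non-decision trade-offs) — then
    conjugate Gibbs for the group means (truncated where the prior is)
    and Metropolis on the log of each group SD.  All proposal scales and
    the empirical covariance adapt during burn-in only and are frozen
    afterwards.
    """
    if burn_in >= n_samples:
        raise ValueError("burn_in must be smaller than n_samples")
    if chains < 1:
        raise ValueError("need at least one chain")
    P = model.n_participants
    n_keep = (n_samples - burn_in + thin - 1) // thin
    out_mu = np.empty((chains, n_keep, 2, N_COEF))
    out_sigma = np.empty((chains, n_keep, 2, N_COEF))
    out_part = np.empty((chains, n_keep, P, 2, N_COEF))
    out_ll = np.empty((chains, n_keep))
    active_idx = np.flatnonzero(model.active)
    d_act = active_idx.size
    # flatten cells for the numba kernel
    cell_keys = sorted(model.cells)
    n_cells = len(cell_keys)
    cell_pi = np.array([int(np.searchsorted(model.participants, p))
                        for p, _ in cell_keys], dtype=np.int64)
    cell_c = np.array([c for _, c in cell_keys], dtype=np.int64)
    sizes = [model.cells[k][0].size for k in cell_keys]
    cell_start = np.zeros(n_cells, dtype=np.int64)
    cell_start[1:] = np.cumsum(sizes)[:-1]
    cell_end = cell_start + np.array(sizes, dtype=np.int64)
    y1 = np.concatenate([model.cells[k][0] for k in cell_keys])
    y2 = np.concatenate([model.cells[k][1] for k in cell_keys])
    sv = np.concatenate([model.cells[k][2] for k in cell_keys])
    rt = np.concatenate([model.cells[k][3] for k in cell_keys])
    corr = np.concatenate([model.cells[k][4] for k in cell_keys])
    blocks = [idx[model.active[idx]] for idx in _BLOCKS.values()]
    blocks_flat = np.concatenate(blocks).astype(np.int64)
    block_start = np.zeros(len(blocks) + 1, dtype=np.int64)
    block_start[1:] = np.cumsum([b.size for b in blocks])

    ss = np.random.SeedSequence(rng_seed)
    for chain, child in enumerate(ss.spawn(chains)):
        rng = np.random.default_rng(child)
        coefs, mu, sigma = _init_state(model, rng)
        if not np.isfinite(model.total_loglik(coefs)):
            raise RuntimeError("non-finite log-likelihood at initialization")
        kernel_seed = int(rng.integers(2**31 - 1))
        kept = _run_chain(
            kernel_seed, n_samples, burn_in, thin, inner_updates,
            coefs, mu, sigma, cell_pi, cell_c, cell_start, cell_end,
            y1, y2, sv, rt, corr, active_idx.astype(np.int64),
            blocks_flat, block_start, _TRUNCATED, _PRIOR_MU0, _PRIOR_S0,
            _SIGMA_PRIOR_SCALE, WFPT_ERR,
            out_mu[chain], out_sigma[chain], out_part[chain], out_ll[chain])
        if kept != n_keep:
            raise RuntimeError("internal bookkeeping error in draw storage")
    return PosteriorSamples(group_mu=out_mu, group_sigma=out_sigma,
                            participant=out_part, loglik=out_ll,
                            active=model.active,
                            participants=model.participants,
                            n_samples=n_samples, burn_in=burn_in, thin=thin)


# ---------------------------------------------------------------------------
# Diagnostics


def gelman_rubin(samples) -> dict[str, float]:
    """Potential scale reduction factor per group-level parameter.

    Accepts a PosteriorSamples or a mapping name -> (chains, draws)
    array.  Requires >= 2 chains.  R-hat compares the between-chain
    variance of chain means with the mean within-chain variance.
    """
    arrays = samples.group_level() if isinstance(samples, PosteriorSamples) \
        else dict(samples)
    out = {}
    for name, arr in arrays.items():
        arr = np.asarray(arr, dtype=float)
        m, n = arr.shape
        if m < 2:
            raise ValueError("R-hat needs at least 2 chains")
        chain_means = arr.mean(axis=1)
        W = arr.var(axis=1, ddof=1).mean()
        B = n * chain_means.var(ddof=1)
        var_hat = (n - 1) / n * W + B / n
        out[name] = float(np.sqrt(var_hat / W)) if W > 0 else 1.0
    return out


def dic(samples: PosteriorSamples, model: HierarchicalModel) -> dict[str, float]:
    """Deviance information criterion from the stored draws.

    DIC = mean deviance + p_D with p_D = mean deviance minus the deviance
    at the posterior mean of the participant-level coefficients.
    """
    dev = -2.0 * samples.loglik.ravel()
    finite = np.isfinite(dev)
    if not finite.all():
        warnings.warn(f"excluding {int((~finite).sum())} non-finite deviances")
        dev = dev[finite]
    mean_dev = float(dev.mean())
    coef_mean = samples.participant.mean(axis=(0, 1))
    dev_at_mean = -2.0 * model.total_loglik(coef_mean)
    p_d = mean_dev - dev_at_mean
    return {"dic": mean_dev + p_d, "mean_deviance": mean_dev, "p_d": p_d}


def posterior_predictive(samples: PosteriorSamples, model: HierarchicalModel,
                         n_draws: int = 50, rng_seed: int = 0) -> pd.DataFrame:
    """Simulate RT/choice data from posterior draws (predictive check).

    For each of ``n_draws`` stored posterior draws the whole pseudo-trial
    table is re-simulated from that draw's participant-level coefficients.
    Returns a long table with ``signed_rt`` (negative = incorrect
    response) per congruency condition and draw.
    """
    rng = np.random.default_rng(rng_seed)
    chains, kept = samples.loglik.shape
    rows = []
    for d in range(n_draws):
        ch = int(rng.integers(chains))
        k = int(rng.integers(kept))
        delta, theta, tau = model.trial_params(samples.participant[ch, k])
        rt, upper = simulate_wiener(delta, theta, tau,
                                    rng_seed=int(rng.integers(2**31 - 1)))
        rows.append(pd.DataFrame({
            "draw": d,
            "congruency": model.table["congruency"],
            "participant_id": model.table["participant_id"],
            "signed_rt": np.where(upper, rt, -rt),
            "correct": upper,
        }))
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# Posterior log-odds hypothesis testing


@dataclass(frozen=True)
class LogOddsResult:
    hypothesis: str
    parameter: str
    direction: str
    proportion: float
    log_odds: float
    threshold: float
    supported: bool


def log_odds_test(samples: PosteriorSamples, parameter: str, direction: str,
                  threshold_p: float = 0.95,
                  hypothesis: str | None = None) -> LogOddsResult:
    """Directional posterior log-odds test on a group-level parameter.

    P = (#draws satisfying the direction + 0.5) / (N + 1) (continuity
    bounds keep the logit finite); the claim is supported when
    logit(P) > logit(threshold_p).
    """
    draws = samples.pooled(parameter)
    if direction not in (">", "<"):
        raise ValueError("direction must be '>' or '<' (vs. zero)")
    k = int((draws > 0).sum()) if direction == ">" else int((draws < 0).sum())
    p = (k + 0.5) / (draws.size + 1)
    lo = math.log(p / (1 - p))
    thr = math.log(threshold_p / (1 - threshold_p))
    return LogOddsResult(
        hypothesis=hypothesis or f"{parameter} {direction} 0",
        parameter=parameter, direction=direction, proportion=float(p),
        log_odds=float(lo), threshold=float(thr), supported=bool(lo > thr))


def default_hypotheses() -> list[tuple[str, str]]:
    """The directional hypothesis set for the congruency design.

    Congruent trials: amplitudes predicted to raise drift and boundary
    slopes positively, incongruent trials negatively; non-decision time
    the converse; modality (visual) positive in both conditions.
    """
    hyp = []
    for coef in ("alpha1", "alpha2", "alpha3"):
        hyp.append((f"mu_{coef}_congruent", ">"))
    for coef in ("alpha1", "alpha2"):
        hyp.append((f"mu_{coef}_incongruent", "<"))
    hyp.append(("mu_alpha3_incongruent", ">"))
    for coef in ("beta1", "beta2"):
        hyp.append((f"mu_{coef}_congruent", "<"))
        hyp.append((f"mu_{coef}_incongruent", ">"))
    for coef in ("gamma1", "gamma2"):
        hyp.append((f"mu_{coef}_congruent", "<"))
        hyp.append((f"mu_{coef}_incongruent", ">"))
    return hyp


def log_odds_table(samples: PosteriorSamples,
                   hypotheses: list[tuple[str, str]] | None = None,
                   threshold_p: float = 0.95) -> pd.DataFrame:
    """Evaluate a set of (parameter, direction) hypotheses as a tidy table."""
    if hypotheses is None:
        hypotheses = default_hypotheses()
    rows = []
    for parameter, direction in hypotheses:
        r = log_odds_test(samples, parameter, direction, threshold_p)
        rows.append({"parameter": r.parameter, "direction": r.direction,
                     "proportion": r.proportion, "log_odds": r.log_odds,
                     "threshold": r.threshold, "supported": r.supported})
    return pd.DataFrame(rows)
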