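"""MCMC machinery for the state-space survival model.

One chain alternates four update blocks:

1. the latent alive states ``z`` by forward-filtering backward-sampling
   (exact 2-state hidden-Markov draw per fish, with unobserved spawning
   states collapsed out of the transition so the chain mixes over
   spawning-period deaths);
2. the unobserved spawning states ``x`` from their Bernoulli full
   conditionals given ``z``;
3. the eleven coefficients by single-site random-walk Metropolis with
   proposal scales adapted toward ~35% acceptance during burn-in and frozen
   afterwards;
4. the seven inclusion indicators by exact Gibbs given the coefficient
   (spike vs slab density ratio), followed by a joint flip move that
   proposes the opposite indicator together with a fresh coefficient drawn
   from the corresponding prior component (prior terms cancel, so the
   acceptance ratio is a pure likelihood ratio).  The joint move is what
   lets a coefficient jump between the spike and a distant slab mode.

Everything is vectorised across fish; per-iteration cost is linear in the
number of fish-periods.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

from .likelihood import (
    INDICATOR_NAMES,
    OPTIONAL_PARAMS,
    PARAM_NAMES,
    PackedData,
    PriorConfig,
)

_IDX = {name: i for i, name in enumerate(PARAM_NAMES)}
_OPT_IDX = np.array([_IDX[p] for p in OPTIONAL_PARAMS])

# which probability block each coefficient belongs to
_BLOCK_OF = {
    "surv_intercept": "phi", "surv_spawn": "phi", "surv_year": "phi",
    "recap_intercept": "rho", "recap_year": "rho",
    "move_intercept": "delta", "move_spawn_season": "delta", "move_year": "delta",
    "spawn_intercept": "kappa", "spawn_length": "kappa", "spawn_year": "kappa",
}

_B = {n: _IDX[n] for n in PARAM_NAMES}


def _log_sigmoid(eta):
    return -np.logaddexp(0.0, -eta)


def _bern_ll_sum(obs, eta):
    return float(np.sum(obs * _log_sigmoid(eta) + (1 - obs) * _log_sigmoid(-eta)))


class _Blocks:
    """Compressed per-block observation vectors, refreshed after z/x moves."""

    def __init__(self, p: PackedData, z: np.ndarray, x: np.ndarray):
        alive = (z == 1)
        znext = np.zeros_like(z)
        znext[:, :-1] = z[:, 1:]
        mk = p.trans & alive
        self.phi_zn = znext[mk].astype(float)
        self.phi_x = x[mk].astype(float)
        self.phi_Y = p.YY[mk]
        mk = p.y_mask & alive
        self.rho_y = p.y[mk].astype(float)
        self.rho_Y = p.YY[mk]
        mk = p.m_mask & alive
        self.del_m = p.m[mk].astype(float)
        self.del_S = p.S[mk].astype(float)
        self.del_Y = p.YY[mk]
        mk = p.S & alive
        self.kap_x = x[mk].astype(float)
        self.kap_L = p.L[mk]
        self.kap_Y = p.YY[mk]

    def ll(self, block: str, b: np.ndarray) -> float:
        if block == "phi":
            eta = b[_B["surv_intercept"]] + b[_B["surv_spawn"]] * self.phi_x \
                + b[_B["surv_year"]] * self.phi_Y
            return _bern_ll_sum(self.phi_zn, eta)
        if block == "rho":
            eta = b[_B["recap_intercept"]] + b[_B["recap_year"]] * self.rho_Y
            return _bern_ll_sum(self.rho_y, eta)
        if block == "delta":
            eta = b[_B["move_intercept"]] + b[_B["move_spawn_season"]] * self.del_S \
                + b[_B["move_year"]] * self.del_Y
            return _bern_ll_sum(self.del_m, eta)
        eta = b[_B["spawn_intercept"]] + b[_B["spawn_length"]] * self.kap_L \
            + b[_B["spawn_year"]] * self.kap_Y
        return _bern_ll_sum(self.kap_x, eta)


def _ffbs_z(p: PackedData, beta: np.ndarray, x: np.ndarray,
            rng: np.random.Generator) -> np.ndarray:
    """Exact joint draw of the alive states given coefficients and observed x."""
    b = beta
    eta_phi0 = b[_B["surv_intercept"]] + b[_B["surv_year"]] * p.YY
    phi1 = expit(eta_phi0 + b[_B["surv_spawn"]])
    phi0 = expit(eta_phi0)
    kappa = expit(b[_B["spawn_intercept"]] + b[_B["spawn_length"]] * p.L
                  + b[_B["spawn_year"]] * p.YY)
    x_obs1 = p.x_obs_mask & (np.nan_to_num(p.x_obs) == 1)
    phi_eff = np.where(p.x_lat_mask, kappa * phi1 + (1 - kappa) * phi0,
                       np.where(x_obs1, phi1, phi0))

    eta_rho = b[_B["recap_intercept"]] + b[_B["recap_year"]] * p.YY
    eta_del = b[_B["move_intercept"]] + b[_B["move_spawn_season"]] * p.S \
        + b[_B["move_year"]] * p.YY
    eta_kap = b[_B["spawn_intercept"]] + b[_B["spawn_length"]] * p.L \
        + b[_B["spawn_year"]] * p.YY
    le1 = np.where(p.y_mask, p.y * _log_sigmoid(eta_rho) + (1 - p.y) * _log_sigmoid(-eta_rho), 0.0) \
        + np.where(p.m_mask, p.m * _log_sigmoid(eta_del) + (1 - p.m) * _log_sigmoid(-eta_del), 0.0)
    xo = np.nan_to_num(p.x_obs)
    le1 += np.where(p.x_obs_mask, xo * _log_sigmoid(eta_kap) + (1 - xo) * _log_sigmoid(-eta_kap), 0.0)
    E1 = np.exp(le1)
    E0 = np.where(p.obs_pos, 0.0, 1.0)

    n, P = p.n, p.P
    A1 = np.zeros((n, P))
    A0 = np.zeros((n, P))
    A1[np.arange(n), p.first] = 1.0
    for t in range(1, P):
        act = (p.first < t) & (t <= p.last)
        if not act.any():
            continue
        w1 = A1[:, t - 1] * phi_eff[:, t - 1] * E1[:, t]
        w0 = (A1[:, t - 1] * (1 - phi_eff[:, t - 1]) + A0[:, t - 1]) * E0[:, t]
        s = w1 + w0
        if np.any(act & (s <= 0)):
            raise ValueError("observation history has zero likelihood")
        s = np.where(s > 0, s, 1.0)
        A1[act, t] = (w1 / s)[act]
        A0[act, t] = (w0 / s)[act]

    z = np.zeros((n, P), dtype=np.int8)
    rows = np.arange(n)
    z[rows, p.first] = 1
    u = rng.random(n)
    z[rows, p.last] = np.where(p.last > p.first,
                               (u < A1[rows, p.last]).astype(np.int8), 1)
    for t in range(P - 2, -1, -1):
        act = (p.first <= t) & (t < p.last)
        if not act.any():
            continue
        znext = z[:, t + 1]
        num = A1[:, t] * (1 - phi_eff[:, t])
        den = num + A0[:, t]
        p1 = np.where(znext == 1, 1.0, np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0))
        draw = (rng.random(n) < p1).astype(np.int8)
        z[act, t] = draw[act]
    z[rows, p.first] = 1
    return z


def _gibbs_x(p: PackedData, beta: np.ndarray, z: np.ndarray,
             rng: np.random.Generator) -> np.ndarray:
    """Draw the unobserved spawning states from their full conditionals."""
    b = beta
    eta_phi0 = b[_B["surv_intercept"]] + b[_B["surv_year"]] * p.YY
    phi1 = expit(eta_phi0 + b[_B["surv_spawn"]])
    phi0 = expit(eta_phi0)
    kappa = expit(b[_B["spawn_intercept"]] + b[_B["spawn_length"]] * p.L
                  + b[_B["spawn_year"]] * p.YY)
    znext = np.zeros_like(z)
    znext[:, :-1] = z[:, 1:]
    has_tr = p.trans
    tr1 = np.where(has_tr, np.where(znext == 1, phi1, 1 - phi1), 1.0)
    tr0 = np.where(has_tr, np.where(znext == 1, phi0, 1 - phi0), 1.0)
    w1 = kappa * tr1
    w0 = (1 - kappa) * tr0
    pr1 = w1 / (w1 + w0)
    draw = (rng.random(z.shape) < pr1).astype(np.int8)
    x = p.x_fixed.astype(np.int8).copy()
    lat = p.x_lat_mask & (z == 1)
    x[lat] = draw[lat]
    x[(z == 0)] = 0
    x[p.x_obs_mask] = np.nan_to_num(p.x_obs)[p.x_obs_mask].astype(np.int8)
    return x


def run_chain(p: PackedData, priors: PriorConfig, n_iter: int, n_retain: int,
              seed, fix_params: dict | None = None,
              fix_indicators: dict | None = None) -> dict:
    """Run one MCMC chain; returns retained draws and acceptance statistics."""
    rng = np.random.default_rng(seed)
    fix_params = fix_params or {}
    fix_indicators = fix_indicators or {}
    for name in fix_params:
        if name not in PARAM_NAMES:
            raise KeyError(f"unknown coefficient {name!r}")
    for name in fix_indicators:
        if name not in INDICATOR_NAMES:
            raise KeyError(f"unknown indicator {name!r}")

    beta = rng.normal(0.0, priors.slab_sd, size=len(PARAM_NAMES)) * 0.1
    gamma = rng.integers(0, 2, size=len(OPTIONAL_PARAMS))
    for name, v in fix_params.items():
        beta[_IDX[name]] = float(v)
    for name, v in fix_indicators.items():
        gamma[INDICATOR_NAMES.index(name)] = int(v)

    z = np.where(p.valid, 1, 0).astype(np.int8)
    x = _gibbs_x(p, beta, z, rng)

    free_params = [n for n in PARAM_NAMES if n not in fix_params]
    free_ind = [j for j, n in enumerate(INDICATOR_NAMES) if n not in fix_indicators]

    scales = {n: 0.3 for n in free_params}
    acc = {n: 0 for n in free_params}
    tries = {n: 0 for n in free_params}
    acc_total = {n: 0 for n in free_params}
    tries_total = {n: 0 for n in free_params}

    burn = n_iter // 2
    keep = n_iter - burn
    stride = max(1, keep // n_retain)
    betas = np.empty((n_retain, len(PARAM_NAMES)))
    gammas = np.empty((n_retain, len(OPTIONAL_PARAMS)), dtype=np.int8)
    saved = 0

    log_pi1 = np.log(priors.indicator_prob)
    log_pi0 = np.log(1.0 - priors.indicator_prob)

    def prior_sd(name: str) -> float:
        if name in OPTIONAL_PARAMS:
            g = gamma[OPTIONAL_PARAMS.index(name)]
            return priors.slab_sd if g == 1 else priors.spike_sd
        return priors.slab_sd

    for it in range(n_iter):
        z = _ffbs_z(p, beta, x, rng)
        x = _gibbs_x(p, beta, z, rng)
        blocks = _Blocks(p, z, x)
        cur_ll = {blk: blocks.ll(blk, beta) for blk in ("phi", "rho", "delta", "kappa")}

        # --- random-walk Metropolis on each free coefficient
        for name in free_params:
            k = _IDX[name]
            blk = _BLOCK_OF[name]
            sd = prior_sd(name)
            prop = beta.copy()
            prop[k] = beta[k] + scales[name] * rng.standard_normal()
            new_ll = blocks.ll(blk, prop)
            d = new_ll - cur_ll[blk] + 0.5 * (beta[k] ** 2 - prop[k] ** 2) / sd ** 2
            tries[name] += 1
            tries_total[name] += 1
            if np.log(rng.random()) < d:
                beta = prop
                cur_ll[blk] = new_ll
                acc[name] += 1
                acc_total[name] += 1

        # --- Gibbs on indicators given the coefficient value
        for j in free_ind:
            name = OPTIONAL_PARAMS[j]
            v = beta[_IDX[name]]
            l1 = log_pi1 - np.log(priors.slab_sd) - 0.5 * (v / priors.slab_sd) ** 2
            l0 = log_pi0 - np.log(priors.spike_sd) - 0.5 * (v / priors.spike_sd) ** 2
            p1 = 1.0 / (1.0 + np.exp(l0 - l1))
            gamma[j] = int(rng.random() < p1)

        # --- joint indicator flip with a fresh prior draw of the coefficient
        for j in free_ind:
            name = OPTIONAL_PARAMS[j]
            k = _IDX[name]
            blk = _BLOCK_OF[name]
            g_new = 1 - gamma[j]
            sd_new = priors.slab_sd if g_new == 1 else priors.spike_sd
            prop = beta.copy()
            prop[k] = rng.normal(0.0, sd_new)
            new_ll = blocks.ll(blk, prop)
            d = new_ll - cur_ll[blk]
            d += (log_pi1 - log_pi0) if g_new == 1 else (log_pi0 - log_pi1)
            if np.log(rng.random()) < d:
                beta = prop
                gamma[j] = g_new
                cur_ll[blk] = new_ll

        # --- adapt proposal scales during burn-in only
        if it < burn and (it + 1) % 50 == 0:
            for name in free_params:
                rate = acc[name] / max(tries[name], 1)
                scales[name] *= float(np.exp(1.2 * (rate - 0.35)))
                scales[name] = float(np.clip(scales[name], 1e-3, 20.0))
                acc[name] = 0
                tries[name] = 0

        if it >= burn and (it - burn) % stride == 0 and saved < n_retain:
            betas[saved] = beta
            gammas[saved] = gamma
            saved += 1

    # fill any tail shortfall with the final state (stride rounding)
    while saved < n_retain:
        betas[saved] = beta
        gammas[saved] = gamma
        saved += 1

    return {
        "beta": betas,
        "gamma": gammas,
        "accept_rate": {n: acc_total[n] / max(tries_total[n], 1) for n in free_params},
        "scales": scales,
    }
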