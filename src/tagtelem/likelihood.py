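"""Model likelihood for the individual state-space survival model.

Each fish carries a latent alive state ``z`` that starts at 1 in the release
period and evolves as ``z[t+1] ~ Bernoulli(z[t] * phi[t])``.  Conditional on
being alive, the observation layers are

* ``y[t] ~ Bernoulli(z[t] * rho[t])`` -- reported angler recapture,
* ``m[t] ~ Bernoulli(z[t] * T[t] * delta[t])`` -- detected moving between
  sections while the transmitter is active,
* ``x[t] ~ Bernoulli(z[t] * S[t] * kappa[t])`` -- spawning in a
  spawning-season period; observed only where the transmitter monitored the
  whole period, latent otherwise.

The four probabilities are logit-linear in the covariates; survival depends
on the period's spawning state, so a spawner pays the survival cost exactly
once per year, in its spawning-season period.

Seven of the eleven coefficients are subject to spike-and-slab selection:
binary indicators choose between a vague Normal(0, 3) slab and a
Normal(0, 0.03) spike that pins the coefficient at effectively zero.

``marginal_loglik`` integrates the latent states out exactly with a per-fish
forward recursion (2-state hidden Markov chain with an absorbing dead state;
unobserved spawning states are summed analytically), which serves both as a
fast likelihood and as the oracle the samplers are tested against.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.special import expit

from .encounters import EncounterData

__all__ = [
    "PARAM_NAMES", "OPTIONAL_PARAMS", "INDICATOR_NAMES",
    "Coefficients", "Indicators", "PriorConfig",
    "linear_predictors", "complete_data_loglik", "log_prior", "log_joint",
    "marginal_loglik",
]

#: Coefficient order used throughout the sampler and posterior containers.
PARAM_NAMES: tuple[str, ...] = (
    "surv_intercept", "surv_spawn", "surv_year",
    "recap_intercept", "recap_year",
    "move_intercept", "move_spawn_season", "move_year",
    "spawn_intercept", "spawn_length", "spawn_year",
)

#: The seven optional coefficients subject to spike-and-slab selection.
OPTIONAL_PARAMS: tuple[str, ...] = (
    "surv_spawn", "surv_year", "recap_year",
    "move_spawn_season", "move_year", "spawn_length", "spawn_year",
)

INDICATOR_NAMES: tuple[str, ...] = tuple("g_" + p for p in OPTIONAL_PARAMS)


@dataclass(frozen=True)
class Coefficients:
    """The eleven log-odds coefficients of the full model."""

    surv_intercept: float = 0.0
    surv_spawn: float = 0.0
    surv_year: float = 0.0
    recap_intercept: float = 0.0
    recap_year: float = 0.0
    move_intercept: float = 0.0
    move_spawn_season: float = 0.0
    move_year: float = 0.0
    spawn_intercept: float = 0.0
    spawn_length: float = 0.0
    spawn_year: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, p) for p in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "Coefficients":
        return cls(**dict(zip(PARAM_NAMES, np.asarray(arr, dtype=float))))

    def replace(self, **kw) -> "Coefficients":
        return replace(self, **kw)


@dataclass(frozen=True)
class Indicators:
    """Binary inclusion indicators for the optional coefficients."""

    g_surv_spawn: int = 1
    g_surv_year: int = 1
    g_recap_year: int = 1
    g_move_spawn_season: int = 1
    g_move_year: int = 1
    g_spawn_length: int = 1
    g_spawn_year: int = 1

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, g) for g in INDICATOR_NAMES], dtype=int)

    @classmethod
    def from_array(cls, arr) -> "Indicators":
        return cls(**{g: int(v) for g, v in zip(INDICATOR_NAMES, arr)})


@dataclass(frozen=True)
class PriorConfig:
    """Spike-and-slab prior settings.

    ``slab_sd`` is the vague prior for included coefficients (the prior
    sensitivity refit doubles it to 6); ``spike_sd`` pins excluded
    coefficients near zero; ``indicator_prob`` is the prior inclusion
    probability.  ``widen_spike_in_sensitivity`` controls whether a
    sensitivity refit also scales the spike.
    """

    slab_sd: float = 3.0
    spike_sd: float = 0.03
    indicator_prob: float = 0.5
    widen_spike_in_sensitivity: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.spike_sd < self.slab_sd):
            raise ValueError("require 0 < spike_sd < slab_sd")
        if not (0.0 < self.indicator_prob < 1.0):
            raise ValueError("indicator_prob must be in (0, 1)")

    def sensitivity(self, factor: float = 2.0) -> "PriorConfig":
        """Prior configuration for the vagueness-sensitivity refit."""
        return PriorConfig(
            slab_sd=self.slab_sd * factor,
            spike_sd=self.spike_sd * (factor if self.widen_spike_in_sensitivity else 1.0),
            indicator_prob=self.indicator_prob,
            widen_spike_in_sensitivity=self.widen_spike_in_sensitivity,
        )


# ----------------------------------------------------------------------
def linear_predictors(coef: Coefficients, cov: dict, indicators: Indicators | None = None) -> dict:
    """Per fish-period probabilities phi, rho, delta, kappa.

    ``cov`` maps ``"L"``, ``"Y"``, ``"S"`` and ``"x"`` to broadcastable
    arrays.  Indicators do not mask anything here: an excluded coefficient
    contributes through its spike-shrunk current value, which is how the
    mixture prior expresses exclusion.
    """
    L = np.asarray(cov["L"], dtype=float)
    Y = np.asarray(cov["Y"], dtype=float)
    S = np.asarray(cov["S"], dtype=float)
    x = np.asarray(cov["x"], dtype=float)
    return {
        "phi": expit(coef.surv_intercept + coef.surv_spawn * x + coef.surv_year * Y),
        "rho": expit(coef.recap_intercept + coef.recap_year * Y),
        "delta": expit(coef.move_intercept + coef.move_spawn_season * S + coef.move_year * Y),
        "kappa": expit(coef.spawn_intercept + coef.spawn_length * L + coef.spawn_year * Y),
    }


# ----------------------------------------------------------------------
# Internal packed representation used by the likelihood and samplers.

class PackedData:
    """Masks and covariate arrays derived once from an EncounterData."""

    def __init__(self, data: EncounterData):
        n, P = data.n_fish, data.n_periods
        self.n, self.P = n, P
        self.first = data.first.astype(int)
        self.last = data.last.astype(int)
        t = np.arange(P)
        self.valid = (t >= self.first[:, None]) & (t <= self.last[:, None])
        self.trans = (t >= self.first[:, None]) & (t < self.last[:, None])
        self.T = data.T & self.valid
        self.S = data.S & self.valid
        self.y = data.y.astype(np.int8)
        self.m = data.m.astype(np.int8)
        self.x_obs = data.x_obs
        self.L = np.nan_to_num(data.L)
        self.YY = np.broadcast_to(data.Y, (n, P)).copy()
        # observation masks; release-period observations are conditioned away
        self.y_mask = self.valid & (t > self.first[:, None])
        self.m_mask = self.T                       # T=0 in the release period
        self.x_obs_mask = self.S & ~np.isnan(self.x_obs)
        self.x_lat_mask = self.S & np.isnan(self.x_obs)
        self.x_fixed = np.where(self.x_obs_mask, np.nan_to_num(self.x_obs), 0.0)
        # periods where a positive observation forbids z = 0
        self.obs_pos = ((self.y == 1) & self.y_mask) | \
                       ((self.m == 1) & self.m_mask) | \
                       (np.nan_to_num(self.x_obs) == 1) & self.x_obs_mask


def _log_sigmoid(eta):
    return -np.logaddexp(0.0, -eta)


def _bern_ll(obs, eta):
    """Elementwise log Bernoulli(sigmoid(eta)) likelihood of 0/1 ``obs``."""
    return obs * _log_sigmoid(eta) + (1 - obs) * _log_sigmoid(-eta)


def complete_data_loglik(data: EncounterData, coef: Coefficients,
                         z: np.ndarray, x: np.ndarray,
                         packed: PackedData | None = None) -> float:
    """Log-likelihood of the observations *and* latent states.

    ``z`` and ``x`` are full ``(n, P)`` 0/1 arrays; ``x`` must hold the
    observed spawning states at observed positions.  Returns ``-inf`` for
    latent configurations inconsistent with the data (e.g. a positive
    observation while dead).
    """
    p = packed or PackedData(data)
    z = np.asarray(z, dtype=np.int8)
    x = np.asarray(x, dtype=np.int8)
    if np.any(z[np.arange(p.n), p.first] != 1):
        return -np.inf
    # z non-increasing within the modelled window
    dz = np.diff(z, axis=1)
    if np.any((dz > 0) & p.trans[:, :-1]):
        return -np.inf
    if np.any((z == 0) & p.obs_pos):
        return -np.inf
    if np.any((x == 1) & ((z == 0) | ~p.S) & p.valid):
        return -np.inf
    if np.any(p.x_obs_mask & (x != np.nan_to_num(p.x_obs))):
        return -np.inf
    alive = (z == 1) & p.valid
    eta_phi = coef.surv_intercept + coef.surv_spawn * x + coef.surv_year * p.YY
    eta_rho = coef.recap_intercept + coef.recap_year * p.YY
    eta_del = coef.move_intercept + coef.move_spawn_season * p.S + coef.move_year * p.YY
    eta_kap = coef.spawn_intercept + coef.spawn_length * p.L + coef.spawn_year * p.YY

    znext = np.zeros_like(z)
    znext[:, :-1] = z[:, 1:]
    tr = p.trans & alive
    ll = np.sum(_bern_ll(znext, eta_phi)[tr])
    ll += np.sum(_bern_ll(p.y, eta_rho)[p.y_mask & alive])
    ll += np.sum(_bern_ll(p.m, eta_del)[p.m_mask & alive])
    ll += np.sum(_bern_ll(x, eta_kap)[p.S & alive])
    return float(ll)


def log_prior(coef: Coefficients, ind: Indicators, priors: PriorConfig) -> float:
    """Log prior density of the coefficients and indicators."""
    def _norm_lpdf(v, sd):
        return -0.5 * np.log(2 * np.pi) - np.log(sd) - 0.5 * (v / sd) ** 2

    lp = 0.0
    gamma = dict(zip(OPTIONAL_PARAMS, ind.as_array()))
    for name in PARAM_NAMES:
        v = getattr(coef, name)
        if name in gamma:
            sd = priors.slab_sd if gamma[name] == 1 else priors.spike_sd
        else:
            sd = priors.slab_sd
        lp += _norm_lpdf(v, sd)
    pi = priors.indicator_prob
    for name in OPTIONAL_PARAMS:
        lp += np.log(pi) if gamma[name] == 1 else np.log(1.0 - pi)
    return float(lp)


def log_joint(data: EncounterData, coef: Coefficients, ind: Indicators,
              z: np.ndarray, x: np.ndarray, priors: PriorConfig,
              packed: PackedData | None = None) -> float:
    """Unnormalised log posterior density at one complete configuration."""
    ll = complete_data_loglik(data, coef, z, x, packed=packed)
    if not np.isfinite(ll):
        return -np.inf
    return ll + log_prior(coef, ind, priors)


# ----------------------------------------------------------------------
def marginal_loglik(data: EncounterData, coef: Coefficients,
                    packed: PackedData | None = None,
                    per_fish: bool = False):
    """Exact observed-data log-likelihood, latent states integrated out.

    Forward recursion over the alive state per fish; unobserved spawning
    states are marginalised analytically, which turns the spawning-season
    survival into the mixture ``kappa * phi(x=1) + (1 - kappa) * phi(x=0)``.
    """
    p = packed or PackedData(data)
    phi1 = expit(coef.surv_intercept + coef.surv_spawn + coef.surv_year * p.YY)
    phi0 = expit(coef.surv_intercept + coef.surv_year * p.YY)
    kappa = expit(coef.spawn_intercept + coef.spawn_length * p.L + coef.spawn_year * p.YY)

    # effective survival out of each period
    phi_eff = np.where(p.x_lat_mask, kappa * phi1 + (1 - kappa) * phi0,
                       np.where(p.x_obs_mask & (np.nan_to_num(p.x_obs) == 1), phi1, phi0))

    # log-emission while alive (release period excluded via the masks)
    eta_rho = coef.recap_intercept + coef.recap_year * p.YY
    eta_del = coef.move_intercept + coef.move_spawn_season * p.S + coef.move_year * p.YY
    eta_kap = coef.spawn_intercept + coef.spawn_length * p.L + coef.spawn_year * p.YY
    le1 = np.where(p.y_mask, _bern_ll(p.y, eta_rho), 0.0) \
        + np.where(p.m_mask, _bern_ll(p.m, eta_del), 0.0) \
        + np.where(p.x_obs_mask, _bern_ll(np.nan_to_num(p.x_obs).astype(np.int8), eta_kap), 0.0)

    E1 = np.exp(le1)
    E0 = np.where(p.obs_pos, 0.0, 1.0)

    ll = np.zeros(p.n)
    a1 = np.ones(p.n)
    a0 = np.zeros(p.n)
    for t in range(1, p.P):
        act = (p.first < t) & (t <= p.last)
        if not act.any():
            continue
        w1 = a1 * phi_eff[:, t - 1] * E1[:, t]
        w0 = (a1 * (1 - phi_eff[:, t - 1]) + a0) * E0[:, t]
        s = w1 + w0
        if np.any(act & (s <= 0)):
            bad = np.where(act & (s <= 0))[0]
            raise ValueError(f"impossible observation history for fish index {bad[:3]}")
        a1 = np.where(act, w1 / np.where(s > 0, s, 1.0), a1)
        a0 = np.where(act, w0 / np.where(s > 0, s, 1.0), a0)
        ll = np.where(act, ll + np.log(np.where(s > 0, s, 1.0)), ll)
    return ll if per_fish else float(ll.sum())
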