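"""Zero-truncated binomial anchor-tag-loss model.

Every double-tagged fish retains each of its two anchor tags independently
with probability ``1 - p`` between release and recapture.  A fish that loses
both tags cannot be identified as a recapture, so the observable counts --
``n_double`` recaptures with both tags and ``n_single`` with exactly one --
follow a binomial truncated at zero retained tags:

    P(both | >= 1 retained)  = (1 - p)^2 / (1 - p^2) = (1 - p) / (1 + p)
    P(one  | >= 1 retained)  = 2 p (1 - p) / (1 - p^2) = 2 p / (1 + p)

With a Uniform(0, 1) prior the posterior is one-dimensional, so the model
offers exact numeric quadrature alongside a random-walk MCMC sampler; both
report the per-tag loss probability ``p`` and the both-tags loss
probability ``p**2``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import simpson


@dataclass(frozen=True)
class TagLossCounts:
    """Recaptured double-tagged fish retaining two vs exactly one tag."""

    n_double: int
    n_single: int

    def __post_init__(self) -> None:
        if self.n_double < 0 or self.n_single < 0:
            raise ValueError("counts must be non-negative")


def tagloss_loglik(p, counts: TagLossCounts):
    """Zero-truncated binomial log-likelihood of the per-tag loss
    probability ``p``; ``-inf`` outside (0, 1)."""
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, -np.inf)
    ok = (p > 0) & (p < 1)
    pv = p[ok]
    out[ok] = counts.n_double * np.log((1 - pv) / (1 + pv)) \
        + counts.n_single * np.log(2 * pv / (1 + pv))
    return float(out) if np.ndim(p) == 0 else out


def tagloss_mle(counts: TagLossCounts) -> float:
    """Closed-form maximiser of the truncated likelihood: solving
    ``2p / (1 + p) = n_single / n`` gives ``p = s / (2n - s)``."""
    n = counts.n_double + counts.n_single
    if n == 0:
        raise ValueError("no recaptures")
    s = counts.n_single
    return s / (2 * n - s)


class TagLossResults:
    """Posterior of the per-tag (``p``) and both-tags (``p_both = p^2``)
    loss probabilities."""

    def __init__(self, table: pd.DataFrame, draws: np.ndarray | None,
                 method: str, counts: TagLossCounts):
        self.table = table
        self.draws = draws
        self.method = method
        self.counts = counts

    def summary(self) -> pd.DataFrame:
        return self.table

    @property
    def mean_p(self) -> float:
        return float(self.table.loc["p", "estimate"])

    @property
    def mean_p_both(self) -> float:
        return float(self.table.loc["p_both", "estimate"])


class TagLossModel:
    """Bayesian zero-truncated binomial tag-loss model (Uniform(0,1) prior)."""

    def __init__(self, counts: TagLossCounts):
        self.counts = counts

    @classmethod
    def from_counts(cls, n_double: int, n_single: int) -> "TagLossModel":
        return cls(TagLossCounts(n_double, n_single))

    # ------------------------------------------------------------------
    def fit(self, method: str = "quadrature", n_draws: int = 10_000,
            seed: int = 1) -> TagLossResults:
        if self.counts.n_double == 0 and self.counts.n_single == 0:
            import warnings
            warnings.warn("no recaptures: returning the Uniform(0,1) prior",
                          stacklevel=2)
        if method == "quadrature":
            return self._fit_quadrature()
        if method == "mcmc":
            return self._fit_mcmc(n_draws=n_draws, seed=seed)
        raise ValueError(f"unknown method {method!r}")

    # ------------------------------------------------------------------
    def _posterior_grid(self, n_grid: int = 20_001):
        grid = np.linspace(0.0, 1.0, n_grid)[1:-1]
        logpost = tagloss_loglik(grid, self.counts)  # flat prior
        logpost -= logpost.max()
        dens = np.exp(logpost)
        dens /= simpson(dens, x=grid)
        return grid, dens

    def _fit_quadrature(self) -> TagLossResults:
        grid, dens = self._posterior_grid()
        cdf = np.concatenate([[0.0], np.cumsum((dens[1:] + dens[:-1]) / 2 * np.diff(grid))])
        cdf /= cdf[-1]

        def q(prob):
            return float(np.interp(prob, cdf, grid))

        mean_p = simpson(grid * dens, x=grid)
        sd_p = np.sqrt(max(simpson(grid ** 2 * dens, x=grid) - mean_p ** 2, 0.0))
        mean_p2 = simpson(grid ** 2 * dens, x=grid)
        sd_p2 = np.sqrt(max(simpson(grid ** 4 * dens, x=grid) - mean_p2 ** 2, 0.0))
        # p -> p^2 is monotone on (0,1): quantiles transform directly
        table = pd.DataFrame(
            [
                {"parameter": "p", "estimate": mean_p, "lower": q(0.025),
                 "upper": q(0.975), "sd": sd_p},
                {"parameter": "p_both", "estimate": mean_p2, "lower": q(0.025) ** 2,
                 "upper": q(0.975) ** 2, "sd": sd_p2},
            ]
        ).set_index("parameter")
        return TagLossResults(table, None, "quadrature", self.counts)

    def _fit_mcmc(self, n_draws: int, seed: int) -> TagLossResults:
        rng = np.random.default_rng(seed)
        n_burn = max(1000, n_draws // 4)
        draws = np.empty(n_draws)
        p = 0.5
        lp = tagloss_loglik(p, self.counts)
        scale = 0.3
        acc = 0
        for it in range(n_burn + n_draws):
            prop = p + scale * rng.standard_normal()
            lprop = tagloss_loglik(prop, self.counts) if 0 < prop < 1 else -np.inf
            if np.log(rng.random()) < lprop - lp:
                p, lp = prop, lprop
                acc += 1
            if it < n_burn and (it + 1) % 100 == 0:
                scale *= float(np.exp((acc / (it + 1)) - 0.4))
            if it >= n_burn:
                draws[it - n_burn] = p
        lo, hi = np.quantile(draws, [0.025, 0.975])
        lo2, hi2 = np.quantile(draws ** 2, [0.025, 0.975])
        table = pd.DataFrame(
            [
                {"parameter": "p", "estimate": draws.mean(), "lower": lo,
                 "upper": hi, "sd": draws.std(ddof=1)},
                {"parameter": "p_both", "estimate": (draws ** 2).mean(),
                 "lower": lo2, "upper": hi2, "sd": (draws ** 2).std(ddof=1)},
            ]
        ).set_index("parameter")
        return TagLossResults(table, draws, "mcmc", self.counts)
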