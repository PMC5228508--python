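"""Convergence diagnostics and posterior summaries.

``rhat`` is the Gelman--Rubin potential scale reduction factor in its
classic between/within-chain variance form; fits are flagged as converged
when every parameter has R-hat <= 1.05.  The same statistic doubles as a
prior-sensitivity metric by pooling each model's draws into a single
pseudo-chain (``between_model_rhat``), with <= 1.2 taken as confirmation
that the posteriors are insensitive to the prior scale.

``summarize`` reports, per parameter: the posterior mean, the central 95%
credible interval (2.5% and 97.5% quantiles), the standard deviation, the
percent relative error (half the interval width over the absolute mean,
times 100) and a two-sided tail-probability significance floored at
``1 / n_draws``.  For inclusion indicators the mean is the selection
probability.
"""

from __future__ import annotations

from typing import Callable

import numpy as np
import pandas as pd


def rhat(chains: np.ndarray) -> float:
    """Potential scale reduction factor for one parameter.

    ``chains`` has shape ``(n_chains, n_draws)``.  If every chain is
    constant and equal the statistic is 1.0 by convention; constant chains
    at different values give ``inf``.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("need a (n_chains >= 2, n_draws) array")
    m, n = chains.shape
    if n < 2:
        raise ValueError("need at least two draws per chain")
    means = chains.mean(axis=1)
    variances = chains.var(axis=1, ddof=1)
    W = variances.mean()
    B_over_n = means.var(ddof=1)
    if W == 0.0:
        return 1.0 if B_over_n == 0.0 else np.inf
    var_hat = (n - 1) / n * W + (1.0 + 1.0 / m) * B_over_n
    return float(np.sqrt(var_hat / W))


def rhat_table(samples: dict[str, np.ndarray]) -> pd.Series:
    """R-hat for every parameter in a name -> (chains, draws) mapping."""
    return pd.Series({name: rhat(arr) for name, arr in samples.items()},
                     name="rhat")


def between_model_rhat(samples_a: dict[str, np.ndarray],
                       samples_b: dict[str, np.ndarray]) -> pd.Series:
    """Prior-sensitivity R-hat: each model's pooled draws as one chain."""
    missing = set(samples_a) ^ set(samples_b)
    if missing:
        raise KeyError(f"parameters not shared by both models: {sorted(missing)}")
    out = {}
    for name in samples_a:
        a = np.asarray(samples_a[name], dtype=float).ravel()
        b = np.asarray(samples_b[name], dtype=float).ravel()
        n = min(a.size, b.size)
        out[name] = rhat(np.vstack([a[:n], b[:n]]))
    return pd.Series(out, name="between_model_rhat")


def relative_error_percent(estimate: float, lower: float, upper: float) -> float:
    """Percent relative error: half the credible-interval width over the
    absolute point estimate, times 100.  Infinite for a zero estimate."""
    if estimate == 0.0:
        return np.inf
    return (upper - lower) / 2.0 / abs(estimate) * 100.0


def tail_significance(draws: np.ndarray) -> float:
    """Two-sided posterior tail probability of the sign, floored at the
    Monte Carlo resolution 1/n_draws."""
    draws = np.asarray(draws, dtype=float).ravel()
    floor = 1.0 / draws.size
    p = 2.0 * min(np.mean(draws > 0), np.mean(draws < 0))
    return float(min(max(p, floor), 1.0))


def summarize(samples: dict[str, np.ndarray]) -> pd.DataFrame:
    """Posterior summary table, one row per parameter.

    Columns: estimate (posterior mean), lower/upper (95% credible interval),
    sd, error (percent relative error; inf when the mean is 0) and
    significance (two-sided tail probability, floored at 1/n_draws).
    """
    rows = []
    for name, arr in samples.items():
        draws = np.asarray(arr, dtype=float).ravel()
        if draws.size == 0:
            raise ValueError(f"no draws for {name}")
        est = draws.mean()
        lower, upper = np.quantile(draws, [0.025, 0.975])
        sd = draws.std(ddof=1) if draws.size > 1 else 0.0
        rows.append({
            "parameter": name, "estimate": est, "lower": lower, "upper": upper,
            "sd": sd, "error": relative_error_percent(est, lower, upper),
            "significance": tail_significance(draws),
        })
    return pd.DataFrame(rows).set_index("parameter")


def predict_quantity(samples: dict[str, np.ndarray],
                     transform: Callable[..., np.ndarray]) -> dict:
    """Posterior summary of a function of the parameters.

    ``transform`` receives every parameter's flattened draws as keyword
    arguments and must return per-draw values; the transform is applied
    draw by draw and summarised afterwards (posterior mean of the function,
    not the function of posterior means).
    """
    flat = {name: np.asarray(arr, dtype=float).ravel() for name, arr in samples.items()}
    values = np.asarray(transform(**flat), dtype=float)
    tab = summarize({"quantity": values})
    row = tab.loc["quantity"]
    return {"mean": float(row["estimate"]), "lower": float(row["lower"]),
            "upper": float(row["upper"]), "sd": float(row["sd"])}
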