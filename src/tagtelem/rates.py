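"""Closed-form fisheries transforms.

Seasonal interval probabilities from the survival model are converted to
annual interval probabilities (four seasonal periods per year), then to
annual instantaneous rates

    F = -log(1 - rho_annual)        fishing mortality
    M = -log(phi_annual)            natural mortality

and onward to catchability (recapture probability per unit angler effort,
q = rho / E), density implied by a known catch (D = (C / rho) / area), and
two empirical natural-mortality estimators: the maximum-age form
M = 4.899 * t_max^-0.916 and the growth-based form
M = 4.188 * k^0.73 * L_inf^-0.33.  A meta-analytic hyperstability curve
q = exp(-0.14 E / (1 + 0.35 D)) / E is included for comparison with the
telemetry-based catchability.

All functions are vectorised, so they can be applied per posterior draw
(the production path via ``CJSResults.predict``) or to plug-in point
estimates for worked examples.
"""

from __future__ import annotations

import numpy as np

#: Main-lake surface area in hectares (388 km^2).
LAKE_AREA_HA: float = 38_800.0


def annual_interval(p_seasonal, kind: str):
    """Annual interval probability from a seasonal one.

    ``kind="survival"``: survive all four seasons, ``p**4``.
    ``kind="recapture"``: recaptured in at least one season,
    ``1 - (1 - p)**4``.
    """
    p = np.asarray(p_seasonal, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    if kind == "survival":
        out = p ** 4
    elif kind == "recapture":
        out = 1.0 - (1.0 - p) ** 4
    else:
        raise ValueError(f"unknown kind {kind!r}")
    return float(out) if np.isscalar(p_seasonal) else out


def annual_survival_spawner(phi_nonspawn_seasonal, phi_spawn_seasonal):
    """Annual survival of a spawner: three non-spawning seasons and one
    spawning season, ``phi_ns**3 * phi_sp``."""
    a = np.asarray(phi_nonspawn_seasonal, dtype=float)
    b = np.asarray(phi_spawn_seasonal, dtype=float)
    if np.any((a < 0) | (a > 1)) or np.any((b < 0) | (b > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    out = a ** 3 * b
    return float(out) if np.isscalar(phi_nonspawn_seasonal) else out


def instantaneous_F(rho_annual):
    """Annual instantaneous fishing mortality, ``-log(1 - rho)``."""
    rho = np.asarray(rho_annual, dtype=float)
    if np.any((rho < 0) | (rho >= 1)):
        raise ValueError("annual recapture probability must lie in [0, 1)")
    out = -np.log1p(-rho)
    return float(out) if np.isscalar(rho_annual) else out


def instantaneous_M(phi_annual):
    """Annual instantaneous natural mortality, ``-log(phi)``."""
    phi = np.asarray(phi_annual, dtype=float)
    if np.any((phi <= 0) | (phi > 1)):
        raise ValueError("annual survival probability must lie in (0, 1]")
    out = -np.log(phi)
    return float(out) if np.isscalar(phi_annual) else out


def effective_interval_F(rho_annual, release_rate):
    """Annual interval fishing mortality after discounting released fish."""
    rho = np.asarray(rho_annual, dtype=float)
    r = np.asarray(release_rate, dtype=float)
    if np.any((rho < 0) | (rho > 1)) or np.any((r < 0) | (r > 1)):
        raise ValueError("inputs must lie in [0, 1]")
    out = rho * (1.0 - r)
    return float(out) if np.isscalar(rho_annual) else out


def angler_effort(angler_hours, area_ha=LAKE_AREA_HA):
    """Angler effort E in angler-hr per hectare per year."""
    if area_ha <= 0:
        raise ValueError("area must be positive")
    return float(angler_hours) / float(area_ha)


def catchability(rho_annual, effort):
    """Catchability q = rho / E (per angler-hr ha^-1 yr^-1)."""
    rho = np.asarray(rho_annual, dtype=float)
    if effort <= 0:
        raise ValueError("effort must be positive")
    out = rho / effort
    return float(out) if np.isscalar(rho_annual) else out


def density(catch, rho_annual, area_ha=LAKE_AREA_HA):
    """Density (fish per ha) implied by an annual catch and recapture rate."""
    rho = np.asarray(rho_annual, dtype=float)
    if np.any(rho <= 0):
        raise ValueError("recapture probability must be positive")
    if area_ha <= 0:
        raise ValueError("area must be positive")
    out = (catch / rho) / area_ha
    return float(out) if np.isscalar(rho_annual) else out


def empirical_M_tmax(t_max):
    """Maximum-age natural-mortality estimator, 4.899 * t_max^-0.916."""
    t = np.asarray(t_max, dtype=float)
    if np.any(t <= 0):
        raise ValueError("maximum age must be positive")
    out = 4.899 * t ** -0.916
    return float(out) if np.isscalar(t_max) else out


def empirical_M_growth(k, l_inf_mm):
    """Growth-based natural-mortality estimator, 4.188 * k^0.73 * L_inf^-0.33."""
    k = np.asarray(k, dtype=float)
    li = np.asarray(l_inf_mm, dtype=float)
    if np.any(k <= 0) or np.any(li <= 0):
        raise ValueError("growth parameters must be positive")
    out = 4.188 * k ** 0.73 * li ** -0.33
    return float(out) if np.isscalar(li) and np.ndim(k) == 0 else out


def derived_table(draws: dict, year_covariate: float, effort: float,
                  catch: float, area_ha: float = LAKE_AREA_HA,
                  release_rate: float | None = None,
                  t_max_yr: float | None = None,
                  growth=None) -> "pd.DataFrame":
    """Posterior summaries of the derived fisheries quantities.

    ``draws`` maps coefficient names to flattened posterior draws (the
    survival-model parameterisation); every transform is applied per draw
    and summarised afterwards.  Point-input estimators (empirical M,
    hyperstability q) are appended as degenerate rows when their inputs are
    supplied.
    """
    import pandas as pd
    from scipy.special import expit

    from .diagnostics import summarize

    Y = year_covariate
    phi_ns = expit(draws["surv_intercept"] + draws["surv_year"] * Y)
    phi_sp = expit(draws["surv_intercept"] + draws["surv_spawn"]
                   + draws["surv_year"] * Y)
    rho = expit(draws["recap_intercept"] + draws["recap_year"] * Y)

    per_draw = {
        "annual_recapture": annual_interval(rho, "recapture"),
        "annual_survival_nonspawner": annual_interval(phi_ns, "survival"),
        "annual_survival_spawner": annual_survival_spawner(phi_ns, phi_sp),
    }
    per_draw["F_instantaneous"] = instantaneous_F(per_draw["annual_recapture"])
    per_draw["M_instantaneous_nonspawner"] = instantaneous_M(
        per_draw["annual_survival_nonspawner"])
    per_draw["M_instantaneous_spawner"] = instantaneous_M(
        per_draw["annual_survival_spawner"])
    per_draw["catchability"] = catchability(per_draw["annual_recapture"], effort)
    per_draw["density_fish_ha"] = density(catch, per_draw["annual_recapture"], area_ha)
    if release_rate is not None:
        per_draw["effective_interval_F"] = effective_interval_F(
            per_draw["annual_recapture"], release_rate)

    tab = summarize(per_draw)
    extra = []
    if t_max_yr is not None:
        extra.append(("empirical_M_tmax", empirical_M_tmax(t_max_yr)))
    if growth is not None:
        extra.append(("empirical_M_growth",
                      empirical_M_growth(growth.k, growth.l_inf_mm)))
        mean_D = float(np.mean(per_draw["density_fish_ha"]))
        extra.append(("hyperstability_q", hyperstability_q(effort, mean_D)))
    for name, v in extra:
        tab.loc[name] = {"estimate": v, "lower": np.nan, "upper": np.nan,
                         "sd": np.nan, "error": np.nan, "significance": np.nan}
    return tab


def hyperstability_q(effort, density_fish_ha):
    """Meta-analytic catchability-density curve,
    q = exp(-0.14 E / (1 + 0.35 D)) / E."""
    E = np.asarray(effort, dtype=float)
    D = np.asarray(density_fish_ha, dtype=float)
    if np.any(E <= 0) or np.any(D < 0):
        raise ValueError("require E > 0 and D >= 0")
    out = np.exp(-0.14 * E / (1.0 + 0.35 * D)) / E
    return float(out) if np.isscalar(effort) and np.isscalar(density_fish_ha) else out
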