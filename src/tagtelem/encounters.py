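"""Seasonal encounter histories.

:class:`EncounterData` is the observation set consumed by the survival model:
for each fish ``i`` and seasonal period ``t`` between first capture ``f_i``
and the censoring period it records whether the fish was monitored by an
active transmitter (``T``), detected moving between lake sections (``m``,
defined only where ``T = 1``), reported recaptured by an angler (``y``),
and observed spawning (``x_obs``, available only where the transmitter
monitored the whole spawning-season period), together with the
spawning-season flag ``S``, the interpolated fork length and the
standardised year covariate.

Fish are censored after the period of a reported recapture: rows for later
periods simply do not exist.  Observations in the release period itself are
not modelled (the history is conditioned on release), so ``y`` counts only
for ``t > f_i`` and ``T`` is always 0 at ``f_i``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .periods import SPAWN_SEASON, PeriodCalendar

LONG_COLUMNS = [
    "fish_id", "species", "period", "year", "season",
    "T", "m", "y", "x_obs", "S", "fork_length_mm", "L", "Y",
]


@dataclass
class EncounterData:
    """Rectangular per-fish x per-period encounter arrays.

    All ``(n_fish, n_periods)`` arrays are defined on ``first[i] <= t <=
    last[i]`` and should be ignored elsewhere.  ``x_obs`` uses NaN for
    unobserved spawning states (unmonitored spawn seasons); ``m`` is only
    meaningful where ``T`` is True.
    """

    fish_ids: np.ndarray            # (n,) object/str
    species: np.ndarray             # (n,) str
    first: np.ndarray               # (n,) int, period of first capture
    last: np.ndarray                # (n,) int, censoring period (inclusive)
    T: np.ndarray                   # (n, P) bool
    S: np.ndarray                   # (n, P) bool
    y: np.ndarray                   # (n, P) int8
    m: np.ndarray                   # (n, P) int8
    x_obs: np.ndarray               # (n, P) float (NaN = unobserved)
    fork_length_mm: np.ndarray      # (n, P) float
    L: np.ndarray                   # (n, P) float, (FL-600)/100
    Y: np.ndarray                   # (P,) float, standardised year
    calendar: PeriodCalendar
    meta: dict = field(default_factory=dict)

    # ------------------------------------------------------------------
    @property
    def n_fish(self) -> int:
        return len(self.fish_ids)

    @property
    def n_periods(self) -> int:
        return self.calendar.n_periods

    def valid_mask(self) -> np.ndarray:
        """(n, P) bool: first[i] <= t <= last[i]."""
        t = np.arange(self.n_periods)
        return (t >= self.first[:, None]) & (t <= self.last[:, None])

    def validate(self) -> None:
        n, P = self.n_fish, self.n_periods
        for name in ("T", "S", "y", "m", "x_obs", "fork_length_mm", "L"):
            arr = getattr(self, name)
            if arr.shape != (n, P):
                raise ValueError(f"{name} has shape {arr.shape}, expected {(n, P)}")
        if self.Y.shape != (P,):
            raise ValueError("Y must be per-period")
        if np.any(self.last < self.first):
            raise ValueError("censoring period precedes first capture")
        valid = self.valid_mask()
        if np.any(self.y * valid).sum() and np.any(self.y.sum(axis=1) > 1):
            raise ValueError("a fish can be reported recaptured at most once")
        if np.any(self.y[~valid]):
            raise ValueError("recapture recorded outside the modelled window")
        if np.any(self.T[np.arange(n), self.first]):
            raise ValueError("transmitter cannot be active for the whole release period")
        # spawn-season flags must match the species' season
        seasons = self.calendar.seasons()
        for i in range(n):
            want = SPAWN_SEASON[str(self.species[i])]
            bad = self.S[i] & (seasons != want)
            if bad.any():
                raise ValueError(f"fish {self.fish_ids[i]}: S=1 outside {want}")
        if np.any(~np.isnan(self.x_obs) & ~self.S):
            raise ValueError("spawning observations outside spawning seasons")

    # ------------------------------------------------------------------
    def subset(self, species: str | None = None, fish_ids=None) -> "EncounterData":
        """Return a copy restricted to one species and/or a set of fish."""
        keep = np.ones(self.n_fish, dtype=bool)
        if species is not None:
            keep &= self.species == species
        if fish_ids is not None:
            keep &= np.isin(self.fish_ids, list(fish_ids))
        return EncounterData(
            fish_ids=self.fish_ids[keep],
            species=self.species[keep],
            first=self.first[keep],
            last=self.last[keep],
            T=self.T[keep],
            S=self.S[keep],
            y=self.y[keep],
            m=self.m[keep],
            x_obs=self.x_obs[keep],
            fork_length_mm=self.fork_length_mm[keep],
            L=self.L[keep],
            Y=self.Y.copy(),
            calendar=self.calendar,
            meta=dict(self.meta),
        )

    # ------------------------------------------------------------------
    def to_long(self) -> pd.DataFrame:
        """Long-format data frame, one row per modelled fish-period."""
        rows = []
        years = self.calendar.years()
        seasons = self.calendar.seasons()
        for i in range(self.n_fish):
            for t in range(self.first[i], self.last[i] + 1):
                rows.append({
                    "fish_id": self.fish_ids[i],
                    "species": self.species[i],
                    "period": t,
                    "year": int(years[t]),
                    "season": seasons[t],
                    "T": int(self.T[i, t]),
                    "m": int(self.m[i, t]) if self.T[i, t] else np.nan,
                    "y": int(self.y[i, t]),
                    "x_obs": self.x_obs[i, t],
                    "S": int(self.S[i, t]),
                    "fork_length_mm": self.fork_length_mm[i, t],
                    "L": self.L[i, t],
                    "Y": self.Y[t],
                })
        return pd.DataFrame(rows, columns=LONG_COLUMNS)

    @classmethod
    def from_long(cls, df: pd.DataFrame, calendar: PeriodCalendar) -> "EncounterData":
        """Rebuild the rectangular arrays from :meth:`to_long` output."""
        P = calendar.n_periods
        ids = df["fish_id"].drop_duplicates().to_numpy()
        n = len(ids)
        idx = {f: i for i, f in enumerate(ids)}
        species = np.empty(n, dtype=object)
        first = np.full(n, P, dtype=int)
        last = np.full(n, -1, dtype=int)
        T = np.zeros((n, P), dtype=bool)
        S = np.zeros((n, P), dtype=bool)
        y = np.zeros((n, P), dtype=np.int8)
        m = np.zeros((n, P), dtype=np.int8)
        x_obs = np.full((n, P), np.nan)
        fl = np.full((n, P), np.nan)
        Y = np.zeros(P)
        for _, r in df.iterrows():
            i, t = idx[r["fish_id"]], int(r["period"])
            species[i] = r["species"]
            first[i] = min(first[i], t)
            last[i] = max(last[i], t)
            T[i, t] = bool(r["T"])
            S[i, t] = bool(r["S"])
            y[i, t] = int(r["y"])
            if not pd.isna(r["m"]):
                m[i, t] = int(r["m"])
            x_obs[i, t] = r["x_obs"]
            fl[i, t] = r["fork_length_mm"]
            Y[t] = r["Y"]
        data = cls(
            fish_ids=ids, species=species.astype(str), first=first, last=last,
            T=T, S=S, y=y, m=m, x_obs=x_obs, fork_length_mm=fl,
            L=(fl - 600.0) / 100.0, Y=Y, calendar=calendar,
        )
        return data
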