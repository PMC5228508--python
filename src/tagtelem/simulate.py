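"""Synthetic tagging + telemetry data generator.

Two fidelity levels:

* :func:`simulate_encounters` draws seasonal encounter histories directly
  from the state-space model's Bernoulli structure (alive states, spawning
  states, movement detections, angler recaptures) with Von Bertalanffy
  length covariates, returning the true latent states for recovery tests.

* :func:`simulate_telemetry` emits a raw data bundle -- hourly detections,
  captures, angler recaptures, section metadata and the receiver-section
  map -- that is *consistent by construction* with an underlying encounter
  simulation: movement within a period is realised as a section switch,
  spawning is realised as the species-appropriate detection hiatus (or an
  outflow-section visit for Rainbow Trout), planted post-release failures
  are silent or single-section from day 0, and noise rows (<= 2 detections
  per hour) plus post-tag-life rows are sprinkled in for the filters to
  remove.  The ground truth (encounter matrices, latent states, expected
  post-release classification and the clean daily track) is returned as a
  sidecar so every reduction step can be checked exactly.

Default design sizes mirror the study that motivated the package: two
species released 2008-2013 (~88 + ~149 fish), acoustic transmitters in
2008-2011 with tag lives of 455, 830 or 1,239 days, anchor-tag-only
cohorts in the final two years, and 30 lake sections with unique areas.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .encounters import EncounterData
from .growth import SPECIES_GROWTH, length_covariate, standardize_year, vb_length
from .likelihood import Coefficients, Indicators
from .periods import SPAWN_SEASON, PeriodCalendar

#: Generating coefficients of study-like magnitude, per species.
DEFAULT_COEFFICIENTS = {
    "BullTrout": Coefficients(
        surv_intercept=2.73, surv_spawn=0.0, surv_year=-0.98,
        recap_intercept=-3.07, recap_year=0.0,
        move_intercept=2.36, move_spawn_season=-2.40, move_year=0.0,
        spawn_intercept=2.43, spawn_length=1.15, spawn_year=0.0,
    ),
    "RainbowTrout": Coefficients(
        surv_intercept=2.70, surv_spawn=-2.67, surv_year=0.0,
        recap_intercept=-3.29, recap_year=0.0,
        move_intercept=2.98, move_spawn_season=0.0, move_year=0.0,
        spawn_intercept=0.16, spawn_length=4.46, spawn_year=-2.15,
    ),
}

DEFAULT_INDICATORS = {
    "BullTrout": Indicators(g_surv_spawn=0, g_surv_year=1, g_recap_year=0,
                            g_move_spawn_season=1, g_move_year=0,
                            g_spawn_length=1, g_spawn_year=0),
    "RainbowTrout": Indicators(g_surv_spawn=1, g_surv_year=0, g_recap_year=0,
                               g_move_spawn_season=0, g_move_year=0,
                               g_spawn_length=1, g_spawn_year=1),
}

DEFAULT_RELEASES = {
    "BullTrout": {2009: 22, 2010: 26, 2011: 21, 2012: 13, 2013: 6},
    "RainbowTrout": {2008: 18, 2009: 31, 2010: 29, 2011: 36, 2012: 26, 2013: 9},
}


@dataclass
class SimDesign:
    """Study design for the generator; defaults emulate the source study."""

    calendar: PeriodCalendar = field(default_factory=lambda: PeriodCalendar(2008, 6))
    releases: dict = field(default_factory=lambda: {
        sp: dict(y) for sp, y in DEFAULT_RELEASES.items()})
    acoustic_last_year: int = 2011
    pilot_tag_life_days: int = 455
    long_tag_life_days: int = 1239
    short_tag_life_days: int = 830
    long_tag_prob: float = 0.7
    coefficients: dict = field(default_factory=lambda: dict(DEFAULT_COEFFICIENTS))
    indicators: dict = field(default_factory=lambda: dict(DEFAULT_INDICATORS))
    length_mean_mm: float = 650.0
    length_sd_mm: float = 80.0
    length_min_mm: float = 500.0
    length_max_mm: float = 980.0
    post_release_frac: dict = field(default_factory=lambda: {
        "BullTrout": 0.07, "RainbowTrout": 0.25})
    emission_step_days: int = 3
    hourly_extra_rate: float = 4.0
    noise_row_prob: float = 0.03
    stale_row_prob: float = 0.02
    multi_section_day_prob: float = 0.07
    n_sections: int = 30
    seed: int = 42

    def species(self) -> list[str]:
        return list(self.releases)


def small_design(species: str = "BullTrout", n_fish: int = 30,
                 n_years: int = 4, start_year: int = 2008,
                 coefficients: Coefficients | None = None,
                 seed: int = 42, **kw) -> SimDesign:
    """Compact single-species design for tests: everyone released in the
    first year with a transmitter outliving the whole calendar."""
    cal = PeriodCalendar(start_year, n_years)
    d = SimDesign(
        calendar=cal,
        releases={species: {start_year: n_fish}},
        acoustic_last_year=start_year,
        pilot_tag_life_days=4000, long_tag_life_days=4000,
        short_tag_life_days=4000,
        post_release_frac={species: 0.0},
        seed=seed,
        **kw,
    )
    if coefficients is not None:
        d.coefficients = {species: coefficients}
    return d


# ----------------------------------------------------------------------
def _draw_lengths(design: SimDesign, n: int, rng) -> np.ndarray:
    out = np.empty(n)
    for i in range(n):
        while True:
            v = rng.normal(design.length_mean_mm, design.length_sd_mm)
            if design.length_min_mm <= v <= design.length_max_mm:
                out[i] = v
                break
    return out


def _tag_life(design: SimDesign, year: int, rng) -> float:
    if year > design.acoustic_last_year:
        return np.nan
    if year == design.calendar.start_year:
        return float(design.pilot_tag_life_days)
    long = rng.random() < design.long_tag_prob
    return float(design.long_tag_life_days if long else design.short_tag_life_days)


def simulate_encounters(design: SimDesign, seed: int | None = None,
                        condition_first_survival: bool = False
                        ) -> tuple[EncounterData, dict]:
    """Forward-simulate encounter histories from the generative model.

    Returns the encounter data and a truth dict with the latent alive and
    spawning states, capture metadata and the generating coefficients.
    ``condition_first_survival`` forces survival of the first transition
    (used by the raw-telemetry generator so post-release classification has
    an unambiguous ground truth).
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    cal = design.calendar
    P = cal.n_periods
    seasons = cal.seasons()
    years = cal.years().astype(float)
    # a single-year calendar has no year trend to standardise
    Y = standardize_year(years) if np.unique(years).size > 1 else np.zeros_like(years)

    rows = []
    for sp in design.species():
        for year, count in sorted(design.releases[sp].items()):
            for j in range(count):
                day = int(rng.integers(0, 245))  # Mar 1 .. Oct 31
                date = pd.Timestamp(year=year, month=3, day=1) + pd.Timedelta(days=day)
                rows.append({"species": sp, "capture_date": date,
                             "tag_life_days": _tag_life(design, year, rng)})
    n = len(rows)
    fish_ids = np.array([f"{r['species'][0]}T{i:03d}" for i, r in enumerate(rows)],
                        dtype=object)
    species = np.array([r["species"] for r in rows], dtype=str)
    capture_dates = pd.Series([r["capture_date"] for r in rows], index=fish_ids)
    tag_life = np.array([r["tag_life_days"] for r in rows])
    lengths = _draw_lengths(design, n, rng)

    first = np.array([cal.period_of(d) for d in capture_dates], dtype=int)
    last = np.full(n, P - 1, dtype=int)
    T = np.zeros((n, P), dtype=bool)
    S = np.zeros((n, P), dtype=bool)
    z = np.zeros((n, P), dtype=np.int8)
    x = np.zeros((n, P), dtype=np.int8)
    y = np.zeros((n, P), dtype=np.int8)
    m = np.zeros((n, P), dtype=np.int8)
    x_obs = np.full((n, P), np.nan)
    fl = np.full((n, P), np.nan)

    for i in range(n):
        sp = str(species[i])
        coef = design.coefficients[sp]
        S[i] = seasons == SPAWN_SEASON[sp]
        if np.isfinite(tag_life[i]):
            death = capture_dates.iloc[i] + pd.Timedelta(days=tag_life[i])
            for t in range(first[i] + 1, P):
                T[i, t] = death >= cal.end(t)
        params = SPECIES_GROWTH[sp]
        ts = np.arange(first[i], P)
        fl[i, ts] = vb_length(lengths[i], first[i], ts, params)
        L = length_covariate(fl[i])

        z[i, first[i]] = 1
        for t in range(first[i], P):
            if z[i, t] == 0:
                break
            if S[i, t]:
                kappa = expit(coef.spawn_intercept + coef.spawn_length * L[t]
                              + coef.spawn_year * Y[t])
                x[i, t] = int(rng.random() < kappa)
            if T[i, t] and S[i, t]:
                x_obs[i, t] = x[i, t]
            if T[i, t]:
                delta = expit(coef.move_intercept
                              + coef.move_spawn_season * float(S[i, t])
                              + coef.move_year * Y[t])
                m[i, t] = int(rng.random() < delta)
            if t > first[i]:
                rho = expit(coef.recap_intercept + coef.recap_year * Y[t])
                if rng.random() < rho:
                    y[i, t] = 1
                    last[i] = t
                    break
            if t + 1 < P:
                phi = expit(coef.surv_intercept + coef.surv_spawn * x[i, t]
                            + coef.surv_year * Y[t])
                alive = rng.random() < phi
                if condition_first_survival and t == first[i]:
                    alive = True
                z[i, t + 1] = int(alive)
        # dead-but-monitored spawn seasons are observed as non-spawning
        for t in range(first[i], last[i] + 1):
            if T[i, t] and S[i, t] and np.isnan(x_obs[i, t]):
                x_obs[i, t] = 0.0
        # clip matrices to the censoring window
        if last[i] < P - 1:
            T[i, last[i] + 1:] = False
            m[i, last[i] + 1:] = 0
            x_obs[i, last[i] + 1:] = np.nan
            fl[i, last[i] + 1:] = np.nan

    data = EncounterData(
        fish_ids=fish_ids, species=species, first=first, last=last,
        T=T, S=S, y=y, m=m, x_obs=x_obs, fork_length_mm=fl,
        L=length_covariate(fl), Y=Y, calendar=cal,
        meta={"generator": "simulate_encounters", "seed": design.seed if seed is None else seed},
    )
    data.validate()
    truth = {
        "z": z, "x": x,
        "capture_dates": capture_dates,
        "tag_life_days": pd.Series(tag_life, index=fish_ids),
        "fork_length_at_capture": pd.Series(lengths, index=fish_ids),
        "coefficients": design.coefficients,
        "indicators": design.indicators,
    }
    return data, truth


# ----------------------------------------------------------------------
# raw-telemetry level

def default_sections(design: SimDesign) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Section metadata (unique areas) and the receiver-section map."""
    n = design.n_sections
    ids = [f"S{i + 1:02d}" for i in range(n)]
    rows, recv = [], []
    for i, sid in enumerate(ids):
        n_rec = 2 if i % 5 == 1 else 1
        rows.append({
            "section_id": sid,
            "n_receivers": n_rec,
            "area_ha": 900.0 + 23.7 * i,
            "north_arm_top": sid == "S07",
            "west_arm_head": sid == "S20",
            "south_arm_bottom": sid == f"S{n:02d}",
            "trout_lake_outflow": sid == "S02",
            "upper_north": sid in ("S07", "S08", "S09"),
        })
        for j in range(n_rec):
            recv.append({"receiver_id": f"R{sid}{j}", "section_id": sid})
    return pd.DataFrame(rows), pd.DataFrame(recv)


def _emission_days(start: pd.Timestamp, end: pd.Timestamp, step: int) -> list:
    if end < start:
        return []
    days = list(pd.date_range(start, end, freq=f"{step}D"))
    if days and days[-1] != end:
        days.append(end)
    return days


class _TrackBuilder:
    """Accumulates consistent daily positions and hourly detection rows."""

    def __init__(self, design: SimDesign, sections: pd.DataFrame,
                 receivers: pd.DataFrame, rng):
        self.design = design
        self.rng = rng
        self.receiver_of = receivers.groupby("section_id")["receiver_id"].first()
        special = sections.loc[sections["trout_lake_outflow"], "section_id"]
        self.pool = [s for s in sections["section_id"] if s not in set(special)]
        self.upper = list(sections.loc[sections["upper_north"], "section_id"])
        self.daily = []      # truth: fish, date, section
        self.hourly = []     # emitted detection rows

    def pick(self, exclude=()) -> str:
        while True:
            s = self.pool[int(self.rng.integers(0, len(self.pool)))]
            if s not in exclude:
                return s

    def emit(self, fish: str, day: pd.Timestamp, section: str) -> None:
        n_det = 5 + int(self.rng.poisson(self.design.hourly_extra_rate))
        self.daily.append({"fish_id": fish, "date": day, "section_id": section})
        self.hourly.append({
            "fish_id": fish, "receiver_id": self.receiver_of[section],
            "hour": day + pd.Timedelta(hours=9), "n_detections": n_det,
        })
        if self.rng.random() < self.design.multi_section_day_prob:
            other = self.pick(exclude=(section,))
            self.hourly.append({
                "fish_id": fish, "receiver_id": self.receiver_of[other],
                "hour": day + pd.Timedelta(hours=14), "n_detections": 3,
            })

    def emit_range(self, fish: str, start, end, section: str) -> None:
        for day in _emission_days(start, end, self.design.emission_step_days):
            self.emit(fish, day, section)


def simulate_telemetry(design: SimDesign, seed: int | None = None
                       ) -> tuple[dict, dict]:
    """Raw data bundle plus ground-truth sidecar.

    Returns ``(bundle, truth)`` where ``bundle`` holds the data frames
    ``detections``, ``captures``, ``recaptures``, ``sections`` and
    ``receivers`` (the CSV schemas the prep pipeline reads), and ``truth``
    holds the underlying encounter data, latent states, the expected
    post-release classification and the noise-free daily track.
    """
    master = np.random.default_rng(design.seed if seed is None else seed)
    enc_seed = int(master.integers(2 ** 31))
    rng = np.random.default_rng(int(master.integers(2 ** 31)))

    enc, truth = simulate_encounters(design, seed=enc_seed,
                                     condition_first_survival=True)
    cal = design.calendar
    P = cal.n_periods
    sections, receivers = default_sections(design)
    tb = _TrackBuilder(design, sections, receivers, rng)

    captures_rows, recapture_rows = [], []
    status = {}
    z, x = truth["z"], truth["x"]
    cap_dates = truth["capture_dates"]
    tag_life = truth["tag_life_days"]

    for i, fish in enumerate(enc.fish_ids):
        sp = str(enc.species[i])
        release = pd.Timestamp(cap_dates[fish])
        life = tag_life[fish]
        # last whole day of transmitter life: daytime pings on the expiry
        # day itself would land past the expected tag life and be filtered
        tag_death = (release + pd.Timedelta(days=life - 1)
                     if np.isfinite(life) else pd.NaT)
        f, last = enc.first[i], enc.last[i]

        # recapture date: final 20 days of the recapture period
        rec_date = None
        if enc.y[i, last] == 1:
            end = cal.end(last)
            rec_date = end - pd.Timedelta(days=int(rng.integers(0, 20)))
            rec_date = max(rec_date, release + pd.Timedelta(days=1))
            recapture_rows.append({"fish_id": fish, "date": rec_date,
                                   "tags_returned": "100;10"})

        home_rel = tb.pick()
        captures_rows.append({
            "fish_id": fish, "species": sp,
            "capture_date": release.date().isoformat(),
            "fork_length_mm": round(float(truth["fork_length_at_capture"][fish]), 1),
            "tag_life_days": life, "reward1": 100, "reward2": 10,
            "release_section": home_rel,
        })
        status[fish] = "retained"
        if not np.isfinite(life):
            continue  # anchor-only fish: no acoustic track

        prev_home = home_rel
        for t in range(f, last + 1):
            if z[i, t] == 0:
                break
            start = max(cal.start(t), release)
            end = min(cal.end(t), tag_death)
            if rec_date is not None and t == last:
                end = min(end, rec_date - pd.Timedelta(days=1))
            if end < start:
                continue
            if t == f:
                # release period: switch section after 35 days so every
                # retained fish spans two sections even if it never moves
                split = release + pd.Timedelta(days=35)
                if split <= end:
                    second = tb.pick(exclude=(home_rel,))
                    tb.emit_range(fish, start, split - pd.Timedelta(days=1), home_rel)
                    tb.emit_range(fish, split, end, second)
                    prev_home = second
                else:
                    tb.emit_range(fish, start, end, home_rel)
                continue
            moved = enc.m[i, t] == 1 and enc.T[i, t]
            if enc.S[i, t] and x[i, t] == 1 and enc.T[i, t]:
                if sp == "BullTrout":
                    # hiatus Jul 26 - Aug 31 inside the summer period
                    a = tb.pick(exclude=(prev_home,))
                    b = tb.pick(exclude=(a,)) if moved else a
                    gap_before = pd.Timestamp(f"{cal.year(t)}-07-25")
                    gap_after = pd.Timestamp(f"{cal.year(t)}-09-01")
                    tb.emit_range(fish, start, min(gap_before, end), a)
                    if gap_after <= end:
                        tb.emit_range(fish, gap_after, end, b)
                    prev_home = b
                else:
                    if rng.random() < 0.5:
                        # outflow-section visit in April-May
                        a = "S02"
                        if moved:
                            b = tb.pick(exclude=(a,))
                            mid = pd.Timestamp(f"{cal.year(t)}-05-15")
                            tb.emit_range(fish, start,
                                          min(mid - pd.Timedelta(days=1), end), a)
                            if mid <= end:
                                tb.emit_range(fish, mid, end, b)
                            prev_home = b
                        else:
                            tb.emit_range(fish, start, end, a)
                            prev_home = a
                    else:
                        # three-week hiatus bracketed in the upper lake
                        a = tb.upper[0]
                        b = tb.upper[1] if moved else a
                        tb.emit_range(fish, start,
                                      min(pd.Timestamp(f"{cal.year(t)}-04-02"), end), a)
                        resume = pd.Timestamp(f"{cal.year(t)}-05-15")
                        if resume <= end:
                            tb.emit_range(fish, resume, end, b)
                        prev_home = b
            else:
                a = tb.pick(exclude=(prev_home,))
                if moved:
                    b = tb.pick(exclude=(a,))
                    mid = start + (end - start) / 2
                    mid = pd.Timestamp(mid.date())
                    tb.emit_range(fish, start, mid, a)
                    tb.emit_range(fish, mid + pd.Timedelta(days=1), end, b)
                    prev_home = b
                else:
                    tb.emit_range(fish, start, end, a)
                    prev_home = a

    # planted post-release failures (extra fish, silent or single-section)
    failure_rows = []
    for sp in design.species():
        frac = design.post_release_frac.get(sp, 0.0)
        acoustic = [(i, f) for i, f in enumerate(enc.fish_ids)
                    if str(enc.species[i]) == sp and np.isfinite(tag_life[f])]
        n_fail = int(round(len(acoustic) * frac))
        for j in range(n_fail):
            fish = f"{sp[0]}F{j:03d}"
            year = min(design.releases[sp]) if design.releases[sp] else cal.start_year
            release = pd.Timestamp(year=year, month=5, day=1) + pd.Timedelta(
                days=int(rng.integers(0, 120)))
            life = _tag_life(design, year, rng)
            if not np.isfinite(life):
                life = float(design.short_tag_life_days)
            sec = tb.pick()
            captures_rows.append({
                "fish_id": fish, "species": sp,
                "capture_date": release.date().isoformat(),
                "fork_length_mm": round(float(_draw_lengths(design, 1, rng)[0]), 1),
                "tag_life_days": life, "reward1": 100, "reward2": 10,
                "release_section": sec,
            })
            status[fish] = "post_release_mortality"
            failure_rows.append(fish)
            if j % 2 == 0:
                continue  # silent from day 0
            tb.emit_range(fish, release, release + pd.Timedelta(days=90), sec)

    detections = pd.DataFrame(tb.hourly)
    daily_truth = pd.DataFrame(tb.daily)

    # acoustic noise: sparse hours (<= 2 detections) and post-tag-life rows
    noise = []
    if len(detections):
        for _, r in detections.iterrows():
            if rng.random() < design.noise_row_prob:
                noise.append({"fish_id": r["fish_id"], "receiver_id": r["receiver_id"],
                              "hour": r["hour"] + pd.Timedelta(hours=-7),
                              "n_detections": int(rng.integers(1, 3))})
        for fish in enc.fish_ids:
            if np.isfinite(tag_life[fish]) and rng.random() < 20 * design.stale_row_prob:
                death = pd.Timestamp(cap_dates[fish]) + pd.Timedelta(days=tag_life[fish])
                noise.append({"fish_id": fish,
                              "receiver_id": tb.receiver_of[tb.pool[0]],
                              "hour": death + pd.Timedelta(days=5, hours=5),
                              "n_detections": 6})
    detections = pd.concat([detections, pd.DataFrame(noise)], ignore_index=True) \
        if noise else detections
    if len(detections):
        detections = detections.sort_values(["fish_id", "hour"]).reset_index(drop=True)

    bundle = {
        "detections": detections,
        "captures": pd.DataFrame(captures_rows),
        "recaptures": pd.DataFrame(recapture_rows,
                                   columns=["fish_id", "date", "tags_returned"]),
        "sections": sections,
        "receivers": receivers,
    }
    truth_out = {
        "encounters": enc,
        "z": z, "x": x,
        "status": pd.Series(status, name="status"),
        "planted_failures": failure_rows,
        "daily": daily_truth,
        "design": design,
    }
    return bundle, truth_out
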