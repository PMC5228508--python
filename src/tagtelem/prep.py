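"""Reduction of raw telemetry to seasonal encounter histories.

The pipeline mirrors how fixed-station acoustic data are cleaned for
mark-recapture analysis:

1. ``filter_hourly`` -- drop hours with two or fewer detections of a fish at
   a receiver (likely acoustic collisions/echoes) and any detections after
   the transmitter's expected tag life.
2. ``assign_daily_sections`` -- collapse hourly detections to at most one
   lake section per fish-day; multi-section days are resolved in favour of
   the section with the most detections, ties broken by fewest receivers,
   then smallest area (areas are unique, so the cascade always resolves).
3. ``classify_post_release`` -- acoustically tagged fish that 30 days after
   release are no longer detected, or that were only ever detected in a
   single section, are classified as post-release mortalities and excluded.
4. ``infer_spawning`` -- species-specific spawning rules: a Bull Trout
   spawns in a year if its detections show a hiatus of at least four weeks
   overlapping August--September (it left the main lake for a tributary),
   with detections both before and after; a Rainbow Trout spawns if it is
   detected at the outflow spawning grounds in April--May, or shows a
   three-week hiatus in April--May bracketed by detections in the uppermost
   lake sections.
5. ``build_encounter_data`` -- assemble the per-fish, per-season logical
   matrices (monitored / moved / reported / spawned) the survival model
   consumes, censoring each fish after the period of a reported recapture.
6. ``emigration_audit`` -- the last-detection table used to audit the
   no-emigration assumption.

Inputs are plain data frames; see ``io.py`` for the CSV schemas.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .encounters import EncounterData
from .growth import SPECIES_GROWTH, length_covariate, standardize_year, vb_length
from .periods import SPAWN_SEASON, PeriodCalendar

#: Detections per receiver-hour required to keep the record.
MIN_HOURLY_DETECTIONS = 3

#: Spawning hiatus thresholds (days of absence) and windows per species.
SPAWN_RULES = {
    "BullTrout": {"gap_days": 28, "window": ("08-01", "09-30")},
    "RainbowTrout": {"gap_days": 21, "window": ("04-01", "05-31")},
}


def _tag_death(captures: pd.DataFrame) -> pd.Series:
    """Transmitter expiry timestamp per fish (NaT for anchor-only fish)."""
    cap = captures.set_index("fish_id")
    release = pd.to_datetime(cap["capture_date"])
    life = pd.to_timedelta(cap["tag_life_days"], unit="D")
    return release + life


def filter_hourly(detections: pd.DataFrame, captures: pd.DataFrame) -> pd.DataFrame:
    """Remove sparse hours and post-tag-life detections.

    Keeps records with at least three detections of the fish at the
    receiver within the hour and with the hour inside the transmitter's
    expected life.  Unknown fish and detections before the fish's release
    are rejected outright, because they indicate corrupt inputs rather
    than acoustic noise.
    """
    det = detections.copy()
    det["hour"] = pd.to_datetime(det["hour"])
    known = set(captures["fish_id"])
    unknown = sorted(set(det["fish_id"]) - known)
    if unknown:
        raise ValueError(f"detections reference unknown fish: {unknown[:5]}")
    cap = captures.set_index("fish_id")
    release = pd.to_datetime(cap["capture_date"])
    rel = det["fish_id"].map(release)
    if (det["hour"] < rel).any():
        bad = det.loc[det["hour"] < rel, "fish_id"].unique()
        raise ValueError(f"detections before release for fish: {list(bad[:5])}")
    death = _tag_death(captures)
    dd = det["fish_id"].map(death)
    keep = (det["n_detections"] >= MIN_HOURLY_DETECTIONS) & det["hour"].le(dd).fillna(False)
    return det.loc[keep].reset_index(drop=True)


def assign_daily_sections(detections: pd.DataFrame, sections: pd.DataFrame,
                          receivers: pd.DataFrame) -> pd.DataFrame:
    """At most one section per fish-day.

    ``receivers`` maps receiver_id to section_id.  Daily multi-section
    conflicts are resolved by (1) most detections that day, (2) fewest
    receivers in the section, (3) smallest sectional area; identical
    triples raise, which the unique-areas invariant makes unreachable on
    valid metadata.
    """
    if sections["area_ha"].duplicated().any():
        raise ValueError("sectional areas must be unique")
    det = detections.copy()
    det["hour"] = pd.to_datetime(det["hour"])
    det["date"] = det["hour"].dt.normalize()
    rec_map = receivers.set_index("receiver_id")["section_id"]
    missing = sorted(set(det["receiver_id"]) - set(rec_map.index))
    if missing:
        raise ValueError(f"receivers without a section: {missing[:5]}")
    det["section_id"] = det["receiver_id"].map(rec_map)

    tally = (det.groupby(["fish_id", "date", "section_id"], as_index=False)
             ["n_detections"].sum())
    meta = sections.set_index("section_id")
    tally["n_receivers"] = tally["section_id"].map(meta["n_receivers"])
    tally["area_ha"] = tally["section_id"].map(meta["area_ha"])
    tally = tally.sort_values(
        ["fish_id", "date", "n_detections", "n_receivers", "area_ha"],
        ascending=[True, True, False, True, True],
    )
    # the unique-area invariant (checked above) guarantees the cascade
    # always resolves; duplicated triples would need duplicated areas
    winners = tally.groupby(["fish_id", "date"], as_index=False).head(1)
    return winners[["fish_id", "date", "section_id"]].reset_index(drop=True)


def classify_post_release(daily: pd.DataFrame, captures: pd.DataFrame,
                          window_days: int = 30) -> pd.Series:
    """Per-fish status: ``retained`` or ``post_release_mortality``.

    Applies only to acoustically tagged fish: a fish is a post-release
    mortality if it has no daily assignments after release + ``window_days``
    or if its entire record lies in a single section.  Anchor-only fish
    cannot be assessed acoustically and are always retained.
    """
    release = pd.to_datetime(captures.set_index("fish_id")["capture_date"])
    has_tag = captures.set_index("fish_id")["tag_life_days"].notna()
    by_fish = daily.groupby("fish_id") if len(daily) else None
    status = {}
    for fish in captures["fish_id"]:
        if not has_tag.get(fish, False):
            status[fish] = "retained"
            continue
        if by_fish is not None and fish in by_fish.groups:
            g = by_fish.get_group(fish)
            after = (pd.to_datetime(g["date"]) >
                     release[fish] + pd.Timedelta(days=window_days)).any()
            single = g["section_id"].nunique() <= 1
        else:
            after, single = False, True
        status[fish] = "retained" if (after and not single) else "post_release_mortality"
    return pd.Series(status, name="status")


def _gaps(dates: pd.Series):
    """Consecutive-assignment gaps: (gap_start, gap_end, before_idx, after_idx)
    where the gap is the open run of days with no assignments."""
    d = pd.to_datetime(dates).sort_values().reset_index(drop=True)
    out = []
    for j in range(len(d) - 1):
        run = (d[j + 1] - d[j]).days - 1
        if run > 0:
            out.append((d[j] + pd.Timedelta(days=1),
                        d[j + 1] - pd.Timedelta(days=1), j, run))
    return d, out


def _window_overlap(gap_start, gap_end, win_start, win_end) -> int:
    lo = max(gap_start, win_start)
    hi = min(gap_end, win_end)
    return max((hi - lo).days + 1, 0)


def infer_spawning(daily: pd.DataFrame, captures: pd.DataFrame,
                   calendar: PeriodCalendar, sections: pd.DataFrame,
                   strict_containment: bool = False) -> pd.DataFrame:
    """Spawn flag per (fish, year); NaN when the fish was not monitored for
    the species' whole spawning-season period that year.

    With ``strict_containment=False`` (default) a hiatus counts when its
    total length reaches the species threshold and it overlaps the spawning
    window at all; with ``True`` the overlap itself must reach the
    threshold.
    """
    cap = captures.set_index("fish_id")
    death = _tag_death(captures)
    meta = sections.set_index("section_id")
    rows = []
    daily = daily.copy()
    daily["date"] = pd.to_datetime(daily["date"])
    grouped = dict(tuple(daily.groupby("fish_id"))) if len(daily) else {}
    for fish in captures["fish_id"]:
        species = cap.loc[fish, "species"]
        rule = SPAWN_RULES[species]
        season = SPAWN_SEASON[species]
        release = pd.Timestamp(cap.loc[fish, "capture_date"])
        g = grouped.get(fish)
        for year in range(calendar.start_year, calendar.end_year + 1):
            p_start, p_end = calendar.season_window(year, season)
            monitored = (pd.notna(death.get(fish)) and release <= p_start
                         and death[fish] >= p_end)
            if not monitored:
                rows.append({"fish_id": fish, "year": year, "spawned": np.nan})
                continue
            w_start = pd.Timestamp(f"{year}-{rule['window'][0]}")
            w_end = pd.Timestamp(f"{year}-{rule['window'][1]}")
            flag = 0.0
            if g is not None and len(g):
                if species == "RainbowTrout":
                    outflow = meta.index[meta["trout_lake_outflow"].astype(bool)]
                    visits = g[(g["section_id"].isin(outflow)) &
                               g["date"].between(w_start, w_end)]
                    if len(visits):
                        flag = 1.0
                if flag == 0.0:
                    d, gaps = _gaps(g["date"])
                    for gs, ge, j, run in gaps:
                        overlap = _window_overlap(gs, ge, w_start, w_end)
                        long_enough = (overlap >= rule["gap_days"]
                                       if strict_containment
                                       else run >= rule["gap_days"] and overlap > 0)
                        if not long_enough:
                            continue
                        if species == "RainbowTrout":
                            upper = set(meta.index[meta["upper_north"].astype(bool)])
                            before = g.loc[g["date"] == d[j], "section_id"].iloc[0]
                            after = g.loc[g["date"] == d[j + 1], "section_id"].iloc[0]
                            if before not in upper or after not in upper:
                                continue
                        flag = 1.0
                        break
            rows.append({"fish_id": fish, "year": year, "spawned": flag})
    return pd.DataFrame(rows)


def build_encounter_data(daily: pd.DataFrame, captures: pd.DataFrame,
                         recaptures: pd.DataFrame, statuses: pd.Series,
                         spawn_flags: pd.DataFrame,
                         calendar: PeriodCalendar) -> EncounterData:
    """Assemble the seasonal encounter matrices the survival model uses.

    Post-release mortalities are dropped.  Per fish-period: ``T = 1`` iff
    the transmitter was active for the entire period, ``m = 1`` iff the
    fish was assigned to two or more distinct sections within the period,
    ``y = 1`` in the period of the reported recapture, after which the
    history is censored (observations in the recapture period itself are
    retained).  The spawning observation is the per-year spawn flag placed
    in the spawning-season period wherever ``T = 1``.
    """
    keep = [f for f in captures["fish_id"] if statuses.get(f) == "retained"]
    cap = captures.set_index("fish_id").loc[keep]
    n, P = len(keep), calendar.n_periods

    rec = recaptures.copy()
    rec_idx: set = set()
    if len(rec):
        rec["date"] = pd.to_datetime(rec["date"])
        rec = rec.set_index("fish_id")
        rec_idx = set(rec.index)
        for fish in rec.index:
            if fish in cap.index and rec.loc[fish, "date"] < pd.Timestamp(cap.loc[fish, "capture_date"]):
                raise ValueError(f"recapture before capture for fish {fish}")

    death = _tag_death(captures)
    daily = daily.copy()
    if len(daily):
        daily["date"] = pd.to_datetime(daily["date"])
        daily["period"] = calendar.period_of_many(daily["date"])
    grouped = dict(tuple(daily.groupby("fish_id"))) if len(daily) else {}
    sf = spawn_flags.set_index(["fish_id", "year"])["spawned"] if len(spawn_flags) else pd.Series(dtype=float)

    species = np.array([cap.loc[f, "species"] for f in keep], dtype=object)
    first = np.zeros(n, dtype=int)
    last = np.zeros(n, dtype=int)
    T = np.zeros((n, P), dtype=bool)
    S = np.zeros((n, P), dtype=bool)
    y = np.zeros((n, P), dtype=np.int8)
    m = np.zeros((n, P), dtype=np.int8)
    x_obs = np.full((n, P), np.nan)
    fl = np.full((n, P), np.nan)

    years = calendar.years()
    seasons = calendar.seasons()
    Y = standardize_year(years.astype(float))

    for i, fish in enumerate(keep):
        release = pd.Timestamp(cap.loc[fish, "capture_date"])
        first[i] = calendar.period_of(release)
        if fish in rec_idx:
            last[i] = calendar.period_of(rec.loc[fish, "date"])
            y[i, last[i]] = 1
        else:
            last[i] = P - 1
        sp = cap.loc[fish, "species"]
        S[i] = (seasons == SPAWN_SEASON[sp])
        dd = death.get(fish)
        if pd.notna(dd):
            # the release period is never fully monitored: the history is
            # conditioned on the release itself
            for t in range(first[i] + 1, last[i] + 1):
                T[i, t] = release <= calendar.start(t) and dd >= calendar.end(t)
        g = grouped.get(fish)
        if g is not None:
            per_t = g.groupby("period")["section_id"].nunique()
            for t, k in per_t.items():
                if first[i] <= t <= last[i] and T[i, t]:
                    m[i, t] = int(k >= 2)
        for t in range(first[i], last[i] + 1):
            if S[i, t] and T[i, t]:
                x_obs[i, t] = sf.get((fish, int(years[t])), np.nan)
        params = SPECIES_GROWTH[sp]
        ts = np.arange(first[i], last[i] + 1)
        fl[i, ts] = vb_length(float(cap.loc[fish, "fork_length_mm"]), first[i], ts, params)

    data = EncounterData(
        fish_ids=np.array(keep, dtype=object), species=species.astype(str),
        first=first, last=last, T=T, S=S, y=y, m=m, x_obs=x_obs,
        fork_length_mm=fl, L=length_covariate(fl), Y=Y, calendar=calendar,
    )
    data.validate()
    return data


def emigration_audit(daily: pd.DataFrame, captures: pd.DataFrame,
                     recaptures: pd.DataFrame, calendar: PeriodCalendar,
                     min_remaining_days: int = 120) -> pd.DataFrame:
    """Last-detection counts by section and season for possible emigrants.

    Includes acoustically tagged fish whose final daily assignment precedes
    the end of their transmitter life by at least ``min_remaining_days`` and
    that were never reported recaptured.  The row order follows the section
    ids; columns are the four seasons.
    """
    death = _tag_death(captures)
    recaptured = set(recaptures["fish_id"]) if len(recaptures) else set()
    daily = daily.copy()
    daily["date"] = pd.to_datetime(daily["date"])
    rows = []
    for fish, g in daily.groupby("fish_id"):
        dd = death.get(fish)
        if pd.isna(dd) or fish in recaptured:
            continue
        last_row = g.sort_values("date").iloc[-1]
        if (dd - last_row["date"]).days < min_remaining_days:
            continue
        t = calendar.period_of(last_row["date"])
        rows.append({"section_id": last_row["section_id"],
                     "season": calendar.season(t)})
    if not rows:
        return pd.DataFrame(columns=["winter", "spring", "summer", "autumn"])
    df = pd.DataFrame(rows)
    table = (df.groupby(["section_id", "season"]).size().unstack(fill_value=0)
             .reindex(columns=["winter", "spring", "summer", "autumn"], fill_value=0))
    table.columns.name = None
    return table.sort_index()
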