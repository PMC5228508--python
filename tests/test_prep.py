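import numpy as np
import pandas as pd
import pytest

from tagtelem import PeriodCalendar
from tagtelem import prep
from tagtelem.simulate import SimDesign, simulate_telemetry

from conftest import make_captures


def _det(fish, receiver, hour, n):
    return {"fish_id": fish, "receiver_id": receiver, "hour": hour,
            "n_detections": n}


class TestFilterHourly:
    def test_sparse_hours_dropped(self):
        caps = make_captures([{"fish_id": "F1", "capture_date": "2009-05-01"}])
        det = pd.DataFrame([_det("F1", "RS010", "2009-06-01T10:00", 2),
                            _det("F1", "RS010", "2009-06-01T11:00", 3)])
        out = prep.filter_hourly(det, caps)
        assert len(out) == 1 and out["n_detections"].iloc[0] == 3

    def test_empty_input(self):
        caps = make_captures([{"fish_id": "F1", "capture_date": "2009-05-01"}])
        det = pd.DataFrame(columns=["fish_id", "receiver_id", "hour", "n_detections"])
        assert len(prep.filter_hourly(det, caps)) == 0

    def test_fixture_counts(self):
        # ten records: three sparse, one past tag life -> six survive
        caps = make_captures([{"fish_id": "F1", "capture_date": "2009-05-01",
                               "tag_life_days": 100.0}])
        rows = [_det("F1", "R", f"2009-05-{d:02d}T10:00", 5) for d in range(2, 8)]
        rows += [_det("F1", "R", f"2009-06-{d:02d}T10:00", n)
                 for d, n in [(1, 1), (2, 2), (3, 2)]]
        rows += [_det("F1", "R", "2009-09-01T10:00", 8)]  # day 123 > tag life
        out = prep.filter_hourly(pd.DataFrame(rows), caps)
        assert len(out) == 6

    def test_unknown_fish_rejected(self):
        caps = make_captures([{"fish_id": "F1", "capture_date": "2009-05-01"}])
        det = pd.DataFrame([_det("GHOST", "R", "2009-06-01T10:00", 5)])
        with pytest.raises(ValueError, match="GHOST"):
            prep.filter_hourly(det, caps)

    def test_detection_before_release_rejected(self):
        caps = make_captures([{"fish_id": "F1", "capture_date": "2009-05-01"}])
        det = pd.DataFrame([_det("F1", "R", "2009-04-30T10:00", 5)])
        with pytest.raises(ValueError, match="before release"):
            prep.filter_hourly(det, caps)


class TestDailySections:
    def test_most_detections_wins(self, sections_fixture):
        sections, receivers = sections_fixture
        det = pd.DataFrame([_det("F1", "RS010", "2009-06-01T10:00", 5),
                            _det("F1", "RS070", "2009-06-01T11:00", 3)])
        out = prep.assign_daily_sections(det, sections, receivers)
        assert len(out) == 1 and out["section_id"].iloc[0] == "S01"

    def test_single_section_day(self, sections_fixture):
        sections, receivers = sections_fixture
        det = pd.DataFrame([_det("F1", "RS070", "2009-06-01T10:00", 4)])
        out = prep.assign_daily_sections(det, sections, receivers)
        assert out["section_id"].iloc[0] == "S07"

    def test_tie_broken_by_fewer_receivers(self, sections_fixture):
        sections, receivers = sections_fixture
        # S01 has 2 receivers, S07 has 1: a 4 vs 4 tie goes to S07
        det = pd.DataFrame([_det("F1", "RS010", "2009-06-01T10:00", 4),
                            _det("F1", "RS070", "2009-06-01T11:00", 4)])
        out = prep.assign_daily_sections(det, sections, receivers)
        assert out["section_id"].iloc[0] == "S07"

    def test_final_tie_broken_by_smaller_area(self, sections_fixture):
        sections, receivers = sections_fixture
        # S07 (900 ha) and S02 (300 ha) both have one receiver
        det = pd.DataFrame([_det("F1", "RS070", "2009-06-01T10:00", 4),
                            _det("F1", "RS020", "2009-06-01T11:00", 4)])
        out = prep.assign_daily_sections(det, sections, receivers)
        assert out["section_id"].iloc[0] == "S02"

    def test_duplicate_areas_rejected(self, sections_fixture):
        sections, receivers = sections_fixture
        bad = sections.copy()
        bad.loc[:, "area_ha"] = 500.0
        det = pd.DataFrame([_det("F1", "RS010", "2009-06-01T10:00", 4)])
        with pytest.raises(ValueError, match="unique"):
            prep.assign_daily_sections(det, bad, receivers)

    def test_one_assignment_per_fish_day(self, sections_fixture):
        sections, receivers = sections_fixture
        det = pd.DataFrame([
            _det("F1", "RS010", "2009-06-01T10:00", 5),
            _det("F1", "RS011", "2009-06-01T12:00", 6),
            _det("F1", "RS070", "2009-06-02T10:00", 3),
            _det("F2", "RS070", "2009-06-01T10:00", 3),
        ])
        out = prep.assign_daily_sections(det, sections, receivers)
        assert len(out) == 3
        assert not out.duplicated(["fish_id", "date"]).any()


def _daily(fish, dates, sections):
    return pd.DataFrame({"fish_id": fish, "date": pd.to_datetime(dates),
                         "section_id": sections})


class TestPostRelease:
    def test_multi_section_long_track_retained(self):
        caps = make_captures([{"fish_id": "F1", "capture_date": "2009-05-01"}])
        daily = _daily("F1", ["2009-05-10", "2009-06-20", "2009-07-30"],
                       ["S01", "S07", "S02"])
        status = prep.classify_post_release(daily, caps)
        assert status["F1"] == "retained"

    def test_single_section_flagged(self):
        caps = make_captures([{"fish_id": "F1", "capture_date": "2009-05-01"}])
        daily = _daily("F1", ["2009-05-10", "2009-06-20", "2009-08-30"],
                       ["S01", "S01", "S01"])
        assert prep.classify_post_release(daily, caps)["F1"] == "post_release_mortality"

    def test_silent_after_window_flagged(self):
        caps = make_captures([{"fish_id": "F1", "capture_date": "2009-05-01"}])
        daily = _daily("F1", ["2009-05-10", "2009-05-20"], ["S01", "S07"])
        assert prep.classify_post_release(daily, caps)["F1"] == "post_release_mortality"

    def test_anchor_only_always_retained(self):
        caps = make_captures([{"fish_id": "F1", "capture_date": "2012-05-01",
                               "tag_life_days": np.nan}])
        daily = _daily("F9", ["2012-06-01"], ["S01"])  # no detections of F1
        assert prep.classify_post_release(daily, caps)["F1"] == "retained"


class TestSpawnInference:
    def _caps(self, species="BullTrout"):
        return make_captures([{"fish_id": "F1", "capture_date": "2008-11-01",
                               "species": species, "tag_life_days": 2000.0}])

    def test_continuous_summer_detections_no_spawn(self, sections_fixture, calendar):
        sections, _ = sections_fixture
        dates = pd.date_range("2009-06-01", "2009-10-31", freq="3D")
        daily = _daily("F1", dates, ["S01"] * len(dates))
        flags = prep.infer_spawning(daily, self._caps(), calendar, sections)
        row = flags[(flags.fish_id == "F1") & (flags.year == 2009)]
        assert row["spawned"].iloc[0] == 0.0

    def test_planted_august_hiatus_is_spawn(self, sections_fixture, calendar):
        sections, _ = sections_fixture
        dates = list(pd.date_range("2009-06-01", "2009-07-28", freq="3D"))
        dates += list(pd.date_range("2009-09-02", "2009-10-31", freq="3D"))
        daily = _daily("F1", dates, ["S01"] * len(dates))
        flags = prep.infer_spawning(daily, self._caps(), calendar, sections)
        row = flags[(flags.fish_id == "F1") & (flags.year == 2009)]
        assert row["spawned"].iloc[0] == 1.0

    def test_rainbow_outflow_visit_is_spawn(self, sections_fixture, calendar):
        sections, _ = sections_fixture
        daily = _daily("F1", ["2009-03-20", "2009-05-03", "2009-06-25"],
                       ["S01", "S02", "S01"])
        flags = prep.infer_spawning(daily, self._caps("RainbowTrout"),
                                    calendar, sections)
        row = flags[(flags.fish_id == "F1") & (flags.year == 2009)]
        assert row["spawned"].iloc[0] == 1.0

    def test_rainbow_hiatus_needs_upper_lake_brackets(self, sections_fixture, calendar):
        sections, _ = sections_fixture
        # 40-day April-May gap, but flanked in S01: not a spawning migration
        daily = _daily("F1", ["2009-04-02", "2009-05-20", "2009-06-25"],
                       ["S01", "S01", "S01"])
        flags = prep.infer_spawning(daily, self._caps("RainbowTrout"),
                                    calendar, sections)
        assert flags[(flags.fish_id == "F1") & (flags.year == 2009)]["spawned"].iloc[0] == 0.0
        daily2 = _daily("F1", ["2009-04-02", "2009-05-20", "2009-06-25"],
                        ["S07", "S08", "S01"])
        flags2 = prep.infer_spawning(daily2, self._caps("RainbowTrout"),
                                     calendar, sections)
        assert flags2[(flags2.fish_id == "F1") & (flags2.year == 2009)]["spawned"].iloc[0] == 1.0

    def test_unmonitored_year_missing(self, sections_fixture, calendar):
        sections, _ = sections_fixture
        caps = make_captures([{"fish_id": "F1", "capture_date": "2009-08-15",
                               "tag_life_days": 455.0}])
        daily = _daily("F1", ["2009-09-01"], ["S01"])
        flags = prep.infer_spawning(daily, caps, calendar, sections)
        by_year = flags.set_index("year")["spawned"]
        # released mid-season 2009 and tag dead by summer 2011
        assert np.isnan(by_year[2009]) and np.isnan(by_year[2011])
        assert by_year[2010] in (0.0, 1.0)

    def test_strict_containment_switch(self, sections_fixture, calendar):
        sections, _ = sections_fixture
        # 30-day gap but only 10 days overlap August: loose rule spawns,
        # strict rule does not
        dates = [pd.Timestamp("2009-07-01"), pd.Timestamp("2009-07-10")]
        dates += list(pd.date_range("2009-08-11", "2009-10-05", freq="3D"))
        daily = _daily("F1", dates, ["S01"] * len(dates))
        loose = prep.infer_spawning(daily, self._caps(), calendar, sections)
        strict = prep.infer_spawning(daily, self._caps(), calendar, sections,
                                     strict_containment=True)
        get = lambda f: f[(f.fish_id == "F1") & (f.year == 2009)]["spawned"].iloc[0]
        assert get(loose) == 1.0 and get(strict) == 0.0


class TestBuildEncounters:
    def _inputs(self, calendar):
        caps = make_captures([{"fish_id": "F1", "capture_date": "2008-11-01",
                               "tag_life_days": 2000.0}])
        dates = pd.date_range("2008-11-02", "2010-02-20", freq="3D")
        secs = ["S01" if i % 11 else "S07" for i in range(len(dates))]
        daily = _daily("F1", dates, secs)
        rec = pd.DataFrame([{"fish_id": "F1", "date": "2010-02-25",
                             "tags_returned": "100;10"}])
        status = pd.Series({"F1": "retained"})
        flags = pd.DataFrame(columns=["fish_id", "year", "spawned"])
        return daily, caps, rec, status, flags

    def test_censored_after_recapture_period(self, calendar):
        daily, caps, rec, status, flags = self._inputs(calendar)
        enc = prep.build_encounter_data(daily, caps, rec, status, flags, calendar)
        assert enc.first[0] == calendar.period_of("2008-11-01")
        assert enc.last[0] == calendar.period_of("2010-02-25")
        assert enc.y[0, enc.last[0]] == 1
        df = enc.to_long()
        assert df["period"].max() == enc.last[0]

    def test_single_section_period_not_moved(self, calendar):
        caps = make_captures([{"fish_id": "F1", "capture_date": "2008-11-01",
                               "tag_life_days": 2000.0}])
        dates = pd.date_range("2008-11-02", "2009-12-20", freq="3D")
        daily = _daily("F1", dates, ["S01"] * len(dates))
        enc = prep.build_encounter_data(
            daily, caps, pd.DataFrame(columns=["fish_id", "date"]),
            pd.Series({"F1": "retained"}),
            pd.DataFrame(columns=["fish_id", "year", "spawned"]), calendar)
        t = calendar.period_of("2009-05-01")
        assert enc.T[0, t] and enc.m[0, t] == 0

    def test_recapture_before_capture_rejected(self, calendar):
        daily, caps, rec, status, flags = self._inputs(calendar)
        rec.loc[0, "date"] = "2008-01-01"
        with pytest.raises(ValueError, match="before capture"):
            prep.build_encounter_data(daily, caps, rec, status, flags, calendar)

    def test_release_period_never_monitored(self, calendar):
        daily, caps, rec, status, flags = self._inputs(calendar)
        enc = prep.build_encounter_data(daily, caps, rec, status, flags, calendar)
        assert not enc.T[0, enc.first[0]]


class TestEmigrationAudit:
    def _caps(self, ids):
        return make_captures([{"fish_id": f, "capture_date": "2009-05-01",
                               "tag_life_days": 400.0} for f in ids])

    def test_recaptured_fish_excluded(self, calendar):
        caps = self._caps(["F1"])
        daily = _daily("F1", ["2009-06-01"], ["S07"])
        rec = pd.DataFrame([{"fish_id": "F1", "date": "2009-08-01"}])
        table = prep.emigration_audit(daily, caps, rec, calendar)
        assert len(table) == 0

    def test_short_remaining_tag_life_excluded(self, calendar):
        caps = self._caps(["F1"])
        # last detected 10 days before transmitter death
        daily = _daily("F1", ["2010-05-26"], ["S07"])
        table = prep.emigration_audit(daily, caps,
                                      pd.DataFrame(columns=["fish_id", "date"]),
                                      calendar)
        assert len(table) == 0

    def test_planted_disappearances_counted(self, calendar):
        ids = [f"F{i}" for i in range(5)]
        caps = self._caps(ids + ["F9"])
        rows = [_r for _r in []]
        frames = [_daily(f, ["2009-06-10"], ["S07"]) for f in ids]
        frames.append(_daily("F9", ["2010-05-26"], ["S01"]))  # too late
        daily = pd.concat(frames, ignore_index=True)
        table = prep.emigration_audit(daily, caps,
                                      pd.DataFrame(columns=["fish_id", "date"]),
                                      calendar)
        assert table.to_numpy().sum() == 5
        assert table.loc["S07", "spring"] == 5


class TestGeneratorRoundTrip:
    def test_full_pipeline_recovers_truth(self, telemetry_bundle):
        bundle, truth = telemetry_bundle
        cal = truth["design"].calendar
        det = prep.filter_hourly(bundle["detections"], bundle["captures"])
        daily = prep.assign_daily_sections(det, bundle["sections"],
                                           bundle["receivers"])
        # the winning assignments equal the noise-free daily track
        dt = truth["daily"].copy()
        dt["date"] = pd.to_datetime(dt["date"])
        merged = daily.merge(dt, on=["fish_id", "date"], how="outer",
                             suffixes=("_got", "_true"), indicator=True)
        assert (merged["_merge"] == "both").all()
        assert (merged["section_id_got"] == merged["section_id_true"]).all()

        status = prep.classify_post_release(daily, bundle["captures"])
        expected = truth["status"]
        assert status.reindex(expected.index).equals(expected)

        flags = prep.infer_spawning(daily, bundle["captures"], cal,
                                    bundle["sections"])
        enc = prep.build_encounter_data(daily, bundle["captures"],
                                        bundle["recaptures"], status, flags, cal)
        te = truth["encounters"]
        assert set(enc.fish_ids) == set(te.fish_ids)
        sel = np.array([list(te.fish_ids).index(f) for f in enc.fish_ids])
        v = enc.valid_mask()
        assert (enc.first == te.first[sel]).all()
        assert (enc.last == te.last[sel]).all()
        for name in ("T", "y", "m", "S"):
            assert (getattr(enc, name)[v] == getattr(te, name)[sel][v]).all(), name
        a, b = enc.x_obs, te.x_obs[sel]
        assert ((np.isnan(a) == np.isnan(b)) | ~v).all()
        ok = ~np.isnan(a) & v
        assert (a[ok] == b[ok]).all()
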