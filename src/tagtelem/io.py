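"""CSV interchange for every pipeline stage.

Schemas (all plain CSV):

* ``detections.csv``  -- fish_id, receiver_id, hour (ISO 8601), n_detections
* ``captures.csv``    -- fish_id, species, capture_date, fork_length_mm,
  tag_life_days (empty for anchor-tag-only fish), reward1, reward2,
  release_section
* ``recaptures.csv``  -- fish_id, date, tags_returned
* ``sections.csv``    -- section_id, n_receivers, area_ha + zone flags
* ``receivers.csv``   -- receiver_id, section_id
* ``encounters.csv``  -- long-format encounter histories (one row per
  modelled fish-period)
* ``samples.csv``     -- one row per retained draw with chain/draw indices,
  with the run configuration echoed into a YAML sidecar
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .encounters import EncounterData
from .likelihood import PriorConfig
from .model import MCMCConfig, PosteriorSamples
from .periods import PeriodCalendar

BUNDLE_FILES = ("detections", "captures", "recaptures", "sections", "receivers")


def write_bundle(bundle: dict, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name in BUNDLE_FILES:
        bundle[name].to_csv(outdir / f"{name}.csv", index=False)


def read_bundle(indir) -> dict:
    indir = Path(indir)
    out = {}
    for name in BUNDLE_FILES:
        path = indir / f"{name}.csv"
        if not path.exists():
            raise FileNotFoundError(f"missing {path.name} in {indir}")
        out[name] = pd.read_csv(path)
    _require(out["detections"], "detections.csv",
             ["fish_id", "receiver_id", "hour", "n_detections"])
    _require(out["captures"], "captures.csv",
             ["fish_id", "species", "capture_date", "fork_length_mm",
              "tag_life_days"])
    _require(out["recaptures"], "recaptures.csv", ["fish_id", "date"])
    _require(out["sections"], "sections.csv",
             ["section_id", "n_receivers", "area_ha"])
    _require(out["receivers"], "receivers.csv", ["receiver_id", "section_id"])
    return out


def _require(df: pd.DataFrame, name: str, columns) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{name}: missing required columns {missing}")


def write_encounters(data: EncounterData, path) -> None:
    df = data.to_long()
    df.attrs["start_year"] = data.calendar.start_year
    df.to_csv(path, index=False)


def read_encounters(path, calendar: PeriodCalendar) -> EncounterData:
    df = pd.read_csv(path)
    _require(df, Path(path).name, ["fish_id", "species", "period", "T", "m",
                                   "y", "x_obs", "S", "fork_length_mm", "Y"])
    return EncounterData.from_long(df, calendar)


def write_samples(samples: PosteriorSamples, path) -> None:
    path = Path(path)
    samples.to_dataframe().to_csv(path, index=False)
    meta = {
        "priors": {"slab_sd": samples.priors.slab_sd,
                   "spike_sd": samples.priors.spike_sd,
                   "indicator_prob": samples.priors.indicator_prob},
        "mcmc": {"n_chains": samples.mcmc.n_chains,
                 "n_iterations": samples.mcmc.n_iterations,
                 "n_retain_total": samples.mcmc.n_retain_total,
                 "rhat_threshold": samples.mcmc.rhat_threshold,
                 "seed": samples.mcmc.seed},
    }
    path.with_suffix(".meta.yml").write_text(yaml.safe_dump(meta))


def read_samples(path) -> PosteriorSamples:
    path = Path(path)
    df = pd.read_csv(path)
    priors, mcmc = None, None
    meta_path = path.with_suffix(".meta.yml")
    if meta_path.exists():
        meta = yaml.safe_load(meta_path.read_text())
        priors = PriorConfig(**meta["priors"])
        mcmc = MCMCConfig(**meta["mcmc"])
    return PosteriorSamples.from_dataframe(df, priors=priors, mcmc=mcmc)


def write_json(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
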