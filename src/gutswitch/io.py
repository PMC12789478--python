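"""File-format plumbing: tidy time-series CSV, schedule files, manifests.

Tidy time-series files carry the header ``time_h, replicate, variable,
value, unit``; schedules and run manifests are YAML.
"""

from __future__ import annotations

import datetime
import hashlib
from dataclasses import dataclass, field

import pandas as pd
import yaml

from .calibration import ObservationDataset
from .dynamics import MixEvent, PerturbationSchedule, Segment

__all__ = [
    "read_timeseries",
    "write_timeseries",
    "schedule_to_config",
    "schedule_from_config",
    "read_schedule",
    "write_schedule",
    "RunManifest",
]


def write_timeseries(dataset: ObservationDataset, path):
    """Lossless tidy-CSV export of an observation dataset."""
    dataset.records.to_csv(path, index=False,
                           columns=ObservationDataset.REQUIRED)
    return path


def read_timeseries(path, known_variables=None) -> ObservationDataset:
    """Read a tidy time-series CSV, validating schema and values.

    Rejects rows with negative metabolite (mM) values and unknown
    variables (when ``known_variables`` is given), citing the offending
    row number; a missing ``unit`` column is a hard error.
    """
    df = pd.read_csv(path)
    missing = [c for c in ObservationDataset.REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    bad = df[(df["unit"] == "mM") & (df["value"] < 0)]
    if len(bad):
        raise ValueError(f"{path}: negative metabolite value at row "
                         f"{int(bad.index[0]) + 2} (variable "
                         f"{bad.iloc[0]['variable']!r})")
    if known_variables is not None:
        unknown = df[~df["variable"].isin(set(known_variables))]
        if len(unknown):
            raise ValueError(f"{path}: unknown variable "
                             f"{unknown.iloc[0]['variable']!r} at row "
                             f"{int(unknown.index[0]) + 2}")
    return ObservationDataset(records=df)


# ---------------------------------------------------------------------------
# schedules
# ---------------------------------------------------------------------------

def schedule_to_config(schedule: PerturbationSchedule) -> dict:
    segs = []
    for s in schedule.segments:
        seg = dict(t_start=s.t_start, t_end=s.t_end)
        for k in ("dilution", "feed", "feed_ph", "ph_mode", "ph_fixed"):
            v = getattr(s, k)
            if v is not None:
                seg[k] = v
        segs.append(seg)
    return dict(segments=segs,
                events=[dict(time=e.time, fraction=e.fraction)
                        for e in schedule.events])


def schedule_from_config(cfg: dict) -> PerturbationSchedule:
    return PerturbationSchedule(
        segments=[Segment(**s) for s in cfg.get("segments", [])],
        events=[MixEvent(**e) for e in cfg.get("events", [])])


def write_schedule(schedule: PerturbationSchedule, path):
    with open(path, "w") as fh:
        yaml.safe_dump(schedule_to_config(schedule), fh, sort_keys=True)
    return path


def read_schedule(path) -> PerturbationSchedule:
    with open(path) as fh:
        return schedule_from_config(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# run manifests
# ---------------------------------------------------------------------------

@dataclass
class RunManifest:
    """Everything needed to re-run a CLI invocation bit-for-bit."""

    command: str
    arguments: dict = field(default_factory=dict)
    model_hash: str = ""
    config_hash: str = ""
    seed: int = 0
    outputs: list = field(default_factory=list)
    timestamp: str = ""

    def __post_init__(self):
        if not self.timestamp:
            self.timestamp = datetime.datetime.now(
                datetime.timezone.utc).isoformat(timespec="seconds")

    @staticmethod
    def hash_file(path):
        with open(path, "rb") as fh:
            return hashlib.sha256(fh.read()).hexdigest()[:12]

    def write(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=True)
        return path
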