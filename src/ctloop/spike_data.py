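"""Domain types for extracellular spike data and the on-disk TSV exchange format.

A :class:`Recording` bundles spike-sorted units (spike times plus waveform
metadata) with a trial/event table describing the optogenetic (LED) and
whisker-stimulus structure of the session.  Three tab-separated tables make up
the exchange layout of a recording directory::

    spikes.tsv   unit_id, time_s
    units.tsv    unit_id, region, tpt_ms, layer [, extra columns...]
    trials.tsv   trial_id, led_intensity, led_profile, led_onset,
                 stim_times, whisker_moving [, extra columns...]

Times are seconds in recording time, written with microsecond precision.
All analysis windows in this package are half-open ``[start, end)``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SpikeTrain",
    "UnitMeta",
    "AlignedRaster",
    "Recording",
    "ValidationError",
    "read_recording",
    "write_recording",
    "align_to_events",
]

REGIONS = {"S1", "VPm", "TRN"}
LED_PROFILES = {"none", "ramp_hold", "noise10", "noise100", "noise500", "pulse5ms"}

#: Known waveform/classification labels a unit may carry.
LABELS = {"RS", "FS", "L6CT", "stimulus_responsive", "VPm_verified", "TRN_verified"}


class ValidationError(ValueError):
    """Raised when on-disk or in-memory spike data violates an invariant."""


@dataclass(frozen=True)
class SpikeTrain:
    """Sorted spike times (seconds) of one unit over an epoch of known duration.

    Invariants: times strictly increasing, all within ``[0, duration]``.
    """

    times: np.ndarray
    duration: float

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if t.ndim != 1:
            raise ValidationError("spike times must be a 1-d array")
        if self.duration <= 0:
            raise ValidationError("duration must be positive")
        if t.size:
            if not np.all(np.diff(t) > 0):
                raise ValidationError("spike times must be strictly increasing")
            if t[0] < 0 or t[-1] > self.duration:
                raise ValidationError(
                    f"spike times outside [0, {self.duration}]: "
                    f"range [{t[0]}, {t[-1]}]"
                )

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)

    @property
    def rate(self) -> float:
        """Mean firing rate in spikes/s."""
        return self.n_spikes / self.duration

    def slice(self, start: float, end: float) -> "SpikeTrain":
        """Spikes in ``[start, end)`` re-expressed relative to ``start``."""
        i, j = np.searchsorted(self.times, [start, end], side="left")
        return SpikeTrain(self.times[i:j] - start, end - start)


@dataclass
class UnitMeta:
    """Metadata of one spike-sorted unit.

    tpt_ms is the waveform trough-to-peak time in milliseconds (None when the
    mean waveform was not exported).  ``labels`` is only written by the
    classification procedures.
    """

    unit_id: str
    region: str
    tpt_ms: float | None = None
    layer: str | None = None
    labels: set = field(default_factory=set)

    def __post_init__(self):
        if self.region not in REGIONS:
            raise ValidationError(
                f"unit {self.unit_id}: unknown region {self.region!r}"
            )
        if self.tpt_ms is not None and not self.tpt_ms > 0:
            raise ValidationError(f"unit {self.unit_id}: tpt_ms must be > 0")


@dataclass
class AlignedRaster:
    """Per-trial spike times relative to an alignment event.

    ``trials`` holds one array per retained trial; every relative time lies in
    ``[window_start, window_end)``.
    """

    unit_id: str
    event_label: str
    window_start: float
    window_end: float
    trials: list

    def __post_init__(self):
        self.trials = [np.asarray(t, dtype=float) for t in self.trials]
        for k, t in enumerate(self.trials):
            if t.size and (t.min() < self.window_start or t.max() >= self.window_end):
                raise ValidationError(
                    f"raster trial {k}: spike outside "
                    f"[{self.window_start}, {self.window_end})"
                )

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def pooled(self) -> np.ndarray:
        """All relative spike times pooled over trials (sorted)."""
        if not self.trials:
            return np.empty(0)
        return np.sort(np.concatenate(self.trials))


@dataclass
class Recording:
    """A session: spike trains per unit, unit metadata, and a trial table.

    ``trials`` is a DataFrame with at least the columns trial_id,
    led_intensity (mW/mm^2), led_profile, led_onset (s; NaN when profile is
    'none'), stim_times (list of seconds, possibly empty), whisker_moving
    (bool).  Extra columns are preserved on round-trip.
    """

    units: dict  # unit_id -> UnitMeta
    spikes: dict  # unit_id -> SpikeTrain
    trials: pd.DataFrame
    duration: float

    def __post_init__(self):
        if set(self.units) != set(self.spikes):
            raise ValidationError("units and spikes must cover the same unit_ids")
        self.validate()

    def validate(self):
        for uid, st in self.spikes.items():
            if st.duration != self.duration:
                raise ValidationError(
                    f"unit {uid}: train duration {st.duration} != "
                    f"recording duration {self.duration}"
                )
        tr = self.trials
        for col in ("trial_id", "led_intensity", "led_profile", "led_onset",
                    "stim_times", "whisker_moving"):
            if col not in tr.columns:
                raise ValidationError(f"trials table missing column {col!r}")
        for _, row in tr.iterrows():
            prof = row["led_profile"]
            if prof not in LED_PROFILES:
                raise ValidationError(
                    f"trial {row['trial_id']}: unknown led_profile {prof!r}"
                )
            has_onset = not pd.isna(row["led_onset"])
            if (prof != "none") != has_onset:
                raise ValidationError(
                    f"trial {row['trial_id']}: led_onset must be present iff "
                    f"led_profile != 'none'"
                )
            stims = row["stim_times"]
            if has_onset and len(stims) and prof != "pulse5ms":
                # Punctate stimulus embedded in LED trials sits 750 ms after onset.
                off = np.asarray(stims) - row["led_onset"]
                if np.any(np.abs(off - 0.750) > 1e-3):
                    raise ValidationError(
                        f"trial {row['trial_id']}: stim_times must equal "
                        f"led_onset + 0.750 s (tol 1 ms), got offsets {off}"
                    )

    def units_in(self, region: str) -> list:
        return [u for u, m in self.units.items() if m.region == region]


# ---------------------------------------------------------------------------
# TSV exchange format
# ---------------------------------------------------------------------------

_TIME_FMT = "%.6f"  # microsecond precision


def _fmt_stims(stims) -> str:
    return ",".join(_TIME_FMT % s for s in stims)


def _parse_stims(s) -> list:
    if s is None or (isinstance(s, float) and np.isnan(s)) or s == "":
        return []
    return [float(x) for x in str(s).split(",")]


def write_recording(rec: Recording, directory: str | os.PathLike) -> None:
    """Write ``rec`` to ``directory`` as spikes.tsv / units.tsv / trials.tsv.

    Numeric times are serialized with 6 decimal places; a reread yields an
    equal Recording.
    """
    os.makedirs(directory, exist_ok=True)
    d = os.fspath(directory)

    rows = []
    for uid in rec.units:
        for t in rec.spikes[uid].times:
            rows.append((uid, _TIME_FMT % t))
    pd.DataFrame(rows, columns=["unit_id", "time_s"]).to_csv(
        os.path.join(d, "spikes.tsv"), sep="\t", index=False
    )

    urows = []
    for uid, m in rec.units.items():
        urows.append({
            "unit_id": uid,
            "region": m.region,
            "tpt_ms": "" if m.tpt_ms is None else repr(float(m.tpt_ms)),
            "layer": "" if m.layer is None else m.layer,
            "labels": ";".join(sorted(m.labels)),
        })
    pd.DataFrame(
        urows, columns=["unit_id", "region", "tpt_ms", "layer", "labels"]
    ).to_csv(os.path.join(d, "units.tsv"), sep="\t", index=False)

    tr = rec.trials.copy()
    tr["stim_times"] = tr["stim_times"].map(_fmt_stims)
    tr["led_onset"] = tr["led_onset"].map(
        lambda x: "" if pd.isna(x) else _TIME_FMT % x
    )
    tr["whisker_moving"] = tr["whisker_moving"].map(lambda b: str(bool(b)))
    tr.to_csv(os.path.join(d, "trials.tsv"), sep="\t", index=False)

    with open(os.path.join(d, "recording.tsv"), "w") as fh:
        fh.write("key\tvalue\nduration_s\t" + _TIME_FMT % rec.duration + "\n")


def read_recording(directory: str | os.PathLike) -> Recording:
    """Read a recording directory written by :func:`write_recording`.

    Raises FileNotFoundError for a missing table and :class:`ValidationError`
    (naming the unit or trial) for malformed content.
    """
    d = os.fspath(directory)
    for fn in ("spikes.tsv", "units.tsv", "trials.tsv", "recording.tsv"):
        if not os.path.exists(os.path.join(d, fn)):
            raise FileNotFoundError(f"recording table missing: {os.path.join(d, fn)}")

    meta = pd.read_csv(os.path.join(d, "recording.tsv"), sep="\t")
    duration = float(meta.set_index("key").loc["duration_s", "value"])

    units_df = pd.read_csv(
        os.path.join(d, "units.tsv"), sep="\t",
        dtype={"unit_id": str, "layer": str}, keep_default_na=False,
        na_values=[""],
    )
    units: dict = {}
    for i, row in units_df.iterrows():
        try:
            labels = row.get("labels")
            labels = set() if pd.isna(labels) or labels == "" else set(
                str(labels).split(";")
            )
            units[row["unit_id"]] = UnitMeta(
                unit_id=row["unit_id"],
                region=row["region"],
                tpt_ms=None if pd.isna(row["tpt_ms"]) else float(row["tpt_ms"]),
                layer=None if pd.isna(row.get("layer")) else str(row["layer"]),
                labels=labels,
            )
        except (ValidationError, ValueError) as e:
            raise ValidationError(f"units.tsv line {i + 2}: {e}") from e

    spikes_df = pd.read_csv(
        os.path.join(d, "spikes.tsv"), sep="\t", dtype={"unit_id": str}
    )
    spikes: dict = {}
    for uid in units:
        t = spikes_df.loc[spikes_df["unit_id"] == uid, "time_s"].to_numpy(float)
        if t.size and not np.all(np.diff(t) > 0):
            raise ValidationError(
                f"spikes.tsv: non-monotonic or duplicate spike times for unit {uid}"
            )
        try:
            spikes[uid] = SpikeTrain(t, duration)
        except ValidationError as e:
            raise ValidationError(f"spikes.tsv unit {uid}: {e}") from e
    stray = set(spikes_df["unit_id"]) - set(units)
    if stray:
        raise ValidationError(f"spikes.tsv references unknown units: {sorted(stray)}")

    trials = pd.read_csv(
        os.path.join(d, "trials.tsv"), sep="\t",
        dtype={"led_profile": str}, keep_default_na=False, na_values=[""],
    )
    trials["stim_times"] = trials["stim_times"].map(_parse_stims) \
        if "stim_times" in trials else [[] for _ in range(len(trials))]
    if "led_onset" in trials:
        trials["led_onset"] = pd.to_numeric(trials["led_onset"], errors="coerce")
    trials["whisker_moving"] = trials["whisker_moving"].map(
        lambda s: str(s).strip().lower() in ("true", "1")
    )
    return Recording(units=units, spikes=spikes, trials=trials, duration=duration)


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

def align_to_events(
    train: SpikeTrain,
    event_times,
    window_start: float,
    window_end: float,
    unit_id: str = "",
    event_label: str = "event",
) -> AlignedRaster:
    """Extract per-event spike times relative to each event.

    Trial ``k`` contains exactly the spikes ``t`` with
    ``event_k + window_start <= t < event_k + window_end`` (half-open on the
    right), expressed relative to ``event_k``.  An empty event list yields an
    empty raster.
    """
    if not window_start < window_end:
        raise ValueError("window_start must be < window_end")
    ev = np.asarray(event_times, dtype=float)
    out = []
    for e in ev:
        i = np.searchsorted(train.times, e + window_start, side="left")
        j = np.searchsorted(train.times, e + window_end, side="left")
        out.append(train.times[i:j] - e)
    return AlignedRaster(
        unit_id=unit_id, event_label=event_label,
        window_start=window_start, window_end=window_end, trials=out,
    )
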