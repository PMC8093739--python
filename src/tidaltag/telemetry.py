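"""Acoustic-telemetry detection QC, resident events, and residency statistics.

A *detection* is one decoded tag transmission at one receiver.  The module
covers the standard passive-acoustic-telemetry workflow for a receiver array
around a reef aggregation site:

* reading and de-duplicating raw detection logs,
* screening suspected false detections (tag-ID collisions / noise) with the
  short-vs-long inter-detection-interval ratio method,
* segmenting detections into *resident events* (contiguous occupancy of one
  receiver's range), and
* residency indices and cohort summary statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date

import numpy as np
import pandas as pd

from ._util import round_half_up

logger = logging.getLogger(__name__)

#: default thresholds of the false-detection interval-ratio screen
SHORT_INTERVAL = pd.Timedelta(minutes=30)
LONG_INTERVAL = pd.Timedelta(hours=12)

#: resident-event rules: detections at the same receiver within this window
#: chain into one event; this many detections at a different receiver close it
EVENT_TIMEOUT = pd.Timedelta(minutes=60)
SWITCH_COUNT = 2

#: diel convention: hours counted as day (06:00-18:59) and night (19:00-05:59)
DAY_HOURS = frozenset(range(6, 19))
NIGHT_HOURS = frozenset(list(range(19, 24)) + list(range(0, 6)))


@dataclass(frozen=True)
class ResidentEvent:
    """A contiguous occupancy interval of one tag at one receiver."""

    tag_id: str
    receiver_id: str
    start: pd.Timestamp
    end: pd.Timestamp
    n_detections: int

    @property
    def duration(self) -> float:
        """Event duration in minutes."""
        return (self.end - self.start).total_seconds() / 60.0

    def __post_init__(self):
        if self.n_detections < 2:
            raise ValueError("a resident event needs >= 2 detections")
        if self.end < self.start:
            raise ValueError("event end precedes start")


def read_detections(
    path,
    *,
    timestamp_col: str = "timestamp",
    receiver_col: str = "receiver_id",
    tag_col: str = "tag_id",
    sep: str = ",",
    dayfirst: bool = False,
) -> pd.DataFrame:
    """Read a delimited detection log into a tidy, time-sorted frame.

    Returns a DataFrame with columns ``timestamp`` (UTC-naive), ``tag_id``
    and ``receiver_id``, sorted by timestamp.  Exact duplicate rows are
    dropped and the count logged.  Timestamps may be ISO-8601 or
    ``DD/MM/YYYY HH:MM:SS`` (set ``dayfirst=True`` for the latter).

    Raises ``ValueError`` naming the first offending line for unparsable
    timestamps.
    """
    raw = pd.read_csv(path, sep=sep, dtype=str)
    if raw.empty:
        logger.warning("detection log %s is empty", path)
        return pd.DataFrame(columns=["timestamp", "tag_id", "receiver_id"])
    for col in (timestamp_col, receiver_col, tag_col):
        if col not in raw.columns:
            raise ValueError(f"missing column {col!r} in {path}")
    ts = pd.to_datetime(raw[timestamp_col], errors="coerce", dayfirst=dayfirst,
                        format="mixed")
    bad = ts.isna() & raw[timestamp_col].notna()
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # header is line 1
        raise ValueError(
            f"unparsable timestamp {raw[timestamp_col][bad].iloc[0]!r} "
            f"at line {line} of {path}"
        )
    out = pd.DataFrame(
        {"timestamp": ts, "tag_id": raw[tag_col], "receiver_id": raw[receiver_col]}
    )
    n0 = len(out)
    out = out.drop_duplicates()
    if len(out) < n0:
        logger.info("dropped %d duplicate detection rows", n0 - len(out))
    return out.sort_values("timestamp", kind="stable").reset_index(drop=True)


def filter_false_detections(
    dets: pd.DataFrame,
    short: pd.Timedelta = SHORT_INTERVAL,
    long: pd.Timedelta = LONG_INTERVAL,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Screen suspected false detections per (tag, receiver) stream.

    Inter-detection intervals within each stream are classed *short*
    (< ``short``) or *long* (> ``long``).  A detection is flagged when it is
    temporally isolated — both neighbouring intervals exceed ``long`` (a
    single neighbouring interval suffices at stream endpoints) — AND its
    stream has fewer short than long intervals.  A stream with plenty of
    short intervals is taken as genuinely resident and nothing in it is
    flagged.  Single-detection streams carry zero short intervals and are
    flagged.

    Returns ``(kept, flagged)``; the two frames partition the input.
    """
    if short >= long:
        raise ValueError("short threshold must be below long threshold")
    if dets.empty:
        return dets.copy(), dets.iloc[0:0].copy()
    flagged_mask = np.zeros(len(dets), dtype=bool)
    dets = dets.reset_index(drop=True)
    for _, idx in dets.groupby(["tag_id", "receiver_id"], sort=False).groups.items():
        sub = dets.loc[idx]
        t = sub["timestamp"].to_numpy()
        gaps = np.diff(t)
        n_short = int((gaps < short.to_timedelta64()).sum())
        n_long = int((gaps > long.to_timedelta64()).sum())
        # ratio < 1 simply means fewer short than long intervals
        ratio_low = n_short < max(n_long, 1)
        if not ratio_low:
            continue
        is_long = gaps > long.to_timedelta64()
        for k in range(len(sub)):
            prev_long = is_long[k - 1] if k > 0 else True
            next_long = is_long[k] if k < len(gaps) else True
            if prev_long and next_long:
                flagged_mask[idx[k]] = True
    kept = dets.loc[~flagged_mask].reset_index(drop=True)
    flagged = dets.loc[flagged_mask].reset_index(drop=True)
    if len(flagged):
        logger.info("flagged %d suspected false detections", len(flagged))
    return kept, flagged


def detect_resident_events(
    dets: pd.DataFrame,
    timeout: pd.Timedelta = EVENT_TIMEOUT,
    switch_count: int = SWITCH_COUNT,
) -> list[ResidentEvent]:
    """Segment detections into resident events with a per-tag state machine.

    An event at receiver R opens at the second detection at R within
    ``timeout`` of the previous one and extends while same-receiver
    detections keep arriving within ``timeout``.  It closes at its last
    member detection when (a) the next detection at R is more than
    ``timeout`` away, or (b) ``switch_count`` detections accumulate at a
    single other receiver before the next detection at R.  Detections at
    the closing receiver then seed the next candidate.
    """
    events: list[ResidentEvent] = []
    for tag_id, sub in dets.groupby("tag_id", sort=False):
        sub = sub.sort_values("timestamp", kind="stable")
        stream = list(zip(sub["timestamp"], sub["receiver_id"]))
        events.extend(_walk_stream(str(tag_id), stream, timeout, switch_count))
    events.sort(key=lambda e: (e.start, e.tag_id, e.receiver_id))
    return events


def _walk_stream(tag_id, stream, timeout, switch_count):
    """Run the resident-event state machine over one tag's detections.

    Detections at other receivers are buffered while a candidate is open:
    they are dropped once the same-receiver chain continues, but when the
    candidate closes — by timeout or by ``switch_count`` detections at one
    other receiver — everything buffered after the event's end is replayed
    chronologically to seed the next candidate.
    """
    from collections import deque

    events = []
    pending = deque(stream)
    cand = None  # [receiver, start, last, n]
    buffered: list = []  # (t, r) at other receivers since the last member
    counts: dict[str, int] = {}

    def close():
        if cand is not None and cand[3] >= 2:
            events.append(
                ResidentEvent(tag_id, cand[0], cand[1], cand[2], cand[3])
            )

    while pending:
        t, r = pending.popleft()
        if cand is None:
            cand = [r, t, t, 1]
            buffered, counts = [], {}
            continue
        if r == cand[0]:
            if t - cand[2] <= timeout:
                cand[2] = t
                cand[3] += 1
                buffered, counts = [], {}  # intervening singles forgiven
            else:
                close()
                # replay what arrived after the event ended, then this one
                pending.extendleft(reversed(buffered + [(t, r)]))
                cand, buffered, counts = None, [], {}
        else:
            buffered.append((t, r))
            counts[r] = counts.get(r, 0) + 1
            if counts[r] >= switch_count:
                close()
                pending.extendleft(reversed(buffered))
                cand, buffered, counts = None, [], {}
    close()
    return events


def events_to_frame(events: list[ResidentEvent]) -> pd.DataFrame:
    """Tidy table of resident events (one row per event)."""
    return pd.DataFrame(
        [
            {
                "tag_id": e.tag_id,
                "receiver_id": e.receiver_id,
                "start": e.start,
                "end": e.end,
                "n_detections": e.n_detections,
                "duration_min": e.duration,
            }
            for e in events
        ]
    )


def residency_index(detection_days: int, tracking_days: int) -> float:
    """Residency index (%) = 100 x days detected / days tracked.

    ``tracking_days`` is the inclusive day span from first to last
    detection; ``detection_days`` the number of distinct calendar days with
    at least one detection.
    """
    if tracking_days < 1:
        raise ValueError("tracking_days must be >= 1")
    if detection_days > tracking_days:
        raise ValueError("detection_days cannot exceed tracking_days")
    return 100.0 * detection_days / tracking_days


def _day_span(first: pd.Timestamp, last: pd.Timestamp) -> int:
    """Inclusive tracking span in calendar days (same-day span = 1).

    Counting calendar dates inclusively keeps detection_days <= tracking_days
    for any detection pattern and matches published deployment tables
    (e.g. 19/11 to 21/11 spans 3 days).
    """
    return (last.normalize() - first.normalize()).days + 1


def summarize_tracking(
    dets: pd.DataFrame,
    tags: pd.DataFrame,
    download_date: date,
) -> pd.DataFrame:
    """Per-tag tracking summary from a detection log plus tag metadata.

    ``tags`` needs columns ``tag_id``, ``manta_id``, ``deploy_date`` (and
    optionally ``sex``/``maturity``).  Tags with zero detections are
    excluded and logged.  Returns one row per detected tag with
    ``tracking_days`` (inclusive first-to-last span), ``detection_days``
    (distinct calendar days), ``total_time_days`` (deployment to download)
    and ``ri_percent``.
    """
    rows = []
    meta = tags.set_index("tag_id")
    for tag_id, sub in dets.groupby("tag_id", sort=False):
        if tag_id not in meta.index:
            raise ValueError(f"tag {tag_id!r} missing from metadata")
        first, last = sub["timestamp"].min(), sub["timestamp"].max()
        td = _day_span(first, last)
        dd = sub["timestamp"].dt.normalize().nunique()
        deploy = pd.Timestamp(meta.loc[tag_id, "deploy_date"])
        row = {
            "tag_id": tag_id,
            "manta_id": meta.loc[tag_id, "manta_id"],
            "first_detection": first,
            "last_detection": last,
            "n_detections": len(sub),
            "tracking_days": td,
            "detection_days": dd,
            "total_time_days": (pd.Timestamp(download_date) - deploy).days,
            "ri_percent": residency_index(dd, td),
        }
        for extra in ("sex", "maturity"):
            if extra in meta.columns:
                row[extra] = meta.loc[tag_id, extra]
        rows.append(row)
    missing = set(meta.index) - set(dets["tag_id"])
    if missing:
        logger.info("tags with zero detections excluded: %s", sorted(missing))
    return pd.DataFrame(rows)


def cohort_statistics(summary: pd.DataFrame) -> dict:
    """Cohort means/SDs/ranges for a per-tag summary table.

    Uses the table's ``ri_percent`` column as-is, the sample SD (ddof=1),
    and half-up integer rounding, matching the conventions of published
    deployment-summary tables.
    """

    def stat(col):
        v = summary[col].astype(float)
        return {
            "mean": round_half_up(v.mean()),
            "sd": float(v.std(ddof=1)),
            "min": float(v.min()),
            "max": float(v.max()),
        }

    out = {
        "n_tags": len(summary),
        "total_detections": int(summary["n_detections"].sum()),
        "ri": stat("ri_percent"),
        "detection_days": stat("detection_days"),
        "tracking_days": stat("tracking_days"),
        "total_time_days": stat("total_time_days"),
    }
    if "maturity" in summary.columns:
        adults = summary[summary["maturity"].str.lower() == "adult"]
        juv = summary[summary["maturity"].str.lower() != "adult"]
        if len(adults):
            out["ri_adult_mean"] = round_half_up(
                adults["ri_percent"].astype(float).mean()
            )
        if len(juv):
            out["ri_juvenile_mean"] = round_half_up(
                juv["ri_percent"].astype(float).mean()
            )
    return out


def diel_distribution(
    dets: pd.DataFrame,
    day_hours: frozenset[int] = DAY_HOURS,
    night_hours: frozenset[int] = NIGHT_HOURS,
    by: pd.Series | None = None,
) -> dict:
    """Hour-of-day detection percentages and the day/night split.

    ``by`` optionally maps tag_id -> class (e.g. maturity) for a per-class
    breakdown.  Per-hour percentages sum to 100 over the 24 bins; the
    day/night split is computed over the union of the two hour sets.
    """

    def one(sub):
        hours = sub["timestamp"].dt.hour
        counts = hours.value_counts().reindex(range(24), fill_value=0)
        pct = 100.0 * counts / max(counts.sum(), 1)
        covered = day_hours | night_hours
        in_cov = counts[sorted(covered)].sum()
        day = 100.0 * counts[sorted(day_hours)].sum() / max(in_cov, 1)
        night = 100.0 * counts[sorted(night_hours)].sum() / max(in_cov, 1)
        return {"per_hour_percent": pct.to_dict(), "day_percent": float(day),
                "night_percent": float(night)}

    out = {"all": one(dets)}
    if by is not None:
        cls = dets["tag_id"].map(by)
        for name, sub in dets.groupby(cls):
            out[str(name)] = one(sub)
    return out


def site_share(dets: pd.DataFrame, receivers: pd.DataFrame) -> pd.Series:
    """Percentage of detections per site; shares sum to 100.

    ``receivers`` needs ``receiver_id`` and ``site_name`` columns.  Unknown
    receiver ids raise with the offending id named.
    """
    site_of = receivers.set_index("receiver_id")["site_name"]
    unknown = set(dets["receiver_id"]) - set(site_of.index)
    if unknown:
        raise ValueError(f"unknown receiver id(s): {sorted(unknown)}")
    counts = dets["receiver_id"].map(site_of).value_counts()
    return 100.0 * counts / counts.sum()
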