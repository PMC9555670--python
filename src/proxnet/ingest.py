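"""Raw proximity-tag log ingestion.

A wearable ultra-wideband tag assesses, once per second, the distance in
centimetres to every other tag in range.  Each assessment is one row of the
raw log::

    timestamp_s,reporter_tag,opposing_tag,distance_cm

Physical tags are handed out to several customers over a day, so a tag's
activity must be split into *wearing sessions* before its records can be
attributed to unique participants.  A participant id is the tag id plus a
session ordinal, e.g. ``T03#2`` for the second customer who wore tag T03.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

RAW_LOG_COLUMNS = ["timestamp_s", "reporter_tag", "opposing_tag", "distance_cm"]

#: default idle gap (seconds) separating two wearings of the same tag
DEFAULT_GAP_THRESHOLD_S = 120


@dataclass(frozen=True)
class TagRecord:
    """One 1 Hz distance assessment between two tags."""

    timestamp_s: int
    reporter_tag: str
    opposing_tag: str
    distance_cm: int


@dataclass(frozen=True)
class VisitSession:
    """One participant's interval of wearing a physical tag.

    Intervals are closed ``[start_s, end_s]`` on integer seconds; the visit
    duration is ``end_s - start_s + 1`` seconds.
    """

    participant_id: str
    tag_id: str
    start_s: int
    end_s: int

    @property
    def duration_s(self) -> int:
        return self.end_s - self.start_s + 1


def parse_raw_log(path: str | Path) -> pd.DataFrame:
    """Read a raw tag log into a records table.

    Rows are validated: a malformed row (wrong column count or non-numeric
    field) raises :class:`ValueError` naming the line number; rows with a
    negative distance or a self-report (reporter equals opposing tag) are
    dropped with a logged count.  Sub-second timestamps are floored to
    integer seconds.  The result is sorted by timestamp.

    Returns a DataFrame with columns ``timestamp_s`` (int), ``reporter_tag``
    (str), ``opposing_tag`` (str), ``distance_cm`` (int) — one row per
    :class:`TagRecord`.
    """
    path = Path(path)
    timestamps: list[int] = []
    reporters: list[str] = []
    opposings: list[str] = []
    distances: list[int] = []
    n_self = 0
    n_negative = 0
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header] != RAW_LOG_COLUMNS:
            raise ValueError(
                f"{path}: expected header {','.join(RAW_LOG_COLUMNS)!r}, got {header!r}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 fields, got {len(row)}")
            try:
                t = int(float(row[0]))
                d = int(float(row[3]))
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-numeric timestamp or distance") from None
            rep, opp = row[1].strip(), row[2].strip()
            if not rep or not opp:
                raise ValueError(f"{path}:{lineno}: empty tag id")
            if rep == opp:
                n_self += 1
                continue
            if d < 0:
                n_negative += 1
                continue
            timestamps.append(t)
            reporters.append(rep)
            opposings.append(opp)
            distances.append(d)
    if n_self:
        logger.info("parse_raw_log: dropped %d self-report rows", n_self)
    if n_negative:
        logger.info("parse_raw_log: dropped %d negative-distance rows", n_negative)
    frame = pd.DataFrame(
        {
            "timestamp_s": pd.Series(timestamps, dtype=np.int64),
            "reporter_tag": pd.Series(reporters, dtype=str),
            "opposing_tag": pd.Series(opposings, dtype=str),
            "distance_cm": pd.Series(distances, dtype=np.int64),
        }
    )
    frame.sort_values("timestamp_s", kind="stable", inplace=True, ignore_index=True)
    return frame


def sessionize(
    records: pd.DataFrame, gap_threshold_s: int = DEFAULT_GAP_THRESHOLD_S
) -> list[VisitSession]:
    """Split each tag's activity timeline into wearing sessions.

    A tag is "seen" at a second if it appears in any record, as reporter or
    opposing tag.  Whenever two consecutive appearances of one tag are more
    than ``gap_threshold_s`` seconds apart the timeline is split; each
    maximal run of appearances becomes one :class:`VisitSession` whose bounds
    are the first and last appearance.  Session ordinals are 1-based in time
    order, so the resulting sessions of one tag are disjoint.

    A worn tag that never came within range of another tag produces no
    records and therefore no session; such silent wearings are invisible to
    the whole pipeline.
    """
    if len(records) == 0:
        return []
    seen = pd.concat(
        [
            records[["timestamp_s", "reporter_tag"]].rename(columns={"reporter_tag": "tag"}),
            records[["timestamp_s", "opposing_tag"]].rename(columns={"opposing_tag": "tag"}),
        ],
        ignore_index=True,
    )
    sessions: list[VisitSession] = []
    for tag, sub in seen.groupby("tag", sort=True):
        times = np.unique(sub["timestamp_s"].to_numpy())
        breaks = np.flatnonzero(np.diff(times) > gap_threshold_s)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [len(times) - 1]])
        for ordinal, (a, b) in enumerate(zip(starts, ends), start=1):
            sessions.append(
                VisitSession(
                    participant_id=f"{tag}#{ordinal}",
                    tag_id=str(tag),
                    start_s=int(times[a]),
                    end_s=int(times[b]),
                )
            )
    return sessions


def _session_lookup(sessions: list[VisitSession]) -> dict[str, tuple[np.ndarray, np.ndarray, list[str]]]:
    """Per-tag (starts, ends, participant ids) arrays, validated disjoint."""
    by_tag: dict[str, list[VisitSession]] = {}
    for s in sessions:
        if s.start_s > s.end_s:
            raise ValueError(f"session {s.participant_id}: start after end")
        by_tag.setdefault(s.tag_id, []).append(s)
    lookup = {}
    for tag, sess in by_tag.items():
        sess.sort(key=lambda s: s.start_s)
        starts = np.array([s.start_s for s in sess], dtype=np.int64)
        ends = np.array([s.end_s for s in sess], dtype=np.int64)
        if np.any(starts[1:] <= ends[:-1]):
            raise ValueError(f"tag {tag}: overlapping sessions")
        lookup[tag] = (starts, ends, [s.participant_id for s in sess])
    return lookup


def assign_participants(
    records: pd.DataFrame, sessions: list[VisitSession]
) -> pd.DataFrame:
    """Annotate records with the participant wearing each tag.

    Each record maps its reporter and opposing tag to the unique session
    enclosing the record's timestamp.  Records whose timestamp falls inside
    no session for either tag are dropped, with the count logged.
    Overlapping sessions for one tag are an invariant breach and raise
    :class:`ValueError`.

    Returns the records table with added ``participant_rep`` and
    ``participant_opp`` columns.
    """
    lookup = _session_lookup(sessions)
    t = records["timestamp_s"].to_numpy()
    out = {}
    for col, new in [("reporter_tag", "participant_rep"), ("opposing_tag", "participant_opp")]:
        pid = np.full(len(records), None, dtype=object)
        tags = records[col].to_numpy()
        for tag in pd.unique(tags):
            mask = tags == tag
            if tag not in lookup:
                continue
            starts, ends, pids = lookup[tag]
            idx = np.searchsorted(starts, t[mask], side="right") - 1
            ok = (idx >= 0) & (t[mask] <= ends[np.clip(idx, 0, None)])
            sel = np.flatnonzero(mask)[ok]
            pid[sel] = np.array(pids, dtype=object)[idx[ok]]
        out[new] = pid
    annotated = records.assign(**out)
    keep = annotated["participant_rep"].notna() & annotated["participant_opp"].notna()
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("assign_participants: dropped %d records outside any session", n_dropped)
    return annotated[keep].reset_index(drop=True)


def symmetrize(annotated: pd.DataFrame) -> pd.DataFrame:
    """Collapse reciprocal reports into one distance per (pair, second).

    The two tags of a pair may both report the same second, with slightly
    different measured distances.  The pair is keyed by the unordered
    participant pair (lexicographically ordered columns) and duplicate
    reports are merged by taking the *minimum* distance — the conservative
    rule for a distancing analysis, since it can only declare a pair closer,
    never farther.

    Returns a DataFrame with columns ``participant_a``, ``participant_b``
    (``a < b``), ``second``, ``distance_cm``.
    """
    if len(annotated) == 0:
        return pd.DataFrame(
            columns=["participant_a", "participant_b", "second", "distance_cm"]
        ).astype({"second": np.int64, "distance_cm": np.int64})
    rep = annotated["participant_rep"].to_numpy(dtype=object)
    opp = annotated["participant_opp"].to_numpy(dtype=object)
    swap = rep > opp
    a = np.where(swap, opp, rep)
    b = np.where(swap, rep, opp)
    table = pd.DataFrame(
        {
            "participant_a": a,
            "participant_b": b,
            "second": annotated["timestamp_s"].to_numpy(),
            "distance_cm": annotated["distance_cm"].to_numpy(),
        }
    )
    merged = (
        table.groupby(["participant_a", "participant_b", "second"], sort=True, as_index=False)[
            "distance_cm"
        ]
        .min()
    )
    return merged


def sessions_to_frame(sessions: list[VisitSession]) -> pd.DataFrame:
    """Sessions as a table ``participant_id,tag_id,start_s,end_s``."""
    return pd.DataFrame(
        {
            "participant_id": [s.participant_id for s in sessions],
            "tag_id": [s.tag_id for s in sessions],
            "start_s": pd.Series([s.start_s for s in sessions], dtype=np.int64),
            "end_s": pd.Series([s.end_s for s in sessions], dtype=np.int64),
        }
    )


def frame_to_sessions(frame: pd.DataFrame) -> list[VisitSession]:
    return [
        VisitSession(str(r.participant_id), str(r.tag_id), int(r.start_s), int(r.end_s))
        for r in frame.itertuples(index=False)
    ]
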