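"""Contact extraction and descriptive summaries.

A *contact* is a second at which two participants from different groups were
closer than the distancing threshold (150 cm, matching the 1.5 m regulation;
the inequality is strict and configurable).  A dyad's contact duration is
the summed count of such seconds — qualifying seconds need not be
contiguous.  Unique contacts of a participant are distinct partners, i.e.
the participant's degree in the contact network.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

from .ingest import VisitSession

DEFAULT_CONTACT_THRESHOLD_CM = 150

CONTACT_COLUMNS = ["participant_a", "participant_b", "contact_seconds", "first_s", "last_s"]


def contact_seconds(
    pair_seconds: pd.DataFrame,
    group_map: dict[str, str],
    threshold_cm: int = DEFAULT_CONTACT_THRESHOLD_CM,
) -> pd.DataFrame:
    """Per-second qualifying contacts: distance strictly below the threshold
    and the pair spanning two groups.

    Same columns as the input (``participant_a, participant_b, second,
    distance_cm``), restricted to qualifying rows.
    """
    if len(pair_seconds) == 0:
        return pair_seconds.copy()
    close = pair_seconds["distance_cm"].to_numpy() < threshold_cm
    ga = pair_seconds["participant_a"].map(group_map).to_numpy(dtype=object)
    gb = pair_seconds["participant_b"].map(group_map).to_numpy(dtype=object)
    cross_group = ga != gb
    return pair_seconds[close & cross_group].reset_index(drop=True)


def aggregate_contacts(
    qualifying: pd.DataFrame, min_contact_seconds: int = 1
) -> pd.DataFrame:
    """Aggregate qualifying pair-seconds into one row per dyad.

    Returns columns ``participant_a, participant_b, contact_seconds,
    first_s, last_s``; dyads with fewer than ``min_contact_seconds``
    qualifying seconds are dropped (default 1, i.e. no minimum).
    """
    if len(qualifying) == 0:
        return pd.DataFrame(columns=CONTACT_COLUMNS).astype(
            {"contact_seconds": np.int64, "first_s": np.int64, "last_s": np.int64}
        )
    agg = (
        qualifying.groupby(["participant_a", "participant_b"], sort=True)["second"]
        .agg(contact_seconds="nunique", first_s="min", last_s="max")
        .reset_index()
    )
    return agg[agg["contact_seconds"] >= min_contact_seconds].reset_index(drop=True)


def extract_contacts(
    pair_seconds: pd.DataFrame,
    group_map: dict[str, str],
    threshold_cm: int = DEFAULT_CONTACT_THRESHOLD_CM,
    min_contact_seconds: int = 1,
) -> pd.DataFrame:
    """Between-group dyadic contacts with summed durations (at 1 Hz the
    duration in seconds equals the count of qualifying seconds)."""
    return aggregate_contacts(
        contact_seconds(pair_seconds, group_map, threshold_cm), min_contact_seconds
    )


def participant_degree(
    contacts: pd.DataFrame, participants: Iterable[str]
) -> pd.DataFrame:
    """Number of unique contacts (distinct partners) per participant.

    Participants with no contacts get degree 0.  Returns columns
    ``participant_id, n_unique_contacts``.
    """
    participants = list(participants)
    degree = dict.fromkeys(participants, 0)
    for a, b in zip(contacts["participant_a"], contacts["participant_b"]):
        degree[a] = degree.get(a, 0) + 1
        degree[b] = degree.get(b, 0) + 1
    return pd.DataFrame(
        {"participant_id": participants, "n_unique_contacts": [degree[p] for p in participants]}
    )


def select_window(
    sessions: list[VisitSession],
    qualifying: pd.DataFrame,
    t0: int,
    t1: int,
    min_contact_seconds: int = 1,
) -> tuple[list[str], pd.DataFrame]:
    """Restrict the analysis to a time window ``[t0, t1)``.

    Selected participants are those whose session intersects the half-open
    window.  Contacts are recomputed from the qualifying per-second table
    restricted to seconds inside the window and to pairs with both members
    selected, so durations straddling the window edge are truncated rather
    than kept whole or dropped.
    """
    if t0 >= t1:
        raise ValueError("window must satisfy t0 < t1")
    selected = [s.participant_id for s in sessions if s.start_s < t1 and s.end_s >= t0]
    sel = set(selected)
    if len(qualifying) == 0:
        return selected, aggregate_contacts(qualifying, min_contact_seconds)
    mask = (
        (qualifying["second"] >= t0)
        & (qualifying["second"] < t1)
        & qualifying["participant_a"].isin(sel)
        & qualifying["participant_b"].isin(sel)
    )
    return selected, aggregate_contacts(qualifying[mask], min_contact_seconds)


def hourly_summary(
    sessions: list[VisitSession],
    qualifying: pd.DataFrame,
    hours: Iterable[int] | None = None,
) -> pd.DataFrame:
    """Per one-hour window: participant count and median number of unique
    contacts (the crowdedness/contacts pair the hourly regression consumes).

    ``hours`` are window start times in seconds, aligned to integer hours;
    by default every hour from the first to the last session second.
    Hours with no participants report a missing median.
    """
    if hours is None:
        if not sessions:
            return pd.DataFrame(columns=["hour_start_s", "n_participants", "median_degree"])
        lo = min(s.start_s for s in sessions) // 3600 * 3600
        hi = max(s.end_s for s in sessions)
        hours = range(lo, hi + 1, 3600)
    rows = []
    for h in hours:
        if h % 3600:
            raise ValueError("hour grid must align to integer hours")
        selected, contacts = select_window(sessions, qualifying, h, h + 3600)
        if selected:
            deg = participant_degree(contacts, selected)["n_unique_contacts"]
            med = float(np.median(deg))
        else:
            med = np.nan
        rows.append((h, len(selected), med))
    return pd.DataFrame(rows, columns=["hour_start_s", "n_participants", "median_degree"])


def _five_number(x: np.ndarray) -> dict[str, float]:
    if len(x) == 0:
        return {k: float("nan") for k in ("min", "max", "mean", "sd", "median", "q1", "q3")}
    return {
        "min": float(np.min(x)),
        "max": float(np.max(x)),
        "mean": float(np.mean(x)),
        "sd": float(np.std(x, ddof=1)) if len(x) > 1 else 0.0,
        "median": float(np.median(x)),
        "q1": float(np.percentile(x, 25)),
        "q3": float(np.percentile(x, 75)),
    }


def condition_descriptives(
    contacts: pd.DataFrame, participants: list[str]
) -> dict[str, dict[str, float]]:
    """Range, mean ± SD, median and IQR of per-participant degrees and of
    per-dyad contact durations — the standard descriptive block reported per
    experimental condition."""
    degrees = participant_degree(contacts, participants)["n_unique_contacts"].to_numpy(float)
    durations = contacts["contact_seconds"].to_numpy(float)
    return {
        "n_participants": {"value": float(len(participants))},
        "degree": _five_number(degrees),
        "duration_s": _five_number(durations),
    }
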