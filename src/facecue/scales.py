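"""Scoring of the self-report paternal-involvement instruments.

Three instruments, all on 1-5 item scales:

* **NFS** (Nurturant Fathering Scale) — 9 items on father-child
  relationship quality; no not-applicable option.
* **FIS-involved** — reported involvement across 20 domains; items may
  be marked not applicable (NA).
* **FIS-desired** — desired involvement across the same 20 domains;
  NA permitted.

Each scale is scored as the mean of the applicable (non-NA) items, so
all three live on a comparable 1-5 range; a FIS subscale with every
item NA is undefined and propagates as missing.  Non-fathers answer the
instruments imagining an 8-year-old child; their responses are scored
identically, with father status carried as a subset flag.

Participant-level exclusions mirror the study funnel: no usable
photograph, low seriousness (< 5 of 7), language issues, and duplicate
participation, applied in that order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "INSTRUMENT_ITEMS",
    "ExclusionReport",
    "score_scale",
    "score_participants",
    "apply_participant_exclusions",
]

INSTRUMENT_ITEMS = {"NFS": 9, "FIS_involved": 20, "FIS_desired": 20}

# column prefixes in the participant CSV contract
_PREFIX = {"NFS": "nfs", "FIS_involved": "fisR", "FIS_desired": "fisD"}

EXCLUSION_ORDER = ("no_photo", "seriousness", "language", "duplicate")


def score_scale(item_values, instrument: str, n_items: int | None = None) -> float:
    """Mean of the applicable items of one instrument response.

    Parameters
    ----------
    item_values : sequence of float
        Item responses in 1-5; NaN marks a not-applicable response
        (FIS only).
    instrument : {"NFS", "FIS_involved", "FIS_desired"}
    n_items : int, optional
        Expected item count; defaults to the instrument's standard
        length (9 for NFS, 20 per FIS subscale).

    Returns
    -------
    float
        The scale score in [1, 5], or NaN when every item is NA.
    """
    if instrument not in INSTRUMENT_ITEMS:
        raise ValueError(f"unknown instrument {instrument!r}")
    expected = INSTRUMENT_ITEMS[instrument] if n_items is None else n_items
    vals = np.asarray(item_values, dtype=float)
    if vals.shape != (expected,):
        raise ValueError(
            f"{instrument} expects {expected} items, got {vals.shape}"
        )
    na = np.isnan(vals)
    if instrument == "NFS" and na.any():
        raise ValueError("NFS has no not-applicable option; NA not allowed")
    ok = vals[~na]
    if ok.size == 0:
        return float("nan")
    if ok.min() < 1 or ok.max() > 5:
        raise ValueError("item values must lie in [1, 5]")
    return float(ok.mean())


def score_participants(responses: pd.DataFrame) -> pd.DataFrame:
    """Score NFS and both FIS subscales for every participant row.

    ``responses`` follows the flat CSV contract: one row per
    participant with columns ``nfs_1..nfs_9``, ``fisR_1..fisR_20``,
    ``fisD_1..fisD_20`` (NA permitted in FIS columns only) plus
    ``participant_id`` and ``is_father``.

    Returns a frame with participant_id, nfs, fis_involved,
    fis_desired, is_father.
    """
    out = {"participant_id": responses["participant_id"].to_numpy()}
    for instrument, key in [
        ("NFS", "nfs"),
        ("FIS_involved", "fis_involved"),
        ("FIS_desired", "fis_desired"),
    ]:
        prefix = _PREFIX[instrument]
        cols = [f"{prefix}_{i}" for i in range(1, INSTRUMENT_ITEMS[instrument] + 1)]
        missing = [c for c in cols if c not in responses.columns]
        if missing:
            raise ValueError(f"missing item columns: {missing}")
        block = responses[cols].to_numpy(dtype=float)
        out[key] = [
            score_scale(row, instrument) for row in block
        ]
    result = pd.DataFrame(out)
    if "is_father" in responses.columns:
        result["is_father"] = responses["is_father"].to_numpy()
    return result


@dataclass(frozen=True)
class ExclusionReport:
    counts: dict  # reason -> number excluded
    excluded_ids: dict  # reason -> tuple of participant ids
    n_input: int
    n_kept: int


def apply_participant_exclusions(
    participants: pd.DataFrame, seriousness_threshold: int = 5
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Apply the participant exclusion funnel in its canonical order.

    Expects boolean/flag columns ``has_photo``, ``language_issue``,
    ``duplicate`` and integer ``seriousness`` (1-7).  Exclusion reasons
    are assessed in order — no usable photo, seriousness below
    threshold, language issue, duplicate — and each participant is
    counted once, under the first reason that applies.
    """
    required = {"participant_id", "has_photo", "seriousness", "language_issue", "duplicate"}
    missing = required - set(participants.columns)
    if missing:
        raise ValueError(f"participant table missing columns: {missing}")

    df = participants.copy()
    reasons = {
        "no_photo": ~df["has_photo"].astype(bool),
        "seriousness": df["seriousness"] < seriousness_threshold,
        "language": df["language_issue"].astype(bool),
        "duplicate": df["duplicate"].astype(bool),
    }
    excluded = pd.Series(False, index=df.index)
    counts: dict[str, int] = {}
    ids: dict[str, tuple] = {}
    for reason in EXCLUSION_ORDER:
        hit = reasons[reason] & ~excluded
        counts[reason] = int(hit.sum())
        ids[reason] = tuple(df.loc[hit, "participant_id"])
        excluded |= hit
    kept = df[~excluded].reset_index(drop=True)
    report = ExclusionReport(
        counts=counts, excluded_ids=ids, n_input=len(df), n_kept=len(kept)
    )
    return kept, report
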