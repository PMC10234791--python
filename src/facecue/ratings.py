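"""Rater-level exclusions and per-face aggregation of trait ratings.

Faces are rated on 1-10 scales for attractiveness, perceived
masculinity, and perceived paternal involvement, each rater judging a
random subset of faces on a single trait.  Raters who report low
seriousness (below 5 on a 7-point honesty scale) are dropped wholesale;
per-face trait scores are plain means across the remaining raters, with
optional restriction to male or female raters for robustness splits.
Following the >= 30 raters-per-stimulus guideline, a coverage check
flags under-rated faces.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "TRAITS",
    "RaterExclusionReport",
    "CoverageReport",
    "filter_raters",
    "aggregate_trait",
    "aggregate_all",
    "coverage_check",
]

TRAITS = ("attractiveness", "perceived_masculinity", "perceived_paternal_involvement")

RATING_COLUMNS = ["rater_id", "face_id", "trait", "value", "rater_sex", "seriousness"]


@dataclass(frozen=True)
class RaterExclusionReport:
    excluded_raters: tuple
    n_records_removed: int
    threshold: int


@dataclass(frozen=True)
class CoverageReport:
    flagged: pd.DataFrame  # (face_id, trait, n_ratings) rows below minimum
    mean_ratings_per_face: float
    minimum: int


def _check_columns(records: pd.DataFrame) -> None:
    missing = [c for c in RATING_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"rating table missing columns: {missing}")


def filter_raters(
    records: pd.DataFrame, threshold: int = 5
) -> tuple[pd.DataFrame, RaterExclusionReport]:
    """Drop all records from raters whose seriousness is below threshold.

    Seriousness is a per-rater attribute carried on every record; a
    rater is excluded if any of their records reports a score below the
    threshold.  Returns the kept records and an exclusion report.
    """
    _check_columns(records)
    if records.empty:
        return records, RaterExclusionReport((), 0, threshold)
    low = records.loc[records["seriousness"] < threshold, "rater_id"].unique()
    kept = records[~records["rater_id"].isin(low)].copy()
    return kept, RaterExclusionReport(
        excluded_raters=tuple(sorted(low)),
        n_records_removed=len(records) - len(kept),
        threshold=threshold,
    )


def aggregate_trait(
    records: pd.DataFrame, trait: str, subgroup: str = "all"
) -> pd.DataFrame:
    """Mean rating and count per face for one trait.

    ``subgroup`` restricts to ``male`` or ``female`` raters; ``all``
    keeps every rater including other/unknown sex (who belong to
    neither sex subgroup).
    """
    _check_columns(records)
    if trait not in TRAITS:
        raise ValueError(f"unknown trait {trait!r}; expected one of {TRAITS}")
    if subgroup not in ("all", "male", "female"):
        raise ValueError(f"unknown subgroup {subgroup!r}")
    sub = records[records["trait"] == trait]
    if subgroup != "all":
        sub = sub[sub["rater_sex"] == subgroup]
    grouped = sub.groupby("face_id")["value"].agg(["mean", "count"])
    out = grouped.reset_index().rename(
        columns={"mean": "mean_rating", "count": "n_ratings"}
    )
    out.insert(1, "trait", trait)
    out["subgroup"] = subgroup
    return out


def aggregate_all(records: pd.DataFrame, subgroup: str = "all") -> pd.DataFrame:
    """Wide table of per-face mean ratings, one column per trait.

    Columns: face_id, <trait> and n_<trait> for each of the three
    traits.  Faces missing a trait get NaN.
    """
    pieces = []
    for trait in TRAITS:
        agg = aggregate_trait(records, trait, subgroup)
        agg = agg.set_index("face_id")[["mean_rating", "n_ratings"]]
        agg.columns = [trait, f"n_{trait}"]
        pieces.append(agg)
    wide = pd.concat(pieces, axis=1).reset_index()
    return wide


def coverage_check(scores: pd.DataFrame, minimum: int = 30) -> CoverageReport:
    """Flag (face, trait) cells with fewer than ``minimum`` ratings.

    ``scores`` is the long output of :func:`aggregate_trait` (possibly
    concatenated over traits).  Also reports the overall mean number of
    ratings per face-trait cell.
    """
    needed = {"face_id", "trait", "n_ratings"}
    if not needed.issubset(scores.columns):
        raise ValueError(f"scores table missing columns: {needed - set(scores.columns)}")
    flagged = scores.loc[
        scores["n_ratings"] < minimum, ["face_id", "trait", "n_ratings"]
    ].reset_index(drop=True)
    return CoverageReport(
        flagged=flagged,
        mean_ratings_per_face=float(scores["n_ratings"].mean()),
        minimum=minimum,
    )
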