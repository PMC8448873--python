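"""Behavioral preprocessing: continuous pleasantness streams and familiarity.

During the experimental session listeners hold one of the numeric keys 1-5
for as long as that degree of evoked pleasantness applies (1 = "I don't like
it" ... 5 = "I experience frissons").  Each trial's stream of key-hold
segments is collapsed to a single time-weighted pleasantness index, which is
then dichotomized per subject at that subject's median ("least" vs "most"
pleasant).  Trials are rejected when

* the first response arrives only after half the excerpt has played
  (the trial is halted), or
* the excerpt was rated familiar (rating > 2 on the 7-point scale) in the
  exposure session or in the new condition of the experimental session; such
  an excerpt is removed from *all* conditions for that subject.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "RatingStream",
    "time_weighted_pleasantness",
    "median_split",
    "familiarity_reject",
    "assemble_trial_table",
    "read_trial_table",
    "write_trial_table",
    "FAMILIARITY_CUTOFF",
    "LEAST", "MOST", "HALTED",
]

logger = logging.getLogger(__name__)

FAMILIARITY_CUTOFF: int = 2
LEAST = "least"
MOST = "most"
HALTED = "halted"

#: Column dictionary for the trial table TSV.
TRIAL_TABLE_COLUMNS = [
    "subject",            # subject identifier
    "excerpt_id",         # excerpt identifier (unique within subject+session)
    "familiarity_condition",   # "new" | "old"
    "pleasantness_index",      # time-weighted mean key in [1, 5]; NaN if halted
    "pleasantness_class",      # "least" | "most"; empty if not retained
    "familiarity_rating_exposure",      # 1-7; NaN for new excerpts
    "familiarity_rating_experimental",  # 1-7
    "retained",           # bool
    "rejection_reason",   # "" | "halted" | "familiar" | "eeg_artifact"
]


@dataclass(frozen=True)
class RatingStream:
    """Key-hold segments for one trial: (key, onset_s, offset_s)."""

    excerpt_id: str
    segments: tuple[tuple[int, float, float], ...]
    trial_duration_s: float

    def __post_init__(self) -> None:
        prev_off = 0.0
        for key, on, off in sorted(self.segments, key=lambda s: s[1]):
            if key not in (1, 2, 3, 4, 5):
                raise ValueError(f"key {key} outside 1..5")
            if not (0.0 <= on < off <= self.trial_duration_s):
                raise ValueError(
                    f"segment ({key}, {on}, {off}) outside [0, {self.trial_duration_s}]"
                )
            if on < prev_off - 1e-9:
                raise ValueError("overlapping key-hold segments")
            prev_off = off


def resolve_overlaps(
    raw_segments: list[tuple[int, float, float]], trial_duration_s: float
) -> tuple[tuple[int, float, float], ...]:
    """Truncate simultaneous key holds: the latest-onset key wins.

    Raw keyboard logs may contain a second key pressed before the first was
    released; the earlier segment is clipped at the later one's onset.
    """
    segs = sorted(raw_segments, key=lambda s: (s[1], s[2]))
    out: list[tuple[int, float, float]] = []
    for key, on, off in segs:
        off = min(off, trial_duration_s)
        while out and out[-1][1] >= on:
            out.pop()  # fully shadowed by the new press
        if out and out[-1][2] > on:
            k0, o0, _ = out[-1]
            out[-1] = (k0, o0, on)
        if off > on:
            out.append((key, on, off))
    return tuple(out)


def time_weighted_pleasantness(stream: RatingStream) -> float | None:
    """Hold-duration-weighted mean key value, or ``None`` if the trial halted.

    A trial halts (and is rejected) when no response begins strictly before
    half the excerpt has played.
    """
    if not stream.segments or min(s[1] for s in stream.segments) >= stream.trial_duration_s / 2:
        return None
    keys = np.array([s[0] for s in stream.segments], dtype=float)
    durs = np.array([s[2] - s[1] for s in stream.segments], dtype=float)
    return float(np.sum(keys * durs) / np.sum(durs))


def median_split(indices: "pd.Series | np.ndarray | list[float]") -> np.ndarray:
    """Dichotomize one subject's pleasantness indices at their median.

    Values below the median are "least" pleasant; values equal to or above
    it are "most" pleasant.  The midpoint-of-order-statistics median is used
    for even counts.
    """
    x = np.asarray(indices, dtype=float)
    if x.size < 2:
        raise ValueError("median split needs at least 2 retained trials")
    if np.isnan(x).any():
        raise ValueError("median split input contains NaN")
    med = float(np.median(x))
    if np.all(x == x[0]):
        warnings.warn("all pleasantness indices identical; every trial coded 'most'")
    return np.where(x >= med, MOST, LEAST)


def familiarity_reject(
    exposure_ratings: pd.DataFrame,
    experimental_ratings: pd.DataFrame,
    cutoff: int = FAMILIARITY_CUTOFF,
) -> dict[str, set[str]]:
    """Excerpts to drop per subject because they were already familiar.

    An excerpt is excluded from all of a subject's conditions when its
    familiarity rating exceeds ``cutoff`` in the exposure session, or in the
    new condition of the experimental session.  Rating frames need columns
    ``subject, excerpt_id, rating`` (experimental additionally
    ``familiarity_condition``).
    """
    for df, name in ((exposure_ratings, "exposure"), (experimental_ratings, "experimental")):
        r = df["rating"]
        if ((r < 1) | (r > 7)).any():
            raise ValueError(f"{name} familiarity ratings outside 1..7")
    excluded: dict[str, set[str]] = {}
    hits = exposure_ratings[exposure_ratings["rating"] > cutoff]
    for subj, exc in zip(hits["subject"], hits["excerpt_id"]):
        excluded.setdefault(str(subj), set()).add(str(exc))
    new_rows = experimental_ratings
    if "familiarity_condition" in experimental_ratings.columns:
        new_rows = experimental_ratings[experimental_ratings["familiarity_condition"] == "new"]
    hits = new_rows[new_rows["rating"] > cutoff]
    for subj, exc in zip(hits["subject"], hits["excerpt_id"]):
        excluded.setdefault(str(subj), set()).add(str(exc))
    return excluded


def assemble_trial_table(
    streams: dict[tuple[str, str], RatingStream],
    conditions: pd.DataFrame,
    exposure_ratings: pd.DataFrame,
    experimental_ratings: pd.DataFrame,
    familiarity_cutoff: int = FAMILIARITY_CUTOFF,
    eeg_rejected: set[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Join behavioral outputs into the analysis-ready trial table.

    Parameters
    ----------
    streams
        ``(subject, excerpt_id) -> RatingStream`` for the experimental
        session.
    conditions
        One row per (subject, excerpt_id) with ``familiarity_condition``.
    exposure_ratings, experimental_ratings
        Familiarity rating frames (see :func:`familiarity_reject`).
    eeg_rejected
        Trials dropped by the EEG amplitude criterion, flagged here so that
        the table carries every rejection reason in one place.
    """
    if conditions.duplicated(["subject", "excerpt_id"]).any():
        raise ValueError("duplicate (subject, excerpt_id) keys in conditions")
    for name, df in (("exposure", exposure_ratings), ("experimental", experimental_ratings)):
        if df.duplicated(["subject", "excerpt_id"]).any():
            raise ValueError(f"duplicate (subject, excerpt_id) keys in {name} ratings")
    eeg_rejected = eeg_rejected or set()
    familiar = familiarity_reject(exposure_ratings, experimental_ratings, familiarity_cutoff)

    exp_rate = {
        (str(s), str(e)): r
        for s, e, r in zip(
            experimental_ratings["subject"],
            experimental_ratings["excerpt_id"],
            experimental_ratings["rating"],
        )
    }
    expo_rate = {
        (str(s), str(e)): r
        for s, e, r in zip(
            exposure_ratings["subject"],
            exposure_ratings["excerpt_id"],
            exposure_ratings["rating"],
        )
    }

    rows = []
    for _, row in conditions.iterrows():
        subj, exc = str(row["subject"]), str(row["excerpt_id"])
        stream = streams.get((subj, exc))
        index = time_weighted_pleasantness(stream) if stream is not None else None
        reason = ""
        if exc in familiar.get(subj, set()):
            reason = "familiar"
        elif index is None:
            reason = HALTED
        elif (subj, exc) in eeg_rejected:
            reason = "eeg_artifact"
        rows.append(
            {
                "subject": subj,
                "excerpt_id": exc,
                "familiarity_condition": row["familiarity_condition"],
                "pleasantness_index": np.nan if index is None else index,
                "pleasantness_class": "",
                "familiarity_rating_exposure": expo_rate.get((subj, exc), np.nan),
                "familiarity_rating_experimental": exp_rate.get((subj, exc), np.nan),
                "retained": reason == "",
                "rejection_reason": reason,
            }
        )
    table = pd.DataFrame(rows, columns=TRIAL_TABLE_COLUMNS)

    for subj, grp in table[table["retained"]].groupby("subject"):
        labels = median_split(grp["pleasantness_index"])
        table.loc[grp.index, "pleasantness_class"] = labels

    for subj, grp in table.groupby("subject"):
        frac = 1.0 - grp["retained"].mean()
        logger.info("subject %s: rejected trial proportion %.4f", subj, frac)
    return table


def rejected_proportion(table: pd.DataFrame) -> pd.Series:
    """Per-subject proportion of rejected trials."""
    return table.groupby("subject")["retained"].apply(lambda r: 1.0 - r.mean())


def write_trial_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_trial_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(
        path,
        sep="\t",
        dtype={"subject": str, "excerpt_id": str},
        keep_default_na=False,
        na_values=[""],
    )
    table["retained"] = table["retained"].map(
        {"True": True, "False": False, True: True, False: False}
    )
    table["pleasantness_class"] = table["pleasantness_class"].fillna("")
    table["rejection_reason"] = table["rejection_reason"].fillna("")
    return table
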