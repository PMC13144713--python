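"""Validation, cleaning and summary of two-choice task trial tables.

The task is an emotional-faces gender-identification paradigm: up to 100
trials per subject, five emotion conditions with 20 faces each, responses
recorded as male/female (or none when the deadline passed).  Cleaning
follows the study-style rules:

* subjects are excluded when they completed fewer than 75 trials
  (omission rate > 25%) or their accuracy was below 55% (both strict);
* trials with RT below 200 ms are removed as fast guesses (strict
  less-than);
* exclusion accuracy is computed over completed trials *before* fast-guess
  removal (configurable).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

FAST_GUESS_CUTOFF = 0.200  # seconds; rt < cutoff removed
MIN_COMPLETED = 75
MIN_ACCURACY = 0.55
EMOTIONS = ("fearful", "happy", "angry", "sad", "neutral")

REQUIRED_COLUMNS = ["subject_id", "trial_index", "emotion", "stimulus_gender", "response", "rt_s"]

__all__ = [
    "SchemaError",
    "ExclusionReport",
    "load_trial_table",
    "validate_trial_table",
    "remove_fast_guesses",
    "apply_subject_exclusions",
    "summarize_performance",
]


class SchemaError(ValueError):
    """A trial table violates the documented schema."""


@dataclass
class ExclusionReport:
    """Per-subject completion/accuracy bookkeeping plus cohort totals."""

    table: pd.DataFrame  # subject_id, completed, accuracy, fast_guesses, excluded, reason
    n_input: int
    n_retained: int
    n_excluded: int

    def reason_for(self, subject_id) -> Optional[str]:
        row = self.table[self.table.subject_id == subject_id]
        if row.empty or not bool(row.iloc[0].excluded):
            return None
        return str(row.iloc[0].reason)


def validate_trial_table(df: pd.DataFrame) -> pd.DataFrame:
    """Type and invariant checks; returns a normalised copy.

    Omitted trials must carry ``response == 'none'`` and a missing rt;
    responded trials must carry a finite positive rt.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    df = df.copy()
    df["response"] = df["response"].fillna("none").astype(str).str.lower()
    df["stimulus_gender"] = df["stimulus_gender"].astype(str).str.lower()
    df["emotion"] = df["emotion"].astype(str).str.lower()

    rt = pd.to_numeric(df["rt_s"], errors="coerce")
    bad_rt = df.index[df["rt_s"].notna() & rt.isna()]
    if len(bad_rt):
        raise SchemaError(f"non-numeric rt_s at row(s) {list(bad_rt[:5])}")
    df["rt_s"] = rt

    bad_resp = ~df["response"].isin(["male", "female", "none"])
    if bad_resp.any():
        raise SchemaError(f"invalid response value at row(s) {list(df.index[bad_resp][:5])}")
    bad_gender = ~df["stimulus_gender"].isin(["male", "female"])
    if bad_gender.any():
        raise SchemaError(f"invalid stimulus_gender at row(s) {list(df.index[bad_gender][:5])}")
    bad_emotion = ~df["emotion"].isin(EMOTIONS)
    if bad_emotion.any():
        raise SchemaError(f"invalid emotion at row(s) {list(df.index[bad_emotion][:5])}")

    omitted = df["response"] == "none"
    rt_on_omitted = omitted & df["rt_s"].notna()
    if rt_on_omitted.any():
        raise SchemaError(
            f"rt present on omitted trial(s) at row(s) {list(df.index[rt_on_omitted][:5])}")
    rt_missing = ~omitted & df["rt_s"].isna()
    if rt_missing.any():
        raise SchemaError(
            f"rt missing on responded trial(s) at row(s) {list(df.index[rt_missing][:5])}")
    neg_rt = df["rt_s"].notna() & (df["rt_s"] <= 0)
    if neg_rt.any():
        raise SchemaError(f"non-positive rt at row(s) {list(df.index[neg_rt][:5])}")

    dup = df.duplicated(subset=["subject_id", "trial_index"])
    if dup.any():
        raise SchemaError(
            f"duplicate trial_index within subject at row(s) {list(df.index[dup][:5])}")
    counts = df.groupby("subject_id").size()
    too_many = counts[counts > 100]
    if len(too_many):
        raise SchemaError(f"more than 100 trials for subject(s) {list(too_many.index[:5])}")

    df["correct"] = (~omitted) & (df["response"] == df["stimulus_gender"])
    df["omitted"] = omitted
    return df


def load_trial_table(path: Union[str, Path]) -> pd.DataFrame:
    """Read and validate a trial CSV (columns: subject_id, trial_index,
    emotion, stimulus_gender, response, rt_s)."""
    df = pd.read_csv(path)
    return validate_trial_table(df)


def remove_fast_guesses(trials: pd.DataFrame, cutoff: float = FAST_GUESS_CUTOFF):
    """Drop responded trials with rt strictly below ``cutoff`` seconds.

    Omitted trials are untouched.  Returns (table, removed count); applying
    the filter twice equals applying it once.
    """
    fast = trials["rt_s"].notna() & (trials["rt_s"] < cutoff)
    return trials.loc[~fast].copy(), int(fast.sum())


def apply_subject_exclusions(
    trials: pd.DataFrame,
    accuracy_before_fast_guess_removal: bool = True,
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Exclude subjects with < 75 completed trials or accuracy < 0.55.

    A completed trial is any trial with a response, regardless of fast-guess
    status; by default exclusion accuracy is computed before fast-guess
    removal (set the flag to False for the other reading).
    """
    rows = []
    keep_ids = []
    for sid, g in trials.groupby("subject_id", sort=True):
        completed = int((~g["omitted"]).sum())
        fast = int((g["rt_s"].notna() & (g["rt_s"] < FAST_GUESS_CUTOFF)).sum())
        acc_base = g[~g["omitted"]]
        if not accuracy_before_fast_guess_removal:
            acc_base = acc_base[acc_base["rt_s"] >= FAST_GUESS_CUTOFF]
        accuracy = float(acc_base["correct"].mean()) if len(acc_base) else np.nan
        reasons = []
        if completed < MIN_COMPLETED:
            reasons.append("low-completion")
        if not np.isnan(accuracy) and accuracy < MIN_ACCURACY:
            reasons.append("low-accuracy")
        if np.isnan(accuracy):
            reasons.append("no-usable-trials")
        excluded = bool(reasons)
        if not excluded:
            keep_ids.append(sid)
        rows.append(dict(subject_id=sid, completed=completed, accuracy=accuracy,
                         fast_guesses=fast, excluded=excluded,
                         reason="+".join(reasons) if reasons else ""))
    report = pd.DataFrame(rows)
    out = trials[trials["subject_id"].isin(keep_ids)].copy()
    return out, ExclusionReport(
        table=report,
        n_input=report.shape[0],
        n_retained=len(keep_ids),
        n_excluded=report.shape[0] - len(keep_ids),
    )


def summarize_performance(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-subject completed count, accuracy and mean RT.

    Accuracy over completed trials; mean RT over non-omitted, non-fast-guess
    trials.  Subjects with zero usable trials are flagged, not averaged.
    """
    rows = []
    for sid, g in trials.groupby("subject_id", sort=True):
        comp = g[~g["omitted"]]
        usable = comp[comp["rt_s"] >= FAST_GUESS_CUTOFF]
        rows.append(dict(
            subject_id=sid,
            completed=len(comp),
            accuracy=float(comp["correct"].mean()) if len(comp) else np.nan,
            mean_rt=float(usable["rt_s"].mean()) if len(usable) else np.nan,
            n_usable=len(usable),
            flagged=len(usable) == 0,
        ))
    return pd.DataFrame(rows)
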