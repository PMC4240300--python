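"""Trial-level behavioural analysis: error taxonomy, trimming, indices.

Trial tables are pandas DataFrames with one row per naming trial.  Error
responses on flanked trials fall into three classes:

* Type A — no response (the target was never identified);
* Type B — the participant named a flanker instead of the target
  (e.g. stimulus Z N H answered "Z");
* Type C — the participant named a letter present in neither the target nor
  the flankers (e.g. Y M T answered "V", or 3 T 6 answered "C"), the class
  suggestive of perceptual integration of target and flanker features.

Latency analysis removes error/prompted/distracted trials, then trims
per-participant outliers beyond two standard deviations of the mean, and
works on inverse-transformed latencies (1/latency in 1/s).  Crowding indices
are raw correct-count differences between spacing or polarity conditions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import (
    DegenerateRangeError,
    InvalidLatencyError,
    InvalidResponseError,
    MissingColumnError,
)
from .stimuli import PERMITTED_TARGETS

#: Token recorded when the participant gave no response.
NO_RESPONSE = "NR"

#: Required columns of a trial table (TSV dialect: tab-delimited, header
#: mandatory, missing latency as empty field, no-response as ``NR``).
TRIAL_COLUMNS = [
    "participant_id",
    "group",
    "task",
    "spacing_condition",
    "polarity_condition",
    "target",
    "flanker_left",
    "flanker_right",
    "response",
    "prompted",
    "distracted",
    "latency_ms",
]

GROUPS = ("PCA", "tAD", "control")


def validate_trials(trials: pd.DataFrame) -> None:
    """Raise :class:`MissingColumnError` naming the first absent column."""
    for col in TRIAL_COLUMNS:
        if col not in trials.columns:
            raise MissingColumnError(col)


def read_trials(path) -> pd.DataFrame:
    str_cols = ["target", "response", "flanker_left", "flanker_right", "participant_id", "group"]
    trials = pd.read_csv(path, sep="\t", dtype={c: str for c in str_cols})
    validate_trials(trials)
    # unflanked trials carry empty flanker fields, not missing values
    for col in ("flanker_left", "flanker_right"):
        trials[col] = trials[col].fillna("")
    return trials


def write_trials(trials: pd.DataFrame, path) -> None:
    trials.to_csv(path, sep="\t", index=False)


def classify_error(
    target: str,
    flankers: tuple[str, str],
    response: str,
    permitted: tuple[str, ...] = PERMITTED_TARGETS,
) -> str:
    """Classify one flanked trial as correct / A / B / C.

    The classes partition all flanked trials: correct iff response equals the
    target; A iff no response; B iff the response names a flanker; C for any
    other letter.  Flanker order is irrelevant.
    """
    if response == NO_RESPONSE:
        return "A"
    if response == target:
        return "correct"
    if response in flankers:
        return "B"
    if response not in permitted:
        raise InvalidResponseError(
            f"response {response!r} is not a permitted letter or {NO_RESPONSE!r}"
        )
    return "C"


def classify_trials(trials: pd.DataFrame, permitted: tuple[str, ...] = PERMITTED_TARGETS) -> pd.DataFrame:
    """Return a copy with ``correct`` and (for flanked trials) ``error_class``.

    Task 1 (unflanked) rows receive ``error_class`` ``correct``/``A``/``C``
    by the same rules with an empty flanker set.
    """
    validate_trials(trials)
    out = trials.copy()
    cls = []
    for row in out.itertuples(index=False):
        fl = tuple(f for f in (row.flanker_left, row.flanker_right) if isinstance(f, str) and f)
        cls.append(classify_error(row.target, fl, row.response, permitted))
    out["error_class"] = cls
    out["correct"] = out["error_class"].eq("correct")
    return out


@dataclass(frozen=True)
class ErrorSummary:
    """Error rate and Type A/B/C composition of a set of flanked trials."""

    n_valid: int
    n_errors: int
    error_rate: float
    prop_a: float | None
    prop_b: float | None
    prop_c: float | None

    def as_dict(self) -> dict:
        return {
            "n_valid": self.n_valid,
            "n_errors": self.n_errors,
            "error_rate": self.error_rate,
            "prop_a": self.prop_a,
            "prop_b": self.prop_b,
            "prop_c": self.prop_c,
        }


def error_summary(trials: pd.DataFrame) -> ErrorSummary:
    """Overall error rate and the A/B/C proportions among error trials.

    Proportions are over error trials and sum to 1; with zero errors they are
    reported as ``None`` (undefined), never 0/0.
    """
    if len(trials) == 0:
        raise ValueError("empty trial set")
    t = trials if "error_class" in trials.columns else classify_trials(trials)
    n_valid = len(t)
    errors = t[t["error_class"] != "correct"]
    n_err = len(errors)
    if n_err == 0:
        return ErrorSummary(n_valid, 0, 0.0, None, None, None)
    counts = errors["error_class"].value_counts()
    return ErrorSummary(
        n_valid,
        n_err,
        n_err / n_valid,
        counts.get("A", 0) / n_err,
        counts.get("B", 0) / n_err,
        counts.get("C", 0) / n_err,
    )


def trim_latencies(trials: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Two-stage latency trimming with a conservation ledger.

    Stage 1 removes latencies of erroneous, prompted or distracted trials
    (and rows with no recorded latency).  Stage 2 computes each participant's
    mean and sample SD once, on the stage-1 survivors, and removes latencies
    more than two SDs from that mean.  Participants with fewer than two
    surviving latencies skip stage 2 and are flagged.

    Returns the retained rows and a ledger satisfying
    ``removed_stage1 + removed_stage2 + retained == total``.
    """
    t = trials if "error_class" in trials.columns else classify_trials(trials)
    lat = pd.to_numeric(t["latency_ms"], errors="coerce")
    bad = (
        (t["error_class"] != "correct")
        | t["prompted"].astype(bool)
        | t["distracted"].astype(bool)
        | lat.isna()
    )
    stage1 = t[~bad]
    removed2 = 0
    keep_idx = []
    skipped = []
    for pid, grp in stage1.groupby("participant_id", sort=False):
        x = pd.to_numeric(grp["latency_ms"]).to_numpy(dtype=float)
        if len(x) < 2:
            skipped.append(pid)
            keep_idx.extend(grp.index)
            continue
        mean, sd = x.mean(), x.std(ddof=1)
        keep = np.abs(x - mean) <= 2.0 * sd
        removed2 += int((~keep).sum())
        keep_idx.extend(grp.index[keep])
    retained = stage1.loc[sorted(keep_idx)]
    ledger = {
        "n_total": int(len(t)),
        "n_removed_stage1": int(bad.sum()),
        "n_removed_stage2": int(removed2),
        "n_retained": int(len(retained)),
        "stage2_skipped_participants": [str(p) for p in skipped],
    }
    assert ledger["n_removed_stage1"] + ledger["n_removed_stage2"] + ledger["n_retained"] == ledger["n_total"]
    return retained, ledger


def inverse_transform(latency_ms):
    """Reciprocal naming rate 1/latency in 1/s (800 ms -> 1.25 /s).

    Applied before linear latency models because raw latencies leave
    non-normal residuals; strictly decreasing in latency.
    """
    x = np.asarray(latency_ms, dtype=float)
    if np.any(x <= 0) or np.any(~np.isfinite(x)):
        raise InvalidLatencyError("latencies must be positive and finite")
    out = 1000.0 / x
    return float(out) if np.isscalar(latency_ms) else out


def standardize_scores(raw) -> np.ndarray:
    """Linear map of raw scores to 0-100 anchored at the observed min/max."""
    x = np.asarray(raw, dtype=float)
    if x.size < 2:
        raise DegenerateRangeError("need at least two scores to standardize")
    lo, hi = np.nanmin(x), np.nanmax(x)
    if hi == lo:
        raise DegenerateRangeError("max equals min; standardized range undefined")
    return 100.0 * (x - lo) / (hi - lo)


def composite_score(scores: pd.DataFrame) -> pd.Series:
    """Domain composite: mean of column-wise standardized member tests."""
    std = scores.apply(lambda c: pd.Series(standardize_scores(c), index=scores.index))
    return std.mean(axis=1)


INDEX_NAMES = (
    "spacing_shape",
    "spacing_number",
    "spacing_shapes_numbers",
    "polarity",
    "polarity_condensed",
)


def crowding_indices(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-participant crowding indices as raw correct-count differences.

    * ``spacing_shape`` / ``spacing_number``: spaced minus condensed correct
      counts in the shape (Task 3) / digit (Task 4) flanker task;
    * ``spacing_shapes_numbers``: Tasks 3 and 4 combined;
    * ``polarity``: reverse-polarity (Task 6) minus same-polarity (Task 5);
    * ``polarity_condensed``: the polarity difference in condensed trials only.

    Only unprompted first responses count toward accuracy.  A missing task
    yields a missing (NaN) index, never zero.
    """
    t = trials if "correct" in trials.columns else classify_trials(trials)
    t = t[~t["prompted"].astype(bool)]

    def ncorrect(g: pd.DataFrame, tasks, spacing=None):
        sel = g[g["task"].isin(tasks)]
        if spacing is not None:
            sel = sel[sel["spacing_condition"] == spacing]
        if len(sel) == 0:
            return None
        return int(sel["correct"].sum())

    rows = []
    for pid, g in t.groupby("participant_id", sort=False):
        def diff(tasks_a, tasks_b=None, spacing=None):
            if tasks_b is None:  # spaced - condensed within the same tasks
                a = ncorrect(g, tasks_a, "spaced")
                b = ncorrect(g, tasks_a, "condensed")
            else:  # tasks_a - tasks_b (reverse - same polarity)
                a = ncorrect(g, tasks_a, spacing)
                b = ncorrect(g, tasks_b, spacing)
            return np.nan if a is None or b is None else a - b

        rows.append(
            {
                "participant_id": pid,
                "group": g["group"].iloc[0],
                "spacing_shape": diff([3]),
                "spacing_number": diff([4]),
                "spacing_shapes_numbers": diff([3, 4]),
                "polarity": diff([6], [5]),
                "polarity_condensed": diff([6], [5], spacing="condensed"),
            }
        )
    return pd.DataFrame(rows)


def group_mean_indices(indices: pd.DataFrame) -> pd.DataFrame:
    """Group means of the per-participant crowding indices."""
    return indices.groupby("group")[list(INDEX_NAMES)].mean()
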