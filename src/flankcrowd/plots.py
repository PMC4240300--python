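"""Small plotting helpers (matplotlib, Agg-safe)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .groupstats import prepare_trials


def accuracy_by_condition(trials: pd.DataFrame, ax=None):
    """Group x spacing mean accuracy (flanked tasks), with SD bars."""
    t = prepare_trials(trials)
    t = t[t["task"] != 1]
    per = (
        t.groupby(["group", "spacing_condition", "participant_id"])["correct"]
        .mean()
        .mul(100)
        .reset_index()
    )
    agg = per.groupby(["group", "spacing_condition"])["correct"].agg(["mean", "std"]).reset_index()
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for i, group in enumerate(agg["group"].unique()):
        sub = agg[agg["group"] == group]
        ax.bar(
            [i * 3 + j for j in range(len(sub))],
            sub["mean"],
            yerr=sub["std"].fillna(0),
            tick_label=[f"{group}\n{s}" for s in sub["spacing_condition"]],
            capsize=3,
        )
    ax.set_ylabel("accuracy (%)")
    ax.set_ylim(0, 105)
    ax.set_title("Flanked letter identification accuracy")
    return ax


def model_coefficients(comparison, ax=None):
    """Forest plot of the similarity-model coefficients with 95% CIs."""
    table = comparison.table
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 0.6 * len(table) + 1))
    labels = [f"M{m} {t}" for m, t in zip(table["model"], table["term"])]
    y = range(len(table))
    ax.errorbar(table["coef"], y, xerr=1.96 * table["se"], fmt="o", capsize=3)
    ax.axvline(0.0, color="grey", lw=0.8)
    ax.set_yticks(list(y), labels)
    ax.set_xlabel("coefficient (log-odds per similarity unit)")
    ax.invert_yaxis()
    return ax
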