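"""Averaging vs. substitution: similarity models of error identity.

Three logistic mixed-effects models ask whether the identity of Type B/C
error responses is predicted by pixel-overlap similarity to

* Model 1 — the averaged target+flanker composite (``sim_avg``), testing the
  compulsory-averaging account of crowding;
* Model 2 — the individual flankers (``sim_left``, ``sim_right``), testing
  flanker substitution;
* Model 3 — individual flankers and the target (adds ``sim_target``).

Each error trial expands to one row per candidate letter (the permitted
alphabet minus the trial's target, since a target response would be correct):
the binary outcome marks the candidate actually reported, and the fixed
effects are the candidate's similarity values.  Crossed random intercepts on
participant and on candidate letter absorb participant-level error tendencies
and letter-level response popularity.
"""

from __future__ import annotations

import json
import string
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

from . import stimuli
from .exceptions import InconsistentDesignError, WrongErrorClassError
from .geometry import ViewingGeometry
from .mixedlogit import CrossedRandomLogit, CrossedRandomLogitResults
from .similarity import composite_average, pixel_overlap
from .stimuli import PERMITTED_TARGETS, render_glyph
from .taxonomy import classify_trials

MODEL_FEATURES = {
    1: ["sim_avg"],
    2: ["sim_left", "sim_right"],
    3: ["sim_left", "sim_right", "sim_target"],
}


class GlyphSet:
    """Rendered glyph cache with memoised pairwise and composite similarities.

    All letters (A-Z), digits 2-9 and the three triangle orientations are
    rendered once at a common geometry; similarity lookups are cached so that
    design construction and simulation stay cheap.
    """

    def __init__(self, geometry: ViewingGeometry | None = None,
                 height_deg: float = stimuli.DEFAULT_HEIGHT_DEG, align: bool = True):
        self.geometry = geometry or ViewingGeometry()
        self.height_deg = height_deg
        self.align = align
        symbols = list(string.ascii_uppercase) + list("23456789") + ["TRI0", "TRI120", "TRI240"]
        self._glyphs = {
            s: render_glyph(s, height_deg=height_deg, geometry=self.geometry, role="flanker")
            for s in symbols
        }
        self.permitted = PERMITTED_TARGETS
        self._sim = lru_cache(maxsize=None)(self._sim_uncached)
        self._composite_profile = lru_cache(maxsize=None)(self._composite_profile_uncached)

    def glyph(self, symbol: str):
        return self._glyphs[symbol]

    def _sim_uncached(self, a: str, b: str) -> float:
        if a > b:  # symmetry: canonical order halves the cache
            a, b = b, a
        return pixel_overlap(self._glyphs[a], self._glyphs[b], align=self.align)

    def sim(self, a: str, b: str) -> float:
        """Cached pixel-overlap similarity between two symbols."""
        return self._sim(a, b)

    def _composite_profile_uncached(self, target, left, right, polarity_condition):
        tg = self._glyphs[target]
        lf, rf = self._glyphs[left], self._glyphs[right]
        if polarity_condition == "reverse":
            lf, rf = lf.flipped(), rf.flipped()
        comp = composite_average(tg, (lf, rf))
        return {
            c: pixel_overlap(comp, self._glyphs[c], align=self.align) for c in self.permitted
        }

    def composite_profile(self, target, left, right, polarity_condition="same") -> dict:
        """Similarity of every permitted letter to the averaged array."""
        return self._composite_profile(target, left, right, polarity_condition)

    def nearest_letter(self, symbol: str) -> str:
        """Most similar permitted letter to an arbitrary symbol."""
        sims = {c: self.sim(symbol, c) for c in self.permitted}
        return max(sims, key=sims.get)

    def letter_matrix(self) -> pd.DataFrame:
        """Full permitted-letter similarity matrix (symmetric, unit diagonal)."""
        m = pd.DataFrame(
            [[self.sim(a, b) for b in self.permitted] for a in self.permitted],
            index=self.permitted,
            columns=self.permitted,
        )
        return m


_default_glyphset: GlyphSet | None = None


def default_glyphset() -> GlyphSet:
    global _default_glyphset
    if _default_glyphset is None:
        _default_glyphset = GlyphSet()
    return _default_glyphset


def build_design(
    error_trials: pd.DataFrame,
    model_id: int,
    glyphs: GlyphSet | None = None,
) -> pd.DataFrame:
    """Candidate-expansion design for one similarity model.

    ``error_trials`` must contain only Type B/C errors (flanked trials whose
    response is a letter other than the target); correct or no-response rows
    raise :class:`WrongErrorClassError`.  Every trial contributes one row per
    candidate letter with exactly one ``chosen = 1`` row.
    """
    if model_id not in MODEL_FEATURES:
        raise ValueError(f"model_id must be 1, 2 or 3, got {model_id}")
    glyphs = glyphs or default_glyphset()
    t = error_trials if "error_class" in error_trials.columns else classify_trials(error_trials)
    bad = ~t["error_class"].isin(["B", "C"])
    if bad.any():
        raise WrongErrorClassError(
            f"{int(bad.sum())} trial(s) are not Type B/C errors "
            f"(classes: {sorted(t.loc[bad, 'error_class'].unique())})"
        )
    unflanked = (t["flanker_left"] == "") | (t["flanker_right"] == "")
    if unflanked.any():
        raise WrongErrorClassError(
            f"{int(unflanked.sum())} trial(s) have no flankers; the similarity "
            "models apply to flanked (Tasks 2-6) errors only"
        )
    feats = MODEL_FEATURES[model_id]
    rows = []
    for trial_id, row in enumerate(t.itertuples(index=False)):
        pol = row.polarity_condition if row.polarity_condition in ("same", "reverse") else "same"
        if model_id == 1:
            profile = glyphs.composite_profile(row.target, row.flanker_left, row.flanker_right, pol)
        for cand in glyphs.permitted:
            if cand == row.target:
                continue  # choosing the target would not be an error
            r = {
                "trial_id": trial_id,
                "participant_id": row.participant_id,
                "candidate": cand,
                "chosen": int(cand == row.response),
            }
            if model_id == 1:
                r["sim_avg"] = profile[cand]
            else:
                r["sim_left"] = glyphs.sim(cand, row.flanker_left)
                r["sim_right"] = glyphs.sim(cand, row.flanker_right)
                if model_id == 3:
                    r["sim_target"] = glyphs.sim(cand, row.target)
            rows.append(r)
    design = pd.DataFrame(rows)
    chosen_per_trial = design.groupby("trial_id")["chosen"].sum()
    if not (chosen_per_trial == 1).all():
        raise WrongErrorClassError("each trial must have exactly one chosen candidate")
    return design[["trial_id", "participant_id", "candidate", "chosen"] + feats]


class CrowdingErrorModel:
    """Statsmodels-style front end for one of the three similarity models.

    Build with :meth:`from_trials` (classifies, filters to Type B/C and
    expands candidates) or directly from a prepared design table; ``fit``
    returns a :class:`~flankcrowd.mixedlogit.CrossedRandomLogitResults`.
    """

    def __init__(self, design: pd.DataFrame, model_id: int):
        self.model_id = model_id
        self.design = design
        feats = MODEL_FEATURES[model_id]
        X = np.column_stack(
            [np.ones(len(design))] + [design[f].to_numpy(dtype=float) for f in feats]
        )
        self._core = CrossedRandomLogit(
            design["chosen"].to_numpy(),
            X,
            design["participant_id"],
            design["candidate"],
            exog_names=["const"] + feats,
            group_names=("participant", "error_response"),
        )

    @classmethod
    def from_trials(cls, trials: pd.DataFrame, model_id: int,
                    glyphs: GlyphSet | None = None) -> "CrowdingErrorModel":
        t = trials if "error_class" in trials.columns else classify_trials(trials)
        flanked = t[(t["flanker_left"] != "") & (t["flanker_right"] != "")]
        errors = flanked[flanked["error_class"].isin(["B", "C"])]
        return cls(build_design(errors, model_id, glyphs), model_id)

    @property
    def n_trials(self) -> int:
        return self.design["trial_id"].nunique()

    def fit(self, **kwargs) -> CrossedRandomLogitResults:
        return self._core.fit(**kwargs)


def fit_logistic_mixed(design: pd.DataFrame, model_id: int, **kwargs) -> CrossedRandomLogitResults:
    """Fit one similarity model from its prepared design table."""
    return CrowdingErrorModel(design, model_id).fit(**kwargs)


@dataclass
class ModelComparison:
    """Tabulated comparison of the three fitted similarity models."""

    table: pd.DataFrame
    alpha: float
    n_trials: int
    averaging_supported: bool
    substitution_supported: bool
    supported_account: str

    def to_json(self) -> str:
        return json.dumps(
            {
                "alpha": self.alpha,
                "n_trials": self.n_trials,
                "averaging_supported": self.averaging_supported,
                "substitution_supported": self.substitution_supported,
                "supported_account": self.supported_account,
                "coefficients": self.table.to_dict(orient="records"),
            },
            indent=2,
        )

    def __str__(self) -> str:
        return (
            f"Similarity-model comparison over {self.n_trials} Type B/C errors "
            f"(alpha={self.alpha})\n"
            f"  averaging supported:    {self.averaging_supported}\n"
            f"  substitution supported: {self.substitution_supported}\n"
            f"  supported account:      {self.supported_account}\n\n"
            + self.table.to_string(index=False, float_format=lambda v: f"{v: .4f}")
        )


def compare_models(fits: dict[int, CrossedRandomLogitResults], alpha: float = 0.05) -> ModelComparison:
    """Compare the averaging and substitution accounts across Models 1-3.

    The averaging account is supported when the Model 1 composite-similarity
    coefficient is significantly positive; the substitution account when any
    individual-flanker coefficient in Models 2-3 is.  When both reach
    significance the account with the stronger evidence (larger Wald z) is
    reported as supported.  All fits must come from the same trial set.
    """
    if set(fits) != {1, 2, 3}:
        raise ValueError("fits for models 1, 2 and 3 required")
    nobs = {m: f.nobs for m, f in fits.items()}
    # Models 1-3 expand the same trials over the same candidate sets minus the
    # target, so the (trial x candidate) row count must agree exactly.
    if len(set(nobs.values())) != 1:
        raise InconsistentDesignError(f"designs differ in size across models: {nobs}")
    rows = []
    for m in (1, 2, 3):
        frame = fits[m].to_frame()
        for term, rec in frame.iterrows():
            if term == "const":
                continue
            rows.append(
                {
                    "model": m,
                    "term": term,
                    "coef": rec["coef"],
                    "se": rec["se"],
                    "z": rec["z"],
                    "p": rec["p"],
                    "significant": rec["p"] < alpha,
                    "converged": fits[m].converged,
                }
            )
    table = pd.DataFrame(rows)

    # both accounts predict POSITIVE similarity effects, so support requires a
    # significantly positive coefficient
    avg_row = table[(table["model"] == 1) & (table["term"] == "sim_avg")].iloc[0]
    avg_sig = bool(avg_row["significant"] and avg_row["coef"] > 0)
    flanker = table[table["term"].isin(["sim_left", "sim_right"])]
    fl_sig = bool((flanker["significant"] & (flanker["coef"] > 0)).any())
    z_avg = float(avg_row["z"])
    z_fl = float(flanker["z"].max())
    if avg_sig and not fl_sig:
        account = "averaging"
    elif fl_sig and not avg_sig:
        account = "substitution"
    elif avg_sig and fl_sig:
        account = "averaging" if z_avg >= z_fl else "substitution"
    else:
        account = "indeterminate"
    # each trial contributes (alphabet - 1) candidate rows
    n_trials = fits[1].nobs // (len(PERMITTED_TARGETS) - 1)
    return ModelComparison(
        table=table,
        alpha=alpha,
        n_trials=n_trials,
        averaging_supported=avg_sig,
        substitution_supported=fl_sig,
        supported_account=account,
    )
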