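"""Group-level contrasts with cluster-robust standard errors.

Accuracy is modelled with logistic regression and naming speed with a linear
model on inverse-transformed latency (the latency model includes accuracy as
a covariate); both use sandwich standard errors clustered by participant to
absorb the correlation of repeated trials within a person.  Point estimates
come from the ordinary (quasi-)likelihood fit via statsmodels; the default
sandwich is CR0 (no small-sample correction), with CR1 available.

Also provides Wilcoxon rank-sum / signed-rank utilities (exact null
distribution for small samples via scipy) and a covariate-adjustment screen
that asks which standardized behavioural covariates, if any, absorb an
effect of interest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.genmod.families import Binomial

from .exceptions import DegenerateCovariateError, RobustSEError, SeparationWarning
from .taxonomy import classify_trials

#: Flanker category by task number.
TASK_FLANKER_CATEGORY = {1: "none", 2: "letter", 3: "shape", 4: "digit", 5: "letter", 6: "letter"}


@dataclass(frozen=True)
class ContrastSpec:
    """What to model and how.

    ``outcome`` fixes the model family: accuracy -> logistic, latency ->
    linear on 1/latency with accuracy as a covariate.  ``terms`` are the
    within-participant factors of interest; interactions among them and (when
    several groups are present) with group are included.
    """

    outcome: str = "accuracy"  # or "latency"
    terms: tuple = ("spacing_condition", "flanker_category")
    group_interactions: bool = True
    covariate: str | None = None
    cluster: str = "participant_id"
    cov: str = "CR0"  # or "CR1" (small-sample corrected)

    def __post_init__(self) -> None:
        if self.outcome not in ("accuracy", "latency"):
            raise ValueError("outcome must be 'accuracy' or 'latency'")
        if self.cov not in ("CR0", "CR1"):
            raise ValueError("cov must be 'CR0' or 'CR1'")


def prepare_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Add derived modelling columns (correct, flanker_category, inv_latency)."""
    t = trials if "correct" in trials.columns else classify_trials(trials)
    t = t.copy()
    t["correct"] = t["correct"].astype(int)
    t["flanker_category"] = t["task"].map(TASK_FLANKER_CATEGORY)
    lat = pd.to_numeric(t["latency_ms"], errors="coerce")
    t["inv_latency"] = np.where(lat > 0, 1000.0 / lat, np.nan)
    return t


def _build_formula(df: pd.DataFrame, spec: ContrastSpec) -> str:
    lhs = "correct" if spec.outcome == "accuracy" else "inv_latency"
    usable = [term for term in spec.terms if df[term].nunique() > 1]
    if not usable:
        raise ValueError("no non-constant terms to model")
    parts = [" * ".join(f"C({t})" for t in usable)]
    if df["group"].nunique() > 1:
        # diagnosis always enters as a main effect; factor-by-group
        # interactions are optional
        if spec.group_interactions:
            parts += [f"C({t}) * C(group)" for t in usable]
        else:
            parts.append("C(group)")
    if spec.outcome == "latency":
        parts.append("correct")
    if spec.covariate is not None:
        if df[spec.covariate].nunique() <= 1:
            raise DegenerateCovariateError(f"covariate {spec.covariate!r} is constant")
        parts.append(spec.covariate)
    return lhs + " ~ " + " + ".join(parts)


def fit_cluster_robust(trials: pd.DataFrame, spec: ContrastSpec | None = None):
    """Fit the contrast model with participant-clustered sandwich SEs.

    Returns the statsmodels results object (robust covariance attached);
    use :func:`coef_table` for a tidy coefficient frame.
    """
    spec = spec or ContrastSpec()
    df = prepare_trials(trials)
    if spec.outcome == "latency":
        df = df[df["inv_latency"].notna()]
    # unflanked (task 1) rows carry "none" levels for the flanked factors
    for term in spec.terms:
        df = df[df[term] != "none"]
    n_clusters = df[spec.cluster].nunique()
    if n_clusters < 2:
        raise RobustSEError("cluster-robust SEs require at least two participants")
    formula = _build_formula(df, spec)
    cov_kwds = {
        "groups": df[spec.cluster],
        "use_correction": spec.cov == "CR1",
        "df_correction": spec.cov == "CR1",
    }
    if spec.outcome == "accuracy":
        model = smf.glm(formula, data=df, family=Binomial())
    else:
        model = smf.ols(formula, data=df)
    results = model.fit(cov_type="cluster", cov_kwds=cov_kwds)
    if spec.outcome == "accuracy" and np.abs(results.params).max() > 15.0:
        warnings.warn(
            "possible (quasi-)separation in the accuracy model (a cell at "
            "floor/ceiling); interpret the affected coefficients with care",
            SeparationWarning,
            stacklevel=2,
        )
    return results


def coef_table(results) -> pd.DataFrame:
    """Tidy coefficient table (estimate, robust SE, z/t, p) for TSV export."""
    return pd.DataFrame(
        {
            "coef": results.params,
            "robust_se": results.bse,
            "stat": results.tvalues,
            "p": results.pvalues,
        }
    )


def find_effect(results, effect: str) -> pd.Series:
    """Row of the coefficient table whose name contains ``effect``."""
    table = coef_table(results)
    hits = [name for name in table.index if effect in name]
    if not hits:
        raise KeyError(f"no coefficient matching {effect!r}; have {list(table.index)}")
    return table.loc[hits[0]]


@dataclass
class AdjustmentReport:
    """Per-covariate record of whether an effect of interest survives."""

    effect: str
    table: pd.DataFrame = field(repr=False)

    def absorbed_by(self, alpha: float = 0.05) -> list[str]:
        t = self.table
        return list(t.loc[(t["covariate"] != "<none>") & (t["p"] >= alpha), "covariate"])

    def __str__(self) -> str:
        return (
            f"Covariate adjustment for effect {self.effect!r}\n"
            + self.table.to_string(index=False, float_format=lambda v: f"{v: .4f}")
        )


def covariate_adjustment(
    trials: pd.DataFrame,
    covariates: pd.DataFrame,
    effect: str,
    spec: ContrastSpec | None = None,
    alpha: float = 0.05,
) -> AdjustmentReport:
    """Refit the contrast once per covariate; report effect retention.

    ``covariates`` is indexed by participant_id with one standardized (0-100)
    score per column.  The report's first row is the unadjusted fit; an
    effect is "retained" when its robust p-value stays below ``alpha`` after
    adjustment.  An empty covariate frame reproduces the unadjusted fit only.
    """
    spec = spec or ContrastSpec()
    base = fit_cluster_robust(trials, spec)
    rows = []

    def record(name, results):
        est = find_effect(results, effect)
        rows.append(
            {
                "covariate": name,
                "coef": est["coef"],
                "robust_se": est["robust_se"],
                "stat": est["stat"],
                "p": est["p"],
                "retained": est["p"] < alpha,
            }
        )

    record("<none>", base)
    for name in covariates.columns:
        merged = trials.merge(
            covariates[[name]], left_on="participant_id", right_index=True, how="inner"
        )
        spec_cov = ContrastSpec(
            outcome=spec.outcome,
            terms=spec.terms,
            group_interactions=spec.group_interactions,
            covariate=name,
            cluster=spec.cluster,
            cov=spec.cov,
        )
        record(name, fit_cluster_robust(merged, spec_cov))
    return AdjustmentReport(effect=effect, table=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Wilcoxon utilities

def rank_sum_test(x, y) -> tuple[float, float]:
    """Wilcoxon rank-sum (Mann-Whitney) between-group comparison.

    Exact null distribution when both samples have n <= 25 and no ties;
    otherwise the tie-corrected normal approximation.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    no_ties = len(np.unique(np.concatenate([x, y]))) == len(x) + len(y)
    method = "exact" if (len(x) <= 25 and len(y) <= 25 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def signed_rank_test(x, y=None) -> tuple[float, float]:
    """Wilcoxon signed-rank within-group comparison (paired when y given)."""
    x = np.asarray(x, float)
    d = x if y is None else x - np.asarray(y, float)
    d = d[d != 0]
    if len(d) == 0:
        return 0.0, 1.0
    no_ties = len(np.unique(np.abs(d))) == len(d)
    method = "exact" if (len(d) <= 25 and no_ties) else "approx"
    res = stats.wilcoxon(d, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def holm_correction(pvalues) -> np.ndarray:
    """Holm step-down adjusted p-values (off by default, matching the
    package's unadjusted reporting style)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(pvalues, float), method="holm")[1]
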