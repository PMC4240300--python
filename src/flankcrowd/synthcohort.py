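"""Synthetic flanked-letter-identification cohorts with planted mechanisms.

Generates trial tables with the structure the analysis pipeline assumes:
three groups (default 26 PCA-like, 17 tAD-like, 14 controls), Tasks 1-6,
spacing- and polarity-modulated crowding errors, and contaminated latencies.

The generative model per flanked trial: a crowding strength

    s(gap, polarity) = max(0, 1 - gap / critical_spacing)^k * (rho if reverse)

multiplies three mechanism weights into event probabilities -

* masking  (prob ``s * w_mask``)  -> no response (Type A);
* substitution (``s * w_subst``) -> a flanker is named (Type B; non-letter
  flankers map to the most similar permitted letter, usually Type C);
* averaging (``s * w_avg``)      -> a letter is sampled with probability
  proportional to ``exp(beta_avg * similarity to the averaged array)``;
* otherwise the target is named correctly (up to a small lapse rate).

With the default central critical spacing of 1.2 deg the condensed gap
(0.1 deg) sits deep inside and the spaced gap (1.0 deg) near the edge of the
interference zone, reproducing the condensed << spaced accuracy ordering;
reverse polarity attenuates the strength by ``rho``.  Latencies are a base
plus a crowding cost proportional to strength plus lognormal noise, with
rare scale-5 outlier contamination.  Everything is driven by one integer
seed through numpy's Generator, so identical configs give identical tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errormodels import GlyphSet, default_glyphset
from .stimuli import GAP_DEG, PERMITTED_TARGETS
from .taxonomy import NO_RESPONSE, TRIAL_COLUMNS


@dataclass(frozen=True)
class MechanismParams:
    """Crowding-mechanism weights and interference-zone geometry.

    ``w_mask + w_subst + w_avg`` must not exceed 1; the remainder (scaled by
    crowding strength) is the floor probability of a correct response.
    ``critical_spacing_deg`` is the central-vision interference range per
    participant; ``critical_spacing_fraction`` is the classical Bouma
    fraction (critical spacing as a fraction of eccentricity) kept for
    peripheral-target configurations.  ``rho`` in [0, 1] is the multiplier
    applied under reverse-polarity flankers.
    """

    w_avg: float = 0.105
    w_subst: float = 0.105
    w_mask: float = 0.09
    beta_avg: float = 4.0
    critical_spacing_deg: float = 1.2
    crowding_exponent: float = 1.0
    rho: float = 0.5
    critical_spacing_fraction: float = 0.5
    lapse_rate: float = 0.0

    def __post_init__(self) -> None:
        w = (self.w_avg, self.w_subst, self.w_mask)
        if any(x < 0 for x in w):
            raise ValueError("mechanism weights must be nonnegative")
        if sum(w) > 1.0 + 1e-12:
            raise ValueError("mechanism weights must sum to <= 1")
        if not (0.0 <= self.rho <= 1.0):
            raise ValueError("rho must lie in [0, 1]")
        if self.critical_spacing_deg <= 0:
            raise ValueError("critical spacing must be positive")

    def crowding_strength(self, gap_deg: float, polarity_condition: str = "same") -> float:
        """Interference multiplier in [0, 1]; 0 at or beyond critical spacing."""
        s = max(0.0, 1.0 - gap_deg / self.critical_spacing_deg) ** self.crowding_exponent
        if polarity_condition == "reverse":
            s *= self.rho
        return s

    @property
    def dominant_mechanism(self) -> str:
        w = {"averaging": self.w_avg, "substitution": self.w_subst, "masking": self.w_mask}
        if all(v == 0 for v in w.values()):
            return "none"
        return max(w, key=w.get)


def default_group_params() -> dict:
    """Per-group mechanism defaults.

    The PCA-like group engages crowding on ~30% of maximally crowded trials
    with an approximately even masking/substitution/averaging split (yielding
    roughly balanced Type A/B/C errors and a condensed accuracy near 72%);
    the tAD-like group is near ceiling; controls never err on flanked trials.
    """
    return {
        "PCA": MechanismParams(w_avg=0.105, w_subst=0.105, w_mask=0.09, lapse_rate=0.002),
        "tAD": MechanismParams(w_avg=0.0035, w_subst=0.0035, w_mask=0.003),
        "control": MechanismParams(w_avg=0.0, w_subst=0.0, w_mask=0.0),
    }


@dataclass(frozen=True)
class CohortConfig:
    """Full cohort recipe; the seed is mandatory for reproducibility."""

    seed: int
    n_pca: int = 26
    n_tad: int = 17
    n_control: int = 14
    group_params: dict = field(default_factory=default_group_params)
    items_per_task: int = 24  # flanked items per task, split over two spacings
    unflanked_items: int = 20
    participant_sd: float = 0.3  # lognormal frailty on mechanism engagement
    latency_base_ms: dict = field(
        default_factory=lambda: {"PCA": 600.0, "tAD": 400.0, "control": 350.0}
    )
    latency_crowding_cost_ms: dict = field(
        default_factory=lambda: {"PCA": 1500.0, "tAD": 100.0, "control": 80.0}
    )
    latency_noise_scale_ms: float = 150.0
    latency_sigma: float = 0.6
    outlier_prob: float = 0.02
    outlier_scale: float = 5.0
    distract_prob: float = 0.01

    def __post_init__(self) -> None:
        if not isinstance(self.seed, (int, np.integer)):
            raise ValueError("seed is mandatory and must be an integer")
        if min(self.n_pca, self.n_tad, self.n_control) < 1:
            raise ValueError("group sizes must be >= 1")
        if self.items_per_task % 2 != 0:
            raise ValueError("items_per_task must be even (two spacing conditions)")


TASK_POLARITY = {1: "none", 2: "none", 3: "none", 4: "none", 5: "same", 6: "reverse"}


def _sample_flankers(task: int, target: str, rng: np.random.Generator) -> tuple[str, str]:
    if task == 3:
        tris = ("TRI0", "TRI120", "TRI240")
        return tuple(rng.choice(tris, size=2, replace=False))
    if task == 4:
        return tuple(rng.choice(list("23456789"), size=2, replace=False))
    pool = [c for c in PERMITTED_TARGETS if c != target]
    return tuple(rng.choice(pool, size=2, replace=False))


def simulate_trial(
    target: str,
    flankers: tuple[str, str],
    spacing_condition: str,
    polarity_condition: str,
    params: MechanismParams,
    frailty: float,
    rng: np.random.Generator,
    glyphs: GlyphSet,
    latency_base: float,
    latency_cost: float,
    config: CohortConfig,
) -> dict:
    """Draw one flanked naming trial under the mechanism mixture."""
    gap = GAP_DEG[spacing_condition]
    s = params.crowding_strength(gap, polarity_condition)
    # frailty scales engagement but can never push the mixture past 1
    total_w = params.w_mask + params.w_subst + params.w_avg
    f = frailty if total_w * frailty <= 1.0 else 1.0 / total_w
    p_mask = s * params.w_mask * f
    p_subst = s * params.w_subst * f
    p_avg = s * params.w_avg * f

    u = rng.random()
    if u < p_mask:
        response = NO_RESPONSE
    elif u < p_mask + p_subst:
        side = flankers[int(rng.random() < 0.5)]
        response = side if side in PERMITTED_TARGETS else glyphs.nearest_letter(side)
    elif u < p_mask + p_subst + p_avg:
        # integration error: a letter combining target and flanker features is
        # named.  Verbatim reports of array items are the signature of the
        # substitution (flanker) or correct (target) channels, so the pooled
        # percept is named from the letters NOT present in the array.
        pol = polarity_condition if polarity_condition in ("same", "reverse") else "same"
        profile = glyphs.composite_profile(target, flankers[0], flankers[1], pol)
        letters = [c for c in profile if c != target and c not in flankers]
        logits = params.beta_avg * np.array([profile[c] for c in letters])
        p = np.exp(logits - logits.max())
        p /= p.sum()
        response = letters[rng.choice(len(letters), p=p)]
    elif rng.random() < params.lapse_rate:
        others = [c for c in PERMITTED_TARGETS if c != target]
        response = others[rng.integers(len(others))]
    else:
        response = target

    prompted = response != target and response != NO_RESPONSE and response in flankers
    distracted = bool(rng.random() < config.distract_prob)
    latency = (
        latency_base
        + latency_cost * s
        + rng.lognormal(mean=np.log(config.latency_noise_scale_ms), sigma=config.latency_sigma)
    )
    if rng.random() < config.outlier_prob:
        latency *= config.outlier_scale
    return {
        "target": target,
        "flanker_left": flankers[0],
        "flanker_right": flankers[1],
        "response": response,
        "prompted": prompted,
        "distracted": distracted,
        "latency_ms": round(float(latency), 1),
    }


def _abba_order(n_blocks: int) -> list[str]:
    """Spacing condition per block in an ABBA sequence (A=condensed)."""
    pattern = ["condensed", "spaced", "spaced", "condensed"]
    return [pattern[i % 4] for i in range(n_blocks)]


def simulate_participant(
    pid: str,
    group: str,
    params: MechanismParams,
    frailty: float,
    rng: np.random.Generator,
    glyphs: GlyphSet,
    config: CohortConfig,
) -> list[dict]:
    rows = []
    base = config.latency_base_ms[group]
    cost = config.latency_crowding_cost_ms[group]

    # Task 1: unflanked letters, fixation box 3.2 x 2.9 deg
    targets = list(rng.permutation(PERMITTED_TARGETS))[: config.unflanked_items]
    for tgt in targets:
        lapse = rng.random() < params.lapse_rate
        others = [c for c in PERMITTED_TARGETS if c != tgt]
        response = others[rng.integers(len(others))] if lapse else tgt
        latency = base + rng.lognormal(np.log(config.latency_noise_scale_ms), config.latency_sigma)
        if rng.random() < config.outlier_prob:
            latency *= config.outlier_scale
        rows.append(
            {
                "participant_id": pid,
                "group": group,
                "task": 1,
                "spacing_condition": "none",
                "polarity_condition": "none",
                "target": tgt,
                "flanker_left": "",
                "flanker_right": "",
                "response": response,
                "prompted": False,
                "distracted": bool(rng.random() < config.distract_prob),
                "latency_ms": round(float(latency), 1),
            }
        )

    n_per_cond = config.items_per_task // 2
    for task in (2, 3, 4, 5, 6):
        # one item = target + fixed flanker pair, probed in both spacings
        n_distinct = min(n_per_cond, len(PERMITTED_TARGETS))
        targets = list(rng.choice(PERMITTED_TARGETS, size=n_distinct, replace=False))
        while len(targets) < n_per_cond:  # items-per-task above 40: repeat targets
            targets.append(str(rng.choice(PERMITTED_TARGETS)))
        items = [(tgt, _sample_flankers(task, tgt, rng)) for tgt in targets]
        polarity = TASK_POLARITY[task]
        trial_list = []
        for spacing in ("condensed", "spaced"):
            for tgt, fl in items:
                trial_list.append((spacing, tgt, fl))
        # ABBA block order over spacing conditions, blocks of 6
        by_spacing = {
            "condensed": [t for t in trial_list if t[0] == "condensed"],
            "spaced": [t for t in trial_list if t[0] == "spaced"],
        }
        ordered = []
        n_blocks = max(1, len(trial_list) // 6)
        for cond in _abba_order(n_blocks):
            take, by_spacing[cond] = by_spacing[cond][:6], by_spacing[cond][6:]
            ordered.extend(take)
        ordered.extend(by_spacing["condensed"] + by_spacing["spaced"])
        for spacing, tgt, fl in ordered:
            rec = simulate_trial(
                tgt, fl, spacing, polarity, params, frailty, rng, glyphs, base, cost, config
            )
            rec.update(
                participant_id=pid,
                group=group,
                task=task,
                spacing_condition=spacing,
                polarity_condition=polarity,
            )
            rows.append(rec)
    return rows


def simulate_cohort(config: CohortConfig, glyphs: GlyphSet | None = None) -> pd.DataFrame:
    """Simulate the full three-group cohort; same seed, same table."""
    glyphs = glyphs or default_glyphset()
    rng = np.random.default_rng(config.seed)
    rows = []
    roster = (
        [("PCA", f"PCA{i + 1:02d}") for i in range(config.n_pca)]
        + [("tAD", f"TAD{i + 1:02d}") for i in range(config.n_tad)]
        + [("control", f"CTL{i + 1:02d}") for i in range(config.n_control)]
    )
    for group, pid in roster:
        params = config.group_params[group]
        frailty = float(rng.lognormal(mean=0.0, sigma=config.participant_sd))
        rows.extend(simulate_participant(pid, group, params, frailty, rng, glyphs, config))
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def planted_truth(config: CohortConfig) -> dict:
    """Ground-truth record of the generating mechanisms, for recovery scoring."""
    out = {"seed": int(config.seed), "groups": {}}
    for group, params in config.group_params.items():
        out["groups"][group] = {
            "weights": {"w_avg": params.w_avg, "w_subst": params.w_subst, "w_mask": params.w_mask},
            "beta_avg": params.beta_avg,
            "critical_spacing_deg": params.critical_spacing_deg,
            "rho": params.rho,
            "strength_condensed": params.crowding_strength(GAP_DEG["condensed"]),
            "strength_spaced": params.crowding_strength(GAP_DEG["spaced"]),
            "strength_condensed_reverse": params.crowding_strength(GAP_DEG["condensed"], "reverse"),
            "mechanism": params.dominant_mechanism,
        }
    return out


def simulate_error_trials(
    n_participants: int,
    n_errors_per_participant: int,
    mechanism: str,
    seed: int,
    beta_avg: float = 4.0,
    subst_fidelity: float = 0.9,
    glyphs: GlyphSet | None = None,
    group: str = "PCA",
) -> pd.DataFrame:
    """Directly generate Type B/C error trials under one pure mechanism.

    A focused generator for mechanism-recovery and calibration simulations:
    every trial is an error on a condensed letter-flanker array.

    * ``"averaging"``: an integration error - the response is drawn over the
      letters not present in the array with probability proportional to
      exp(beta_avg * similarity to the averaged target/flanker composite);
    * ``"substitution"``: the response names one flanker (chosen at random)
      with probability ``subst_fidelity``, otherwise a uniform other letter;
    * ``"null"``: the response is uniform over non-target letters
      (similarity plays no role; the null for calibration checks).
    """
    if mechanism not in ("averaging", "substitution", "null"):
        raise ValueError(f"unknown mechanism {mechanism!r}")
    glyphs = glyphs or default_glyphset()
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_participants):
        pid = f"SIM{i + 1:02d}"
        for _ in range(n_errors_per_participant):
            target = str(rng.choice(PERMITTED_TARGETS))
            fl = _sample_flankers(2, target, rng)
            candidates = [c for c in PERMITTED_TARGETS if c != target]
            if mechanism == "averaging":
                profile = glyphs.composite_profile(target, fl[0], fl[1], "same")
                pool = [c for c in candidates if c not in fl]
                logits = beta_avg * np.array([profile[c] for c in pool])
                p = np.exp(logits - logits.max())
                p /= p.sum()
                response = pool[rng.choice(len(pool), p=p)]
            elif mechanism == "substitution":
                if rng.random() < subst_fidelity:
                    response = fl[int(rng.random() < 0.5)]
                else:
                    pool = [c for c in candidates if c not in fl]
                    response = pool[rng.integers(len(pool))]
            else:
                response = candidates[rng.integers(len(candidates))]
            rows.append(
                {
                    "participant_id": pid,
                    "group": group,
                    "task": 2,
                    "spacing_condition": "condensed",
                    "polarity_condition": "none",
                    "target": target,
                    "flanker_left": fl[0],
                    "flanker_right": fl[1],
                    "response": response,
                    "prompted": False,
                    "distracted": False,
                    "latency_ms": 1000.0,
                }
            )
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def sample_design_choices(design: pd.DataFrame, beta: float, feature: str,
                          seed: int) -> pd.DataFrame:
    """Resample the chosen candidate of every trial from the model family.

    Draws each trial's response over the design's own candidate rows with
    probability proportional to ``exp(beta * feature)`` - the data-generating
    process the candidate-expansion logistic model estimates - and returns a
    copy of the design with the new ``chosen`` column.  Used to calibrate and
    validate the estimator (parameter recovery, type-I error at ``beta = 0``)
    without rebuilding similarity features per replicate.
    """
    rng = np.random.default_rng(seed)
    out = design.copy()
    chosen = np.zeros(len(out), dtype=int)
    values = out[feature].to_numpy(dtype=float)
    for _, idx in out.groupby("trial_id", sort=False).indices.items():
        logits = beta * values[idx]
        p = np.exp(logits - logits.max())
        p /= p.sum()
        chosen[idx[rng.choice(len(idx), p=p)]] = 1
    out["chosen"] = chosen
    return out


def truth_to_json(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2)
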