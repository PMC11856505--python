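"""Age x score tertile stratification and the age-averaged counterfactual.

Embryos are cross-classified into nine strata by maternal-age tertile and
Age-Model-score tertile.  Per stratum the report holds the embryo count,
the observed live-birth fraction, the mean predicted probability, and the
within-stratum AUC of three score sets: the Age Model, the Base Model,
and the Age Model re-evaluated after replacing every maternal age by its
age-tier mean.  The counterfactual isolates what age contributes: within
a stratum it removes the between-patient age signal, so its AUCs should
track the Base Model's if age acts additively.

All quantities are in-sample (models fitted on the full cohort), which is
optimistic by construction; the report is descriptive, not a validation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ContractError, DataError, UndefinedAUCError
from .model_core import FittedAdditiveModel, prepare_model_frame
from .validation import auc_mann_whitney

logger = logging.getLogger("kidlb.stratification")

#: Nine-stratum embryo counts of the reference Day-2 transfer cohort that
#: the synthetic generator emulates (rows: age tiers low/mid/high, columns:
#: score tiers low/mid/high).  Used as a structural control: the cell sum
#: is the 2,147 transferred embryos and every marginal sum is 715 or 716.
REFERENCE_STRATUM_COUNTS = np.array(
    [[195, 221, 300],
     [249, 227, 240],
     [272, 268, 175]]
)

_TABLE_FILES = {
    "observed_lb": "table4_observed.csv",
    "predicted_lb": "table5_predicted.csv",
    "counts": "table6_counts.csv",
    "auc_age_model": "table7_auc_age_model.csv",
    "auc_base_model": "table8_auc_base_model.csv",
    "auc_age_averaged": "table9_auc_age_averaged.csv",
}


def tertile_edges(values):
    """Empirical 1/3 and 2/3 quantile edges of ``values``.

    Tier intervals are [min, e1], (e1, e2], (e2, max]; with distinct
    values the three tiers differ in size by at most one.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise DataError(f"tertile_edges: need >= 3 values, got {values.size}")
    e1, e2 = np.quantile(values, [1.0 / 3.0, 2.0 / 3.0], method="linear")
    return float(e1), float(e2)


def assign_tertiles(values, edges) -> np.ndarray:
    """Tier index (0, 1, 2) per value for the given edges."""
    values = np.asarray(values, dtype=float)
    e1, e2 = edges
    return np.where(values <= e1, 0, np.where(values <= e2, 1, 2))


def counterfactual_average_age_scores(
    model_age: FittedAdditiveModel,
    frame: pd.DataFrame,
    age_tiers,
    tier_mean: str = "embryo",
) -> np.ndarray:
    """Age Model scores after setting each age to its tier's mean age.

    ``age_tiers`` is the tier index per embryo row of ``frame``.  The tier
    mean is the arithmetic mean of embryo-level ages by default
    (``tier_mean="cycle"`` averages one age per cycle instead).  All other
    covariates are untouched.
    """
    if not model_age.spec.include_age:
        raise ContractError(
            "counterfactual requires an age term; use the Base Model scores "
            "directly for an age-free comparison"
        )
    age_tiers = np.asarray(age_tiers)
    if age_tiers.shape[0] != len(frame):
        raise ContractError("age_tiers length does not match the frame")
    cf = frame.copy()
    ages = frame["maternal_age"].to_numpy(dtype=float)
    new_age = ages.astype(float).copy()
    for tier in np.unique(age_tiers):
        mask = age_tiers == tier
        if tier_mean == "cycle":
            mean_age = float(
                frame.loc[mask].groupby("cycle_id")["maternal_age"].first().mean()
            )
        else:
            mean_age = float(ages[mask].mean())
        new_age[mask] = mean_age
    cf["maternal_age"] = new_age
    return model_age.predict_frame(cf, use_random_effect="zero")


@dataclass
class StratificationReport:
    """3x3 tables of the age x score stratification."""

    age_edges: tuple
    score_edges: tuple
    counts: np.ndarray
    observed_lb: np.ndarray
    predicted_lb: np.ndarray
    auc_age_model: np.ndarray
    auc_base_model: np.ndarray
    auc_age_averaged: np.ndarray
    tier_mean_ages: np.ndarray

    def save(self, out_dir) -> None:
        """Write the six 3x3 CSV tables plus a JSON bundle."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        idx = ["lowest_age", "medium_age", "highest_age"]
        cols = ["lowest_score", "medium_score", "highest_score"]
        for attr, fname in _TABLE_FILES.items():
            pd.DataFrame(getattr(self, attr), index=idx, columns=cols).to_csv(
                out_dir / fname
            )
        bundle = {
            "age_edges": list(self.age_edges),
            "score_edges": list(self.score_edges),
            "tier_mean_ages": self.tier_mean_ages.tolist(),
        }
        for attr in _TABLE_FILES:
            arr = np.asarray(getattr(self, attr), dtype=float)
            bundle[attr] = [
                [None if not np.isfinite(v) else float(v) for v in row]
                for row in arr
            ]
        with open(out_dir / "stratification.json", "w") as fh:
            json.dump(bundle, fh, indent=2)


def build_stratification(
    model_age: FittedAdditiveModel,
    model_base: FittedAdditiveModel,
    cycles,
    embryos,
    tier_mean: str = "embryo",
) -> StratificationReport:
    """Cross-classify embryos by age and Age-Model-score tertiles.

    Score tertiles are computed from the Age Model scores and reused for
    every table, including the Base Model AUCs.  Strata with a single
    outcome class (or no embryos) get missing AUC entries, logged.
    """
    frame = prepare_model_frame(
        cycles, embryos, cutoffs=model_age.cutoffs,
        t4_threshold=model_age.t4_threshold,
    )
    scores_age = model_age.predict_frame(frame, use_random_effect="zero")
    scores_base = model_base.predict_frame(frame, use_random_effect="zero")
    ages = frame["maternal_age"].to_numpy(dtype=float)
    y = frame["live_birth"].to_numpy(dtype=float)

    age_edges = tertile_edges(ages)
    score_edges = tertile_edges(scores_age)
    age_tier = assign_tertiles(ages, age_edges)
    score_tier = assign_tertiles(scores_age, score_edges)

    scores_cf = counterfactual_average_age_scores(
        model_age, frame, age_tier, tier_mean=tier_mean
    )

    shape = (3, 3)
    counts = np.zeros(shape, dtype=int)
    observed = np.full(shape, np.nan)
    predicted = np.full(shape, np.nan)
    auc_age = np.full(shape, np.nan)
    auc_base = np.full(shape, np.nan)
    auc_cf = np.full(shape, np.nan)
    for i in range(3):
        for j in range(3):
            mask = (age_tier == i) & (score_tier == j)
            counts[i, j] = int(mask.sum())
            if counts[i, j] == 0:
                logger.warning("stratum (%d,%d) is empty", i, j)
                continue
            observed[i, j] = float(y[mask].mean())
            predicted[i, j] = float(scores_age[mask].mean())
            for arr, s in (
                (auc_age, scores_age), (auc_base, scores_base), (auc_cf, scores_cf)
            ):
                try:
                    arr[i, j] = auc_mann_whitney(s[mask], y[mask])
                except UndefinedAUCError:
                    logger.info(
                        "stratum (%d,%d): single outcome class, AUC missing", i, j
                    )

    tier_mean_ages = np.array(
        [ages[age_tier == t].mean() if np.any(age_tier == t) else np.nan
         for t in range(3)]
    )
    return StratificationReport(
        age_edges=age_edges,
        score_edges=score_edges,
        counts=counts,
        observed_lb=observed,
        predicted_lb=predicted,
        auc_age_model=auc_age,
        auc_base_model=auc_base,
        auc_age_averaged=auc_cf,
        tier_mean_ages=tier_mean_ages,
    )
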