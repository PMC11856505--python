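"""AUC computation and clustered bootstrap cross-validation.

Discrimination is measured by the Mann-Whitney (rank) form of the area
under the ROC curve.  Validation resamples whole treatment cycles, never
individual embryos: double-embryo-transfer (DET) cycles carry a shared
outcome, so embryo-level resampling would understate the variance and a
DET pair split across folds would leak its label into the training set.

Two readings of "k-fold with bootstrap" are supported:

``within_fold_bootstrap`` (default)
    One model per fold, then ``n_resamples`` cycle-level bootstrap draws
    of the held-out cycles, one AUC per draw (k x B values).
``repeated_cv``
    The full k-fold split repeated ``n_resamples`` times with fresh
    seeds, one AUC per held-out fold (B x k values).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .exceptions import ConfigError, UndefinedAUCError

logger = logging.getLogger("kidlb.validation")


def auc_mann_whitney(scores, labels) -> float:
    """Rank-based AUC with the tie convention of the Mann-Whitney statistic.

    AUC = P(score_pos > score_neg) + 0.5 * P(score_pos = score_neg),
    computed via midranks in O(n log n).  Raises
    :class:`UndefinedAUCError` if either outcome class is absent.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ConfigError("auc_mann_whitney: scores and labels differ in length")
    pos = labels == 1
    n1 = int(pos.sum())
    n0 = int(labels.size - n1)
    if n1 == 0 or n0 == 0:
        raise UndefinedAUCError(
            f"AUC undefined: {n1} positives and {n0} negatives"
        )
    ranks = rankdata(scores)
    return float((ranks[pos].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def percentile_ci(values, level: float = 0.95):
    """Equal-tailed empirical quantile interval with linear interpolation."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ConfigError("percentile_ci: empty value vector")
    if not (0 < level < 1):
        raise ConfigError(f"percentile_ci: level must be in (0,1), got {level}")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(values, [alpha, 1.0 - alpha], method="linear")
    return float(lo), float(hi)


def clustered_kfold_split(cycles, k: int, seed: int):
    """Randomly partition treatment cycles into k near-equal folds.

    Returns a list of k sets of cycle ids; fold sizes differ by at most
    one cycle.  Embryos inherit their cycle's fold, so DET pairs are
    never split.  Deterministic given ``seed``.
    """
    cycles = list(cycles)
    if cycles and hasattr(cycles[0], "cycle_id"):
        ids = [c.cycle_id for c in cycles]
    else:
        ids = cycles
    if k < 2:
        raise ConfigError(f"clustered_kfold_split: k must be >= 2, got {k}")
    if k > len(ids):
        raise ConfigError(
            f"clustered_kfold_split: k={k} exceeds {len(ids)} cycles"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    return [set(np.asarray(ids, dtype=object)[chunk]) for chunk in np.array_split(perm, k)]


@dataclass
class CVConfig:
    """Settings for the clustered bootstrap cross-validation."""

    k_folds: int = 5
    n_resamples: int = 200
    mode: str = "within_fold_bootstrap"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_folds < 2:
            raise ConfigError(f"CVConfig.k_folds must be >= 2, got {self.k_folds}")
        if self.n_resamples < 1:
            raise ConfigError(
                f"CVConfig.n_resamples must be >= 1, got {self.n_resamples}"
            )
        if self.mode not in ("within_fold_bootstrap", "repeated_cv"):
            raise ConfigError(f"CVConfig.mode unknown: {self.mode!r}")


@dataclass
class CVReport:
    """The k x B out-of-fold AUC values and their summary."""

    auc_values: np.ndarray
    mean_auc: float
    ci95: tuple
    mode: str
    n_missing: int = 0
    per_fold_models: list = field(default_factory=list)

    def save(self, out_dir, prefix: str = "cv") -> None:
        """Write <prefix>.json, <prefix>_auc_values.csv and histogram data."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        finite = self.auc_values[np.isfinite(self.auc_values)]
        with open(out_dir / f"{prefix}.json", "w") as fh:
            json.dump(
                {"mean_auc": self.mean_auc,
                 "ci95": list(self.ci95),
                 "mode": self.mode,
                 "n_auc_values": int(self.auc_values.size),
                 "n_missing": self.n_missing},
                fh, indent=2,
            )
        pd.DataFrame({"auc": self.auc_values}).to_csv(
            out_dir / f"{prefix}_auc_values.csv", index=False
        )
        counts, edges = np.histogram(finite, bins=30)
        pd.DataFrame(
            {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
        ).to_csv(out_dir / f"{prefix}_auc_histogram.csv", index=False)


def bootstrap_cv_auc(
    spec,
    cycles,
    embryos,
    cv: CVConfig = None,
    lambda_mode: str = "reml",
    cutoffs=None,
    t4_threshold=None,
) -> CVReport:
    """Clustered k-fold validation with cycle-level bootstrap AUCs.

    Fits the model specification on each training partition, scores
    held-out embryos at the population level (random intercept zero) and
    aggregates k x B AUC values; see the module docstring for the two
    modes.  Resamples containing a single outcome class yield a missing
    AUC (excluded from the mean/CI, counted in ``n_missing``).
    """
    from . import model_core  # local import to avoid a module cycle
    from .screening import Cc2Cutoffs

    cv = cv or CVConfig()
    cutoffs = cutoffs or Cc2Cutoffs()
    if cv.k_folds > len(cycles):
        raise ConfigError(
            f"bootstrap_cv_auc: k_folds={cv.k_folds} exceeds {len(cycles)} cycles"
        )
    extra = {} if t4_threshold is None else {"t4_threshold": t4_threshold}
    frame = model_core.prepare_model_frame(cycles, embryos, cutoffs=cutoffs, **extra)
    by_id = {c.cycle_id: c for c in cycles}
    root = np.random.SeedSequence(cv.seed)

    aucs = []
    summaries = []
    n_missing = 0

    def fit_and_score(train_ids, test_ids, sub_seed_idx):
        train_cycles = [by_id[i] for i in by_id if i in train_ids]
        train_embryos = [e for e in embryos if e.cycle_id in train_ids]
        model = model_core.fit_penalized_additive_logistic(
            spec, train_cycles, train_embryos, lambda_mode=lambda_mode,
            cutoffs=cutoffs, **extra,
        )
        test_mask = frame["cycle_id"].isin(test_ids).to_numpy()
        scores = model.predict_frame(frame[test_mask], use_random_effect="zero")
        return model, frame.loc[test_mask, "cycle_id"].to_numpy(), scores, \
            frame.loc[test_mask, "live_birth"].to_numpy(dtype=float)

    if cv.mode == "within_fold_bootstrap":
        split_seed = int(root.generate_state(1)[0] % 2**31)
        folds = clustered_kfold_split(cycles, cv.k_folds, split_seed)
        for f_idx, test_ids in enumerate(folds):
            train_ids = set(by_id) - test_ids
            model, cyc_arr, scores, y = fit_and_score(train_ids, test_ids, f_idx)
            summaries.append(
                {"fold": f_idx, "converged": model.converged, "aic": model.aic}
            )
            # group scores by held-out cycle for cycle-level resampling
            order = np.argsort(cyc_arr, kind="stable")
            cyc_sorted = cyc_arr[order]
            uniq, starts = np.unique(cyc_sorted, return_index=True)
            bounds = np.append(starts, cyc_sorted.size)
            groups = [order[bounds[i]:bounds[i + 1]] for i in range(uniq.size)]
            rng = np.random.default_rng(
                np.random.SeedSequence(cv.seed, spawn_key=(1, f_idx))
            )
            for _ in range(cv.n_resamples):
                pick = rng.integers(0, len(groups), size=len(groups))
                idx = np.concatenate([groups[j] for j in pick])
                try:
                    aucs.append(auc_mann_whitney(scores[idx], y[idx]))
                except UndefinedAUCError:
                    aucs.append(np.nan)
                    n_missing += 1
    else:  # repeated_cv
        for rep in range(cv.n_resamples):
            rep_seed = int(
                np.random.SeedSequence(cv.seed, spawn_key=(2, rep))
                .generate_state(1)[0] % 2**31
            )
            folds = clustered_kfold_split(cycles, cv.k_folds, rep_seed)
            for f_idx, test_ids in enumerate(folds):
                train_ids = set(by_id) - test_ids
                model, _, scores, y = fit_and_score(train_ids, test_ids, f_idx)
                summaries.append(
                    {"repeat": rep, "fold": f_idx, "converged": model.converged}
                )
                try:
                    aucs.append(auc_mann_whitney(scores, y))
                except UndefinedAUCError:
                    aucs.append(np.nan)
                    n_missing += 1

    auc_values = np.asarray(aucs, dtype=float)
    finite = auc_values[np.isfinite(auc_values)]
    if n_missing:
        logger.info("bootstrap_cv_auc: %d resamples had one outcome class", n_missing)
    if finite.size == 0:
        raise UndefinedAUCError("bootstrap_cv_auc: no resample had both classes")
    return CVReport(
        auc_values=auc_values,
        mean_auc=float(finite.mean()),
        ci95=percentile_ci(finite, 0.95),
        mode=cv.mode,
        n_missing=n_missing,
        per_fold_models=summaries,
    )
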