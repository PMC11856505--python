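"""Single-variable predictive screening and threshold rules.

Covariate preparation rules used throughout the pipeline:

* the second cell cycle duration ``cc2 = t3 - t2`` (hours) is categorised
  into short / medium / long bands;
* the four-cell timing ``t4`` is reduced to a binary indicator ("reached
  the four-cell stage early") by thresholding, with missing values mapped
  to the negative class;
* each candidate covariate is screened one at a time in a small mixed
  logistic model (intercept + the covariate + a cycle-level random
  intercept) and summarised by its in-sample AUC and an approximate Wald
  p-value.

In-sample screening AUCs are optimistic by construction; they are used
only to rank candidate covariates before multivariable modelling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigError, DataError, UndefinedAUCError
from .validation import auc_mann_whitney

logger = logging.getLogger("kidlb.screening")

#: Default cc2 band edges (hours): cc2 < 9.33 is "short", cc2 > 11.45 is
#: "long", boundaries inclusive to "medium".  These follow the published
#: cleavage-stage selection window for the second cell cycle; clinics may
#: use local cutoffs, so they are configurable everywhere.
DEFAULT_CC2_SHORT_MAX = 9.33
DEFAULT_CC2_LONG_MIN = 11.45

#: Default grid (hours) searched for the optimal t4 threshold.
DEFAULT_T4_GRID = np.round(np.arange(30.0, 50.0 + 1e-9, 0.5), 2)


@dataclass(frozen=True)
class Cc2Cutoffs:
    """Band edges for the second-cell-cycle duration, in hours."""

    short_max: float = DEFAULT_CC2_SHORT_MAX
    long_min: float = DEFAULT_CC2_LONG_MIN

    def __post_init__(self) -> None:
        if not (0 < self.short_max <= self.long_min):
            raise ConfigError(
                "Cc2Cutoffs: require 0 < short_max <= long_min, got "
                f"short_max={self.short_max}, long_min={self.long_min}"
            )


@dataclass
class ScreeningRow:
    """One screened covariate: its in-sample AUC and approximate p-value."""

    variable: str
    auc: float
    pvalue: float


def categorize_cc2(cc2, cutoffs: Cc2Cutoffs = Cc2Cutoffs()):
    """Assign cc2 durations to ``short`` / ``medium`` / ``long`` bands.

    ``cc2 < short_max`` is short, ``cc2 > long_min`` is long, boundaries
    belong to medium.  Accepts a scalar or an array; returns a string or
    an object array accordingly.  Negative cc2 raises :class:`DataError`.
    """
    arr = np.asarray(cc2, dtype=float)
    if np.any(arr < 0):
        raise DataError("categorize_cc2: negative cc2 duration encountered")
    out = np.where(
        arr < cutoffs.short_max, "short",
        np.where(arr > cutoffs.long_min, "long", "medium"),
    )
    if np.isscalar(cc2) or np.ndim(cc2) == 0:
        return str(out[()])
    return out


def binarize_t4(t4, threshold: float):
    """Binary t4 rule: 1 iff t4 is present and strictly below ``threshold``.

    Missing t4 (None / NaN) maps to 0, as does ``t4 == threshold``.
    Accepts scalars or arrays (NaN encodes missing in arrays).
    """
    if threshold <= 0:
        raise ConfigError(f"binarize_t4: threshold must be > 0, got {threshold}")
    scalar = t4 is None or np.ndim(t4) == 0
    arr = np.asarray(
        [np.nan if t4 is None else t4] if t4 is None else t4, dtype=float
    )
    with np.errstate(invalid="ignore"):
        out = np.where(np.isnan(arr), 0, (arr < threshold).astype(int))
    if scalar:
        return int(out.reshape(-1)[0])
    return out


def optimal_t4_threshold(embryos, grid=None, cutoffs: Cc2Cutoffs = Cc2Cutoffs()):
    """Grid-search the t4 threshold maximising the AUC of the binary rule.

    Parameters
    ----------
    embryos
        Sequence of :class:`~kidlb.synthetic_data.EmbryoRecord` or a
        DataFrame with ``t4`` and ``live_birth`` columns.
    grid
        Candidate thresholds in hours; defaults to 30-50 h in 0.5 h steps.

    Returns
    -------
    (threshold, auc)
        The grid value with maximal AUC (ties broken toward the smallest
        threshold) and that AUC.
    """
    grid = DEFAULT_T4_GRID if grid is None else np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ConfigError("optimal_t4_threshold: empty threshold grid")
    t4, y = _t4_outcome_arrays(embryos)
    if len(np.unique(y)) < 2:
        raise UndefinedAUCError(
            "optimal_t4_threshold: outcomes contain a single class"
        )
    best_thr, best_auc = None, -np.inf
    for thr in grid:
        auc = auc_mann_whitney(binarize_t4(t4, thr).astype(float), y)
        if auc > best_auc + 1e-15:
            best_thr, best_auc = float(thr), float(auc)
    return best_thr, best_auc


def _t4_outcome_arrays(embryos):
    if isinstance(embryos, pd.DataFrame):
        t4 = embryos["t4"].to_numpy(dtype=float)
        y = embryos["live_birth"].to_numpy(dtype=float)
    else:
        t4 = np.array(
            [np.nan if e.t4 is None else e.t4 for e in embryos], dtype=float
        )
        y = np.array([e.live_birth for e in embryos], dtype=float)
    return t4, y


# Covariates the screen knows how to wrap in a one-term model.  "smooth"
# variables get a penalized spline, the rest enter parametrically.
_SCREEN_KINDS = {
    "fragmentation_pct": "linear",
    "cc2_category": "categorical",
    "multinucleated": "linear",
    "t4_indicator": "linear",
    "t2": "smooth",
    "maternal_age": "smooth",
}

DEFAULT_SCREEN_VARIABLES = (
    "fragmentation_pct",
    "cc2_category",
    "multinucleated",
    "t4_indicator",
    "t2",
    "maternal_age",
)


def single_variable_screen(
    variables: Sequence[str],
    cycles,
    embryos,
    cutoffs: Cc2Cutoffs = Cc2Cutoffs(),
    t4_threshold: float | None = None,
    lambda_mode: str = "reml",
):
    """Screen covariates one at a time in a mixed logistic model.

    Each variable is fitted as the sole covariate of a model with an
    intercept and a cycle-level random intercept.  Smooth variables (t2,
    maternal age) use a penalized spline; ``cc2_category`` enters as a
    categorical with ``medium`` as the reference; ``t4_indicator`` is the
    binary threshold rule (threshold found by grid search unless given).

    Returns a list of :class:`ScreeningRow` sorted by AUC ascending.
    """
    from . import model_core  # local import: model_core imports this module

    rows = []
    for var in variables:
        kind = _SCREEN_KINDS.get(var)
        if kind is None:
            raise ConfigError(
                f"single_variable_screen: unknown variable '{var}'"
            )
        extra = {}
        if var == "t4_indicator":
            thr = t4_threshold
            if thr is None:
                thr, _ = optimal_t4_threshold(embryos, cutoffs=cutoffs)
                logger.info("screen: optimal t4 threshold %.2f h", thr)
            extra["t4_threshold"] = thr
        spec = _one_term_spec(var, kind)
        model = model_core.fit_penalized_additive_logistic(
            spec, cycles, embryos, lambda_mode=lambda_mode,
            cutoffs=cutoffs, **extra,
        )
        frame = model_core.prepare_model_frame(
            cycles, embryos, cutoffs=cutoffs, **extra
        )
        scores = model.predict_frame(frame, use_random_effect="zero")
        auc = auc_mann_whitney(scores, frame["live_birth"].to_numpy())
        pvalue = model.term_pvalues.get(var, np.nan)
        rows.append(ScreeningRow(variable=var, auc=float(auc), pvalue=float(pvalue)))
    rows.sort(key=lambda r: r.auc)
    return rows


def _one_term_spec(var: str, kind: str):
    from . import model_core

    smooths, linears, cats = (), (), ()
    if kind == "smooth":
        smooths = (model_core.SmoothTerm(var),)
    elif kind == "linear":
        linears = (var,)
    else:
        cats = (model_core.CC2_CATEGORICAL,)
    return model_core.ModelSpec(
        smooth_terms=smooths,
        linear_terms=linears,
        categorical_terms=cats,
        random_intercept="cycle_id",
    )


def screening_report_frame(rows: Sequence[ScreeningRow]) -> pd.DataFrame:
    """Screening rows as a DataFrame (columns: variable, AUC, P)."""
    return pd.DataFrame(
        {"variable": [r.variable for r in rows],
         "AUC": [r.auc for r in rows],
         "P": [r.pvalue for r in rows]}
    )
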