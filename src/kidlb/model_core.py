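"""Penalized additive logistic model with a cycle-level random intercept.

The model is a "GAMM-lite": a binomial generalized additive model whose
smooth terms are P-splines (cubic B-spline bases with a second-order
difference penalty), whose cycle-level random intercepts are treated as
ridge-penalized coefficients (penalty 1/sigma_u^2), and whose smoothing
parameters and random-intercept variance are chosen by a Laplace-
approximate restricted likelihood (REML).  Fitting is penalized
iteratively reweighted least squares (IRLS) with step-halving; the
random-intercept block is profiled out of each weighted least-squares
solve, so the cost per iteration is O(n p^2 + n_cycles p^2) regardless of
the number of cycles.

Effective degrees of freedom (edf) are the trace of the influence matrix
partitioned by term; each smooth's sum-to-zero identifiability constraint
absorbs one dof into the intercept, which is added back to that smooth's
edf so a second-order penalty at lambda -> infinity reports edf 2
(constant + linear null space).  AIC is deviance + 2 * total edf with the
same bookkeeping.  Term p-values are approximate Wald tests on the
penalized coefficients.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.interpolate import BSpline
from scipy.linalg import cho_factor, cho_solve, null_space
from scipy.special import expit, logit
from scipy.stats import chi2

from .exceptions import (
    ConfigError,
    ContractError,
    DataError,
    DegenerateCovariateError,
)
from .screening import Cc2Cutoffs, binarize_t4, categorize_cc2
from .synthetic_data import cohort_frame

logger = logging.getLogger("kidlb.model_core")

IRLS_TOL = 1e-8
IRLS_MAX_ITER = 200
_EPS = 1e-10


# ---------------------------------------------------------------------------
# model specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SmoothTerm:
    """A P-spline smooth of one covariate."""

    variable: str
    n_basis: int = 10
    degree: int = 3
    penalty_order: int = 2


@dataclass(frozen=True)
class CategoricalTerm:
    variable: str
    levels: tuple
    reference: str


#: cc2 band covariate with "medium" as the reference level.
CC2_CATEGORICAL = CategoricalTerm(
    "cc2_category", ("short", "medium", "long"), "medium"
)


@dataclass(frozen=True)
class ModelSpec:
    """Terms of the additive logistic model.

    The Base Model is smooth(t2) + cc2 band + multinucleation + cycle
    random intercept; the Age Model adds smooth(maternal_age).
    """

    smooth_terms: tuple = ()
    linear_terms: tuple = ()
    categorical_terms: tuple = ()
    random_intercept: Optional[str] = "cycle_id"

    @property
    def include_age(self) -> bool:
        return any(s.variable == "maternal_age" for s in self.smooth_terms)

    @property
    def term_names(self) -> tuple:
        return tuple(
            [s.variable for s in self.smooth_terms]
            + [c.variable for c in self.categorical_terms]
            + list(self.linear_terms)
        )

    def with_term(self, term) -> "ModelSpec":
        """Return a new spec with ``term`` appended (no duplicates)."""
        name = term if isinstance(term, str) else term.variable
        if name in self.term_names:
            raise ContractError(f"term '{name}' already present in spec")
        if isinstance(term, SmoothTerm):
            return ModelSpec(
                self.smooth_terms + (term,), self.linear_terms,
                self.categorical_terms, self.random_intercept,
            )
        if isinstance(term, CategoricalTerm):
            return ModelSpec(
                self.smooth_terms, self.linear_terms,
                self.categorical_terms + (term,), self.random_intercept,
            )
        return ModelSpec(
            self.smooth_terms, self.linear_terms + (str(term),),
            self.categorical_terms, self.random_intercept,
        )

    @classmethod
    def base_model(cls) -> "ModelSpec":
        return cls(
            smooth_terms=(SmoothTerm("t2"),),
            linear_terms=("multinucleated",),
            categorical_terms=(CC2_CATEGORICAL,),
            random_intercept="cycle_id",
        )

    @classmethod
    def age_model(cls) -> "ModelSpec":
        return cls(
            smooth_terms=(SmoothTerm("t2"), SmoothTerm("maternal_age")),
            linear_terms=("multinucleated",),
            categorical_terms=(CC2_CATEGORICAL,),
            random_intercept="cycle_id",
        )


# ---------------------------------------------------------------------------
# spline basis
# ---------------------------------------------------------------------------

class SplineBlock:
    """B-spline basis on equally spaced knots with a difference penalty.

    Rows evaluate exactly inside the training range and extrapolate
    linearly beyond it (first-order Taylor expansion at the boundary).
    """

    def __init__(self, variable, knots, degree, penalty_order, lo, hi):
        self.variable = variable
        self.knots = np.asarray(knots, dtype=float)
        self.degree = int(degree)
        self.penalty_order = int(penalty_order)
        self.lo = float(lo)
        self.hi = float(hi)
        self.n_basis = self.knots.size - self.degree - 1
        D = np.diff(np.eye(self.n_basis), n=self.penalty_order, axis=0)
        self.penalty_matrix = D.T @ D
        self.lam = 1.0
        # boundary values/derivatives for linear extrapolation
        ident = np.eye(self.n_basis)
        bs = BSpline(self.knots, ident, self.degree)
        ends = np.array([self.lo, self.hi])
        self._b_end = bs(ends)
        self._db_end = bs.derivative(1)(ends)

    def evaluate(self, x) -> np.ndarray:
        """Basis matrix (len(x), n_basis) with linear extrapolation."""
        x = np.asarray(x, dtype=float)
        xc = np.clip(x, self.lo, self.hi)
        B = BSpline.design_matrix(xc, self.knots, self.degree).toarray()
        below = x < self.lo
        above = x > self.hi
        if below.any():
            B[below] = self._b_end[0] + np.outer(x[below] - self.lo, self._db_end[0])
        if above.any():
            B[above] = self._b_end[1] + np.outer(x[above] - self.hi, self._db_end[1])
        return B

    # spec naming: the builder is the bound evaluate method
    @property
    def basis_matrix_builder(self):
        return self.evaluate


def build_spline_basis(
    x, n_basis: int = 10, degree: int = 3, penalty_order: int = 2
) -> SplineBlock:
    """P-spline block for covariate values ``x``.

    Knots are equally spaced across [min(x), max(x)], padded by ``degree``
    knots on each side; the penalty is D'D with D the ``penalty_order``-th
    difference operator on the coefficient sequence.
    """
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if n_basis < degree + 1:
        raise ConfigError(
            f"build_spline_basis: n_basis={n_basis} must be >= degree+1={degree + 1}"
        )
    if x.size < 2 or np.unique(x).size < 2:
        raise DegenerateCovariateError(
            "build_spline_basis: covariate is constant or near-empty"
        )
    lo, hi = float(x.min()), float(x.max())
    h = (hi - lo) / (n_basis - degree)
    knots = lo + h * np.arange(-degree, n_basis + 1)
    return SplineBlock("x", knots, degree, penalty_order, lo, hi)


def _sum_to_zero_transform(B: np.ndarray) -> np.ndarray:
    """Null-space basis Z of the sum-to-zero constraint 1'B beta = 0."""
    c = B.sum(axis=0, keepdims=True)
    Z = null_space(c)
    if Z.shape[1] != B.shape[1] - 1:
        raise DegenerateCovariateError(
            "sum-to-zero constraint is degenerate for this basis"
        )
    return Z


# ---------------------------------------------------------------------------
# data preparation and design assembly
# ---------------------------------------------------------------------------

def prepare_model_frame(
    cycles,
    embryos,
    cutoffs: Cc2Cutoffs = Cc2Cutoffs(),
    t4_threshold: Optional[float] = None,
) -> pd.DataFrame:
    """Embryo-level frame with derived model covariates attached.

    Adds ``cc2_category`` (band of t3 - t2 under ``cutoffs``) and, when a
    threshold is given, the binary ``t4_indicator``.
    """
    frame = cohort_frame(cycles, embryos)
    frame["cc2_category"] = categorize_cc2(frame["cc2"].to_numpy(), cutoffs)
    if t4_threshold is not None:
        frame["t4_indicator"] = binarize_t4(
            frame["t4"].to_numpy(), t4_threshold
        ).astype(float)
    return frame


class _Design:
    """Assembled fixed-effect design plus penalty bookkeeping."""

    def __init__(self, frame: pd.DataFrame, spec: ModelSpec, blocks=None):
        self.spec = spec
        cols = [np.ones((len(frame), 1))]
        self.slices = {"intercept": slice(0, 1)}
        self.blocks = {}  # var -> (SplineBlock, Z)
        self.penalties = []  # (var, slice, constrained penalty matrix)
        start = 1
        for st in spec.smooth_terms:
            x = frame[st.variable].to_numpy(dtype=float)
            if blocks is not None:
                blk, Z = blocks[st.variable]
            else:
                blk = build_spline_basis(x, st.n_basis, st.degree, st.penalty_order)
                blk.variable = st.variable
                Z = _sum_to_zero_transform(blk.evaluate(x))
            B = blk.evaluate(x) @ Z
            k = B.shape[1]
            self.slices[st.variable] = slice(start, start + k)
            self.penalties.append(
                (st.variable, slice(start, start + k), Z.T @ blk.penalty_matrix @ Z)
            )
            self.blocks[st.variable] = (blk, Z)
            cols.append(B)
            start += k
        for ct in spec.categorical_terms:
            vals = frame[ct.variable].astype(str).to_numpy()
            bad = sorted(set(vals) - set(ct.levels))
            if bad:
                raise DataError(
                    f"unseen level(s) {bad} in categorical '{ct.variable}'"
                )
            lv = [l for l in ct.levels if l != ct.reference]
            dummies = np.column_stack([(vals == l).astype(float) for l in lv])
            self.slices[ct.variable] = slice(start, start + len(lv))
            cols.append(dummies)
            start += len(lv)
        for name in spec.linear_terms:
            v = frame[name].to_numpy(dtype=float)
            if np.any(~np.isfinite(v)):
                raise DataError(f"linear term '{name}' contains missing values")
            self.slices[name] = slice(start, start + 1)
            cols.append(v[:, None])
            start += 1
        self.X = np.hstack(cols)
        self.p = self.X.shape[1]
        # penalty spectra (constant in lambda) for the REML criterion
        self.pen_rank = {}
        self.pen_logdet = {}
        for var, sl, P in self.penalties:
            ev = np.linalg.eigvalsh(P)
            pos = ev[ev > ev.max() * 1e-10] if ev.size else ev
            self.pen_rank[var] = int(pos.size)
            self.pen_logdet[var] = float(np.sum(np.log(pos)))

    def penalty_total(self, lambdas: dict) -> np.ndarray:
        S = np.zeros((self.p, self.p))
        for var, sl, P in self.penalties:
            S[sl, sl] += lambdas[var] * P
        return S


# ---------------------------------------------------------------------------
# penalized IRLS
# ---------------------------------------------------------------------------

def _deviance(y, mu) -> float:
    mu = np.clip(mu, _EPS, 1 - _EPS)
    return float(-2.0 * np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))


class _PIRLSResult:
    def __init__(self, beta, u, deviance, penalty, converged, n_iter, W,
                 obj_trace=None):
        self.beta = beta
        self.u = u
        self.deviance = deviance
        self.penalty = penalty
        self.converged = converged
        self.n_iter = n_iter
        self.W = W
        self.obj_trace = obj_trace or []

    @property
    def objective(self) -> float:
        return self.deviance + self.penalty


def _pirls(X, y, S, g, n_groups, inv_sig2, beta0=None, u0=None):
    """Penalized IRLS with the random-intercept block profiled out.

    ``g`` is the integer group code per row (or None for no random
    intercept); the ridge penalty on the group intercepts is
    ``inv_sig2 * I``.  Step-halving enforces monotone decrease of the
    penalized deviance.
    """
    n, p = X.shape
    has_u = g is not None
    beta = np.zeros(p) if beta0 is None else beta0.copy()
    if beta0 is None:
        ybar = float(np.clip(np.mean(y), 1e-3, 1 - 1e-3))
        beta[0] = logit(ybar)
    u = (np.zeros(n_groups) if u0 is None else u0.copy()) if has_u else None

    def obj(beta_, u_):
        eta = X @ beta_ + (u_[g] if has_u else 0.0)
        mu = expit(eta)
        pen = float(beta_ @ S @ beta_)
        if has_u:
            pen += inv_sig2 * float(u_ @ u_)
        return _deviance(y, mu) + pen, eta, mu

    cur, eta, mu = obj(beta, u)
    trace = [cur]
    converged = False
    W = None
    for it in range(IRLS_MAX_ITER):
        w = np.maximum(mu * (1 - mu), _EPS)
        z = eta + (y - mu) / w
        Xw = X * w[:, None]
        A = X.T @ Xw + S
        rhs = Xw.T @ z
        if has_u:
            bc = np.stack(
                [np.bincount(g, weights=w * X[:, j], minlength=n_groups)
                 for j in range(p)]
            )  # (p, n_groups)
            d = np.bincount(g, weights=w, minlength=n_groups) + inv_sig2
            rc = np.bincount(g, weights=w * z, minlength=n_groups)
            M = A - (bc / d) @ bc.T
            rhs = rhs - bc @ (rc / d)
        else:
            M = A
        try:
            c, low = cho_factor(M)
            beta_new = cho_solve((c, low), rhs)
        except np.linalg.LinAlgError:
            beta_new = np.linalg.lstsq(M, rhs, rcond=None)[0]
        u_new = (rc - bc.T @ beta_new) / d if has_u else None

        d_beta = beta_new - beta
        d_u = (u_new - u) if has_u else None
        step = 1.0
        for _ in range(30):
            cand_beta = beta + step * d_beta
            cand_u = (u + step * d_u) if has_u else None
            new, eta_c, mu_c = obj(cand_beta, cand_u)
            if new <= cur + 1e-12:
                break
            step *= 0.5
        else:
            # no decrease found: stop at current iterate
            converged = True
            W = w
            break
        delta = np.max(np.abs(step * d_beta))
        if has_u:
            delta = max(delta, float(np.max(np.abs(step * d_u))))
        beta, u, cur, eta, mu = cand_beta, cand_u, new, eta_c, mu_c
        trace.append(cur)
        W = np.maximum(mu * (1 - mu), _EPS)
        if delta < IRLS_TOL:
            converged = True
            break

    pen = float(beta @ S @ beta) + (inv_sig2 * float(u @ u) if has_u else 0.0)
    dev = cur - pen
    if W is None:
        W = np.maximum(mu * (1 - mu), _EPS)
    return _PIRLSResult(beta, u, dev, pen, converged, it + 1, W, trace)


def _edf_and_cov(X, W, S, g, n_groups, inv_sig2, slices, penalties):
    """Trace of the influence matrix by term, plus the coefficient covariance.

    Returns (per_coef_edf, edf_random, V_beta) where V_beta is the inverse
    of the Schur complement of the penalized Hessian (the fixed-effect
    block of the full inverse).
    """
    p = X.shape[1]
    Xw = X * W[:, None]
    A = X.T @ Xw + S
    if g is not None:
        bc = np.stack(
            [np.bincount(g, weights=W * X[:, j], minlength=n_groups)
             for j in range(p)]
        )
        d = np.bincount(g, weights=W, minlength=n_groups) + inv_sig2
        M = A - (bc / d) @ bc.T
    else:
        M = A
    V = np.linalg.inv(M)
    per_coef = 1.0 - np.einsum("ij,ji->i", V, S)
    edf_u = 0.0
    if g is not None:
        quad = np.einsum("ci,ij,cj->c", bc.T, V, bc.T)
        edf_u = float(n_groups - inv_sig2 * (np.sum(1.0 / d) + np.sum(quad / d**2)))
    return per_coef, edf_u, V


# ---------------------------------------------------------------------------
# fitted model
# ---------------------------------------------------------------------------

SERIALIZATION_VERSION = 1


@dataclass
class FittedAdditiveModel:
    """A fitted penalized additive logistic model."""

    spec: ModelSpec
    coefficients: np.ndarray
    lambdas: dict
    sigma_u: Optional[float]
    edf: dict
    edf_total: float
    aic: float
    deviance: float
    term_pvalues: dict
    converged: bool
    train_fingerprint: str
    cutoffs: Cc2Cutoffs = field(default_factory=Cc2Cutoffs)
    t4_threshold: Optional[float] = None
    slices: dict = field(default_factory=dict)
    blocks: dict = field(default_factory=dict)  # var -> (SplineBlock, Z)
    random_effects: Optional[dict] = None  # cycle_id -> fitted u
    reml_criterion: Optional[float] = None
    separation_suspected: bool = False
    n_obs: int = 0
    #: penalized-deviance value at each accepted IRLS step (diagnostic)
    fit_trace: list = field(default_factory=list)

    # -- prediction -------------------------------------------------------

    def predict_frame(self, frame: pd.DataFrame, use_random_effect="zero"):
        """Population-level (or training-diagnostic) success probabilities."""
        design = _Design(frame, self.spec, blocks=self.blocks)
        eta = design.X @ self.coefficients
        if use_random_effect == "fitted":
            if self.random_effects is None:
                raise ContractError("model carries no fitted random effects")
            missing = set(frame[self.spec.random_intercept].astype(str)) - set(
                self.random_effects
            )
            if missing:
                raise ContractError(
                    f"no fitted intercept for cycle(s) {sorted(missing)[:5]}"
                )
            eta = eta + np.array(
                [self.random_effects[c]
                 for c in frame[self.spec.random_intercept].astype(str)]
            )
        elif use_random_effect != "zero":
            raise ConfigError(
                f"use_random_effect must be 'zero' or 'fitted', got {use_random_effect!r}"
            )
        return expit(eta)

    def smooth_values(self, variable: str, x) -> np.ndarray:
        """Centered fitted smooth f(x) for one smooth term (log-odds)."""
        if variable not in self.blocks:
            raise ContractError(f"model has no smooth term '{variable}'")
        blk, Z = self.blocks[variable]
        return (blk.evaluate(np.asarray(x, dtype=float)) @ Z) @ self.coefficients[
            self.slices[variable]
        ]

    # -- serialization ----------------------------------------------------

    def to_json_dict(self) -> dict:
        smooths = {}
        for var, (blk, Z) in self.blocks.items():
            smooths[var] = {
                "knots": blk.knots.tolist(),
                "degree": blk.degree,
                "penalty_order": blk.penalty_order,
                "lo": blk.lo,
                "hi": blk.hi,
                "Z": Z.tolist(),
            }
        return {
            "version": SERIALIZATION_VERSION,
            "spec": {
                "smooth_terms": [vars(s) for s in self.spec.smooth_terms],
                "linear_terms": list(self.spec.linear_terms),
                "categorical_terms": [
                    {"variable": c.variable, "levels": list(c.levels),
                     "reference": c.reference}
                    for c in self.spec.categorical_terms
                ],
                "random_intercept": self.spec.random_intercept,
            },
            "coefficients": self.coefficients.tolist(),
            "lambdas": self.lambdas,
            "sigma_u": self.sigma_u,
            "edf": self.edf,
            "edf_total": self.edf_total,
            "aic": self.aic,
            "deviance": self.deviance,
            "term_pvalues": self.term_pvalues,
            "converged": self.converged,
            "train_fingerprint": self.train_fingerprint,
            "cutoffs": {"short_max": self.cutoffs.short_max,
                        "long_min": self.cutoffs.long_min},
            "t4_threshold": self.t4_threshold,
            "slices": {k: [v.start, v.stop] for k, v in self.slices.items()},
            "smooths": smooths,
            "random_effects": self.random_effects,
            "n_obs": self.n_obs,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=2)

    @classmethod
    def load(cls, path) -> "FittedAdditiveModel":
        with open(path) as fh:
            d = json.load(fh)
        if d.get("version") != SERIALIZATION_VERSION:
            raise ConfigError(
                f"unsupported model file version {d.get('version')!r}"
            )
        spec = ModelSpec(
            smooth_terms=tuple(SmoothTerm(**s) for s in d["spec"]["smooth_terms"]),
            linear_terms=tuple(d["spec"]["linear_terms"]),
            categorical_terms=tuple(
                CategoricalTerm(c["variable"], tuple(c["levels"]), c["reference"])
                for c in d["spec"]["categorical_terms"]
            ),
            random_intercept=d["spec"]["random_intercept"],
        )
        blocks = {}
        for var, s in d["smooths"].items():
            blk = SplineBlock(
                var, np.asarray(s["knots"]), s["degree"], s["penalty_order"],
                s["lo"], s["hi"],
            )
            blocks[var] = (blk, np.asarray(s["Z"]))
        return cls(
            spec=spec,
            coefficients=np.asarray(d["coefficients"]),
            lambdas=d["lambdas"],
            sigma_u=d["sigma_u"],
            edf=d["edf"],
            edf_total=d["edf_total"],
            aic=d["aic"],
            deviance=d["deviance"],
            term_pvalues=d["term_pvalues"],
            converged=d["converged"],
            train_fingerprint=d["train_fingerprint"],
            cutoffs=Cc2Cutoffs(**d["cutoffs"]),
            t4_threshold=d["t4_threshold"],
            slices={k: slice(v[0], v[1]) for k, v in d["slices"].items()},
            blocks=blocks,
            random_effects=d["random_effects"],
            n_obs=d["n_obs"],
        )


def predict_probability(model: FittedAdditiveModel, cycles, embryos,
                        use_random_effect: str = "zero") -> np.ndarray:
    """Score embryos with a fitted model (population-level by default)."""
    frame = prepare_model_frame(
        cycles, embryos, cutoffs=model.cutoffs, t4_threshold=model.t4_threshold
    )
    return model.predict_frame(frame, use_random_effect=use_random_effect)


# ---------------------------------------------------------------------------
# fitting and REML smoothing selection
# ---------------------------------------------------------------------------

def _fingerprint(frame: pd.DataFrame, spec: ModelSpec) -> str:
    cols = ["live_birth"] + [
        c for c in (
            [s.variable for s in spec.smooth_terms]
            + [c.variable for c in spec.categorical_terms]
            + list(spec.linear_terms)
            + ([spec.random_intercept] if spec.random_intercept else [])
        )
    ]
    h = hashlib.sha256()
    h.update(pd.util.hash_pandas_object(frame[cols], index=False).values.tobytes())
    return h.hexdigest()[:16]


def _groups(frame: pd.DataFrame, spec: ModelSpec):
    if spec.random_intercept is None:
        return None, 0, None
    labels = frame[spec.random_intercept].astype(str).to_numpy()
    uniq, g = np.unique(labels, return_inverse=True)
    return g, uniq.size, uniq


def _check_fit_inputs(frame: pd.DataFrame, spec: ModelSpec) -> np.ndarray:
    y = frame["live_birth"].to_numpy(dtype=float)
    if np.unique(y).size < 2:
        raise DataError("fit requires both outcome classes to be present")
    for name in spec.term_names:
        if name not in frame.columns:
            raise DataError(f"model variable '{name}' absent from data")
    return y


def _reml_criterion(design, res, lambdas, inv_sig2, g, n_groups):
    """Laplace-approximate restricted likelihood (up to additive constants)."""
    S = design.penalty_total(lambdas)
    X, W = design.X, res.W
    Xw = X * W[:, None]
    A = X.T @ Xw + S
    if g is not None:
        p = X.shape[1]
        bc = np.stack(
            [np.bincount(g, weights=W * X[:, j], minlength=n_groups)
             for j in range(p)]
        )
        d = np.bincount(g, weights=W, minlength=n_groups) + inv_sig2
        M = A - (bc / d) @ bc.T
        logdet_hp = float(np.sum(np.log(d))) + _slogdet(M)
    else:
        logdet_hp = _slogdet(A)
    logdet_s = 0.0
    for var in lambdas:
        logdet_s += design.pen_rank[var] * np.log(lambdas[var])
        logdet_s += design.pen_logdet[var]
    if g is not None:
        logdet_s += n_groups * np.log(inv_sig2)
    return 0.5 * (res.deviance + res.penalty) + 0.5 * logdet_hp - 0.5 * logdet_s


def _slogdet(M) -> float:
    sign, val = np.linalg.slogdet(M)
    if sign <= 0:
        raise np.linalg.LinAlgError("penalized Hessian not positive definite")
    return float(val)


_LOG_LAM_BOUNDS = (-10.0, 14.0)
_LOG_SIG_BOUNDS = (-7.0, 2.5)


def select_smoothing_reml(
    spec: ModelSpec,
    cycles,
    embryos,
    cutoffs: Cc2Cutoffs = Cc2Cutoffs(),
    t4_threshold: Optional[float] = None,
    frame: Optional[pd.DataFrame] = None,
):
    """Choose smoothing parameters (and sigma_u) by Laplace REML.

    Nelder-Mead over log(lambda_j) (and log sigma_u when the spec has a
    random intercept) starting from lambda=1, sigma_u=0.5; the inner loop
    is the penalized IRLS fit.  Falls back to a coordinate-wise log-grid
    search if the optimizer fails.  Deterministic.

    Returns ``(lambdas, sigma_u)``.
    """
    if frame is None:
        frame = prepare_model_frame(cycles, embryos, cutoffs, t4_threshold)
    y = _check_fit_inputs(frame, spec)
    design = _Design(frame, spec)
    g, n_groups, _ = _groups(frame, spec)
    svars = [s.variable for s in spec.smooth_terms]
    has_u = g is not None
    ndim = len(svars) + (1 if has_u else 0)
    if ndim == 0:
        return {}, None

    state = {"warm": None}

    def criterion(theta):
        theta = np.asarray(theta, dtype=float)
        lams = {
            v: float(np.exp(np.clip(t, *_LOG_LAM_BOUNDS)))
            for v, t in zip(svars, theta[: len(svars)])
        }
        inv_sig2 = 0.0
        if has_u:
            sig = float(np.exp(np.clip(theta[-1], *_LOG_SIG_BOUNDS)))
            inv_sig2 = 1.0 / sig**2
        S = design.penalty_total(lams)
        warm = state["warm"]
        res = _pirls(
            design.X, y, S, g, n_groups, inv_sig2,
            beta0=None if warm is None else warm[0],
            u0=None if warm is None else warm[1],
        )
        state["warm"] = (res.beta, res.u)
        try:
            return _reml_criterion(design, res, lams, inv_sig2, g, n_groups)
        except np.linalg.LinAlgError:
            return np.inf

    x0 = np.zeros(ndim)
    if has_u:
        x0[-1] = np.log(0.5)
    best = optimize.minimize(
        criterion, x0, method="Nelder-Mead",
        options={"maxiter": 120 * ndim, "xatol": 0.05, "fatol": 1e-4},
    )
    x_opt, f_opt = best.x, float(best.fun)
    if not np.isfinite(f_opt) or f_opt > criterion(x0) + 1e-9:
        logger.warning(
            "REML optimizer failed (%s); falling back to log-grid search",
            best.message,
        )
        x_opt, f_opt = _grid_fallback(criterion, ndim, has_u)

    lambdas = {
        v: float(np.exp(np.clip(t, *_LOG_LAM_BOUNDS)))
        for v, t in zip(svars, x_opt[: len(svars)])
    }
    sigma_u = (
        float(np.exp(np.clip(x_opt[-1], *_LOG_SIG_BOUNDS))) if has_u else None
    )
    return lambdas, sigma_u


def _grid_fallback(criterion, ndim, has_u):
    """Coordinate-wise search over lambda in 10^{-3..3} (sigma 0.05..1.5)."""
    lam_grid = np.log(10.0 ** np.arange(-3, 4, dtype=float))
    sig_grid = np.log(np.array([0.05, 0.1, 0.2, 0.35, 0.5, 0.75, 1.0, 1.5]))
    x = np.zeros(ndim)
    if has_u:
        x[-1] = np.log(0.5)
    f = criterion(x)
    for _ in range(2):  # two sweeps
        for dim in range(ndim):
            grid = sig_grid if (has_u and dim == ndim - 1) else lam_grid
            for val in grid:
                cand = x.copy()
                cand[dim] = val
                fc = criterion(cand)
                if fc < f:
                    x, f = cand, fc
    return x, f


def fit_penalized_additive_logistic(
    spec: ModelSpec,
    cycles,
    embryos,
    lambda_mode: str = "reml",
    lambdas: Optional[dict] = None,
    sigma_u: Optional[float] = None,
    cutoffs: Cc2Cutoffs = Cc2Cutoffs(),
    t4_threshold: Optional[float] = None,
) -> FittedAdditiveModel:
    """Fit the penalized additive logistic model.

    ``lambda_mode="reml"`` selects smoothing parameters and the
    random-intercept SD by restricted likelihood; ``"fixed"`` uses the
    supplied ``lambdas`` / ``sigma_u`` (defaults: 1.0 per smooth, 0.5).
    Non-convergence is flagged on the returned model, never raised.
    """
    if lambda_mode not in ("fixed", "reml"):
        raise ConfigError(f"lambda_mode must be 'fixed' or 'reml', got {lambda_mode!r}")
    frame = prepare_model_frame(cycles, embryos, cutoffs, t4_threshold)
    return _fit_on_frame(
        spec, frame, lambda_mode, lambdas, sigma_u, cutoffs, t4_threshold,
        cycles, embryos,
    )


def _fit_on_frame(
    spec, frame, lambda_mode, lambdas, sigma_u, cutoffs, t4_threshold,
    cycles=None, embryos=None,
):
    y = _check_fit_inputs(frame, spec)
    svars = [s.variable for s in spec.smooth_terms]
    reml_val = None
    if lambda_mode == "reml" and (svars or spec.random_intercept):
        lambdas, sigma_u = select_smoothing_reml(
            spec, cycles, embryos, cutoffs, t4_threshold, frame=frame
        )
    else:
        lambdas = dict(lambdas or {})
        for v in svars:
            lambdas.setdefault(v, 1.0)
        if spec.random_intercept is not None and sigma_u is None:
            sigma_u = 0.5

    design = _Design(frame, spec)
    g, n_groups, group_labels = _groups(frame, spec)
    inv_sig2 = 0.0 if g is None else 1.0 / max(sigma_u, 1e-6) ** 2
    S = design.penalty_total({v: lambdas[v] for v in svars})
    res = _pirls(design.X, y, S, g, n_groups, inv_sig2)
    if not res.converged:
        logger.warning("IRLS did not converge in %d iterations", res.n_iter)

    per_coef, edf_u, V = _edf_and_cov(
        design.X, res.W, S, g, n_groups, inv_sig2, design.slices, design.penalties
    )

    edf = {}
    for name, sl in design.slices.items():
        val = float(per_coef[sl].sum())
        if name in svars:
            val += 1.0  # dof absorbed by the sum-to-zero constraint
        edf[name] = val
    if g is not None:
        edf["random_intercept"] = edf_u
    edf_total = float(sum(edf.values()))
    aic = res.deviance + 2.0 * edf_total

    term_pvalues = {}
    for name, sl in design.slices.items():
        if name == "intercept":
            continue
        b = res.beta[sl]
        Vj = V[sl, sl]
        try:
            stat = float(b @ np.linalg.solve(Vj, b))
        except np.linalg.LinAlgError:
            stat = float(b @ np.linalg.pinv(Vj) @ b)
        df = max(float(per_coef[sl].sum()), 0.5) if name in svars else (sl.stop - sl.start)
        term_pvalues[name] = float(chi2.sf(stat, df))

    eta = design.X @ res.beta + (res.u[g] if g is not None else 0.0)
    separation = bool(res.deviance < 1e-6 * len(y) and np.max(np.abs(eta)) > 20)
    if separation:
        logger.warning("complete separation suspected (near-zero deviance)")

    if lambda_mode == "reml" and (svars or spec.random_intercept):
        try:
            reml_val = _reml_criterion(
                design, res, {v: lambdas[v] for v in svars}, inv_sig2, g, n_groups
            )
        except np.linalg.LinAlgError:
            reml_val = None

    random_effects = None
    if g is not None:
        random_effects = {
            str(lbl): float(val) for lbl, val in zip(group_labels, res.u)
        }

    return FittedAdditiveModel(
        spec=spec,
        coefficients=res.beta,
        lambdas={v: float(lambdas[v]) for v in svars},
        sigma_u=None if sigma_u is None else float(sigma_u),
        edf=edf,
        edf_total=edf_total,
        aic=float(aic),
        deviance=float(res.deviance),
        term_pvalues=term_pvalues,
        converged=res.converged,
        train_fingerprint=_fingerprint(frame, spec),
        cutoffs=cutoffs,
        t4_threshold=t4_threshold,
        slices=design.slices,
        blocks=design.blocks,
        random_effects=random_effects,
        reml_criterion=reml_val,
        separation_suspected=separation,
        n_obs=len(y),
        fit_trace=list(res.obj_trace),
    )


# ---------------------------------------------------------------------------
# AIC forward selection
# ---------------------------------------------------------------------------

@dataclass
class SelectionResult:
    spec: ModelSpec
    steps: list  # one dict per step: candidate AICs and the decision


def aic_forward_selection(
    candidates: Sequence[Union[SmoothTerm, CategoricalTerm, str]],
    base: ModelSpec,
    cycles,
    embryos,
    lambda_mode: str = "reml",
    cutoffs: Cc2Cutoffs = Cc2Cutoffs(),
    t4_threshold: Optional[float] = None,
) -> SelectionResult:
    """Greedy forward selection by AIC (deviance + 2 * total edf).

    At each step the candidate with the largest AIC decrease is added;
    selection stops when no candidate decreases the AIC.  Candidates must
    be disjoint from the base terms.
    """
    base_names = set(base.term_names)
    cand = list(candidates)
    for t in cand:
        name = t if isinstance(t, str) else t.variable
        if name in base_names:
            raise ContractError(f"candidate '{name}' duplicates a base term")
    frame = prepare_model_frame(cycles, embryos, cutoffs, t4_threshold)

    def fit(spec):
        return _fit_on_frame(
            spec, frame, lambda_mode, None, None, cutoffs, t4_threshold
        )

    current = base
    current_aic = fit(base).aic
    steps = []
    while cand:
        trials = {}
        for t in cand:
            name = t if isinstance(t, str) else t.variable
            trials[name] = fit(current.with_term(t)).aic
        best_name = min(trials, key=trials.get)
        step = {"current_aic": current_aic, "candidate_aics": dict(trials)}
        if trials[best_name] < current_aic:
            step["added"] = best_name
            chosen = next(
                t for t in cand
                if (t if isinstance(t, str) else t.variable) == best_name
            )
            current = current.with_term(chosen)
            current_aic = trials[best_name]
            cand.remove(chosen)
            steps.append(step)
        else:
            step["added"] = None
            steps.append(step)
            break
    logger.info(
        "forward selection finished: terms=%s aic=%.2f",
        current.term_names, current_aic,
    )
    return SelectionResult(spec=current, steps=steps)
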