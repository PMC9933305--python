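"""Fully-conditional-specification (chained equations) multiple imputation.

A from-scratch MICE engine tailored to the simulation study: proper
Bayesian-draw linear regression for continuous targets, maximum-likelihood
logistic regression with asymptotic-Gaussian coefficient draws for binary
targets, interaction-aware predictor sets, and an exposure-stratified mode
in which the whole procedure runs independently within each exposure group
(making every exposure interaction implicit).

Method labels and their imputation-model interaction sets:

=========  =============================================  ==========
label      interaction terms                              stratified
=========  =============================================  ==========
MI-NI      none                                           no
MI-ExO     X*Y                                            no
MI-ExC     X*C5                                           no
MI-ExOC    X*Y, X*C5                                      no
MI-ExI     X*v for every variable v actually masked       no
MI-EG      none (all implicit)                            yes
=========  =============================================  ==========

Interaction terms containing the target are excluded from that target's
model, and interaction columns are recomputed from the current imputations
at every refit (passive recomputation; no stale products).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy.special import expit

from .datagen import COLUMNS
from .errors import ConfigError, DegenerateStratumError, ImputationError

__all__ = [
    "MI_METHODS",
    "ALL_METHODS",
    "ImputationSpec",
    "ImputedStack",
    "build_predictor_set",
    "impute_fcs",
    "impute_univariate_gaussian",
    "impute_univariate_logistic",
    "eg_imputation_count",
]

MI_METHODS = ("MI-NI", "MI-ExO", "MI-ExC", "MI-ExOC", "MI-ExI", "MI-EG")
ALL_METHODS = ("CCA",) + MI_METHODS

#: Univariate model per (potentially) incomplete variable.
VARIABLE_METHODS = {"C4": "logistic", "C5": "logistic", "Y": "gaussian", "A": "gaussian"}
#: Update order of incomplete variables within an FCS cycle.
UPDATE_ORDER = ("C4", "C5", "Y")
#: All analysis variables plus the auxiliary, in predictor order.
_PREDICTOR_POOL = ("X", "C1", "C2", "C3", "C4", "C5", "Y", "A")

_FIXED_INTERACTIONS = {
    "MI-NI": frozenset(),
    "MI-ExO": frozenset({("X", "Y")}),
    "MI-ExC": frozenset({("X", "C5")}),
    "MI-ExOC": frozenset({("X", "Y"), ("X", "C5")}),
    "MI-EG": frozenset(),
}

# Ridge used for numerical stability of every logistic fit, and the larger
# fixed penalty (on standardised predictors) engaged on detected separation
# or non-convergence.
_LOGIT_RIDGE = 1e-6
_LOGIT_RIDGE_FALLBACK = 1.0


@dataclass(frozen=True)
class ImputationSpec:
    """One missing-data method: label, interaction set, m and iterations."""

    method_label: str
    m: int = 30
    iterations: int = 5
    interaction_terms: frozenset = frozenset()
    stratify_by_exposure: bool = False
    variable_methods: tuple = tuple(sorted(VARIABLE_METHODS.items()))

    def __post_init__(self) -> None:
        if self.method_label not in ALL_METHODS:
            raise ConfigError(f"unknown method {self.method_label!r}")
        if self.method_label != "CCA":
            if self.m < 2:
                raise ConfigError("m must be >= 2")
            if self.iterations < 1:
                raise ConfigError("iterations must be >= 1")
        for term in self.interaction_terms:
            if not (isinstance(term, tuple) and len(term) == 2 and term[0] == "X"):
                raise ConfigError(f"interaction terms must be ('X', var) pairs, got {term}")
        label = self.method_label
        if label in _FIXED_INTERACTIONS and self.interaction_terms != _FIXED_INTERACTIONS[label]:
            raise ConfigError(f"{label} requires interaction set {set(_FIXED_INTERACTIONS[label])}")
        if self.stratify_by_exposure != (label == "MI-EG"):
            raise ConfigError("stratify_by_exposure is true exactly for MI-EG")

    @classmethod
    def from_method(
        cls,
        method_label: str,
        masked_variables: Sequence[str] = ("Y",),
        m: int = 30,
        iterations: int = 5,
    ) -> "ImputationSpec":
        """Build the spec for a method label given which variables are masked."""
        if method_label == "MI-ExI":
            terms = frozenset(("X", v) for v in masked_variables)
        elif method_label in _FIXED_INTERACTIONS:
            terms = _FIXED_INTERACTIONS[method_label]
        elif method_label == "CCA":
            terms = frozenset()
        else:
            raise ConfigError(f"unknown method {method_label!r}")
        return cls(
            method_label=method_label,
            m=m,
            iterations=iterations,
            interaction_terms=terms,
            stratify_by_exposure=(method_label == "MI-EG"),
        )

    def replace(self, **changes) -> "ImputationSpec":
        return dataclasses.replace(self, **changes)


@dataclass
class ImputedStack:
    """m completed datasets (column order :data:`mistrat.datagen.COLUMNS`)."""

    arrays: list
    spec: ImputationSpec
    seed: int
    provenance: dict = field(default_factory=dict)

    @property
    def m(self) -> int:
        return len(self.arrays)

    @property
    def frames(self) -> list:
        return [pd.DataFrame(a, columns=list(COLUMNS)) for a in self.arrays]

    def to_long_frame(self, original: Optional[np.ndarray] = None) -> pd.DataFrame:
        """Long format with an imputation-index column (0 = original data)."""
        parts = []
        if original is not None:
            df0 = pd.DataFrame(original, columns=list(COLUMNS))
            df0.insert(0, "imputation", 0)
            parts.append(df0)
        for j, a in enumerate(self.arrays, start=1):
            df = pd.DataFrame(a, columns=list(COLUMNS))
            df.insert(0, "imputation", j)
            parts.append(df)
        return pd.concat(parts, ignore_index=True)


def build_predictor_set(target: str, spec: ImputationSpec) -> list:
    """Ordered predictors for one univariate imputation model.

    All analysis variables plus the auxiliary A, excluding the target itself;
    then every interaction term whose components do not include the target.
    In stratified mode X (constant within a stratum) is excluded.
    """
    if target not in VARIABLE_METHODS:
        raise ConfigError(f"{target!r} is not an imputable variable")
    base = [v for v in _PREDICTOR_POOL if v != target]
    if spec.stratify_by_exposure:
        base = [v for v in base if v != "X"]
    inter = sorted(t for t in spec.interaction_terms if target not in t)
    return base + inter


def eg_imputation_count(data, minimum: int = 30) -> int:
    """Imputation count for MI-EG: max(minimum, ceil(% incomplete per stratum)).

    Both strata use the same m so imputed subsets pair up one-to-one.
    """
    x = data.true_values[:, data.column_index["X"]]
    worst = minimum
    for value in (0.0, 1.0):
        sel = x == value
        if sel.any():
            pct = 100.0 * float(data.mask_any[sel].mean())
            worst = max(worst, int(np.ceil(pct)))
    return worst


# ---------------------------------------------------------------------------
# univariate imputers
# ---------------------------------------------------------------------------

def _independent_columns(design: np.ndarray) -> np.ndarray:
    """Boolean mask of a maximal well-conditioned column subset.

    Constant columns (other than the leading intercept) are dropped first;
    any remaining near-collinearity is resolved with a pivoted QR.
    """
    n, p = design.shape
    keep = np.ones(p, dtype=bool)
    ptp = design.max(axis=0) - design.min(axis=0)
    keep[1:] = ptp[1:] > 0
    sub = design[:, keep]
    r = sla.qr(sub, mode="r", pivoting=True)
    diag = np.abs(np.diag(r[0]))
    tol = max(n, sub.shape[1]) * np.finfo(float).eps * (diag[0] if diag.size else 1.0)
    rank = int(np.sum(diag > tol))
    if rank < sub.shape[1]:
        pivots = r[1]
        kept_idx = np.flatnonzero(keep)[np.sort(pivots[:rank])]
        keep = np.zeros(p, dtype=bool)
        keep[kept_idx] = True
    return keep


def _gaussian_fit(target_obs: np.ndarray, design_obs: np.ndarray):
    """Least-squares sufficient statistics for the Bayesian draw step."""
    xo = design_obs
    keep = None
    try:
        chol = np.linalg.cholesky(xo.T @ xo)
    except np.linalg.LinAlgError:
        # collinear design: drop dependent columns and retry
        keep = _independent_columns(design_obs)
        xo = design_obs[:, keep]
        chol = np.linalg.cholesky(xo.T @ xo)
    n, p = xo.shape
    if n < p + 2:
        raise ImputationError(f"gaussian imputer needs >= {p + 2} observed rows, got {n}")
    beta_hat = sla.cho_solve((chol, True), xo.T @ target_obs, check_finite=False)
    resid = target_obs - xo @ beta_hat
    return chol, beta_hat, float(resid @ resid), n - p, keep


def _gaussian_draw(fit, design_mis: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    chol, beta_hat, rss, dof, keep = fit
    xm = design_mis if keep is None else design_mis[:, keep]
    p = beta_hat.size
    g = rng.chisquare(dof)
    sigma2 = rss / g if g > 0 else 0.0
    sigma = np.sqrt(sigma2)
    z = rng.standard_normal(p)
    # beta* = beta_hat + sigma * L^{-T} z has covariance sigma^2 (X'X)^{-1}
    beta_star = beta_hat + sigma * sla.solve_triangular(
        chol, z, lower=True, trans="T", check_finite=False
    )
    mu = xm @ beta_star
    return mu + sigma * rng.standard_normal(xm.shape[0])


def impute_univariate_gaussian(
    target_obs: np.ndarray,
    design_obs: np.ndarray,
    design_mis: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Proper Bayesian linear-regression draws for masked continuous values.

    Least squares on the observed rows; the residual variance is drawn from
    its scaled inverse-chi-square posterior, coefficients from their
    conditional Gaussian posterior, and each masked value from the resulting
    predictive Gaussian (flat prior on coefficients and log-variance).
    """
    return _gaussian_draw(_gaussian_fit(target_obs, design_obs), design_mis, rng)


def _newton_core(x, y, ridge, beta, max_iter, tol):
    """Ridge-stabilised Newton-Raphson for logistic regression.

    The ridge keeps the (penalised) information matrix positive definite even
    under separation or collinearity, so every step is well defined.
    """
    n, p = x.shape
    eye = np.eye(p)
    info = eye * ridge
    converged = False
    for _ in range(max_iter):
        eta = np.minimum(np.maximum(x @ beta, -35.0), 35.0)
        prob = 1.0 / (1.0 + np.exp(-eta))
        w = prob * (1.0 - prob)
        grad = x.T @ (y - prob) - ridge * beta
        info = (x * w.reshape(n, 1)).T @ x + ridge * eye
        step = np.linalg.solve(info, grad)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    return beta, info, converged


try:  # pragma: no cover - exercised implicitly on every logistic fit
    from numba import njit

    _newton_core = njit(cache=True)(_newton_core)
except ImportError:  # pure-numpy fallback, identical numerics
    pass


def _logistic_newton(x, y, ridge, beta0=None, max_iter=30, tol=1e-5):
    beta = np.zeros(x.shape[1]) if beta0 is None else beta0.copy()
    return _newton_core(
        np.ascontiguousarray(x), np.ascontiguousarray(y), ridge, beta, max_iter, tol
    )


def impute_univariate_logistic(
    target_obs: np.ndarray,
    design_obs: np.ndarray,
    design_mis: np.ndarray,
    rng: np.random.Generator,
    diagnostics: Optional[dict] = None,
    warm_start: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Logistic-regression draws for masked binary values.

    Maximum likelihood on the observed rows; coefficients are drawn from the
    asymptotic Gaussian approximation (mean = MLE, covariance = inverse
    observed information) and each masked value is Bernoulli at the implied
    probability. On separation, perfect prediction or non-convergence the
    fit is ridge-stabilised on standardised predictors with a fixed penalty.
    ``warm_start`` (e.g. the previous cycle's MLE) only speeds convergence.
    """
    fit = _logistic_fit(target_obs, design_obs, diagnostics, warm_start)
    return _logistic_draw(fit, design_mis, rng)


def _logistic_fit(target_obs, design_obs, diagnostics=None, warm_start=None):
    xo = design_obs
    n, p = xo.shape
    if n < p + 2:
        raise ImputationError(f"logistic imputer needs >= {p + 2} observed rows, got {n}")
    one_class = target_obs.min() == target_obs.max()
    beta, info, converged = (np.zeros(p), None, False)
    if not one_class:
        beta0 = warm_start if warm_start is not None and warm_start.shape == (p,) else None
        beta, info, converged = _logistic_newton(xo, target_obs, _LOGIT_RIDGE, beta0=beta0)
    if one_class or not converged or np.max(np.abs(beta)) > 10.0:
        # separation / perfect prediction: refit with a fixed ridge penalty
        # on standardised predictors
        scale = xo.std(axis=0)
        scale[scale == 0] = 1.0
        xs = xo / scale
        beta_s, info_s, converged = _logistic_newton(xs, target_obs, _LOGIT_RIDGE_FALLBACK)
        if not converged:
            raise ImputationError("logistic imputation failed to converge under ridge")
        beta = beta_s / scale
        # information on the original scale: I = S^{-1} I_s S^{-1}
        info = info_s / np.outer(scale, scale)
        if diagnostics is not None:
            diagnostics["n_ridge_fallbacks"] = diagnostics.get("n_ridge_fallbacks", 0) + 1
    # symmetrise the information against roundoff before factorising
    info = 0.5 * (info + info.T)
    try:
        info_chol = np.linalg.cholesky(info)
    except np.linalg.LinAlgError:
        info_chol = np.linalg.cholesky(info + 1e-8 * np.eye(p))
    return beta, info_chol


def _logistic_draw(fit, design_mis: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    beta, info_chol = fit
    # info = L L'; a draw with covariance info^{-1} is beta + L^{-T} z
    z = rng.standard_normal(beta.size)
    beta_star = beta + sla.solve_triangular(
        info_chol, z, lower=True, trans="T", check_finite=False
    )
    prob = expit(design_mis @ beta_star)
    return (rng.random(design_mis.shape[0]) < prob).astype(np.float64)


# ---------------------------------------------------------------------------
# the chained-equations engine
# ---------------------------------------------------------------------------

def _build_design(work: np.ndarray, col: dict, terms: list, rows=None) -> np.ndarray:
    src = work if rows is None else work[rows]
    out = np.empty((src.shape[0], len(terms) + 1))
    out[:, 0] = 1.0
    for j, t in enumerate(terms, start=1):
        if isinstance(t, str):
            out[:, j] = src[:, col[t]]
        else:
            out[:, j] = src[:, col[t[0]]] * src[:, col[t[1]]]
    return out


def _run_chain(
    values: np.ndarray,
    mask: np.ndarray,
    col: dict,
    order: list,
    predictor_sets: dict,
    methods: dict,
    iterations: int,
    rng: np.random.Generator,
    diagnostics: dict,
) -> np.ndarray:
    work = values.copy()
    # initialise masked cells by resampling observed values of the variable
    for v in order:
        j = col[v]
        miss = mask[:, j]
        obs = work[~miss, j]
        if obs.size == 0:
            raise ImputationError(f"no observed values of {v} to initialise from")
        work[miss, j] = obs[rng.integers(0, obs.size, int(miss.sum()))]
    warm: dict = {}
    for _ in range(iterations):
        for v in order:
            j = col[v]
            miss = mask[:, j]
            design = _build_design(work, col, predictor_sets[v])
            target_obs = work[~miss, j]
            if methods[v] == "gaussian":
                draws = impute_univariate_gaussian(
                    target_obs, design[~miss], design[miss], rng
                )
            else:
                fit = _logistic_fit(
                    target_obs, design[~miss], diagnostics, warm_start=warm.get(v)
                )
                warm[v] = fit[0]
                draws = _logistic_draw(fit, design[miss], rng)
            work[miss, j] = draws
    return work


def _fit_single(values, mask, col, variable, predictor_sets, methods, diagnostics):
    """Fit the single incomplete variable's model once (predictors complete)."""
    j = col[variable]
    design = _build_design(values, col, predictor_sets[variable])
    miss = mask[:, j]
    obs = values[~miss, j]
    if methods[variable] == "gaussian":
        return ("gaussian", _gaussian_fit(obs, design[~miss]), design, miss)
    return ("logistic", _logistic_fit(obs, design[~miss], diagnostics), design, miss)


def _draw_single(fit_state, rng):
    kind, fit, design, miss = fit_state
    if kind == "gaussian":
        return _gaussian_draw(fit, design[miss], rng)
    return _logistic_draw(fit, design[miss], rng)


def impute_fcs(data, spec: ImputationSpec, seed) -> ImputedStack:
    """Run chained-equations MI and return the m completed datasets.

    Each of the m streams initialises masked cells from the observed
    marginals, then cycles ``spec.iterations`` times over the incomplete
    variables in the order C4, C5, Y, refitting that variable's univariate
    model on rows where it is observed and redrawing its masked values.
    In stratified mode the whole procedure runs independently within the
    X=0 and X=1 subsets, which are recombined per imputed dataset.
    """
    if spec.method_label == "CCA":
        raise ConfigError("CCA is not an imputation method")
    values = data.values
    mask = data.mask
    col = data.column_index
    order = [v for v in UPDATE_ORDER if mask[:, col[v]].any()]
    seed_label = int(seed) if isinstance(seed, (int, np.integer)) else -1
    if not order:
        arrays = [data.true_values.copy() for _ in range(spec.m)]
        return ImputedStack(arrays=arrays, spec=spec, seed=seed_label, provenance={})
    predictor_sets = {v: build_predictor_set(v, spec) for v in order}
    methods = dict(spec.variable_methods)
    diagnostics: dict = {}
    arrays = []
    # With a single incomplete variable its imputation model is refitted on
    # the same (fully observed) rows at every cycle, so the fit is shared
    # across streams and cycles and only the posterior draws differ.
    single = len(order) == 1
    if spec.stratify_by_exposure:
        x = data.true_values[:, col["X"]]
        if mask[:, col["X"]].any():
            raise ConfigError("stratified imputation requires fully observed exposure")
        strata = [np.flatnonzero(x == v) for v in (0.0, 1.0)]
        for s, idx in zip(("X=0", "X=1"), strata):
            if idx.size == 0:
                raise DegenerateStratumError(f"empty exposure stratum {s}")
            n_pred = max(len(predictor_sets[v]) for v in order) + 1
            n_obs_min = min(int((~mask[idx][:, col[v]]).sum()) for v in order)
            if n_obs_min < n_pred + 2:
                raise DegenerateStratumError(
                    f"stratum {s}: {n_obs_min} observed rows for {n_pred} predictors"
                )
        if single:
            fits = [
                _fit_single(values[idx], mask[idx], col, order[0],
                            predictor_sets, methods, diagnostics)
                for idx in strata
            ]
        for j in range(spec.m):
            full = np.empty_like(values)
            for k, idx in enumerate(strata):
                rng = np.random.Generator(
                    np.random.PCG64(np.random.SeedSequence((_entropy(seed), j, k)))
                )
                if single:
                    sub = values[idx].copy()
                    sub[fits[k][3], col[order[0]]] = _draw_single(fits[k], rng)
                    full[idx] = sub
                else:
                    full[idx] = _run_chain(
                        values[idx], mask[idx], col, order, predictor_sets,
                        methods, spec.iterations, rng, diagnostics,
                    )
            arrays.append(full)
    else:
        if single:
            fit_state = _fit_single(
                values, mask, col, order[0], predictor_sets, methods, diagnostics
            )
        for j in range(spec.m):
            rng = np.random.Generator(
                np.random.PCG64(np.random.SeedSequence((_entropy(seed), j)))
            )
            if single:
                work = values.copy()
                work[fit_state[3], col[order[0]]] = _draw_single(fit_state, rng)
                arrays.append(work)
            else:
                arrays.append(
                    _run_chain(
                        values, mask, col, order, predictor_sets,
                        methods, spec.iterations, rng, diagnostics,
                    )
                )
    return ImputedStack(arrays=arrays, spec=spec, seed=seed_label, provenance=diagnostics)


def _entropy(seed) -> int:
    if isinstance(seed, (int, np.integer)):
        return int(seed)
    if isinstance(seed, np.random.SeedSequence):
        return int(seed.entropy if isinstance(seed.entropy, int) else seed.entropy[0])
    raise ConfigError("seed must be an int or SeedSequence")
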