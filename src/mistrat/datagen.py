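"""Complete-data generation for the simulation study.

Generates cohort-like datasets with one standardised continuous auxiliary
variable ``A``, five binary confounders ``C1``–``C5`` drawn sequentially from
logistic models on all previously generated variables, a binary exposure ``X``
drawn from a logistic model on ``(A, C1..C5)``, and a continuous outcome ``Y``
from a linear model whose mean includes a main exposure effect and an
exposure-by-``C5`` interaction of relative strength ``delta``:

    E[Y | X, C] = a0 + a1*C1 + ... + a5*C5 + a6*X + delta*a6*X*C5

Both exposure terms carry ``a6``, so the large-sample coefficient of ``X`` in
the no-interaction analysis model is linear in ``a6`` at fixed ``delta``; the
calibration routines below exploit this to pin the target estimand (the
marginal exposure coefficient) to a design value, and to pin the exposure
prevalence to 10/30/50%.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .errors import CalibrationError, ConfigError

__all__ = [
    "COLUMNS",
    "CONFOUNDERS",
    "GenerationConfig",
    "CompleteDataset",
    "default_config",
    "generate_complete",
    "calibrate_exposure_intercept",
    "calibrate_alpha6",
    "calibrate_confounder_intercepts",
]

#: Column order of a generated dataset (also the sequential generation order).
COLUMNS = ("A", "C1", "C2", "C3", "C4", "C5", "X", "Y")
CONFOUNDERS = ("C1", "C2", "C3", "C4", "C5")

#: Dedicated seed for calibration draws, independent of replicate seeds so
#: that scenario parameters are constants across replicates.
CALIBRATION_SEED = 202302

_DELTA_GRID = (0.0, 0.25, -0.25, 0.5, -0.5, 0.75, -0.75)
_PREVALENCE_GRID = (0.10, 0.30, 0.50)

# Default coefficient set. The slopes are chosen so that (a) the marginal
# confounder prevalences track the case-study descriptive table and (b) the
# exposure is strongly positively associated with C2-C5 (most strongly with
# C4 and C5) and weakly with A and C1, mirroring the exposed-vs-unexposed
# contrasts in that table. Intercepts for C2-C5 were fixed once by
# `calibrate_confounder_intercepts` at n=10^6 (see docs/methods.md).
DEFAULT_C1_PREVALENCE = 0.375
DEFAULT_CONFOUNDER_COEFFS: Mapping[str, tuple[float, ...]] = {
    #        icpt,    A,   C1,   C2,   C3,   C4
    "C2": (-1.4441, 0.0, 0.40),
    "C3": (-2.4539, 0.0, 0.30, 0.70),
    "C4": (-0.8316, 0.1, 0.20, 0.40, 0.90),
    "C5": (-0.1332, 0.1, 0.30, 0.40, 0.60, 0.70),
}
#            icpt,    A,   C1,   C2,   C3,   C4,   C5
DEFAULT_EXPOSURE_COEFFS = (0.0, 0.15, 0.10, 0.80, 1.20, 1.80, 0.80)
#                a0,   a1,   a2,   a3,   a4,   a5,   a6
DEFAULT_ALPHA = (0.0, 0.10, 0.15, 0.20, 0.15, 0.40, 0.30)
# Residual SD of Y given (X, C): fixed once so that the complete-data
# analysis at (n=700, 30% prevalence) has ~80% power for theta1=0.3 at the
# 5% level (see docs/methods.md).
DEFAULT_SIGMA_Y = 1.125


@dataclass(frozen=True)
class GenerationConfig:
    """All parameters of the sequential complete-data generator."""

    n: int
    exposure_prevalence: float
    delta: float
    alpha: tuple[float, ...] = DEFAULT_ALPHA
    sigma_y: float = DEFAULT_SIGMA_Y
    c1_prevalence: float = DEFAULT_C1_PREVALENCE
    confounder_coeffs: Mapping[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_CONFOUNDER_COEFFS)
    )
    exposure_coeffs: tuple[float, ...] = DEFAULT_EXPOSURE_COEFFS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ConfigError(f"n must be >= 1, got {self.n}")
        if not any(np.isclose(self.exposure_prevalence, p) for p in _PREVALENCE_GRID):
            raise ConfigError(
                f"exposure_prevalence must be one of {_PREVALENCE_GRID}, "
                f"got {self.exposure_prevalence}"
            )
        if not any(np.isclose(self.delta, d) for d in _DELTA_GRID):
            raise ConfigError(f"delta must be in {sorted(_DELTA_GRID)}, got {self.delta}")
        if not self.sigma_y >= 0:
            raise ConfigError(f"sigma_y must be >= 0, got {self.sigma_y}")
        if len(self.alpha) != 7:
            raise ConfigError("alpha must have 7 entries (a0..a6)")
        if not 0 < self.c1_prevalence < 1:
            raise ConfigError("c1_prevalence must lie in (0, 1)")
        for k, name in enumerate(("C2", "C3", "C4", "C5"), start=2):
            coeffs = self.confounder_coeffs.get(name)
            if coeffs is None or len(coeffs) != k + 1:
                raise ConfigError(
                    f"confounder_coeffs[{name!r}] must have {k + 1} entries "
                    f"(intercept + slopes on A, C1..C{k - 1})"
                )
        if len(self.exposure_coeffs) != 7:
            raise ConfigError("exposure_coeffs must have 7 entries (intercept + A, C1..C5)")

    @property
    def alpha6(self) -> float:
        return self.alpha[6]

    def replace(self, **changes) -> "GenerationConfig":
        return dataclasses.replace(self, **changes)

    def with_alpha6(self, alpha6: float) -> "GenerationConfig":
        return self.replace(alpha=self.alpha[:6] + (float(alpha6),))

    def with_exposure_intercept(self, intercept: float) -> "GenerationConfig":
        return self.replace(
            exposure_coeffs=(float(intercept),) + tuple(self.exposure_coeffs[1:])
        )


@dataclass(frozen=True)
class CompleteDataset:
    """A fully observed simulated cohort plus its generating configuration."""

    frame: pd.DataFrame
    config: GenerationConfig
    seed: int

    def __post_init__(self) -> None:
        if list(self.frame.columns) != list(COLUMNS):
            raise ConfigError(f"dataset columns must be {COLUMNS}")

    @property
    def n(self) -> int:
        return len(self.frame)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def default_config(
    n: int,
    exposure_prevalence: float,
    delta: float,
    seed: int = 0,
    **overrides,
) -> GenerationConfig:
    """Default-coefficient configuration; exposure intercept and the main
    exposure effect still require calibration (see :mod:`mistrat.scenarios`)."""
    return GenerationConfig(
        n=n,
        exposure_prevalence=exposure_prevalence,
        delta=delta,
        seed=seed,
        **overrides,
    )


def _as_generator(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.Generator(np.random.PCG64(seed))


def _logistic_prob(linear_predictor: np.ndarray) -> np.ndarray:
    if not np.all(np.isfinite(linear_predictor)):
        raise ConfigError("non-finite linear predictor in logistic model")
    return expit(linear_predictor)


def _draw_covariates(config: GenerationConfig, rng: np.random.Generator, n: int):
    """Draw (A, C1..C5) following the sequential generation order."""
    a = rng.standard_normal(n)
    cols = {"A": a}
    c1 = (rng.random(n) < config.c1_prevalence).astype(np.float64)
    cols["C1"] = c1
    for name in ("C2", "C3", "C4", "C5"):
        coeffs = np.asarray(config.confounder_coeffs[name], dtype=np.float64)
        lp = coeffs[0] + _stack_previous(cols, name) @ coeffs[1:]
        p = _logistic_prob(lp)
        cols[name] = (rng.random(n) < p).astype(np.float64)
    return cols


def _stack_previous(cols: dict, upto: str) -> np.ndarray:
    order = ["A", "C1", "C2", "C3", "C4", "C5"]
    prev = order[: order.index(upto)]
    return np.column_stack([cols[v] for v in prev])


def _exposure_linear_predictor(config: GenerationConfig, cols: dict) -> np.ndarray:
    coeffs = np.asarray(config.exposure_coeffs, dtype=np.float64)
    design = np.column_stack([cols[v] for v in ("A", "C1", "C2", "C3", "C4", "C5")])
    return coeffs[0] + design @ coeffs[1:]


def _outcome_mean(config: GenerationConfig, cols: dict, x: np.ndarray) -> np.ndarray:
    a = np.asarray(config.alpha, dtype=np.float64)
    c = np.column_stack([cols[v] for v in CONFOUNDERS])
    return a[0] + c @ a[1:6] + a[6] * x + config.delta * a[6] * x * cols["C5"]


def generate_complete(config: GenerationConfig, seed=None) -> CompleteDataset:
    """Generate ``config.n`` records following the sequential scheme.

    ``A`` is standard normal; ``C1`` is Bernoulli at its marginal prevalence;
    ``C2..C5`` and ``X`` are Bernoulli with logistic-linear probabilities in
    all previously generated variables; ``Y`` is the interaction-model mean
    plus Gaussian noise with SD ``config.sigma_y``. Bit-reproducible given
    ``(config, seed)``.
    """
    used_seed = config.seed if seed is None else seed
    rng = _as_generator(used_seed)
    n = config.n
    cols = _draw_covariates(config, rng, n)
    px = _logistic_prob(_exposure_linear_predictor(config, cols))
    x = (rng.random(n) < px).astype(np.float64)
    y = _outcome_mean(config, cols, x)
    if config.sigma_y > 0:
        y = y + config.sigma_y * rng.standard_normal(n)
    frame = pd.DataFrame(
        {**{v: cols[v] for v in ("A", "C1", "C2", "C3", "C4", "C5")}, "X": x, "Y": y},
        columns=list(COLUMNS),
    )
    seed_label = used_seed if isinstance(used_seed, (int, np.integer)) else -1
    return CompleteDataset(frame=frame, config=config, seed=int(seed_label))


def _brentq_intercept(expected_rate, target: float, bracket: tuple[float, float], what: str):
    lo, hi = bracket
    f_lo = expected_rate(lo) - target
    f_hi = expected_rate(hi) - target
    if f_lo * f_hi > 0:
        raise CalibrationError(
            f"{what}: target {target} not bracketed by intercepts in [{lo}, {hi}]"
        )
    return float(brentq(lambda b: expected_rate(b) - target, lo, hi, xtol=1e-10))


def calibrate_exposure_intercept(
    config: GenerationConfig,
    target_prevalence: float,
    n_calibration: int = 10**6,
    seed: int = CALIBRATION_SEED,
) -> float:
    """Intercept of the exposure model such that marginal P(X=1) hits the target.

    Root-finding is on the *expected* prevalence — the mean of each simulated
    record's logistic probability — over one large covariate draw, which is a
    lower-variance version of redrawing X at every candidate intercept. The
    prevalence is monotone in the intercept, so the root is unique.
    """
    if not 0 < target_prevalence < 1:
        raise ConfigError("target_prevalence must lie in (0, 1)")
    if n_calibration < 10**5:
        raise ConfigError("n_calibration must be >= 1e5")
    rng = _as_generator(seed)
    cols = _draw_covariates(config, rng, n_calibration)
    slopes = np.asarray(config.exposure_coeffs[1:], dtype=np.float64)
    design = np.column_stack([cols[v] for v in ("A", "C1", "C2", "C3", "C4", "C5")])
    lp = design @ slopes

    def expected_rate(b0: float) -> float:
        return float(np.mean(expit(b0 + lp)))

    return _brentq_intercept(expected_rate, target_prevalence, (-10.0, 10.0), "exposure intercept")


def calibrate_alpha6(
    config: GenerationConfig,
    target_theta1: float = 0.3,
    n_calibration: int = 10**6,
    seed: int = CALIBRATION_SEED,
) -> float:
    """Main exposure effect ``a6`` pinning the no-interaction X-coefficient.

    Both exposure terms in the outcome mean carry ``a6``, so the large-sample
    coefficient of X in the no-interaction analysis model is ``a6 * c`` where
    ``c`` depends only on ``delta`` and the covariate/exposure distribution.
    Fit once on a large noiseless dataset with ``a6 = 1`` to measure ``c``,
    then return ``target_theta1 / c``.
    """
    if not np.isfinite(target_theta1):
        raise ConfigError("target_theta1 must be finite")
    if target_theta1 == 0:
        return 0.0
    probe = config.replace(n=int(n_calibration), sigma_y=0.0).with_alpha6(1.0)
    data = generate_complete(probe, seed=seed)
    from .estimation import fit_outcome_regression

    fit = fit_outcome_regression(data.frame)
    c = fit.params["X"]
    if abs(c) < 1e-8:
        raise CalibrationError("degenerate design: X coefficient vanishes at a6=1")
    return float(target_theta1 / c)


def calibrate_confounder_intercepts(
    config: GenerationConfig,
    targets: Mapping[str, float],
    n_calibration: int = 10**6,
    seed: int = CALIBRATION_SEED,
) -> GenerationConfig:
    """Return a config whose C2..C5 intercepts hit the given marginal prevalences.

    Calibration is sequential in generation order because each confounder's
    distribution depends on the earlier ones: each intercept is root-found on
    the expected prevalence, after which the confounder is actually drawn to
    feed the next model.
    """
    rng = _as_generator(seed)
    n = int(n_calibration)
    cols = {"A": rng.standard_normal(n)}
    cols["C1"] = (rng.random(n) < config.c1_prevalence).astype(np.float64)
    new_coeffs = {}
    for name in ("C2", "C3", "C4", "C5"):
        coeffs = np.asarray(config.confounder_coeffs[name], dtype=np.float64)
        lp = _stack_previous(cols, name) @ coeffs[1:]
        target = targets.get(name)
        if target is None:
            icpt = coeffs[0]
        else:
            icpt = _brentq_intercept(
                lambda b0: float(np.mean(expit(b0 + lp))),
                target,
                (-10.0, 10.0),
                f"{name} intercept",
            )
        new_coeffs[name] = (float(icpt),) + tuple(coeffs[1:])
        cols[name] = (rng.random(n) < expit(icpt + lp)).astype(np.float64)
    return config.replace(confounder_coeffs=new_coeffs)
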