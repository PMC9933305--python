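"""MAR missingness mechanisms and their intercept calibration.

Two missingness structures are supported:

* ``outcome_only`` — only the outcome ``Y`` can be missing, with indicator

      logit P(M_Y = 1) = b0 + 0.030*A + log(3)*X + b1*C5 + b2*X*C5

* ``outcome_and_confounders`` — ``C4``, ``C5`` and ``Y`` become missing
  sequentially:

      logit P(M_C4 = 1) = g0 + 0.323*A - 0.624*X
      logit P(M_C5 = 1) = z0 - 0.029*A + 3.835*M_C4 + log(3)*X + z1*C5 + z2*X*C5
      logit P(M_Y  = 1) = e0 - 0.025*A + 0.685*M_C4 + 0.658*M_C5
                          + log(3)*X + e1*C5 + e2*X*C5

Three scenarios set the C5 and X*C5 slopes: (i) both zero (missingness
depends on exposure only), (ii) C5 slope log(3), (iii) C5 slope log(3) and
interaction slope log(2). Intercepts are calibrated so the marginal
missingness proportions hit 30% (outcome-only) or 10/10/20% (multivariable);
in the multivariable structure ~30% of records end up with any missing value.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from functools import cached_property

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .datagen import COLUMNS, CompleteDataset, GenerationConfig, CALIBRATION_SEED, generate_complete
from .errors import CalibrationError, ConfigError

__all__ = [
    "STRUCTURES",
    "SCENARIOS",
    "MissingnessConfig",
    "IncompleteDataset",
    "impose_missingness",
    "calibrate_missingness_intercepts",
]

STRUCTURES = ("outcome_only", "outcome_and_confounders")
SCENARIOS = ("i", "ii", "iii")
INDICATORS = ("M_C4", "M_C5", "M_Y")

LOG3 = math.log(3.0)
LOG2 = math.log(2.0)

# Fixed (non-calibrated) slopes of the missingness models.
A_SLOPE_MY_OUTCOME_ONLY = 0.030
A_SLOPE_MC4, X_SLOPE_MC4 = 0.323, -0.624
A_SLOPE_MC5, MC4_SLOPE_MC5 = -0.029, 3.835
A_SLOPE_MY, MC4_SLOPE_MY, MC5_SLOPE_MY = -0.025, 0.685, 0.658

_SCENARIO_SLOPES = {"i": (0.0, 0.0), "ii": (LOG3, 0.0), "iii": (LOG3, LOG2)}

#: Target marginal missingness proportions per structure.
TARGETS_OUTCOME_ONLY = {"Y": 0.30}
TARGETS_MULTIVARIABLE = {"C4": 0.10, "C5": 0.10, "Y": 0.20}


@dataclass(frozen=True)
class MissingnessConfig:
    """One missingness mechanism: structure, scenario and model intercepts.

    Intercepts default to NaN ("not yet calibrated"); the C5 / X*C5 slopes
    are set by the scenario and validated against it.
    """

    structure: str
    scenario: str
    beta0: float = math.nan   # M_Y intercept, outcome-only structure
    gamma0: float = math.nan  # M_C4 intercept
    zeta0: float = math.nan   # M_C5 intercept
    eta0: float = math.nan    # M_Y intercept, multivariable structure
    beta1: float = 0.0
    beta2: float = 0.0
    zeta1: float = 0.0
    zeta2: float = 0.0
    eta1: float = 0.0
    eta2: float = 0.0

    def __post_init__(self) -> None:
        if self.structure not in STRUCTURES:
            raise ConfigError(f"structure must be one of {STRUCTURES}")
        if self.scenario not in SCENARIOS:
            raise ConfigError(f"scenario must be one of {SCENARIOS}")
        c5, inter = _SCENARIO_SLOPES[self.scenario]
        if self.structure == "outcome_only":
            expected = {"beta1": c5, "beta2": inter, "zeta1": 0.0, "zeta2": 0.0,
                        "eta1": 0.0, "eta2": 0.0}
        else:
            expected = {"beta1": 0.0, "beta2": 0.0, "zeta1": c5, "zeta2": inter,
                        "eta1": c5, "eta2": inter}
        for name, value in expected.items():
            if not np.isclose(getattr(self, name), value):
                raise ConfigError(
                    f"slope {name}={getattr(self, name)} inconsistent with "
                    f"scenario ({self.scenario}) / structure {self.structure}"
                )

    @classmethod
    def for_scenario(cls, structure: str, scenario: str) -> "MissingnessConfig":
        if scenario not in _SCENARIO_SLOPES:
            raise ConfigError(f"scenario must be one of {SCENARIOS}")
        c5, inter = _SCENARIO_SLOPES[scenario]
        if structure == "outcome_only":
            return cls(structure, scenario, beta1=c5, beta2=inter)
        return cls(structure, scenario, zeta1=c5, zeta2=inter, eta1=c5, eta2=inter)

    @property
    def target_proportions(self) -> dict:
        if self.structure == "outcome_only":
            return dict(TARGETS_OUTCOME_ONLY)
        return dict(TARGETS_MULTIVARIABLE)

    @property
    def calibrated(self) -> bool:
        if self.structure == "outcome_only":
            return np.isfinite(self.beta0)
        return all(np.isfinite(v) for v in (self.gamma0, self.zeta0, self.eta0))

    def replace(self, **changes) -> "MissingnessConfig":
        return dataclasses.replace(self, **changes)


@dataclass
class IncompleteDataset:
    """A complete dataset plus its missingness indicators.

    ``masked_frame`` carries NaN where a value is missing and is what the
    missing-data methods see. The underlying complete data are retained for
    oracle checks only and must never inform estimation.
    """

    complete: CompleteDataset
    indicators: pd.DataFrame
    config: MissingnessConfig
    seed: int

    def __post_init__(self) -> None:
        if list(self.indicators.columns) != list(INDICATORS):
            raise ConfigError(f"indicator columns must be {INDICATORS}")
        if len(self.indicators) != self.complete.n:
            raise ConfigError("indicator matrix length mismatch")

    @property
    def n(self) -> int:
        return self.complete.n

    @cached_property
    def column_index(self) -> dict:
        return {v: j for j, v in enumerate(COLUMNS)}

    @cached_property
    def true_values(self) -> np.ndarray:
        """(n x 8) matrix of the underlying complete values — oracle use only."""
        return np.ascontiguousarray(self.complete.frame.to_numpy(dtype=np.float64))

    @cached_property
    def mask(self) -> np.ndarray:
        """(n x 8) boolean matrix, True where the value is missing."""
        out = np.zeros(self.true_values.shape, dtype=bool)
        ind = self.indicators.to_numpy(dtype=bool)
        col = self.column_index
        out[:, col["C4"]] = ind[:, 0]
        out[:, col["C5"]] = ind[:, 1]
        out[:, col["Y"]] = ind[:, 2]
        return out

    @cached_property
    def values(self) -> np.ndarray:
        """(n x 8) matrix with NaN at masked cells."""
        out = self.true_values.copy()
        out[self.mask] = np.nan
        return out

    @cached_property
    def mask_any(self) -> np.ndarray:
        """True for records with at least one masked analysis variable."""
        return self.mask.any(axis=1)

    @property
    def masked_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=list(COLUMNS))

    def to_csv(self, path, indicator_path=None) -> None:
        self.masked_frame.to_csv(path, index=False)
        if indicator_path is not None:
            self.indicators.to_csv(indicator_path, index=False)


def _linear_predictors(config: MissingnessConfig, a, x, c5):
    """Per-record linear predictors excluding intercepts and M_* terms."""
    if config.structure == "outcome_only":
        return {
            "Y": A_SLOPE_MY_OUTCOME_ONLY * a + LOG3 * x
            + config.beta1 * c5 + config.beta2 * x * c5
        }
    return {
        "C4": A_SLOPE_MC4 * a + X_SLOPE_MC4 * x,
        "C5": A_SLOPE_MC5 * a + LOG3 * x + config.zeta1 * c5 + config.zeta2 * x * c5,
        "Y": A_SLOPE_MY * a + LOG3 * x + config.eta1 * c5 + config.eta2 * x * c5,
    }


def impose_missingness(data: CompleteDataset, config: MissingnessConfig, seed) -> IncompleteDataset:
    """Draw missingness indicators and mask the corresponding cells.

    In the multivariable structure the indicators are drawn sequentially:
    M_C4 first, then M_C5 given M_C4, then M_Y given both. A, C1, C2, C3 and
    X are always fully observed. Deterministic given (data, config, seed).
    """
    if not config.calibrated:
        raise ConfigError("missingness intercepts are not calibrated")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.Generator(np.random.PCG64(seed))
    frame = data.frame
    a = frame["A"].to_numpy()
    x = frame["X"].to_numpy()
    c5 = frame["C5"].to_numpy()
    n = len(frame)
    lps = _linear_predictors(config, a, x, c5)
    zeros = np.zeros(n, dtype=np.int8)
    if config.structure == "outcome_only":
        m_y = (rng.random(n) < expit(config.beta0 + lps["Y"])).astype(np.int8)
        ind = pd.DataFrame({"M_C4": zeros, "M_C5": zeros, "M_Y": m_y})
    else:
        m_c4 = (rng.random(n) < expit(config.gamma0 + lps["C4"])).astype(np.int8)
        m_c5 = (
            rng.random(n) < expit(config.zeta0 + MC4_SLOPE_MC5 * m_c4 + lps["C5"])
        ).astype(np.int8)
        m_y = (
            rng.random(n)
            < expit(config.eta0 + MC4_SLOPE_MY * m_c4 + MC5_SLOPE_MY * m_c5 + lps["Y"])
        ).astype(np.int8)
        ind = pd.DataFrame({"M_C4": m_c4, "M_C5": m_c5, "M_Y": m_y})
    seed_label = seed if isinstance(seed, (int, np.integer)) else -1
    return IncompleteDataset(complete=data, indicators=ind, config=config, seed=int(seed_label))


def _solve_intercept(expected_rate, target: float, what: str) -> float:
    lo, hi = -15.0, 15.0
    if (expected_rate(lo) - target) * (expected_rate(hi) - target) > 0:
        raise CalibrationError(f"{what}: target {target} unreachable in [{lo}, {hi}]")
    return float(brentq(lambda b: expected_rate(b) - target, lo, hi, xtol=1e-10))


def calibrate_missingness_intercepts(
    config: MissingnessConfig,
    generator: GenerationConfig,
    n_calibration: int = 10**6,
    seed: int = CALIBRATION_SEED,
) -> MissingnessConfig:
    """Calibrate the model intercepts to the target marginal proportions.

    One large complete dataset is drawn; each intercept is then root-found on
    the *expected* missingness proportion, averaging every record's logistic
    probability and marginalising analytically over the earlier indicators
    (which enter the later models). Calibration is sequential — M_C4, then
    M_C5 given the calibrated M_C4 model, then M_Y given both — because the
    chain of models is triangular in the indicators.
    """
    if n_calibration < 10**5:
        raise ConfigError("n_calibration must be >= 1e5")
    data = generate_complete(generator.replace(n=int(n_calibration)), seed=seed)
    frame = data.frame
    a = frame["A"].to_numpy()
    x = frame["X"].to_numpy()
    c5 = frame["C5"].to_numpy()
    lps = _linear_predictors(config, a, x, c5)
    targets = config.target_proportions

    if config.structure == "outcome_only":
        beta0 = _solve_intercept(
            lambda b: float(np.mean(expit(b + lps["Y"]))), targets["Y"], "beta0"
        )
        return config.replace(beta0=beta0)

    gamma0 = _solve_intercept(
        lambda b: float(np.mean(expit(b + lps["C4"]))), targets["C4"], "gamma0"
    )
    p4 = expit(gamma0 + lps["C4"])

    def rate_c5(z0: float) -> float:
        p = p4 * expit(z0 + MC4_SLOPE_MC5 + lps["C5"]) + (1 - p4) * expit(z0 + lps["C5"])
        return float(np.mean(p))

    zeta0 = _solve_intercept(rate_c5, targets["C5"], "zeta0")
    p5_given_m4 = expit(zeta0 + MC4_SLOPE_MC5 + lps["C5"])
    p5_given_not4 = expit(zeta0 + lps["C5"])

    def rate_y(e0: float) -> float:
        total = np.zeros_like(p4)
        for m4, m5_prob in ((1.0, p5_given_m4), (0.0, p5_given_not4)):
            w4 = p4 if m4 else 1 - p4
            for m5 in (1.0, 0.0):
                w = w4 * (m5_prob if m5 else 1 - m5_prob)
                total += w * expit(e0 + MC4_SLOPE_MY * m4 + MC5_SLOPE_MY * m5 + lps["Y"])
        return float(np.mean(total))

    eta0 = _solve_intercept(rate_y, targets["Y"], "eta0")
    return config.replace(gamma0=gamma0, zeta0=zeta0, eta0=eta0)
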