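"""Calibrated scenario parameters, with text-file persistence.

Every simulation cell is described by (exposure prevalence, sample size,
delta, missingness structure, missingness scenario). The calibrated
quantities are shared across cells where possible:

* the exposure-model intercept depends only on the prevalence;
* the outcome main effect a6 depends on (prevalence, delta);
* the missingness intercepts depend on (prevalence, structure, scenario) —
  the missingness models involve only A, X, C5 and earlier indicators, whose
  joint distribution does not change with delta.

A :class:`ScenarioTable` computes each quantity on first use (with the
dedicated calibration seed) and can be saved to / loaded from JSON so that
simulation runs never re-calibrate.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

from . import datagen
from .datagen import GenerationConfig, default_config
from .missingness import MissingnessConfig, calibrate_missingness_intercepts

__all__ = ["DEFAULT_SAMPLE_SIZES", "SECONDARY_SAMPLE_SIZES", "ScenarioTable"]

#: Primary-grid sample size for each exposure prevalence (chosen to give
#: comparable standard errors for the effect estimate across prevalences).
DEFAULT_SAMPLE_SIZES = {0.10: 1300, 0.30: 700, 0.50: 550}
#: Secondary grid: sample sizes at 10% prevalence.
SECONDARY_SAMPLE_SIZES = (500, 1300, 2000, 2750)

_DELTAS = (-0.75, -0.5, -0.25, 0.0, 0.25, 0.5, 0.75)


def _pkey(prevalence: float) -> str:
    return f"{prevalence:.2f}"


def _dkey(prevalence: float, delta: float) -> str:
    return f"{prevalence:.2f}|{delta:+.2f}"


def _mkey(prevalence: float, structure: str, scenario: str) -> str:
    return f"{prevalence:.2f}|{structure}|{scenario}"


class ScenarioTable:
    """Lazily calibrated scenario parameters keyed by cell identifiers."""

    def __init__(self, n_calibration: int = 10**6, seed: int = datagen.CALIBRATION_SEED):
        self.n_calibration = int(n_calibration)
        self.seed = int(seed)
        self.exposure_intercepts: dict[str, float] = {}
        self.alpha6: dict[str, float] = {}
        self.missingness: dict[str, dict] = {}

    # -- calibration-on-demand -------------------------------------------
    def exposure_intercept(self, prevalence: float) -> float:
        key = _pkey(prevalence)
        if key not in self.exposure_intercepts:
            probe = default_config(n=1, exposure_prevalence=prevalence, delta=0.0)
            self.exposure_intercepts[key] = datagen.calibrate_exposure_intercept(
                probe, prevalence, self.n_calibration, seed=self.seed
            )
        return self.exposure_intercepts[key]

    def alpha6_for(self, prevalence: float, delta: float) -> float:
        key = _dkey(prevalence, delta)
        if key not in self.alpha6:
            probe = default_config(
                n=1, exposure_prevalence=prevalence, delta=delta
            ).with_exposure_intercept(self.exposure_intercept(prevalence))
            self.alpha6[key] = datagen.calibrate_alpha6(
                probe, 0.3, self.n_calibration, seed=self.seed
            )
        return self.alpha6[key]

    def generation_config(
        self, prevalence: float, delta: float, n: int, **overrides
    ) -> GenerationConfig:
        """Fully calibrated generator for one cell."""
        return (
            default_config(n=n, exposure_prevalence=prevalence, delta=delta, **overrides)
            .with_exposure_intercept(self.exposure_intercept(prevalence))
            .with_alpha6(self.alpha6_for(prevalence, delta))
        )

    def missingness_config(
        self, prevalence: float, structure: str, scenario: str
    ) -> MissingnessConfig:
        key = _mkey(prevalence, structure, scenario)
        if key not in self.missingness:
            generator = self.generation_config(prevalence, 0.0, n=1)
            raw = MissingnessConfig.for_scenario(structure, scenario)
            cal = calibrate_missingness_intercepts(
                raw, generator, self.n_calibration, seed=self.seed
            )
            intercepts = {
                "beta0": cal.beta0, "gamma0": cal.gamma0,
                "zeta0": cal.zeta0, "eta0": cal.eta0,
            }
            self.missingness[key] = {
                k: v for k, v in intercepts.items() if math.isfinite(v)
            }
        raw = MissingnessConfig.for_scenario(structure, scenario)
        return raw.replace(**self.missingness[key])

    def cell(
        self, prevalence: float, delta: float, structure: str, scenario: str, n: int
    ) -> tuple[GenerationConfig, MissingnessConfig]:
        return (
            self.generation_config(prevalence, delta, n),
            self.missingness_config(prevalence, structure, scenario),
        )

    def calibrate_all(
        self,
        prevalences=(0.10, 0.30, 0.50),
        deltas=_DELTAS,
        structures=("outcome_only", "outcome_and_confounders"),
        scenarios=("i", "ii", "iii"),
    ) -> "ScenarioTable":
        for p in prevalences:
            for d in deltas:
                self.alpha6_for(p, d)
            for st in structures:
                for sc in scenarios:
                    self.missingness_config(p, st, sc)
        return self

    # -- persistence ------------------------------------------------------
    def save(self, path) -> None:
        payload = {
            "n_calibration": self.n_calibration,
            "seed": self.seed,
            "exposure_intercepts": self.exposure_intercepts,
            "alpha6": self.alpha6,
            "missingness": self.missingness,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def load(cls, path) -> "ScenarioTable":
        payload = json.loads(Path(path).read_text())
        table = cls(n_calibration=payload["n_calibration"], seed=payload["seed"])
        table.exposure_intercepts = dict(payload["exposure_intercepts"])
        table.alpha6 = dict(payload["alpha6"])
        table.missingness = {k: dict(v) for k, v in payload["missingness"].items()}
        return table
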