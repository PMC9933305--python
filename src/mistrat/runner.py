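"""Scenario-grid orchestration: calibration, replication, seeding, summaries.

Every replicate generates one complete dataset, imposes missingness once,
and hands the *same* incomplete dataset to every applicable method (common
random numbers), so method contrasts are not inflated by dataset-to-dataset
noise. Seeding is counter-based: the stream for each (cell, replicate,
method) is derived from the master seed and the cell identifiers alone, so
results are independent of execution order and of the number of workers.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datagen import GenerationConfig, generate_complete
from .errors import DegenerateStratumError, EstimationError, ImputationError
from .estimation import apply_method
from .fcs_imputer import ImputationSpec
from .metrics import summarize_frame
from .missingness import MissingnessConfig, impose_missingness
from .scenarios import DEFAULT_SAMPLE_SIZES, SECONDARY_SAMPLE_SIZES, ScenarioTable

__all__ = [
    "RunConfig",
    "methods_for_structure",
    "primary_grid",
    "secondary_grid",
    "full_grid",
    "run_cell",
    "run_grid",
]

ALL_DELTAS = (-0.75, -0.5, -0.25, 0.0, 0.25, 0.5, 0.75)

#: Estimate-table columns written by :func:`run_cell`.
ESTIMATE_COLUMNS = [
    "prevalence", "n", "delta", "structure", "mscenario",
    "replicate", "method", "estimate", "se", "df", "ci_low", "ci_high",
    "n_complete_cases", "m_used", "failure", "data_hash",
]


def methods_for_structure(structure: str) -> tuple[str, ...]:
    """Outcome-only missingness collapses the interaction variants:
    MI-ExO == MI-NI and MI-ExOC == MI-ExI == MI-ExC, leaving four methods."""
    if structure == "outcome_only":
        return ("CCA", "MI-NI", "MI-ExC", "MI-EG")
    return ("CCA", "MI-NI", "MI-ExO", "MI-ExC", "MI-ExOC", "MI-ExI", "MI-EG")


def primary_grid() -> list[dict]:
    cells = []
    for prevalence, n in DEFAULT_SAMPLE_SIZES.items():
        for structure in ("outcome_only", "outcome_and_confounders"):
            for scenario in ("i", "ii", "iii"):
                for delta in ALL_DELTAS:
                    cells.append(
                        dict(prevalence=prevalence, n=n, delta=delta,
                             structure=structure, mscenario=scenario)
                    )
    return cells


def secondary_grid() -> list[dict]:
    """Sample-size sweep at 10% prevalence (the n=1300 row is the primary one)."""
    cells = []
    for n in SECONDARY_SAMPLE_SIZES:
        if n == DEFAULT_SAMPLE_SIZES[0.10]:
            continue
        for structure in ("outcome_only", "outcome_and_confounders"):
            for scenario in ("i", "ii", "iii"):
                for delta in ALL_DELTAS:
                    cells.append(
                        dict(prevalence=0.10, n=n, delta=delta,
                             structure=structure, mscenario=scenario)
                    )
    return cells


def full_grid() -> list[dict]:
    """All 252 distinct study cells: the 126 primary cells plus the secondary
    sample-size sweep at 10% prevalence (whose n=1300 row is already primary)."""
    return primary_grid() + secondary_grid()


@dataclass
class RunConfig:
    """Grid selection, replication and seeding for one simulation run."""

    prevalences: Sequence[float] = (0.10, 0.30, 0.50)
    structures: Sequence[str] = ("outcome_only", "outcome_and_confounders")
    scenarios: Sequence[str] = ("i", "ii", "iii")
    deltas: Sequence[float] = ALL_DELTAS
    sample_sizes: Optional[dict] = None  # prevalence -> n; default primary sizes
    replicates: int = 2000
    base_seed: int = 0
    m: int = 30
    iterations: int = 5
    df_method: str = "barnard-rubin"
    output_dir: Optional[str] = None
    workers: int = 1
    n_calibration: int = 10**6
    scenario_file: Optional[str] = None
    methods: Optional[Sequence[str]] = None  # default: all applicable

    def cells(self) -> list[dict]:
        sizes = self.sample_sizes or DEFAULT_SAMPLE_SIZES
        out = []
        for prevalence in self.prevalences:
            for structure in self.structures:
                for scenario in self.scenarios:
                    for delta in self.deltas:
                        out.append(
                            dict(prevalence=prevalence, n=sizes[prevalence],
                                 delta=delta, structure=structure,
                                 mscenario=scenario)
                        )
        return out


def _cell_entropy(base_seed: int, cell: dict) -> tuple[int, ...]:
    return (
        int(base_seed),
        int(round(cell["prevalence"] * 100)),
        int(round(cell["delta"] * 100)) + 100,
        0 if cell["structure"] == "outcome_only" else 1,
        ("i", "ii", "iii").index(cell["mscenario"]),
        int(cell["n"]),
    )


def _hash_incomplete(data) -> str:
    h = hashlib.sha1()
    h.update(np.ascontiguousarray(data.true_values).tobytes())
    h.update(np.ascontiguousarray(data.mask).tobytes())
    return h.hexdigest()[:16]


def _run_replicate(
    replicate: int,
    cell: dict,
    gen_config: GenerationConfig,
    mis_config: MissingnessConfig,
    methods: Sequence[str],
    base_seed: int,
    m: int,
    iterations: int,
    df_method: str,
) -> list[dict]:
    entropy = _cell_entropy(base_seed, cell) + (int(replicate),)
    streams = np.random.SeedSequence(entropy).spawn(2 + len(methods))
    complete = generate_complete(
        gen_config, seed=np.random.Generator(np.random.PCG64(streams[0]))
    )
    incomplete = impose_missingness(
        complete, mis_config, np.random.Generator(np.random.PCG64(streams[1]))
    )
    data_hash = _hash_incomplete(incomplete)
    masked = [
        v for v in ("C4", "C5", "Y")
        if incomplete.indicators[f"M_{v}"].to_numpy().any()
    ]
    rows = []
    for method, stream in zip(methods, streams[2:]):
        spec = ImputationSpec.from_method(method, masked_variables=masked or ("Y",),
                                          m=m, iterations=iterations)
        method_seed = int(stream.generate_state(1)[0] & 0x7FFFFFFF)
        row = dict(cell)
        row.update(replicate=replicate, method=method, data_hash=data_hash,
                   failure="", estimate=np.nan, se=np.nan, df=np.nan,
                   ci_low=np.nan, ci_high=np.nan,
                   n_complete_cases=np.nan, m_used=np.nan)
        try:
            rec = apply_method(
                incomplete, spec, method_seed,
                replicate=replicate, scenario=cell, df_method=df_method,
            )
        except (DegenerateStratumError, ImputationError, EstimationError) as exc:
            row["failure"] = type(exc).__name__
        else:
            row.update(
                estimate=rec.theta1_hat, se=rec.se, df=rec.df,
                ci_low=rec.ci_low, ci_high=rec.ci_high,
                n_complete_cases=rec.n_complete_cases if rec.n_complete_cases is not None else np.nan,
                m_used=rec.m_used if rec.m_used is not None else np.nan,
            )
        rows.append(row)
    return rows


def run_cell(
    cell: dict,
    table: ScenarioTable,
    replicates: int,
    base_seed: int = 0,
    m: int = 30,
    iterations: int = 5,
    methods: Optional[Sequence[str]] = None,
    df_method: str = "barnard-rubin",
    workers: int = 1,
) -> pd.DataFrame:
    """Run all replicates of one scenario cell; returns the estimates table."""
    gen_config, mis_config = table.cell(
        cell["prevalence"], cell["delta"], cell["structure"], cell["mscenario"], cell["n"]
    )
    methods = tuple(methods or methods_for_structure(cell["structure"]))
    args = (cell, gen_config, mis_config, methods, base_seed, m, iterations, df_method)
    if workers > 1:
        from joblib import Parallel, delayed

        chunks = Parallel(n_jobs=workers)(
            delayed(_run_replicate)(r, *args) for r in range(replicates)
        )
    else:
        chunks = [_run_replicate(r, *args) for r in range(replicates)]
    rows = [row for chunk in chunks for row in chunk]
    return pd.DataFrame(rows, columns=ESTIMATE_COLUMNS)


def run_grid(config: RunConfig, table: Optional[ScenarioTable] = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run every selected cell; returns (per-replicate estimates, summaries).

    If ``config.scenario_file`` exists it is loaded instead of re-calibrating;
    if given but absent, calibration results are saved there afterwards.
    """
    if table is None:
        path = Path(config.scenario_file) if config.scenario_file else None
        if path is not None and path.exists():
            table = ScenarioTable.load(path)
        else:
            table = ScenarioTable(n_calibration=config.n_calibration)
    estimates = []
    for cell in config.cells():
        estimates.append(
            run_cell(
                cell, table,
                replicates=config.replicates, base_seed=config.base_seed,
                m=config.m, iterations=config.iterations,
                methods=config.methods, df_method=config.df_method,
                workers=config.workers,
            )
        )
    est = pd.concat(estimates, ignore_index=True)
    ok = est[est["failure"] == ""]
    summary = summarize_frame(
        ok, group_cols=("prevalence", "n", "structure", "mscenario", "delta", "method")
    )
    failures = (
        est.assign(failed=est["failure"] != "")
        .groupby(["prevalence", "n", "structure", "mscenario", "delta", "method"])["failed"]
        .sum()
        .rename("n_failures")
        .reset_index()
    )
    summary = summary.merge(
        failures, on=["prevalence", "n", "structure", "mscenario", "delta", "method"]
    )
    if config.scenario_file:
        path = Path(config.scenario_file)
        if not path.exists():
            path.parent.mkdir(parents=True, exist_ok=True)
            table.save(path)
    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        est.to_csv(out / "estimates.csv", index=False)
        summary.to_csv(out / "summary.csv", index=False)
    return est, summary
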