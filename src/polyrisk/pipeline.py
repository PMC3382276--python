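"""Scenario orchestration: the disease grid, replicates, and result tables.

A scenario run draws a fresh architecture per replicate, ascertains the
case-control sample, estimates per-locus effects on the training half, and
evaluates one or more predictors on the validation half:

* ``true-effects``   — the simulated per-locus liability effects,
* ``all-estimated``  — training-half estimates for every locus,
* ``top-15``         — estimates restricted to the loci with the smallest
  training p-values (the count is configurable).

The built-in disease grid covers prostate (PC), breast (BC) and colorectal
(CRC) cancer at all-ages and over-65 prevalences, with 500- or 10,000-locus
architectures.
"""

from __future__ import annotations

import logging
from dataclasses import asdict

import numpy as np
import pandas as pd
import yaml

from .association import PolygenicScorePredictor
from .evaluate import auc, polygenic_score
from .simulate import ScenarioConfig, simulate_dataset

__all__ = [
    "SCENARIOS",
    "DISEASE_GRID",
    "run_scenario",
    "run_grid",
    "summarize",
    "fig4_grid",
    "read_config",
    "write_results",
    "read_results",
]

logger = logging.getLogger("polyrisk")

SCENARIO_TRUE = "true-effects"
SCENARIO_ESTIMATED = "all-estimated"
SCENARIO_TOP_K = "top-15"
SCENARIOS = (SCENARIO_TRUE, SCENARIO_ESTIMATED, SCENARIO_TOP_K)

# (disease, age group, prevalence, heritability)
DISEASE_GRID = (
    ("PC", "all-ages", 0.007, 0.42),
    ("PC", "over-65", 0.04, 0.42),
    ("BC", "all-ages", 0.007, 0.27),
    ("BC", "over-65", 0.025, 0.27),
    ("CRC", "all-ages", 0.004, 0.35),
    ("CRC", "over-65", 0.01, 0.35),
)

RESULT_COLUMNS = [
    "disease", "age_group", "prevalence", "h2", "n_loci",
    "scenario", "replicate", "seed", "auc",
]


def _replicate_seeds(root_seed: int, replicates: int) -> np.ndarray:
    rng = np.random.default_rng(np.random.SeedSequence(root_seed))
    return rng.integers(0, 2**31 - 1, size=replicates)


def run_scenario(
    config: ScenarioConfig,
    scenarios=SCENARIOS,
    replicates: int = 10,
    top_k: int = 15,
    chunk_size: int = 100_000,
) -> pd.DataFrame:
    """Run one scenario cell for several replicates.

    Every replicate draws its own architecture and cohort from a seed
    derived from ``config.seed``; the returned table records that seed so
    any row's dataset can be regenerated standalone with
    :func:`polyrisk.simulate.simulate_dataset`.
    """
    unknown = set(scenarios) - set(SCENARIOS)
    if unknown:
        raise ValueError(f"unknown scenarios {sorted(unknown)}; choose from {SCENARIOS}")
    if replicates < 1:
        raise ValueError(f"replicates must be >= 1, got {replicates}")
    needs_fit = SCENARIO_ESTIMATED in scenarios or SCENARIO_TOP_K in scenarios
    rows = []
    for rep, rep_seed in enumerate(_replicate_seeds(config.seed, replicates)):
        try:
            data = simulate_dataset(config, seed=int(rep_seed), chunk_size=chunk_size)
            X_valid, y_valid = data.validation()
            weights: dict[str, np.ndarray] = {}
            if SCENARIO_TRUE in scenarios:
                weights[SCENARIO_TRUE] = data.architecture.beta
            if needs_fit:
                X_train, y_train = data.training()
                model = PolygenicScorePredictor(method="linear").fit(X_train, y_train)
                if SCENARIO_ESTIMATED in scenarios:
                    weights[SCENARIO_ESTIMATED] = model.effect_
                if SCENARIO_TOP_K in scenarios:
                    weights[SCENARIO_TOP_K] = model.effect_ * (model.rank_ <= top_k)
            for scen in scenarios:
                scores = polygenic_score(X_valid, weights[scen])
                value = auc(scores[y_valid == 1], scores[y_valid == 0])
                rows.append(
                    {
                        "disease": config.disease,
                        "age_group": config.age_group,
                        "prevalence": config.prevalence,
                        "h2": config.h2,
                        "n_loci": config.n_loci,
                        "scenario": scen,
                        "replicate": rep,
                        "seed": int(rep_seed),
                        "auc": value,
                    }
                )
        except Exception:
            logger.exception(
                "replicate %d (seed %d) of scenario %s failed",
                rep, rep_seed, config,
            )
            raise
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def run_grid(
    grid,
    scenarios=SCENARIOS,
    replicates: int = 10,
    top_k: int = 15,
    chunk_size: int = 100_000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run every config in ``grid``; failures are logged, the rest completed.

    Returns the concatenated per-replicate rows and the per-cell summary
    (mean AUC, standard error of the mean, replicate count).
    """
    grid = list(grid)
    if not grid:
        raise ValueError("grid must contain at least one scenario config")
    frames = []
    for config in grid:
        try:
            frames.append(
                run_scenario(config, scenarios, replicates, top_k, chunk_size)
            )
        except Exception:
            logger.exception("grid cell %s failed; continuing", config)
    rows = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=RESULT_COLUMNS)
    )
    return rows, summarize(rows)


def summarize(rows: pd.DataFrame) -> pd.DataFrame:
    """Mean AUC, SE of the mean and replicate count per grid cell."""
    keys = ["disease", "age_group", "prevalence", "h2", "n_loci", "scenario"]
    if rows.empty:
        return pd.DataFrame(columns=keys + ["mean_auc", "se_auc", "replicates"])
    grouped = rows.groupby(keys, sort=False)["auc"]
    out = grouped.agg(
        mean_auc="mean",
        se_auc=lambda a: a.std(ddof=1) / np.sqrt(len(a)) if len(a) > 1 else 0.0,
        replicates="count",
    ).reset_index()
    return out


def fig4_grid(
    n_cases: int = 10_000,
    n_controls: int = 10_000,
    loci_counts=(500, 10_000),
    scaled: bool = False,
    scaled_n: int = 2_000,
    base_seed: int = 0,
) -> list[ScenarioConfig]:
    """The built-in disease x age x loci grid (12 configs, 36 scenario cells).

    With ``scaled=True`` the 10,000-locus cells use ``scaled_n`` cases and
    controls instead of the full quotas, trading sampling error for runtime.
    """
    seeds = np.random.default_rng(np.random.SeedSequence(base_seed)).integers(
        0, 2**31 - 1, size=len(DISEASE_GRID) * len(tuple(loci_counts))
    )
    configs = []
    k = 0
    for n_loci in loci_counts:
        quota = (scaled_n, scaled_n) if (scaled and n_loci >= 10_000) else (n_cases, n_controls)
        for disease, age, prevalence, h2 in DISEASE_GRID:
            configs.append(
                ScenarioConfig(
                    n_loci=n_loci,
                    h2=h2,
                    prevalence=prevalence,
                    n_cases=quota[0],
                    n_controls=quota[1],
                    seed=int(seeds[k]),
                    disease=disease,
                    age_group=age,
                )
            )
            k += 1
    return configs


def read_config(path) -> ScenarioConfig:
    """Read a scenario config from a flat YAML/JSON mapping.

    Keys mirror :class:`~polyrisk.simulate.ScenarioConfig` fields exactly;
    an unknown key is rejected by name.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must contain a key-value mapping")
    allowed = set(ScenarioConfig.field_names())
    for key in raw:
        if key not in allowed:
            raise ValueError(
                f"unknown config key {key!r} in {path}; "
                f"allowed keys: {sorted(allowed)}"
            )
    return ScenarioConfig(**raw)


def write_config(config: ScenarioConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=False)


def write_results(rows: pd.DataFrame, path) -> None:
    """Write result rows as CSV (lossless round trip with read_results)."""
    rows.to_csv(path, index=False)


def read_results(path) -> pd.DataFrame:
    frame = pd.read_csv(path, converters={"disease": str, "age_group": str})
    missing = [c for c in RESULT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"results file {path} is missing columns {missing}")
    return frame[RESULT_COLUMNS]
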