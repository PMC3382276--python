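"""Polygenic architectures and case-control cohorts under the liability model.

The generator emulates a classical polygenic case-control study design:
risk-allele frequencies drawn from a beta distribution (uniform by default,
with a minor-allele-frequency floor so no locus is effectively monomorphic),
additive per-allele effects drawn from a normal distribution and rescaled by
one multiplicative constant so the loci jointly explain exactly ``h2`` of
liability variance, genotypes in Hardy-Weinberg and linkage equilibrium,
and an individual affected when genetic value plus normal residual exceeds
the prevalence threshold.  Cases and controls are ascertained to fixed
quotas by chunked rejection sampling, which preserves the exact joint
distribution of genotypes given affection status, then split at random into
equal training and validation halves, stratified by status.

Randomness policy: one root seed per scenario; architecture, cohort and
partition draw from independent substreams spawned from it, so any dataset
can be regenerated bit-for-bit from (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace

import numpy as np
import pandas as pd

from ._genotypes import hwe_genotypes_block
from .liability import LiabilityModel, liability_threshold

__all__ = [
    "ScenarioConfig",
    "TraitArchitecture",
    "Cohort",
    "CaseControlDataset",
    "draw_architecture",
    "simulate_cohort",
    "ascertain_case_control",
    "simulate_dataset",
    "write_genotypes",
    "read_genotypes",
]


@dataclass(frozen=True)
class ScenarioConfig:
    """One simulation scenario: trait architecture plus study design.

    ``freq_alpha``/``freq_beta`` are the beta-distribution shape parameters
    for risk-allele frequencies (1, 1 = uniform) and ``maf_floor`` the bound
    keeping every frequency inside [floor, 1 - floor].
    """

    n_loci: int
    h2: float
    prevalence: float
    n_cases: int = 10_000
    n_controls: int = 10_000
    freq_alpha: float = 1.0
    freq_beta: float = 1.0
    maf_floor: float = 0.01
    seed: int = 0
    disease: str = ""
    age_group: str = ""

    def __post_init__(self) -> None:
        if self.n_loci <= 0:
            raise ValueError(f"n_loci must be positive, got {self.n_loci}")
        if not 0.0 < self.h2 < 1.0:
            raise ValueError(f"h2 must lie in (0, 1), got {self.h2}")
        if not 0.0 < self.prevalence < 0.5:
            raise ValueError(
                f"prevalence must lie in (0, 0.5), got {self.prevalence}"
            )
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError("case and control quotas must be positive")
        if not 0.0 <= self.maf_floor < 0.5:
            raise ValueError(f"maf_floor must lie in [0, 0.5), got {self.maf_floor}")
        if self.freq_alpha <= 0 or self.freq_beta <= 0:
            raise ValueError("beta-distribution shape parameters must be positive")

    def with_seed(self, seed: int) -> "ScenarioConfig":
        return replace(self, seed=int(seed))

    @classmethod
    def field_names(cls) -> list[str]:
        return [f.name for f in fields(cls)]


@dataclass(frozen=True)
class TraitArchitecture:
    """Realized per-locus frequencies and additive liability effects."""

    p: np.ndarray
    beta: np.ndarray
    h2: float
    prevalence: float

    @property
    def n_loci(self) -> int:
        return self.p.size

    @property
    def threshold(self) -> float:
        return liability_threshold(self.prevalence)

    @property
    def model(self) -> LiabilityModel:
        return LiabilityModel(K=self.prevalence, h2=self.h2)

    @property
    def variance_contributions(self) -> np.ndarray:
        """Per-locus liability variance, 2 p (1-p) beta^2; sums to h2."""
        return 2.0 * self.p * (1.0 - self.p) * self.beta**2

    @property
    def expected_genetic_value(self) -> float:
        """Population mean of the uncentered genetic value, sum 2 p beta."""
        return float(2.0 * self.p @ self.beta)


def draw_architecture(
    config: ScenarioConfig, rng: np.random.Generator | None = None
) -> TraitArchitecture:
    """Draw a trait architecture from the configured distributions.

    Raw effects come from a standard normal and are rescaled by a single
    constant so that ``sum 2 p (1-p) beta^2 = h2`` exactly; frequencies are
    beta draws resampled into [maf_floor, 1 - maf_floor].
    """
    if rng is None:
        rng = np.random.default_rng(
            np.random.SeedSequence(config.seed).spawn(2)[0]
        )
    m = config.n_loci
    p = rng.beta(config.freq_alpha, config.freq_beta, size=m)
    lo, hi = config.maf_floor, 1.0 - config.maf_floor
    bad = (p < lo) | (p > hi)
    while bad.any():
        p[bad] = rng.beta(config.freq_alpha, config.freq_beta, size=int(bad.sum()))
        bad = (p < lo) | (p > hi)
    raw = rng.standard_normal(m)
    var_raw = float(2.0 * p * (1.0 - p) @ raw**2)
    while var_raw == 0.0:  # unreachable in practice
        raw = rng.standard_normal(m)
        var_raw = float(2.0 * p * (1.0 - p) @ raw**2)
    beta = raw * np.sqrt(config.h2 / var_raw)
    return TraitArchitecture(
        p=p, beta=beta, h2=config.h2, prevalence=config.prevalence
    )


@dataclass
class Cohort:
    """An unascertained population sample from one architecture."""

    genotypes: np.ndarray       # (n, m) int8, 0/1/2 risk-allele copies
    genetic_values: np.ndarray  # centered, population mean 0
    liabilities: np.ndarray     # genetic value + N(0, 1-h2) residual
    affected: np.ndarray        # liability > T


def _spawn_streams(seed) -> tuple[int, np.random.Generator, np.random.Generator]:
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    ss_geno, ss_resid, ss_part = ss.spawn(3)
    key = int(ss_geno.generate_state(1, np.uint64)[0])
    return key, np.random.default_rng(ss_resid), np.random.default_rng(ss_part)


def simulate_cohort(
    arch: TraitArchitecture, n: int, seed, chunk_size: int = 100_000
) -> Cohort:
    """Simulate ``n`` individuals from the population (no ascertainment)."""
    if n <= 0:
        raise ValueError(f"cohort size must be positive, got {n}")
    key, rng_resid, _ = _spawn_streams(seed)
    resid_sd = np.sqrt(1.0 - arch.h2)
    mean_g = arch.expected_genetic_value
    T = arch.threshold
    Xs, gs, ls = [], [], []
    row0 = 0
    while row0 < n:
        k = min(chunk_size, n - row0)
        X, g = hwe_genotypes_block(arch.p, arch.beta, k, key, row0)
        g -= mean_g
        liab = g + rng_resid.normal(0.0, resid_sd, size=k)
        Xs.append(X)
        gs.append(g)
        ls.append(liab)
        row0 += k
    X = np.vstack(Xs)
    g = np.concatenate(gs)
    liab = np.concatenate(ls)
    return Cohort(genotypes=X, genetic_values=g, liabilities=liab, affected=liab > T)


@dataclass
class CaseControlDataset:
    """Ascertained case-control sample with a training/validation split."""

    genotypes: np.ndarray
    affected: np.ndarray        # bool, exactly n_cases True
    genetic_values: np.ndarray
    liabilities: np.ndarray
    is_training: np.ndarray     # bool, half of each status group
    architecture: TraitArchitecture

    @property
    def n_cases(self) -> int:
        return int(self.affected.sum())

    @property
    def n_controls(self) -> int:
        return int((~self.affected).sum())

    def training(self) -> tuple[np.ndarray, np.ndarray]:
        m = self.is_training
        return self.genotypes[m], self.affected[m].astype(np.int8)

    def validation(self) -> tuple[np.ndarray, np.ndarray]:
        m = ~self.is_training
        return self.genotypes[m], self.affected[m].astype(np.int8)


def _stratified_half_split(
    affected: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Random half/half training mask within each affection-status group."""
    is_training = np.zeros(affected.size, dtype=bool)
    for status in (True, False):
        idx = np.flatnonzero(affected == status)
        perm = rng.permutation(idx)
        is_training[perm[: idx.size // 2]] = True
    return is_training


def ascertain_case_control(
    arch: TraitArchitecture,
    n_cases: int,
    n_controls: int,
    seed,
    chunk_size: int = 100_000,
    max_individuals: int | None = None,
) -> CaseControlDataset:
    """Ascertain fixed case/control quotas by chunked rejection sampling.

    Population chunks are simulated until both quotas are exactly filled;
    retained individuals keep their simulated genotypes, so the joint
    distribution of genotypes given status is exact.  ``max_individuals``
    (default ``100 / K`` times the total quota) guards against a mis-set
    prevalence making the case quota practically unreachable.
    """
    if n_cases <= 0 or n_controls <= 0:
        raise ValueError("case and control quotas must be positive")
    if max_individuals is None:
        max_individuals = int(100.0 * (n_cases + n_controls) / arch.prevalence)
    key, rng_resid, rng_part = _spawn_streams(seed)
    resid_sd = np.sqrt(1.0 - arch.h2)
    mean_g = arch.expected_genetic_value
    T = arch.threshold

    Xs, gs, ls, ys = [], [], [], []
    need_ca, need_co = n_cases, n_controls
    row0 = 0
    while need_ca > 0 or need_co > 0:
        if row0 >= max_individuals:
            raise RuntimeError(
                f"simulated {row0} individuals without filling quotas "
                f"({need_ca} cases, {need_co} controls still missing); "
                f"check the configured prevalence {arch.prevalence}"
            )
        k = min(chunk_size, max_individuals - row0)
        X, g = hwe_genotypes_block(arch.p, arch.beta, k, key, row0)
        g -= mean_g
        liab = g + rng_resid.normal(0.0, resid_sd, size=k)
        aff = liab > T
        row0 += k
        for status, need in ((True, need_ca), (False, need_co)):
            if need <= 0:
                continue
            idx = np.flatnonzero(aff == status)[:need]
            if idx.size == 0:
                continue
            Xs.append(X[idx])
            gs.append(g[idx])
            ls.append(liab[idx])
            ys.append(np.full(idx.size, status))
            if status:
                need_ca -= idx.size
            else:
                need_co -= idx.size

    X = np.vstack(Xs)
    g = np.concatenate(gs)
    liab = np.concatenate(ls)
    affected = np.concatenate(ys)
    is_training = _stratified_half_split(affected, rng_part)
    return CaseControlDataset(
        genotypes=X,
        affected=affected,
        genetic_values=g,
        liabilities=liab,
        is_training=is_training,
        architecture=arch,
    )


def simulate_dataset(
    config: ScenarioConfig,
    seed: int | None = None,
    chunk_size: int = 100_000,
) -> CaseControlDataset:
    """Architecture draw + ascertainment + partition from one root seed."""
    root = config.seed if seed is None else seed
    ss = np.random.SeedSequence(root)
    ss_arch, ss_data = ss.spawn(2)
    arch = draw_architecture(config, rng=np.random.default_rng(ss_arch))
    return ascertain_case_control(
        arch,
        config.n_cases,
        config.n_controls,
        seed=ss_data,
        chunk_size=chunk_size,
    )


def write_genotypes(dataset: CaseControlDataset, path) -> None:
    """Export as tab-delimited text: id, status, partition, then one column
    per locus with 0/1/2 risk-allele counts."""
    m = dataset.genotypes.shape[1]
    frame = pd.DataFrame(
        dataset.genotypes, columns=[f"locus_{j}" for j in range(m)]
    )
    frame.insert(0, "partition", np.where(dataset.is_training, "train", "valid"))
    frame.insert(0, "status", dataset.affected.astype(int))
    frame.insert(0, "id", np.arange(dataset.genotypes.shape[0]))
    frame.to_csv(path, sep="\t", index=False)


def read_genotypes(path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read the export format back: (genotypes, affected, is_training)."""
    frame = pd.read_csv(path, sep="\t")
    for col in ("id", "status", "partition"):
        if col not in frame.columns:
            raise ValueError(f"genotype file {path} is missing column {col!r}")
    loci = [c for c in frame.columns if c.startswith("locus_")]
    X = frame[loci].to_numpy(dtype=np.int8)
    return X, frame["status"].to_numpy(bool), (frame["partition"] == "train").to_numpy()
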