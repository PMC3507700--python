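"""Synthetic populations and balanced case-control samples.

Two sampling routes yield statistically identical case-control data:

* the two-step design — simulate a large population (genotype under
  Hardy-Weinberg equilibrium, exposure uniform on [0, 100], disease status
  Bernoulli of the penetrance) and then draw cases and controls without
  replacement from the status strata; and
* a direct conditional sampler that draws (g, u) from P(g, u | Y=1) and
  P(g, u | Y=0) by rejection against F and 1-F.

The direct route avoids materializing the multi-million-row population and is
the default for replicated experiments; the equivalence of the two routes is a
tested property, not an assumption.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .risk_models import ENV_HI, ENV_LO, GenotypeDistribution, PenetranceSpec

__all__ = [
    "PopulationConfig",
    "CaseControlDataset",
    "simulate_population",
    "draw_case_control",
    "direct_case_control",
]


@dataclass(frozen=True)
class PopulationConfig:
    """Settings of the simulated source population."""

    n_population: int = 5_000_000
    maf: float = 0.30
    env_low: float = ENV_LO
    env_high: float = ENV_HI
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_population <= 0:
            raise ValueError("n_population must be positive")
        if not 0.0 <= self.maf <= 0.5:
            raise ValueError("maf must be in [0, 0.5]")
        if not self.env_low < self.env_high:
            raise ValueError("env_low must be below env_high")


@dataclass
class CaseControlDataset:
    """A balanced (or user-sized) case-control sample."""

    genotype: np.ndarray
    exposure: np.ndarray
    status: np.ndarray

    def __post_init__(self) -> None:
        self.genotype = np.asarray(self.genotype, dtype=np.int64)
        self.exposure = np.asarray(self.exposure, dtype=float)
        self.status = np.asarray(self.status, dtype=np.int64)
        if not (len(self.genotype) == len(self.exposure) == len(self.status)):
            raise ValueError("genotype, exposure and status must have equal length")

    @property
    def n_cases(self) -> int:
        return int(self.status.sum())

    @property
    def n_controls(self) -> int:
        return int(len(self.status) - self.status.sum())

    def __len__(self) -> int:
        return len(self.status)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"genotype": self.genotype, "exposure": self.exposure, "status": self.status}
        )

    def to_csv(self, path, manifest: dict | None = None) -> None:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        if manifest is not None:
            meta = dict(manifest)
            meta.update(n_cases=self.n_cases, n_controls=self.n_controls)
            path.with_suffix(".manifest.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def from_csv(cls, path) -> "CaseControlDataset":
        df = pd.read_csv(path)
        return cls(df["genotype"].to_numpy(), df["exposure"].to_numpy(), df["status"].to_numpy())


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_population(spec: PenetranceSpec, cfg: PopulationConfig) -> pd.DataFrame:
    """Simulate the source population under a calibrated penetrance model.

    Genotype and exposure are drawn marginally independent; status is one
    uniform draw per individual compared against F(g, u).
    """
    if not spec.calibrated:
        raise ValueError(f"{spec.key}: calibrate the spec before simulating")
    rng = _as_rng(cfg.seed)
    g = rng.binomial(2, cfg.maf, cfg.n_population).astype(np.int8)
    u = rng.uniform(cfg.env_low, cfg.env_high, cfg.n_population)
    F = spec.penetrance(g, u)
    y = (rng.random(cfg.n_population) < F).astype(np.int8)
    return pd.DataFrame({"genotype": g, "exposure": u, "status": y})


def draw_case_control(
    population: pd.DataFrame, n_cases: int, n_controls: int, seed=None
) -> CaseControlDataset:
    """Simple random sample without replacement within each status stratum."""
    rng = _as_rng(seed)
    status = population["status"].to_numpy()
    case_idx = np.flatnonzero(status == 1)
    ctrl_idx = np.flatnonzero(status == 0)
    if len(case_idx) < n_cases or len(ctrl_idx) < n_controls:
        raise ValueError(
            f"population has {len(case_idx)} cases / {len(ctrl_idx)} controls, "
            f"requested {n_cases} + {n_controls}"
        )
    take = np.concatenate(
        [
            rng.choice(case_idx, size=n_cases, replace=False),
            rng.choice(ctrl_idx, size=n_controls, replace=False),
        ]
    )
    take = rng.permutation(take)  # downstream fits never see status-sorted rows
    sub = population.iloc[take]
    return CaseControlDataset(
        sub["genotype"].to_numpy(), sub["exposure"].to_numpy(), sub["status"].to_numpy()
    )


def _rejection_stratum(
    spec: PenetranceSpec,
    dist: GenotypeDistribution,
    n: int,
    case: bool,
    rng: np.random.Generator,
    env_low: float,
    env_high: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw n (g, u) pairs from P(g, u | Y=case) by rejection against F / 1-F."""
    rate = spec.K if case else 1.0 - spec.K  # expected acceptance probability
    if rate <= 0:
        raise ValueError(f"{spec.key}: degenerate stratum, acceptance probability 0")
    if n == 0:
        return np.empty(0, dtype=np.int64), np.empty(0)
    gs, us = [], []
    got = 0
    while got < n:
        batch = int((n - got) / rate * 1.2) + 64
        g = rng.binomial(2, dist.maf, batch)
        u = rng.uniform(env_low, env_high, batch)
        F = spec.penetrance(g, u)
        keep = rng.random(batch) < (F if case else 1.0 - F)
        gs.append(g[keep])
        us.append(u[keep])
        got += int(keep.sum())
    g = np.concatenate(gs)[:n]
    u = np.concatenate(us)[:n]
    return g, u


def direct_case_control(
    spec: PenetranceSpec,
    dist: GenotypeDistribution,
    n_cases: int,
    n_controls: int,
    seed=None,
    env_low: float = ENV_LO,
    env_high: float = ENV_HI,
) -> CaseControlDataset:
    """Sample a case-control dataset directly from the conditional distributions.

    Equivalent in distribution to `draw_case_control` applied to a population
    from `simulate_population`, without building the population.
    """
    if not spec.calibrated:
        raise ValueError(f"{spec.key}: calibrate the spec before sampling")
    rng = _as_rng(seed)
    g1, u1 = _rejection_stratum(spec, dist, n_cases, True, rng, env_low, env_high)
    g0, u0 = _rejection_stratum(spec, dist, n_controls, False, rng, env_low, env_high)
    g = np.concatenate([g1, g0])
    u = np.concatenate([u1, u0])
    y = np.concatenate([np.ones(n_cases, dtype=np.int64), np.zeros(n_controls, dtype=np.int64)])
    order = rng.permutation(len(y))
    return CaseControlDataset(g[order], u[order], y[order])
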