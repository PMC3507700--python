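"""Fit evaluation: mean-absolute-difference matrix and empirical prediction bands.

The study's fit statistic compares replicate predictions f-hat_k(g, u') with
the theoretic case-control risk surface f(g, u') on the fixed exposure grid
u' = 0, 0.1, ..., 100 for every genotype:

    E_{g,u'} = (1/K) * sum_k | f(g, u') - f-hat_k(g, u') |,

a 3 x 1001 matrix whose grand sum is zero exactly when every replicate
reproduces the theoretic model.  Variation is summarized by pointwise
empirical 95% prediction bands — the 3rd and 98th ordered predictions when
there are 100 replicates — and, for a single observed data set, by pointwise
bootstrap percentile bands over refits to resampled rows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .population import CaseControlDataset
from .risk_models import exposure_grid

__all__ = [
    "EvalGrid",
    "EMatrix",
    "Band",
    "e_matrix",
    "prediction_band",
    "coverage_check",
    "bootstrap_band",
]


@dataclass
class EvalGrid:
    """Theoretic surface and replicate predictions on the shared exposure grid."""

    theoretic: np.ndarray  # (3, G)
    predictions: np.ndarray  # (K, 3, G)
    u_grid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.theoretic = np.asarray(self.theoretic, dtype=float)
        self.predictions = np.asarray(self.predictions, dtype=float)
        if self.u_grid is None:
            self.u_grid = exposure_grid()
        if self.predictions.ndim == 2:
            self.predictions = self.predictions[None]
        if self.theoretic.shape != (3, len(self.u_grid)):
            raise ValueError(f"theoretic surface must be (3, {len(self.u_grid)})")
        if self.predictions.shape[0] < 1 or self.predictions.shape[1:] != self.theoretic.shape:
            raise ValueError("predictions must be (K, 3, G) matching the theoretic surface")
        for name, a in (("theoretic", self.theoretic), ("predictions", self.predictions)):
            if np.any(a < 0) or np.any(a > 1):
                raise ValueError(f"{name} values must lie in [0, 1]")

    @property
    def n_replicates(self) -> int:
        return self.predictions.shape[0]

    def mean_prediction(self) -> np.ndarray:
        return self.predictions.mean(axis=0)


@dataclass
class EMatrix:
    """Element-wise mean absolute differences and their grand sum."""

    values: np.ndarray  # (3, G)
    total: float


@dataclass
class Band:
    """Pointwise lower/upper surfaces, shapes (3, G)."""

    lower: np.ndarray
    upper: np.ndarray

    def width(self) -> np.ndarray:
        return self.upper - self.lower


def e_matrix(grid: EvalGrid) -> EMatrix:
    """Mean absolute difference matrix E and its sum over all grid cells."""
    values = np.abs(grid.theoretic[None] - grid.predictions).mean(axis=0)
    return EMatrix(values=values, total=float(values.sum()))


def _default_orders(k_rep: int) -> tuple[int, int]:
    # ceil/floor pair reproduces the (3rd, 98th) order statistics at 100 reps
    lo = math.ceil((k_rep + 1) * 0.025)
    hi = math.floor((k_rep + 1) * 0.975)
    return max(lo, 1), min(hi, k_rep)


def prediction_band(
    grid: EvalGrid, k_lower: int | None = None, k_upper: int | None = None
) -> Band:
    """Pointwise band between the k_lower-th and k_upper-th ordered predictions.

    Defaults give the empirical 95% interval: (3, 98) for 100 replicates.
    """
    K = grid.n_replicates
    if k_lower is None or k_upper is None:
        k_lower, k_upper = _default_orders(K)
    if not 1 <= k_lower <= k_upper <= K:
        raise ValueError(f"need 1 <= k_lower <= k_upper <= {K}, got ({k_lower}, {k_upper})")
    s = np.sort(grid.predictions, axis=0)
    return Band(lower=s[k_lower - 1], upper=s[k_upper - 1])


def coverage_check(band: Band, theoretic: np.ndarray) -> tuple[bool, float]:
    """Does the band contain the theoretic surface (endpoints inclusive)?

    Returns (covered everywhere, fraction of grid cells covered).
    """
    theoretic = np.asarray(theoretic, dtype=float)
    if theoretic.shape != band.lower.shape:
        raise ValueError("theoretic surface and band shapes differ")
    covered = (band.lower <= theoretic) & (theoretic <= band.upper)
    return bool(covered.all()), float(covered.mean())


def bootstrap_band(
    dataset: CaseControlDataset,
    fit_and_predict: Callable[[CaseControlDataset], np.ndarray],
    B: int = 100,
    level: float = 0.95,
    seed=None,
) -> Band:
    """Pointwise bootstrap percentile band over B refits to resampled rows.

    `fit_and_predict` maps a dataset to a (3, G) predicted surface.  Rows are
    resampled with replacement (plain nonparametric bootstrap, ignoring the
    case-control strata, as appropriate for a band on the fitted curve of one
    observed data set).
    """
    if B < 2:
        raise ValueError("need at least 2 bootstrap replications")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(dataset)
    surfaces = []
    for _ in range(B):
        idx = rng.integers(0, n, n)
        boot = CaseControlDataset(
            dataset.genotype[idx], dataset.exposure[idx], dataset.status[idx]
        )
        surfaces.append(np.asarray(fit_and_predict(boot), dtype=float))
    stack = np.stack(surfaces)
    alpha = (1.0 - level) / 2.0
    lower, upper = np.quantile(stack, [alpha, 1.0 - alpha], axis=0)
    return Band(lower=lower, upper=upper)
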