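"""Logistic regression reference models with BIC selection.

The competitor to the perceptron: for each case-control data set, five
candidate logistic regressions are fitted — the null model, the three main
effect models (environment only, gene only, both) and the full model with
gene-environment interaction term(s) — and the BIC-best one is selected.

Two genotype codings are supported:

* ``codominant`` — the genotype enters as the allele count 0/1/2 (one column;
  the full model has a single count x exposure interaction term);
* ``design_variables`` — two indicators, heterozygous and homozygous mutated
  (the full model carries two interaction terms).

Fitting is maximum likelihood via IRLS (statsmodels GLM, binomial family);
BIC = -2 loglik + p log(N) is computed here so the identity is exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .population import CaseControlDataset
from .risk_models import exposure_grid

__all__ = [
    "ModelSpec",
    "FittedGLM",
    "CANDIDATE_MODELS",
    "candidate_models",
    "build_design",
    "fit_logistic",
    "select_best_glm",
    "predict_grid_glm",
]

CODINGS = ("codominant", "design_variables")

#: coefficient magnitude beyond which a fit is flagged as (quasi-)separated
_SEPARATION_BOUND = 50.0


@dataclass(frozen=True)
class ModelSpec:
    """One candidate regression: genotype coding plus included terms."""

    coding: str
    terms: frozenset
    name: str

    def __post_init__(self) -> None:
        if self.coding not in CODINGS:
            raise ValueError(f"unknown coding {self.coding!r}")
        if not self.terms <= {"env_main", "gene_main", "interaction"}:
            raise ValueError(f"unknown terms in {sorted(self.terms)}")
        if "interaction" in self.terms and not {"env_main", "gene_main"} <= self.terms:
            raise ValueError("interaction requires both main effects (hierarchy)")

    @property
    def n_params(self) -> int:
        gene_cols = 1 if self.coding == "codominant" else 2
        p = 1  # intercept
        if "env_main" in self.terms:
            p += 1
        if "gene_main" in self.terms:
            p += gene_cols
        if "interaction" in self.terms:
            p += gene_cols
        return p


def candidate_models(coding: str) -> list[ModelSpec]:
    """The five-model candidate set for one genotype coding."""
    make = lambda name, *terms: ModelSpec(coding, frozenset(terms), name)
    return [
        make("null"),
        make("env", "env_main"),
        make("gene", "gene_main"),
        make("gene+env", "env_main", "gene_main"),
        make("full", "env_main", "gene_main", "interaction"),
    ]


CANDIDATE_MODELS = {c: candidate_models(c) for c in CODINGS}


def build_design(
    genotype, exposure, spec: ModelSpec, check_rank: bool = False
) -> tuple[np.ndarray, list[str]]:
    """Design matrix (with intercept) and column names for one candidate model.

    ``check_rank=True`` (used at fit time) raises on collinear columns; the
    check is skipped for prediction grids, where the genotype is constant by
    construction.
    """
    g = np.asarray(genotype, dtype=float)
    u = np.asarray(exposure, dtype=float)
    if not np.isin(g, (0.0, 1.0, 2.0)).all():
        raise ValueError("genotype must be 0, 1 or 2")
    cols: list[np.ndarray] = [np.ones_like(u)]
    names = ["intercept"]
    if "env_main" in spec.terms:
        cols.append(u)
        names.append("exposure")
    if spec.coding == "codominant":
        gene_cols = [("genotype", g)]
    else:
        gene_cols = [("het", (g == 1).astype(float)), ("hom", (g == 2).astype(float))]
    if "gene_main" in spec.terms:
        for nm, col in gene_cols:
            cols.append(col)
            names.append(nm)
    if "interaction" in spec.terms:
        for nm, col in gene_cols:
            cols.append(col * u)
            names.append(f"{nm}:exposure")
    X = np.column_stack(cols)
    if check_rank and np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient (columns {names})"
        )
    return X, names


@dataclass
class FittedGLM:
    """A fitted candidate logistic regression."""

    spec: ModelSpec
    coefficients: np.ndarray
    names: list[str]
    loglik: float
    bic: float
    converged: bool
    separation_flag: bool
    n_obs: int

    def linear_predictor(self, genotype, exposure) -> np.ndarray:
        X, _ = build_design(genotype, exposure, self.spec)
        return X @ self.coefficients

    def predict(self, genotype, exposure) -> np.ndarray:
        from scipy.special import expit

        return expit(self.linear_predictor(genotype, exposure))


def fit_logistic(X: np.ndarray, y: np.ndarray, spec: ModelSpec, names=None) -> FittedGLM:
    """Maximum-likelihood logistic fit (IRLS) of one design matrix."""
    y = np.asarray(y, dtype=float)
    res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=50, tol=1e-8)
    coefs = np.asarray(res.params)
    p = X.shape[1]
    bic = -2.0 * float(res.llf) + p * np.log(len(y))
    return FittedGLM(
        spec=spec,
        coefficients=coefs,
        names=list(names) if names is not None else [f"x{i}" for i in range(p)],
        loglik=float(res.llf),
        bic=float(bic),
        converged=bool(res.converged),
        separation_flag=bool(np.abs(coefs).max() > _SEPARATION_BOUND),
        n_obs=len(y),
    )


def select_best_glm(dataset: CaseControlDataset, coding: str) -> FittedGLM:
    """Fit the five candidates for one coding and return the BIC-best.

    Ties are broken toward fewer parameters (candidates are enumerated from
    the null model upward, so a stable min suffices).
    """
    if coding not in CODINGS:
        raise ValueError(f"unknown coding {coding!r}; choose from {CODINGS}")
    fits = []
    for spec in CANDIDATE_MODELS[coding]:
        X, names = build_design(dataset.genotype, dataset.exposure, spec, check_rank=True)
        fits.append(fit_logistic(X, dataset.status, spec, names))
    best = min(enumerate(fits), key=lambda kv: (kv[1].bic, kv[1].spec.n_params, kv[0]))[1]
    return best


def predict_grid_glm(fit: FittedGLM, u_grid: np.ndarray | None = None) -> np.ndarray:
    """Predicted surface f-hat(g, u') on the exposure grid, shape (3, len(grid))."""
    if u_grid is None:
        u_grid = exposure_grid()
    out = np.empty((3, len(u_grid)))
    for g in range(3):
        out[g] = fit.predict(np.full(len(u_grid), g), u_grid)
    return out
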