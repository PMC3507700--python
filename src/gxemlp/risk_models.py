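"""Penetrance models for a gene-environment interaction acting on disease risk.

The generative layer of the simulation study: nine population-level penetrance
functions ``F(g, u) = P(Y = 1 | G = g, U = u)`` for a biallelic locus
(genotype ``g`` in {0, 1, 2}, coded as the number of mutated alleles) and a
continuous environmental exposure ``u`` on [0, 100].

Two families of models carry a genuine gene-environment structure:

* *Sigmoid (Amato-type) models* — ``F(g, u) = z / (1 + exp(alpha_g + beta_g u))``
  with genotype-specific intercepts ``alpha_g`` and slopes ``beta_g``.  The four
  members (genetic, environmental, additive, interaction) differ in which of
  ``alpha`` and ``beta`` vary with the genotype.
* *Masking models 1-4* — piecewise models in which one genotype class shows a
  sigmoid exposure-risk relationship centred at u = 50 with risk increase ``r``
  while the other classes sit at (multiples of) a constant baseline risk ``c``;
  the genotype "masks" the environmental effect.

A ninth *null* model has constant risk ``K`` (no association at all).

Each model carries an upper bound ``z`` on the penetrance that is calibrated so
the population prevalence equals a target ``K`` (0.10 by default) under
Hardy-Weinberg genotype frequencies and a uniform exposure.  Because the
prevalence is affine in ``z`` for every family, the calibration is solved in
closed form; a bisection fallback covers user-defined families.

Population penetrance is converted to the within-sample disease probability of
a balanced case-control draw via the standard outcome-dependent-sampling odds
correction (`penetrance_to_casecontrol`).
"""

from __future__ import annotations


from dataclasses import dataclass, replace, asdict
from functools import lru_cache


import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "GenotypeDistribution",
    "PenetranceSpec",
    "CalibrationError",
    "AMATO_FAMILIES",
    "MASKING_FAMILIES",
    "FAMILIES",
    "amato_penetrance",
    "masking_penetrance",
    "null_penetrance",
    "population_prevalence",
    "population_prevalence_quad",
    "calibrate_z",
    "calibrate_z_bisect",
    "penetrance_to_casecontrol",
    "exposure_grid",
    "theoretic_surface",
    "make_spec",
    "calibrate",
    "get_spec",
    "list_models",
    "table1",
]

AMATO_FAMILIES = (
    "amato_genetic",
    "amato_environmental",
    "amato_additive",
    "amato_interaction",
)
MASKING_FAMILIES = ("masking_1", "masking_2", "masking_3", "masking_4")
FAMILIES = AMATO_FAMILIES + MASKING_FAMILIES + ("null",)

#: exposure domain shared by all models
ENV_LO, ENV_HI = 0.0, 100.0


class CalibrationError(ValueError):
    """Raised when no admissible upper bound z reproduces the target prevalence."""


@dataclass(frozen=True)
class GenotypeDistribution:
    """Hardy-Weinberg genotype distribution at a given minor allele frequency."""

    maf: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.maf <= 1.0:
            raise ValueError(f"minor allele frequency must be in [0, 1], got {self.maf}")

    @property
    def probs(self) -> np.ndarray:
        """(P(G=0), P(G=1), P(G=2)) = ((1-p)^2, 2p(1-p), p^2)."""
        p = self.maf
        return np.array([(1.0 - p) ** 2, 2.0 * p * (1.0 - p), p**2])


@dataclass(frozen=True)
class PenetranceSpec:
    """A named risk-model family with its parameters and calibrated scale.

    ``alpha``/``beta`` apply to the sigmoid (Amato-type) families, ``c``/``r``
    to the masking families.  ``z`` is the penetrance upper bound; it is None
    until the spec has been calibrated to the target prevalence ``K``.
    """

    family: str
    scenario: str = "high"
    K: float = 0.10
    alpha: tuple[float, float, float] | None = None
    beta: tuple[float, float, float] | None = None
    c: float | None = None
    r: float | None = None
    z: float | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; known: {FAMILIES}")
        if not 0.0 < self.K < 1.0:
            raise ValueError(f"target prevalence K must be in (0, 1), got {self.K}")
        if self.z is not None and not 0.0 < self.z <= 1.0:
            raise ValueError(f"upper bound z must be in (0, 1], got {self.z}")
        if self.family in AMATO_FAMILIES and (self.alpha is None or self.beta is None):
            raise ValueError(f"{self.family} requires alpha and beta 3-vectors")
        if self.family in MASKING_FAMILIES:
            if self.c is None or self.r is None:
                raise ValueError(f"{self.family} requires c and r")
            if self.c < 0:
                raise ValueError("baseline risk c must be nonnegative")
            if self.z is not None and self.c >= self.z:
                raise ValueError(f"need c < z, got c={self.c}, z={self.z}")

    @property
    def key(self) -> str:
        if self.family == "null":
            return "null"
        return f"{self.family}:{self.scenario}"

    @property
    def calibrated(self) -> bool:
        return self.family == "null" or self.z is not None

    def penetrance(self, g, u) -> np.ndarray:
        """Population penetrance F(g, u), vectorized over g and u."""
        if self.family == "null":
            return null_penetrance(self.K, g, u)
        if self.family in AMATO_FAMILIES:
            return amato_penetrance(self, g, u)
        return masking_penetrance(self, g, u)

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["alpha"] is not None:
            d["alpha"] = list(d["alpha"])
        if d["beta"] is not None:
            d["beta"] = list(d["beta"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PenetranceSpec":
        d = dict(d)
        for k in ("alpha", "beta"):
            if d.get(k) is not None:
                d[k] = tuple(d[k])
        return cls(**d)


def _check_domain(g, u):
    g = np.asarray(g)
    u = np.asarray(u, dtype=float)
    if not np.isin(g, (0, 1, 2)).all():
        raise ValueError("genotype must be 0, 1 or 2")
    if np.any(u < ENV_LO) or np.any(u > ENV_HI):
        raise ValueError(f"exposure must lie in [{ENV_LO}, {ENV_HI}]")
    return g.astype(np.int64), u


def amato_penetrance(spec: PenetranceSpec, g, u) -> np.ndarray:
    """Sigmoid penetrance z / (1 + exp(alpha_g + beta_g u))."""
    if spec.family not in AMATO_FAMILIES:
        raise ValueError(f"{spec.family} is not a sigmoid (Amato-type) family")
    g, u = _check_domain(g, u)
    z = 1.0 if spec.z is None else spec.z
    a = np.asarray(spec.alpha)[g]
    b = np.asarray(spec.beta)[g]
    return z * expit(-(a + b * u))


def masking_penetrance(spec: PenetranceSpec, g, u) -> np.ndarray:
    """Piecewise penetrance of masking models 1-4.

    Exactly one genotype class (g=0 in models 1-2, g=2 in models 3-4) follows a
    sigmoid in the exposure centred at u=50 with slope r; the others are held
    at constants derived from the baseline risk c.
    """
    if spec.family not in MASKING_FAMILIES:
        raise ValueError(f"{spec.family} is not a masking family")
    g, u = _check_domain(g, u)
    z = 1.0 if spec.z is None else spec.z
    c, r = spec.c, spec.r
    s = expit(r * (u - 50.0))
    g, s = np.broadcast_arrays(g, s)
    if spec.family == "masking_1":
        branches = [(z - c) * s + c, np.full_like(s, c), np.full_like(s, c)]
    elif spec.family == "masking_2":
        branches = [z * s, np.full_like(s, c), np.full_like(s, 2 * c)]
    elif spec.family == "masking_3":
        branches = [np.full_like(s, c), np.full_like(s, c), (z - c) * s + c]
    else:  # masking_4
        branches = [np.full_like(s, c / 2), np.full_like(s, c), (z - 2 * c) * s + 2 * c]
    return np.choose(g, branches)


def null_penetrance(K: float, g=0, u=0.0) -> np.ndarray:
    """Constant penetrance K: no genetic and no environmental association."""
    if not 0.0 < K < 1.0:
        raise ValueError("K must be in (0, 1)")
    g, u = _check_domain(g, u)
    return np.broadcast_arrays(np.full_like(u, K, dtype=float), g)[0]


def _mean_sigmoid(a: float, b: float, lo: float = ENV_LO, hi: float = ENV_HI) -> float:
    """Exposure-average of expit(-(a + b*u)) over [lo, hi], in closed form.

    Uses the antiderivative -(1/b) * softplus(-(a + b u)); exact for b = 0.
    """
    if b == 0.0:
        return float(expit(-a))
    sp_lo = np.logaddexp(0.0, -(a + b * lo))
    sp_hi = np.logaddexp(0.0, -(a + b * hi))
    return float((sp_lo - sp_hi) / (b * (hi - lo)))


def _genotype_mean_penetrance(spec: PenetranceSpec, g: int, z: float | None = None) -> float:
    """Exposure-average of F(g, .) with an optional z override (closed form)."""
    zz = spec.z if z is None else z
    if spec.family == "null":
        return spec.K
    if spec.family in AMATO_FAMILIES:
        if zz is None:
            zz = 1.0
        return zz * _mean_sigmoid(spec.alpha[g], spec.beta[g])
    c, r = spec.c, spec.r
    if zz is None:
        zz = 1.0
    m = _mean_sigmoid(50.0 * r, -r)  # mean of expit(r(u-50)); 0.5 on [0,100]
    if spec.family == "masking_1":
        branch = [(zz - c) * m + c, c, c]
    elif spec.family == "masking_2":
        branch = [zz * m, c, 2 * c]
    elif spec.family == "masking_3":
        branch = [c, c, (zz - c) * m + c]
    else:
        branch = [c / 2, c, (zz - 2 * c) * m + 2 * c]
    return float(branch[g])


def population_prevalence(spec: PenetranceSpec, dist: GenotypeDistribution) -> float:
    """Marginal P(Y=1) = sum_g P(g) * mean_u F(g, u), via the closed-form integral."""
    probs = dist.probs
    return float(sum(probs[g] * _genotype_mean_penetrance(spec, g) for g in range(3)))


def population_prevalence_quad(spec: PenetranceSpec, dist: GenotypeDistribution) -> float:
    """Numeric-quadrature cross-check of `population_prevalence`."""
    from scipy.integrate import quad

    probs = dist.probs
    total = 0.0
    for g in range(3):
        val, _ = quad(lambda u: float(spec.penetrance(g, u)), ENV_LO, ENV_HI, limit=200)
        total += probs[g] * val / (ENV_HI - ENV_LO)
    return float(total)


def calibrate_z(spec: PenetranceSpec, dist: GenotypeDistribution) -> float:
    """Solve for the upper bound z giving population prevalence K.

    The prevalence is affine in z for every built-in family, prevalence(z) =
    A*z + B with A > 0, so z = (K - B) / A exactly.
    """
    if spec.family == "null":
        raise ValueError("the null model has no scale to calibrate")
    prev0 = sum(dist.probs[g] * _genotype_mean_penetrance(spec, g, z=0.0) for g in range(3))
    prev1 = sum(dist.probs[g] * _genotype_mean_penetrance(spec, g, z=1.0) for g in range(3))
    A = prev1 - prev0
    if A <= 0:
        raise CalibrationError(f"{spec.key}: prevalence does not increase in z")
    z = (spec.K - prev0) / A
    _validate_z(spec, z)
    return float(z)


def calibrate_z_bisect(spec: PenetranceSpec, dist: GenotypeDistribution) -> float:
    """Root-finding fallback for user-defined families (no affinity assumed)."""
    from scipy.optimize import brentq

    def gap(z):
        s = replace(spec, z=None)
        return sum(
            dist.probs[g] * _genotype_mean_penetrance(s, g, z=z) for g in range(3)
        ) - spec.K

    lo, hi = 1e-12, 1.0
    if gap(lo) > 0 or gap(hi) < 0:
        raise CalibrationError(
            f"{spec.key}: no z in (0, 1] gives prevalence {spec.K} "
            f"(params alpha={spec.alpha} beta={spec.beta} c={spec.c} r={spec.r})"
        )
    z = brentq(gap, lo, hi, xtol=1e-12)
    _validate_z(spec, z)
    return float(z)


def _validate_z(spec: PenetranceSpec, z: float) -> None:
    if not 0.0 < z <= 1.0:
        raise CalibrationError(
            f"{spec.key}: calibrated z = {z:.4f} outside (0, 1] "
            f"(params alpha={spec.alpha} beta={spec.beta} c={spec.c} r={spec.r}, K={spec.K})"
        )
    if spec.c is not None and spec.c >= z:
        raise CalibrationError(f"{spec.key}: baseline risk c={spec.c} >= calibrated z={z:.4f}")


def penetrance_to_casecontrol(F, K: float, case_fraction: float = 0.5):
    """Convert population penetrance to the case-control disease probability.

    For a sample drawn with case fraction pi from a population with prevalence
    K, Bayes' rule under outcome-dependent sampling gives

        f = pi*F*(1-K) / (pi*F*(1-K) + (1-pi)*(1-F)*K).

    Strictly increasing in F, with f(0)=0, f(K)=pi-at-pi=0.5 for pi=0.5, f(1)=1.
    """
    if not 0.0 < K < 1.0:
        raise ValueError("population prevalence K must be strictly inside (0, 1)")
    pi = case_fraction
    if not 0.0 <= pi <= 1.0:
        raise ValueError("case_fraction must be in [0, 1]")
    F = np.asarray(F, dtype=float)
    num = pi * F * (1.0 - K)
    den = num + (1.0 - pi) * (1.0 - F) * K
    out = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
    return out if out.ndim else float(out)


def exposure_grid(step: float = 0.1) -> np.ndarray:
    """The fixed evaluation grid u' = 0, 0.1, ..., 100 (1001 points by default)."""
    n = int(round((ENV_HI - ENV_LO) / step)) + 1
    return np.linspace(ENV_LO, ENV_HI, n)


def theoretic_surface(
    spec: PenetranceSpec, u_grid: np.ndarray | None = None, case_fraction: float = 0.5
) -> np.ndarray:
    """Theoretic case-control risk surface f(g, u') on the grid, shape (3, len(grid))."""
    if not spec.calibrated:
        raise ValueError(f"{spec.key}: calibrate the spec before building the surface")
    if u_grid is None:
        u_grid = exposure_grid()
    F = np.stack([spec.penetrance(g, u_grid) for g in range(3)])
    return penetrance_to_casecontrol(F, spec.K, case_fraction)


# ---------------------------------------------------------------------------
# model registry

_AMATO_TABLE = {
    # family -> scenario -> (alpha triple, beta triple)
    "amato_genetic": {
        "high": ((2 / 3 * 2.5, 2.5, 4 / 3 * 2.5), (0.0, 0.0, 0.0)),
        "low": ((2 / 3 * 1.25, 1.25, 4 / 3 * 1.25), (0.0, 0.0, 0.0)),
    },
    "amato_environmental": {
        "high": ((7.5, 7.5, 7.5), (-0.15, -0.15, -0.15)),
        "low": ((3.75, 3.75, 3.75), (-0.075, -0.075, -0.075)),
    },
    "amato_additive": {
        "high": ((2 / 3 * 7.5, 7.5, 4 / 3 * 7.5), (-0.15, -0.15, -0.15)),
        "low": ((2 / 3 * 3.75, 3.75, 4 / 3 * 3.75), (-0.075, -0.075, -0.075)),
    },
    "amato_interaction": {
        "high": ((7.5, 7.5, 7.5), (2 * -0.15, -0.15, 0.5 * -0.15)),
        "low": ((3.75, 3.75, 3.75), (2 * -0.075, -0.075, 0.5 * -0.075)),
    },
}

_MASKING_TABLE = {
    # family -> baseline risk c; risk increase r is 0.150 (high) / 0.075 (low)
    "masking_1": 0.05,
    "masking_2": 0.05,
    "masking_3": 0.075,
    "masking_4": 0.075,
}
_MASKING_R = {"high": 0.150, "low": 0.075}


def make_spec(family: str, scenario: str = "high", K: float = 0.10) -> PenetranceSpec:
    """Build an uncalibrated spec (z=None) from the built-in parameter table."""
    if family == "null":
        return PenetranceSpec(family="null", scenario="none", K=K)
    if family in _AMATO_TABLE:
        alpha, beta = _AMATO_TABLE[family][scenario]
        return PenetranceSpec(family=family, scenario=scenario, K=K, alpha=alpha, beta=beta)
    if family in _MASKING_TABLE:
        return PenetranceSpec(
            family=family,
            scenario=scenario,
            K=K,
            c=_MASKING_TABLE[family],
            r=_MASKING_R[scenario],
        )
    raise ValueError(f"unknown family {family!r}")


def calibrate(spec: PenetranceSpec, dist: GenotypeDistribution) -> PenetranceSpec:
    """Return a copy of the spec with z calibrated to its target prevalence."""
    if spec.family == "null":
        return spec
    return replace(spec, z=calibrate_z(spec, dist))


@lru_cache(maxsize=None)
def get_spec(key: str, maf: float = 0.30, K: float = 0.10) -> PenetranceSpec:
    """Resolve a registry key like ``"amato_interaction:high"`` to a calibrated spec."""
    if key == "null":
        return make_spec("null", K=K)
    family, _, scenario = key.partition(":")
    if not scenario:
        raise ValueError(f"model key must look like 'family:scenario', got {key!r}")
    return calibrate(make_spec(family, scenario, K=K), GenotypeDistribution(maf))


def list_models(include_null: bool = True) -> list[str]:
    keys = [f"{fam}:{sc}" for fam in AMATO_FAMILIES + MASKING_FAMILIES for sc in ("high", "low")]
    if include_null:
        keys.append("null")
    return keys


def table1(maf: float = 0.30, K: float = 0.10) -> pd.DataFrame:
    """Calibrated constants of all models as a table (one row per family/scenario)."""
    rows = []
    for key in list_models(include_null=False):
        spec = get_spec(key, maf=maf, K=K)
        rows.append(
            {
                "model": spec.family,
                "scenario": spec.scenario,
                "alpha0": spec.alpha[0] if spec.alpha else np.nan,
                "alpha1": spec.alpha[1] if spec.alpha else np.nan,
                "alpha2": spec.alpha[2] if spec.alpha else np.nan,
                "beta0": spec.beta[0] if spec.beta else np.nan,
                "beta1": spec.beta[1] if spec.beta else np.nan,
                "beta2": spec.beta[2] if spec.beta else np.nan,
                "c": spec.c if spec.c is not None else np.nan,
                "r": spec.r if spec.r is not None else np.nan,
                "z": spec.z,
            }
        )
    return pd.DataFrame(rows)
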