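"""Multilayer perceptron for binary disease status, trained by rprop+.

A single-hidden-layer perceptron with logistic activation everywhere and
cross-entropy error.  With ``m`` hidden neurons and inputs ``x`` (plus a
constant neuron ``x_0 = 1``) the predicted disease probability is

    mu(x) = sigma( w_0 + sum_j w_j * sigma( sum_i w_ij * x_i ) ),

so an ``m = 0`` network is algebraically a logistic regression and its trained
weights coincide with the maximum-likelihood coefficients.  Training uses
resilient backpropagation (rprop+: sign-based per-weight adaptive step sizes
with weight backtracking) on the full data set, restarted from several random
standard-normal weight initializations; the reported fit minimizes

    BIC = 2 * E + p * log(N),

with E the cross-entropy (the exact negative Bernoulli log-likelihood) and p
the number of weights.  `select_topology` runs the restarts for every hidden
layer width in a candidate set (0..5 by default) and returns the BIC-best fit.

Follows the statsmodels convention of a model object (`MLP`) whose `fit`
returns a results object (`MLPResults`).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import _rprop
from .risk_models import exposure_grid

__all__ = [
    "Topology",
    "WeightSet",
    "TrainConfig",
    "MLP",
    "MLPResults",
    "SelectionError",
    "n_params",
    "forward",
    "cross_entropy",
    "gradients",
    "init_weights",
    "select_topology",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Topology:
    """Network shape: number of inputs and hidden neurons (single hidden layer)."""

    n_inputs: int = 2
    m_hidden: int = 0

    def __post_init__(self) -> None:
        if self.n_inputs < 1:
            raise ValueError("need at least one input")
        if self.m_hidden < 0:
            raise ValueError("m_hidden must be nonnegative")


def n_params(topology: Topology) -> int:
    """Weight count: (n+1)*m + m + 1 for m >= 1; n + 1 for the no-hidden-layer net."""
    n, m = topology.n_inputs, topology.m_hidden
    if m == 0:
        return n + 1
    return (n + 1) * m + m + 1


@dataclass
class WeightSet:
    """Weights of one network: hidden block (n+1, m) and output block (m+1,).

    For m = 0 the hidden block is None and the output block holds the n+1
    input-to-output weights [intercept, w_1, ..., w_n].
    """

    topology: Topology
    hidden: np.ndarray | None
    output: np.ndarray

    def __post_init__(self) -> None:
        n, m = self.topology.n_inputs, self.topology.m_hidden
        if m == 0:
            if self.hidden is not None or self.output.shape != (n + 1,):
                raise ValueError("m=0 network has a single (n+1,) weight vector")
        else:
            if self.hidden is None or self.hidden.shape != (n + 1, m):
                raise ValueError(f"hidden block must have shape {(n + 1, m)}")
            if self.output.shape != (m + 1,):
                raise ValueError(f"output block must have shape {(m + 1,)}")

    def flat(self) -> np.ndarray:
        if self.topology.m_hidden == 0:
            return self.output.copy()
        return np.concatenate([self.hidden.ravel(), self.output])

    @classmethod
    def from_flat(cls, topology: Topology, w: np.ndarray) -> "WeightSet":
        w = np.asarray(w, dtype=float)
        if w.size != n_params(topology):
            raise ValueError(f"expected {n_params(topology)} weights, got {w.size}")
        n, m = topology.n_inputs, topology.m_hidden
        if m == 0:
            return cls(topology, None, w.copy())
        hidden = w[: (n + 1) * m].reshape(n + 1, m).copy()
        return cls(topology, hidden, w[(n + 1) * m :].copy())


@dataclass(frozen=True)
class TrainConfig:
    """rprop+ hyperparameters and the training protocol."""

    eta_plus: float = 1.2
    eta_minus: float = 0.5
    delta_zero: float = 0.1
    delta_max: float = 50.0
    # with raw exposures on [0, 100] the error curvature along the exposure
    # weight reaches ~1e6, so a 1e-6 step floor cannot push the gradient
    # max-norm below the 0.01 stopping bound and rprop+ stalls in a
    # step/revert cycle; 1e-9 restores convergence
    delta_min: float = 1e-9
    threshold: float = 0.01  # convergence bound on max |dE/dw|
    stepmax: int = 100_000
    n_restarts: int = 5
    clip_eps: float = 1e-12

    def __post_init__(self) -> None:
        if not 0.0 < self.eta_minus < 1.0 < self.eta_plus:
            raise ValueError("need 0 < eta_minus < 1 < eta_plus")
        if not self.delta_min <= self.delta_zero <= self.delta_max:
            raise ValueError("need delta_min <= delta_zero <= delta_max")
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")


class SelectionError(RuntimeError):
    """No admissible training run to select from."""


def _add_constant(X: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return np.hstack([np.ones((X.shape[0], 1)), X])


def forward(weights: WeightSet, x) -> np.ndarray | float:
    """Predicted probability mu(x); x is one input vector or an (N, n) matrix."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X1 = _add_constant(x)
    if X1.shape[1] != weights.topology.n_inputs + 1:
        raise ValueError(
            f"expected {weights.topology.n_inputs} inputs, got {X1.shape[1] - 1}"
        )
    from scipy.special import expit

    if weights.topology.m_hidden == 0:
        mu = expit(X1 @ weights.output)
    else:
        h = expit(X1 @ weights.hidden)
        mu = expit(weights.output[0] + h @ weights.output[1:])
    return float(mu[0]) if single else mu


def cross_entropy(y, mu, clip_eps: float = 1e-12) -> float:
    """Summed cross-entropy -sum[y log mu + (1-y) log(1-mu)], clipped to stay finite."""
    y = np.asarray(y, dtype=float)
    mu = np.clip(np.asarray(mu, dtype=float), clip_eps, 1.0 - clip_eps)
    if y.shape != mu.shape:
        raise ValueError("y and mu must have equal length")
    return float(-(y * np.log(mu) + (1.0 - y) * np.log(1.0 - mu)).sum())


def gradients(weights: WeightSet, X, y) -> np.ndarray:
    """Exact partials dE/dw (flat layout), summed over observations.

    Backpropagation for the logistic-output / cross-entropy pair, whose
    output-layer residual is mu - y.
    """
    X1 = _add_constant(X)
    y = np.asarray(y, dtype=float)
    m = weights.topology.m_hidden
    if m == 0:
        from scipy.special import expit

        mu = expit(X1 @ weights.output)
        return X1.T @ (mu - y)
    from scipy.special import expit

    h = expit(X1 @ weights.hidden)  # (N, m)
    mu = expit(weights.output[0] + h @ weights.output[1:])
    d = mu - y
    g_out = np.concatenate([[d.sum()], d @ h])
    dh = np.outer(d, weights.output[1:]) * h * (1.0 - h)  # (N, m)
    g_hidden = X1.T @ dh  # (n+1, m)
    return np.concatenate([g_hidden.ravel(), g_out])


def init_weights(topology: Topology, rng: np.random.Generator) -> WeightSet:
    """Random starting weights, i.i.d. standard normal."""
    return WeightSet.from_flat(topology, rng.standard_normal(n_params(topology)))


class MLP:
    """Perceptron model bound to a case-control data set.

    Parameters
    ----------
    endog : array of 0/1 disease status
    exog : (N, n) array of inputs; by convention column 0 is the co-dominant
        genotype 0/1/2 and column 1 the raw exposure (no standardization).
    m_hidden : hidden layer width (0 gives a logistic regression).
    """

    def __init__(self, endog, exog, m_hidden: int = 0):
        self.endog = np.asarray(endog, dtype=float)
        self.exog = np.atleast_2d(np.asarray(exog, dtype=float))
        if self.exog.shape[0] != self.endog.shape[0]:
            raise ValueError("endog and exog must have the same number of rows")
        if not np.isin(self.endog, (0.0, 1.0)).all():
            raise ValueError("endog must be binary 0/1")
        self.topology = Topology(n_inputs=self.exog.shape[1], m_hidden=m_hidden)
        self._X1 = _add_constant(self.exog)

    @property
    def nobs(self) -> int:
        return self.endog.shape[0]

    def loglike(self, flat_w) -> float:
        ws = WeightSet.from_flat(self.topology, flat_w)
        return -cross_entropy(self.endog, forward(ws, self.exog))

    def fit(
        self,
        config: TrainConfig | None = None,
        start_weights: WeightSet | None = None,
        rng: np.random.Generator | int | None = None,
    ) -> "MLPResults":
        """Train with rprop+ from one start (random N(0,1) unless given)."""
        config = config or TrainConfig()
        if start_weights is None:
            if not isinstance(rng, np.random.Generator):
                rng = np.random.default_rng(rng)
            start_weights = init_weights(self.topology, rng)
        if self.endog.min() == self.endog.max():
            raise ValueError("training data must contain both statuses")
        w = start_weights.flat()
        err, n_iter, converged, diverged = _rprop.rprop_train(
            self._X1,
            self.endog,
            w,
            self.topology.m_hidden,
            config.eta_plus,
            config.eta_minus,
            config.delta_zero,
            config.delta_max,
            config.delta_min,
            config.threshold,
            config.stepmax,
            config.clip_eps,
        )
        p = n_params(self.topology)
        bic = 2.0 * err + p * np.log(self.nobs) if np.isfinite(err) else np.inf
        return MLPResults(
            model=self,
            weights=WeightSet.from_flat(self.topology, w),
            final_error=float(err),
            converged=bool(converged),
            diverged=bool(diverged),
            n_iterations=int(n_iter),
            bic=float(bic),
            config=config,
        )


@dataclass
class MLPResults:
    """Trained network: weights, convergence diagnostics and BIC."""

    model: MLP
    weights: WeightSet
    final_error: float
    converged: bool
    diverged: bool
    n_iterations: int
    bic: float
    config: TrainConfig
    selection_log: list = field(default_factory=list)

    @property
    def topology(self) -> Topology:
        return self.weights.topology

    @property
    def params(self) -> np.ndarray:
        return self.weights.flat()

    @property
    def df_model(self) -> int:
        return n_params(self.topology)

    def predict(self, exog=None):
        exog = self.model.exog if exog is None else exog
        return forward(self.weights, exog)

    def predict_grid(self, u_grid: np.ndarray | None = None) -> np.ndarray:
        """Predicted surface f-hat(g, u') for g = 0,1,2 on the exposure grid."""
        if u_grid is None:
            u_grid = exposure_grid()
        out = np.empty((3, len(u_grid)))
        for g in range(3):
            X = np.column_stack([np.full(len(u_grid), float(g)), u_grid])
            out[g] = forward(self.weights, X)
        return out

    def summary(self) -> str:
        t = self.topology
        lines = [
            "Multilayer perceptron (logistic activation, cross-entropy error)",
            f"  inputs: {t.n_inputs}   hidden neurons: {t.m_hidden}   weights: {self.df_model}",
            f"  observations: {self.model.nobs}",
            f"  cross-entropy: {self.final_error:.4f}   BIC: {self.bic:.4f}",
            f"  converged: {self.converged}   iterations: {self.n_iterations}",
        ]
        if t.m_hidden == 0:
            coef = ", ".join(f"{v:+.4f}" for v in self.weights.output)
            lines.append(f"  weights [intercept, inputs]: {coef}")
        return "\n".join(lines)

    def to_json(self, path=None) -> str:
        d = {
            "topology": asdict(self.topology),
            "hidden": None if self.weights.hidden is None else self.weights.hidden.tolist(),
            "output": self.weights.output.tolist(),
            "final_error": self.final_error,
            "converged": self.converged,
            "diverged": self.diverged,
            "n_iterations": self.n_iterations,
            "bic": self.bic,
            "config": asdict(self.config),
        }
        text = json.dumps(d, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def select_topology(
    endog,
    exog,
    topologies=range(6),
    config: TrainConfig | None = None,
    rng: np.random.Generator | int | None = None,
    converged_only: bool = False,
) -> MLPResults:
    """Train every candidate hidden-layer width with random restarts, pick by BIC.

    Each width in `topologies` is trained `config.n_restarts` times from fresh
    standard-normal weights.  The minimum-BIC fit wins, with ties broken
    toward fewer weights and then lower final error.  Diverged runs
    (non-finite error) are always excluded.  By default runs that stopped at
    the iteration cap still compete — their error is a valid likelihood and
    BIC penalizes poor fits on its own, so at reduced step budgets this
    approximates the fully-trained selection far better than discarding them;
    ``converged_only=True`` restricts the pool to converged runs and raises a
    `SelectionError` listing every run's status if there is none.
    """
    config = config or TrainConfig()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    topologies = list(topologies)
    if not topologies:
        raise ValueError("need at least one candidate topology")
    runs: list[tuple[MLPResults, int, int]] = []
    log = []
    for m in topologies:
        model = MLP(endog, exog, m_hidden=m)
        for rep in range(config.n_restarts):
            res = model.fit(config=config, rng=rng)
            runs.append((res, m, rep))
            log.append(
                {
                    "m_hidden": m,
                    "restart": rep,
                    "n_iterations": res.n_iterations,
                    "final_error": res.final_error,
                    "bic": res.bic,
                    "converged": res.converged,
                    "diverged": res.diverged,
                }
            )
            logger.debug(
                "m=%d restart=%d iter=%d error=%.4f bic=%.4f converged=%s",
                m, rep, res.n_iterations, res.final_error, res.bic, res.converged,
            )
    finite = [r for r in runs if not r[0].diverged and np.isfinite(r[0].bic)]
    if converged_only:
        admissible = [r for r in finite if r[0].converged]
    else:
        admissible = finite
    if not admissible:
        status = "; ".join(
            f"m={m} rep={rep}: iter={r.n_iterations} bic={r.bic:.2f} "
            f"converged={r.converged} diverged={r.diverged}"
            for r, m, rep in runs
        )
        raise SelectionError(f"no admissible training run to select from ({status})")
    # stable ordering makes ties deterministic
    best = min(
        enumerate(admissible),
        key=lambda ir: (ir[1][0].bic, ir[1][0].df_model, ir[1][0].final_error, ir[0]),
    )[1][0]
    best.selection_log = log
    return best
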