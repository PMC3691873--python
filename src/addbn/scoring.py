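"""Node scoring: Laplace-approximated log marginal likelihood of additive GLM nodes.

Each node of an additive Bayesian network is a generalised linear model of the
node given its parents: identity link with Gaussian errors for continuous
variables, logit link for binary ones.  The score of a (child, parent-set)
pair is the log evidence

    log P(D_child | parents) = log ∫ p(D_child | parents, θ) p(θ) dθ,

approximated by Laplace: locate the posterior mode, then

    log p(θ̂ | D) + (d/2)·log 2π − ½·log det(−H(θ̂)),

with H the Hessian of the log posterior and d the parameter count.  Under a
uniform prior over structures, the log evidence of a whole DAG is the sum of
its node scores, which is what makes exact structure search tractable.

Priors are deliberately diffuse: iid Normal(0, 1000) on every coefficient and
Gamma(shape 0.001, rate 0.001) on the Gaussian error precision.  The Gaussian
precision is treated as a parameter inside the Laplace approximation, on the
log scale so the mode is interior; both families therefore share one code
path, and the closed-form conjugate evidence serves only as a test oracle.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .constraints import SearchConstraints
from .data_io import DAG, ConfigurationError, Dataset, Family

logger = logging.getLogger(__name__)

__all__ = [
    "PriorSpec",
    "NodeModel",
    "NodeFit",
    "ScoreCache",
    "ScoringError",
    "EvidenceReport",
    "score_node",
    "fit_node",
    "build_score_cache",
    "network_score",
    "compare_evidence",
]

_MAX_ITER = 200
_GRAD_TOL = 1e-6


class ScoringError(RuntimeError):
    """Raised when a node model cannot be scored (collinearity, non-convergence)."""


@dataclass(frozen=True)
class PriorSpec:
    """Diffuse parameter priors shared by every node model."""

    coef_mean: float = 0.0
    coef_variance: float = 1000.0
    precision_shape: float = 0.001
    precision_rate: float = 0.001

    def __post_init__(self):
        if (self.coef_variance <= 0 or self.precision_shape <= 0
                or self.precision_rate <= 0):
            raise ConfigurationError("prior variances, shapes and rates must be > 0")


@dataclass(frozen=True)
class NodeModel:
    """A fitted (or specified) node-conditional GLM."""

    child: str
    parents: tuple[str, ...]
    family: Family
    coefficients: tuple[float, ...]  # intercept first, then one slope per parent
    precision: Optional[float] = None  # Gaussian family only

    def __post_init__(self):
        if self.child in self.parents:
            raise ConfigurationError(f"node {self.child!r} cannot be its own parent")
        if len(self.coefficients) != len(self.parents) + 1:
            raise ConfigurationError(
                f"{self.child!r}: expected {len(self.parents) + 1} coefficients, "
                f"got {len(self.coefficients)}")
        if self.family is Family.GAUSSIAN:
            if self.precision is None or self.precision <= 0:
                raise ConfigurationError(
                    f"Gaussian node {self.child!r} needs a positive precision")


# ---------------------------------------------------------------------------
# Newton fits
# ---------------------------------------------------------------------------

@dataclass
class NodeFit:
    """Posterior mode fit of one node model, with everything Laplace needs.

    ``mode`` stacks the regression coefficients (intercept first) and, for
    Gaussian nodes, the log precision as the last entry.  ``neg_hessian`` is
    −H at the mode.  ``profile_logpost(j, grid)`` evaluates the log posterior
    along parameter ``j`` with the remaining parameters at their conditional
    mode given the scanned value (the ridge path): for a quadratic log
    posterior this is the exact profile, whose curvature equals the marginal
    precision 1/(H⁻¹)ⱼⱼ — the basis for the deterministic marginal-posterior
    summaries.
    """

    child: str
    parents: tuple[str, ...]
    family: Family
    param_names: tuple[str, ...]
    mode: np.ndarray
    neg_hessian: np.ndarray
    logpost: float
    logml: float
    _colwise: object = field(repr=False, default=None)

    @property
    def coefficients(self) -> np.ndarray:
        p = len(self.parents) + 1
        return self.mode[:p]

    @property
    def precision(self) -> Optional[float]:
        if self.family is Family.GAUSSIAN:
            return float(np.exp(self.mode[-1]))
        return None

    def to_node_model(self) -> NodeModel:
        return NodeModel(self.child, self.parents, self.family,
                         tuple(float(c) for c in self.coefficients),
                         self.precision)

    def profile_logpost(self, j: int, grid: np.ndarray) -> np.ndarray:
        grid = np.asarray(grid, dtype=float)
        cov = np.linalg.inv(self.neg_hessian)
        direction = cov[:, j] / cov[j, j]
        theta = (self.mode[:, None]
                 + direction[:, None] * (grid - self.mode[j])[None, :])
        return self._colwise(theta)


def _check_rank(xtx: np.ndarray, child: str, parents: Sequence[str]) -> None:
    if np.linalg.matrix_rank(xtx, hermitian=True) < xtx.shape[0]:
        raise ScoringError(
            f"design matrix for {child!r} | {sorted(parents)} is rank deficient "
            "(perfectly collinear parents)")


def _gaussian_fit(y: np.ndarray, X: np.ndarray, child: str,
                  parents: tuple[str, ...], prior: PriorSpec) -> NodeFit:
    n, p = X.shape
    xtx = X.T @ X
    _check_rank(xtx, child, parents)
    xty = X.T @ y
    yty = float(y @ y)
    m0, v0 = prior.coef_mean, prior.coef_variance
    a, b = prior.precision_shape, prior.precision_rate

    def rss(beta: np.ndarray) -> float:
        return yty - 2.0 * beta @ xty + beta @ xtx @ beta

    def logpost(beta: np.ndarray, lam: float) -> float:
        s = rss(beta)
        return (-0.5 * n * math.log(2 * math.pi) + 0.5 * n * lam
                - 0.5 * math.exp(lam) * s
                - 0.5 * np.sum((beta - m0) ** 2) / v0
                - 0.5 * p * math.log(2 * math.pi * v0)
                + a * math.log(b) - gammaln(a) + a * lam - b * math.exp(lam))

    # Block ascent: β | λ is an exact ridge solve, λ | β is exact in closed
    # form; the fixed point is the joint posterior mode.
    var_y = max(float(np.var(y)), 1e-12)
    lam = -math.log(var_y)
    beta = np.zeros(p)
    eye = np.eye(p)
    converged = False
    for _ in range(_MAX_ITER):
        tau = math.exp(lam)
        beta = np.linalg.solve(tau * xtx + eye / v0, tau * xty + m0 / v0 * np.ones(p))
        s = rss(beta)
        lam_new = math.log((0.5 * n + a) / (0.5 * s + b))
        grad_beta = tau * (xty - xtx @ beta) - (beta - m0) / v0
        grad_lam = 0.5 * n + a - math.exp(lam_new) * (0.5 * s + b)
        lam = lam_new
        if max(np.max(np.abs(grad_beta)), abs(grad_lam)) < _GRAD_TOL:
            converged = True
            break
    if not converged:
        raise ScoringError(
            f"Newton iteration for {child!r} | {sorted(parents)} did not converge "
            f"(last gradient {np.max(np.abs(grad_beta)):.3g})")

    tau = math.exp(lam)
    s = rss(beta)
    d = p + 1
    neg_h = np.zeros((d, d))
    neg_h[:p, :p] = tau * xtx + eye / v0
    cross = -tau * (xty - xtx @ beta)
    neg_h[:p, p] = cross
    neg_h[p, :p] = cross
    neg_h[p, p] = tau * (0.5 * s + b)
    lp = logpost(beta, lam)
    sign, logdet = np.linalg.slogdet(neg_h)
    if sign <= 0:
        raise ScoringError(f"non positive-definite Hessian for {child!r}")
    logml = lp + 0.5 * d * math.log(2 * math.pi) - 0.5 * logdet
    mode = np.concatenate([beta, [lam]])

    def colwise(theta: np.ndarray) -> np.ndarray:
        B, lams = theta[:p], theta[p]
        rss_cols = (yty - 2.0 * xty @ B
                    + np.einsum("im,ij,jm->m", B, xtx, B))
        taus = np.exp(lams)
        return ((0.5 * n + a) * lams - taus * (0.5 * rss_cols + b)
                - 0.5 * np.sum((B - m0) ** 2, axis=0) / v0)

    names = ("(intercept)",) + parents + ("log_precision",)
    return NodeFit(child, parents, Family.GAUSSIAN, names, mode, neg_h,
                   lp, logml, _colwise=colwise)


def _bernoulli_fit(y: np.ndarray, X: np.ndarray, child: str,
                   parents: tuple[str, ...], prior: PriorSpec) -> NodeFit:
    n, p = X.shape
    _check_rank(X.T @ X, child, parents)
    m0, v0 = prior.coef_mean, prior.coef_variance

    def logpost(beta: np.ndarray) -> float:
        eta = X @ beta
        ll = float(y @ eta - np.sum(np.logaddexp(0.0, eta)))
        return (ll - 0.5 * np.sum((beta - m0) ** 2) / v0
                - 0.5 * p * math.log(2 * math.pi * v0))

    beta = np.zeros(p)
    lp = logpost(beta)
    eye = np.eye(p)
    converged = False
    for _ in range(_MAX_ITER):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        grad = X.T @ (y - mu) - (beta - m0) / v0
        if np.max(np.abs(grad)) < _GRAD_TOL:
            converged = True
            break
        w = mu * (1.0 - mu)
        neg_h = X.T @ (X * w[:, None]) + eye / v0
        step = np.linalg.solve(neg_h, grad)
        # step-halving keeps the ascent monotone
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            lp_new = logpost(cand)
            if lp_new >= lp:
                break
            scale *= 0.5
        # near the mode the log posterior is flat to machine precision and
        # halving can stall with the gradient a hair above tolerance; a
        # vanishing accepted step is convergence too
        if np.max(np.abs(scale * step)) < 1e-9 and np.max(np.abs(grad)) < 1e-4:
            converged = True
            beta, lp = cand, lp_new
            break
        beta, lp = cand, lp_new
    if not converged:
        raise ScoringError(
            f"Newton iteration for {child!r} | {sorted(parents)} did not converge")

    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    neg_h = X.T @ (X * w[:, None]) + eye / v0
    sign, logdet = np.linalg.slogdet(neg_h)
    if sign <= 0:
        raise ScoringError(f"non positive-definite Hessian for {child!r}")
    lp = logpost(beta)
    logml = lp + 0.5 * p * math.log(2 * math.pi) - 0.5 * logdet

    def colwise(theta: np.ndarray) -> np.ndarray:
        etas = X @ theta
        ll = y @ etas - np.sum(np.logaddexp(0.0, etas), axis=0)
        return ll - 0.5 * np.sum((theta - m0) ** 2, axis=0) / v0

    names = ("(intercept)",) + parents
    return NodeFit(child, parents, Family.BERNOULLI, names, beta.copy(), neg_h,
                   lp, logml, _colwise=colwise)


def _design(data: Dataset, child: str, parents: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    y = data.column(child)
    X = np.column_stack([np.ones(data.n)] + [data.column(p) for p in parents])
    return y, X


def fit_node(data: Dataset, child: str, parents: Iterable[str],
             prior: PriorSpec | None = None) -> NodeFit:
    """Fit one node-conditional GLM at its posterior mode.

    Returns the mode, negative Hessian, Laplace log marginal likelihood and a
    conditional-log-posterior evaluator.  Deterministic: identical inputs give
    bit-identical output.
    """
    prior = prior or PriorSpec()
    parents = tuple(sorted(parents))
    if child in parents:
        raise ConfigurationError(f"{child!r} cannot be its own parent")
    for v in (child, *parents):
        if v not in data.names:
            raise ConfigurationError(f"unknown variable {v!r}")
    y, X = _design(data, child, parents)
    if data.family(child) is Family.GAUSSIAN:
        return _gaussian_fit(y, X, child, parents, prior)
    return _bernoulli_fit(y, X, child, parents, prior)


def score_node(data: Dataset, child: str, parents: Iterable[str],
               prior: PriorSpec | None = None) -> float:
    """Laplace-approximated log marginal likelihood of ``child | parents``."""
    return fit_node(data, child, parents, prior).logml


# ---------------------------------------------------------------------------
# Score cache
# ---------------------------------------------------------------------------

class ScoreCache:
    """Log marginal likelihoods for every admissible (child, parent-set) pair."""

    def __init__(self, nodes: tuple[str, ...], families: dict[str, Family],
                 constraints: SearchConstraints, prior: PriorSpec,
                 fingerprint: str):
        self.nodes = nodes
        self.families = families
        self.constraints = constraints
        self.prior = prior
        self.fingerprint = fingerprint
        self._scores: dict[tuple[str, frozenset[str]], float] = {}
        self.invalid: dict[tuple[str, frozenset[str]], str] = {}

    def put(self, child: str, parents: Iterable[str], score: float) -> None:
        if not np.isfinite(score):
            raise ScoringError(f"non-finite score for {child!r}")
        self._scores[(child, frozenset(parents))] = float(score)

    def score(self, child: str, parents: Iterable[str]) -> float:
        key = (child, frozenset(parents))
        if key in self._scores:
            return self._scores[key]
        if key in self.invalid:
            raise ScoringError(f"entry {key} is invalid: {self.invalid[key]}")
        raise KeyError(f"no cached score for child {child!r} with parents "
                       f"{sorted(key[1])}")

    def entries(self) -> dict[tuple[str, frozenset[str]], float]:
        return dict(self._scores)

    def parent_sets(self, child: str) -> list[tuple[frozenset[str], float]]:
        return [(ps, s) for (c, ps), s in self._scores.items() if c == child]

    def __len__(self) -> int:
        return len(self._scores)

    def __contains__(self, key: tuple[str, Iterable[str]]) -> bool:
        child, parents = key
        return (child, frozenset(parents)) in self._scores

    # -- persistence -------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = [{"child": c, "parents": "|".join(sorted(ps)), "logml": s}
                for (c, ps), s in sorted(self._scores.items(),
                                         key=lambda kv: (kv[0][0], sorted(kv[0][1])))]
        return pd.DataFrame(rows, columns=["child", "parents", "logml"])

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, nodes: tuple[str, ...],
                   families: dict[str, Family],
                   constraints: SearchConstraints | None = None,
                   prior: PriorSpec | None = None,
                   fingerprint: str = "external") -> "ScoreCache":
        cache = cls(nodes, families, constraints or SearchConstraints(),
                    prior or PriorSpec(), fingerprint)
        for row in frame.itertuples(index=False):
            parents = tuple(p for p in str(row.parents).split("|") if p) \
                if isinstance(row.parents, str) else ()
            cache.put(row.child, parents, float(row.logml))
        return cache

    @classmethod
    def read_csv(cls, path: str | Path, nodes: tuple[str, ...],
                 families: dict[str, Family], **kw) -> "ScoreCache":
        return cls.from_frame(pd.read_csv(path, keep_default_na=False), nodes,
                              families, **kw)


def _estimate_cache_size(n_candidates: Sequence[int], maxp: Sequence[int]) -> int:
    total = 0
    for nc, mp in zip(n_candidates, maxp):
        total += sum(math.comb(nc, k) for k in range(min(nc, mp) + 1))
    return total


def build_score_cache(data: Dataset, constraints: SearchConstraints | None = None,
                      prior: PriorSpec | None = None, *,
                      cache_cap: int = 2_000_000) -> ScoreCache:
    """Score every admissible (child, parent-set) pair under the constraints.

    Parent sets run over all subsets of the allowed parents up to
    ``max_parents`` that contain the child's retained parents.  Entries that
    cannot be scored (collinear designs, non-convergence) are recorded as
    invalid with the reason rather than aborting the whole cache.
    """
    constraints = constraints or SearchConstraints()
    prior = prior or PriorSpec()
    constraints.validate_against(data.names)

    cand = {c: constraints.allowed_parents(c, data.names) for c in data.names}
    maxp = {c: constraints.effective_max_parents(len(cand[c])) for c in data.names}
    est = _estimate_cache_size([len(cand[c]) for c in data.names],
                               [maxp[c] for c in data.names])
    if est > cache_cap:
        raise ConfigurationError(
            f"estimated cache size {est} exceeds cap {cache_cap}; "
            "lower max_parents or add banned arcs")

    families = {s.name: s.family for s in data.specs}
    cache = ScoreCache(tuple(data.names), families, constraints, prior,
                       data.fingerprint())
    ones = np.ones(data.n)
    for child in data.names:
        retained = tuple(sorted(constraints.retained_parents(child)))
        free = [p for p in cand[child] if p not in retained]
        y = data.column(child)
        cols = {p: data.column(p) for p in cand[child]}
        gaussian = families[child] is Family.GAUSSIAN
        if gaussian:
            # sufficient statistics over the full candidate design; per-set
            # fits then slice, making the Gaussian sweep O(p^3) not O(n p^2)
            full = np.column_stack([ones] + [cols[p] for p in cand[child]])
            full_xtx = full.T @ full
            full_xty = full.T @ y
            yty = float(y @ y)
            idx_of = {p: i + 1 for i, p in enumerate(cand[child])}
        for k in range(max(0, maxp[child] - len(retained)) + 1):
            for extra in itertools.combinations(free, k):
                parents = tuple(sorted(retained + extra))
                if len(parents) > maxp[child]:
                    continue
                try:
                    if gaussian:
                        sel = [0] + [idx_of[p] for p in parents]
                        fit = _gaussian_fit_suffstats(
                            full_xtx[np.ix_(sel, sel)], full_xty[sel], yty,
                            data.n, child, parents, prior)
                    else:
                        X = np.column_stack([ones] + [cols[p] for p in parents])
                        fit = _bernoulli_fit(y, X, child, parents, prior)
                    cache.put(child, parents, fit.logml)
                except ScoringError as exc:
                    cache.invalid[(child, frozenset(parents))] = str(exc)
                    logger.warning("invalid cache entry %s | %s: %s",
                                   child, parents, exc)
    return cache


def _gaussian_fit_suffstats(xtx: np.ndarray, xty: np.ndarray, yty: float,
                            n: int, child: str, parents: tuple[str, ...],
                            prior: PriorSpec) -> NodeFit:
    """Gaussian Laplace fit from sufficient statistics (cache fast path)."""
    p = xtx.shape[0]
    _check_rank(xtx, child, parents)
    m0, v0 = prior.coef_mean, prior.coef_variance
    a, b = prior.precision_shape, prior.precision_rate

    var_y = max(yty / n - (xty[0] / n) ** 2, 1e-12)
    lam = -math.log(var_y)
    beta = np.zeros(p)
    eye = np.eye(p)
    converged = False
    for _ in range(_MAX_ITER):
        tau = math.exp(lam)
        beta = np.linalg.solve(tau * xtx + eye / v0, tau * xty + m0 / v0 * np.ones(p))
        s = yty - 2.0 * beta @ xty + beta @ xtx @ beta
        lam_new = math.log((0.5 * n + a) / (0.5 * s + b))
        grad_beta = tau * (xty - xtx @ beta) - (beta - m0) / v0
        grad_lam = 0.5 * n + a - math.exp(lam_new) * (0.5 * s + b)
        lam = lam_new
        if max(np.max(np.abs(grad_beta)), abs(grad_lam)) < _GRAD_TOL:
            converged = True
            break
    if not converged:
        raise ScoringError(f"Newton iteration for {child!r} did not converge")

    tau = math.exp(lam)
    s = yty - 2.0 * beta @ xty + beta @ xtx @ beta
    d = p + 1
    neg_h = np.zeros((d, d))
    neg_h[:p, :p] = tau * xtx + eye / v0
    cross = -tau * (xty - xtx @ beta)
    neg_h[:p, p] = cross
    neg_h[p, :p] = cross
    neg_h[p, p] = tau * (0.5 * s + b)
    lp = (-0.5 * n * math.log(2 * math.pi) + 0.5 * n * lam - 0.5 * tau * s
          - 0.5 * float(np.sum((beta - m0) ** 2)) / v0
          - 0.5 * p * math.log(2 * math.pi * v0)
          + a * math.log(b) - gammaln(a) + a * lam - b * math.exp(lam))
    sign, logdet = np.linalg.slogdet(neg_h)
    if sign <= 0:
        raise ScoringError(f"non positive-definite Hessian for {child!r}")
    logml = lp + 0.5 * d * math.log(2 * math.pi) - 0.5 * logdet
    names = ("(intercept)",) + parents + ("log_precision",)
    return NodeFit(child, parents, Family.GAUSSIAN, names,
                   np.concatenate([beta, [lam]]), neg_h, lp, logml)


# ---------------------------------------------------------------------------
# Network score and evidence comparison
# ---------------------------------------------------------------------------

def network_score(dag: DAG, cache: ScoreCache) -> float:
    """Log marginal likelihood of a DAG: the sum of its node scores.

    Under a uniform structure prior this is, up to an additive constant, the
    log posterior probability of the structural hypothesis.
    """
    total = 0.0
    for node in dag.nodes:
        total += cache.score(node, dag.parents(node))
    return total


@dataclass(frozen=True)
class EvidenceReport:
    """Signed log-evidence difference with a Jeffreys-style category."""

    difference: float          # logml_1 − logml_2
    category: str
    favoured: Optional[int]    # 1, 2, or None on a tie


_CATEGORIES = [(0.0, "none"), (2.0, "weak"), (6.0, "positive"),
               (10.0, "strong"), (math.inf, "very strong")]


def compare_evidence(logml_1: float, logml_2: float) -> EvidenceReport:
    """Compare two log marginal likelihoods.

    A difference of more than 10 on the natural-log scale is conventionally
    read as very strong evidence for the higher-scoring model.
    """
    if not (np.isfinite(logml_1) and np.isfinite(logml_2)):
        raise ValueError("both log marginal likelihoods must be finite")
    diff = logml_1 - logml_2
    mag = abs(diff)
    for bound, label in _CATEGORIES:
        if mag <= bound:
            category = label
            break
    favoured = None if diff == 0 else (1 if diff > 0 else 2)
    return EvidenceReport(difference=diff, category=category, favoured=favoured)
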