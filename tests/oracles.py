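"""Independent oracles: closed forms, quadrature, and brute-force enumeration.

Everything here is deliberately implemented without touching the package's
production code paths (Laplace fits, subset DP), so agreement between the two
routes is meaningful evidence of correctness.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import integrate
from scipy.special import gammaln


# ---------------------------------------------------------------------------
# Closed-form conjugate evidence for the Gaussian linear model
# ---------------------------------------------------------------------------

def conjugate_gaussian_evidence(y: np.ndarray, X: np.ndarray,
                                coef_variance: float = 1000.0,
                                shape: float = 0.001,
                                rate: float = 0.001) -> float:
    """Exact log evidence under the conjugate normal–gamma prior.

    beta | tau ~ N(0, tau^-1 * v0 I), tau ~ Gamma(shape, rate); the marginal
    p(y) is available in closed form (multivariate-t algebra).
    """
    n, p = X.shape
    v0_inv = np.eye(p) / coef_variance
    vn_inv = v0_inv + X.T @ X
    vn = np.linalg.inv(vn_inv)
    mn = vn @ (X.T @ y)
    a_n = shape + 0.5 * n
    b_n = rate + 0.5 * (y @ y - mn @ vn_inv @ mn)
    _, logdet_vn = np.linalg.slogdet(vn)
    logdet_v0 = p * math.log(coef_variance)
    return (-0.5 * n * math.log(2 * math.pi)
            + 0.5 * (logdet_vn - logdet_v0)
            + shape * math.log(rate) - a_n * math.log(b_n)
            + gammaln(a_n) - gammaln(shape))


# ---------------------------------------------------------------------------
# Numerical quadrature for the Bernoulli-logit evidence (<= 2 parameters)
# ---------------------------------------------------------------------------

def _logistic_logpost(beta: np.ndarray, y: np.ndarray, X: np.ndarray,
                      coef_variance: float) -> float:
    eta = X @ beta
    ll = float(y @ eta - np.sum(np.logaddexp(0.0, eta)))
    p = len(beta)
    return (ll - 0.5 * float(beta @ beta) / coef_variance
            - 0.5 * p * math.log(2 * math.pi * coef_variance))


def _ml_center(y: np.ndarray, X: np.ndarray, coef_variance: float = 1000.0):
    """Posterior location/scale from an independent ridge-IRLS fit.

    The prior penalty keeps the centre finite under quasi-separation, where a
    plain ML fit diverges and would send the integration region to infinity.
    """
    p = X.shape[1]
    beta = np.zeros(p)
    for _ in range(200):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        grad = X.T @ (y - mu) - beta / coef_variance
        H = X.T @ (X * (mu * (1 - mu))[:, None]) + np.eye(p) / coef_variance
        delta = np.linalg.solve(H, grad)
        beta = beta + delta
        if np.max(np.abs(delta)) < 1e-10:
            break
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    H = X.T @ (X * (mu * (1 - mu))[:, None]) + np.eye(p) / coef_variance
    scale = np.sqrt(np.diag(np.linalg.inv(H)))
    return beta, scale


def quadrature_bernoulli_evidence(y: np.ndarray, X: np.ndarray,
                                  coef_variance: float = 1000.0) -> float:
    """Log evidence of a 1- or 2-parameter logit model by adaptive quadrature."""
    n, p = X.shape
    assert p in (1, 2)
    center, scale = _ml_center(y, X)
    scale = np.maximum(scale, 1e-3)
    shift = _logistic_logpost(center, y, X, coef_variance)
    half = 14.0
    if p == 1:
        val, _ = integrate.quad(
            lambda b0: math.exp(
                _logistic_logpost(np.array([b0]), y, X, coef_variance) - shift),
            center[0] - half * scale[0], center[0] + half * scale[0],
            limit=200)
    else:
        val, _ = integrate.dblquad(
            lambda b1, b0: math.exp(
                _logistic_logpost(np.array([b0, b1]), y, X, coef_variance) - shift),
            center[0] - half * scale[0], center[0] + half * scale[0],
            lambda _: center[1] - half * scale[1],
            lambda _: center[1] + half * scale[1])
    return shift + math.log(val)


# ---------------------------------------------------------------------------
# Brute-force DAG enumeration
# ---------------------------------------------------------------------------

def robinson_dag_count(n: int) -> int:
    """Number of labelled DAGs on n nodes (Robinson's recurrence)."""
    a = [1]
    for m in range(1, n + 1):
        total = 0
        for k in range(1, m + 1):
            total += (-1) ** (k + 1) * math.comb(m, k) * 2 ** (k * (m - k)) * a[m - k]
        a.append(total)
    return a[n]


def enumerate_dags(nodes: tuple[str, ...], *, constraints=None,
                   max_parents: int | None = None):
    """Yield every labelled DAG on ``nodes`` as a {child: parent frozenset} map.

    Acyclicity is checked by repeated sink removal, independently of the
    package's networkx-backed check.  Optional constraints mirror the
    package's semantics: banned/retained arcs, parent limit, response
    restriction.
    """
    def admissible(parent, child):
        if constraints is None:
            return True
        return constraints.arc_admissible(parent, child)

    def retained(child):
        if constraints is None:
            return frozenset()
        return constraints.retained_parents(child)

    per_child = []
    for child in nodes:
        others = [p for p in nodes if p != child and admissible(p, child)]
        need = retained(child)
        sets = []
        limit = len(others) if max_parents is None else max_parents
        for k in range(limit + 1):
            for combo in itertools.combinations(others, k):
                s = frozenset(combo)
                if need <= s:
                    sets.append(s)
        per_child.append(sets)

    for assignment in itertools.product(*per_child):
        parent_map = dict(zip(nodes, assignment))
        # sink elimination
        remaining = dict(parent_map)
        progress = True
        while remaining and progress:
            progress = False
            has_child = set()
            for c, ps in remaining.items():
                has_child |= {p for p in ps if p in remaining}
            sinks = [c for c in remaining if c not in has_child]
            for s in sinks:
                del remaining[s]
                progress = True
        if not remaining:
            yield parent_map


def best_network_by_enumeration(cache, nodes, *, constraints=None,
                                max_parents: int | None = None):
    """Maximum network score over every enumerated DAG, via cache lookups."""
    best = -math.inf
    best_map = None
    count = 0
    for parent_map in enumerate_dags(nodes, constraints=constraints,
                                     max_parents=max_parents):
        count += 1
        try:
            score = sum(cache.score(c, ps) for c, ps in parent_map.items())
        except KeyError:
            continue
        if score > best:
            best, best_map = score, parent_map
    return best, best_map, count
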