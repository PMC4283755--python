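"""Analytic interim selection probabilities via multivariate normal integration.

Both interim rules select the arm maximizing a vector of unit-variance
statistics with pairwise correlation 1/2 (the many-to-one structure).  The
probability that arm ``i`` wins is the orthant probability that all
differences against arm ``i`` are nonpositive -- a (k-1)-dimensional normal
CDF with difference variances 1 and correlations 1/2.

The joint probability that *both* rules pick the same arm couples the
early-endpoint differences with the score differences through the
within-patient correlation: writing gamma = rho_w * sigma * sqrt(I / (2 N1)),
Cov(S_i, Z~_j) = gamma * (1 + [i == j]), so the 2(k-1)-dimensional difference
vector has cross-covariance block gamma * (1 + [j == l]).  Unlike each
marginal law, this cross term changes sign with rho_w, which is why the
agreement probability of the two rules depends on the sign of the
within-patient correlation even though neither marginal does.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad, simpson
from scipy.special import ndtr
from scipy.stats import multivariate_normal, norm, qmc

from .stats_engine import score_information
from .trial_model import EndpointModel, TrialDesign

__all__ = [
    "JointSelectionTable",
    "mvn_orthant",
    "friede_selection_prob",
    "stallard_selection_prob",
    "joint_selection_prob",
]

_MVN_SEED = 20140502  # fixed internal randomization: reproducible integrals
_EIG_TOL = 1e-9

# quadrature grid for the exact equicorrelated (rho = 1/2) reduction
_GRID = np.linspace(-9.0, 9.0, 401)
_PHI = norm.pdf(_GRID)


@dataclass(frozen=True)
class JointSelectionTable:
    """2x2 agreement table of the two rules for one arm, with marginals."""

    arm: int
    p_both: float
    p_stallard_only: float
    p_friede_only: float
    p_neither: float

    @property
    def p_stallard(self) -> float:
        return self.p_both + self.p_stallard_only

    @property
    def p_friede(self) -> float:
        return self.p_both + self.p_friede_only

    @property
    def p_at_least_one(self) -> float:
        return 1.0 - self.p_neither


# ---------------------------------------------------------------------------
# multivariate normal orthant probabilities
# ---------------------------------------------------------------------------

def mvn_orthant(mean, cov, *, abs_tol: float = 1e-6) -> float:
    """P(X <= 0 componentwise) for X ~ N(mean, cov).

    Uses scipy's quasi-Monte-Carlo normal CDF with a fixed internal seed, so
    results are deterministic to roughly ``abs_tol``.  Singular covariance
    matrices (e.g. from |rho_w| = 1) are handled by eigen-truncation to the
    supported subspace: rank 1 reduces to an interval probability, rank 2 to
    a one-dimensional adaptive quadrature, higher ranks to scrambled-Sobol
    integration on the subspace.
    """
    mean = np.atleast_1d(np.asarray(mean, dtype=float))
    cov = np.atleast_2d(np.asarray(cov, dtype=float))
    d = mean.size
    if d == 0:
        return 1.0
    if cov.shape != (d, d):
        raise ValueError("cov shape does not match mean")
    if not np.allclose(cov, cov.T, atol=1e-10):
        raise ValueError("cov must be symmetric")
    if d == 1:
        v = cov[0, 0]
        if v <= _EIG_TOL:
            return float(mean[0] <= 0.0)
        return float(norm.cdf(-mean[0] / np.sqrt(v)))
    w, V = np.linalg.eigh(cov)
    scale = max(w.max(), 1.0)
    if w.min() < -1e-8 * scale:
        raise ValueError("cov must be positive semi-definite")
    keep = w > _EIG_TOL * scale
    rank = int(keep.sum())
    if rank == d:
        p = multivariate_normal.cdf(
            np.zeros(d),
            mean=mean,
            cov=cov,
            maxpts=1_000_000 * d,
            abseps=abs_tol / 5.0,
            releps=0.0,
            rng=np.random.default_rng(_MVN_SEED),
        )
        return float(np.clip(p, 0.0, 1.0))
    L = V[:, keep] * np.sqrt(w[keep])  # X = mean + L W, W ~ N(0, I_rank)
    return _degenerate_orthant(mean, L, rank)


def _degenerate_orthant(mean: np.ndarray, L: np.ndarray, rank: int) -> float:
    """P(mean + L W <= 0) for standard normal W of dimension ``rank`` < d."""
    if rank == 0:
        return float(np.all(mean <= 0.0))
    if rank == 1:
        lo, hi = -np.inf, np.inf
        for a, m in zip(L[:, 0], mean):
            if abs(a) <= 1e-12:
                if m > 0:
                    return 0.0
            elif a > 0:
                hi = min(hi, -m / a)
            else:
                lo = max(lo, -m / a)
        return float(max(norm.cdf(hi) - norm.cdf(lo), 0.0))
    if rank == 2:
        return _orthant_rank2(mean, L)
    return _orthant_qmc(mean, L, rank)


def _orthant_rank2(mean: np.ndarray, L: np.ndarray) -> float:
    """Exact-to-quadrature polytope probability for a rank-2 support."""
    a, b = L[:, 0], L[:, 1]

    def slice_prob(w1: float) -> float:
        lo, hi = -np.inf, np.inf
        for ai, bi, mi in zip(a, b, mean):
            c = -(mi + ai * w1)
            if abs(bi) <= 1e-12:
                if c < 0:
                    return 0.0
            elif bi > 0:
                hi = min(hi, c / bi)
            else:
                lo = max(lo, c / bi)
        if hi <= lo:
            return 0.0
        return norm.cdf(hi) - norm.cdf(lo)

    val, _ = quad(
        lambda w1: norm.pdf(w1) * slice_prob(w1), -9.0, 9.0, epsabs=1e-9, limit=200
    )
    return float(np.clip(val, 0.0, 1.0))


def _orthant_qmc(mean: np.ndarray, L: np.ndarray, rank: int) -> float:
    sob = qmc.Sobol(rank, scramble=True, seed=_MVN_SEED)
    total = 0.0
    n = 0
    for _ in range(8):
        u = sob.random(2**17)
        w = norm.ppf(np.clip(u, 1e-15, 1 - 1e-15))
        x = mean + w @ L.T
        total += float((x <= 0.0).all(axis=1).sum())
        n += u.shape[0]
    return total / n


# ---------------------------------------------------------------------------
# equicorrelated argmax probabilities (exact 1-d reduction)
# ---------------------------------------------------------------------------

def _argmax_prob(index: int, means: np.ndarray) -> float:
    """P(T_index = max_j T_j) for unit-variance T with correlation 1/2.

    Writing T_j = (V_j + V_0)/sqrt(2) + m_j with i.i.d. standard normal V,
    the event reduces to V_j <= V_i + sqrt(2)(m_i - m_j) for all j, giving a
    one-dimensional integral of a product of normal CDFs.
    """
    means = np.asarray(means, dtype=float)
    k = means.size
    if k == 1:
        return 1.0
    shifts = np.sqrt(2.0) * (means[index] - np.delete(means, index))
    integrand = _PHI * np.prod(ndtr(_GRID[:, None] + shifts[None, :]), axis=1)
    return float(simpson(integrand, x=_GRID))


def _argmax_prob_batch(index: np.ndarray, means: np.ndarray) -> np.ndarray:
    """Vectorized :func:`_argmax_prob` over a batch of mean vectors."""
    B, k = means.shape
    if k == 1:
        return np.ones(B)
    own = means[np.arange(B), index]
    shifts = np.sqrt(2.0) * (own[:, None] - means)
    cdfs = ndtr(_GRID[None, :, None] + shifts[:, None, :])  # (B, G, k)
    cdfs[np.arange(B)[:, None], :, index[:, None]] = 1.0
    integrand = _PHI[None, :] * np.prod(cdfs, axis=2)
    return simpson(integrand, x=_GRID, axis=1)


# ---------------------------------------------------------------------------
# marginal selection probabilities
# ---------------------------------------------------------------------------

def _check_arm(i: int, k: int) -> None:
    if not 1 <= i <= k:
        raise ValueError(f"arm index {i} out of range 1..{k}")


def friede_selection_prob(
    i: int, mu_b, sigma0: float, N1: int
) -> float:
    """Probability that the early-endpoint rule selects arm ``i``.

    ``mu_b`` holds the k+1 early-endpoint group means (control first).  The
    result depends only on the early-endpoint model -- not on the final
    endpoint or the within-patient correlation.
    """
    mu_b = np.asarray(mu_b, dtype=float)
    k = mu_b.size - 1
    _check_arm(i, k)
    if not sigma0 > 0:
        raise ValueError("sigma0 must be positive")
    if N1 < 1:
        raise ValueError("N1 must be >= 1")
    means = (mu_b[1:] - mu_b[0]) * np.sqrt(N1 / 2.0) / sigma0
    return _argmax_prob(i - 1, means)


def stallard_selection_prob(
    i: int, model: EndpointModel, n1: int, N1: int
) -> float:
    """Probability that the score-statistic rule selects arm ``i``.

    Depends on rho_w only through rho_w**2 (via the effective information),
    hence is invariant to the sign of the within-patient correlation.
    """
    _check_arm(i, model.k)
    rho = float(np.clip(model.rho_w, -0.999999, 0.999999)) if n1 < N1 else model.rho_w
    info = score_information(n1, N1, model.sigma, rho)
    means = model.theta * np.sqrt(info)
    return _argmax_prob(i - 1, means)


# ---------------------------------------------------------------------------
# joint (both-rules) selection probabilities
# ---------------------------------------------------------------------------

def _joint_difference_law(
    i: int, model: EndpointModel, design: TrialDesign
) -> tuple[np.ndarray, np.ndarray]:
    """Mean and covariance of the 2(k-1) differences (early block, score block)."""
    k = model.k
    n1, N1 = design.n1, design.N1
    rho = model.rho_w
    rho_eff = rho if n1 == N1 else float(np.clip(rho, -1.0, 1.0))
    info = score_information(n1, N1, model.sigma, np.clip(rho_eff, -0.999999999, 0.999999999))
    others = [j for j in range(1, k + 1) if j != i]
    mF = np.array(
        [(model.mu_b[j] - model.mu_b[i]) * np.sqrt(N1 / 2.0) / model.sigma0 for j in others]
    )
    mS = np.array([(model.mu_B[j] - model.mu_B[i]) * np.sqrt(info) for j in others])
    gamma = rho * model.sigma * np.sqrt(info / (2.0 * N1))
    m = k - 1
    block = np.full((m, m), 0.5) + 0.5 * np.eye(m)
    cross = gamma * (np.ones((m, m)) + np.eye(m))
    cov = np.block([[block, cross], [cross.T, block]])
    return np.concatenate([mF, mS]), cov


def joint_selection_prob(
    i: int, model: EndpointModel, design: TrialDesign
) -> JointSelectionTable:
    """Full 2x2 table of which rules select arm ``i``, with exact marginals.

    ``p_both`` integrates the joint 2(k-1)-dimensional normal law of the
    early-endpoint and score differences; the off-diagonal cells follow from
    the analytic marginals.  At |rho_w| = 1 the joint covariance is singular
    and the orthant probability is computed on the supported subspace.
    """
    _check_arm(i, model.k)
    if model.k == 1:
        return JointSelectionTable(arm=1, p_both=1.0, p_stallard_only=0.0, p_friede_only=0.0, p_neither=0.0)
    pF = friede_selection_prob(i, model.mu_b, model.sigma0, design.N1)
    pS = stallard_selection_prob(i, model, design.n1, design.N1)
    mean, cov = _joint_difference_law(i, model, design)
    p_both = mvn_orthant(mean, cov)
    p_both = float(np.clip(p_both, 0.0, min(pF, pS)))
    p_s_only = max(pS - p_both, 0.0)
    p_f_only = max(pF - p_both, 0.0)
    p_neither = max(1.0 - p_both - p_s_only - p_f_only, 0.0)
    return JointSelectionTable(
        arm=i,
        p_both=p_both,
        p_stallard_only=p_s_only,
        p_friede_only=p_f_only,
        p_neither=p_neither,
    )
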