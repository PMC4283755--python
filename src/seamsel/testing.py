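"""Confirmatory analysis: Dunnett subset tests, combination test, closure.

Strong familywise-error control at one-sided level alpha follows the closed
testing principle: every intersection hypothesis H_S, S a nonempty subset of
{1..k}, is tested by combining a stage-1 Dunnett p-value (many-to-one
maximum statistic over S, correlation 1/2) with a stage-2 p-value through the
weighted inverse-normal combination

    C(p1, p2) = 1 - Phi(w1 * Phi^-1(1 - p1) + w2 * Phi^-1(1 - p2)).

The stage-2 p-value for H_S is the selected arm's p-value when the selected
arm belongs to S and 1 otherwise (the conservative policy of Posch et al.),
which keeps the procedure valid for any selection rule based on stage-1
data.  An elementary hypothesis H_0i is rejected iff C(p1(S), p2(S)) <= alpha
for every S containing i.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.integrate import simpson
from scipy.special import ndtr
from scipy.stats import norm

from .trial_model import TrialDesign, validate_design

__all__ = [
    "ClosedTestResult",
    "dunnett_pvalue",
    "combine_pvalues",
    "stage2_pvalue_policy",
    "closed_test",
]

_MAX_K = 20  # combinatorial guard for exhaustive subset enumeration

_GRID = np.linspace(-9.0, 9.0, 401)
_PHI = norm.pdf(_GRID)


@dataclass(frozen=True)
class ClosedTestResult:
    """Per-subset p-values and the closure rejection decisions of one trial."""

    subsets: tuple[tuple[int, ...], ...]
    p1: np.ndarray
    p2: np.ndarray
    combined: np.ndarray
    rejected: np.ndarray  # boolean, length k, elementary hypotheses
    selected: int
    alpha: float

    def subset_table(self) -> list[dict]:
        return [
            {"subset": s, "p1": float(a), "p2": float(b), "combined": float(c)}
            for s, a, b, c in zip(self.subsets, self.p1, self.p2, self.combined)
        ]


def dunnett_pvalue(z_obs: float, m: int) -> float:
    """One-sided p-value of the many-to-one maximum statistic.

    ``1 - P(max of m unit-variance, equicorrelated (rho = 1/2) standard
    normals <= z_obs)``.  Writing each statistic as (V_i + V_0)/sqrt(2) the
    probability reduces to a one-dimensional integral of Phi(v + sqrt(2) z)^m,
    evaluated by fixed high-resolution quadrature.
    """
    p = _dunnett_pvalue_batch(np.asarray([z_obs], dtype=float), m)
    return float(p[0])


def _dunnett_pvalue_batch(z_obs: np.ndarray, m: int) -> np.ndarray:
    if m < 1:
        raise ValueError("subset size m must be >= 1")
    z_obs = np.asarray(z_obs, dtype=float)
    if m == 1:
        return norm.sf(z_obs)
    out = np.empty(z_obs.shape)
    lo = np.isneginf(z_obs)
    hi = np.isposinf(z_obs)
    out[lo] = 1.0
    out[hi] = 0.0
    fin = ~(lo | hi)
    if fin.any():
        zf = z_obs[fin]
        integrand = _PHI[None, :] * ndtr(_GRID[None, :] + np.sqrt(2.0) * zf[:, None]) ** m
        out[fin] = np.clip(1.0 - simpson(integrand, x=_GRID, axis=1), 0.0, 1.0)
    return out


def combine_pvalues(p1: float, p2: float, w1: float, w2: float) -> float:
    """Weighted inverse-normal combination of two stagewise p-values."""
    if abs(w1**2 + w2**2 - 1.0) > 1e-9 or w1 < 0 or w2 < 0:
        raise ValueError("weights not normalized")
    for p in (p1, p2):
        if not 0.0 < p <= 1.0:
            raise ValueError("p-values must lie in (0, 1]")
    return float(_combine_batch(np.asarray([p1]), np.asarray([p2]), w1, w2)[0])


def _combine_batch(p1: np.ndarray, p2: np.ndarray, w1: float, w2: float) -> np.ndarray:
    # Phi^-1(1 - 1) = -inf; a zero weight must kill that term rather than
    # produce 0 * inf = nan
    t1 = norm.isf(p1)
    t2 = norm.isf(p2)
    z = np.where(w1 == 0.0, 0.0, w1 * t1) + np.where(w2 == 0.0, 0.0, w2 * t2)
    return norm.sf(z)


def stage2_pvalue_policy(S, I: int, p_I: float) -> float:
    """Conservative stage-2 p-value for H_S: p_I if the selected arm is in S, else 1."""
    if not 0.0 < p_I <= 1.0:
        raise ValueError("p_I must lie in (0, 1]")
    return p_I if I in set(S) else 1.0


def closed_test(
    z1_final, I: int, z2: float, design: TrialDesign
) -> ClosedTestResult:
    """Run the full closed testing procedure for one trial.

    ``z1_final`` are the stage-1 final-endpoint statistics on all N1 patients
    per group (computed at the end of follow-up), ``z2`` the stage-2
    statistic of the selected arm ``I``.
    """
    validate_design(design)
    z1_final = np.asarray(z1_final, dtype=float)
    k = z1_final.size
    if k != design.k:
        raise ValueError("z1_final length must equal design.k")
    if k > _MAX_K:
        raise ValueError(f"k = {k} refused: exhaustive closure over 2^k subsets")
    if not 1 <= I <= k:
        raise ValueError("selected arm out of range")
    p_I = float(norm.sf(z2))
    subsets: list[tuple[int, ...]] = []
    p1s, p2s, combs = [], [], []
    for size in range(1, k + 1):
        for S in combinations(range(1, k + 1), size):
            zmax = float(np.max(z1_final[[i - 1 for i in S]]))
            p1 = dunnett_pvalue(zmax, size)
            p2 = stage2_pvalue_policy(S, I, max(p_I, np.finfo(float).tiny))
            c = float(_combine_batch(np.asarray([p1]), np.asarray([p2]), design.w1, design.w2)[0])
            subsets.append(S)
            p1s.append(p1)
            p2s.append(p2)
            combs.append(c)
    p1a, p2a, ca = map(np.asarray, (p1s, p2s, combs))
    rejected = np.ones(k, dtype=bool)
    for S, c in zip(subsets, ca):
        if c > design.alpha:
            for i in S:
                rejected[i - 1] = False
    return ClosedTestResult(
        subsets=tuple(subsets),
        p1=p1a,
        p2=p2a,
        combined=ca,
        rejected=rejected,
        selected=I,
        alpha=design.alpha,
    )
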