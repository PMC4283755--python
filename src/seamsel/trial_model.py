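"""Domain types for a two-stage seamless phase II/III trial with an early endpoint.

The trial compares ``k`` experimental treatments ``T_1..T_k`` against a common
control ``T_0``.  Each patient contributes an early (surrogate) outcome ``X``
and, after longer follow-up, a final (primary) outcome ``Y``; the pair is
bivariate normal with means ``(mu_b[i], mu_B[i])`` in arm ``i``, standard
deviations ``(sigma0, sigma)`` common to all arms, and within-patient
correlation ``rho_w``.  At the interim analysis early data are available on
``N1`` patients per arm, final data on a subset of ``n1`` of them; ``n2``
patients per group are newly recruited into stage two on the selected arm and
the control.

Arm index 0 is always the control; larger endpoint values encode benefit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "EndpointModel",
    "TrialDesign",
    "Stage1Data",
    "Stage1FinalData",
    "Stage2Data",
    "validate_design",
    "default_weights",
]


@dataclass(frozen=True)
class EndpointModel:
    """Bivariate-normal early/final endpoint model shared by all arms.

    Parameters
    ----------
    mu_b : array-like, shape (k+1,)
        Early-endpoint group means, index 0 = control.
    mu_B : array-like, shape (k+1,)
        Final-endpoint group means, same indexing.
    sigma0 : float
        Early-endpoint standard deviation (> 0).
    sigma : float
        Final-endpoint standard deviation (> 0).
    rho_w : float
        Within-patient correlation between the two endpoints, in [-1, 1].
    """

    mu_b: np.ndarray
    mu_B: np.ndarray
    sigma0: float
    sigma: float
    rho_w: float

    def __post_init__(self) -> None:
        mu_b = np.atleast_1d(np.asarray(self.mu_b, dtype=float))
        mu_B = np.atleast_1d(np.asarray(self.mu_B, dtype=float))
        object.__setattr__(self, "mu_b", mu_b)
        object.__setattr__(self, "mu_B", mu_B)
        if mu_b.ndim != 1 or mu_B.ndim != 1:
            raise ValueError("mu_b and mu_B must be one-dimensional")
        if mu_b.shape != mu_B.shape:
            raise ValueError("mu_b and mu_B must have the same length k+1")
        if mu_b.size < 2:
            raise ValueError("need at least one experimental arm (k >= 1)")
        if not (np.isfinite(mu_b).all() and np.isfinite(mu_B).all()):
            raise ValueError("group means must be finite")
        if not self.sigma0 > 0:
            raise ValueError("sigma0 must be positive")
        if not self.sigma > 0:
            raise ValueError("sigma must be positive")
        if not -1.0 <= self.rho_w <= 1.0:
            raise ValueError("rho_w must lie in [-1, 1]")

    @property
    def k(self) -> int:
        """Number of experimental arms."""
        return self.mu_b.size - 1

    @property
    def theta(self) -> np.ndarray:
        """Final-endpoint treatment effects ``mu_B[i] - mu_B[0]``, i = 1..k."""
        return self.mu_B[1:] - self.mu_B[0]

    @property
    def delta(self) -> np.ndarray:
        """Early-endpoint treatment effects ``mu_b[i] - mu_b[0]``, i = 1..k."""
        return self.mu_b[1:] - self.mu_b[0]


@dataclass(frozen=True)
class TrialDesign:
    """Stagewise sample sizes, significance level and combination weights.

    ``w1, w2`` are the weights of the inverse-normal combination test; by
    default their squares are proportional to the planned per-group sample
    sizes of the two stages (``N1`` and ``n2``), the standard convention that
    guarantees ``w1**2 + w2**2 == 1``.
    """

    k: int
    N1: int
    n1: int
    n2: int
    alpha: float = 0.025
    w1: float = field(default=math.nan)
    w2: float = field(default=math.nan)

    def __post_init__(self) -> None:
        if math.isnan(self.w1) != math.isnan(self.w2):
            raise ValueError("supply both weights or neither")
        if math.isnan(self.w1):
            w1, w2 = default_weights(self.N1, self.n2)
            object.__setattr__(self, "w1", w1)
            object.__setattr__(self, "w2", w2)
        validate_design(self)


@dataclass(frozen=True)
class Stage1Data:
    """Interim stage-1 data: per arm, N1 early values and n1 paired final values.

    ``early`` has shape (k+1, N1) and ``final`` shape (k+1, n1); the final
    values are paired with the first n1 early values of the same arm.
    """

    early: np.ndarray
    final: np.ndarray

    def __post_init__(self) -> None:
        early = np.asarray(self.early, dtype=float)
        final = np.asarray(self.final, dtype=float)
        object.__setattr__(self, "early", early)
        object.__setattr__(self, "final", final)
        if early.ndim != 2 or final.ndim != 2:
            raise ValueError("early and final must be 2-d (arm x patient)")
        if early.shape[0] != final.shape[0]:
            raise ValueError("early and final must cover the same arms")
        if final.shape[1] > early.shape[1]:
            raise ValueError("n1 exceeds N1")
        if not (np.isfinite(early).all() and np.isfinite(final).all()):
            raise ValueError("all observations must be finite")

    @property
    def k(self) -> int:
        return self.early.shape[0] - 1

    @property
    def N1(self) -> int:
        return self.early.shape[1]

    @property
    def n1(self) -> int:
        return self.final.shape[1]


@dataclass(frozen=True)
class Stage1FinalData:
    """Final-endpoint values of all N1 stage-1 patients, once follow-up is complete.

    ``final`` has shape (k+1, N1); its first n1 columns coincide with the
    interim :class:`Stage1Data.final` of the same trial.
    """

    final: np.ndarray

    def __post_init__(self) -> None:
        final = np.asarray(self.final, dtype=float)
        object.__setattr__(self, "final", final)
        if final.ndim != 2:
            raise ValueError("final must be 2-d (arm x patient)")
        if not np.isfinite(final).all():
            raise ValueError("all observations must be finite")

    @property
    def k(self) -> int:
        return self.final.shape[0] - 1

    @property
    def N1(self) -> int:
        return self.final.shape[1]


@dataclass(frozen=True)
class Stage2Data:
    """Stage-2 final-endpoint data on the selected arm and the control."""

    selected: int
    control: np.ndarray
    treatment: np.ndarray

    def __post_init__(self) -> None:
        control = np.asarray(self.control, dtype=float)
        treatment = np.asarray(self.treatment, dtype=float)
        object.__setattr__(self, "control", control)
        object.__setattr__(self, "treatment", treatment)
        if self.selected < 1:
            raise ValueError("selected arm index must be >= 1")
        if control.ndim != 1 or treatment.ndim != 1:
            raise ValueError("stage-2 groups must be 1-d vectors")
        if control.size != treatment.size:
            raise ValueError("stage-2 groups must have equal size n2")
        if not (np.isfinite(control).all() and np.isfinite(treatment).all()):
            raise ValueError("all observations must be finite")

    @property
    def n2(self) -> int:
        return self.control.size


def validate_design(design: TrialDesign) -> TrialDesign:
    """Check all design invariants, returning the design unchanged if valid."""
    if design.k < 1:
        raise ValueError("k must be >= 1")
    if design.n1 < 1:
        raise ValueError("n1 must be >= 1")
    if design.n1 > design.N1:
        raise ValueError("n1 exceeds N1")
    if design.n2 < 1:
        raise ValueError("n2 must be >= 1")
    if not 0.0 < design.alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if design.w1 < 0 or design.w2 < 0:
        raise ValueError("weights must be nonnegative")
    if abs(design.w1**2 + design.w2**2 - 1.0) > 1e-9:
        raise ValueError("weights not normalized: w1**2 + w2**2 must equal 1")
    return design


def default_weights(stage1_n: int, stage2_n: int) -> tuple[float, float]:
    """Combination weights with squares proportional to stagewise sample sizes."""
    if stage1_n < 1 or stage2_n < 1:
        raise ValueError("stage sample sizes must be >= 1")
    total = stage1_n + stage2_n
    return math.sqrt(stage1_n / total), math.sqrt(stage2_n / total)


def with_selected_weights(design: TrialDesign, w1: float, w2: float) -> TrialDesign:
    """Return a copy of ``design`` with user-chosen combination weights."""
    return replace(design, w1=w1, w2=w2)
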