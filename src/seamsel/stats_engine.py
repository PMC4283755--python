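"""Test and score statistics, and interim parameter estimation.

All standardized statistics share the many-to-one structure of a comparison
against a common control: for each experimental arm ``i`` the statistic has
unit variance and the pairwise correlation between arms is 1/2.

* ``early_z`` -- standardized early-endpoint statistics on N1 patients per
  group (the interim selection statistic of the early-endpoint-only rule).
* ``final_z_stage1`` / ``final_z_stage2`` -- standardized final-endpoint
  statistics for the two stages of the confirmatory analysis; stage one uses
  all N1 stage-1 patients (whose follow-up is complete by the final
  analysis), stage two only the n2 newly recruited patients, which makes the
  two stages independent.
* ``score_statistics_known`` -- the interim score statistic S_i for the
  final-endpoint effect that augments the n1 observed final outcomes with the
  N1 early outcomes.  With known parameters it is the standardized
  covariate-adjusted mean difference

      theta_hat_i = (Ybar_i - Ybar_0)
                    + (rho_w sigma / sigma0) * [(Xbar_i - xbar_i) - (Xbar_0 - xbar_0)]

  where ``Ybar``/``xbar`` are means over the n1 paired patients and ``Xbar``
  over all N1 early values, and S_i = theta_hat_i * sqrt(I) with effective
  information per comparison

      I = n1 / (2 sigma**2 (1 - rho_w**2 (1 - n1/N1))).

  I reduces to the n1-patient final-only information at rho_w = 0, to the
  N1-patient information at n1 = N1, and grows with |rho_w| and N1.
* ``score_statistics_estimated`` -- the double-regression plug-in version for
  unknown variances/correlation: a pooled within-arm regression of final on
  early endpoint supplies the adjustment slope, and pooled variance
  estimates are substituted into the known-parameter formula.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trial_model import EndpointModel, Stage1Data, Stage1FinalData, Stage2Data

__all__ = [
    "StatisticsBundle",
    "EstimatedModel",
    "early_z",
    "final_z_stage1",
    "final_z_stage2",
    "score_information",
    "score_statistics_known",
    "score_statistics_estimated",
    "estimate_model",
]

RHO_CLIP = 0.99  # keeps the plug-in information finite at degenerate correlation


@dataclass(frozen=True)
class StatisticsBundle:
    """All interim statistics of one trial: early z, stage-1 final z, scores."""

    z_early: np.ndarray
    z1_final: np.ndarray
    score: np.ndarray
    info: float

    def __post_init__(self) -> None:
        if not (len(self.z_early) == len(self.z1_final) == len(self.score)):
            raise ValueError("statistic vectors must all have length k")
        if not self.info > 0:
            raise ValueError("information must be positive")


class EstimatedModel(EndpointModel):
    """An :class:`EndpointModel` whose fields are interim estimates."""


# ---------------------------------------------------------------------------
# standardized z statistics
# ---------------------------------------------------------------------------

def _z_from_values(values: np.ndarray, sd: float) -> np.ndarray:
    """Standardized many-to-one mean differences from (..., k+1, n) values."""
    values = np.asarray(values, dtype=float)
    if values.shape[-1] == 0:
        raise ValueError("empty data")
    if not sd > 0:
        raise ValueError("standard deviation must be positive")
    n = values.shape[-1]
    means = values.mean(axis=-1)
    return (means[..., 1:] - means[..., :1]) * np.sqrt(n / 2.0) / sd


def early_z(stage1: Stage1Data, sigma0: float) -> np.ndarray:
    """Early-endpoint statistics Z~_i on the N1 stage-1 patients per group.

    Z~_i has mean ``delta_i * sqrt(N1/2) / sigma0``, unit variance and
    pairwise correlation 1/2 across arms.
    """
    return _z_from_values(stage1.early, sigma0)


def final_z_stage1(stage1_final: Stage1FinalData, sigma: float) -> np.ndarray:
    """Stage-1 final-endpoint statistics Z_{i,1} on all N1 patients per group."""
    return _z_from_values(stage1_final.final, sigma)


def final_z_stage2(stage2: Stage2Data, sigma: float) -> float:
    """Stage-2 statistic Z_{I,2} for the selected arm on n2 patients per group."""
    if stage2.n2 == 0:
        raise ValueError("empty data")
    if not sigma > 0:
        raise ValueError("standard deviation must be positive")
    diff = stage2.treatment.mean() - stage2.control.mean()
    return float(diff * np.sqrt(stage2.n2 / 2.0) / sigma)


# ---------------------------------------------------------------------------
# score statistics
# ---------------------------------------------------------------------------

def score_information(n1: int, N1: int, sigma: float, rho_w: float) -> float:
    """Effective information per treatment-control comparison of the score statistic."""
    if not 1 <= n1 <= N1:
        raise ValueError("need 1 <= n1 <= N1")
    if not sigma > 0:
        raise ValueError("sigma must be positive")
    frac = 1.0 - rho_w**2 * (1.0 - n1 / N1)
    if frac <= 0:
        raise ValueError("degenerate information: |rho_w| = 1 with n1 < N1")
    return n1 / (2.0 * sigma**2 * frac)


def _scores_from_arrays(
    early: np.ndarray,
    final: np.ndarray,
    sigma0,
    sigma,
    rho_w,
) -> tuple[np.ndarray, np.ndarray]:
    """Score statistics; parameters may be scalars or batch arrays."""
    n1 = final.shape[-1]
    N1 = early.shape[-1]
    sigma0 = np.asarray(sigma0, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    rho_w = np.asarray(rho_w, dtype=float)
    if n1 == N1:
        rho_eff = rho_w  # adjustment term vanishes; any rho_w gives the same S
    else:
        rho_eff = np.clip(rho_w, -RHO_CLIP, RHO_CLIP)
    frac = 1.0 - rho_eff**2 * (1.0 - n1 / N1)
    info = n1 / (2.0 * sigma**2 * frac)
    ybar = final.mean(axis=-1)
    xbar_all = early.mean(axis=-1)
    xbar_paired = early[..., :n1].mean(axis=-1)
    c = rho_eff * sigma / sigma0
    adj = ybar + c[..., None] * (xbar_all - xbar_paired)
    theta_hat = adj[..., 1:] - adj[..., :1]
    return theta_hat * np.sqrt(info)[..., None], info


def score_statistics_known(
    stage1: Stage1Data, model: EndpointModel
) -> tuple[np.ndarray, float]:
    """Score statistics S_i with known sigma0, sigma and rho_w.

    Returns the length-k vector of standardized scores and the effective
    information I; E[S_i] = theta_i * sqrt(I), Var(S_i) = 1,
    Corr(S_i, S_j) = 1/2.
    """
    if stage1.n1 < 1:
        raise ValueError("need at least one paired observation per arm")
    scores, info = _scores_from_arrays(
        stage1.early, stage1.final, model.sigma0, model.sigma, model.rho_w
    )
    return scores, float(info)


def _double_regression(
    early: np.ndarray, final: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Pooled within-arm slope, residual SD, early SD and implied correlation.

    Works on batched arrays (..., k+1, n); returns batch-shaped estimates
    (slope b, sigma_hat, sigma0_hat, rho_hat with rho clipped).
    """
    n1 = final.shape[-1]
    N1 = early.shape[-1]
    n_arms = final.shape[-2]
    if n1 < 3:
        raise ValueError("double regression needs n1 >= 3 per arm")
    x = early[..., :n1]
    xc = x - x.mean(axis=-1, keepdims=True)
    yc = final - final.mean(axis=-1, keepdims=True)
    sxx = np.sum(xc * xc, axis=(-2, -1))
    sxy = np.sum(xc * yc, axis=(-2, -1))
    syy = np.sum(yc * yc, axis=(-2, -1))
    if np.any(sxx <= 0):
        raise ValueError("singular regression: zero early-endpoint variance among paired patients")
    b = sxy / sxx
    df_res = n_arms * (n1 - 1) - 1
    rss = np.maximum(syy - b * sxy, 0.0)
    s_e2 = rss / df_res
    ec = early - early.mean(axis=-1, keepdims=True)
    s0_2 = np.sum(ec * ec, axis=(-2, -1)) / (n_arms * (N1 - 1))
    if np.any(s0_2 <= 0):
        raise ValueError("zero variance in early-endpoint data")
    sigma2_hat = s_e2 + b * b * s0_2
    if np.any(sigma2_hat <= 0):
        raise ValueError("zero variance in final-endpoint data")
    sigma_hat = np.sqrt(sigma2_hat)
    sigma0_hat = np.sqrt(s0_2)
    rho_hat = np.clip(b * sigma0_hat / sigma_hat, -RHO_CLIP, RHO_CLIP)
    return b, sigma_hat, sigma0_hat, rho_hat


def score_statistics_estimated(stage1: Stage1Data) -> tuple[np.ndarray, float]:
    """Double-regression plug-in score statistics for unknown parameters.

    The final endpoint is regressed on the early endpoint within arms with a
    common slope; the slope, pooled residual variance and pooled
    early-endpoint variance are substituted into the known-parameter score
    formula.  The implied correlation estimate is clipped to +/-0.99 so the
    plug-in information stays finite.
    """
    _, sigma_hat, sigma0_hat, rho_hat = _double_regression(stage1.early, stage1.final)
    scores, info = _scores_from_arrays(
        stage1.early, stage1.final, float(sigma0_hat), float(sigma_hat), float(rho_hat)
    )
    return scores, float(info)


def estimate_model(stage1: Stage1Data) -> EstimatedModel:
    """Interim moment estimates of all endpoint-model parameters.

    Early-endpoint means use all N1 values per arm, final-endpoint means the
    n1 paired values; SDs pool within-arm variation across all arms; the
    correlation pools within-arm cross-products of the n1 pairs and is
    clipped to +/-0.99.
    """
    if stage1.n1 < 3:
        raise ValueError("parameter estimation needs n1 >= 3 per arm")
    early, final = stage1.early, stage1.final
    n_arms, N1 = early.shape
    n1 = final.shape[1]
    mu_b_hat = early.mean(axis=1)
    mu_B_hat = final.mean(axis=1)
    ec = early - mu_b_hat[:, None]
    s0_2 = np.sum(ec * ec) / (n_arms * (N1 - 1))
    x = early[:, :n1]
    xc = x - x.mean(axis=1, keepdims=True)
    yc = final - mu_B_hat[:, None]
    syy = np.sum(yc * yc)
    sxx = np.sum(xc * xc)
    sxy = np.sum(xc * yc)
    s2 = syy / (n_arms * (n1 - 1))
    if s0_2 <= 0 or s2 <= 0 or sxx <= 0:
        raise ValueError("zero variance in stage-1 data")
    rho_hat = float(np.clip(sxy / np.sqrt(sxx * syy), -RHO_CLIP, RHO_CLIP))
    return EstimatedModel(
        mu_b=mu_b_hat,
        mu_B=mu_B_hat,
        sigma0=float(np.sqrt(s0_2)),
        sigma=float(np.sqrt(s2)),
        rho_w=rho_hat,
    )


def statistics_bundle(
    stage1: Stage1Data,
    stage1_final: Stage1FinalData | None,
    model: EndpointModel,
) -> StatisticsBundle:
    """Convenience constructor computing all interim statistics at once."""
    z_early = early_z(stage1, model.sigma0)
    if stage1_final is not None:
        z1 = final_z_stage1(stage1_final, model.sigma)
    else:
        z1 = np.full(stage1.k, np.nan)
    score, info = score_statistics_known(stage1, model)
    return StatisticsBundle(z_early=z_early, z1_final=z1, score=score, info=info)
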