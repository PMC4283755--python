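"""Synthetic-trial generator for the bivariate-normal endpoint model.

Every dataset analysed by this package comes from here (or from external data
in the same tidy CSV shape).  Patients are i.i.d. within arm and arms are
mutually independent.  Reproducibility follows numpy's ``SeedSequence``
spawning: the pair ``(seed, replicate)`` plus a small stream id is hashed into
an independent Philox-quality substream, so identical seeds give bit-identical
data and distinct replicate ids give independent trials.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trial_model import (
    EndpointModel,
    Stage1Data,
    Stage1FinalData,
    Stage2Data,
    TrialDesign,
    validate_design,
)

__all__ = [
    "SimSeed",
    "simulate_stage1",
    "simulate_stage2",
    "stage1_to_frame",
    "stage1_from_frame",
]

_STAGE1_STREAM = 0
_STAGE2_STREAM_BASE = 1


@dataclass(frozen=True)
class SimSeed:
    """Master seed plus per-trial replicate id.

    The generator for stream ``s`` of replicate ``r`` is
    ``default_rng(SeedSequence(seed, spawn_key=(r, s)))``; stream 0 is
    stage one, stream ``1 + selected`` is stage two for a given selected arm
    (so two rules selecting the same arm see the same stage-2 data).
    """

    seed: int
    replicate: int = 0

    def rng(self, stream: int = 0) -> np.random.Generator:
        ss = np.random.SeedSequence(self.seed, spawn_key=(self.replicate, stream))
        return np.random.default_rng(ss)


def _bivariate_pairs(
    model: EndpointModel, n_arms: int, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (n_arms, n) early/final pairs from the endpoint model."""
    zx = rng.standard_normal((n_arms, n))
    zy = rng.standard_normal((n_arms, n))
    rho = model.rho_w
    x = model.mu_b[:, None] + model.sigma0 * zx
    y = model.mu_B[:, None] + model.sigma * (rho * zx + np.sqrt(1.0 - rho**2) * zy)
    return x, y


def simulate_stage1(
    model: EndpointModel, design: TrialDesign, seed: SimSeed
) -> tuple[Stage1Data, Stage1FinalData]:
    """Simulate stage one of a trial.

    Returns the interim view (all N1 early values, first n1 final values per
    arm) together with the end-of-follow-up view holding all N1 final values.
    """
    validate_design(design)
    if model.k != design.k:
        raise ValueError("model and design disagree on the number of arms")
    rng = seed.rng(_STAGE1_STREAM)
    x, y = _bivariate_pairs(model, design.k + 1, design.N1, rng)
    return Stage1Data(early=x, final=y[:, : design.n1]), Stage1FinalData(final=y)


def simulate_stage2(
    model: EndpointModel, design: TrialDesign, selected: int, seed: SimSeed
) -> Stage2Data:
    """Simulate the n2 newly recruited stage-2 patients per group.

    Stage-2 data are independent of stage one; the stream is keyed by the
    selected arm, so the control/selected-arm data are shared between rules
    that select the same arm and independent otherwise.
    """
    validate_design(design)
    if not 1 <= selected <= design.k:
        raise ValueError(f"selected arm {selected} out of range 1..{design.k}")
    rng = seed.rng(_STAGE2_STREAM_BASE + selected)
    z = rng.standard_normal((2, design.n2))
    control = model.mu_B[0] + model.sigma * z[0]
    treatment = model.mu_B[selected] + model.sigma * z[1]
    return Stage2Data(selected=selected, control=control, treatment=treatment)


def stage1_to_frame(
    stage1: Stage1Data, stage1_final: Stage1FinalData | None = None
) -> pd.DataFrame:
    """Export stage-1 data as tidy rows: arm, patient, early_value, final_value.

    ``final_value`` is NaN for patients whose final endpoint is unobserved at
    interim; pass ``stage1_final`` to export the completed follow-up instead.
    """
    n_arms, N1 = stage1.early.shape
    final = np.full((n_arms, N1), np.nan)
    if stage1_final is not None:
        if stage1_final.final.shape != stage1.early.shape:
            raise ValueError("stage1_final shape does not match stage1")
        final[:] = stage1_final.final
    else:
        final[:, : stage1.n1] = stage1.final
    return pd.DataFrame(
        {
            "arm": np.repeat(np.arange(n_arms), N1),
            "patient": np.tile(np.arange(N1), n_arms),
            "early_value": stage1.early.ravel(),
            "final_value": final.ravel(),
        }
    )


def stage1_from_frame(frame: pd.DataFrame) -> Stage1Data:
    """Rebuild :class:`Stage1Data` from the tidy CSV layout.

    Requires every arm to have the same number of early values and the same
    leading block of observed final values.
    """
    required = {"arm", "patient", "early_value", "final_value"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    frame = frame.sort_values(["arm", "patient"])
    arms = frame["arm"].unique()
    if not np.array_equal(arms, np.arange(arms.size)):
        raise ValueError("arms must be labelled 0..k with 0 the control")
    early = []
    final = []
    for arm in arms:
        sub = frame[frame["arm"] == arm]
        early.append(sub["early_value"].to_numpy())
        observed = sub["final_value"].to_numpy()
        final.append(observed[~np.isnan(observed)])
    n1 = min(len(f) for f in final)
    if any(len(f) != n1 for f in final):
        raise ValueError("every arm must have the same number of observed final values")
    return Stage1Data(early=np.vstack(early), final=np.vstack([f[:n1] for f in final]))
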