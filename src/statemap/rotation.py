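"""Reference-direction (rotational offset) inference for circular cues.

Circular cue observations are only defined up to a common rotation of the
reference frame: two feature vectors describe the same cue arrangement if
one is a rotated copy of the other.  Before comparing a new observation to
a hidden state's history, the animal therefore picks the offset phi that
maximizes the posterior predictive of the rotated observation,

    phi* = argmax_phi  P(y_new - phi | Y_state),

with a single global phi shared by all circular dimensions.  The offset of
the winning state corresponds to the rotation of the place-field map; the
state evidence ratio is then computed with each state's own best offset.

Offsets are searched on a uniform grid (default 1 degree) and reported in
(-180, 180].  A novel (empty) state has no reference direction of its own;
its offset is fixed at 0, which is immaterial because the prior predictive
is nearly rotation-invariant under the default vague hyperparameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._angles import wrap_180
from .crp import Concentration, Partition, next_state_probabilities
from .inference import NOVEL, EvidenceResult
from .observation_models import VonMisesModel, _predictive_profile_1d
from .observations import ObservationSet

__all__ = ["OffsetResult", "best_offset", "rotation_assignment"]


@dataclass(frozen=True)
class OffsetResult:
    """Per-state best offsets and the evidence ratio computed at them."""

    per_state_offset: dict
    per_state_log_predictive: dict
    best_state: int | str
    evidence: EvidenceResult


def _offset_grid(step_deg: float) -> np.ndarray:
    """Uniform offsets covering (-180, 180], ascending."""
    n = int(round(360.0 / step_deg))
    if not np.isclose(n * step_deg, 360.0):
        raise ValueError("offset step must divide 360 degrees")
    return -180.0 + step_deg * np.arange(1, n + 1)


def best_offset(
    y_new,
    train: ObservationSet,
    model: VonMisesModel,
    step_deg: float = 1.0,
) -> tuple[float, float]:
    """Best global rotational offset for a probe against one state's history.

    Returns (offset in (-180, 180], joint log predictive at that offset).
    For an empty training set the offset is 0 and the prior predictive is
    returned.  Ties break toward the smallest offset on the grid.
    """
    y = np.atleast_1d(np.asarray(y_new, dtype=float))
    if not train.all_circular:
        raise ValueError("offset inference requires all-circular features")
    if y.size != train.n_features:
        raise ValueError(f"probe must be {train.n_features}-dimensional")
    if train.n_obs == 0:
        return 0.0, model.log_predictive(y, train)
    offsets = _offset_grid(step_deg)
    total = np.zeros(offsets.size)
    for d in range(train.n_features):
        # profile of log P(y_d - phi | train_d) over the ascending phi grid:
        # z_i = y_d - offsets[i] = (y_d - offsets[0]) - i * step
        total += _predictive_profile_1d(
            model.hyper,
            train.data[:, d],
            model.grid,
            z0_deg=float(y[d]) - float(offsets[0]),
            n_z=offsets.size,
            step_deg=step_deg,
        )
    i = int(np.argmax(total))
    return float(wrap_180(offsets[i])), float(total[i])


def rotation_assignment(
    y_new,
    obs: ObservationSet,
    partition: Partition,
    conc: Concentration,
    model: VonMisesModel,
    step_deg: float = 1.0,
) -> OffsetResult:
    """Offset-corrected state assignment of a circular probe.

    Each existing state is scored with its own best offset; the novel-state
    option uses the prior predictive at offset 0.  The returned evidence is
    the state evidence ratio between the best-scoring existing state and
    the novel state, both at their offsets.
    """
    if partition.num_obs != obs.n_obs:
        raise ValueError("partition must cover the observations")
    if partition.num_states < 1:
        raise ValueError("at least one trained state is required")
    offsets: dict = {}
    log_preds: dict = {}
    for k in range(partition.num_states):
        phi, lp = best_offset(y_new, obs.select(partition.members(k)), model, step_deg)
        offsets[k] = phi
        log_preds[k] = lp
    phi0, lp_novel = best_offset(y_new, ObservationSet.empty(obs.feature_kinds), model, step_deg)
    offsets[NOVEL] = phi0
    log_preds[NOVEL] = lp_novel

    crp = next_state_probabilities(partition, conc)
    with np.errstate(divide="ignore"):
        log_crp = np.log(crp)
    scores = {k: log_preds[k] + log_crp[k] for k in range(partition.num_states)}
    scores[NOVEL] = lp_novel + log_crp[-1]
    best_state = max(scores, key=lambda k: (scores[k], k != NOVEL))

    best_existing = max(range(partition.num_states), key=scores.__getitem__)
    evidence = EvidenceResult(
        scores[best_existing] - scores[NOVEL], f"state_{best_existing}", NOVEL
    )
    return OffsetResult(offsets, log_preds, best_state, evidence)
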