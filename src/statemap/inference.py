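"""Posterior scoring of partitions and state assignments; evidence ratios.

Two log-odds quantities map onto the degree of place-field remapping:

* the **partition evidence ratio** compares whole partitions of the
  observation history (e.g. "everything came from one hidden state" vs
  "the two session types came from two states"), and

* the **state evidence ratio** compares assignments of a single new
  observation (to an existing state or to a novel one), conditional on a
  hypothetical partition of the past.

Both are differences of unnormalized log posteriors, so any shared
normalizing constants cancel.  Values near 0 correspond to high state
uncertainty (partial remapping); strongly positive or negative values to
confident single-state or multi-state beliefs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
from scipy.special import logsumexp

from .crp import Concentration, Partition, next_state_probabilities, partition_log_prior
from .observations import ObservationSet

__all__ = [
    "NOVEL",
    "EvidenceResult",
    "Hypothesis",
    "partition_log_posterior",
    "partition_evidence_ratio",
    "assignment_posterior",
    "state_evidence_ratio",
    "hypothesis_set_log_odds",
]

NOVEL = "novel"
Assignment = Union[int, str]  # an existing state index or NOVEL


@dataclass(frozen=True)
class EvidenceResult:
    """Log odds between two named hypotheses (antisymmetric under swap)."""

    log_odds: float
    numerator: str
    denominator: str

    def swapped(self) -> "EvidenceResult":
        return EvidenceResult(-self.log_odds, self.denominator, self.numerator)


@dataclass(frozen=True)
class Hypothesis:
    """A partition of the training observations, optionally extended by a
    probe assignment (an existing state index of the partition, or NOVEL)."""

    name: str
    partition: Partition
    probe_assignment: Assignment | None = None


def _check_cover(obs: ObservationSet, partition: Partition) -> None:
    if partition.num_obs != obs.n_obs:
        raise ValueError(
            f"partition covers {partition.num_obs} observations but {obs.n_obs} were given"
        )


def partition_log_posterior(
    obs: ObservationSet, partition: Partition, conc: Concentration, model
) -> float:
    """Unnormalized log posterior of a partition: per-state marginal
    likelihoods plus the CRP log prior."""
    _check_cover(obs, partition)
    total = partition_log_prior(partition, conc)
    for k in range(partition.num_states):
        total += model.log_marginal(obs.select(partition.members(k)))
    return total


def partition_evidence_ratio(
    obs: ObservationSet,
    hyp_num: Hypothesis,
    hyp_den: Hypothesis,
    conc: Concentration,
    model,
) -> EvidenceResult:
    """Log odds between two partitions of the same observations."""
    if hyp_num.partition == hyp_den.partition:
        return EvidenceResult(0.0, hyp_num.name, hyp_den.name)
    num = partition_log_posterior(obs, hyp_num.partition, conc, model)
    den = partition_log_posterior(obs, hyp_den.partition, conc, model)
    return EvidenceResult(num - den, hyp_num.name, hyp_den.name)


def _assignment_log_terms(
    y_new, obs: ObservationSet, partition: Partition, conc: Concentration, model
) -> np.ndarray:
    """Unnormalized log posterior of assigning y_new to each of the K
    existing states or (last entry) a novel state."""
    _check_cover(obs, partition)
    crp = next_state_probabilities(partition, conc)
    k = partition.num_states
    terms = np.empty(k + 1)
    for state in range(k):
        terms[state] = model.log_predictive(y_new, obs.select(partition.members(state)))
    terms[k] = model.log_predictive(y_new, ObservationSet.empty(obs.feature_kinds))
    with np.errstate(divide="ignore"):
        return terms + np.log(crp)


def assignment_posterior(
    y_new, obs: ObservationSet, partition: Partition, conc: Concentration, model
) -> np.ndarray:
    """Posterior over the K+1 assignment options for a new observation."""
    terms = _assignment_log_terms(y_new, obs, partition, conc, model)
    return np.exp(terms - logsumexp(terms))


def _option_label(option: Assignment) -> str:
    return NOVEL if option == NOVEL else f"state_{option}"


def state_evidence_ratio(
    y_new,
    obs: ObservationSet,
    partition: Partition,
    conc: Concentration,
    model,
    option_a: Assignment,
    option_b: Assignment = NOVEL,
) -> EvidenceResult:
    """Log odds between two assignment options for a new observation."""
    if option_a == option_b:
        raise ValueError("assignment options must be distinct")
    terms = _assignment_log_terms(y_new, obs, partition, conc, model)

    def term(option: Assignment) -> float:
        idx = partition.num_states if option == NOVEL else int(option)
        if not 0 <= idx <= partition.num_states:
            raise IndexError(f"assignment option {option} out of range")
        return terms[idx]

    return EvidenceResult(
        term(option_a) - term(option_b), _option_label(option_a), _option_label(option_b)
    )


def _hypothesis_score(
    obs: ObservationSet, y_probe, hyp: Hypothesis, conc: Concentration, model
) -> float:
    """Joint unnormalized log posterior of a training partition plus,
    when present, the probe's assignment under it."""
    score = partition_log_posterior(obs, hyp.partition, conc, model)
    if hyp.probe_assignment is not None:
        if y_probe is None:
            raise ValueError(f"hypothesis {hyp.name!r} assigns a probe but none was given")
        terms = _assignment_log_terms(y_probe, obs, hyp.partition, conc, model)
        idx = (
            hyp.partition.num_states
            if hyp.probe_assignment == NOVEL
            else int(hyp.probe_assignment)
        )
        score += terms[idx]
    return score


def hypothesis_set_log_odds(
    obs: ObservationSet,
    y_probe,
    set_s: Sequence[Hypothesis],
    set_d: Sequence[Hypothesis],
    conc: Concentration,
    model,
    names: tuple[str, str] = ("S", "D"),
) -> EvidenceResult:
    """Log odds between two sets of hypotheses (log-sum-exp of joint scores).

    Used for the morph comparisons, where "same state as the square" and
    "different state from the square" are each unions of several partitions
    plus probe assignments.
    """
    if not set_s or not set_d:
        raise ValueError("hypothesis sets must be non-empty")
    s_scores = [_hypothesis_score(obs, y_probe, h, conc, model) for h in set_s]
    d_scores = [_hypothesis_score(obs, y_probe, h, conc, model) for h in set_d]
    return EvidenceResult(
        float(logsumexp(s_scores) - logsumexp(d_scores)), names[0], names[1]
    )
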