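"""Chinese restaurant process (CRP) prior over partitions of observations.

The CRP is a sequential prior over assignments of observations to an
unbounded set of hidden states.  Observation t joins an existing state k
with probability m_k / (t - 1 + alpha) (where m_k counts earlier members
of state k) and opens a new state with probability alpha / (t - 1 + alpha).
The concentration parameter alpha controls the propensity to create new
states: alpha = 0 collapses to a single state, large alpha favours many.

The joint probability of a full assignment sequence c_1..c_T is

    log P(c) = K log(alpha) + sum_k log Gamma(m_k)
               + log Gamma(alpha) - log Gamma(T + alpha)

which is exactly the product of the sequential terms above (and hence a
normalized distribution over partitions, verified by enumeration in the
test suite).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
from scipy.special import gammaln

__all__ = [
    "Concentration",
    "Partition",
    "next_state_probabilities",
    "partition_log_prior",
    "sample_partition",
    "enumerate_partitions",
]


@dataclass(frozen=True)
class Concentration:
    """CRP concentration parameter alpha >= 0 (default 0.1)."""

    alpha: float = 0.1

    def __post_init__(self) -> None:
        if not np.isfinite(self.alpha) or self.alpha < 0:
            raise ValueError(f"alpha must be a finite non-negative real, got {self.alpha}")


def _canonical_labels(labels: Sequence[int]) -> tuple[int, ...]:
    """Relabel states 0..K-1 in order of first appearance."""
    mapping: dict[int, int] = {}
    out = []
    for lab in labels:
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out.append(mapping[lab])
    return tuple(out)


@dataclass(frozen=True)
class Partition:
    """Assignment of a sequence of observations to hidden-state labels.

    Labels are canonicalized to 0..K-1 in order of first appearance, so two
    partitions describing the same grouping compare equal regardless of the
    label values used to construct them.  The empty partition is allowed.
    """

    assignments: tuple[int, ...] = field(default=())

    def __init__(self, assignments: Iterable[int] = ()) -> None:
        object.__setattr__(self, "assignments", _canonical_labels(list(assignments)))

    @property
    def num_obs(self) -> int:
        return len(self.assignments)

    @property
    def num_states(self) -> int:
        return max(self.assignments) + 1 if self.assignments else 0

    @property
    def counts(self) -> np.ndarray:
        """Per-state member counts m_k, ordered by state label."""
        return np.bincount(self.assignments, minlength=self.num_states).astype(int)

    def members(self, state: int) -> np.ndarray:
        """Indices of the observations assigned to ``state``."""
        if not 0 <= state < self.num_states:
            raise IndexError(f"state {state} out of range for K={self.num_states}")
        return np.flatnonzero(np.asarray(self.assignments) == state)

    @classmethod
    def single_state(cls, num_obs: int) -> "Partition":
        return cls([0] * num_obs)

    @classmethod
    def alternating(cls, num_obs: int, period: int = 2) -> "Partition":
        """Round-robin assignment 0,1,..,period-1,0,1,.. (e.g. A/B sessions)."""
        return cls([t % period for t in range(num_obs)])


def next_state_probabilities(partition: Partition, conc: Concentration) -> np.ndarray:
    """Sequential CRP probabilities for the next observation.

    Returns a length K+1 vector: entries 0..K-1 are m_k / (T + alpha) for
    the existing states, entry K is alpha / (T + alpha) for a new state.
    For the empty partition the new state is certain: returns [1.0].
    """
    t_minus_1 = partition.num_obs
    if t_minus_1 == 0:
        return np.array([1.0])
    denom = t_minus_1 + conc.alpha
    return np.append(partition.counts / denom, conc.alpha / denom)


def partition_log_prior(partition: Partition, conc: Concentration) -> float:
    """Log CRP probability of a full assignment sequence.

    alpha = 0 is handled as the degenerate single-state prior: probability 1
    for the all-one-state partition, -inf (not an exception) for any
    multi-state partition, so evidence ratios remain well defined.
    """
    if partition.num_obs == 0:
        raise ValueError("partition_log_prior requires a non-empty partition")
    alpha, counts = conc.alpha, partition.counts
    k, t = partition.num_states, partition.num_obs
    if alpha == 0.0:
        return 0.0 if k <= 1 else -np.inf
    return float(
        k * np.log(alpha)
        + gammaln(counts).sum()
        + gammaln(alpha)
        - gammaln(t + alpha)
    )


def sample_partition(num_obs: int, conc: Concentration, seed) -> Partition:
    """Draw a partition from the sequential CRP process.

    ``seed`` may be an int, a SeedSequence, or a Generator.
    """
    if num_obs < 1:
        raise ValueError("num_obs must be >= 1")
    rng = np.random.default_rng(seed)
    u = rng.random(num_obs)
    alpha = conc.alpha
    labels = [0]
    counts = [1]
    for t in range(2, num_obs + 1):
        denom = t - 1 + alpha
        r = u[t - 1] * denom
        acc = 0.0
        choice = len(counts)  # new state unless an existing one absorbs r
        for k, m in enumerate(counts):
            acc += m
            if r < acc:
                choice = k
                break
        if choice == len(counts):
            counts.append(1)
        else:
            counts[choice] += 1
        labels.append(choice)
    return Partition(labels)


def enumerate_partitions(num_obs: int, max_obs: int = 10) -> Iterator[Partition]:
    """Yield every partition of ``num_obs`` observations (Bell-number many).

    Enumerates restricted growth strings; guarded to small problems since
    the count grows super-exponentially.
    """
    if num_obs > max_obs:
        raise ValueError(f"exhaustive enumeration limited to {max_obs} observations")

    def rec(prefix: list[int], k: int):
        if len(prefix) == num_obs:
            yield Partition(prefix)
            return
        for lab in range(k + 1):
            yield from rec(prefix + [lab], max(k, lab + 1))

    if num_obs == 0:
        yield Partition(())
        return
    yield from rec([0], 1)
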