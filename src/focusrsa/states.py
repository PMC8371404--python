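"""Bitmask state spaces over small domains of named individuals.

A wh-question like "Which of Audrey, Bob, Dale danced?" partitions the
possibilities into 2**k *partial states*, one per subset ("target set") of
the k contextually relevant individuals: the state in which exactly that
subset performed the action.  States are encoded as integers whose set bits
pick out the alphabetical positions of the target-set members, with the
first name at the least-significant bit, so e.g. over {Audrey, Bob, Dale}
the state {Audrey, Dale} has index 0b101 = 5.  Under this encoding the
exhaustive state of the first-named individual is always index 1.
"""

from __future__ import annotations

import string
from dataclasses import dataclass
from math import comb

import numpy as np

__all__ = [
    "Domain",
    "encode_target_set",
    "decode_target_set",
    "state_sizes",
    "binomial_prior",
    "backoff_prior",
    "expand_size_probs",
    "compatible_states",
    "condition_on_focus",
]


@dataclass(frozen=True)
class Domain:
    """The set of contextually relevant individuals, alphabetically ordered.

    Parameters
    ----------
    labels
        Distinct names; they are sorted on construction so that the bitmask
        encoding is well defined regardless of input order.
    """

    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        labels = tuple(sorted(str(x) for x in self.labels))
        if len(labels) == 0:
            raise ValueError("a domain needs at least one individual")
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate labels in domain: {labels}")
        object.__setattr__(self, "labels", labels)

    @classmethod
    def from_size(cls, k: int) -> "Domain":
        """Generic domain of size ``k`` with labels 'A', 'B', 'C', ..."""
        if not 1 <= k <= 26:
            raise ValueError(f"domain size must be in 1..26, got {k}")
        return cls(tuple(string.ascii_uppercase[:k]))

    @property
    def k(self) -> int:
        return len(self.labels)

    @property
    def n_states(self) -> int:
        return 1 << self.k


def encode_target_set(subset, domain: Domain) -> int:
    """Bitmask index of the state in which exactly ``subset`` acted."""
    i = 0
    for label in subset:
        try:
            pos = domain.labels.index(label)
        except ValueError:
            raise KeyError(
                f"label {label!r} is not in the domain {domain.labels}"
            ) from None
        i |= 1 << pos
    return i


def decode_target_set(i: int, domain: Domain) -> frozenset:
    """Inverse of :func:`encode_target_set`."""
    if not 0 <= i < domain.n_states:
        raise ValueError(f"state index {i} out of range for k={domain.k}")
    return frozenset(
        label for pos, label in enumerate(domain.labels) if i >> pos & 1
    )


def state_sizes(k: int) -> np.ndarray:
    """Target-set size m_i = |B_i| (bit count) for every state index."""
    return np.array([int(i).bit_count() for i in range(1 << k)], dtype=np.int64)


def binomial_prior(k: int, p: float) -> np.ndarray:
    """Prior over all 2**k states when each individual acts independently
    with probability ``p``: the state with m set bits gets p^m (1-p)^(k-m).
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"binomial success probability must be in (0,1), got {p}")
    m = state_sizes(k)
    return p**m * (1.0 - p) ** (k - m)


def backoff_prior(prior: np.ndarray, weight: float) -> np.ndarray:
    """Convex mixture of ``prior`` with the uniform distribution.

    ``weight=1`` is the pure uniform back-off used for "wonky" priors;
    ``weight=0`` returns the prior unchanged.
    """
    if not 0.0 <= weight <= 1.0:
        raise ValueError(f"back-off weight must be in [0,1], got {weight}")
    prior = np.asarray(prior, dtype=float)
    return weight / prior.size + (1.0 - weight) * prior


def expand_size_probs(p_sizes, k: int) -> np.ndarray:
    """Distribute a probability vector over target-set sizes 0..k onto the
    full 2**k state space.

    States that share a target-set size are treated as interchangeable, so
    state i receives ``p_sizes[m_i] / C(k, m_i)``.  The result sums to one.
    """
    p_sizes = np.asarray(p_sizes, dtype=float)
    if p_sizes.shape[-1] != k + 1:
        raise ValueError(
            f"size-probability vector must have length k+1={k + 1}, "
            f"got {p_sizes.shape[-1]}"
        )
    m = state_sizes(k)
    denom = np.array([comb(k, int(mm)) for mm in m], dtype=float)
    return p_sizes[..., m] / denom


def compatible_states(k: int, mentioned_bit: int = 0) -> np.ndarray:
    """Indices of the 2**(k-1) states containing the mentioned individual."""
    idx = np.arange(1 << k)
    return idx[(idx >> mentioned_bit) & 1 == 1]


def condition_on_focus(Q, k: int, mentioned_bit: int = 0) -> np.ndarray:
    """Restrict a full-state prior to the states compatible with a focus
    utterance naming one individual, and renormalize.

    The compatible states are the half of the state space whose target set
    contains the mentioned individual (bit ``mentioned_bit``).
    """
    Q = np.asarray(Q, dtype=float)
    if Q.shape[-1] != 1 << k:
        raise ValueError(f"prior must have length 2**k={1 << k}, got {Q.shape[-1]}")
    qc = Q[..., compatible_states(k, mentioned_bit)]
    total = qc.sum(axis=-1, keepdims=True)
    if np.any(total <= 0):
        raise ValueError("no prior mass on states compatible with the utterance")
    return qc / total
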