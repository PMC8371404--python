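"""Rational Speech Act model of narrow-focus interpretation.

The model stack is the standard three-level recursion: a literal listener

    L0(s|e) ∝ [[e]](s) p(s),

a soft-max rational speaker

    S1(e|s) ∝ exp(alpha * (log L0(s|e) - C(e))),

and a pragmatic listener

    L2(s|e) ∝ S1(e|s) p(s).

*Exhaustivity* E(k) is the pragmatic listener's probability of the
exhaustive state (only the mentioned individual acted) after hearing a
focus utterance naming one individual, in a domain of size k, with an
i.i.d.-Bernoulli ("binomial") state prior with success probability p.

Under the default convention -- a lexicon with one focus expression per
nonempty subset (at-least semantics) plus a zero-cost null message that is
true everywhere, and zero expression costs -- exhaustivity has the closed
form

    E(k) = E(2)**(k-1),   E(2) = 1 / (1 + (1 + p**-alpha)**-1 * p/(1-p)),

implemented in :func:`closed_form_exhaustivity` and verified against the
full-matrix recursion in the test suite.

Model variants cover expression costs proportional to the number of focused
words, exclusive ("only ...") alternatives, and collapsed two-state /
two-alternative spaces in which all non-exhaustive states are pooled,
optionally with a k-independent constant prior.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .states import Domain, binomial_prior

__all__ = [
    "Expression",
    "Lexicon",
    "RSAParams",
    "ConditionalTable",
    "build_lexicon",
    "denotation",
    "denotation_matrix",
    "collapsed_prior",
    "literal_listener",
    "utility",
    "utility_matrix",
    "speaker",
    "pragmatic_listener",
    "exhaustivity",
    "closed_form_exhaustivity",
    "k2_posterior",
]

VARIANTS = (
    "focus_only",
    "focus_plus_exclusives",
    "collapsed_two_state",
    "collapsed_constant_prior",
)

#: state labels of the collapsed two-state space
COLLAPSED_STATES = ("exh", "nonexh")


@dataclass(frozen=True)
class Expression:
    """One utterance alternative.

    ``kind`` is one of ``focus`` (at-least semantics: true iff the mentioned
    set is contained in the target set), ``exclusive`` (true iff the target
    set equals the mentioned set), ``collapsed_nonexh`` (the pooled
    non-exhaustive description of the collapsed space) or ``null`` (the
    trivially true zero-cost message).  ``mask`` is the bitmask of mentioned
    individuals (0 only for ``null``).
    """

    kind: str
    mask: int
    cost: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        if self.cost < 0:
            raise ValueError("expression cost must be nonnegative")
        if self.kind in ("focus", "exclusive") and self.mask == 0:
            raise ValueError(f"{self.kind} expression must mention someone")


@dataclass(frozen=True)
class Lexicon:
    expressions: tuple[Expression, ...]
    variant: str
    domain: Domain

    def __post_init__(self) -> None:
        seen = set()
        for e in self.expressions:
            key = (e.kind, e.mask)
            if key in seen:
                raise ValueError(f"duplicate expression {key} in lexicon")
            seen.add(key)

    @property
    def collapsed(self) -> bool:
        return self.variant.startswith("collapsed")

    @property
    def n_states(self) -> int:
        return 2 if self.collapsed else self.domain.n_states

    @property
    def costs(self) -> np.ndarray:
        return np.array([e.cost for e in self.expressions])

    def index_of(self, kind: str, mask: int) -> int:
        for i, e in enumerate(self.expressions):
            if e.kind == kind and e.mask == mask:
                return i
        raise KeyError(f"no expression ({kind}, {mask}) in lexicon")


@dataclass(frozen=True)
class RSAParams:
    """Forward-model parameters: soft-max temperature ``alpha`` of the
    speaker, Bernoulli success probability ``p`` of the state prior, and
    cost per focused word."""

    alpha: float = 3.0
    p: float = 0.5
    cost_per_word: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.alpha) or self.alpha < 0:
            raise ValueError("alpha must be finite and >= 0")
        if self.alpha > 100:
            warnings.warn(
                "alpha > 100: the strictly-optimal speaker limit is "
                "approximated, not represented exactly",
                stacklevel=2,
            )
        if not 0.0 < self.p < 1.0:
            raise ValueError("p must be in (0,1)")
        if self.cost_per_word < 0:
            raise ValueError("cost_per_word must be >= 0")


def _mask_label(mask: int, domain: Domain) -> str:
    return ",".join(l for i, l in enumerate(domain.labels) if mask >> i & 1)


def build_lexicon(
    domain: Domain,
    variant: str = "focus_only",
    cost_per_word: float = 0.0,
    include_null: bool = True,
    collapsed_exclusives: bool = False,
) -> Lexicon:
    """Construct the utterance alternatives for a model variant.

    ``focus_only`` has one focus expression per nonempty subset (2**k - 1),
    plus the null message when ``include_null``; ``focus_plus_exclusives``
    adds one exclusive per nonempty subset.  Costs are ``cost_per_word``
    times the number of mentioned names, with one extra word for the
    exclusive marker.  The collapsed variants have exactly two expressions
    over the pooled two-state space ("A acted" / "A and at least one other
    acted"); ``collapsed_exclusives`` adds "only A acted".
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown lexicon variant {variant!r}; expected one of {VARIANTS}")
    k = domain.k
    if variant.startswith("collapsed"):
        exprs = [
            Expression("focus", 1, cost_per_word * 1.0, f"FOC[{domain.labels[0]}]"),
            Expression(
                "collapsed_nonexh", 1, cost_per_word * float(k), "NONEXH"
            ),
        ]
        if collapsed_exclusives:
            exprs.append(
                Expression("exclusive", 1, cost_per_word * 2.0, f"ONLY[{domain.labels[0]}]")
            )
        return Lexicon(tuple(exprs), variant, domain)

    exprs = []
    for mask in range(1, domain.n_states):
        n_words = int(mask).bit_count()
        exprs.append(
            Expression(
                "focus", mask, cost_per_word * n_words, f"FOC[{_mask_label(mask, domain)}]"
            )
        )
    if variant == "focus_plus_exclusives":
        for mask in range(1, domain.n_states):
            n_words = int(mask).bit_count() + 1
            exprs.append(
                Expression(
                    "exclusive",
                    mask,
                    cost_per_word * n_words,
                    f"ONLY[{_mask_label(mask, domain)}]",
                )
            )
    if include_null:
        exprs.append(Expression("null", 0, 0.0, "NULL"))
    return Lexicon(tuple(exprs), variant, domain)


def denotation(e: Expression, i: int, collapsed: bool = False) -> bool:
    """Truth of expression ``e`` in state ``i``.

    Focus expressions have at-least ("mention-some") semantics: true iff the
    mentioned set is a subset of the target set.  Exclusives are true only
    in the state identical to the mentioned set.  In the collapsed space
    (states 0=exh, 1=nonexh) the plain focus description is true in both
    states, the pooled non-exhaustive description only in state 1, and the
    exclusive only in state 0.
    """
    if collapsed:
        if e.kind == "focus" or e.kind == "null":
            return True
        if e.kind == "collapsed_nonexh":
            return i == 1
        if e.kind == "exclusive":
            return i == 0
        raise ValueError(f"unknown expression kind {e.kind!r}")
    if e.kind == "focus":
        return (i & e.mask) == e.mask
    if e.kind == "exclusive":
        return i == e.mask
    if e.kind == "null":
        return True
    raise ValueError(f"expression kind {e.kind!r} undefined on the full state space")


def denotation_matrix(lex: Lexicon) -> np.ndarray:
    """Boolean (n_expressions, n_states) truth table."""
    S = lex.n_states
    return np.array(
        [[denotation(e, i, lex.collapsed) for i in range(S)] for e in lex.expressions]
    )


def collapsed_prior(k: int, p: float, constant: bool = False) -> np.ndarray:
    """Prior over the collapsed (exhaustive, pooled non-exhaustive) space.

    The binomial masses of all compatible states are pooled: conditional on
    the mentioned individual acting, the exhaustive state keeps mass
    (1-p)**(k-1).  The constant-prior variant fixes both states at 0.5 for
    every k.
    """
    if constant:
        return np.array([0.5, 0.5])
    if not 0.0 < p < 1.0:
        raise ValueError(f"p must be in (0,1), got {p}")
    q_exh = (1.0 - p) ** (k - 1)
    return np.array([q_exh, 1.0 - q_exh])


@dataclass
class ConditionalTable:
    """Row-stochastic conditional distribution with labelled axes.

    Rows with no support (an expression true in no positive-prior state, or
    a state no speaker can describe) are all-zero and flagged in ``empty``.
    """

    probs: np.ndarray
    rows: tuple
    cols: tuple
    empty: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.empty is None:
            self.empty = np.zeros(self.probs.shape[0], dtype=bool)
        sums = self.probs.sum(axis=1)
        ok = np.where(self.empty, np.abs(sums) < 1e-12, np.abs(sums - 1.0) < 1e-9)
        if not ok.all():
            bad = [self.rows[i] for i in np.flatnonzero(~ok)]
            raise ValueError(f"rows not normalized: {bad}")

    def row(self, label) -> np.ndarray:
        return self.probs[self.rows.index(label)]

    def __getitem__(self, key) -> float:
        r, c = key
        return float(self.probs[self.rows.index(r), self.cols.index(c)])


def _state_labels(lex: Lexicon) -> tuple:
    if lex.collapsed:
        return COLLAPSED_STATES
    return tuple(range(lex.n_states))


def literal_listener(lex: Lexicon, prior: np.ndarray) -> ConditionalTable:
    """L0(s|e): the prior restricted to the denotation of e, per expression."""
    prior = np.asarray(prior, dtype=float)
    if prior.shape != (lex.n_states,):
        raise ValueError(f"prior must have length {lex.n_states}")
    if abs(prior.sum() - 1.0) > 1e-9:
        raise ValueError("prior must be normalized")
    T = denotation_matrix(lex)
    mass = T * prior
    totals = mass.sum(axis=1)
    empty = totals == 0
    probs = np.where(empty[:, None], 0.0, mass / np.where(empty, 1.0, totals)[:, None])
    return ConditionalTable(
        probs, tuple(e.label for e in lex.expressions), _state_labels(lex), empty
    )


def utility_matrix(L0: ConditionalTable, lex: Lexicon) -> np.ndarray:
    """U(e,s) = log L0(s|e) - C(e); -inf where the expression is false."""
    with np.errstate(divide="ignore"):
        return np.log(L0.probs) - lex.costs[:, None]


def utility(e: Expression, i: int, L0: ConditionalTable) -> float:
    """Utility of uttering ``e`` in state ``i`` given a literal listener."""
    with np.errstate(divide="ignore"):
        return float(np.log(L0[e.label, L0.cols[i]]) - e.cost)


def speaker(
    L0: ConditionalTable,
    alpha: float,
    lex: Lexicon,
    on_empty: str = "flag",
) -> ConditionalTable:
    """S1(e|s): soft-max over the utilities of the true expressions of s.

    At alpha=0 the speaker picks uniformly among the expressions true in s;
    false expressions always have probability zero (the -inf utility is
    represented by exact zeros, never by exponentiating -inf).  States in
    which no expression is true get an all-zero row flagged empty, or raise
    if ``on_empty="raise"``.
    """
    if not np.isfinite(alpha) or alpha < 0:
        raise ValueError("alpha must be finite and >= 0")
    T = denotation_matrix(lex)
    with np.errstate(divide="ignore"):
        logL0 = np.log(L0.probs)
    # alpha * (logL0 - cost), with false expressions masked out exactly
    logw = np.where(T, alpha * (np.where(T, logL0, 0.0) - lex.costs[:, None]), -np.inf)
    logw = logw.T  # (states, expressions)
    finite = np.isfinite(logw)
    empty = ~finite.any(axis=1)
    if empty.any() and on_empty == "raise":
        bad = [_state_labels(lex)[i] for i in np.flatnonzero(empty)]
        raise ValueError(f"no true expression in states {bad}: speaker cannot normalize")
    shift = np.where(empty, 0.0, np.max(np.where(finite, logw, -np.inf), axis=1))
    w = np.exp(logw - shift[:, None], where=finite, out=np.zeros_like(logw))
    totals = w.sum(axis=1)
    probs = np.where(empty[:, None], 0.0, w / np.where(empty, 1.0, totals)[:, None])
    return ConditionalTable(
        probs, _state_labels(lex), tuple(e.label for e in lex.expressions), empty
    )


def pragmatic_listener(S1: ConditionalTable, prior: np.ndarray) -> ConditionalTable:
    """L2(s|e) ∝ S1(e|s) p(s), per expression."""
    prior = np.asarray(prior, dtype=float)
    mass = S1.probs.T * prior  # (expressions, states)
    totals = mass.sum(axis=1)
    empty = totals == 0
    probs = np.where(empty[:, None], 0.0, mass / np.where(empty, 1.0, totals)[:, None])
    return ConditionalTable(probs, S1.cols, S1.rows, empty)


def exhaustivity(
    k: int,
    params: RSAParams,
    variant: str = "focus_only",
    include_null: bool = True,
    collapsed_exclusives: bool = False,
) -> float:
    """E(k): the pragmatic listener's probability of the exhaustive state
    after a focus utterance naming one individual, from the full matrix
    recursion of the requested variant."""
    if k < 2:
        raise ValueError("exhaustivity needs a domain of size k >= 2")
    domain = Domain.from_size(k)
    lex = build_lexicon(
        domain,
        variant,
        cost_per_word=params.cost_per_word,
        include_null=include_null,
        collapsed_exclusives=collapsed_exclusives,
    )
    if lex.collapsed:
        prior = collapsed_prior(k, params.p, constant=variant == "collapsed_constant_prior")
        exh_col, foc_label = "exh", lex.expressions[0].label
    else:
        prior = binomial_prior(k, params.p)
        exh_col, foc_label = 1, lex.expressions[lex.index_of("focus", 1)].label
    L0 = literal_listener(lex, prior)
    S1 = speaker(L0, params.alpha, lex)
    L2 = pragmatic_listener(S1, prior)
    return L2[foc_label, exh_col]


def closed_form_exhaustivity(k: int, p: float, alpha: float) -> float:
    """E(k) = E(2)**(k-1) with E(2) = 1/(1 + (1+p**-alpha)**-1 * p/(1-p)).

    Exact for the focus-only, zero-cost lexicon with a null message and the
    binomial state prior; strictly decreasing in k for p in (0,1) and
    finite alpha.
    """
    if k < 2:
        raise ValueError("closed form defined for k >= 2")
    if not 0.0 < p < 1.0:
        raise ValueError(f"p must be in (0,1), got {p}")
    if not np.isfinite(alpha) or alpha < 0:
        raise ValueError("alpha must be finite and >= 0")
    e2 = 1.0 / (1.0 + (1.0 / (1.0 + p**-alpha)) * p / (1.0 - p))
    return float(e2 ** (k - 1))


def k2_posterior(speaker_prob_nonexh: float, prior_exh: float) -> float:
    """Bayes posterior of the exhaustive state at domain size 2.

    With only two states compatible with the utterance, the posterior is
    1 / (1 + s * (1-q)/q) where q is the prior of the exhaustive state and
    s the speaker's relative probability of producing the focus utterance
    in the non-exhaustive state.  Degenerate priors return the forced
    limits (q=0 -> 0, q=1 -> 1).
    """
    s, q = float(speaker_prob_nonexh), float(prior_exh)
    if not 0.0 <= s <= 1.0:
        raise ValueError("speaker probability must be in [0,1]")
    if not 0.0 <= q <= 1.0:
        raise ValueError("prior must be in [0,1]")
    if q == 0.0:
        return 0.0
    if q == 1.0:
        return 1.0
    return 1.0 / (1.0 + s * (1.0 - q) / q)
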