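import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from focusrsa.rsa import (
    Expression,
    RSAParams,
    build_lexicon,
    closed_form_exhaustivity,
    collapsed_prior,
    denotation,
    exhaustivity,
    k2_posterior,
    literal_listener,
    pragmatic_listener,
    speaker,
    utility,
)
from focusrsa.states import Domain, binomial_prior

D2 = Domain.from_size(2)
D3 = Domain.from_size(3)


class TestLexicon:
    def test_focus_only_counts(self):
        assert len(build_lexicon(D3, "focus_only", include_null=False).expressions) == 7
        assert len(build_lexicon(D3, "focus_only").expressions) == 8  # + null

    def test_collapsed_has_two_alternatives(self):
        assert len(build_lexicon(D3, "collapsed_two_state").expressions) == 2

    def test_exclusives_double_the_alternatives(self):
        lex = build_lexicon(D2, "focus_plus_exclusives", include_null=False)
        assert len(lex.expressions) == 6

    def test_costs_scale_with_mentioned_names(self):
        lex = build_lexicon(D3, "focus_plus_exclusives", cost_per_word=0.5)
        assert lex.expressions[lex.index_of("focus", 0b111)].cost == pytest.approx(1.5)
        # exclusives pay one extra word for the marker
        assert lex.expressions[lex.index_of("exclusive", 0b001)].cost == pytest.approx(1.0)
        assert lex.expressions[lex.index_of("null", 0)].cost == 0.0

    def test_unknown_variant(self):
        with pytest.raises(ValueError, match="variant"):
            build_lexicon(D2, "focus_sometimes")

    def test_expression_validation(self):
        with pytest.raises(ValueError):
            Expression("focus", 0)
        with pytest.raises(ValueError):
            Expression("focus", 1, cost=-1.0)


class TestDenotation:
    def test_focus_has_at_least_semantics(self):
        foc_a = Expression("focus", 0b01)
        assert denotation(foc_a, 0b11)  # "SKYLAR ate" is true if Ashanti did too
        assert not denotation(foc_a, 0b10)

    def test_exclusive_requires_exact_match(self):
        only_a = Expression("exclusive", 0b01)
        assert denotation(only_a, 0b01)
        assert not denotation(only_a, 0b11)

    def test_focus_of_a_group_needs_the_whole_group(self):
        assert not denotation(Expression("focus", 0b11), 0b01)

    def test_null_is_trivially_true(self):
        assert all(denotation(Expression("null", 0), i) for i in range(8))


class TestListenersAndSpeaker:
    def test_literal_listener_conditions_the_prior(self):
        lex = build_lexicon(D2, "focus_only")
        L0 = literal_listener(lex, binomial_prior(2, 0.5))
        assert L0["FOC[A]", 1] == pytest.approx(0.5)
        assert L0["FOC[A]", 3] == pytest.approx(0.5)
        assert np.allclose(L0.row("NULL"), 0.25)  # null returns the prior

    def test_empty_support_is_flagged(self):
        lex = build_lexicon(D2, "focus_only", include_null=False)
        prior = np.array([0.5, 0.5, 0.0, 0.0])  # no mass on states with B
        L0 = literal_listener(lex, prior)
        assert L0.empty[lex.index_of("focus", 0b10)]

    def test_utility_is_log_accuracy_minus_cost(self):
        lex = build_lexicon(D2, "focus_only")
        L0 = literal_listener(lex, binomial_prior(2, 0.5))
        e = lex.expressions[lex.index_of("focus", 1)]
        assert utility(e, 1, L0) == pytest.approx(np.log(0.5))
        costly = Expression("focus", 1, cost=1.0, label=e.label)
        assert utility(costly, 1, L0) == pytest.approx(np.log(0.5) - 1.0)
        assert utility(e, 2, L0) == -np.inf  # false expression

    def test_indifferent_speaker_is_uniform_over_true_expressions(self):
        lex = build_lexicon(D2, "focus_only")
        S1 = speaker(literal_listener(lex, binomial_prior(2, 0.5)), 0.0, lex)
        # state {A}: FOC[A] and NULL are true
        assert S1[1, "FOC[A]"] == pytest.approx(0.5)
        assert S1[1, "NULL"] == pytest.approx(0.5)
        assert S1[1, "FOC[B]"] == 0.0

    def test_soft_max_speaker_hand_anchors(self):
        lex = build_lexicon(D2, "focus_only")
        S1 = speaker(literal_listener(lex, binomial_prior(2, 0.5)), 3.0, lex)
        assert S1[1, "FOC[A]"] == pytest.approx(8 / 9)
        assert S1[3, "FOC[A]"] == pytest.approx(8 / 81)

    def test_speechless_state_flag_and_strict_mode(self):
        lex = build_lexicon(D2, "focus_only", include_null=False)
        L0 = literal_listener(lex, binomial_prior(2, 0.5))
        S1 = speaker(L0, 1.0, lex)
        assert S1.empty[0] and np.all(S1.probs[0] == 0)  # empty-set state
        with pytest.raises(ValueError, match="no true expression"):
            speaker(L0, 1.0, lex, on_empty="raise")

    def test_pragmatic_listener_hand_anchor(self):
        lex = build_lexicon(D2, "focus_only")
        prior = binomial_prior(2, 0.5)
        L2 = pragmatic_listener(speaker(literal_listener(lex, prior), 3.0, lex), prior)
        assert L2["FOC[A]", 1] == pytest.approx(0.9)

    def test_point_prior_forces_the_listener(self):
        lex = build_lexicon(D2, "focus_only")
        prior = np.array([0.0, 1.0, 0.0, 0.0])
        L2 = pragmatic_listener(speaker(literal_listener(lex, prior), 2.0, lex), prior)
        assert L2["FOC[A]", 1] == pytest.approx(1.0)

    def test_indifferent_speaker_without_null_still_shapes_l2(self):
        # at alpha=0 the speaker is uniform over TRUE expressions, whose count
        # differs across states (1 in {A} vs 3 in {A,B}), so L2 is NOT the
        # conditioned prior: it tilts toward states with fewer alternatives
        lex = build_lexicon(D2, "focus_only", include_null=False)
        prior = binomial_prior(2, 0.5)
        L2 = pragmatic_listener(speaker(literal_listener(lex, prior), 0.0, lex), prior)
        assert L2["FOC[A]", 1] == pytest.approx(0.75)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.floats(0.05, 0.95), st.floats(0.0, 5.0), st.integers(2, 4))
    def test_rows_are_normalized(self, p, alpha, k):
        lex = build_lexicon(Domain.from_size(k), "focus_only")
        prior = binomial_prior(k, p)
        L0 = literal_listener(lex, prior)
        S1 = speaker(L0, alpha, lex)
        L2 = pragmatic_listener(S1, prior)
        for table in (L0, S1, L2):
            sums = table.probs.sum(axis=1)
            assert np.all(np.abs(sums[~table.empty] - 1.0) < 1e-12)


class TestExhaustivity:
    def test_hand_computed_anchors(self):
        assert exhaustivity(2, RSAParams(alpha=3, p=0.5)) == pytest.approx(0.9)
        assert exhaustivity(2, RSAParams(alpha=0, p=0.5)) == pytest.approx(2 / 3)
        assert exhaustivity(4, RSAParams(alpha=3, p=0.5)) == pytest.approx(0.9**3)

    def test_closed_form_anchors_and_limit(self):
        assert closed_form_exhaustivity(2, 0.5, 3) == pytest.approx(0.9)
        assert closed_form_exhaustivity(3, 0.5, 3) == pytest.approx(0.81)
        assert closed_form_exhaustivity(2, 1e-9, 4.0) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            closed_form_exhaustivity(2, 1.0, 3)

    def test_collapsed_space_pools_the_nonexhaustive_mass(self):
        q = collapsed_prior(3, 0.5)
        assert q[0] == pytest.approx(0.25)  # (1-p)^(k-1)
        assert np.allclose(collapsed_prior(5, 0.3, constant=True), 0.5)
        e_full = exhaustivity(3, RSAParams(alpha=3, p=0.5))
        e_coll = exhaustivity(3, RSAParams(alpha=3, p=0.5), "collapsed_two_state")
        assert e_coll < e_full

    def test_constant_prior_variant_ignores_domain_size(self):
        es = [
            exhaustivity(k, RSAParams(alpha=3, p=0.5), "collapsed_constant_prior")
            for k in (2, 3, 4, 5)
        ]
        assert np.allclose(es, es[0])

    def test_alpha_above_soft_limit_warns(self):
        with pytest.warns(UserWarning, match="alpha"):
            RSAParams(alpha=150.0)


class TestK2Posterior:
    @pytest.mark.parametrize(
        "s,q,expected",
        [
            (1.0, 0.5, 0.5),   # uninformative utterance: posterior = prior
            (0.0, 0.3, 1.0),   # utterance rules out the non-exhaustive state
            (1 / 9, 0.5, 0.9),
            (0.5, 0.0, 0.0),   # forced limits at degenerate priors
            (0.5, 1.0, 1.0),
        ],
    )
    def test_two_state_bayes(self, s, q, expected):
        assert k2_posterior(s, q) == pytest.approx(expected)

    def test_rejects_non_probabilities(self):
        with pytest.raises(ValueError):
            k2_posterior(1.2, 0.5)
        with pytest.raises(ValueError):
            k2_posterior(0.5, -0.1)

    def test_matches_the_full_matrix_model_at_k2(self):
        from focusrsa.rsa import build_lexicon, literal_listener, pragmatic_listener, speaker

        rng = np.random.default_rng(314)
        lex = build_lexicon(D2, "focus_only")
        for _ in range(20):
            p = rng.uniform(0.05, 0.95)
            alpha = rng.uniform(0.0, 6.0)
            prior = binomial_prior(2, p)
            S1 = speaker(literal_listener(lex, prior), alpha, lex)
            L2 = pragmatic_listener(S1, prior)
            ratio = S1[3, "FOC[A]"] / S1[1, "FOC[A]"]
            q = prior[1] / (prior[1] + prior[3])
            assert k2_posterior(ratio, q) == pytest.approx(L2["FOC[A]", 1], abs=1e-10)
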