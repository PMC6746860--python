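import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_random_landscape
from epicube.operators import (
    EpistasisSpectrum,
    Form,
    Landscape,
    build_operator,
    epistasis_transform,
    fast_transform,
    goodness_of_fit,
    inverse_fast_transform,
    rank_terms,
    reconstruct,
    rereference,
    term_contributions,
)


class TestBuildOperator:
    def test_n1_background_averaged(self):
        op = build_operator(1, Form.BACKGROUND_AVERAGED)
        assert np.array_equal(op.matrix, [[0.5, 0.5], [-1.0, 1.0]])

    def test_n1_single_reference(self):
        op = build_operator(1, Form.SINGLE_REFERENCE)
        assert np.array_equal(op.matrix, [[1.0, 0.0], [-1.0, 1.0]])

    @pytest.mark.parametrize("form", list(Form))
    def test_n2_invertible(self, form):
        op = build_operator(2, form)
        assert op.matrix.shape == (4, 4)
        assert np.allclose(op.matrix @ op.inverse, np.eye(4), atol=1e-12)

    @pytest.mark.parametrize("n", [1, 2, 3, 5, 8])
    @pytest.mark.parametrize("form", list(Form))
    def test_analytic_inverse(self, n, form):
        op = build_operator(n, form)
        size = 1 << n
        assert np.allclose(op.inverse @ op.matrix, np.eye(size), atol=1e-10)

    def test_generator_recursions_hold(self):
        # printed 2x2 block structure, checked against explicit recursion
        for n in (1, 2, 3):
            op = build_operator(n, Form.BACKGROUND_AVERAGED)
            prev = build_operator(n - 1, Form.BACKGROUND_AVERAGED) if n > 1 else None
            Vp = prev.V if prev else np.array([[1.0]])
            Hp = prev.H if prev else np.array([[1.0]])
            assert np.array_equal(op.V, np.block([[0.5 * Vp, 0 * Vp], [0 * Vp, -Vp]]))
            assert np.array_equal(op.H, np.block([[Hp, Hp], [Hp, -Hp]]))
        assert np.allclose(op.H @ op.H, (1 << 3) * np.eye(8))

    def test_v_entries_are_signed_dyadics(self):
        op = build_operator(4, Form.BACKGROUND_AVERAGED)
        from epicube.genotype_space import order_of_index

        o = order_of_index(np.arange(16))
        assert np.array_equal(np.abs(np.diag(op.V)), 0.5 ** (4 - o))

    def test_unknown_form_rejected(self):
        with pytest.raises(ValueError):
            build_operator(2, "taylor")


class TestTransform:
    def test_n1_background_averaged_example(self):
        s = epistasis_transform(Landscape(1, [0.0, 1.0]), Form.BACKGROUND_AVERAGED)
        assert np.allclose(s.terms, [0.5, 1.0])

    def test_order0_terms(self, random_landscape):
        ba = epistasis_transform(random_landscape, Form.BACKGROUND_AVERAGED)
        sr = epistasis_transform(random_landscape, Form.SINGLE_REFERENCE)
        assert np.isclose(ba.terms[0], random_landscape.phenotypes.mean())
        assert np.isclose(sr.terms[0], random_landscape.phenotypes[0])

    @pytest.mark.parametrize("form", list(Form))
    def test_additive_landscape_has_no_interactions(self, form):
        n = 5
        rng = np.random.default_rng(0)
        b = rng.normal(size=n)
        idx = np.arange(1 << n)
        y = 0.3 + ((idx[:, None] >> np.arange(n)) & 1) @ b
        s = epistasis_transform(Landscape(n, y), form)
        from epicube.genotype_space import order_of_index

        high = order_of_index(idx) >= 2
        assert np.allclose(s.terms[high], 0.0, atol=1e-12)

    def test_first_order_term_is_background_averaged_effect(self):
        # fixes the sign convention against brute force, N=6
        L = make_random_landscape(6, 11)
        s = epistasis_transform(L, Form.BACKGROUND_AVERAGED)
        y = L.phenotypes
        for j in range(6):
            mask = 1 << j
            effects = [
                y[g | mask] - y[g]
                for g in range(64)
                if not g & mask
            ]
            assert np.isclose(s.terms[mask], np.mean(effects), atol=1e-12)

    @pytest.mark.parametrize("form", list(Form))
    @pytest.mark.parametrize("n", [3, 8, 12])
    def test_fast_matches_dense(self, form, n):
        L = make_random_landscape(n, n)
        fast = fast_transform(L.phenotypes, n, form)
        if n <= 8:
            dense = build_operator(n, form).matrix @ L.phenotypes
            assert np.allclose(fast, dense, rtol=1e-10, atol=1e-12)
        # inverse round trip at any size
        back = inverse_fast_transform(fast, n, form)
        assert np.allclose(back, L.phenotypes, rtol=1e-10, atol=1e-12)

    def test_constant_landscape_only_order0(self):
        s = epistasis_transform(Landscape(4, np.full(16, 2.5)), Form.BACKGROUND_AVERAGED)
        assert np.isclose(s.terms[0], 2.5)
        assert np.allclose(s.terms[1:], 0.0, atol=1e-14)

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            Landscape(3, np.zeros(7))


class TestReconstruct:
    def test_full_keep_roundtrip(self, random_landscape):
        for form in Form:
            s = epistasis_transform(random_landscape, form)
            back = reconstruct(s)
            assert np.allclose(
                back.phenotypes, random_landscape.phenotypes, atol=1e-10
            )

    def test_keep_order0_gives_mean(self, random_landscape):
        s = epistasis_transform(random_landscape, Form.BACKGROUND_AVERAGED)
        back = reconstruct(s, keep={0})
        assert np.allclose(back.phenotypes, random_landscape.phenotypes.mean())

    def test_empty_keep_gives_zero(self, random_landscape):
        s = epistasis_transform(random_landscape, Form.BACKGROUND_AVERAGED)
        assert np.array_equal(reconstruct(s, keep=set()).phenotypes, np.zeros(64))

    def test_planted_terms_reconstruct_exactly(self):
        from epicube.synthetic import SyntheticSpec, simulate_sparse_landscape

        spec = SyntheticSpec(n_positions=6, n_terms=5, seed=3)
        L, truth = simulate_sparse_landscape(spec)
        keep = set(np.flatnonzero(truth.terms).tolist())
        s = epistasis_transform(L, Form.BACKGROUND_AVERAGED)
        back = reconstruct(s, keep=keep)
        assert np.allclose(back.phenotypes, L.phenotypes, atol=1e-10)


class TestGoodnessOfFit:
    def test_perfect_fit(self, random_landscape):
        m = goodness_of_fit(random_landscape, random_landscape)
        assert m.r_squared == 1.0 and m.gop == 1.0

    def test_mean_prediction(self, random_landscape):
        y = random_landscape.phenotypes
        m = goodness_of_fit(y, np.full_like(y, y.mean()))
        assert np.isclose(m.r_squared, 0.0) and np.isclose(m.gop, 0.5)

    def test_anticorrelated_negative_r2(self):
        m = goodness_of_fit(np.array([0.0, 1.0]), np.array([1.0, 0.0]))
        assert np.isclose(m.r_squared, -3.0)

    def test_constant_target_rejected(self):
        with pytest.raises(ValueError):
            goodness_of_fit(np.ones(4), np.zeros(4))


class TestRankTerms:
    def test_planted_term_ranked_first(self):
        n = 6
        rng = np.random.default_rng(5)
        terms = rng.normal(0, 1e-3, 64)
        terms[0b000111] = 2.0  # strong order-3 interaction
        y = inverse_fast_transform(terms, n, Form.BACKGROUND_AVERAGED)
        s = epistasis_transform(Landscape(n, y), Form.BACKGROUND_AVERAGED)
        assert rank_terms(s)[0] == 0b000111

    def test_contributions_sum_to_sse(self, random_landscape):
        # orthogonal decomposition: dropped-term contributions add exactly
        s = epistasis_transform(random_landscape, Form.BACKGROUND_AVERAGED)
        contrib = term_contributions(s)
        rng = np.random.default_rng(0)
        keep = set(rng.choice(64, size=20, replace=False).tolist())
        back = reconstruct(s, keep=keep)
        sse = np.sum((back.phenotypes - random_landscape.phenotypes) ** 2)
        dropped = [i for i in range(64) if i not in keep]
        assert np.isclose(sse, contrib[dropped].sum(), rtol=1e-9)

    def test_matches_greedy_ordering_on_noise(self):
        # greedy-by-delta-SSE oracle equals contribution ranking
        L = make_random_landscape(5, 17)
        s = epistasis_transform(L, Form.BACKGROUND_AVERAGED)
        contrib = term_contributions(s)
        ranked = rank_terms(s)
        greedy = sorted(range(32), key=lambda i: -contrib[i])
        assert list(contrib[ranked]) == sorted(contrib, reverse=True)
        assert np.allclose(contrib[ranked], contrib[greedy])

    def test_r2_nondecreasing_and_reaches_one(self, random_landscape):
        s = epistasis_transform(random_landscape, Form.BACKGROUND_AVERAGED)
        ranked = rank_terms(s)
        prev = -np.inf
        for k in (1, 4, 16, 64):
            fit = goodness_of_fit(
                random_landscape, reconstruct(s, keep=set(ranked[:k].tolist()))
            )
            assert fit.r_squared >= prev - 1e-12
            prev = fit.r_squared
        assert np.isclose(prev, 1.0)

    def test_orthogonality_of_inverse_columns(self):
        op = build_operator(6, Form.BACKGROUND_AVERAGED)
        gram = op.inverse.T @ op.inverse
        assert np.allclose(gram - np.diag(np.diag(gram)), 0.0, atol=1e-10)


class TestRereference:
    def test_identity_and_involution(self, random_landscape):
        assert np.array_equal(
            rereference(random_landscape, 0).phenotypes, random_landscape.phenotypes
        )
        double = rereference(rereference(random_landscape, 37), 37)
        assert np.array_equal(double.phenotypes, random_landscape.phenotypes)

    def test_reference_moves_to_origin(self):
        L = Landscape(2, [0.0, 1.0, 2.0, 3.0])
        assert rereference(L, 3).phenotypes[0] == 3.0

    def test_single_reference_transform_around_new_reference(self):
        # expansion around g0: first-order terms are neighbor differences
        L = make_random_landscape(4, 23)
        ref = 0b1010
        s = epistasis_transform(L, Form.SINGLE_REFERENCE, reference=ref)
        y = L.phenotypes
        assert np.isclose(s.terms[0], y[ref])
        for j in range(4):
            assert np.isclose(s.terms[1 << j], y[ref ^ (1 << j)] - y[ref])


@given(st.integers(0, 10_000))
@settings(max_examples=25, deadline=None)
def test_transform_linearity(seed):
    """The transform is linear: T(a*y1 + y2) = a*T(y1) + T(y2)."""
    rng = np.random.default_rng(seed)
    y1, y2 = rng.normal(size=(2, 32))
    a = float(rng.normal())
    lhs = fast_transform(a * y1 + y2, 5, Form.BACKGROUND_AVERAGED)
    rhs = a * fast_transform(y1, 5, Form.BACKGROUND_AVERAGED) + fast_transform(
        y2, 5, Form.BACKGROUND_AVERAGED
    )
    assert np.allclose(lhs, rhs, rtol=1e-9, atol=1e-9)
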