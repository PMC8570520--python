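import numpy as np
import pytest

from codondecay.counting import (
    ALL_CONTEXTS,
    BASES,
    CANONICAL_CONTEXTS,
    SubstitutionCounts,
    merge_complements,
)
from codondecay.models import (
    MutationModel,
    build_probability_model,
    k2p_model,
    lookup_row,
    stationary_vector,
    summarize_model,
)
from conftest import random_count_matrices


def uniform_counts(diagonal=90, sub=10):
    """Counts with one G->A substitution channel per context, equal rows."""
    matrices = {}
    for ctx in CANONICAL_CONTEXTS:
        m = np.eye(4, dtype=np.int64) * (diagonal + sub)
        m[2, 2] = diagonal
        m[2, 0] = sub
        matrices[ctx] = m
    return SubstitutionCounts(matrices)


class TestBuildProbabilityModel:
    def test_row_division_before_rescaling(self):
        counts = uniform_counts(diagonal=90, sub=10)
        model = build_probability_model(counts, target_max_rate=0.1)
        # target equals r_max (0.1), so the model is the plain row-normalized one
        assert model.matrices["A_A"][2, 0] == pytest.approx(0.1)
        assert model.matrices["A_A"][2, 2] == pytest.approx(0.9)
        assert model.normalization_scale == pytest.approx(1.0)

    def test_global_rescaling_preserves_relative_rates(self):
        matrices = {ctx: np.eye(4, dtype=np.int64) * 100 for ctx in CANONICAL_CONTEXTS}
        m = matrices["A_A"].copy()
        m[0] = [80, 10, 5, 5]   # off-diagonal sum 0.2 (the max)
        m[1] = [5, 90, 3, 2]    # off-diagonal sum 0.1
        matrices["A_A"] = m
        model = build_probability_model(SubstitutionCounts(matrices), 1.0)
        p = model.matrices["A_A"]
        assert p[0].sum() == pytest.approx(1.0)
        assert 1 - p[0, 0] == pytest.approx(1.0)   # fastest row scaled to target
        assert 1 - p[1, 1] == pytest.approx(0.5)   # slower row keeps the ratio
        np.testing.assert_allclose(p[0, 1:] / np.array([10, 5, 5]), 0.05)

    def test_rows_remain_stochastic(self, rng):
        counts = merge_complements(random_count_matrices(rng))
        model = build_probability_model(counts)
        for m in model.matrices.values():
            np.testing.assert_allclose(m.sum(axis=1), 1.0, atol=1e-12)

    def test_zero_row_total_raises_with_context_and_base(self):
        matrices = {ctx: np.eye(4, dtype=np.int64) * 10 for ctx in CANONICAL_CONTEXTS}
        matrices["C_G"][3, 3] = 0
        with pytest.raises(ValueError, match="C_G.*T"):
            build_probability_model(SubstitutionCounts(matrices))

    def test_no_substitutions_raises(self):
        matrices = {
            ctx: np.eye(4, dtype=np.int64) * 10 for ctx in CANONICAL_CONTEXTS
        }
        with pytest.raises(ValueError, match="no substitutions"):
            build_probability_model(SubstitutionCounts(matrices))


class TestLookupRow:
    def test_k2p_three_to_one_pattern(self, k2p):
        row = lookup_row(k2p, "C", "C", "A")
        np.testing.assert_allclose(row, [0.0, 0.2, 0.6, 0.2])

    def test_non_canonical_context_resolves_by_complement(self, context_model):
        # G_T complements to A_C; current C reads row G relabelled
        p = context_model.matrices["A_C"]
        row = lookup_row(context_model, "G", "T", "C")
        assert row[3] == pytest.approx(p[2, 0])  # P(C->T) = canonical P(G->A)
        np.testing.assert_allclose(row, p[2, ::-1])

    def test_total_and_complement_consistent_over_all_contexts(self, context_model):
        """Lookups resolve for all 16 contexts; complement pairs share one matrix.

        The relabelled-identity between a context and its complement holds for
        the 12 contexts forming complement pairs.  The four self-complementary
        contexts keep their own unsymmetrized matrix (strand-specific counts
        are not mirrored there), so the identity is not imposed on them.
        """
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        from codondecay.counting import SELF_COMPLEMENTARY

        for five in BASES:
            for three in BASES:
                for cur in BASES:
                    row = lookup_row(context_model, five, three, cur)
                    assert row.shape == (4,)
                    assert row.sum() == pytest.approx(1.0)
                    if f"{five}_{three}" in SELF_COMPLEMENTARY:
                        continue
                    mirror = lookup_row(
                        context_model, comp[three], comp[five], comp[cur]
                    )
                    np.testing.assert_allclose(row, mirror[::-1])


class TestStationaryVector:
    def test_k2p_is_uniform(self, k2p):
        pi = stationary_vector(k2p.matrices["A_A"])
        np.testing.assert_allclose(pi, 0.25, atol=1e-12)

    def test_two_state_closed_form(self):
        a, b = 0.3, 0.12
        chain = np.array([[1 - a, a], [b, 1 - b]])
        pi = stationary_vector(chain)
        assert pi[0] / pi[1] == pytest.approx(b / a, rel=1e-8)

    def test_matches_eigenvector_oracle(self, rng):
        for _ in range(100):
            m = rng.dirichlet(np.ones(4) * 2, size=4)
            pi = stationary_vector(m)
            vals, vecs = np.linalg.eig(m.T)
            lead = vecs[:, np.argmin(np.abs(vals - 1.0))].real
            lead /= lead.sum()
            np.testing.assert_allclose(pi, lead, atol=1e-8)

    def test_periodic_chain_raises(self):
        flip = np.array([[0.0, 1.0], [1.0, 0.0]])
        with pytest.raises(RuntimeError, match="converge"):
            stationary_vector(flip)

    def test_satisfies_pi_p_equals_pi(self, context_model):
        for m in context_model.matrices.values():
            pi = stationary_vector(m)
            np.testing.assert_allclose(pi @ m, pi, atol=1e-8)


class TestSummarizeModel:
    def test_ratio_and_rate_examples(self):
        matrices = {ctx: np.eye(4, dtype=np.int64) * 100 for ctx in CANONICAL_CONTEXTS}
        m = matrices["A_A"].copy()
        # from ancestral G: 6 transitions (G->A) and 2 transversions (G->C)
        m[2] = [6, 2, 92, 0]
        matrices["A_A"] = m
        counts = SubstitutionCounts(matrices)
        model = build_probability_model(counts)
        summary = summarize_model(counts, model)
        assert summary.loc["A_A", "ts_tv_gc"] == pytest.approx(3.0)
        # 8 substitutions over 400 sites
        assert summary.loc["A_A", "sub_rate_per100"] == pytest.approx(2.0)

    def test_sub_rate_footnote_example(self):
        matrices = {ctx: np.eye(4, dtype=np.int64) * 25 for ctx in CANONICAL_CONTEXTS}
        m = matrices["A_T"].copy()
        m[0, 2] = 1
        m[0, 0] = 24  # 100 sites total, 1 substitution
        matrices["A_T"] = m
        counts = SubstitutionCounts(matrices)
        summary = summarize_model(counts, build_probability_model(counts))
        assert summary.loc["A_T", "sub_rate_per100"] == pytest.approx(1.0)

    def test_skews_from_known_stationary_vector(self):
        pi = np.array([0.3, 0.25, 0.2, 0.25])
        matrices = {ctx: np.tile(pi, (4, 1)) for ctx in CANONICAL_CONTEXTS}
        model = MutationModel(matrices, kind="synthetic")
        counts = uniform_counts()
        summary = summarize_model(counts, model)
        assert summary.loc["C_C", "equil_gc"] == pytest.approx(45.0)
        assert summary.loc["C_C", "equil_cg_skew"] == pytest.approx(100 * 0.05 / 0.45)
        assert summary.loc["C_C", "equil_ta_skew"] == pytest.approx(-100 * 0.05 / 0.55)

    def test_undefined_ratios_reported_as_nan(self):
        counts = uniform_counts()  # only G->A: transitions only, GC-ancestral only
        summary = summarize_model(counts, build_probability_model(counts))
        assert np.isnan(summary.loc["A_A", "ts_tv_gc"])  # no transversions
        assert np.isnan(summary.loc["A_A", "ts_tv_at"])  # no A/T substitutions


class TestModelSerialization:
    def test_json_round_trip(self, context_model):
        back = MutationModel.from_json(context_model.to_json())
        assert back.kind == context_model.kind
        for ctx in CANONICAL_CONTEXTS:
            np.testing.assert_array_equal(
                back.matrices[ctx], context_model.matrices[ctx]
            )

    def test_external_matrices_loadable(self):
        """The loader accepts any externally estimated row-stochastic matrices."""
        payload = k2p_model().to_json().replace('"K2P"', '"MC"')
        model = MutationModel.from_json(payload)
        assert model.kind == "MC"
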