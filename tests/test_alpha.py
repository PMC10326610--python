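"""Alpha-diversity estimators and McNaughton dominance screening."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ednadiv import (
    CommunityMatrix,
    alpha_table,
    chao1,
    dominant_taxa,
    goods_coverage,
    mcnaughton,
    pielou,
    shannon,
    simpson,
)
from ednadiv.alpha import simpson_probability

count_vectors = st.lists(
    st.integers(min_value=0, max_value=500), min_size=1, max_size=30
).filter(lambda v: sum(v) > 0)


class TestScalarEstimators:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ([5, 5, 5], 3.0),  # no singletons: estimate = observed richness
            ([1, 1, 2, 3], 4.5),  # n1=2, n2=1: 4 + 2*1/(2*2)
            ([1], 1.0),  # lone singleton: correction term vanishes
        ],
    )
    def test_chao1(self, counts, expected):
        assert chao1(counts) == pytest.approx(expected)

    def test_chao1_classic_form(self):
        # n1=2, n2=1: 4 + 4/2 = 6
        assert chao1([1, 1, 2, 3], bias_corrected=False) == pytest.approx(6.0)
        with pytest.raises(ZeroDivisionError):
            chao1([1, 3, 3], bias_corrected=False)

    @pytest.mark.parametrize(
        "counts, expected",
        [
            ([10], 0.0),
            ([7, 7, 7, 7], math.log(4)),
            ([1, 1, 2], 1.0397207708399179),
        ],
    )
    def test_shannon(self, counts, expected):
        assert shannon(counts) == pytest.approx(expected, abs=1e-9)

    def test_shannon_base_option(self):
        assert shannon([2, 2], base=2) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "counts, expected",
        [
            ([9], 1.0),  # single species: minimal diversity
            ([1, 1, 1], 0.0),  # all singletons
            ([2, 2], 4 / 12),
        ],
    )
    def test_simpson(self, counts, expected):
        assert simpson(counts) == pytest.approx(expected)

    def test_simpson_probability_form_differs_at_finite_n(self):
        counts = [2, 2]
        assert simpson_probability([0.5, 0.5]) == pytest.approx(0.5)
        assert simpson(counts) < simpson_probability([0.5, 0.5])

    @pytest.mark.parametrize(
        "counts, expected",
        [
            ([4, 4, 4], 1.0),
            ([1, 1, 2], 1.0397207708399179 / math.log(3)),
        ],
    )
    def test_pielou(self, counts, expected):
        assert pielou(counts) == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize(
        "counts, expected",
        [
            ([5, 5], 1.0),  # no singletons
            ([1, 1, 8], 0.8),  # 1 - 2/10
            ([1], 0.0),
        ],
    )
    def test_goods_coverage(self, counts, expected):
        assert goods_coverage(counts) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "fn, counts",
        [
            (chao1, [0, 0]),
            (shannon, [0]),
            (simpson, [1]),  # N < 2
            (pielou, [9]),  # S_obs < 2
        ],
    )
    def test_degenerate_inputs_rejected(self, fn, counts):
        with pytest.raises(ValueError):
            fn(counts)


class TestEstimatorProperties:
    @settings(max_examples=200, deadline=None)
    @given(count_vectors)
    def test_chao1_at_least_observed_richness(self, counts):
        s_obs = sum(1 for c in counts if c > 0)
        est = chao1(counts)
        assert est >= s_obs - 1e-12
        n1 = sum(1 for c in counts if c == 1)
        if n1 * (n1 - 1) == 0:
            assert est == pytest.approx(s_obs)

    @settings(max_examples=100, deadline=None)
    @given(count_vectors.filter(lambda v: sum(1 for c in v if c > 0) >= 2))
    def test_shannon_bounded_by_log_richness(self, counts):
        s_obs = sum(1 for c in counts if c > 0)
        assert -1e-12 <= shannon(counts) <= math.log(s_obs) + 1e-12

    def test_shannon_maximal_at_uniformity(self, rng):
        uniform = [20] * 8
        h_max = shannon(uniform)
        assert h_max == pytest.approx(math.log(8))
        for _ in range(20):
            skew = rng.multinomial(160, rng.dirichlet(np.ones(8) * 0.3))
            if (skew > 0).sum() == 8 and np.ptp(skew) > 0:
                assert shannon(skew) < h_max

    @settings(max_examples=100, deadline=None)
    @given(
        count_vectors.filter(lambda v: sum(1 for c in v if c > 0) >= 2),
        st.integers(min_value=2, max_value=7),
    )
    def test_pielou_invariant_under_count_scaling(self, counts, factor):
        scaled = [c * factor for c in counts]
        assert pielou(scaled) == pytest.approx(pielou(counts), abs=1e-9)

    def test_chao1_recovers_uniform_richness(self, rng):
        # multinomial samples from a uniform 20-species community at
        # depth 50*S: mean estimate within 5% of the true richness
        s_true, depth, n_rep = 20, 1000, 200
        p = np.ones(s_true) / s_true
        estimates = [
            chao1(rng.multinomial(depth, p)) for _ in range(n_rep)
        ]
        assert abs(np.mean(estimates) - s_true) / s_true < 0.05


class TestCrossCheckAgainstSkbio:
    """Independent oracle: scikit-bio's implementations."""

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_chao1_shannon_coverage_match(self, seed):
        skbio_alpha = pytest.importorskip("skbio.diversity.alpha")
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 40, size=25)
        counts[0] = 1  # ensure singletons exist
        assert chao1(counts) == pytest.approx(
            float(skbio_alpha.chao1(counts, bias_corrected=True))
        )
        assert shannon(counts) == pytest.approx(
            float(skbio_alpha.shannon(counts, base=math.e))
        )
        assert goods_coverage(counts) == pytest.approx(
            float(skbio_alpha.goods_coverage(counts))
        )


class TestAlphaTable:
    def test_one_record_per_section(self, survey_matrix):
        records = alpha_table(survey_matrix)
        assert [r.sample_id for r in records] == survey_matrix.sample_ids
        assert len(records) == 12

    def test_fields_equal_scalar_calls(self, small_matrix):
        for rec in alpha_table(small_matrix):
            counts = small_matrix.sample(rec.sample_id)
            assert rec.chao1 == pytest.approx(chao1(counts))
            assert rec.shannon == pytest.approx(shannon(counts))
            assert rec.simpson == pytest.approx(simpson(counts))
            assert rec.coverage == pytest.approx(goods_coverage(counts))
            assert rec.pielou == pytest.approx(pielou(counts))
            assert rec.s_obs == (counts > 0).sum()

    def test_taxon_order_invariance(self, survey_matrix):
        base = alpha_table(survey_matrix)
        shuffled = CommunityMatrix(
            survey_matrix.counts.sample(frac=1, random_state=3),
            survey_matrix.samples,
        )
        for a, b in zip(alpha_table(shuffled), base):
            assert a.sample_id == b.sample_id
            assert (a.s_obs, a.n1, a.n2, a.n_total) == (b.s_obs, b.n1, b.n2, b.n_total)
            for fld in ("chao1", "shannon", "simpson", "pielou", "coverage"):
                assert getattr(a, fld) == pytest.approx(
                    getattr(b, fld), abs=1e-12, nan_ok=True
                )

    def test_single_taxon_sample_gets_nan_pielou(self):
        m = CommunityMatrix(pd.DataFrame({"s1": [5, 5], "s2": [9, 0]},
                                         index=["a", "b"]))
        recs = alpha_table(m)
        assert recs[0].pielou == pytest.approx(1.0)
        assert math.isnan(recs[1].pielou)

    def test_error_annotated_with_sample(self):
        m = CommunityMatrix(pd.DataFrame({"s1": [5], "s2": [1]}, index=["a"]))
        with pytest.raises(ValueError, match="s2"):
            alpha_table(m)  # Simpson needs N >= 2 in s2


class TestMcNaughton:
    def test_printed_dominance_values_reproduce(self, survey):
        matrix, records = survey
        by_species = {r.species: r.taxon_id for r in records}
        doms = {d.taxon_id: d for d in mcnaughton(matrix)}
        # species spanning full, 11/12, and half presence
        expected = {
            "H. tchangi": (0.41719473, 1.0),
            "D. rerio": (0.00015320, 11 / 12),
            "M. asiaticus": (0.00000176, 6 / 12),
        }
        for species, (y, f) in expected.items():
            rec = doms[by_species[species]]
            assert rec.f_i == pytest.approx(f)
            assert rec.y == pytest.approx(y, abs=1e-8)

    def test_single_ubiquitous_taxon(self):
        m = CommunityMatrix(
            pd.DataFrame({"s1": [3], "s2": [5]}, index=["a"])
        )
        rec = mcnaughton(m)[0]
        assert rec.y == pytest.approx(1.0)
        assert rec.dominant

    def test_relative_abundances_sum_to_one(self, survey_matrix):
        doms = mcnaughton(survey_matrix)
        assert sum(d.n_i / d.n_total for d in doms) == pytest.approx(1.0)

    def test_y_bounded_by_abundance_and_frequency(self, survey_matrix):
        for d in mcnaughton(survey_matrix):
            assert d.y <= d.n_i / d.n_total + 1e-15
            assert d.y <= d.f_i + 1e-15

    def test_threshold_is_strict(self):
        counts = pd.DataFrame({"s1": [2, 98]}, index=["a", "b"])
        recs = mcnaughton(CommunityMatrix(counts), threshold=0.02)
        by_id = {r.taxon_id: r for r in recs}
        assert by_id["a"].y == pytest.approx(0.02)
        assert not by_id["a"].dominant  # exactly at threshold: not dominant
        assert by_id["b"].dominant


class TestDominantTaxa:
    def test_fixture_dominant_set(self, survey):
        matrix, records = survey
        names = {r.taxon_id: r.species for r in records}
        doms = dominant_taxa(mcnaughton(matrix))
        assert [names[t] for t in doms] == [
            "H. tchangi",
            "C. carpio",
            "R.cliffordpopei",
            "O. bidens",
            "I. punctatus",
            "C. zillii",
        ]

    def test_empty_when_nothing_dominant(self):
        m = CommunityMatrix(
            pd.DataFrame({"s1": np.ones(60, dtype=int)},
                         index=[f"t{i}" for i in range(60)])
        )
        assert dominant_taxa(mcnaughton(m)) == []

    def test_constructed_hyperdominant_first(self):
        counts = pd.DataFrame(
            {"s1": [990, 5, 5], "s2": [990, 5, 5]}, index=["big", "x", "y"]
        )
        doms = dominant_taxa(mcnaughton(CommunityMatrix(counts)))
        assert doms[0] == "big"
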