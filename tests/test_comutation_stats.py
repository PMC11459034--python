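"""Fisher co-mutation statistics, background rates, spectra, correlations."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from compmut.comutation_stats import (
    ContingencyTable,
    EmptyStratumError,
    SUBSTITUTION_CLASSES,
    ZeroVarianceError,
    complementary_relationship,
    compute_background_rate,
    fisher_exact,
    substitution_spectrum,
)
from compmut.comutation_stats import test_comutations as run_comutation_tests
from compmut.composite_caller import call_composites, extract_driver_events
from compmut.io_formats import ValidationError, load_cohort
from compmut.synthetic_data import default_layout

from oracles import fisher_two_sided_oracle, pearson_r_closed_form


class TestFisherExact:
    def test_identical_proportions_give_p_one(self):
        p, odds = fisher_exact(ContingencyTable(5, 5, 5, 5))
        assert p == pytest.approx(1.0)
        assert odds == pytest.approx(1.0)

    def test_small_table_matches_enumeration(self):
        p, _ = fisher_exact(ContingencyTable(3, 1, 1, 5))
        assert p == pytest.approx(fisher_two_sided_oracle(3, 1, 1, 5), abs=1e-12)

    def test_perfect_separation_matches_enumeration(self):
        p, odds = fisher_exact(ContingencyTable(10, 0, 0, 10))
        assert p == pytest.approx(2 / math.comb(20, 10), abs=1e-12)
        assert math.isinf(odds)

    def test_degenerate_column_margin_gives_p_one(self):
        p, odds = fisher_exact(ContingencyTable(0, 5, 0, 5))
        assert p == 1.0
        assert math.isnan(odds)

    def test_zero_group_margin_rejected(self):
        with pytest.raises(ValidationError):
            fisher_exact(ContingencyTable(0, 0, 3, 4))

    def test_negative_count_rejected(self):
        with pytest.raises(ValidationError):
            ContingencyTable(-1, 1, 1, 1)

    @settings(max_examples=300, derandomize=True, deadline=None)
    @given(
        a=st.integers(0, 15),
        b=st.integers(0, 15),
        c=st.integers(0, 15),
        d=st.integers(0, 15),
    )
    def test_matches_enumeration_oracle(self, a, b, c, d):
        if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
            return
        p, _ = fisher_exact(ContingencyTable(a, b, c, d))
        assert p == pytest.approx(fisher_two_sided_oracle(a, b, c, d), abs=1e-9)

    def test_planted_odds_ratio_power(self):
        """An odds ratio of 8 with 30 composite vs 300 non-composite samples
        is detected at P<0.05 in at least 80% of simulations."""
        rng = np.random.default_rng(42)
        p0 = 0.1
        p1 = 8 * p0 / (1 - p0 + 8 * p0)
        detected = 0
        n_sim = 100
        for _ in range(n_sim):
            a = int(rng.binomial(30, p1))
            c = int(rng.binomial(300, p0))
            p, _ = fisher_exact(ContingencyTable(a, 30 - a, c, 300 - c))
            detected += p < 0.05
        assert detected / n_sim >= 0.80


class TestBackgroundRate:
    def _cohort_with_frequencies(self):
        # 10 lung samples; G1 mutated in 1, G2 in 2, G3 in 3 -> median 0.2
        samples = pd.DataFrame(
            {
                "sample_id": [f"S{i}" for i in range(10)],
                "tumor_type": "lung",
                "source": "tissue",
            }
        )
        annotations = pd.DataFrame(
            [
                ("G1", "oncogene", "1", 100, 200),
                ("G2", "oncogene", "2", 100, 200),
                ("G3", "oncogene", "3", 100, 200),
            ],
            columns=["symbol", "role", "chromosome", "start", "end"],
        )
        rows = []
        for gene, k in (("G1", 1), ("G2", 2), ("G3", 3)):
            for i in range(k):
                rows.append((f"S{i}", gene, f"A{100+i}T", annotations.set_index("symbol").loc[gene, "chromosome"], 150, "C", "T"))
        mutations = pd.DataFrame(
            rows,
            columns=["sample_id", "gene", "protein_change", "chromosome", "position", "ref_allele", "alt_allele"],
        )
        from compmut.io_formats import HotspotCatalog

        return load_cohort(
            maf=mutations,
            cnv=pd.DataFrame(columns=["sample_id", "gene", "call"]),
            annotations=annotations,
            hotspots=HotspotCatalog.from_pairs([("G1", "A100T")]),
            samples=samples,
            layout=default_layout(),
        )

    def test_median_and_multiplier(self):
        cohort = self._cohort_with_frequencies()
        rate = compute_background_rate(cohort, "lung")
        assert rate.background_rate == pytest.approx(0.2)
        assert rate.threshold == pytest.approx(0.208)
        assert rate.threshold / rate.background_rate == pytest.approx(1.04)

    def test_uniform_frequency(self):
        cohort = self._cohort_with_frequencies()
        # mean statistic on the same stratum: (0.1+0.2+0.3)/3 = 0.2 as well
        rate = compute_background_rate(cohort, "lung", statistic="mean")
        assert rate.threshold == pytest.approx(1.04 * 0.2)

    def test_empty_stratum_raises(self):
        cohort = self._cohort_with_frequencies()
        with pytest.raises(EmptyStratumError):
            compute_background_rate(cohort, "bone")


class TestComutationSelection:
    def test_extreme_separation_is_significant(self, demo_cohort):
        # build a stratum by hand: 10 composite all carrying the co-gene,
        # 40 non-composite none -> Fisher p tiny
        p, odds = fisher_exact(ContingencyTable(10, 0, 0, 40))
        assert p < 1e-8 and math.isinf(odds)

    def test_results_internally_consistent_with_fisher(self, demo_cohort):
        events = extract_driver_events(demo_cohort)
        calls = call_composites(events, demo_cohort.annotations)
        res = run_comutation_tests(demo_cohort, calls, "BRAF", "skin", events=events)
        for _, row in res.iterrows():
            p, odds = fisher_exact(
                ContingencyTable(row["a"], row["b"], row["c"], row["d"])
            )
            assert row["p_value"] == pytest.approx(p)
            assert row["freq_composite"] == pytest.approx(row["a"] / (row["a"] + row["b"]))

    def test_composite_gene_not_among_candidates(self, demo_cohort):
        events = extract_driver_events(demo_cohort)
        calls = call_composites(events, demo_cohort.annotations)
        res = run_comutation_tests(demo_cohort, calls, "BRAF", "skin", events=events)
        assert "BRAF" not in set(res["co_gene"])

    def test_empty_stratum_typed_error(self, demo_cohort):
        events = extract_driver_events(demo_cohort)
        calls = call_composites(events, demo_cohort.annotations)
        with pytest.raises(EmptyStratumError):
            run_comutation_tests(demo_cohort, calls, "BRAF", "lung", events=events)


class TestComplementaryRelationship:
    def test_identical_vectors_give_r_one(self):
        df = pd.DataFrame(
            {"freq_noncomposite": [0.1, 0.2, 0.3, 0.4], "freq_composite": [0.1, 0.2, 0.3, 0.4]}
        )
        fit = complementary_relationship(df)
        assert fit.pearson_r == pytest.approx(1.0)
        assert fit.slope == pytest.approx(1.0)

    def test_constant_vector_raises_zero_variance(self):
        df = pd.DataFrame(
            {"freq_noncomposite": [0.1, 0.2, 0.3], "freq_composite": [0.2, 0.2, 0.2]}
        )
        with pytest.raises(ZeroVarianceError):
            complementary_relationship(df)

    def test_too_few_pairs_raises(self):
        df = pd.DataFrame({"freq_noncomposite": [0.1, 0.2], "freq_composite": [0.3, 0.1]})
        with pytest.raises(ValidationError):
            complementary_relationship(df)

    def test_five_pair_toy_matches_closed_form(self):
        x = np.array([0.05, 0.10, 0.22, 0.31, 0.44])
        y = np.array([0.07, 0.12, 0.19, 0.33, 0.41])
        fit = complementary_relationship(
            pd.DataFrame({"freq_noncomposite": x, "freq_composite": y})
        )
        assert fit.pearson_r == pytest.approx(pearson_r_closed_form(x, y), abs=1e-12)
        assert fit.n_pairs == 5

    def test_recovers_planted_correlation(self):
        """Mean estimated r over 100 replicates of 50 frequency pairs lies
        within 0.05 of the planted correlation."""
        rho = 0.6
        rng = np.random.default_rng(11)
        cov = np.array([[1.0, rho], [rho, 1.0]])
        estimates = []
        for _ in range(100):
            z = rng.multivariate_normal([0, 0], cov, size=50)
            x = 0.2 + 0.04 * z[:, 0]
            y = 0.2 + 0.04 * z[:, 1]
            fit = complementary_relationship(
                pd.DataFrame({"freq_noncomposite": x, "freq_composite": y})
            )
            estimates.append(fit.pearson_r)
        assert abs(np.mean(estimates) - rho) < 0.05


class TestSubstitutionSpectrum:
    def _frame(self, pairs):
        return pd.DataFrame(
            [("S1", "G", "A1B", "1", 100, r, a) for r, a in pairs],
            columns=["sample_id", "gene", "protein_change", "chromosome", "position", "ref_allele", "alt_allele"],
        )

    def test_all_c_to_t(self):
        spec = substitution_spectrum(self._frame([("C", "T")] * 4))
        assert spec.fractions["C>T"] == pytest.approx(1.0)

    def test_purine_reference_complemented(self):
        spec = substitution_spectrum(self._frame([("G", "A")]))
        assert spec.fractions["C>T"] == pytest.approx(1.0)
        spec = substitution_spectrum(self._frame([("T", "G")]))
        assert spec.fractions["A>C"] == pytest.approx(1.0)

    def test_mixed_ten_records_match_hand_counts(self):
        pairs = [
            ("C", "T"), ("C", "T"), ("G", "A"),     # 3x C>T
            ("C", "A"), ("G", "T"),                 # 2x C>A
            ("A", "G"), ("T", "C"),                 # 2x A>G
            ("A", "T"),                             # 1x A>T
            ("C", "G"),                             # 1x C>G
            ("A", "C"),                             # 1x A>C
        ]
        spec = substitution_spectrum(self._frame(pairs))
        assert spec.n_snv == 10
        assert spec.fractions["C>T"] == pytest.approx(0.3)
        assert spec.fractions["C>A"] == pytest.approx(0.2)
        assert spec.fractions["A>G"] == pytest.approx(0.2)
        assert spec.fractions["A>T"] == pytest.approx(0.1)
        assert spec.fractions["C>G"] == pytest.approx(0.1)
        assert spec.fractions["A>C"] == pytest.approx(0.1)

    def test_non_snv_skipped_with_count(self):
        frame = self._frame([("C", "T"), ("CA", "T"), ("C", "N")])
        spec = substitution_spectrum(frame)
        assert spec.n_skipped == 2
        assert spec.n_snv == 1

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.sampled_from(["A", "C", "G", "T"]), min_size=2, max_size=30))
    def test_fractions_sum_to_one(self, refs):
        rng = np.random.default_rng(len(refs))
        pairs = []
        for r in refs:
            alts = [b for b in "ACGT" if b != r]
            pairs.append((r, alts[int(rng.integers(3))]))
        spec = substitution_spectrum(self._frame(pairs))
        assert sum(spec.fractions.values()) == pytest.approx(1.0, abs=1e-12)
        assert set(spec.fractions) == set(SUBSTITUTION_CLASSES)
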