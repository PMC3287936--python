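"""Window construction, carrier indicators and 2x2 association tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rarepath.collapsing import (
    carrier_status,
    carrier_test,
    collapsing_scan,
    make_windows,
    single_snp_test,
)
from rarepath.experiments import fisher_two_sided_oracle
from rarepath.synthetic_data import (
    ConfigurationError,
    GeneAnnotation,
    GenotypeMatrix,
    SimConfig,
    simulate_cohort,
)


def _matrix(dosages):
    d = np.asarray(dosages, dtype=np.int8)
    return GenotypeMatrix(d, [f"s{i}" for i in range(d.shape[0])],
                          [f"v{j}" for j in range(d.shape[1])])


class TestMakeWindows:
    def test_tiling_arithmetic(self):
        genes = [GeneAnnotation("G1", "1", 0, 12000)]
        wins = make_windows(genes, 5000, 2500)
        assert [w.start for w in wins] == [0, 2500, 5000, 7500, 10000]
        assert wins[-1].end == 12000  # truncated at the span end

    def test_span_shorter_than_size_gives_one_window(self):
        wins = make_windows([GeneAnnotation("G1", "1", 100, 2100)], 5000, 2500)
        assert [(w.start, w.end) for w in wins] == [(0, 2100)]

    def test_step_larger_than_size_rejected(self):
        with pytest.raises(ConfigurationError):
            make_windows([GeneAnnotation("G1", "1", 0, 1000)], 100, 200)

    def test_every_variant_covered_and_twice_with_half_step(self, rng):
        pos = np.sort(rng.integers(0, 50_000, size=300))
        genes = [GeneAnnotation("G1", "1", 0, 50_000)]
        wins = make_windows(genes, 5000, 2500, positions={"1": pos})
        counts = np.array([sum(w.start <= p < w.end for w in wins)
                           for p in pos])
        assert (counts >= 1).all()
        interior = (pos >= 2500) & (pos < wins[-1].start + 2500)
        assert (counts[interior] >= 2).all()

    def test_gene_overlap_annotation_requires_one_bp(self):
        genes = [GeneAnnotation("GA", "1", 8999, 20000),
                 GeneAnnotation("GB", "1", 9000, 20000)]
        wins = make_windows(genes, 9000, 9000, positions={"1": np.array([0, 19999])})
        first = wins[0]  # [0, 9000): touches GA by 1 bp, misses GB
        assert first.gene_overlaps == ("GA",)


class TestCarrierStatus:
    def test_indicator_logic_and_maf_threshold(self):
        # v0 rare het carrier; v1 has MAF 0.06 > 0.05 so it never counts
        n = 50
        dos = np.zeros((n, 2), dtype=np.int8)
        dos[0, 0] = 1          # subject 0 carries the rare variant
        dos[1:7, 1] = 1        # 6/100 alleles -> MAF 0.06 at v1
        g = _matrix(dos)
        carriers = carrier_status(g, ["v0", "v1"], maf_max=0.05)
        assert carriers[0] == 1
        assert carriers[1] == 0          # its only minor allele is at v1
        assert carriers[2:].sum() == 0

    def test_empty_rare_set_returns_none(self):
        dos = np.ones((10, 1), dtype=np.int8)  # MAF 0.5
        assert carrier_status(_matrix(dos), ["v0"], maf_max=0.05) is None

    def test_missing_dosage_counts_as_noncarrier(self):
        dos = np.zeros((40, 1), dtype=np.int8)
        dos[0, 0] = -1
        dos[1, 0] = 1
        carriers = carrier_status(_matrix(dos), ["v0"], maf_max=0.5)
        assert carriers[0] == 0 and carriers[1] == 1


class TestCarrierTest:
    def test_equal_proportions_give_p_one(self):
        carriers = np.array([1] * 10 + [0] * 90 + [1] * 20 + [0] * 180)
        affected = np.array([1] * 100 + [0] * 200)
        res = carrier_test(carriers, affected)
        assert res.test_used == "chisq"
        assert res.p_value == pytest.approx(1.0)

    def test_small_cells_fall_back_to_fisher(self):
        carriers = np.array([1] * 5 + [0] * 95 + [1] * 1 + [0] * 199)
        affected = np.array([1] * 100 + [0] * 200)
        res = carrier_test(carriers, affected)
        assert res.test_used == "fisher"
        # frozen from the exhaustive hypergeometric enumeration oracle
        assert res.p_value == pytest.approx(0.016877, abs=1e-6)
        assert res.p_value == pytest.approx(
            fisher_two_sided_oracle(5, 95, 1, 199), abs=1e-12)

    def test_degenerate_margins_are_untestable(self):
        affected = np.array([1] * 5 + [0] * 5)
        res = carrier_test(np.ones(10, dtype=int), affected)
        assert res.p_value is None and res.test_used == "none"
        res = carrier_test(np.zeros(10, dtype=int), affected)
        assert res.p_value is None

    def test_one_affected_class_is_an_error(self):
        with pytest.raises(ConfigurationError):
            carrier_test(np.array([0, 1]), np.array([1, 1]))

    @given(st.integers(0, 25), st.integers(0, 25),
           st.integers(0, 25), st.integers(0, 25))
    @settings(deadline=None, max_examples=150)
    def test_fisher_branch_matches_enumeration_oracle(self, a, b, c, d):
        if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
            return
        carriers = np.array([1] * a + [0] * b + [1] * c + [0] * d)
        affected = np.array([1] * (a + b) + [0] * (c + d))
        res = carrier_test(carriers, affected)
        if res.test_used == "fisher":
            assert res.p_value == pytest.approx(
                fisher_two_sided_oracle(a, b, c, d), abs=1e-9)

    def test_chisq_and_fisher_agree_on_large_expected_counts(self, rng):
        from scipy.stats import fisher_exact
        # asymptotic equivalence of the two branches: the worst-case gap
        # between chi-square and two-sided Fisher p-values shrinks like
        # n^-1/2 (measured: ~0.045 at margins 600/900, ~0.019 at 3000/4500),
        # so the 0.02 agreement bound is checked in the converged regime
        for _ in range(40):
            n1, n2 = 3000, 4500
            p0 = rng.uniform(0.3, 0.7)
            a = int(rng.binomial(n1, p0))
            c = int(rng.binomial(n2, p0))
            res = carrier_test(
                np.array([1] * a + [0] * (n1 - a) + [1] * c + [0] * (n2 - c)),
                np.array([1] * n1 + [0] * n2))
            assert res.test_used == "chisq"
            p_f = fisher_exact([[a, n1 - a], [c, n2 - c]])[1]
            assert abs(res.p_value - p_f) <= 0.02


class TestSingleSnp:
    def test_proportional_allele_counts_give_p_one(self):
        dos = np.array([2] * 10 + [0] * 90 + [2] * 20 + [0] * 180, dtype=np.int8)
        affected = np.array([1] * 100 + [0] * 200)
        res = single_snp_test(dos, affected)
        assert res.p_value == pytest.approx(1.0)

    def test_allelic_table_matches_textbook_chi_square(self):
        from scipy.stats import chi2
        # cases: 15 hom alt of 100 -> 30/170; controls: 20 het of 200 -> 20/380
        dos = np.array([2] * 15 + [0] * 85 + [1] * 20 + [0] * 180, dtype=np.int8)
        affected = np.array([1] * 100 + [0] * 200)
        res = single_snp_test(dos, affected)
        t = np.array([[30, 170], [20, 380]], dtype=float)
        e = np.outer(t.sum(1), t.sum(0)) / t.sum()
        stat = ((t - e) ** 2 / e).sum()
        assert res.table == (30, 170, 20, 380)
        assert res.p_value == pytest.approx(chi2.sf(stat, 1))

    def test_monomorphic_is_untestable(self):
        res = single_snp_test(np.zeros(50, dtype=np.int8),
                              np.array([1] * 20 + [0] * 30))
        assert res.p_value is None


class TestScan:
    def test_unit_counts_match_window_arithmetic(self, default_cohort):
        res = collapsing_scan(default_cohort, window_sizes_kb=(5,))
        genes = default_cohort.genes
        span = max(g.end for g in genes)
        pos = [v.pos for v in default_cohort.variants]
        lo, hi = min(pos), max(pos) + 1
        first = (lo // 2500) * 2500
        expected = len(range(first, hi, 2500))
        assert len(res["window_5kb"]) == expected

    def test_zero_rare_variants_makes_all_units_untestable(self):
        from rarepath.collapsing import sample_maf
        cohort = simulate_cohort(SimConfig(
            seed=2, n_genes=20, n_sets=2, genes_per_set=5, n_causal_genes=2,
            rare_fraction=0.0, very_rare_fraction=0.0))
        # drop the occasional variant whose realized MAF dipped below 0.05
        maf = sample_maf(cohort.genotypes)
        g = cohort.genotypes.subset_variants(np.where(maf >= 0.05)[0])
        res = collapsing_scan(cohort, genotypes=g, window_sizes_kb=(5,),
                              include_snp=False)
        assert res["gene"]["p_value"].isna().all()
        assert res["window_5kb"]["p_value"].isna().all()
        assert (res["gene"]["test_used"] == "none").all()

    def test_strong_causal_gene_power(self):
        # carrier frequency 15% in 209 cases vs 5% in 488 controls: the
        # Monte-Carlo power of the carrier test at alpha=0.001 is ~0.86
        # (normal approximation ~0.87), so well above 0.80
        hits = 0
        N = 300
        rng = np.random.default_rng(900)
        affected = np.array([1] * 209 + [0] * 488)
        for _ in range(N):
            carriers = np.concatenate([
                rng.binomial(1, 0.15, 209), rng.binomial(1, 0.05, 488)])
            res = carrier_test(carriers, affected)
            hits += res.p_value < 0.001
        assert hits / N >= 0.80

    def test_power_nondecreasing_in_carrier_effect(self):
        mean_causal_p = []
        for effect in (0.0, 1.0, 2.0):
            ps = []
            for s in range(3):
                cohort = simulate_cohort(SimConfig(seed=300 + s,
                                                   carrier_effect=effect))
                res = collapsing_scan(cohort, window_sizes_kb=(),
                                      include_snp=False)
                gene_res = res["gene"].set_index("unit_id")
                causal = [g for g in cohort.truth["causal_genes"]
                          if g in gene_res.index
                          and not np.isnan(gene_res.loc[g, "p_value"])]
                ps += [gene_res.loc[g, "p_value"] for g in causal]
            mean_causal_p.append(np.mean(ps))
        assert mean_causal_p[0] > mean_causal_p[1] > mean_causal_p[2]
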