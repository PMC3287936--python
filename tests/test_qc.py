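"""HWE filtering, LD pruning and IBS-MDS behaviour."""

from itertools import permutations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2

from rarepath.qc import (
    hwe_filter,
    hwe_test,
    ibs_distance_matrix,
    mds_components,
    prune_correlated,
)
from rarepath.synthetic_data import (
    ConfigurationError,
    GenotypeMatrix,
    SimConfig,
    simulate_cohort,
)


def _matrix(dosages):
    d = np.asarray(dosages, dtype=np.int8)
    return GenotypeMatrix(d, [f"s{i}" for i in range(d.shape[0])],
                          [f"v{j}" for j in range(d.shape[1])])


class TestHweTest:
    def test_exact_hwe_counts_give_p_one(self):
        assert hwe_test(25, 50, 25) == 1.0

    def test_monomorphic_convention(self):
        assert hwe_test(100, 0, 0) == 1.0
        assert hwe_test(0, 0, 100) == 1.0

    def test_known_statistic(self):
        # counts (10,10,10): statistic 10/3 on 1 df
        assert hwe_test(10, 10, 10) == pytest.approx(chi2.sf(10 / 3, 1))
        assert hwe_test(10, 10, 10) == pytest.approx(0.0679, abs=2e-4)

    def test_zero_total_is_an_error(self):
        with pytest.raises(ValueError):
            hwe_test(0, 0, 0)

    @given(st.integers(0, 200), st.integers(0, 200), st.integers(0, 200))
    @settings(deadline=None, max_examples=200)
    def test_p_value_bounds(self, a, b, c):
        if a + b + c == 0:
            return
        assert 0.0 <= hwe_test(a, b, c) <= 1.0

    def test_null_rejection_rate_is_calibrated(self, rng):
        # genotypes drawn exactly under HWE: rejection at 0.05 near nominal
        n, m = 500, 10_000
        p = rng.uniform(0.1, 0.5, size=m)
        dos = rng.binomial(2, p[None, :], size=(n, m)).astype(np.int8)
        n0 = (dos == 0).sum(axis=0)
        n1 = (dos == 1).sum(axis=0)
        n2 = (dos == 2).sum(axis=0)
        pvals = np.array([hwe_test(int(a), int(b), int(c))
                          for a, b, c in zip(n0[:2000], n1[:2000], n2[:2000])])
        rate = (pvals <= 0.05).mean()
        assert 0.03 <= rate <= 0.07


class TestHweFilter:
    def test_null_common_variant_cohort_loses_almost_nothing(self):
        # one homogeneous population (no Wahlund effect) and common MAFs:
        # the chi-square HWE screen at 1e-4 removes essentially nothing.
        # (Very rare alleles are excluded: the 1-df chi-square is
        # anti-conservative there, e.g. a lone minor-allele homozygote.)
        cohort = simulate_cohort(SimConfig(seed=5, n_populations=1,
                                           rare_fraction=0.0,
                                           very_rare_fraction=0.0,
                                           n_genes=1250, n_sets=10,
                                           genes_per_set=8))
        kept, removed = hwe_filter(cohort.genotypes, cohort.phenotypes)
        assert len(removed) / cohort.genotypes.n_variants <= 0.001

    def test_alpha_zero_removes_nothing(self, default_cohort):
        kept, removed = hwe_filter(default_cohort.genotypes,
                                   default_cohort.phenotypes, alpha=0.0)
        assert removed == []
        assert kept.n_variants == default_cohort.genotypes.n_variants

    def test_borderline_variant_removed_at_loose_alpha(self):
        # control counts (10,10,10) -> p ~ 0.068 < 0.1
        import pandas as pd
        dos = np.array([[0] * 10 + [1] * 10 + [2] * 10]).T.astype(np.int8)
        g = _matrix(dos)
        ph = pd.DataFrame({"subject_id": g.subject_ids,
                           "affected": [0] * 30})
        kept, removed = hwe_filter(g, ph, alpha=0.1)
        assert removed == ["v0"]

    def test_no_controls_is_an_error(self, default_cohort):
        import pandas as pd
        ph = default_cohort.phenotypes.copy()
        ph["affected"] = 1
        with pytest.raises(ConfigurationError):
            hwe_filter(default_cohort.genotypes, ph)


class TestPruneCorrelated:
    def test_duplicated_column_keeps_exactly_one(self, rng):
        col = rng.binomial(2, 0.3, size=(80, 1))
        g = _matrix(np.hstack([col, col]))
        assert prune_correlated(g) == ["v0"]

    def test_r2_max_one_keeps_everything(self, rng):
        col = rng.binomial(2, 0.3, size=(80, 1))
        g = _matrix(np.hstack([col, col]))
        assert prune_correlated(g, r2_max=1.0) == ["v0", "v1"]

    def test_independent_variants_survive(self, rng):
        dos = rng.binomial(2, 0.3, size=(400, 120)).astype(np.int8)
        g = _matrix(dos)
        kept = prune_correlated(g, r2_max=0.2)
        assert len(kept) >= 118  # chance removals are rare at n=400

    def test_deterministic_given_input_order(self, rng):
        dos = rng.binomial(2, 0.25, size=(60, 40)).astype(np.int8)
        dos[:, 1] = dos[:, 0]
        dos[:, 20] = dos[:, 21]
        g = _matrix(dos)
        assert prune_correlated(g) == prune_correlated(g)

    def test_single_variant_passes_through(self, rng):
        g = _matrix(rng.binomial(2, 0.3, size=(30, 1)))
        assert prune_correlated(g) == ["v0"]


class TestMds:
    def test_identical_subjects_have_zero_distance(self):
        dos = np.array([[0, 1, 2, 1], [0, 1, 2, 1], [2, 1, 0, 0]], dtype=np.int8)
        d = ibs_distance_matrix(_matrix(dos))
        assert d[0, 1] == 0.0
        assert np.allclose(d, d.T)
        assert np.all(np.diag(d) == 0.0)
        mds = mds_components(_matrix(dos), k=1)
        assert mds.coordinates[0, 0] == pytest.approx(mds.coordinates[1, 0])

    def test_k_must_be_smaller_than_n(self):
        g = _matrix(np.zeros((3, 4), dtype=np.int8))
        with pytest.raises(ConfigurationError):
            mds_components(g, k=3)

    def test_three_populations_recovered_by_kmeans(self, default_cohort):
        from sklearn.cluster import KMeans

        cohort = default_cohort
        kept, _ = hwe_filter(cohort.genotypes, cohort.phenotypes)
        pruned = set(prune_correlated(kept))
        idx = [i for i, v in enumerate(kept.variant_ids) if v in pruned]
        mds = mds_components(kept.subset_variants(idx), k=2)
        labels = KMeans(3, n_init=10, random_state=0).fit_predict(mds.coordinates)
        true = cohort.phenotypes["population_label"].map(
            {"POP1": 0, "POP2": 1, "POP3": 2}).to_numpy()
        agreement = max(
            (np.array([perm[l] for l in labels]) == true).mean()
            for perm in permutations(range(3)))
        assert agreement >= 0.90

    def test_invariant_to_subject_order_up_to_sign(self, rng):
        dos = rng.binomial(2, 0.3, size=(40, 60)).astype(np.int8)
        g = _matrix(dos)
        perm = rng.permutation(40)
        gp = GenotypeMatrix(dos[perm], [g.subject_ids[i] for i in perm],
                            g.variant_ids)
        a = mds_components(g, k=2).coordinates
        b = mds_components(gp, k=2).coordinates
        inv = np.empty_like(b)
        inv[perm] = b
        for col in range(2):
            assert (np.allclose(a[:, col], inv[:, col], atol=1e-8)
                    or np.allclose(a[:, col], -inv[:, col], atol=1e-8))
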