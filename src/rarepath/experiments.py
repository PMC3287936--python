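"""Calibration and recovery experiments for the analysis pipeline.

Self-contained, seeded experiments that measure the statistical behaviour
of each stage on synthetic cohorts with known ground truth: null
calibration of the collapsing carrier test and of the permutation set
p-values, exact-test agreement with an independent enumeration oracle,
power to rank a truly enriched pathway first, recovery of causal SNPs by
the boosted ensemble, and end-to-end determinism.  The test suite and the
reproduction script both run these functions; nothing here depends on
files outside the package.
"""

from __future__ import annotations

from math import comb

import numpy as np
import pandas as pd

from .boosting import SGBParams, fit_sgb, variable_importance
from .collapsing import collapsing_scan
from .enrichment import GeneSetCollection, permutation_p, rank_gene_sets
from .gene_stats import score_genes
from .synthetic_data import SimConfig, simulate_cohort

__all__ = [
    "fisher_two_sided_oracle",
    "max_fisher_discrepancy",
    "carrier_null_rejection",
    "mlp_null_rejection",
    "enrichment_rank1_rate",
    "sgb_recovery",
    "pipeline_is_deterministic",
]


# ---------------------------------------------------------------------------
# exact-test oracle


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exhaustive hypergeometric enumeration.

    Integer arithmetic throughout: sums the probabilities of all tables
    with the observed margins whose (rational) probability is at most the
    observed table's, so ties are handled exactly.
    """
    n1, n2, k = a + b, c + d, a + c
    lo, hi = max(0, k - n2), min(n1, k)
    p_obs = comb(n1, a) * comb(n2, k - a)
    num = sum(p for x in range(lo, hi + 1)
              if (p := comb(n1, x) * comb(n2, k - x)) <= p_obs)
    return num / comb(n1 + n2, k)


def max_fisher_discrepancy(max_margin: int = 30) -> tuple[float, int]:
    """Max |implementation - oracle| Fisher p over all small 2x2 tables.

    Enumerates every table whose four margins are all <= ``max_margin`` and
    non-degenerate; returns (max absolute difference, number of tables).
    """
    from scipy.stats import fisher_exact

    worst = 0.0
    n_tables = 0
    for n1 in range(1, max_margin + 1):
        for n2 in range(1, max_margin + 1):
            for a in range(n1 + 1):
                b = n1 - a
                for c in range(n2 + 1):
                    d = n2 - c
                    if a + c == 0 or b + d == 0:
                        continue
                    if a + c > max_margin or b + d > max_margin:
                        continue
                    n_tables += 1
                    p_impl = min(float(fisher_exact([[a, b], [c, d]])[1]), 1.0)
                    p_oracle = fisher_two_sided_oracle(a, b, c, d)
                    worst = max(worst, abs(p_impl - p_oracle))
    return worst, n_tables


# ---------------------------------------------------------------------------
# null calibration


def carrier_null_rejection(
    seed: int,
    n_cohorts: int = 6,
    alpha: float = 0.05,
    min_units: int = 2000,
) -> tuple[float, int]:
    """Empirical type-I error of the 5-kb-window carrier test.

    Simulates null cohorts (``carrier_effect = 0``, otherwise the default
    697-subject study conditions), pools the p-values of all testable 5-kb
    windows across cohorts until at least ``min_units`` accrue, and returns
    (rejection rate at ``alpha``, number of units).
    """
    rng = np.random.default_rng(seed)
    pooled: list[np.ndarray] = []
    total = 0
    i = 0
    while i < n_cohorts or total < min_units:
        cohort = simulate_cohort(SimConfig(
            seed=int(rng.integers(2 ** 31)), carrier_effect=0.0))
        res = collapsing_scan(cohort, window_sizes_kb=(5,),
                              include_genewise=False, include_snp=False)
        p = res["window_5kb"]["p_value"].dropna().to_numpy()
        pooled.append(p)
        total += p.size
        i += 1
    p = np.concatenate(pooled)
    return float((p <= alpha).mean()), int(p.size)


def mlp_null_rejection(
    seed: int,
    n_tests: int = 1000,
    n_perm: int = 1000,
    universe_size: int = 2000,
    set_size: int = 10,
    alpha: float = 0.05,
) -> float:
    """Rejection rate of permutation set p-values under a null universe.

    Gene scores are i.i.d. -log10(Uniform) (the null distribution of a
    -log10 p-value) and each tested set is a random draw from the universe,
    so every rejection is a false positive.
    """
    rng = np.random.default_rng(seed)
    universe = -np.log10(rng.random(universe_size))
    children = np.random.SeedSequence(seed).spawn(n_tests)
    rejections = 0
    for child in children:
        members = rng.choice(universe_size, size=set_size, replace=False)
        observed = float(universe[members].mean())
        p, _ = permutation_p(observed, universe, set_size, n_perm, child)
        rejections += p <= alpha
    return rejections / n_tests


# ---------------------------------------------------------------------------
# recovery


def enrichment_rank1_rate(
    seed: int,
    n_runs: int = 100,
    n_perm: int = 1000,
    carrier_effect: float = 2.0,
    statistic_id: str = "S2_min_window",
) -> float:
    """How often a truly enriched pathway ranks first among 50 null sets.

    Each run simulates a cohort whose causal rare variants all sit in the
    genes of one designated set (strong carrier effect), scores genes from
    the 5-kb-window scan, and ranks all 51 sets by permutation p-value.
    """
    rng = np.random.default_rng(seed)
    wins = 0
    for _ in range(n_runs):
        cfg = SimConfig(seed=int(rng.integers(2 ** 31)), n_genes=255,
                        n_sets=51, genes_per_set=5, causal_set_ids=("SET01",),
                        n_causal_genes=5, carrier_effect=carrier_effect)
        cohort = simulate_cohort(cfg)
        res = collapsing_scan(cohort, window_sizes_kb=(5,),
                              include_genewise=False, include_snp=False)
        scores = score_genes(res["window_5kb"], cohort.genes, statistic_id)
        collection = GeneSetCollection(
            {k: list(v) for k, v in cohort.gene_sets.items()},
            {k: "" for k in cohort.gene_sets})
        frame, _ = rank_gene_sets(collection, scores, n_perm=n_perm,
                                  seed=int(rng.integers(2 ** 31)))
        wins += frame.iloc[0]["set_name"] == "SET01"
    return wins / n_runs


def sgb_recovery(
    seed: int,
    n_seeds: int = 50,
    n_subjects: int = 697,
    n_snps: int = 500,
    n_causal: int = 5,
    beta: float = 1.0,
    n_trees: int = 500,
) -> dict:
    """Causal-SNP recovery of the boosted ensemble amid false positives.

    Per seed: dosages at common MAFs, a logistic outcome driven by
    ``n_causal`` SNPs (per-allele log-odds ``beta``, ~30% cases), a
    ``n_trees``-tree fit, and selection at the default scaled-importance
    cutoff.  Returns the fraction of seeds recovering >= 3 of the causal
    SNPs, mean counts of hits and false positives, and the fraction of
    seeds whose selected set contains any false positive.
    """
    rng = np.random.default_rng(seed)
    hits, fps = [], []
    causal = {f"SNP{j:04d}" for j in range(n_causal)}
    for _ in range(n_seeds):
        srng = np.random.default_rng(int(rng.integers(2 ** 31)))
        maf = srng.uniform(0.05, 0.4, size=n_snps)
        x = srng.binomial(2, maf[None, :], size=(n_subjects, n_snps)).astype(float)
        lin = x[:, :n_causal] @ np.full(n_causal, beta)
        b0 = -np.quantile(lin, 0.7)
        y = srng.binomial(1, 1.0 / (1.0 + np.exp(-(b0 + lin))))
        feats = pd.DataFrame(x, columns=[f"SNP{j:04d}" for j in range(n_snps)])
        params = SGBParams(n_trees=n_trees, seed=int(rng.integers(2 ** 31)))
        model = fit_sgb(feats, y, params)
        imp = variable_importance(model)
        selected = set(imp.loc[imp["selected"], "variable"])
        hits.append(len(selected & causal))
        fps.append(len(selected - causal))
    hits_arr, fps_arr = np.array(hits), np.array(fps)
    return {
        "frac_runs_ge3_causal": float((hits_arr >= 3).mean()),
        "mean_causal_selected": float(hits_arr.mean()),
        "mean_false_positives": float(fps_arr.mean()),
        "frac_runs_with_false_positives": float((fps_arr > 0).mean()),
    }


# ---------------------------------------------------------------------------
# determinism


def pipeline_is_deterministic(out_a: str, out_b: str, seed: int,
                              n_perm: int = 1000, n_trees: int = 500) -> bool:
    """Run the full pipeline twice at test scale; compare outputs byte-wise."""
    import hashlib
    import os

    from .pipeline import PipelineConfig, run_pipeline

    def run(out_dir: str) -> dict[str, str]:
        cfg = PipelineConfig(out_dir=out_dir, seed=seed, n_perm=n_perm,
                             sgb=SGBParams(n_trees=n_trees))
        run_pipeline(cfg)
        hashes = {}
        for root, _, files in os.walk(out_dir):
            for name in files:
                if name in ("run.log", "manifest.json"):
                    continue
                path = os.path.join(root, name)
                with open(path, "rb") as fh:
                    hashes[os.path.relpath(path, out_dir)] = hashlib.sha256(
                        fh.read()).hexdigest()
        return hashes

    return run(out_a) == run(out_b)
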