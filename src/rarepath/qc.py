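"""Marker QC and population-stratification components.

Two concerns live here: (1) excluding variants that violate Hardy-Weinberg
equilibrium in control subjects, a standard genotyping-quality screen, and
(2) summarising population structure as the leading coordinates of a
classical multidimensional scaling (MDS) of pairwise identity-by-state
genetic distances, computed on a correlation-pruned marker set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic_data import MISSING, ConfigurationError, GenotypeMatrix

__all__ = [
    "MDSResult",
    "hwe_test",
    "hwe_filter",
    "prune_correlated",
    "ibs_distance_matrix",
    "mds_components",
]


@dataclass(frozen=True)
class MDSResult:
    """Top-k MDS coordinates; rows align with ``subject_ids``."""

    coordinates: np.ndarray
    subject_ids: list[str]
    eigenvalues: np.ndarray
    distance_metric: str = "1-IBS"

    @property
    def k(self) -> int:
        return self.coordinates.shape[1]

    def to_frame(self) -> pd.DataFrame:
        cols = {f"C{i + 1}": self.coordinates[:, i] for i in range(self.k)}
        return pd.DataFrame({"subject_id": self.subject_ids, **cols})


# ---------------------------------------------------------------------------
# Hardy-Weinberg equilibrium


def hwe_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """1-df chi-square goodness-of-fit p-value against HWE proportions.

    Expected genotype counts are p^2, 2pq, q^2 times n with p the sample
    allele frequency.  A monomorphic sample carries no information against
    HWE and returns p = 1 by convention.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("total genotype count must be positive")
    p = (2 * n_AA + n_Aa) / (2 * n)
    if p in (0.0, 1.0):
        return 1.0
    q = 1.0 - p
    expected = np.array([n * p * p, 2 * n * p * q, n * q * q])
    observed = np.array([n_AA, n_Aa, n_aa], dtype=float)
    stat = ((observed - expected) ** 2 / expected).sum()
    return float(stats.chi2.sf(stat, df=1))


def _hwe_pvalues(dosages: np.ndarray) -> np.ndarray:
    """Vectorised HWE p-values per variant column (missing excluded)."""
    called = dosages != MISSING
    n0 = ((dosages == 0) & called).sum(axis=0).astype(float)
    n1 = (dosages == 1).sum(axis=0).astype(float)
    n2 = (dosages == 2).sum(axis=0).astype(float)
    n = n0 + n1 + n2
    if (n == 0).any():
        raise ValueError("variant with no called genotypes")
    p = (2 * n2 + n1) / (2 * n)  # frequency of the counted (alt) allele
    q = 1.0 - p
    with np.errstate(divide="ignore", invalid="ignore"):
        e0, e1, e2 = n * q * q, 2 * n * p * q, n * p * p
        stat = ((n0 - e0) ** 2 / e0 + (n1 - e1) ** 2 / e1 + (n2 - e2) ** 2 / e2)
    pvals = stats.chi2.sf(stat, df=1)
    pvals[(p == 0.0) | (p == 1.0)] = 1.0  # monomorphic convention
    return pvals


def hwe_filter(
    genotypes: GenotypeMatrix,
    phenotypes: pd.DataFrame,
    alpha: float = 1e-4,
) -> tuple[GenotypeMatrix, list[str]]:
    """Remove variants with HWE p < ``alpha`` computed in control subjects.

    Returns the filtered matrix and the removed variant ids.  Cases are
    ignored because a true disease association itself distorts genotype
    proportions among cases.
    """
    ph = phenotypes.set_index("subject_id").loc[genotypes.subject_ids]
    controls = np.asarray(ph["affected"] == 0)
    if not controls.any():
        raise ConfigurationError("HWE filter requires at least one control subject")
    pvals = _hwe_pvalues(genotypes.dosages[controls])
    removed = pvals < alpha
    kept = genotypes.subset_variants(np.where(~removed)[0])
    removed_ids = [genotypes.variant_ids[i] for i in np.where(removed)[0]]
    return kept, removed_ids


# ---------------------------------------------------------------------------
# correlated-marker pruning


def _fill_missing_with_mean(dosages: np.ndarray) -> np.ndarray:
    x = dosages.astype(float)
    miss = dosages == MISSING
    if miss.any():
        x[miss] = np.nan
        col_mean = np.nanmean(x, axis=0)
        col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
        inds = np.where(miss)
        x[inds] = col_mean[inds[1]]
    return x


def prune_correlated(
    genotypes: GenotypeMatrix,
    r2_max: float = 0.2,
    window: int = 50,
    step: int = 5,
) -> list[str]:
    """Greedy windowed LD pruning; returns surviving variant ids.

    Within each sliding window of ``window`` variants (advanced by ``step``),
    while any surviving pair has squared Pearson dosage correlation strictly
    above ``r2_max``, the member of the pair with the lower MAF is dropped
    (ties drop the later variant).  Deterministic given the input order.
    """
    m = genotypes.n_variants
    if m < 2:
        return list(genotypes.variant_ids)
    x = _fill_missing_with_mean(genotypes.dosages)
    af = x.mean(axis=0) / 2.0
    maf = np.minimum(af, 1.0 - af)
    sd = x.std(axis=0)
    keep = np.ones(m, dtype=bool)

    if m <= window:
        starts = [0]
    else:
        starts = list(range(0, m - window + 1, step))
        if starts[-1] != m - window:  # make the final window reach the tail
            starts.append(m - window)
    for start in starts:
        idx = np.arange(start, min(start + window, m))
        idx = idx[keep[idx]]
        changed = True
        while changed and idx.size >= 2:
            sub = x[:, idx]
            with np.errstate(invalid="ignore"):
                c = np.corrcoef(sub, rowvar=False)
            c[~np.isfinite(c)] = 0.0  # constant columns cannot exceed the bound
            np.fill_diagonal(c, 0.0)
            r2 = c ** 2
            viol = np.argwhere(np.triu(r2 > r2_max, k=1))
            if viol.size == 0:
                changed = False
                break
            i, j = viol[0]  # first violating pair in position order
            gi, gj = idx[i], idx[j]
            if maf[gi] < maf[gj]:
                drop = gi
            elif maf[gj] < maf[gi]:
                drop = gj
            else:
                drop = gj  # tie: drop the later position
            keep[drop] = False
            idx = idx[idx != drop]
    return [genotypes.variant_ids[i] for i in np.where(keep)[0]]


# ---------------------------------------------------------------------------
# identity-by-state distance and classical MDS


def ibs_distance_matrix(genotypes: GenotypeMatrix) -> np.ndarray:
    """Pairwise genetic distance 1 - IBS over non-missing variant pairs.

    Per-variant IBS between subjects i and j is (2 - |d_i - d_j|)/2; the
    distance averages (|d_i - d_j|)/2 across variants called in both.
    """
    d = genotypes.dosages
    called = (d != MISSING).astype(np.float64)
    onehot = [(d == k).astype(np.float64) for k in (0, 1, 2)]
    a0, a1, a2 = onehot
    # sum over variants of |d_i - d_j|: pairs (0,1) and (1,2) differ by 1,
    # (0,2) differs by 2
    diff = (a0 @ a1.T + a1 @ a0.T + a1 @ a2.T + a2 @ a1.T
            + 2.0 * (a0 @ a2.T + a2 @ a0.T))
    n_pairs = called @ called.T
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = diff / (2.0 * n_pairs)
    dist[n_pairs == 0] = 0.0
    np.fill_diagonal(dist, 0.0)
    return dist


def mds_components(genotypes: GenotypeMatrix, k: int = 2) -> MDSResult:
    """Classical (Torgerson) MDS of the 1-IBS distance matrix.

    Double-centers the squared distance matrix and returns the top-``k``
    eigencoordinates ordered by eigenvalue.  Axis signs are arbitrary, as in
    any eigendecomposition.
    """
    n = genotypes.n_subjects
    if k >= n:
        raise ConfigurationError(f"k={k} must be smaller than n_subjects={n}")
    if k < 1:
        raise ConfigurationError("k must be >= 1")
    dist = ibs_distance_matrix(genotypes)
    d2 = dist ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * (j @ d2 @ j)
    b = 0.5 * (b + b.T)  # symmetrize against fp noise
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1][:k]
    lam = np.clip(evals[order], 0.0, None)
    coords = evecs[:, order] * np.sqrt(lam)[None, :]
    return MDSResult(coords, list(genotypes.subject_ids), lam)
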