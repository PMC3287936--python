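"""Rare-variant collapsing association and single-SNP tests.

The collapsing (burden) strategy aggregates rare variants within a unit —
a gene or a sliding genomic window — into one per-subject carrier
indicator (carries >= 1 minor allele at any rare variant in the unit) and
compares carrier proportions between cases and controls with a Pearson
chi-square test, falling back to a two-sided Fisher exact test when any
expected cell count is small (< 5, the Cochran rule).  Common variants are
tested one SNP at a time on the allelic 2x2 table under the same rule.

All coordinates are 0-based half-open internally.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic_data import (
    MISSING,
    Cohort,
    ConfigurationError,
    GeneAnnotation,
    GenotypeMatrix,
)

__all__ = [
    "Window",
    "AssociationResult",
    "make_windows",
    "carrier_status",
    "carrier_test",
    "single_snp_test",
    "collapsing_scan",
    "sample_maf",
    "WINDOW_SIZES_KB",
]

WINDOW_SIZES_KB = (1, 5, 25, 50, 100)


@dataclass(frozen=True)
class Window:
    """One sliding-window unit (0-based half-open span)."""

    chrom: str
    start: int
    end: int
    unit_id: str
    member_variants: tuple[str, ...] = ()
    gene_overlaps: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"window {self.unit_id}: start must be < end")


@dataclass(frozen=True)
class AssociationResult:
    """Association outcome for one tested unit (gene, window or SNP)."""

    unit_id: str
    unit_kind: str                      # gene | window | snp
    table: tuple[int, int, int, int]    # case_carr, case_non, ctrl_carr, ctrl_non
    test_used: str                      # chisq | fisher | none
    p_value: float | None
    position: int                       # midpoint bp, for Manhattan output
    chrom: str = "1"
    start: int = 0
    end: int = 0
    n_rare_variants: int = 0
    genes: tuple[str, ...] = ()

    @property
    def testable(self) -> bool:
        return self.p_value is not None


# ---------------------------------------------------------------------------
# windows


def make_windows(
    gene_annotation: Sequence[GeneAnnotation],
    size: int,
    step: int,
    positions: dict[str, np.ndarray] | None = None,
) -> list[Window]:
    """Tile each chromosome with windows of ``size`` bp advanced by ``step``.

    Window starts sit at multiples of ``step``; tiling runs from the first
    variant-bearing position (or the first gene start when ``positions`` is
    not given) to the last, with the final window truncated at the span end.
    Each window is annotated with every gene it overlaps by >= 1 bp.
    """
    if size <= 0:
        raise ConfigurationError("window size must be positive")
    if step <= 0 or step > size:
        raise ConfigurationError("step must satisfy 0 < step <= size")

    by_chrom: dict[str, list[GeneAnnotation]] = {}
    for g in gene_annotation:
        by_chrom.setdefault(g.chrom, []).append(g)

    windows: list[Window] = []
    for chrom in sorted(by_chrom):
        genes = by_chrom[chrom]
        if positions is not None and chrom in positions and len(positions[chrom]):
            lo = int(np.min(positions[chrom]))
            hi = int(np.max(positions[chrom])) + 1
        else:
            lo = min(g.start for g in genes)
            hi = max(g.end for g in genes)
        start = (lo // step) * step
        while start < hi:
            end = min(start + size, hi)
            overlaps = tuple(g.gene for g in genes
                             if g.start < end and start < g.end)
            windows.append(Window(chrom, start, end,
                                  f"{chrom}:{start}-{end}", (), overlaps))
            start += step
    return windows


# ---------------------------------------------------------------------------
# carrier indicators


def sample_maf(genotypes: GenotypeMatrix) -> np.ndarray:
    """Per-variant sample minor-allele frequency over non-missing calls."""
    d = genotypes.dosages
    called = d != MISSING
    n_alleles = 2 * called.sum(axis=0)
    alt = np.where(called, d, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        af = np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1), 0.0)
    return np.minimum(af, 1.0 - af)


def minor_dosage(genotypes: GenotypeMatrix) -> np.ndarray:
    """Dosage of the sample minor allele (flips columns with alt freq > 0.5).

    Missing stays MISSING.
    """
    d = genotypes.dosages
    called = d != MISSING
    n_alleles = 2 * called.sum(axis=0)
    alt = np.where(called, d, 0).sum(axis=0)
    af = np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1), 0.0)
    flip = af > 0.5
    out = d.copy()
    out[:, flip] = 2 - d[:, flip]
    out[~called] = MISSING
    return out


def carrier_status(
    genotypes: GenotypeMatrix,
    variant_subset: Iterable[str],
    maf_max: float = 0.05,
) -> np.ndarray | None:
    """Per-subject carrier indicator over the rare variants of a unit.

    The rare set is the subset of ``variant_subset`` with sample MAF strictly
    below ``maf_max`` (minor allele defined on the full sample); a subject is
    a carrier iff it has >= 1 minor allele at any rare-set variant.  Missing
    dosages count as non-carrying.  Returns ``None`` when the rare set is
    empty (the unit is untestable, not an error).
    """
    subset = list(variant_subset)
    if not subset:
        raise ValueError("variant subset must be non-empty")
    index = {v: i for i, v in enumerate(genotypes.variant_ids)}
    cols = np.array([index[v] for v in subset])
    sub = genotypes.subset_variants(cols)
    maf = sample_maf(sub)
    rare = maf < maf_max
    if not rare.any():
        return None
    md = minor_dosage(sub)[:, rare]
    return ((md >= 1) & (md != MISSING)).any(axis=1).astype(np.int8)


# ---------------------------------------------------------------------------
# 2x2 tests


def _table_test(a: int, b: int, c: int, d: int) -> tuple[str, float]:
    """Pearson chi-square (no continuity correction) or two-sided Fisher.

    Fisher is used when any expected cell count under independence is < 5.
    Callers must ensure both margins are non-degenerate.
    """
    table = np.array([[a, b], [c, d]], dtype=float)
    n = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
    if (expected >= 5).all():
        stat = ((table - expected) ** 2 / expected).sum()
        return "chisq", float(stats.chi2.sf(stat, df=1))
    return "fisher", float(stats.fisher_exact([[a, b], [c, d]])[1])


def carrier_test(
    carriers: np.ndarray,
    affected: np.ndarray,
    unit_id: str = "",
    unit_kind: str = "window",
    **meta,
) -> AssociationResult:
    """Test the case/control difference in rare-carrier proportions."""
    carriers = np.asarray(carriers)
    affected = np.asarray(affected)
    if carriers.shape != affected.shape:
        raise ValueError("carrier and affected vectors must align")
    if affected.min() == affected.max():
        raise ConfigurationError("both affected classes must be present")
    case = affected == 1
    a = int((carriers[case] == 1).sum())
    b = int((carriers[case] == 0).sum())
    c = int((carriers[~case] == 1).sum())
    d = int((carriers[~case] == 0).sum())
    if a + c == 0 or b + d == 0:  # degenerate carrier margin
        return AssociationResult(unit_id, unit_kind, (a, b, c, d), "none",
                                 None, meta.pop("position", 0), **meta)
    test, p = _table_test(a, b, c, d)
    return AssociationResult(unit_id, unit_kind, (a, b, c, d), test, p,
                             meta.pop("position", 0), **meta)


def single_snp_test(
    dosages: np.ndarray,
    affected: np.ndarray,
    unit_id: str = "",
    **meta,
) -> AssociationResult:
    """Allelic 2x2 test of a single SNP (minor-allele counts, cases vs controls).

    Missing dosages are excluded.  Monomorphic SNPs are untestable.
    """
    dosages = np.asarray(dosages)
    affected = np.asarray(affected)
    called = dosages != MISSING
    d = dosages[called]
    aff = affected[called]
    alt = d.sum()
    total = 2 * d.size
    if alt == 0 or alt == total:
        return AssociationResult(unit_id, "snp", (0, 0, 0, 0), "none", None,
                                 meta.pop("position", 0), **meta)
    if alt > total / 2:  # count the minor allele
        d = 2 - d
    case = aff == 1
    a = int(d[case].sum())
    b = int(2 * case.sum() - a)
    c = int(d[~case].sum())
    dd = int(2 * (~case).sum() - c)
    test, p = _table_test(a, b, c, dd)
    return AssociationResult(unit_id, "snp", (a, b, c, dd), test, p,
                             meta.pop("position", 0), **meta)


# ---------------------------------------------------------------------------
# vectorised scan helpers


def _tables_to_pvalues(tables: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised chi-square with Fisher fallback for rows of 2x2 counts.

    ``tables`` is (n, 4) of (a, b, c, d).  Returns (p_values, test_used)
    with NaN/"none" for degenerate margins.
    """
    t = tables.astype(float)
    n = t.sum(axis=1)
    row1 = t[:, 0] + t[:, 1]
    row2 = t[:, 2] + t[:, 3]
    col1 = t[:, 0] + t[:, 2]
    col2 = t[:, 1] + t[:, 3]
    p = np.full(len(t), np.nan)
    used = np.array(["none"] * len(t), dtype=object)
    ok = (row1 > 0) & (row2 > 0) & (col1 > 0) & (col2 > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        e = np.stack([row1 * col1, row1 * col2, row2 * col1, row2 * col2],
                     axis=1) / n[:, None]
        chisq_ok = ok & (e >= 5).all(axis=1)
        stat = np.where(e > 0, (t - e) ** 2 / np.maximum(e, 1e-300), 0.0).sum(axis=1)
    p[chisq_ok] = stats.chi2.sf(stat[chisq_ok], df=1)
    used[chisq_ok] = "chisq"
    for i in np.where(ok & ~chisq_ok)[0]:
        a, b, c, d = tables[i]
        p[i] = stats.fisher_exact([[a, b], [c, d]])[1]
        used[i] = "fisher"
    return p, used


def _unit_results(
    units: list[tuple[str, str, str, int, int, tuple[str, ...], np.ndarray]],
    rare_any: np.ndarray,
    affected: np.ndarray,
) -> list[AssociationResult]:
    """Carrier-test a batch of units given the rare carrier matrix.

    ``units`` holds (unit_id, kind, chrom, start, end, genes, rare column
    index array); ``rare_any`` is subjects x n_rare boolean (dosage >= 1).
    """
    case = affected == 1
    n_case, n_ctrl = int(case.sum()), int((~case).sum())
    tables = np.zeros((len(units), 4), dtype=np.int64)
    n_rare = np.zeros(len(units), dtype=int)
    for i, (_, _, _, _, _, _, cols) in enumerate(units):
        n_rare[i] = cols.size
        if cols.size:
            carr = rare_any[:, cols].any(axis=1)
            a = int(carr[case].sum())
            c = int(carr[~case].sum())
            tables[i] = (a, n_case - a, c, n_ctrl - c)
    p, used = _tables_to_pvalues(tables)
    p[n_rare == 0] = np.nan
    used[n_rare == 0] = "none"
    out = []
    for i, (uid, kind, chrom, start, end, genes, _) in enumerate(units):
        out.append(AssociationResult(
            uid, kind, tuple(int(x) for x in tables[i]), str(used[i]),
            None if np.isnan(p[i]) else float(p[i]),
            position=(start + end) // 2, chrom=chrom, start=start, end=end,
            n_rare_variants=int(n_rare[i]), genes=genes))
    return out


def _results_frame(results: list[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame({
        "unit_id": [r.unit_id for r in results],
        "unit_kind": [r.unit_kind for r in results],
        "chrom": [r.chrom for r in results],
        "start": [r.start for r in results],
        "end": [r.end for r in results],
        "position": [r.position for r in results],
        "n_rare_variants": [r.n_rare_variants for r in results],
        "case_carriers": [r.table[0] for r in results],
        "control_carriers": [r.table[2] for r in results],
        "test_used": [r.test_used for r in results],
        "p_value": [np.nan if r.p_value is None else r.p_value for r in results],
        "genes": [",".join(r.genes) for r in results],
    })


def collapsing_scan(
    cohort: Cohort,
    genotypes: GenotypeMatrix | None = None,
    window_sizes_kb: Sequence[int] = WINDOW_SIZES_KB,
    include_genewise: bool = True,
    include_snp: bool = True,
    maf_max: float = 0.05,
    step_fraction: float = 0.5,
) -> dict[str, pd.DataFrame]:
    """Run the full association scan over genes, windows and single SNPs.

    Returns a dict with keys ``"gene"`` (gene-wise collapsing),
    ``"window_<size>kb"`` per window size (overlapping windows, step =
    ``step_fraction`` x size), and ``"snp"`` (allelic tests of common
    variants, sample MAF >= ``maf_max``).  ``genotypes`` defaults to the
    cohort's (pass the QC-filtered matrix in a pipeline).
    """
    g = genotypes if genotypes is not None else cohort.genotypes
    ph = cohort.phenotypes.set_index("subject_id").loc[g.subject_ids]
    affected = np.asarray(ph["affected"].astype(int))

    vid_index = {v: i for i, v in enumerate(g.variant_ids)}
    variants = [v for v in cohort.variants if v.variant_id in vid_index]
    cols = np.array([vid_index[v.variant_id] for v in variants])
    maf = sample_maf(g)[cols]
    md = minor_dosage(g)[:, cols]
    rare = maf < maf_max
    rare_any = (md[:, rare] >= 1) & (md[:, rare] != MISSING)
    # map rare variants by position/gene for unit assembly
    rare_pos = np.array([v.pos for v, r in zip(variants, rare) if r])
    rare_gene = np.array([v.gene for v, r in zip(variants, rare) if r])
    rare_chrom = np.array([v.chrom for v, r in zip(variants, rare) if r])
    out: dict[str, pd.DataFrame] = {}

    if include_genewise:
        units = []
        for ga in cohort.genes:
            idx = np.where(rare_gene == ga.gene)[0]
            units.append((ga.gene, "gene", ga.chrom, ga.start, ga.end,
                          (ga.gene,), idx))
        out["gene"] = _results_frame(_unit_results(units, rare_any, affected))

    positions = {}
    for v in variants:
        positions.setdefault(v.chrom, []).append(v.pos)
    positions = {c: np.array(p) for c, p in positions.items()}

    for size_kb in window_sizes_kb:
        size = int(size_kb * 1000)
        step = max(int(size * step_fraction), 1)
        wins = make_windows(cohort.genes, size, step, positions)
        units = []
        for w in wins:
            sel = np.where((rare_chrom == w.chrom) & (rare_pos >= w.start)
                           & (rare_pos < w.end))[0]
            units.append((w.unit_id, "window", w.chrom, w.start, w.end,
                          w.gene_overlaps, sel))
        out[f"window_{size_kb}kb"] = _results_frame(
            _unit_results(units, rare_any, affected))

    if include_snp:
        common_idx = np.where(~rare)[0]
        tables = np.zeros((common_idx.size, 4), dtype=np.int64)
        case = affected == 1
        for i, j in enumerate(common_idx):
            dj = md[:, j]
            called = dj != MISSING
            a = int(dj[case & called].sum())
            b = int(2 * (case & called).sum() - a)
            c = int(dj[~case & called].sum())
            d = int(2 * (~case & called).sum() - c)
            tables[i] = (a, b, c, d)
        p, used = _tables_to_pvalues(tables)
        rows = []
        for i, j in enumerate(common_idx):
            v = variants[j]
            rows.append(AssociationResult(
                v.variant_id, "snp", tuple(int(x) for x in tables[i]),
                str(used[i]), None if np.isnan(p[i]) else float(p[i]),
                position=v.pos, chrom=v.chrom, start=v.pos, end=v.pos + 1,
                genes=(v.gene,)))
        out["snp"] = _results_frame(rows)
    return out


def manhattan_frame(results: pd.DataFrame) -> pd.DataFrame:
    """Manhattan-plot coordinates (position, -log10 p) for testable units."""
    ok = results["p_value"].notna()
    df = results.loc[ok, ["unit_id", "chrom", "position", "p_value"]].copy()
    df["neg_log10_p"] = -np.log10(df["p_value"].clip(lower=1e-300))
    return df.drop(columns="p_value")
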