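"""Mapping unit-level association p-values onto per-gene scores.

A gene accumulates several p-values — one from gene-wise collapsing, one
per overlapping sliding window, one per member SNP — and five summary rules
turn those into a single per-gene score on the -log10 p scale:

=============  ====================================================
statistic id   definition
=============  ====================================================
S1_genewise    -log10 of the gene-wise collapsing p-value
S2_min_window  -log10 of the minimum p among 5-kb windows in the gene
S3_mlp_window  mean of -log10 p over those windows
S4_min_snp     -log10 of the minimum p among SNPs in the gene
S5_mlp_snp     mean of -log10 p over SNPs in the gene
=============  ====================================================

Untestable units never contribute, and a gene with no testable unit is
absent from the output rather than scored zero: imputing p = 1 would bias
downstream set statistics toward sparsely covered genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .synthetic_data import ConfigurationError, GeneAnnotation

__all__ = ["GeneScore", "STATISTIC_IDS", "assign_windows_to_genes", "score_genes"]

STATISTIC_IDS = ("S1_genewise", "S2_min_window", "S3_mlp_window",
                 "S4_min_snp", "S5_mlp_snp")

_P_FLOOR = 1e-300  # keeps -log10 finite for p underflowing to 0


@dataclass(frozen=True)
class GeneScore:
    gene: str
    statistic_id: str
    score: float     # -log10 p scale, >= 0
    n_units: int

    def __post_init__(self) -> None:
        if self.score < 0 or self.n_units < 1:
            raise ValueError("score must be >= 0 with >= 1 contributing unit")


def assign_windows_to_genes(
    windows: pd.DataFrame | Sequence,
    annotation: Sequence[GeneAnnotation],
) -> dict[str, list[str]]:
    """Map each gene to the window unit ids overlapping it by >= 1 bp.

    ``windows`` may be a results DataFrame (unit_id/chrom/start/end columns)
    or a sequence of objects with those attributes.  Coordinates are 0-based
    half-open, so a window ending exactly at a gene start does not overlap.
    Genes with no overlapping window are omitted.
    """
    if isinstance(windows, pd.DataFrame):
        rows = list(windows[["unit_id", "chrom", "start", "end"]].itertuples(index=False))
    else:
        rows = [(w.unit_id, w.chrom, w.start, w.end) for w in windows]
    out: dict[str, list[str]] = {}
    for g in annotation:
        hits = [uid for uid, chrom, start, end in rows
                if chrom == g.chrom and start < g.end and g.start < end]
        if hits:
            out[g.gene] = hits
    return out


def _neg_log10(p: np.ndarray) -> np.ndarray:
    return -np.log10(np.clip(p, _P_FLOOR, None))


def score_genes(
    results: pd.DataFrame,
    annotation: Sequence[GeneAnnotation],
    statistic_id: str,
) -> list[GeneScore]:
    """Compute one of the five per-gene scores from an association table.

    ``results`` must be the matching unit kind: gene-wise rows for
    S1_genewise, 5-kb window rows for S2/S3, per-SNP rows for S4/S5
    (mismatches raise a configuration error).  Output order follows the
    annotation; input row order never matters.
    """
    if statistic_id not in STATISTIC_IDS:
        raise ConfigurationError(f"unknown statistic id {statistic_id!r}")
    kinds = set(results["unit_kind"].unique())
    need = {"S1_genewise": "gene", "S2_min_window": "window",
            "S3_mlp_window": "window", "S4_min_snp": "snp",
            "S5_mlp_snp": "snp"}[statistic_id]
    if kinds and kinds != {need}:
        raise ConfigurationError(
            f"{statistic_id} needs unit_kind={need!r} results, got {sorted(kinds)}")

    ok = results[results["p_value"].notna()]
    scores: list[GeneScore] = []

    if statistic_id == "S1_genewise":
        by_gene = dict(zip(ok["unit_id"], ok["p_value"]))
        for g in annotation:
            if g.gene in by_gene:
                scores.append(GeneScore(
                    g.gene, statistic_id,
                    float(_neg_log10(np.array([by_gene[g.gene]]))[0]), 1))
        return scores

    if statistic_id in ("S2_min_window", "S3_mlp_window"):
        mapping = assign_windows_to_genes(ok, annotation)
        p_by_unit = dict(zip(ok["unit_id"], ok["p_value"]))
        for g in annotation:
            uids = mapping.get(g.gene, [])
            ps = np.array([p_by_unit[u] for u in uids])
            if ps.size == 0:
                continue
            if statistic_id == "S2_min_window":
                val = float(_neg_log10(np.array([ps.min()]))[0])
            else:
                val = float(_neg_log10(ps).mean())
            scores.append(GeneScore(g.gene, statistic_id, val, int(ps.size)))
        return scores

    # SNP statistics: rows carry their gene in the `genes` column
    gene_col = ok["genes"].astype(str)
    for g in annotation:
        ps = np.asarray(ok.loc[gene_col == g.gene, "p_value"])
        if ps.size == 0:
            continue
        if statistic_id == "S4_min_snp":
            val = float(_neg_log10(np.array([ps.min()]))[0])
        else:
            val = float(_neg_log10(ps).mean())
        scores.append(GeneScore(g.gene, statistic_id, val, int(ps.size)))
    return scores


def scores_to_frame(scores: Sequence[GeneScore]) -> pd.DataFrame:
    return pd.DataFrame({
        "gene": [s.gene for s in scores],
        "statistic_id": [s.statistic_id for s in scores],
        "score": [s.score for s in scores],
        "n_units": [s.n_units for s in scores],
    })
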