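"""Mean-log-p (MLP) gene-set enrichment with a permutation null.

A pathway's statistic is the arithmetic mean of its member genes' scores on
the -log10 p scale.  Significance is assessed competitively: each
permutation draws a random same-size gene set from the scored universe
(without replacement) and recomputes the mean, and the set's p-value is the
plus-one-corrected fraction of null draws at least as large as the observed
statistic.  Sets are then rank-ordered by permutation p-value.

Gene-label resampling (rather than phenotype permutation) follows the
gene-expression MLP procedure this statistic originates from, and avoids
rerunning the genome scan once per permutation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .gene_stats import GeneScore

__all__ = [
    "GeneSetCollection",
    "GeneSetResult",
    "GmtParseError",
    "read_gmt",
    "write_gmt",
    "gene_set_mlp",
    "permutation_p",
    "rank_gene_sets",
]


class GmtParseError(ValueError):
    """Malformed GMT input (reported with its line number)."""


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets plus their descriptions, in file order."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str]

    def __len__(self) -> int:
        return len(self.sets)


@dataclass(frozen=True)
class GeneSetResult:
    set_name: str
    n_genes_used: int
    observed_mlp: float
    perm_p: float
    rank: int
    n_perm: int
    seed: int


# ---------------------------------------------------------------------------
# GMT I/O


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: ``set_name<TAB>description<TAB>gene1<TAB>gene2...``.

    Duplicate genes within a line are collapsed (first occurrence wins);
    a line with fewer than three fields — i.e. an empty set — is rejected.
    """
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise GmtParseError(
                    f"{path}:{lineno}: expected >= 3 tab-separated fields, "
                    f"got {len(parts)}")
            name, desc = parts[0], parts[1]
            members = list(dict.fromkeys(p for p in parts[2:] if p))
            if not members:
                raise GmtParseError(f"{path}:{lineno}: gene set {name!r} is empty")
            sets[name] = members
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write(name + "\t" + desc + "\t" + "\t".join(members) + "\n")


# ---------------------------------------------------------------------------
# set statistic and permutation null


def _universe_from_scores(
    scores: Sequence[GeneScore] | Mapping[str, float],
) -> dict[str, float]:
    if isinstance(scores, Mapping):
        return dict(scores)
    return {s.gene: s.score for s in scores}


def gene_set_mlp(
    scores: Sequence[GeneScore] | Mapping[str, float],
    set_members: Sequence[str],
    min_set_size: int = 3,
) -> tuple[float, int] | None:
    """Observed MLP of a set: mean member score over the scored universe.

    Returns ``(observed_mlp, n_genes_used)``, or ``None`` when fewer than
    ``min_set_size`` members have scores (the set is skipped, not an error).
    """
    universe = _universe_from_scores(scores)
    used = [universe[g] for g in dict.fromkeys(set_members) if g in universe]
    if len(used) < min_set_size:
        return None
    return float(np.mean(used)), len(used)


def permutation_p(
    observed_mlp: float,
    universe_scores: np.ndarray,
    set_size: int,
    n_perm: int,
    seed: int | np.random.SeedSequence,
) -> tuple[float, np.ndarray]:
    """Monte-Carlo set p-value against random same-size gene sets.

    Each permutation draws ``set_size`` scores from the universe without
    replacement and takes their mean; the returned p is
    ``(1 + #{null >= observed}) / (n_perm + 1)`` (plus-one correction, so p
    is never zero).  Also returns the null sample for diagnostics.
    """
    universe_scores = np.asarray(universe_scores, dtype=float)
    n_universe = universe_scores.size
    if set_size > n_universe:
        raise ValueError(f"set_size {set_size} exceeds universe size {n_universe}")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    # vectorised draws without replacement: argpartition of uniform keys
    keys = rng.random((n_perm, n_universe))
    idx = np.argpartition(keys, set_size - 1, axis=1)[:, :set_size]
    null = universe_scores[idx].mean(axis=1)
    p = (1 + int((null >= observed_mlp - 1e-12).sum())) / (n_perm + 1)
    return float(p), null


def rank_gene_sets(
    collection: GeneSetCollection,
    scores: Sequence[GeneScore] | Mapping[str, float],
    n_perm: int = 10_000,
    seed: int = 0,
    min_set_size: int = 3,
    top_k: int = 20,
    report_k: int = 6,
) -> tuple[pd.DataFrame, list[GeneSetResult]]:
    """Score, permute and rank every analyzable set in the collection.

    All sets share one master seed; each set's null uses an independent
    child stream, so results do not depend on the order sets are analysed.
    Output is sorted ascending by permutation p-value, ties broken by larger
    observed MLP and then by name, and ranked 1..N.  ``top_k``/``report_k``
    only select how many rows the caller typically reports; the full table
    is always returned.
    """
    universe = _universe_from_scores(scores)
    uni_arr = np.array(list(universe.values()), dtype=float)
    master = np.random.SeedSequence(seed)
    children = master.spawn(len(collection.sets))

    rows = []
    for child, (name, members) in zip(children, collection.sets.items()):
        obs = gene_set_mlp(universe, members, min_set_size=min_set_size)
        if obs is None:
            continue
        observed_mlp, n_used = obs
        p, _ = permutation_p(observed_mlp, uni_arr, n_used, n_perm, child)
        rows.append((name, n_used, observed_mlp, p))

    rows.sort(key=lambda r: (r[3], -r[2], r[0]))
    results = [
        GeneSetResult(name, n_used, observed_mlp, p, rank, n_perm, seed)
        for rank, (name, n_used, observed_mlp, p) in enumerate(rows, start=1)
    ]
    frame = pd.DataFrame({
        "set_name": [r.set_name for r in results],
        "n_genes_used": [r.n_genes_used for r in results],
        "observed_mlp": [r.observed_mlp for r in results],
        "perm_p": [r.perm_p for r in results],
        "rank": [r.rank for r in results],
    })
    return frame, results


def top_report(frame: pd.DataFrame, statistic_id: str, report_k: int = 6) -> str:
    """Markdown report of the top-k pathways for one gene statistic."""
    lines = [f"### Top {report_k} gene sets — {statistic_id}", "",
             "| rank | gene set | MLP | permutation p |",
             "| --- | --- | --- | --- |"]
    for r in frame.head(report_k).itertuples(index=False):
        lines.append(f"| {r.rank} | {r.set_name} | {r.observed_mlp:.4g} "
                     f"| {r.perm_p:.4g} |")
    return "\n".join(lines) + "\n"
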