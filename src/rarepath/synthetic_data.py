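"""Synthetic case-control mini-exome cohorts with known ground truth.

Generates a cohort of ~700 subjects drawn from a small number of diverged
subpopulations, genotyped at variants whose minor-allele-frequency spectrum
is dominated by rare (1-5%) and very rare (<1%) sites, with gene annotation,
pathway (gene-set) membership, and a binary affection status driven by a
logistic model on rare-allele carrier status in designated causal genes plus
a smoking covariate.  Every downstream stage (QC, collapsing association,
gene scoring, pathway enrichment, boosting) can therefore be exercised and
validated against the generator's truth records without any external data.

Population structure follows the Balding-Nichols model: each subpopulation's
allele frequency is a Beta draw around the ancestral frequency with variance
controlled by a single Fst-like ``divergence`` parameter.  Within each
subpopulation genotypes are Hardy-Weinberg binomial draws.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "Cohort",
    "GenotypeMatrix",
    "VariantRecord",
    "GeneAnnotation",
    "simulate_cohort",
    "write_cohort",
    "read_cohort",
]

MISSING = -1  # sentinel for a missing dosage in the int8 genotype matrix


class ConfigurationError(ValueError):
    """Raised when a simulation or pipeline configuration is inconsistent."""


# ---------------------------------------------------------------------------
# containers


@dataclass(frozen=True)
class GenotypeMatrix:
    """Subjects x variants minor-allele dosage matrix.

    ``dosages`` holds values in {0, 1, 2} with ``MISSING`` (-1) for no-calls.
    Rows align with ``subject_ids``, columns with ``variant_ids``.
    """

    dosages: np.ndarray
    subject_ids: list[str]
    variant_ids: list[str]

    def __post_init__(self) -> None:
        d = np.asarray(self.dosages)
        if d.ndim != 2:
            raise ValueError("dosages must be 2-D (subjects x variants)")
        if d.shape != (len(self.subject_ids), len(self.variant_ids)):
            raise ValueError("dosage dimensions inconsistent with id lists")
        ok = np.isin(d, (0, 1, 2, MISSING))
        if not ok.all():
            raise ValueError("dosage values must be in {0,1,2} or missing")

    @property
    def n_subjects(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def subset_variants(self, keep: Sequence[int]) -> "GenotypeMatrix":
        keep = np.asarray(keep, dtype=int)
        return GenotypeMatrix(
            self.dosages[:, keep],
            self.subject_ids,
            [self.variant_ids[i] for i in keep],
        )


@dataclass(frozen=True)
class VariantRecord:
    """One variant site on the synthetic chromosome (0-based position)."""

    variant_id: str
    chrom: str
    pos: int          # 0-based
    gene: str
    ancestral_maf: float


@dataclass(frozen=True)
class GeneAnnotation:
    """Gene span, 0-based half-open coordinates."""

    gene: str
    chrom: str
    start: int
    end: int
    variant_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"gene {self.gene}: start must be < end")


@dataclass(frozen=True)
class Cohort:
    genotypes: GenotypeMatrix
    phenotypes: pd.DataFrame        # subject_id, affected, age, sex, smoke, population_label
    variants: list[VariantRecord]
    genes: list[GeneAnnotation]
    gene_sets: dict[str, list[str]]  # set name -> member genes
    truth: dict                      # causal_genes, causal_variants, causal_sets

    @property
    def n_subjects(self) -> int:
        return self.genotypes.n_subjects


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic cohort generator.

    Defaults emulate the structure of the study cohort this package targets:
    697 subjects with a ~30% case fraction drawn from three subpopulations,
    a variant spectrum in which ~74% of sites have MAF < 1% and a further
    ~13% fall between 1% and 5%, causal rare alleles concentrated in genes
    of a designated pathway, and a smoking covariate associated with case
    status (odds ratio ~2).
    """

    n_subjects: int = 697
    case_fraction_target: float = 0.30
    n_populations: int = 3
    divergence: float = 0.10          # Fst-like Balding-Nichols parameter
    n_genes: int = 100
    genes_per_set: int = 8
    n_sets: int = 12
    causal_set_ids: tuple[str, ...] = ("SET01",)
    n_causal_genes: int = 5
    rare_fraction: float = 0.87       # P(MAF < 0.05)
    very_rare_fraction: float = 0.74  # P(MAF < 0.01)
    carrier_effect: float = 1.1       # log-odds per causal-gene rare carrier
    smoke_effect: float = 0.69        # log-odds for smokers (~OR 2)
    base_rate: float | None = None    # None -> intercept solved for target
    seed: int = 0
    # layout of the single synthetic chromosome
    gene_length: int = 20_000
    gene_gap: int = 5_000
    variants_per_gene: int = 8
    smoke_prevalence: float = 0.25
    pop_intercept: float = 0.1        # +/- spread of population log-odds offsets

    def validate(self) -> None:
        for name in ("case_fraction_target", "rare_fraction", "very_rare_fraction",
                     "smoke_prevalence"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        if not 0.0 <= self.divergence < 1.0:
            raise ConfigurationError("divergence must be in [0, 1)")
        if self.very_rare_fraction > self.rare_fraction:
            raise ConfigurationError("very_rare_fraction must be <= rare_fraction")
        if self.n_sets * self.genes_per_set > self.n_genes:
            raise ConfigurationError("n_sets * genes_per_set exceeds n_genes")
        if self.n_causal_genes > self.genes_per_set * len(self.causal_set_ids):
            raise ConfigurationError(
                "n_causal_genes exceeds genes available in the causal sets")
        known = {f"SET{i + 1:02d}" for i in range(self.n_sets)}
        unknown = set(self.causal_set_ids) - known
        if unknown:
            raise ConfigurationError(f"causal_set_ids not among generated sets: {unknown}")

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)


# ---------------------------------------------------------------------------
# allele-frequency spectrum

# stratum bounds for very rare / rare / common sites, on the MAF scale
_VR_LO, _VR_HI = 5e-4, 0.01
_R_HI = 0.05
_C_HI = 0.50


def _draw_stratum_maf(rng: np.random.Generator, stratum: np.ndarray) -> np.ndarray:
    """Ancestral MAF per variant given its stratum code (0=vr, 1=rare, 2=common).

    Rare components are Beta-skewed toward the low end of their stratum so the
    post-drift sample spectrum keeps its mass below the stratum boundary.
    """
    n = stratum.size
    p = np.empty(n)
    vr = stratum == 0
    r = stratum == 1
    c = stratum == 2
    p[vr] = _VR_LO + (_VR_HI - _VR_LO) * rng.beta(1.0, 3.0, size=vr.sum())
    p[r] = _VR_HI + (_R_HI - _VR_HI) * rng.beta(1.0, 2.0, size=r.sum())
    p[c] = rng.uniform(_R_HI, _C_HI, size=c.sum())
    return p


def _drift_frequencies(
    rng: np.random.Generator, p: np.ndarray, fst: float, n_pops: int
) -> np.ndarray:
    """Balding-Nichols subpopulation frequencies, shape (n_pops, n_variants)."""
    if fst <= 0.0:
        return np.tile(p, (n_pops, 1))
    a = p * (1.0 - fst) / fst
    b = (1.0 - p) * (1.0 - fst) / fst
    return rng.beta(a[None, :], b[None, :], size=(n_pops, p.size))


def _sample_variant_frequencies(
    rng: np.random.Generator, stratum: np.ndarray, cfg: SimConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (ancestral MAF, per-population frequencies) per variant stratum.

    Stratified rejection: a variant whose post-drift expected sample MAF
    (mean over equal-sized subpopulations, folded at 0.5) leaves its
    configured stratum is redrawn, so the configured rare / very-rare
    fractions hold in the realized sample and not just ancestrally.  The
    floor ``0.5 / n_subjects`` keeps the expected minor-allele count >= 1
    so the site can segregate.
    """
    n_variants = stratum.size
    bounds = {0: (max(0.5 / cfg.n_subjects, 1e-6), _VR_HI),
              1: (_VR_HI, _R_HI), 2: (_R_HI, 0.5 + 1e-12)}

    anc = np.empty(n_variants)
    pop = np.empty((cfg.n_populations, n_variants))
    todo = np.arange(n_variants)
    for _ in range(500):  # rejection rounds; nearly all settle in a handful
        p = _draw_stratum_maf(rng, stratum[todo])
        f = _drift_frequencies(rng, p, cfg.divergence, cfg.n_populations)
        exp_maf = np.minimum(f.mean(axis=0), 1.0 - f.mean(axis=0))
        lo = np.array([bounds[s][0] for s in stratum[todo]])
        hi = np.array([bounds[s][1] for s in stratum[todo]])
        ok = (exp_maf >= lo) & (exp_maf < hi)
        anc[todo[ok]] = p[ok]
        pop[:, todo[ok]] = f[:, ok]
        todo = todo[~ok]
        if todo.size == 0:
            break
    else:  # pragma: no cover - pathological configuration
        raise ConfigurationError("could not realize the configured MAF spectrum")
    return anc, pop


def _draw_strata(rng: np.random.Generator, n_variants: int, cfg: SimConfig) -> np.ndarray:
    w = np.array([
        cfg.very_rare_fraction,
        cfg.rare_fraction - cfg.very_rare_fraction,
        1.0 - cfg.rare_fraction,
    ])
    return rng.choice(3, size=n_variants, p=w)


# ---------------------------------------------------------------------------
# cohort simulation


def _solve_intercept(terms: np.ndarray, target: float) -> float:
    """Bisection for b with mean(sigmoid(b + terms)) == target."""
    lo, hi = -20.0, 20.0
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        if np.mean(1.0 / (1.0 + np.exp(-(mid + terms)))) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_cohort(config: SimConfig) -> Cohort:
    """Simulate a full cohort (genotypes, phenotypes, annotation, truth).

    The affection status follows a logistic model:

        logit P(affected) = b0 + carrier_effect * carrier
                               + smoke_effect * smoke + pop_offset

    where ``carrier`` flags subjects with >= 1 minor allele at any rare
    (MAF < 0.05) variant in a causal gene.  With ``base_rate`` unset, the
    intercept b0 is solved so the expected case fraction equals
    ``case_fraction_target``; an explicit ``base_rate`` is used directly as
    logit(base_rate).

    Identical configs (including seed) give bit-identical cohorts.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    n, n_genes = config.n_subjects, config.n_genes
    chrom = "1"

    # --- gene layout on one synthetic chromosome (0-based half-open spans)
    gene_names = [f"GENE{i + 1:04d}" for i in range(n_genes)]
    pitch = config.gene_length + config.gene_gap
    starts = np.arange(n_genes, dtype=np.int64) * pitch
    ends = starts + config.gene_length

    # --- variants uniform within genes
    n_variants = n_genes * config.variants_per_gene
    gene_idx = np.repeat(np.arange(n_genes), config.variants_per_gene)
    offs = rng.integers(0, config.gene_length, size=n_variants)
    pos = starts[gene_idx] + offs
    order = np.lexsort((offs, gene_idx))
    gene_idx, pos = gene_idx[order], pos[order]
    variant_ids = [f"V{i + 1:06d}" for i in range(n_variants)]

    stratum = _draw_strata(rng, n_variants, config)
    anc_maf, pop_freq = _sample_variant_frequencies(rng, stratum, config)

    # --- subjects assigned round-robin-balanced to populations, then genotyped
    pop_label = rng.permuted(np.arange(n) % config.n_populations)
    pop_rows = [np.where(pop_label == k)[0] for k in range(config.n_populations)]

    def _draw_genotypes(freqs: np.ndarray) -> np.ndarray:
        g = np.empty((n, freqs.shape[1]), dtype=np.int8)
        for k, rows in enumerate(pop_rows):
            g[rows] = rng.binomial(2, freqs[k][None, :], size=(rows.size, freqs.shape[1]))
        return g

    dos = _draw_genotypes(pop_freq)
    # cohort variants are ascertained segregating sites: redraw any column
    # that came out monomorphic (frequencies and genotypes together)
    for _ in range(1000):
        counts = dos.sum(axis=0)
        mono = (counts == 0) | (counts == 2 * n)
        if not mono.any():
            break
        cols = np.where(mono)[0]
        a, f = _sample_variant_frequencies(rng, stratum[cols], config)
        anc_maf[cols] = a
        pop_freq[:, cols] = f
        dos[:, cols] = _draw_genotypes(f)
    else:  # pragma: no cover - pathological configuration
        raise ConfigurationError("could not ascertain segregating variants")

    variants = [
        VariantRecord(variant_ids[j], chrom, int(pos[j]), gene_names[gene_idx[j]],
                      float(anc_maf[j]))
        for j in range(n_variants)
    ]
    by_gene: dict[str, list[str]] = {g: [] for g in gene_names}
    for v in variants:
        by_gene[v.gene].append(v.variant_id)
    genes = [
        GeneAnnotation(gene_names[i], chrom, int(starts[i]), int(ends[i]),
                       tuple(by_gene[gene_names[i]]))
        for i in range(n_genes)
    ]

    # --- gene sets: disjoint blocks of a shuffled gene list
    shuffled = list(rng.permutation(gene_names))
    gene_sets = {
        f"SET{i + 1:02d}": sorted(shuffled[i * config.genes_per_set:(i + 1) * config.genes_per_set])
        for i in range(config.n_sets)
    }

    # --- causal genes: sampled from the designated causal sets
    pool = sorted({g for s in config.causal_set_ids for g in gene_sets[s]})
    causal_genes = sorted(rng.choice(pool, size=config.n_causal_genes, replace=False))

    # causal variants: rare (sample MAF < 0.05) sites within causal genes
    with np.errstate(invalid="ignore"):
        called = dos != MISSING
        af = np.where(called, dos, 0).sum(axis=0) / np.maximum(2 * called.sum(axis=0), 1)
    maf = np.minimum(af, 1.0 - af)
    causal_gene_set = set(causal_genes)
    causal_mask = np.array(
        [v.gene in causal_gene_set and maf[j] < 0.05 for j, v in enumerate(variants)]
    )
    causal_variants = [v.variant_id for j, v in enumerate(variants) if causal_mask[j]]
    minor = np.where(af[None, :] <= 0.5, dos, 2 - dos)  # minor-allele dosage
    carrier = (minor[:, causal_mask] >= 1).any(axis=1).astype(float)

    # --- phenotypes
    smoke = rng.binomial(1, config.smoke_prevalence, size=n)
    sex = rng.binomial(1, 0.5, size=n)
    age = np.clip(rng.normal(50, 12, size=n).round(), 18, 90).astype(int)
    offsets = np.linspace(-config.pop_intercept, config.pop_intercept,
                          config.n_populations)
    terms = (config.carrier_effect * carrier
             + config.smoke_effect * smoke
             + offsets[pop_label])
    if config.base_rate is None:
        b0 = _solve_intercept(terms, config.case_fraction_target)
    else:
        b0 = float(np.log(config.base_rate / (1.0 - config.base_rate)))
    p_aff = 1.0 / (1.0 + np.exp(-(b0 + terms)))
    affected = rng.binomial(1, p_aff)

    phen = pd.DataFrame({
        "subject_id": [f"S{i + 1:04d}" for i in range(n)],
        "affected": affected.astype(int),
        "age": age,
        "sex": sex.astype(int),
        "smoke": smoke.astype(int),
        "population_label": [f"POP{k + 1}" for k in pop_label],
    })

    truth = {
        "causal_sets": list(config.causal_set_ids),
        "causal_genes": list(causal_genes),
        "causal_variants": causal_variants,
    }
    gmat = GenotypeMatrix(dos, list(phen["subject_id"]), variant_ids)
    return Cohort(gmat, phen, variants, genes, gene_sets, truth)


# ---------------------------------------------------------------------------
# on-disk round trip


def write_cohort(cohort: Cohort, directory: str | os.PathLike) -> dict[str, str]:
    """Write a cohort to ``directory`` as VCF / TSV / BED-like TSV / GMT.

    Returns a manifest mapping logical names to file paths.  Gene spans are
    written 1-based inclusive (BED-like annotation convention used
    pipeline-wide at the file boundary); internal coordinates stay 0-based
    half-open.
    """
    directory = os.fspath(directory)
    os.makedirs(directory, exist_ok=True)
    paths = {
        "vcf": os.path.join(directory, "genotypes.vcf"),
        "phenotypes": os.path.join(directory, "phenotypes.tsv"),
        "genes": os.path.join(directory, "genes.tsv"),
        "gene_sets": os.path.join(directory, "gene_sets.gmt"),
        "truth": os.path.join(directory, "truth.tsv"),
    }

    gt_codes = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    dos = cohort.genotypes.dosages
    with open(paths["vcf"], "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=rarepath-synthetic\n")
        chroms = sorted({v.chrom for v in cohort.variants}) or ["1"]
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(cohort.genotypes.subject_ids) + "\n")
        for j, v in enumerate(cohort.variants):
            gts = "\t".join(gt_codes[int(d)] for d in dos[:, j])
            fh.write(f"{v.chrom}\t{v.pos + 1}\t{v.variant_id}\tA\tT\t.\tPASS\t"
                     f"GENE={v.gene}\tGT\t{gts}\n")

    cohort.phenotypes.to_csv(paths["phenotypes"], sep="\t", index=False)

    with open(paths["genes"], "w") as fh:
        fh.write("chrom\tstart\tend\tgene\n")
        for g in cohort.genes:  # 1-based inclusive on disk
            fh.write(f"{g.chrom}\t{g.start + 1}\t{g.end}\t{g.gene}\n")

    with open(paths["gene_sets"], "w") as fh:
        for name, members in cohort.gene_sets.items():
            fh.write(name + "\t" + f"synthetic gene set {name}" + "\t"
                     + "\t".join(members) + "\n")

    with open(paths["truth"], "w") as fh:
        fh.write("kind\tname\n")
        for s in cohort.truth["causal_sets"]:
            fh.write(f"causal_set\t{s}\n")
        for g in cohort.truth["causal_genes"]:
            fh.write(f"causal_gene\t{g}\n")
        for v in cohort.truth["causal_variants"]:
            fh.write(f"causal_variant\t{v}\n")
    return paths


def read_cohort(directory: str | os.PathLike) -> Cohort:
    """Read a cohort previously written by :func:`write_cohort`."""
    from cyvcf2 import VCF

    directory = os.fspath(directory)
    phen = pd.read_csv(os.path.join(directory, "phenotypes.tsv"), sep="\t",
                       dtype={"subject_id": str})
    subject_ids = list(phen["subject_id"])

    variants: list[VariantRecord] = []
    rows = []
    vcf_path = os.path.join(directory, "genotypes.vcf")
    vcf = VCF(vcf_path)
    if list(vcf.samples) != subject_ids:
        raise ValueError("VCF sample order does not match phenotype table")
    # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
    gt_map = np.array([0, 1, MISSING, 2], dtype=np.int8)
    for rec in vcf:
        gene = rec.INFO.get("GENE", "")
        variants.append(VariantRecord(rec.ID, rec.CHROM, rec.POS - 1, gene, np.nan))
        rows.append(gt_map[rec.gt_types])
    vcf.close()
    dos = (np.stack(rows, axis=1) if rows
           else np.empty((len(subject_ids), 0), dtype=np.int8))

    gdf = pd.read_csv(os.path.join(directory, "genes.tsv"), sep="\t")
    by_gene: dict[str, list[str]] = {}
    for v in variants:
        by_gene.setdefault(v.gene, []).append(v.variant_id)
    genes = [
        GeneAnnotation(r.gene, str(r.chrom), int(r.start) - 1, int(r.end),
                       tuple(by_gene.get(r.gene, ())))
        for r in gdf.itertuples()
    ]

    gene_sets: dict[str, list[str]] = {}
    with open(os.path.join(directory, "gene_sets.gmt")) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                gene_sets[parts[0]] = parts[2:]

    truth: dict = {"causal_sets": [], "causal_genes": [], "causal_variants": []}
    tdf = pd.read_csv(os.path.join(directory, "truth.tsv"), sep="\t")
    for r in tdf.itertuples():
        truth[r.kind + "s"].append(r.name)

    gmat = GenotypeMatrix(dos, subject_ids, [v.variant_id for v in variants])
    return Cohort(gmat, phen, variants, genes, gene_sets, truth)
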