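"""End-to-end orchestration: simulate/load -> QC -> scan -> score -> enrich -> boost.

Every stage is a pure function of (inputs, config, seed); the pipeline
writes each stage's outputs as TSV/JSON under the output directory at fixed
float precision and records them in ``manifest.json`` together with input
hashes, the stage seed and wall time.  Rerunning with the same config and
master seed reproduces every output file byte for byte, and completed
stages whose inputs are unchanged are skipped on resume.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
import yaml

from . import collapsing, enrichment, gene_stats, qc
from .boosting import SGBParams, fit_sgb, predict_sgb, variable_importance
from .synthetic_data import (
    Cohort,
    ConfigurationError,
    SimConfig,
    read_cohort,
    simulate_cohort,
    write_cohort,
)

__all__ = ["PipelineConfig", "run_pipeline", "cohort_summary"]

log = logging.getLogger("rarepath")

_FLOAT_FMT = "%.17g"  # round-trip precision => byte-identical resumed reruns

STAGES = ("simulate", "qc", "collapse", "score", "enrich", "boost", "report")


@dataclass
class PipelineConfig:
    """Single configuration object for a full run.

    In synthetic mode (``input_dir`` unset) the cohort comes from
    ``sim``; otherwise ``input_dir`` must hold the files written by
    :func:`rarepath.synthetic_data.write_cohort` (VCF, phenotype TSV, gene
    TSV, GMT).  The master ``seed`` deterministically seeds every
    stochastic stage.
    """

    out_dir: str = "rarepath_out"
    seed: int = 0
    input_dir: str | None = None
    sim: SimConfig = field(default_factory=SimConfig)
    # QC
    hwe_alpha: float = 1e-4
    prune_r2_max: float = 0.2
    prune_window: int = 50
    prune_step: int = 5
    mds_k: int = 2
    # collapsing
    window_sizes_kb: tuple[int, ...] = collapsing.WINDOW_SIZES_KB
    maf_max: float = 0.05
    step_fraction: float = 0.5
    # gene scoring / enrichment
    statistics: tuple[str, ...] = gene_stats.STATISTIC_IDS
    score_window_kb: int = 5
    n_perm: int = 10_000
    min_set_size: int = 3
    top_k: int = 20
    report_k: int = 6
    # boosting
    sgb: SGBParams = field(default_factory=SGBParams)
    boost_top_n_snps: int = 100
    boost_top_n_rare_units: int = 100

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimConfig(**{**raw.pop("sim", {})})
        sgb = SGBParams(**{**raw.pop("sgb", {})})
        for key in ("window_sizes_kb", "statistics", "causal_set_ids"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(sim=sim, sgb=sgb, **raw)

    def config_hash(self) -> str:
        d = dataclasses.asdict(self)
        return hashlib.sha256(
            json.dumps(d, sort_keys=True, default=str).encode()).hexdigest()[:16]


def cohort_summary(n_cases: int, n_controls: int) -> dict:
    """Case/control counts and percentages for the summary report."""
    n = n_cases + n_controls
    if n == 0:
        raise ConfigurationError("empty cohort")
    return {
        "n_subjects": n,
        "n_cases": int(n_cases),
        "n_controls": int(n_controls),
        "pct_affected": round(100.0 * n_cases / n, 1),
        "pct_unaffected": round(100.0 * n_controls / n, 1),
    }


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


class _Manifest:
    """Stage ledger persisted as manifest.json; supports resume."""

    def __init__(self, out_dir: str, config_hash: str):
        self.path = os.path.join(out_dir, "manifest.json")
        self.data = {"config_hash": config_hash, "stages": {}}
        if os.path.exists(self.path):
            try:
                with open(self.path) as fh:
                    old = json.load(fh)
                if old.get("config_hash") == config_hash:
                    self.data = old
            except (json.JSONDecodeError, OSError):
                pass

    def done(self, stage: str) -> bool:
        entry = self.data["stages"].get(stage)
        if not entry or entry.get("status") != "complete":
            return False
        return all(os.path.exists(p) and _sha256(p) == h
                   for p, h in entry["outputs"].items())

    def record(self, stage: str, outputs: list[str], seed: int,
               wall: float, status: str = "complete",
               error: str | None = None) -> None:
        self.data["stages"][stage] = {
            "status": status,
            "seed": seed,
            "wall_time_s": round(wall, 3),
            "outputs": {p: _sha256(p) for p in outputs if os.path.exists(p)},
            **({"error": error} if error else {}),
        }
        with open(self.path, "w") as fh:
            json.dump(self.data, fh, indent=2, sort_keys=True)


def _stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage 31-bit child seed from the master seed."""
    h = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


def run_pipeline(config: PipelineConfig, through: str = "report") -> dict:
    """Execute stages in order up to ``through``; returns the manifest dict.

    A stage failure is recorded in the manifest and downstream stages are
    skipped.  On a rerun, a stage whose recorded outputs still exist with
    unchanged hashes (under the same config hash) is resumed: its state is
    reloaded from those files instead of being recomputed.
    """
    if through not in STAGES:
        raise ConfigurationError(f"unknown stage {through!r}")
    os.makedirs(config.out_dir, exist_ok=True)
    _setup_logging(config.out_dir)
    manifest = _Manifest(config.out_dir, config.config_hash())
    state: dict = {}

    plan: list[tuple[str, Callable, Callable]] = [
        ("simulate", _stage_simulate, _load_simulate),
        ("qc", _stage_qc, _load_qc),
        ("collapse", _stage_collapse, _load_collapse),
        ("score", _stage_score, _load_score),
        ("enrich", _stage_enrich, _load_enrich),
        ("boost", _stage_boost, _load_boost),
        ("report", _stage_report, None),
    ]
    for stage, fn, loader in plan:
        t0 = time.time()
        seed = _stage_seed(config.seed, stage)
        state["stage_seed"] = seed
        if manifest.done(stage) and loader is not None:
            loader(config, state)
            log.info("stage %s resumed from existing outputs", stage)
            if stage == through:
                break
            continue
        try:
            outputs = fn(config, state)
        except Exception as exc:  # record the failure point, stop the run
            log.exception("stage %s failed", stage)
            manifest.record(stage, [], seed, time.time() - t0,
                            status="failed", error=f"{type(exc).__name__}: {exc}")
            break
        manifest.record(stage, outputs, seed, time.time() - t0)
        log.info("stage %s complete (%.2fs)", stage, time.time() - t0)
        if stage == through:
            break
    return manifest.data


def _setup_logging(out_dir: str) -> None:
    if not log.handlers:
        log.setLevel(logging.INFO)
        log.addHandler(logging.StreamHandler())
    fh = logging.FileHandler(os.path.join(out_dir, "run.log"))
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)


# ---------------------------------------------------------------------------
# resume loaders (reconstruct stage state from previously written outputs)


def _load_simulate(config: PipelineConfig, state: dict) -> None:
    state["cohort"] = read_cohort(_cohort_dir(config))


def _load_qc(config: PipelineConfig, state: dict) -> None:
    cohort: Cohort = state["cohort"]
    removed = set(pd.read_csv(os.path.join(config.out_dir, "hwe_removed.tsv"),
                              sep="\t")["variant_id"].astype(str))
    keep = [i for i, v in enumerate(cohort.genotypes.variant_ids)
            if v not in removed]
    state["genotypes_qc"] = cohort.genotypes.subset_variants(keep)
    mds_df = pd.read_csv(os.path.join(config.out_dir, "mds_components.tsv"),
                         sep="\t", dtype={"subject_id": str},
                         float_precision="round_trip")
    coords = mds_df.drop(columns="subject_id").to_numpy(dtype=float)
    state["mds"] = qc.MDSResult(coords, list(mds_df["subject_id"]),
                                np.full(coords.shape[1], np.nan))


def _load_collapse(config: PipelineConfig, state: dict) -> None:
    out = config.out_dir
    res: dict[str, pd.DataFrame] = {}
    gene_path = os.path.join(out, "collapsing_gene.tsv")
    if os.path.exists(gene_path):
        res["gene"] = pd.read_csv(gene_path, sep="\t", keep_default_na=False,
                                  na_values=[""], float_precision="round_trip")
    for size in config.window_sizes_kb:
        path = os.path.join(out, f"collapsing_{size}kb.tsv")
        if os.path.exists(path):
            res[f"window_{size}kb"] = pd.read_csv(
                path, sep="\t", keep_default_na=False, na_values=[""],
                float_precision="round_trip")
    snp_path = os.path.join(out, "snp_assoc.tsv")
    if os.path.exists(snp_path):
        res["snp"] = pd.read_csv(snp_path, sep="\t", keep_default_na=False,
                                 na_values=[""], float_precision="round_trip")
    state["scan"] = res


def _load_score(config: PipelineConfig, state: dict) -> None:
    state["scores"] = {}
    for stat in config.statistics:
        df = pd.read_csv(os.path.join(config.out_dir, f"gene_scores_{stat}.tsv"),
                         sep="\t", float_precision="round_trip")
        state["scores"][stat] = [
            gene_stats.GeneScore(r.gene, r.statistic_id, float(r.score),
                                 int(r.n_units))
            for r in df.itertuples(index=False)
        ]


def _load_enrich(config: PipelineConfig, state: dict) -> None:
    state["enrichment"] = {}
    for stat in config.statistics:
        state["enrichment"][stat] = pd.read_csv(
            os.path.join(config.out_dir, f"gene_set_results_{stat}.tsv"),
            sep="\t", float_precision="round_trip")


def _load_boost(config: PipelineConfig, state: dict) -> None:
    state["importance"] = pd.read_csv(
        os.path.join(config.out_dir, "sgb_importance.tsv"), sep="\t",
        float_precision="round_trip")


# ---------------------------------------------------------------------------
# stages (each returns the list of files it wrote)


def _cohort_dir(config: PipelineConfig) -> str:
    return config.input_dir or os.path.join(config.out_dir, "cohort")


def _stage_simulate(config: PipelineConfig, state: dict) -> list[str]:
    if config.input_dir is not None:
        state["cohort"] = read_cohort(config.input_dir)
        return []
    sim = dataclasses.replace(config.sim, seed=state["stage_seed"])
    cohort = simulate_cohort(sim)
    state["cohort"] = cohort
    paths = write_cohort(cohort, _cohort_dir(config))
    return list(paths.values())


def _stage_qc(config: PipelineConfig, state: dict) -> list[str]:
    cohort: Cohort = state["cohort"]
    out = config.out_dir
    kept, removed = qc.hwe_filter(cohort.genotypes, cohort.phenotypes,
                                  alpha=config.hwe_alpha)
    state["genotypes_qc"] = kept
    removed_path = os.path.join(out, "hwe_removed.tsv")
    _write_tsv(pd.DataFrame({"variant_id": removed}), removed_path)

    pruned_ids = qc.prune_correlated(kept, r2_max=config.prune_r2_max,
                                     window=config.prune_window,
                                     step=config.prune_step)
    idx = [i for i, v in enumerate(kept.variant_ids) if v in set(pruned_ids)]
    mds = qc.mds_components(kept.subset_variants(idx), k=config.mds_k)
    state["mds"] = mds
    mds_path = os.path.join(out, "mds_components.tsv")
    _write_tsv(mds.to_frame(), mds_path)
    return [removed_path, mds_path]


def _stage_collapse(config: PipelineConfig, state: dict) -> list[str]:
    cohort: Cohort = state["cohort"]
    res = collapsing.collapsing_scan(
        cohort, genotypes=state["genotypes_qc"],
        window_sizes_kb=config.window_sizes_kb,
        maf_max=config.maf_max, step_fraction=config.step_fraction)
    state["scan"] = res
    out = config.out_dir
    written = []
    for key, df in res.items():
        name = ("collapsing_gene.tsv" if key == "gene"
                else "snp_assoc.tsv" if key == "snp"
                else f"collapsing_{key.removeprefix('window_')}.tsv")
        path = os.path.join(out, name)
        _write_tsv(df, path)
        written.append(path)
    mh_key = f"window_{config.score_window_kb}kb"
    if mh_key in res:
        path = os.path.join(out, "manhattan.tsv")
        _write_tsv(collapsing.manhattan_frame(res[mh_key]), path)
        written.append(path)
    return written


def _stage_score(config: PipelineConfig, state: dict) -> list[str]:
    cohort: Cohort = state["cohort"]
    res = state["scan"]
    source = {
        "S1_genewise": res.get("gene"),
        "S2_min_window": res.get(f"window_{config.score_window_kb}kb"),
        "S3_mlp_window": res.get(f"window_{config.score_window_kb}kb"),
        "S4_min_snp": res.get("snp"),
        "S5_mlp_snp": res.get("snp"),
    }
    written = []
    state["scores"] = {}
    for stat in config.statistics:
        df = source.get(stat)
        if df is None:
            raise ConfigurationError(
                f"statistic {stat} needs a scan table that was not produced")
        scores = gene_stats.score_genes(df, cohort.genes, stat)
        state["scores"][stat] = scores
        path = os.path.join(config.out_dir, f"gene_scores_{stat}.tsv")
        _write_tsv(gene_stats.scores_to_frame(scores), path)
        written.append(path)
    return written


def _stage_enrich(config: PipelineConfig, state: dict) -> list[str]:
    cohort: Cohort = state["cohort"]
    collection = enrichment.GeneSetCollection(
        {k: list(v) for k, v in cohort.gene_sets.items()},
        {k: "" for k in cohort.gene_sets})
    written = []
    state["enrichment"] = {}
    report_parts = []
    for stat in config.statistics:
        frame, _ = enrichment.rank_gene_sets(
            collection, state["scores"][stat], n_perm=config.n_perm,
            seed=state["stage_seed"], min_set_size=config.min_set_size,
            top_k=config.top_k, report_k=config.report_k)
        state["enrichment"][stat] = frame
        path = os.path.join(config.out_dir, f"gene_set_results_{stat}.tsv")
        _write_tsv(frame, path)
        written.append(path)
        report_parts.append(enrichment.top_report(frame, stat, config.report_k))
    path = os.path.join(config.out_dir, "top_pathways.md")
    with open(path, "w") as fh:
        fh.write("\n".join(report_parts))
    written.append(path)
    return written


def _select_boost_features(config: PipelineConfig, state: dict) -> pd.DataFrame:
    """Assemble the boosting feature table: preselected SNPs + MDS + covariates.

    SNP preselection takes the top single-SNP results by p-value plus every rare
    variant inside the top rare collapsing units (5-kb windows), mirroring a
    two-track common + rare hand-off from the association stage.
    """
    cohort: Cohort = state["cohort"]
    g = state["genotypes_qc"]
    res = state["scan"]
    chosen: list[str] = []
    snp = res.get("snp")
    if snp is not None:
        ok = snp[snp["p_value"].notna()].sort_values(["p_value", "unit_id"])
        chosen += list(ok["unit_id"].head(config.boost_top_n_snps))
    win = res.get(f"window_{config.score_window_kb}kb")
    if win is not None:
        ok = win[win["p_value"].notna()].sort_values(["p_value", "unit_id"])
        top_windows = ok.head(config.boost_top_n_rare_units)
        vid_pos = {v.variant_id: (v.chrom, v.pos) for v in cohort.variants}
        maf = collapsing.sample_maf(g)
        rare_ids = {v for v, m in zip(g.variant_ids, maf) if m < config.maf_max}
        for row in top_windows.itertuples(index=False):
            for vid in rare_ids:
                chrom, pos = vid_pos[vid]
                if chrom == row.chrom and row.start <= pos < row.end:
                    chosen.append(vid)
    chosen = list(dict.fromkeys(chosen))
    idx = {v: i for i, v in enumerate(g.variant_ids)}
    cols = [idx[v] for v in chosen if v in idx]
    dos = g.dosages[:, cols].astype(float)
    dos[dos < 0] = 0.0  # missing treated as reference
    feat = pd.DataFrame(dos, columns=[g.variant_ids[i] for i in cols])
    mds = state["mds"]
    for i in range(mds.k):
        feat[f"MDS{i + 1}"] = mds.coordinates[:, i]
    ph = cohort.phenotypes.set_index("subject_id").loc[g.subject_ids]
    for c in ("age", "sex", "smoke"):
        feat[c] = np.asarray(ph[c], dtype=float)
    return feat


def _stage_boost(config: PipelineConfig, state: dict) -> list[str]:
    cohort: Cohort = state["cohort"]
    feat = _select_boost_features(config, state)
    ph = cohort.phenotypes.set_index("subject_id").loc[
        state["genotypes_qc"].subject_ids]
    y = np.asarray(ph["affected"].astype(int))
    params = dataclasses.replace(config.sgb, seed=state["stage_seed"])
    model = fit_sgb(feat, y, params)
    imp = variable_importance(model)
    gene_of = {v.variant_id: v.gene for v in cohort.variants}
    imp["gene"] = [gene_of.get(v, "") for v in imp["variable"]]
    causal = set(state["cohort"].truth.get("causal_variants", []))
    if causal:
        imp["is_causal"] = imp["variable"].isin(causal)
    state["importance"] = imp
    out = config.out_dir
    imp_path = os.path.join(out, "sgb_importance.tsv")
    _write_tsv(imp, imp_path)
    pred_path = os.path.join(out, "sgb_predictions.tsv")
    _write_tsv(pd.DataFrame({
        "subject_id": state["genotypes_qc"].subject_ids,
        "p_case": predict_sgb(model, feat),
    }), pred_path)
    model_path = os.path.join(out, "sgb_model.json")
    with open(model_path, "w") as fh:
        fh.write(model.to_json())
    return [imp_path, pred_path, model_path]


def _stage_report(config: PipelineConfig, state: dict) -> list[str]:
    cohort: Cohort = state["cohort"]
    aff = np.asarray(cohort.phenotypes["affected"].astype(int))
    summary = cohort_summary(int(aff.sum()), int((1 - aff).sum()))
    maf = collapsing.sample_maf(cohort.genotypes)
    summary.update({
        "n_variants": int(cohort.genotypes.n_variants),
        "n_variants_after_qc": int(state["genotypes_qc"].n_variants),
        "n_rare_1_5pct": int(((maf >= 0.01) & (maf < 0.05)).sum()),
        "n_very_rare_lt1pct": int(((maf > 0) & (maf < 0.01)).sum()),
    })
    path = os.path.join(config.out_dir, "cohort_summary.json")
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)

    # Table-2-style top-SNP list with truth flags (synthetic mode)
    paths = [path]
    if "importance" in state:
        imp = state["importance"]
        sel = imp[imp["selected"]]
        path2 = os.path.join(config.out_dir, "top_snps.tsv")
        _write_tsv(sel, path2)
        paths.append(path2)
    return paths
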