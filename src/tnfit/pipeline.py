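"""End-to-end orchestration: simulate -> process -> summarize -> fitness -> report.

A run is driven by a :class:`RunConfig` (loadable from YAML, unknown keys
rejected) and is fully deterministic given the config, including its master
seed. Biological replicates are modeled as independent read-level
resamplings of one master library — the two replicate samples of a real
experiment are aliquots of the same physical mutant pool, which is what
makes their per-gene insertion indices agree so tightly. Treatment
durations are modeled as scale factors on the per-gene log2 effects, each
compared against the same control pool.

When ground truth is present (simulated runs), a :class:`RecoveryReport`
tabulates gated calls against true effect classes, essentiality recovery,
log2FC error and replicate agreement.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import essentiality as ess
from . import fitness as fit
from .genome import AnnotatedGenome
from .insertion import replicate_correlation, summarize_genes, write_gene_stats
from .profiles import InsertionProfile
from .reads import ProcessingReport, process_fastq
from .simulate import (
    DEFAULT_INSERTIONS_PER_BP,
    DEFAULT_MEAN_READS_PER_SITE,
    DEFAULT_NB_DISPERSION,
    DEFAULT_TAG,
    EffectMap,
    apply_selection,
    emit_reads,
    generate_genome,
    random_effects,
    simulate_library,
)

log = logging.getLogger("tnfit")


def _strict(cls, data: dict):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown config keys for {cls.__name__}: {sorted(unknown)}")
    return cls(**data)


@dataclass
class GenomeConfig:
    length_bp: int = 50_000
    n_genes: int = 40
    gc_fraction: float = 0.5
    mean_gene_length: int = 900


@dataclass
class EffectsConfig:
    n_essential: int = 4
    n_loss: int = 4
    n_gain: int = 2
    loss_log2: float = -3.0
    gain_log2: float = 2.0


@dataclass
class LibraryConfig:
    insertions_per_bp: float = DEFAULT_INSERTIONS_PER_BP
    mean_reads_per_site: float = DEFAULT_MEAN_READS_PER_SITE
    nb_dispersion: float = DEFAULT_NB_DISPERSION


@dataclass
class TreatmentConfig:
    # duration label -> effect scale factor; compared against one control pool
    timepoints: dict = field(default_factory=lambda: {"T30": 1.0, "T90": 1.6})
    replicates: int = 2


@dataclass
class ReadsConfig:
    enabled: bool = True  # False: pass profiles straight through (fast path)
    tag: str = DEFAULT_TAG
    read_length: int = 75
    error_rate: float = 0.0
    barcode_length: int = 6


@dataclass
class ProcessingConfig:
    max_mismatch: int = 2
    min_junction_len: int = 20
    seed_k: int = 13
    collapse_strands: bool = False


@dataclass
class AnalysisConfig:
    end_trim_fraction: float = 0.0
    lfc_threshold: float = 1.0
    alpha: float = 0.005
    prior_count: float = 0.5
    llr_lo: float = -2.0
    llr_hi: float = 2.0
    enrich_alpha: float = 0.005
    fallback_index_threshold: float = 0.01


@dataclass
class RunConfig:
    seed: int = 1
    genome: GenomeConfig = field(default_factory=GenomeConfig)
    effects: EffectsConfig = field(default_factory=EffectsConfig)
    library: LibraryConfig = field(default_factory=LibraryConfig)
    treatment: TreatmentConfig = field(default_factory=TreatmentConfig)
    reads: ReadsConfig = field(default_factory=ReadsConfig)
    processing: ProcessingConfig = field(default_factory=ProcessingConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        sections = {
            "genome": GenomeConfig,
            "effects": EffectsConfig,
            "library": LibraryConfig,
            "treatment": TreatmentConfig,
            "reads": ReadsConfig,
            "processing": ProcessingConfig,
            "analysis": AnalysisConfig,
        }
        kwargs: dict = {}
        for key, sub_cls in sections.items():
            if key in data:
                kwargs[key] = _strict(sub_cls, data.pop(key) or {})
        if "seed" not in data:
            raise ValueError("config must set an explicit seed")
        kwargs["seed"] = int(data.pop("seed"))
        if data:
            raise ValueError(f"unknown top-level config keys: {sorted(data)}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


@dataclass
class RecoveryReport:
    """Ground-truth bookkeeping of a simulated run."""

    confusion: dict  # timepoint -> {true_class: {gated_class: count}}
    essentiality_sensitivity: float
    essentiality_specificity: float
    log2fc_rmse: dict  # timepoint -> RMSE over true-effect genes
    replicate_r_squared: dict  # condition -> r^2
    funnel: dict | None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PipelineResult:
    outdir: Path
    genome: AnnotatedGenome
    effects: EffectMap
    profiles: dict  # sample -> InsertionProfile
    gene_stats: dict  # sample -> list[GeneInsertionStats]
    essentiality: pd.DataFrame
    fitness: dict  # timepoint -> results DataFrame
    classification: fit.TimepointClassification
    recovery: RecoveryReport | None
    report: ProcessingReport | None


def _sample_names(cfg: RunConfig) -> dict[str, list[str]]:
    names = {"control": [f"TL0_{r + 1}" for r in range(cfg.treatment.replicates)]}
    for tp in cfg.treatment.timepoints:
        names[tp] = [f"{tp}_{r + 1}" for r in range(cfg.treatment.replicates)]
    return names


def _barcodes(samples: list[str], length: int) -> dict[str, str]:
    """Deterministic distinct fixed-length barcodes (prefix-free by equality
    of length)."""
    alphabet = "ACGT"
    codes: dict[str, str] = {}
    for i, s in enumerate(samples):
        digits = []
        v = i
        for _ in range(length):
            digits.append(alphabet[v % 4])
            v //= 4
        codes[s] = "".join(reversed(digits))
    return codes


def run_pipeline(cfg: RunConfig, outdir: str | os.PathLike) -> PipelineResult:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config.used.yaml")
    an = cfg.analysis

    log.info("generating genome: %d bp, %d genes", cfg.genome.length_bp, cfg.genome.n_genes)
    genome = generate_genome(
        cfg.genome.length_bp,
        cfg.genome.n_genes,
        gc_fraction=cfg.genome.gc_fraction,
        seed=cfg.seed,
        mean_gene_length=cfg.genome.mean_gene_length,
    )
    genome.write_fasta(out / "genome.fasta")
    genome.write_gff3(out / "genes.gff3")

    effects = random_effects(
        genome,
        n_essential=cfg.effects.n_essential,
        n_loss=cfg.effects.n_loss,
        n_gain=cfg.effects.n_gain,
        loss_log2=cfg.effects.loss_log2,
        gain_log2=cfg.effects.gain_log2,
        seed=cfg.seed,
    )
    effects.write_tsv(out / "true_effects.tsv")

    edge_margin = cfg.reads.read_length if cfg.reads.enabled else 0
    master = simulate_library(
        genome,
        effects,
        insertions_per_bp=cfg.library.insertions_per_bp,
        mean_reads_per_site=cfg.library.mean_reads_per_site,
        nb_dispersion=cfg.library.nb_dispersion,
        seed=cfg.seed,
        edge_margin=edge_margin,
        sample_id="master_library",
    )
    master.write_tsv(out / "master_library.sites.tsv")
    log.info("master library: %d sites, %d reads", master.n_sites, master.total_reads)

    names = _sample_names(cfg)
    neutral = EffectMap.neutral(genome)
    true_profiles: dict[str, InsertionProfile] = {}
    sample_seed = 1000
    for cond, samples in names.items():
        scale = 0.0 if cond == "control" else float(cfg.treatment.timepoints[cond])
        cond_effects = neutral if cond == "control" else effects.scaled(scale)
        for s in samples:
            sample_seed += 1
            derived = (cfg.seed * 100_000 + sample_seed) % (2**31 - 1)
            true_profiles[s] = apply_selection(
                master, genome, cond_effects, seed=derived, sample_id=s
            )

    report: ProcessingReport | None = None
    if cfg.reads.enabled:
        all_samples = [s for ss in names.values() for s in ss]
        barcodes = _barcodes(all_samples, cfg.reads.barcode_length)
        fastq_path = out / "reads.fastq"
        total = 0
        with open(fastq_path, "w") as fh:
            for si, s in enumerate(all_samples):
                for read_id, seq, qual in emit_reads(
                    true_profiles[s],
                    genome,
                    tag_seq=cfg.reads.tag,
                    barcode=barcodes[s],
                    read_length=cfg.reads.read_length,
                    error_rate=cfg.reads.error_rate,
                    seed=(cfg.seed * 100_000 + 50_000 + si) % (2**31 - 1),
                ):
                    fh.write(f"@{read_id}\n{seq}\n+\n{qual}\n")
                    total += 1
        log.info("emitted %d reads to %s", total, fastq_path)
        profiles, report = process_fastq(
            [fastq_path],
            genome,
            barcodes,
            tag_seq=cfg.reads.tag,
            max_mismatch=cfg.processing.max_mismatch,
            min_junction_len=cfg.processing.min_junction_len,
            seed_k=cfg.processing.seed_k,
            collapse_strands=cfg.processing.collapse_strands,
        )
        report.write_json(out / "processing_report.json")
    else:
        profiles = true_profiles

    gene_stats = {
        s: summarize_genes(p, genome, end_trim_fraction=an.end_trim_fraction)
        for s, p in profiles.items()
    }
    for s, stats in gene_stats.items():
        write_gene_stats(stats, out / f"{s}.genes.tsv")

    replicate_r2: dict[str, float] = {}
    for cond, samples in names.items():
        if len(samples) >= 2:
            rep = replicate_correlation(gene_stats[samples[0]], gene_stats[samples[1]])
            replicate_r2[cond] = rep.r_squared
            rep.write_json(out / f"correlation.{cond}.json")

    # essentiality from the mean control insertion index
    ctrl_samples = names["control"]
    gene_ids = genome.gene_ids
    idx_matrix = np.array(
        [[st.insertion_index for st in gene_stats[s]] for s in ctrl_samples]
    )
    mean_index = idx_matrix.mean(axis=0)
    max_len = max((g.length_bp for g in genome.genes), default=1)
    try:
        model = ess.fit_essentiality_mixture(
            mean_index, seed=cfg.seed, floor=1.0 / (2.0 * max_len)
        )
        ess_table = ess.essentiality_table(
            gene_ids, mean_index, model, llr_lo=an.llr_lo, llr_hi=an.llr_hi
        )
    except (ValueError, ess.DegenerateFitError) as exc:
        log.info("mixture unavailable (%s); using index threshold %.3g", exc,
                 an.fallback_index_threshold)
        calls = [
            "essential" if v <= an.fallback_index_threshold else "nonessential"
            for v in mean_index
        ]
        ess_table = pd.DataFrame(
            {
                "gene_id": gene_ids,
                "insertion_index": mean_index,
                "llr": np.where(np.array(calls) == "essential", np.inf, -np.inf),
                "call": calls,
            }
        )
    ess.write_essentiality(ess_table, out / "essentiality.tsv")
    essential_called = set(ess_table.loc[ess_table["call"] == "essential", "gene_id"])

    # treated-vs-control fitness per timepoint, essential genome excluded
    tested_genes = [g for g in gene_ids if g not in essential_called]
    read_counts = pd.DataFrame(
        {
            s: [st.read_count for st in gene_stats[s]]
            for s in profiles
        },
        index=gene_ids,
    )
    fitness_results: dict[str, pd.DataFrame] = {}
    sig_sets: dict[str, frozenset[str]] = {}
    for tp in cfg.treatment.timepoints:
        cols = names["control"] + names[tp]
        design = {s: fit.CONTROL for s in names["control"]}
        design.update({s: fit.TREATED for s in names[tp]})
        results = fit.fitness_table(
            read_counts.loc[tested_genes, cols],
            design,
            lfc_threshold=an.lfc_threshold,
            alpha=an.alpha,
            prior_count=an.prior_count,
        )
        fitness_results[tp] = results
        sig_sets[tp] = fit.significant_genes(results)
        fit.write_fitness_results(results, out / f"fitness.{tp}.tsv")

    tps = list(cfg.treatment.timepoints)
    if len(tps) >= 2:
        classification = fit.classify_timepoints(sig_sets[tps[0]], sig_sets[tps[1]])
    else:
        only = sig_sets[tps[0]] if tps else frozenset()
        classification = fit.TimepointClassification(frozenset(), only, frozenset())
    fit.write_run_summary(out / "run_summary.json", fitness_results, classification)

    recovery = _recovery_report(
        cfg, genome, effects, ess_table, fitness_results, replicate_r2, report
    )
    with open(out / "recovery_report.json", "w") as fh:
        json.dump(recovery.to_dict(), fh, indent=2)
        fh.write("\n")

    return PipelineResult(
        outdir=out,
        genome=genome,
        effects=effects,
        profiles=profiles,
        gene_stats=gene_stats,
        essentiality=ess_table,
        fitness=fitness_results,
        classification=classification,
        recovery=recovery,
        report=report,
    )


def _recovery_report(
    cfg: RunConfig,
    genome: AnnotatedGenome,
    effects: EffectMap,
    ess_table: pd.DataFrame,
    fitness_results: dict,
    replicate_r2: dict,
    report: ProcessingReport | None,
) -> RecoveryReport:
    an = cfg.analysis
    calls = dict(zip(ess_table["gene_id"], ess_table["call"]))
    true_ess = {g for g in genome.gene_ids if effects[g].essential}
    noness = [g for g in genome.gene_ids if g not in true_ess]
    tp_ess = sum(1 for g in true_ess if calls.get(g) == "essential")
    tn = sum(1 for g in noness if calls.get(g) != "essential")
    sens = tp_ess / len(true_ess) if true_ess else float("nan")
    spec = tn / len(noness) if noness else float("nan")

    confusion: dict[str, dict[str, dict[str, int]]] = {}
    rmse: dict[str, float] = {}
    for tp, results in fitness_results.items():
        scale = float(cfg.treatment.timepoints[tp])
        gated = dict(zip(results.index, results["sig_class"]))
        table: dict[str, dict[str, int]] = {
            t: {"loss": 0, "gain": 0, "ns": 0, "excluded": 0}
            for t in ("loss", "gain", "neutral")
        }
        sq_err: list[float] = []
        for g in noness:
            f_true = effects[g].fitness_log2 * scale
            if f_true < -an.lfc_threshold:
                t_class = "loss"
            elif f_true > an.lfc_threshold:
                t_class = "gain"
            else:
                t_class = "neutral"
            g_class = gated.get(g, "excluded")
            table[t_class][g_class] += 1
            if t_class in ("loss", "gain") and g in results.index:
                sq_err.append((float(results.loc[g, "log2fc"]) - f_true) ** 2)
        confusion[tp] = table
        rmse[tp] = float(np.sqrt(np.mean(sq_err))) if sq_err else float("nan")

    return RecoveryReport(
        confusion=confusion,
        essentiality_sensitivity=sens,
        essentiality_specificity=spec,
        log2fc_rmse=rmse,
        replicate_r_squared=replicate_r2,
        funnel=dataclasses.asdict(report) if report is not None else None,
    )


def render_report(result: PipelineResult) -> dict:
    """Human-readable run summary: ranked log2FC curves and set sizes.

    The ranked table per timepoint is the data behind the classic
    S-shaped fitness curve (genes sorted from strongest depletion to
    strongest enrichment).
    """
    ranked = {}
    counts = {}
    for tp, results in result.fitness.items():
        ordered = results.sort_values("log2fc")
        ranked[tp] = pd.DataFrame(
            {
                "rank": np.arange(1, len(ordered) + 1),
                "gene_id": ordered.index,
                "log2fc": ordered["log2fc"].to_numpy(),
                "sig_class": ordered["sig_class"].to_numpy(),
            }
        )
        vc = results["sig_class"].value_counts()
        counts[tp] = {
            "loss": int(vc.get("loss", 0)),
            "gain": int(vc.get("gain", 0)),
            "ns": int(vc.get("ns", 0)),
        }
    return {
        "ranked_log2fc": ranked,
        "sig_counts": counts,
        "sets": {
            "both": sorted(result.classification.both),
            "early_only": sorted(result.classification.early_only),
            "late_only": sorted(result.classification.late_only),
        },
    }
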