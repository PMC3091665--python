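"""End-to-end pipeline: simulate -> digest -> align -> call -> survey.

Every artifact is stamped with a hash of the configuration and the seed,
and the whole run is deterministic under a fixed configuration. In
simulation mode the run finishes with a truth-based recovery evaluation
restricted to unique selected-tag footprints, quantifying paralog- and
repeat-driven false calls separately.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd
import yaml

from ._intervals import GenomeIntervals
from .align import (TagAlignment, UniqueTag, align_tags, alignment_rate,
                    build_index, collapse_unique)
from .digest import compute_digest_report, digest, reports_to_frame
from .enzymes import BUILTIN_ENZYMES
from .io import write_bed, write_fasta, write_fastq, write_tsv
from .simulate import (SimConfig, SimulatedGenomes, make_parent_genomes,
                       mark_discoverable, fit_gamma_overdispersion,
                       selected_tag_footprints, simulate_tag_reads)
from .snpcall import (SNPCandidate, build_pileup, call_candidates,
                      cross_assembly_filter, extract_flanks, filter_lenient,
                      filter_stringent, write_vcf)
from .survey import (coverage_histogram, high_coverage_repeat_enrichment,
                     pearson_r, snp_read_position_distribution, window_stats,
                     window_stats_frame)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    enzyme: str = "CviRI"
    min_fragment_len: int = 70
    max_fragment_len: int = 200
    tag_len: int = 33
    max_mismatches: int = 2
    index_k: int = 11
    lenient_min_alt_reads: int = 3
    window: int = 10
    window_min_count: int = 3
    stringent_min_support: int = 10
    stringent_mq_min: int = 40
    stringent_cq_min: int = 10
    indel_flank: int = 3
    flank: int = 60
    survey_window: int = 10_000
    high_coverage_threshold: int = 200
    seed: int = 42
    sim: SimConfig = field(default_factory=SimConfig)

    def __post_init__(self):
        if isinstance(self.sim, dict):
            self.sim = SimConfig(**self.sim)
        self.sim.seed = self.seed
        if self.min_fragment_len > self.max_fragment_len:
            raise ValueError("min_fragment_len > max_fragment_len")
        for name in ("lenient_min_alt_reads", "stringent_min_support",
                     "window", "tag_len", "flank"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def size_range(self) -> Tuple[int, int]:
        return (self.min_fragment_len, self.max_fragment_len)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class PipelineResult:
    config: PipelineConfig
    genomes: SimulatedGenomes
    unique_tags: List[UniqueTag]
    collapse_summary: Dict[str, float]
    alignments: List[Tuple[UniqueTag, Optional[TagAlignment]]]
    alignment_rate_pct: float
    candidates: List[SNPCandidate]
    lenient: List[SNPCandidate]
    stringent: List[SNPCandidate]
    final: List[SNPCandidate]
    metrics: Dict[str, float]
    outdir: Optional[Path] = None


def eval_footprint_regions(
    genomes: SimulatedGenomes, config: PipelineConfig
) -> GenomeIntervals:
    """Selected-tag footprints that are unique and informative.

    A footprint qualifies when its reference tag sequence places uniquely
    (single best hit, mapping quality 40), and the footprint overlaps
    neither the repeat mask (the lenient filter removes such calls by
    construction) nor a segmental duplication (ambiguous by design).
    """
    tags, _ = selected_tag_footprints(
        genomes.reference, BUILTIN_ENZYMES[config.enzyme],
        config.size_range, config.tag_len,
    )
    index = build_index(genomes.reference, config.index_k)
    by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    from .align import align_tag

    for t in tags:
        if t.collapsed or len(t.sequence) != config.tag_len or "N" in t.sequence:
            continue
        if genomes.repeats.overlaps(t.chrom, t.start, t.end):
            continue
        if genomes.duplications.overlaps(t.chrom, t.start, t.end):
            continue
        aln = align_tag(t.sequence, index, config.max_mismatches)
        if aln is None or aln.n_best_hits > 1 or aln.mapping_quality < 40:
            continue
        by_chrom.setdefault(t.chrom, []).append((t.start, t.end))
    return GenomeIntervals(by_chrom)


def evaluate_calls(
    calls: Sequence[SNPCandidate],
    genomes: SimulatedGenomes,
    eval_regions: GenomeIntervals,
) -> Dict[str, float]:
    """Recall/precision of calls against spiked truth, inside eval regions."""
    truth = {
        (v.chrom, v.position): v.alt
        for v in genomes.truth
        if v.kind == "SNP" and v.in_footprint
        and eval_regions.covers(v.chrom, v.position)
    }
    calls_in = [c for c in calls if eval_regions.covers(c.chrom, c.position)]
    tp = sum(
        1 for c in calls_in if truth.get((c.chrom, c.position)) == c.alt
    )
    n_truth = len(truth)
    n_calls = len(calls_in)
    return {
        "n_truth_eval": n_truth,
        "n_calls_eval": n_calls,
        "true_positives": tp,
        "recall": tp / n_truth if n_truth else float("nan"),
        "precision": tp / n_calls if n_calls else float("nan"),
    }


def run_pipeline(
    config: PipelineConfig, outdir: str | Path | None = None
) -> PipelineResult:
    """Execute the full simulated study and (optionally) write all artifacts."""
    enzyme = BUILTIN_ENZYMES[config.enzyme]
    stamp = [f"config_hash={config.hash()}", f"seed={config.seed}"]

    logger.info("simulate: building parent genomes (%d bp)", config.sim.genome_length)
    genomes = make_parent_genomes(config.sim)
    mark_discoverable(genomes, enzyme, config.size_range, config.tag_len)

    logger.info("digest: %s digest of the reference", enzyme.name)
    fragments = digest(genomes.reference, enzyme)
    report = compute_digest_report(
        fragments,
        genome_length=sum(len(s) for s in genomes.reference.values()),
        repeat_intervals=genomes.repeats,
        enzyme_name=enzyme.name,
        min_len=config.min_fragment_len,
        max_len=config.max_fragment_len,
        tag_len=config.tag_len,
        run_output_bp=1.9242e9,
    )

    logger.info("simulate: pooled tag reads")
    reads, tag_records = simulate_tag_reads(
        genomes, enzyme, config.size_range, config.sim
    )

    logger.info("align: collapsing %d reads", len(reads))
    unique_tags, collapse_summary = collapse_unique(reads)
    index = build_index(genomes.reference, config.index_k)
    alignments = align_tags(unique_tags, index, config.max_mismatches)
    rate_pct = alignment_rate(alignments)

    logger.info("call: pileup and filter ladders")
    pileup = build_pileup(alignments, genomes.reference)
    candidates = call_candidates(pileup)
    lenient = filter_lenient(
        candidates, genomes.repeats,
        config.lenient_min_alt_reads, config.window, config.window_min_count,
    )
    stringent = filter_stringent(
        lenient, genomes.indel_positions,
        config.stringent_min_support, config.stringent_mq_min,
        config.stringent_cq_min, config.indel_flank,
        config.window, config.window_min_count,
    )
    final = cross_assembly_filter(
        stringent, genomes.reference, genomes.repeats,
        config.max_mismatches, config.index_k,
    )

    eval_regions = eval_footprint_regions(genomes, config)
    metrics = evaluate_calls(final, genomes, eval_regions)
    metrics["alignment_rate_pct"] = rate_pct
    metrics["n_candidates"] = len(candidates)
    metrics["n_lenient"] = len(lenient)
    metrics["n_stringent"] = len(stringent)
    metrics["n_final"] = len(final)
    metrics["paralog_or_repeat_false_calls"] = _count_paralog_false(
        lenient, genomes
    )
    fit = fit_gamma_overdispersion([r.read_count for r in tag_records])
    metrics["gamma_shape_fit"] = fit.shape
    metrics["var_mean_ratio"] = fit.var_mean_ratio

    result = PipelineResult(
        config=config,
        genomes=genomes,
        unique_tags=unique_tags,
        collapse_summary=collapse_summary,
        alignments=alignments,
        alignment_rate_pct=rate_pct,
        candidates=candidates,
        lenient=lenient,
        stringent=stringent,
        final=final,
        metrics=metrics,
    )
    if outdir is not None:
        result.outdir = Path(outdir)
        _write_artifacts(result, report, reads, tag_records, stamp)
    return result


def _count_paralog_false(
    calls: Sequence[SNPCandidate], genomes: SimulatedGenomes
) -> int:
    """Lenient-tier calls at duplicated or repeat loci with no truth variant."""
    truth_pos = {(v.chrom, v.position) for v in genomes.truth}
    n = 0
    for c in calls:
        if (c.chrom, c.position) in truth_pos:
            continue
        if genomes.duplications.covers(c.chrom, c.position) or genomes.repeats.covers(
            c.chrom, c.position
        ):
            n += 1
    return n


def _write_artifacts(result, report, reads, tag_records, stamp) -> None:
    out = result.outdir
    out.mkdir(parents=True, exist_ok=True)
    cfg = result.config
    genomes = result.genomes

    cfg.to_yaml(out / "config.yaml")
    write_fasta(genomes.reference, out / "reference.fa")
    write_fasta(genomes.alternate, out / "alternate.fa")
    write_bed(genomes.repeats.to_bed_rows(), out / "repeats.bed")
    write_bed(genomes.duplications.to_bed_rows(), out / "duplications.bed")
    truth_frame = pd.DataFrame(
        {
            "chrom": [v.chrom for v in genomes.truth],
            "pos": [v.position + 1 for v in genomes.truth],
            "ref": [v.ref for v in genomes.truth],
            "alt": [v.alt for v in genomes.truth],
            "type": [v.kind for v in genomes.truth],
            "in_footprint": [int(bool(v.in_footprint)) for v in genomes.truth],
        }
    )
    write_tsv(truth_frame, out / "truth.tsv", stamp)
    write_fastq(reads, out / "reads.fastq")
    write_tsv(reports_to_frame([report]), out / "digest_report.tsv", stamp)

    aln_frame = alignments_frame(result.alignments)
    write_tsv(aln_frame, out / "alignments.tsv", stamp)

    write_vcf(result.final, genomes.reference, out / "calls.vcf", stamp)
    write_vcf(
        sorted(
            result.candidates,
            key=lambda c: (list(genomes.reference).index(c.chrom), c.position),
        ),
        genomes.reference,
        out / "candidates_all.vcf",
        stamp,
    )

    audit_rows = []
    for c in result.candidates:
        row = {
            "chrom": c.chrom, "pos": c.position + 1, "ref": c.ref, "alt": c.alt,
            "depth": c.depth, "alt_count": c.alt_count,
            "consensus_quality": c.consensus_quality, "max_mq": c.max_mq,
            "tier": c.tier,
        }
        row.update({k: int(v) for k, v in c.audit.items()})
        audit_rows.append(row)
    write_tsv(pd.DataFrame(audit_rows), out / "filter_audit.tsv", stamp)

    flanks = [extract_flanks(c, genomes.reference, cfg.flank) for c in result.final]
    flank_frame = pd.DataFrame(
        {
            "id": [f"snp{i + 1}" for i in range(len(flanks))],
            "chrom": [f.candidate.chrom for f in flanks],
            "pos": [f.candidate.position + 1 for f in flanks],
            "context": [f.context for f in flanks],
            "truncated": [int(f.left_truncated or f.right_truncated) for f in flanks],
        }
    )
    write_tsv(flank_frame, out / "flanks.tsv", stamp)

    # survey reports
    hist = coverage_histogram(result.unique_tags)
    write_tsv(hist.reset_index(), out / "coverage_histogram.tsv", stamp)
    wstats = window_stats(
        genomes.reference, genomes.repeats, result.alignments, cfg.survey_window
    )
    wframe = window_stats_frame(wstats)
    write_tsv(wframe, out / "window_stats.tsv", stamp)
    if len(wframe) >= 3:
        result.metrics["r_repeat_coverage"] = pearson_r(
            wframe["repetitive_fraction"], wframe["read_count"]
        )
        result.metrics["r_gc_coverage"] = pearson_r(
            wframe["gc_fraction"], wframe["read_count"]
        )
    pct_above, pct_below = high_coverage_repeat_enrichment(
        result.alignments, genomes.repeats, cfg.high_coverage_threshold
    )
    result.metrics["pct_repetitive_high_coverage"] = pct_above
    result.metrics["pct_repetitive_low_coverage"] = pct_below
    aln_by_seq = {a.sequence: a for _, a in result.alignments if a is not None}
    posdist = snp_read_position_distribution(result.final, aln_by_seq, cfg.tag_len)
    write_tsv(
        pd.DataFrame({"read_position": range(1, cfg.tag_len + 1), "n_snps": posdist}),
        out / "snp_read_positions.tsv",
        stamp,
    )
    for k, v in result.collapse_summary.items():
        result.metrics[k] = v
    with open(out / "metrics.json", "w") as fh:
        json.dump(result.metrics, fh, indent=2, sort_keys=True, default=float)


def alignments_frame(
    alignments: Sequence[Tuple[UniqueTag, Optional[TagAlignment]]]
) -> pd.DataFrame:
    """Alignment table: tag, 1-based position, strand, mismatches, hits, MQ."""
    rows = []
    for tag, aln in alignments:
        if aln is None:
            rows.append(
                {
                    "tag": tag.sequence, "read_count": tag.read_count,
                    "chrom": "*", "pos": 0, "strand": ".",
                    "mismatches": -1, "best_hits": 0, "mq": 0,
                    "mean_qual": round(tag.mean_qual, 2),
                }
            )
        else:
            rows.append(
                {
                    "tag": tag.sequence, "read_count": tag.read_count,
                    "chrom": aln.chrom, "pos": aln.position + 1,
                    "strand": aln.strand, "mismatches": aln.n_mismatches,
                    "best_hits": aln.n_best_hits, "mq": aln.mapping_quality,
                    "mean_qual": round(tag.mean_qual, 2),
                }
            )
    return pd.DataFrame(rows)
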