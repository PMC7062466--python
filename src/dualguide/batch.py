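"""Batch orchestration over many genes and library-level reports."""

from __future__ import annotations

import csv
import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from .config import RunConfig
from .filters import PamSiteIndex
from .genome_io import GenomeSequence, read_fasta, read_gene_models
from .oligo_cloning import assemble_two_step, make_oligo, write_oligo_sheet
from .pair_select import DesignResult, design_gene
from .screen_stats import percent

logger = logging.getLogger(__name__)

PAIR_COLUMNS = [
    "gene", "rank", "proto_a", "pam_a", "strand_a", "cut_a",
    "proto_b", "pam_b", "strand_b", "cut_b",
    "genomic_cut_distance", "coding_separation",
    "transcript_bonus", "five_prime_bonus", "tss_bonus",
    "close_penalty", "near_penalty", "offtarget_penalty", "total", "status",
]


def gene_seed(base_seed: int, gene_id: str) -> int:
    """Stable per-gene sampling seed derived from the run seed."""
    h = int(hashlib.sha1(gene_id.encode()).hexdigest()[:8], 16)
    return (base_seed + h) % (2**31)


@dataclass
class BatchReport:
    results: dict[str, DesignResult]
    missing: list[str]
    config_hash: str
    seed: int

    @property
    def status_tally(self) -> dict[str, int]:
        tally: dict[str, int] = {}
        for r in self.results.values():
            tally[r.status] = tally.get(r.status, 0) + 1
        return tally


def design_batch(
    genome: GenomeSequence,
    models: list,
    gene_list: list[str] | None,
    config: RunConfig,
) -> BatchReport:
    """Design pairs for every requested gene; per-gene failures do not abort."""
    by_id = {m.gene_id: m for m in models}
    requested = list(by_id) if gene_list is None else list(gene_list)
    missing = [g for g in requested if g not in by_id]
    for g in missing:
        logger.warning("gene %s not present in the annotation", g)
    index = PamSiteIndex(genome, config.offtarget)
    results: dict[str, DesignResult] = {}
    for g in requested:
        if g in missing:
            continue
        results[g] = design_gene(
            genome,
            by_id[g],
            policy=config.offtarget,
            weights=config.scoring,
            max_pairs=config.sampling.max_pairs,
            seed=gene_seed(config.sampling.seed, g),
            k=config.sampling.pairs_per_gene,
            disjoint=config.sampling.disjoint_pairs,
            index=index,
        )
    return BatchReport(
        results=results,
        missing=missing,
        config_hash=config.config_hash(),
        seed=config.sampling.seed,
    )


def pair_rows(report: BatchReport) -> list[list]:
    rows = []
    for gene_id in sorted(report.results):
        r = report.results[gene_id]
        if not r.pairs:
            rows.append([gene_id] + [""] * (len(PAIR_COLUMNS) - 2) + [r.status])
            continue
        for rank, p in enumerate(r.pairs, start=1):
            s = p.score
            rows.append([
                gene_id, rank,
                p.guide_a.protospacer, p.guide_a.pam, p.guide_a.strand, p.guide_a.cut_site,
                p.guide_b.protospacer, p.guide_b.pam, p.guide_b.strand, p.guide_b.cut_site,
                p.genomic_cut_distance, p.coding_separation,
                f"{s.transcript_bonus:.4f}", f"{s.five_prime_bonus:.4f}",
                f"{s.tss_bonus:.4f}", f"{s.close_penalty:.4f}", f"{s.near_penalty:.4f}",
                f"{s.offtarget_penalty:.4f}", f"{s.total:.4f}", r.status,
            ])
    return rows


def run_design_batch(
    genome_path: str | Path,
    gff_path: str | Path,
    gene_list: list[str] | None,
    config: RunConfig,
    out_dir: str | Path,
) -> BatchReport:
    """File-level batch entry point: reads inputs, writes all run artifacts.

    Outputs under ``out_dir``: per-gene JSON audits, ``pairs.tsv``,
    ``oligos.tsv``, ``manifest.json`` and the resolved ``effective_config.yaml``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome = read_fasta(genome_path)
    models = read_gene_models(gff_path, genome)
    report = design_batch(genome, models, gene_list, config)

    with open(out / "pairs.tsv", "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(PAIR_COLUMNS)
        w.writerows(pair_rows(report))

    oligo_rows = []
    lib_no = 1
    for gene_id in sorted(report.results):
        for p in report.results[gene_id].pairs:
            oligo = make_oligo(p, config.cloning)
            oligo_rows.append({
                "library_id": f"DG{lib_no:05d}",
                "gene": gene_id,
                "proto1": p.guide_a.protospacer,
                "proto2": p.guide_b.protospacer,
                "oligo": oligo.full_sequence,
            })
            lib_no += 1
    write_oligo_sheet(oligo_rows, out / "oligos.tsv")

    audits = out / "genes"
    audits.mkdir(exist_ok=True)
    for gene_id, r in report.results.items():
        with open(audits / f"{gene_id}.json", "w") as fh:
            json.dump(_audit_dict(r), fh, indent=2)

    manifest = {
        "config_hash": report.config_hash,
        "seed": report.seed,
        "n_requested": len(report.results) + len(report.missing),
        "status_tally": report.status_tally,
        "missing": report.missing,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    config.write_effective(out / "effective_config.yaml")
    return report


def _audit_dict(r: DesignResult) -> dict:
    return {
        "gene_id": r.gene_id,
        "status": r.status,
        "seed": r.seed,
        "n_enumerated": r.n_enumerated,
        "n_filtered": r.n_filtered,
        "n_pairs_scored": r.n_pairs_scored,
        "pairs": [
            {
                "proto_a": p.guide_a.protospacer,
                "proto_b": p.guide_b.protospacer,
                "genomic_cut_distance": p.genomic_cut_distance,
                "coding_separation": p.coding_separation,
                "score": dataclasses.asdict(p.score) | {"total": p.score.total},
            }
            for p in r.pairs
        ],
        "filter_fails": [
            dataclasses.asdict(f) for f in r.filter_records if f.verdict == "fail"
        ],
    }


def assemble_batch(report: BatchReport, config: RunConfig) -> dict[str, "AssembledCassette"]:
    """Run the two-step assembly for every selected pair in a batch."""
    cassettes = {}
    for gene_id in sorted(report.results):
        for rank, p in enumerate(report.results[gene_id].pairs, start=1):
            cassettes[f"{gene_id}.pair{rank}"] = assemble_two_step(p, config.cloning)
    return cassettes


@dataclass
class CoverageRow:
    group: str
    designed: int
    total: int
    pct: int | None


def coverage_report(
    designed_genes: set[str], category_map: dict[str, str], rounding: str = "half_away"
) -> list[CoverageRow]:
    """Per-functional-group designed/total counts and integer percentages."""
    groups: dict[str, list[str]] = {}
    for gene, group in category_map.items():
        groups.setdefault(group, []).append(gene)
    rows = []
    for group in sorted(groups):
        members = groups[group]
        done = sum(1 for g in members if g in designed_genes)
        rows.append(CoverageRow(group, done, len(members),
                                percent(done, len(members), rounding)))
    return rows


def write_coverage_report(rows: list[CoverageRow], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["group", "designed", "total", "percent"])
        for r in rows:
            w.writerow([r.group, r.designed, r.total, "NA" if r.pct is None else r.pct])
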