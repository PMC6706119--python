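"""Batch guide design and table export.

Runs the full pipeline (resolve -> scan -> off-target search -> score ->
annotate -> filter) for up to 100 target queries and emits the 14-column
design table as RFC-4180 CSV plus a tabix-ready sorted BED6.  Locations in
the CSV use the 1-based colon dialect; BED output stays 0-based half-open.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field
from pathlib import Path

from .annotate_filter import (
    FilterConfig,
    apply_filters,
    closest_mismatch,
    hit_exon,
    mismatch_histogram,
)
from .config import ScoringConfig
from .genome_io import (
    GeneModel,
    GenomeSequence,
    GenomicInterval,
    QueryLimits,
    resolve_target,
)
from .offtarget_search import OffTargetHit, build_index, enumerate_offtargets
from .scoring import (
    EfficiencyModel,
    default_weights,
    efficiency_score,
    score_guide,
)
from .site_scanner import ProtospacerSite, scan_protospacers

__all__ = [
    "CSV_COLUMNS",
    "DesignRecord",
    "BatchRequest",
    "BatchResult",
    "design_batch",
    "guide_id",
    "parse_guide_id",
    "export_csv",
    "write_sorted_bed",
    "write_detail_json",
]

CSV_COLUMNS = [
    "Guide RNA", "Location", "Strand", "Target", "HitExon", "MM", "SpecMIT",
    "EffiSSC", "Exon", "OtExon", "OtExonDist", "OT", "OtDist", "GuideID",
]


@dataclass
class DesignRecord:
    """One row of the design table."""

    guide_rna: str  # spacer sequence (PAM excluded)
    location: GenomicInterval
    strand: str
    target: str  # the originating query text
    hit_exon: int | None  # composite/transcript exon rank; None when n/a
    mm: int | None  # closest mismatch over all off-targets; None = no hits
    spec_mit: float
    effi_ssc: float | None
    exon: bool
    ot_exon: int
    ot_exon_dist: str
    ot: int
    ot_dist: str
    guide_id: str
    budget: int = 4
    pam: str = ""
    offtargets: list[OffTargetHit] = field(default_factory=list, repr=False)


@dataclass
class BatchRequest:
    entries: list[str]
    genome: GenomeSequence
    gene_models: list[GeneModel] = field(default_factory=list)
    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    filters: FilterConfig | None = None
    efficiency_model: EfficiencyModel | None = None
    allow_oversize: bool = False  # override of the 100-entry cap


@dataclass
class BatchResult:
    records: list[DesignRecord]
    errors: list[tuple[str, str]] = field(default_factory=list)  # (entry, message)


def guide_id(
    record_or_locus, assembly_label: str, guide_length: int | None = None
) -> str:
    """Stable identifier ``<assembly>_<chrom>_<start0>_<strand>_<L>``."""
    if isinstance(record_or_locus, GenomicInterval):
        locus = record_or_locus
    elif hasattr(record_or_locus, "locus"):
        locus = record_or_locus.locus
    else:
        locus = record_or_locus.location
    L = guide_length if guide_length is not None else len(locus)
    return f"{assembly_label}_{locus.chrom}_{locus.start}_{locus.strand}_{L}"


_GUIDE_ID_RE = re.compile(r"^(?P<asm>.+)_(?P<chrom>[\w.]+)_(?P<start>\d+)_(?P<strand>[+-])_(?P<L>\d+)$")


def parse_guide_id(text: str) -> tuple[str, GenomicInterval, int]:
    """Invert guide_id: (assembly, spacer interval with strand, guide length)."""
    m = _GUIDE_ID_RE.match(text)
    if not m:
        raise ValueError(f"malformed guide id {text!r}")
    start = int(m.group("start"))
    L = int(m.group("L"))
    return (
        m.group("asm"),
        GenomicInterval(m.group("chrom"), start, start + L, m.group("strand")),
        L,
    )


def _exonic(interval: GenomicInterval, gene_models: list[GeneModel]) -> bool:
    for gene in gene_models:
        if gene.chrom != interval.chrom:
            continue
        if any(interval.overlaps(e) for e in gene.composite_exons):
            return True
    return False


def _design_site(
    site: ProtospacerSite,
    target_label: str,
    ranking_mode: str,
    report_hit_exon: bool,
    index,
    request: BatchRequest,
    budget: int,
    weights,
) -> DesignRecord:
    cfg = request.scoring
    hits = enumerate_offtargets(
        site.spacer,
        site.locus,
        index,
        budget=budget,
        include_repeats=cfg.include_repeats,
    )
    spec = score_guide(site.spacer, hits, weights, cfg.pam_multipliers)
    exonic_hits = [
        h for h in hits if _exonic(h.locus, request.gene_models)
    ]
    effi = None
    if request.efficiency_model is not None:
        effi = efficiency_score(site, request.genome, request.efficiency_model)
    rank = None
    if report_hit_exon:
        ranked = hit_exon(site.locus, request.gene_models, ranking_mode)
        rank = ranked[1] if ranked else None
    return DesignRecord(
        guide_rna=site.spacer,
        location=site.locus,
        strand=site.strand,
        target=target_label,
        hit_exon=rank,
        mm=closest_mismatch(hits),
        spec_mit=spec.aggregate,
        effi_ssc=effi,
        exon=_exonic(site.locus, request.gene_models),
        ot_exon=len(exonic_hits),
        ot_exon_dist=mismatch_histogram(exonic_hits, budget).text,
        ot=len(hits),
        ot_dist=mismatch_histogram(hits, budget).text,
        guide_id=guide_id(site.locus, request.genome.assembly_label, site.guide_length),
        budget=budget,
        pam=site.pam,
        offtargets=hits,
    )


def design_batch(request: BatchRequest) -> BatchResult:
    """Design guides for every entry; per-entry failures are collected.

    Raises on more than ``scoring.max_entries`` entries (default 100) unless
    ``allow_oversize`` is set — the cap protects shared runs, it is not a
    method limit.
    """
    cfg = request.scoring
    if len(request.entries) > cfg.max_entries and not request.allow_oversize:
        raise ValueError(
            f"batch of {len(request.entries)} entries exceeds the "
            f"{cfg.max_entries}-entry limit"
        )
    budget = cfg.resolved_budget()
    weights = default_weights(cfg.guide_length)
    index = build_index(
        request.genome, cfg.guide_length, budget, cfg.offtarget_pams
    )
    limits = QueryLimits(cfg.sequence_max_bases)
    records: list[DesignRecord] = []
    errors: list[tuple[str, str]] = []
    for entry in request.entries:
        try:
            query = resolve_target(entry, request.genome, request.gene_models, limits)
            # coordinate input: exon rank is not reported
            report_hit_exon = query.resolved_kind in {"gene", "transcript"}
            for interval in query.intervals:
                for site in scan_protospacers(
                    request.genome, interval, cfg.guide_length, cfg.pam_pattern
                ):
                    records.append(
                        _design_site(
                            site,
                            entry.strip(),
                            query.ranking_mode,
                            report_hit_exon,
                            index,
                            request,
                            budget,
                            weights,
                        )
                    )
        except (ValueError, KeyError) as exc:
            errors.append((entry, str(exc)))
    if request.filters is not None:
        records = apply_filters(records, request.filters)
    return BatchResult(records, errors)


def _format_mm(record: DesignRecord) -> str:
    if record.mm is None:
        return f"> {record.budget}"
    return str(record.mm)


def record_to_row(record: DesignRecord) -> list[str]:
    return [
        record.guide_rna,
        record.location.to_region_string(),
        record.strand,
        record.target,
        "" if record.hit_exon is None else str(record.hit_exon),
        _format_mm(record),
        f"{record.spec_mit:.2f}",
        "" if record.effi_ssc is None else f"{record.effi_ssc:.2f}",
        "yes" if record.exon else "no",
        str(record.ot_exon),
        record.ot_exon_dist,
        str(record.ot),
        record.ot_dist,
        record.guide_id,
    ]


def export_csv(records: list[DesignRecord], path: str | Path) -> None:
    """Write the 14-column design table (RFC-4180; scores to 2 decimals)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for record in records:
            writer.writerow(record_to_row(record))


def write_sorted_bed(records: list[DesignRecord], path: str | Path) -> None:
    """BED6 of guide loci sorted (chrom lexicographic, start numeric) —
    the order bgzip/tabix indexing requires."""
    rows = sorted(records, key=lambda r: (r.location.chrom, r.location.start))
    with open(path, "w") as fh:
        for r in rows:
            fh.write(
                f"{r.location.chrom}\t{r.location.start}\t{r.location.end}\t"
                f"{r.guide_id}\t{round(r.spec_mit)}\t{r.strand}\n"
            )


def _format_offtarget_sequence(spacer: str, hit: OffTargetHit) -> str:
    """Off-target protospacer with mismatched bases upper-case, matches lower."""
    out = []
    mism = set(hit.mismatch_positions)
    for i, base in enumerate(hit.sequence, start=1):
        out.append(base.upper() if i in mism else base.lower())
    return "".join(out)


def write_detail_json(
    records: list[DesignRecord],
    gene_models: list[GeneModel],
    path: str | Path,
) -> None:
    """Per-guide off-target detail dump: sequence (mismatches upper-cased),
    location with strand, mismatch count, score, and hit-exon gene."""
    payload = {}
    for record in records:
        rows = []
        for hit in record.offtargets:
            hexon = hit_exon(hit.locus, gene_models)
            rows.append(
                {
                    "off_target_sequence": _format_offtarget_sequence(
                        record.guide_rna, hit
                    ),
                    "location": hit.locus.to_region_string() + hit.strand,
                    "mismatch": hit.mismatch_count,
                    "score": None if hit.hit_score is None else round(hit.hit_score, 4),
                    "pam": hit.pam,
                    "hit_exon": hexon[0] if hexon else None,
                }
            )
        payload[record.guide_id] = rows
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
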