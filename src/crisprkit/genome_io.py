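"""Genome and annotation I/O plus target-query resolution.

Everything downstream speaks one coordinate currency: :class:`GenomicInterval`,
0-based half-open on a named contig.  Region text in the UCSC-browser colon
dialect (``chr1:100-200``) is interpreted as 1-based inclusive and converted on
parse; BED lines pass through unchanged.  Reference FASTA is read with case
preserved, since lowercase soft-masking marks repeat regions and drives repeat
handling in the scanner and off-target search.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

__all__ = [
    "GenomicInterval",
    "GenomeSequence",
    "Transcript",
    "GeneModel",
    "TargetQuery",
    "QueryLimits",
    "read_fasta",
    "parse_region",
    "read_gene_models",
    "resolve_target",
    "merge_intervals",
]

# IUPAC nucleotide codes (both cases accepted everywhere; lowercase = soft-masked)
IUPAC_CHARS = set("ACGTURYSWKMBDHVN") | set("acgturyswkmbdhvn")

UNSTRANDED = "."

_REGION_RE = re.compile(r"^(?P<chrom>[\w.]+):(?P<start>[\d,]+)-(?P<end>[\d,]+)$")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open span on a contig with optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = UNSTRANDED

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in {"+", "-", UNSTRANDED}:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def to_region_string(self) -> str:
        """Colon-dialect text, 1-based inclusive (browser convention)."""
        return f"{self.chrom}:{self.start + 1}-{self.end}"


@dataclass
class GenomeSequence:
    """A reference genome held in memory: contig name -> nucleotide string."""

    contigs: dict[str, str]
    assembly_label: str = "custom"

    def __post_init__(self) -> None:
        for name, seq in self.contigs.items():
            if not name:
                raise ValueError("empty contig name")
            bad = set(seq) - IUPAC_CHARS
            if bad:
                raise ValueError(
                    f"contig {name!r} contains non-IUPAC characters: {sorted(bad)}"
                )

    def fetch(self, interval: GenomicInterval) -> str:
        """Forward-strand genomic text for an interval (case preserved)."""
        self.check_bounds(interval)
        return self.contigs[interval.chrom][interval.start : interval.end]

    def check_bounds(self, interval: GenomicInterval) -> None:
        if interval.chrom not in self.contigs:
            raise KeyError(f"unknown contig {interval.chrom!r}")
        if interval.end > len(self.contigs[interval.chrom]):
            raise ValueError(
                f"interval {interval.chrom}:{interval.start}-{interval.end} "
                f"extends beyond contig length {len(self.contigs[interval.chrom])}"
            )


@dataclass
class Transcript:
    transcript_id: str
    chrom: str
    strand: str
    exons: list[GenomicInterval]

    def __post_init__(self) -> None:
        exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(exons, exons[1:]):
            if a.end > b.start:
                raise ValueError(
                    f"transcript {self.transcript_id}: overlapping exons "
                    f"{a.start}-{a.end} and {b.start}-{b.end}"
                )
        self.exons = exons

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    def ranked_exons(self) -> list[tuple[int, GenomicInterval]]:
        """Exons with 1-based ranks in transcription (5'->3') order."""
        ordered = self.exons if self.strand != "-" else list(reversed(self.exons))
        return [(i + 1, e) for i, e in enumerate(ordered)]


def merge_intervals(intervals: list[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals on one contig, returned sorted and disjoint."""
    if not intervals:
        return []
    chroms = {iv.chrom for iv in intervals}
    if len(chroms) > 1:
        raise ValueError(f"cannot merge intervals across contigs {sorted(chroms)}")
    srt = sorted(intervals, key=lambda e: e.start)
    merged = [[srt[0].start, srt[0].end]]
    for iv in srt[1:]:
        if iv.start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], iv.end)
        else:
            merged.append([iv.start, iv.end])
    chrom = srt[0].chrom
    return [GenomicInterval(chrom, s, e) for s, e in merged]


@dataclass
class GeneModel:
    """A gene: its transcripts plus the composite (merged-exon) model.

    ``composite_exons`` is the interval union of all transcript exons,
    ranked 1..n in transcription direction — the basis of "HitExon"
    numbering when a gene symbol is the query.
    """

    gene_symbol: str
    aliases: set[str] = field(default_factory=set)
    transcripts: list[Transcript] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValueError(f"gene {self.gene_symbol}: no transcripts")
        chroms = {t.chrom for t in self.transcripts}
        if len(chroms) > 1:
            raise ValueError(
                f"gene {self.gene_symbol}: transcripts on multiple contigs {sorted(chroms)}"
            )

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom

    @property
    def strand(self) -> str:
        return self.transcripts[0].strand

    @property
    def span(self) -> GenomicInterval:
        start = min(t.span.start for t in self.transcripts)
        end = max(t.span.end for t in self.transcripts)
        return GenomicInterval(self.chrom, start, end, self.strand)

    @property
    def composite_exons(self) -> list[GenomicInterval]:
        all_exons = [e for t in self.transcripts for e in t.exons]
        return merge_intervals(all_exons)

    def ranked_composite_exons(self) -> list[tuple[int, GenomicInterval]]:
        merged = self.composite_exons
        ordered = merged if self.strand != "-" else list(reversed(merged))
        return [(i + 1, e) for i, e in enumerate(ordered)]


@dataclass
class QueryLimits:
    sequence_max_bases: int = 20000


@dataclass
class TargetQuery:
    """A resolved user query: gene symbol, transcript ID, region, or raw DNA."""

    raw_text: str
    resolved_kind: str  # gene | transcript | region | sequence
    intervals: list[GenomicInterval]
    gene: GeneModel | None = None
    ranking_mode: str = "composite"  # or "transcript:<id>"


def read_fasta(path: str | Path, assembly_label: str | None = None) -> GenomeSequence:
    """Read a (possibly multi-contig) FASTA; headers truncate at whitespace.

    Case is preserved so soft-masking survives the round trip.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    contigs: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        name = record.id  # SeqIO already truncates at first whitespace
        if name in contigs:
            raise ValueError(f"duplicate contig name {name!r} in {path}")
        contigs[name] = str(record.seq)
    if not contigs:
        raise ValueError(f"no sequences in {path}")
    return GenomeSequence(contigs, assembly_label or path.stem)


def parse_region(text: str) -> GenomicInterval:
    """Parse one region in either dialect.

    ``chrX:NNNNN-NNNNN`` is 1-based inclusive; a tab-separated BED line is
    0-based half-open with strand taken from column 6 when present.
    """
    text = text.strip()
    if "\t" in text:
        fields = text.split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed BED line: {text!r}")
        chrom, start_s, end_s = fields[0], fields[1], fields[2]
        try:
            start, end = int(start_s), int(end_s)
        except ValueError as exc:
            raise ValueError(f"malformed BED coordinates in {text!r}") from exc
        strand = UNSTRANDED
        if len(fields) >= 6 and fields[5] in {"+", "-"}:
            strand = fields[5]
        if start >= end:
            raise ValueError(f"empty or inverted BED interval: {text!r}")
        return GenomicInterval(chrom, start, end, strand)
    m = _REGION_RE.match(text)
    if not m:
        raise ValueError(f"malformed region text: {text!r}")
    start1 = int(m.group("start").replace(",", ""))
    end1 = int(m.group("end").replace(",", ""))
    if start1 < 1 or start1 > end1:
        raise ValueError(f"invalid region coordinates: {text!r}")
    return GenomicInterval(m.group("chrom"), start1 - 1, end1, UNSTRANDED)


def _parse_int_list(text: str) -> list[int]:
    return [int(x) for x in text.strip().rstrip(",").split(",") if x != ""]


def _parse_refgene_line(fields: list[str], lineno: int) -> tuple[str, Transcript]:
    """One refGene row -> (gene symbol, transcript).

    Handles both layouts: with the UCSC ``bin`` column first and without.
    """
    # with bin: bin, name, chrom, strand, txStart, txEnd, cdsStart, cdsEnd,
    #           exonCount, exonStarts, exonEnds, score, name2, ...
    offset = None
    if len(fields) >= 13 and fields[0].lstrip("-").isdigit() and fields[3] in "+-":
        offset = 1
    elif len(fields) >= 12 and fields[2] in "+-":
        offset = 0
    if offset is None:
        raise ValueError(f"line {lineno}: unparseable refGene row")
    try:
        name = fields[offset + 0]
        chrom = fields[offset + 1]
        strand = fields[offset + 2]
        exon_count = int(fields[offset + 7])
        exon_starts = _parse_int_list(fields[offset + 8])
        exon_ends = _parse_int_list(fields[offset + 9])
        name2 = fields[offset + 11]
    except (IndexError, ValueError) as exc:
        raise ValueError(f"line {lineno}: unparseable refGene row") from exc
    if len(exon_starts) != len(exon_ends) or len(exon_starts) != exon_count:
        raise ValueError(
            f"line {lineno}: exonStarts/exonEnds length mismatch for {name}"
        )
    exons = [
        GenomicInterval(chrom, s, e, strand) for s, e in zip(exon_starts, exon_ends)
    ]
    return name2, Transcript(name, chrom, strand, exons)


def _parse_bed12_line(fields: list[str], lineno: int) -> tuple[str, Transcript]:
    if len(fields) < 12:
        raise ValueError(f"line {lineno}: BED12 requires 12 fields")
    try:
        chrom = fields[0]
        start = int(fields[1])
        name = fields[3]
        strand = fields[5]
        block_count = int(fields[9])
        sizes = _parse_int_list(fields[10])
        offsets = _parse_int_list(fields[11])
    except ValueError as exc:
        raise ValueError(f"line {lineno}: unparseable BED12 row") from exc
    if len(sizes) != block_count or len(offsets) != block_count:
        raise ValueError(f"line {lineno}: block size/offset length mismatch")
    exons = [
        GenomicInterval(chrom, start + o, start + o + sz, strand)
        for o, sz in zip(offsets, sizes)
    ]
    return name, Transcript(name, chrom, strand, exons)


def read_gene_models(path: str | Path, dialect: str = "refgene") -> list[GeneModel]:
    """Read gene models from a refGene-style table or a BED12 file.

    refGene transcripts are grouped into genes by the ``name2`` symbol; in
    BED12 the ``name`` column serves as both transcript and gene identifier.
    """
    if dialect not in {"refgene", "bed12"}:
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    by_gene: dict[str, list[Transcript]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if dialect == "refgene":
                symbol, tx = _parse_refgene_line(fields, lineno)
            else:
                symbol, tx = _parse_bed12_line(fields, lineno)
            by_gene.setdefault(symbol, []).append(tx)
    models = []
    for symbol, txs in by_gene.items():
        aliases = {t.transcript_id for t in txs}
        models.append(GeneModel(symbol, aliases, txs))
    return models


def _is_dna(text: str) -> bool:
    return bool(text) and set(text.upper()) <= set("ACGTN")


def _build_lookup(
    gene_models: list[GeneModel],
) -> dict[str, list[tuple[GeneModel, str | None]]]:
    lookup: dict[str, list[tuple[GeneModel, str | None]]] = {}
    for gene in gene_models:
        lookup.setdefault(gene.gene_symbol.lower(), []).append((gene, None))
        for tx in gene.transcripts:
            lookup.setdefault(tx.transcript_id.lower(), []).append(
                (gene, tx.transcript_id)
            )
        for alias in gene.aliases - {t.transcript_id for t in gene.transcripts}:
            lookup.setdefault(alias.lower(), []).append((gene, None))
    return lookup


def _find_exact_matches(
    seq: str, genome: GenomeSequence
) -> list[GenomicInterval]:
    """All exact genomic occurrences of seq (forward and reverse complement)."""
    from .site_scanner import reverse_complement

    query_fwd = seq.upper()
    query_rev = reverse_complement(query_fwd)
    hits = []
    for chrom, contig in genome.contigs.items():
        text = contig.upper()
        for query, strand in ((query_fwd, "+"), (query_rev, "-")):
            pos = text.find(query)
            while pos != -1:
                hits.append(GenomicInterval(chrom, pos, pos + len(query), strand))
                pos = text.find(query, pos + 1)
    # a palindromic query matches both strands at one locus: one site
    uniq = {(h.chrom, h.start, h.end) for h in hits}
    if len(uniq) < len(hits):
        hits = sorted(hits, key=lambda h: (h.chrom, h.start, h.strand))
        hits = [
            h
            for i, h in enumerate(hits)
            if i == 0
            or (h.chrom, h.start, h.end)
            != (hits[i - 1].chrom, hits[i - 1].start, hits[i - 1].end)
        ]
    return hits


def resolve_target(
    raw_text: str,
    genome: GenomeSequence,
    gene_models: list[GeneModel] | None = None,
    limits: QueryLimits | None = None,
) -> TargetQuery:
    """Resolve a query to genomic intervals.

    Resolution order: region text, then gene/transcript identifier
    (case-insensitive), then raw DNA placed by exact match (unique occurrence
    required; fuzzy placement is out of scope).
    """
    limits = limits or QueryLimits()
    gene_models = gene_models or []
    text = raw_text.strip()
    if not text:
        raise ValueError("empty target query")

    if "\t" in text or _REGION_RE.match(text):
        interval = parse_region(text)
        genome.check_bounds(interval)
        return TargetQuery(raw_text, "region", [interval])

    lookup = _build_lookup(gene_models)
    entries = lookup.get(text.lower())
    if entries:
        genes = {g.gene_symbol for g, _ in entries}
        if len(genes) > 1:
            raise ValueError(
                f"ambiguous identifier {text!r}: matches genes {sorted(genes)}"
            )
        gene, tx_id = entries[0]
        if tx_id is not None:
            tx = next(t for t in gene.transcripts if t.transcript_id == tx_id)
            return TargetQuery(
                raw_text,
                "transcript",
                [tx.span],
                gene=gene,
                ranking_mode=f"transcript:{tx_id}",
            )
        return TargetQuery(raw_text, "gene", [gene.span], gene=gene)

    if _is_dna(text):
        if len(text) > limits.sequence_max_bases:
            raise ValueError(
                f"input sequence of {len(text)} bases exceeds the "
                f"{limits.sequence_max_bases}-base limit"
            )
        hits = _find_exact_matches(text, genome)
        if not hits:
            raise ValueError("input sequence has no exact genomic match")
        if len(hits) > 1:
            raise ValueError(
                f"input sequence matches the genome at {len(hits)} loci; "
                "a unique placement is required"
            )
        return TargetQuery(raw_text, "sequence", hits)

    raise ValueError(f"unknown identifier {text!r}")
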