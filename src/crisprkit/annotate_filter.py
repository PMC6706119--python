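"""Exon annotation, mismatch-distribution summaries, and batch filters.

"Exonic" means at least one spacer base overlaps at least one exon base
(the PAM is excluded — cleavage happens inside the spacer).  Exon ranks come
from either the gene's composite model (the merged exon union, numbered in
transcription direction) or a single transcript's exon list when a
transcript ID was the query.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genome_io import GeneModel, GenomicInterval
from .offtarget_search import OffTargetHit

__all__ = [
    "MismatchHistogram",
    "FilterConfig",
    "hit_exon",
    "mismatch_histogram",
    "closest_mismatch",
    "apply_filters",
]


@dataclass(frozen=True)
class MismatchHistogram:
    """Counts of off-target hits per mismatch number, 0..budget.

    The text form is colon-joined, e.g. ``0:0:0:0:4`` for four hits all at
    4 mismatches under a budget of 4.
    """

    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts):
            raise ValueError("histogram counts must be non-negative")

    @property
    def text(self) -> str:
        return ":".join(str(c) for c in self.counts)

    @property
    def total(self) -> int:
        return sum(self.counts)

    @classmethod
    def from_text(cls, text: str) -> "MismatchHistogram":
        return cls(tuple(int(x) for x in text.split(":")))


def mismatch_histogram(
    hits: list[OffTargetHit], budget: int = 4
) -> MismatchHistogram:
    """Tally hits into budget+1 bins by mismatch count."""
    counts = [0] * (budget + 1)
    for h in hits:
        if h.mismatch_count > budget:
            raise ValueError(
                f"hit with {h.mismatch_count} mismatches exceeds budget {budget}"
            )
        counts[h.mismatch_count] += 1
    return MismatchHistogram(tuple(counts))


def closest_mismatch(hits: list[OffTargetHit]) -> int | None:
    """Minimum mismatch count over hits; None when there are no hits."""
    if not hits:
        return None
    return min(h.mismatch_count for h in hits)


def hit_exon(
    interval: GenomicInterval,
    gene_models: list[GeneModel],
    ranking_mode: str = "composite",
) -> tuple[str, int] | None:
    """(gene symbol, exon rank) for the exon a guide overlaps, else None.

    Composite mode ranks against each gene's merged exons in transcription
    order; ``transcript:<id>`` mode ranks against that transcript's own
    exons.  A guide touching several merged exons reports the lowest rank.
    Genes are visited in symbol order so ties resolve deterministically.
    """
    if ranking_mode.startswith("transcript:"):
        tx_id = ranking_mode.split(":", 1)[1]
        for gene in gene_models:
            for tx in gene.transcripts:
                if tx.transcript_id == tx_id:
                    ranks = [
                        rank
                        for rank, exon in tx.ranked_exons()
                        if interval.overlaps(exon)
                    ]
                    if ranks:
                        return (gene.gene_symbol, min(ranks))
                    return None
        raise KeyError(f"unknown transcript id {tx_id!r}")
    if ranking_mode != "composite":
        raise ValueError(f"unknown ranking mode {ranking_mode!r}")
    for gene in sorted(gene_models, key=lambda g: g.gene_symbol):
        if gene.chrom != interval.chrom:
            continue
        ranks = [
            rank
            for rank, exon in gene.ranked_composite_exons()
            if interval.overlaps(exon)
        ]
        if ranks:
            return (gene.gene_symbol, min(ranks))
    return None


@dataclass
class FilterConfig:
    """The four batch-design presets.

    Thresholds follow the panel semantics: specificity is inclusive
    (``>= 50``), efficiency and closest-mismatch are strict (``> 0``,
    ``> 1``).  Setting a numeric threshold to None disables that predicate;
    ``none()`` disables everything.
    """

    exonic_only: bool = True
    min_specificity: float | None = 50.0
    min_efficiency_exclusive: float | None = 0.0
    min_closest_mismatch_exclusive: int | None = 1

    @classmethod
    def none(cls) -> "FilterConfig":
        return cls(False, None, None, None)


def _require(record, attr: str):
    if not hasattr(record, attr):
        raise ValueError(f"record lacks field {attr!r} needed by an enabled filter")
    return getattr(record, attr)


def apply_filters(records: list, config: FilterConfig) -> list:
    """Keep records satisfying every enabled predicate; order preserved.

    Records with no off-target hits (closest mismatch None) pass the
    mismatch predicate vacuously — no similar sequence exists anywhere.
    """
    kept = []
    for rec in records:
        if config.exonic_only and not _require(rec, "exon"):
            continue
        if config.min_specificity is not None:
            if _require(rec, "spec_mit") < config.min_specificity:
                continue
        if config.min_efficiency_exclusive is not None:
            eff = _require(rec, "effi_ssc")
            if eff is None:
                raise ValueError(
                    "efficiency filter enabled but record has no efficiency score"
                )
            if eff <= config.min_efficiency_exclusive:
                continue
        if config.min_closest_mismatch_exclusive is not None:
            mm = _require(rec, "mm")
            if mm is not None and mm <= config.min_closest_mismatch_exclusive:
                continue
        kept.append(rec)
    return kept
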