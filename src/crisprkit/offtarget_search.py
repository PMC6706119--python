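"""Mismatch-budgeted genome-wide off-target enumeration.

Every genomic window (both strands) whose 3'-adjacent 3-mer is an allowed
PAM (NGG or NAG by default) is a potential off-target locus for some guide.
Enumeration is exact within the Hamming budget via pigeonhole seed-and-verify:
the spacer is partitioned into ``budget + 1`` contiguous blocks, so any
occurrence with at most ``budget`` mismatches must match at least one block
exactly.  Candidate windows sharing a block are then verified by a full
Hamming comparison.  ``brute_force_offtargets`` scans every window instead
and serves as the independent correctness oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .genome_io import GenomeSequence, GenomicInterval
from .site_scanner import pam_matches, reverse_complement

__all__ = [
    "OffTargetHit",
    "SearchIndex",
    "build_index",
    "enumerate_offtargets",
    "brute_force_offtargets",
    "DEFAULT_PAM_SET",
]

DEFAULT_PAM_SET = ("NGG", "NAG")


@dataclass
class OffTargetHit:
    """One genomic occurrence of a spacer within the mismatch budget.

    ``mismatch_positions`` are 1-based, counted from the PAM-distal (5') end
    of the spacer — the convention of the mismatch-weight vector, whose large
    weights sit PAM-proximal.
    """

    locus: GenomicInterval
    strand: str
    sequence: str  # genomic protospacer, 5'->3' on the hit strand, uppercase
    pam: str
    pam_class: str  # "NGG" or "NAG"
    mismatch_count: int
    mismatch_positions: list[int]
    hit_score: float | None = None
    in_repeat: bool = False

    def key(self) -> tuple:
        return (self.locus.chrom, self.locus.start, self.strand)


def _classify_pam(pam: str) -> str | None:
    pam = pam.upper()
    if pam[1:] == "GG":
        return "NGG"
    if pam[1:] == "AG":
        return "NAG"
    return None


def seed_blocks(guide_length: int, budget: int) -> list[tuple[int, int]]:
    """Partition 0..guide_length into budget+1 contiguous blocks (near-even)."""
    k = budget + 1
    if guide_length < k:
        raise ValueError(
            f"guide_length {guide_length} cannot be split into {k} seed blocks"
        )
    base, extra = divmod(guide_length, k)
    blocks = []
    pos = 0
    for i in range(k):
        size = base + (1 if i < extra else 0)
        blocks.append((pos, pos + size))
        pos += size
    return blocks


@dataclass
class _Window:
    chrom: str
    start: int
    strand: str
    protospacer: str  # uppercase, 5'->3' on strand
    pam: str  # uppercase
    pam_class: str
    in_repeat: bool


@dataclass
class SearchIndex:
    """Seed tables over every PAM-adjacent window of a genome."""

    guide_length: int
    budget: int
    pam_set: tuple[str, ...]
    blocks: list[tuple[int, int]]
    windows: list[_Window]
    tables: list[dict[str, list[int]]] = field(repr=False, default_factory=list)

    @property
    def seed_count(self) -> int:
        return self.budget + 1


def _iter_pam_windows(genome: GenomeSequence, guide_length: int, pam_set):
    """Yield every PAM-adjacent window on both strands (N-containing skipped)."""
    L = guide_length
    rc_patterns = [reverse_complement(p) for p in pam_set]
    for chrom, contig in genome.contigs.items():
        n = len(contig)
        for i in range(0, n - L + 1):
            if i + L + 3 <= n:
                pam = contig[i + L : i + L + 3]
                if any(pam_matches(pam, p) for p in pam_set):
                    window = contig[i : i + L]
                    if "N" not in window.upper() and "N" not in pam.upper():
                        cls = _classify_pam(pam)
                        if cls is not None:
                            yield _Window(
                                chrom, i, "+", window.upper(), pam.upper(), cls,
                                in_repeat=not (window + pam).isupper(),
                            )
            if i - 3 >= 0:
                pam_fwd = contig[i - 3 : i]
                if any(pam_matches(pam_fwd, p) for p in rc_patterns):
                    window = contig[i : i + L]
                    if "N" not in window.upper() and "N" not in pam_fwd.upper():
                        pam = reverse_complement(pam_fwd).upper()
                        cls = _classify_pam(pam)
                        if cls is not None:
                            yield _Window(
                                chrom, i, "-",
                                reverse_complement(window).upper(), pam, cls,
                                in_repeat=not (window + pam_fwd).isupper(),
                            )


def build_index(
    genome: GenomeSequence,
    guide_length: int = 20,
    budget: int = 4,
    pam_set: tuple[str, ...] = DEFAULT_PAM_SET,
) -> SearchIndex:
    """Index all PAM-adjacent windows for seed lookup.

    With ``budget + 1`` disjoint seed blocks, the pigeonhole principle
    guarantees any occurrence within the budget shares one exact block.
    """
    if budget < 0:
        raise ValueError("budget must be >= 0")
    blocks = seed_blocks(guide_length, budget)
    windows = list(_iter_pam_windows(genome, guide_length, tuple(pam_set)))
    tables: list[dict[str, list[int]]] = [dict() for _ in blocks]
    for wi, w in enumerate(windows):
        for bi, (s, e) in enumerate(blocks):
            tables[bi].setdefault(w.protospacer[s:e], []).append(wi)
    return SearchIndex(guide_length, budget, tuple(pam_set), blocks, windows, tables)


def _hamming(a: str, b: str) -> list[int]:
    """1-based mismatch positions (5' end = position 1)."""
    return [i + 1 for i, (x, y) in enumerate(zip(a, b)) if x != y]


def _make_hit(spacer: str, w: _Window, guide_length: int) -> OffTargetHit:
    positions = _hamming(spacer, w.protospacer)
    return OffTargetHit(
        locus=GenomicInterval(w.chrom, w.start, w.start + guide_length, w.strand),
        strand=w.strand,
        sequence=w.protospacer,
        pam=w.pam,
        pam_class=w.pam_class,
        mismatch_count=len(positions),
        mismatch_positions=positions,
        in_repeat=w.in_repeat,
    )


def _check_spacer(spacer: str, guide_length: int) -> str:
    spacer = spacer.upper()
    if len(spacer) != guide_length:
        raise ValueError(
            f"spacer length {len(spacer)} != guide length {guide_length}"
        )
    if set(spacer) - set("ACGT"):
        raise ValueError("spacer must contain only A/C/G/T")
    return spacer


def _filter_hits(
    hits: list[OffTargetHit],
    on_target_locus: GenomicInterval | None,
    include_repeats: bool,
) -> list[OffTargetHit]:
    out = []
    seen = set()
    for h in hits:
        if h.key() in seen:
            continue
        seen.add(h.key())
        if on_target_locus is not None:
            if (
                h.locus.chrom == on_target_locus.chrom
                and h.locus.start == on_target_locus.start
                and h.strand == on_target_locus.strand
            ):
                continue  # the on-target site itself is not an off-target
        if not include_repeats and h.in_repeat:
            continue
        out.append(h)
    out.sort(key=lambda h: (h.mismatch_count, h.locus.chrom, h.locus.start, h.strand))
    return out


def enumerate_offtargets(
    spacer: str,
    on_target_locus: GenomicInterval | None,
    index: SearchIndex,
    budget: int | None = None,
    include_repeats: bool = False,
) -> list[OffTargetHit]:
    """All off-target loci of ``spacer`` within the Hamming budget.

    The hit at ``on_target_locus`` (same interval and strand) is excluded;
    a perfect duplicate elsewhere counts as a 0-mismatch off-target.
    """
    if budget is None:
        budget = index.budget
    if budget > index.budget:
        raise ValueError(
            f"budget {budget} exceeds the index budget {index.budget}"
        )
    spacer = _check_spacer(spacer, index.guide_length)
    candidates: set[int] = set()
    for bi, (s, e) in enumerate(index.blocks):
        candidates.update(index.tables[bi].get(spacer[s:e], ()))
    hits = []
    for wi in candidates:
        w = index.windows[wi]
        positions = _hamming(spacer, w.protospacer)
        if len(positions) <= budget:
            hits.append(_make_hit(spacer, w, index.guide_length))
    return _filter_hits(hits, on_target_locus, include_repeats)


def brute_force_offtargets(
    spacer: str,
    on_target_locus: GenomicInterval | None,
    genome: GenomeSequence,
    budget: int = 4,
    pam_set: tuple[str, ...] = DEFAULT_PAM_SET,
    include_repeats: bool = False,
) -> list[OffTargetHit]:
    """Exhaustive-scan oracle with the same contract as enumerate_offtargets."""
    guide_length = len(spacer)
    spacer = _check_spacer(spacer, guide_length)
    hits = []
    for w in _iter_pam_windows(genome, guide_length, tuple(pam_set)):
        positions = _hamming(spacer, w.protospacer)
        if len(positions) <= budget:
            hits.append(_make_hit(spacer, w, guide_length))
    return _filter_hits(hits, on_target_locus, include_repeats)
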