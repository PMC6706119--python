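"""Protospacer (candidate guide) enumeration on both strands.

A candidate site is a ``guide_length``-nt spacer whose 3'-adjacent 3-mer
matches the on-target PAM pattern (NGG for SpCas9).  Minus-strand sites are
detected as the reverse-complement pattern on the forward text, so one pass
over each contig covers both strands.  Sites whose spacer or PAM contains N
are dropped; sites touching soft-masked (lowercase) bases are kept but
flagged ``in_repeat`` — exclusion is a downstream policy, not a scanner one.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genome_io import GenomeSequence, GenomicInterval

__all__ = ["ProtospacerSite", "scan_protospacers", "reverse_complement", "pam_matches"]

_COMPLEMENT = str.maketrans(
    "ACGTURYSWKMBDHVNacgturyswkmbdhvn",
    "TGCAAYRSWMKVHDBNtgcaayrswmkvhdbn",
)

# IUPAC code -> set of concrete bases it stands for
IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "GC", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def reverse_complement(seq: str) -> str:
    """Reverse complement of an IUPAC nucleotide string, case preserved."""
    bad = set(seq) - set("ACGTURYSWKMBDHVNacgturyswkmbdhvn")
    if bad:
        raise ValueError(f"non-IUPAC characters in sequence: {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


def pam_matches(pam: str, pattern: str) -> bool:
    """Does a concrete 3-mer match an IUPAC PAM pattern? N never matches."""
    if len(pam) != len(pattern):
        return False
    for base, code in zip(pam.upper(), pattern.upper()):
        if base not in IUPAC_SETS.get(code, ""):
            return False
    return True


@dataclass(frozen=True)
class ProtospacerSite:
    """A candidate guide: spacer + PAM anchored at a genomic locus.

    ``locus`` covers the spacer only (PAM excluded); ``spacer`` and ``pam``
    are stored uppercase, read 5'->3' on the site's strand.  ``in_repeat``
    records whether any spacer/PAM base was soft-masked in the reference.
    """

    locus: GenomicInterval
    strand: str
    spacer: str
    pam: str
    guide_length: int
    in_repeat: bool = False

    def __post_init__(self) -> None:
        if len(self.spacer) != self.guide_length:
            raise ValueError("spacer length does not match guide_length")
        if len(self.pam) != 3:
            raise ValueError("PAM must be 3 nt")


def scan_protospacers(
    genome: GenomeSequence,
    interval: GenomicInterval,
    guide_length: int = 20,
    pam_pattern: str = "NGG",
) -> list[ProtospacerSite]:
    """All candidate sites whose spacer lies within ``interval``, both strands.

    The spacer must fit inside the interval; the PAM may use genome context
    just beyond it (guides at an exon edge still get their genomic PAM).
    Output is sorted by (start, strand).
    """
    if guide_length not in (20, 18):
        raise ValueError(f"guide_length must be 20 or 18, got {guide_length}")
    genome.check_bounds(interval)
    contig = genome.contigs[interval.chrom]
    L = guide_length
    rc_pattern = reverse_complement(pam_pattern)  # e.g. NGG -> CCN on forward text
    sites = []
    for i in range(interval.start, interval.end - L + 1):
        window = contig[i : i + L]
        # plus strand: PAM immediately 3' on the forward text
        if i + L + 3 <= len(contig):
            pam = contig[i + L : i + L + 3]
            if pam_matches(pam, pam_pattern):
                spacer = window
                if "N" not in spacer.upper() and "N" not in pam.upper():
                    sites.append(
                        ProtospacerSite(
                            GenomicInterval(interval.chrom, i, i + L, "+"),
                            "+",
                            spacer.upper(),
                            pam.upper(),
                            L,
                            in_repeat=not (spacer + pam).isupper(),
                        )
                    )
        # minus strand: PAM is 5' on the forward text, reverse-complemented
        if i - 3 >= 0:
            pam_fwd = contig[i - 3 : i]
            if pam_matches(pam_fwd, rc_pattern):
                spacer = reverse_complement(window)
                pam = reverse_complement(pam_fwd)
                if "N" not in spacer.upper() and "N" not in pam.upper():
                    sites.append(
                        ProtospacerSite(
                            GenomicInterval(interval.chrom, i, i + L, "-"),
                            "-",
                            spacer.upper(),
                            pam.upper(),
                            L,
                            in_repeat=not (window + pam_fwd).isupper(),
                        )
                    )
    sites.sort(key=lambda s: (s.locus.start, s.strand))
    return sites
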