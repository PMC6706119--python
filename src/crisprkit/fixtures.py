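"""Deterministic synthetic genomes with planted guides and off-targets.

Every test runs against genomes built here: random base sequence, planted
protospacer+PAM sites at declared loci, planted off-targets at exact Hamming
distances, optional soft-masked repeat blocks, and simple gene models.  After
writing, every planted guide is re-checked by the brute-force off-target
scanner: the enumerated hit set must equal the planted one exactly, otherwise
the genome is regenerated with a fresh stream (bounded retries).  The emitted
manifest is therefore the unique ground truth for the whole pipeline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genome_io import GenomeSequence, GenomicInterval
from .offtarget_search import brute_force_offtargets, DEFAULT_PAM_SET
from .site_scanner import reverse_complement

__all__ = [
    "PlantedOffTarget",
    "PlantedGuide",
    "GeneDef",
    "FixtureSpec",
    "FixtureFiles",
    "generate_fixture",
    "random_genome",
]

BASES = "ACGT"


@dataclass
class PlantedOffTarget:
    """An off-target copy of a guide's spacer at an exact Hamming distance."""

    contig: str
    position: int  # spacer start, 0-based forward coordinates
    strand: str = "+"
    mismatch_positions: tuple[int, ...] = ()  # 1-based from the 5' end
    pam: str = "TGG"  # concrete PAM written into the genome
    soft_masked: bool = False

    @property
    def n_mismatches(self) -> int:
        return len(self.mismatch_positions)


@dataclass
class PlantedGuide:
    """An on-target site plus its declared off-target copies."""

    contig: str
    position: int
    strand: str = "+"
    spacer: str | None = None  # None -> drawn from the RNG
    guide_length: int = 20
    pam: str = "TGG"
    offtargets: list[PlantedOffTarget] = field(default_factory=list)


@dataclass
class GeneDef:
    """A gene to write into the annotation: (tx id, exon spans) per transcript."""

    symbol: str
    contig: str
    strand: str = "+"
    transcripts: list[tuple[str, list[tuple[int, int]]]] = field(default_factory=list)


@dataclass
class FixtureSpec:
    contig_lengths: dict[str, int]
    seed: int = 0
    gc: float = 0.5
    guides: list[PlantedGuide] = field(default_factory=list)
    genes: list[GeneDef] = field(default_factory=list)
    repeat_blocks: list[GenomicInterval] = field(default_factory=list)
    budget: int = 4
    pam_set: tuple[str, ...] = DEFAULT_PAM_SET
    assembly_label: str = "synth1"
    max_attempts: int = 50


@dataclass
class FixtureFiles:
    genome: GenomeSequence
    fasta_path: Path
    annotation_path: Path
    manifest_path: Path
    manifest: dict


def random_genome(
    rng: np.random.Generator, contig_lengths: dict[str, int], gc: float = 0.5
) -> dict[str, str]:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return {
        name: "".join(
            np.array(list(BASES))[rng.choice(4, size=length, p=probs)]
        )
        for name, length in contig_lengths.items()
    }


def _mutate(spacer: str, positions: tuple[int, ...], rng: np.random.Generator) -> str:
    out = list(spacer)
    for p in positions:
        if p < 1 or p > len(spacer):
            raise ValueError(f"mismatch position {p} outside spacer 1..{len(spacer)}")
        choices = [b for b in BASES if b != out[p - 1]]
        out[p - 1] = choices[rng.integers(len(choices))]
    return "".join(out)


def _write_site(
    contigs: dict[str, list[str]],
    contig: str,
    position: int,
    strand: str,
    protospacer: str,
    pam: str,
) -> None:
    """Write protospacer+PAM into the forward text at the spacer locus."""
    if strand == "+":
        text = protospacer + pam
        start = position
    else:
        text = reverse_complement(protospacer + pam)
        start = position - len(pam)
    seq = contigs[contig]
    if start < 0 or start + len(text) > len(seq):
        raise ValueError(
            f"planted site {contig}:{position}{strand} does not fit the contig"
        )
    seq[start : start + len(text)] = list(text)


def _plant(spec: FixtureSpec, rng: np.random.Generator):
    """One generation attempt: returns (contigs dict of str, guide truths)."""
    contigs = {
        name: list(seq)
        for name, seq in random_genome(rng, spec.contig_lengths, spec.gc).items()
    }
    truths = []
    for guide in spec.guides:
        spacer = guide.spacer or "".join(
            BASES[i] for i in rng.integers(4, size=guide.guide_length)
        )
        _write_site(
            contigs, guide.contig, guide.position, guide.strand, spacer, guide.pam
        )
        planted_hits = []
        for ot in guide.offtargets:
            variant = _mutate(spacer, ot.mismatch_positions, rng)
            _write_site(
                contigs, ot.contig, ot.position, ot.strand, variant, ot.pam
            )
            if ot.soft_masked:
                seq = contigs[ot.contig]
                if ot.strand == "+":
                    lo, hi = ot.position, ot.position + len(variant) + len(ot.pam)
                else:
                    lo, hi = ot.position - len(ot.pam), ot.position + len(variant)
                seq[lo:hi] = [c.lower() for c in seq[lo:hi]]
            planted_hits.append((ot, variant))
        truths.append((guide, spacer, planted_hits))
    # soft-mask declared repeat blocks last so planted bases keep their case flags
    masked = {name: seq for name, seq in contigs.items()}
    for block in spec.repeat_blocks:
        seq = masked[block.chrom]
        seq[block.start : block.end] = [
            c.lower() for c in seq[block.start : block.end]
        ]
    return {name: "".join(seq) for name, seq in masked.items()}, truths


def _verify(spec: FixtureSpec, genome: GenomeSequence, truths) -> list[dict] | None:
    """Check each guide's brute-force hit set equals its planted set.

    Returns per-guide manifest entries, or None when an accidental
    within-budget occurrence collides with the plant.
    """
    entries = []
    for guide, spacer, planted_hits in truths:
        on_locus = GenomicInterval(
            guide.contig,
            guide.position,
            guide.position + len(spacer),
            guide.strand,
        )
        expected = {}
        for ot, _variant in planted_hits:
            # the repeat flag covers spacer + PAM on the hit's strand
            if ot.strand == "+":
                win = GenomicInterval(
                    ot.contig, ot.position, ot.position + len(spacer) + 3
                )
            else:
                win = GenomicInterval(
                    ot.contig, max(0, ot.position - 3), ot.position + len(spacer)
                )
            masked = ot.soft_masked or any(
                block.overlaps(win) for block in spec.repeat_blocks
            )
            if ot.n_mismatches <= spec.budget and not masked:
                expected[(ot.contig, ot.position, ot.strand)] = ot.n_mismatches
        found = brute_force_offtargets(
            spacer, on_locus, genome, spec.budget, spec.pam_set, include_repeats=False
        )
        found_map = {h.key(): h.mismatch_count for h in found}
        if found_map != expected:
            return None
        counts = [0] * (spec.budget + 1)
        for n in expected.values():
            counts[n] += 1
        entries.append(
            {
                "spacer": spacer,
                "contig": guide.contig,
                "start": guide.position,
                "strand": guide.strand,
                "guide_length": len(spacer),
                "pam": guide.pam,
                "offtargets": [
                    {
                        "contig": ot.contig,
                        "start": ot.position,
                        "strand": ot.strand,
                        "mismatches": ot.n_mismatches,
                        "expected_found": (ot.contig, ot.position, ot.strand)
                        in expected,
                    }
                    for ot, _ in planted_hits
                ],
                "n_offtargets": len(expected),
                "histogram": ":".join(str(c) for c in counts),
                "closest_mismatch": min(expected.values()) if expected else None,
            }
        )
    return entries


def _write_refgene(spec: FixtureSpec, path: Path) -> None:
    with open(path, "w") as fh:
        for gene in spec.genes:
            for tx_id, exons in gene.transcripts:
                exons = sorted(exons)
                starts = ",".join(str(s) for s, _ in exons) + ","
                ends = ",".join(str(e) for _, e in exons) + ","
                fh.write(
                    "\t".join(
                        [
                            tx_id,
                            gene.contig,
                            gene.strand,
                            str(exons[0][0]),
                            str(exons[-1][1]),
                            str(exons[0][0]),
                            str(exons[-1][1]),
                            str(len(exons)),
                            starts,
                            ends,
                            "0",
                            gene.symbol,
                        ]
                    )
                    + "\n"
                )


def generate_fixture(spec: FixtureSpec, outdir: str | Path) -> FixtureFiles:
    """Write FASTA + refGene annotation + JSON manifest for a fixture spec.

    Same spec (same seed) always produces byte-identical files.  Raises when
    no collision-free genome is found within ``max_attempts``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for attempt in range(spec.max_attempts):
        rng = np.random.default_rng(
            np.random.SeedSequence([spec.seed, attempt])
        )
        contigs, truths = _plant(spec, rng)
        genome = GenomeSequence(contigs, spec.assembly_label)
        entries = _verify(spec, genome, truths)
        if entries is not None:
            break
    else:
        raise RuntimeError(
            f"no collision-free genome found in {spec.max_attempts} attempts; "
            "the fixture spec may be infeasible"
        )
    fasta_path = outdir / "genome.fa"
    with open(fasta_path, "w") as fh:
        for name, seq in contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    annotation_path = outdir / "genes.refgene.txt"
    _write_refgene(spec, annotation_path)
    manifest = {
        "assembly": spec.assembly_label,
        "seed": spec.seed,
        "budget": spec.budget,
        "pam_set": list(spec.pam_set),
        "attempt": attempt,
        "guides": entries,
    }
    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1)
    return FixtureFiles(genome, fasta_path, annotation_path, manifest_path, manifest)
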