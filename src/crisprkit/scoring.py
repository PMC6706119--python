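"""Specificity and efficiency scoring of candidate guides.

Specificity follows the MIT/Hsu scheme: each off-target hit contributes

    s = prod_p (1 - M[p]) * D * 1/n^2

where the product runs over the mismatch positions ``p`` (1 = PAM-distal 5'
end), ``M`` is the per-position mismatch-weight vector, ``n`` the mismatch
count, and ``D = 1 / (((L-1-dbar)/(L-1)) * 4 + 1)`` penalises tightly
clustered mismatches through their mean pairwise spacing
``dbar = (max - min)/(n - 1)``.  Hits are aggregated as

    S = 10000 / (100 + 100 * sum_h s_h)

so a guide with no similar genomic sequence scores 100 and one perfect
genomic duplicate halves the score to 50.  Truncated (18-nt) guides are
scored with the two PAM-distal weight positions removed and L = 18.

Efficiency scoring is a pluggable linear model over the guide's genomic
context (upstream flank + spacer + PAM + downstream flank), loaded from a
TSV coefficient file; the geometry travels with the coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .genome_io import GenomeSequence, GenomicInterval
from .offtarget_search import OffTargetHit
from .site_scanner import ProtospacerSite, reverse_complement

__all__ = [
    "MIT_MISMATCH_WEIGHTS",
    "MismatchWeightVector",
    "SpecificityResult",
    "EfficiencyModel",
    "single_hit_score",
    "aggregate_specificity",
    "truncated_weights",
    "score_guide",
    "load_efficiency_model",
    "efficiency_score",
]

# Experimentally determined per-position mismatch effects, PAM-distal first.
MIT_MISMATCH_WEIGHTS = (
    0.0, 0.0, 0.014, 0.0, 0.0,
    0.395, 0.317, 0.0, 0.389, 0.079,
    0.445, 0.508, 0.613, 0.851, 0.732,
    0.828, 0.615, 0.804, 0.685, 0.583,
)


@dataclass(frozen=True)
class MismatchWeightVector:
    weights: tuple[float, ...] = MIT_MISMATCH_WEIGHTS
    source_label: str = "MIT/Hsu 20-nt"

    def __post_init__(self) -> None:
        if any(w < 0 or w > 1 for w in self.weights):
            raise ValueError("mismatch weights must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.weights)


@dataclass
class SpecificityResult:
    aggregate: float
    per_hit: list[tuple[OffTargetHit, float]] = field(default_factory=list)


def truncated_weights(
    weights20: MismatchWeightVector | tuple[float, ...] = MIT_MISMATCH_WEIGHTS,
) -> MismatchWeightVector:
    """18-nt weight vector: drop the two PAM-distal positions of a 20-vector."""
    if isinstance(weights20, MismatchWeightVector):
        label = weights20.source_label
        weights20 = weights20.weights
    else:
        label = "truncated"
    if len(weights20) != 20:
        raise ValueError(f"expected a 20-position weight vector, got {len(weights20)}")
    return MismatchWeightVector(tuple(weights20[2:]), f"{label} (18-nt truncated)")


def default_weights(guide_length: int) -> MismatchWeightVector:
    if guide_length == 20:
        return MismatchWeightVector()
    if guide_length == 18:
        return truncated_weights()
    raise ValueError(f"no default weight vector for guide length {guide_length}")


def single_hit_score(
    spacer: str,
    hit: OffTargetHit,
    weights: MismatchWeightVector | None = None,
) -> float:
    """Per-hit specificity contribution in [0, 1]; 1 = a perfect duplicate."""
    L = len(spacer)
    if weights is None:
        weights = default_weights(L)
    if len(weights) != L:
        raise ValueError(f"weight vector length {len(weights)} != spacer length {L}")
    positions = sorted(hit.mismatch_positions)
    if any(p < 1 or p > L for p in positions):
        raise ValueError(f"mismatch position out of range 1..{L}: {positions}")
    n = len(positions)
    if n == 0:
        return 1.0
    product = 1.0
    for p in positions:
        product *= 1.0 - weights.weights[p - 1]
    if n == 1:
        return product  # D = 1 and 1/n^2 = 1 for a lone mismatch
    dbar = (positions[-1] - positions[0]) / (n - 1)
    distance_factor = 1.0 / (((L - 1 - dbar) / (L - 1)) * 4.0 + 1.0)
    return product * distance_factor / (n * n)


def aggregate_specificity(per_hit_scores) -> float:
    """Aggregate score in (0, 100]; empty hit list scores 100."""
    total = 0.0
    for s in per_hit_scores:
        if s < 0 or s > 1:
            raise ValueError(f"per-hit score outside [0, 1]: {s}")
        total += s
    return 10000.0 / (100.0 + 100.0 * total)


def score_guide(
    spacer: str,
    hits: list[OffTargetHit],
    weights: MismatchWeightVector | None = None,
    pam_multipliers: dict[str, float] | None = None,
) -> SpecificityResult:
    """Score every hit, fill ``hit_score`` in place, and aggregate.

    ``pam_multipliers`` optionally down-weights non-canonical PAM classes
    (default 1.0 for both NGG and NAG).
    """
    pam_multipliers = pam_multipliers or {}
    per_hit = []
    for hit in hits:
        s = single_hit_score(spacer, hit, weights)
        s *= pam_multipliers.get(hit.pam_class, 1.0)
        hit.hit_score = s
        per_hit.append((hit, s))
    return SpecificityResult(
        aggregate_specificity([s for _, s in per_hit]), per_hit
    )


@dataclass
class EfficiencyModel:
    """Linear sequence model over the guide's genomic context.

    ``window_offsets = (upstream, spacer, pam, downstream)`` lengths define
    the scored window; coefficients are keyed by (1-based window position,
    nucleotide), missing entries scoring 0.
    """

    window_offsets: tuple[int, int, int, int] = (4, 20, 3, 3)
    coefficients: dict[tuple[int, str], float] = field(default_factory=dict)
    intercept: float = 0.0
    model_label: str = "toy"

    @property
    def window_length(self) -> int:
        return sum(self.window_offsets)

    def score_context(self, context: str) -> float:
        if len(context) != self.window_length:
            raise ValueError(
                f"context length {len(context)} != window length {self.window_length}"
            )
        total = self.intercept
        for pos, nt in enumerate(context.upper(), start=1):
            total += self.coefficients.get((pos, nt), 0.0)
        return total


def load_efficiency_model(path: str | Path) -> EfficiencyModel:
    """Read a coefficient TSV.

    Header lines: ``#model <label>``, ``#window <up> <spacer> <pam> <down>``,
    ``#intercept <value>``; body rows are ``position<TAB>nucleotide<TAB>weight``
    with positions 1-based over the declared window.
    """
    path = Path(path)
    window = None
    intercept = None
    label = path.stem
    coefficients: dict[tuple[int, str], float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].split()
                key = parts[0].lower()
                if key == "window":
                    if len(parts) != 5:
                        raise ValueError(f"line {lineno}: #window needs 4 lengths")
                    window = tuple(int(x) for x in parts[1:])
                elif key == "intercept":
                    intercept = float(parts[1])
                elif key == "model":
                    label = " ".join(parts[1:]) or label
                continue
            if window is None or intercept is None:
                raise ValueError(
                    "missing #window/#intercept header before coefficient rows"
                )
            fields = line.split("\t")
            if len(fields) != 3:
                raise ValueError(f"line {lineno}: expected 3 tab-separated fields")
            pos = int(fields[0])
            nt = fields[1].upper()
            if nt not in "ACGT":
                raise ValueError(f"line {lineno}: unknown nucleotide {fields[1]!r}")
            if pos < 1 or pos > sum(window):
                raise ValueError(
                    f"line {lineno}: position {pos} outside window 1..{sum(window)}"
                )
            coefficients[(pos, nt)] = float(fields[2])
    if window is None or intercept is None:
        raise ValueError(f"{path}: missing #window/#intercept header")
    return EfficiencyModel(window, coefficients, intercept, label)


def efficiency_score(
    site: ProtospacerSite,
    genome: GenomeSequence,
    model: EfficiencyModel,
) -> float | None:
    """Model score of a site's genomic context, or None near a contig edge.

    The context is upstream flank + spacer + PAM + downstream flank read
    5'->3' on the site's strand (minus-strand context is reverse-complemented
    before scoring).
    """
    up, spacer_len, pam_len, down = model.window_offsets
    if spacer_len != site.guide_length:
        raise ValueError(
            f"model expects a {spacer_len}-nt spacer, site has {site.guide_length}"
        )
    contig = genome.contigs[site.locus.chrom]
    if site.strand == "+":
        start = site.locus.start - up
        end = site.locus.end + pam_len + down
        if start < 0 or end > len(contig):
            return None
        context = contig[start:end]
    else:
        start = site.locus.start - pam_len - down
        end = site.locus.end + up
        if start < 0 or end > len(contig):
            return None
        context = reverse_complement(contig[start:end])
    return model.score_context(context)
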