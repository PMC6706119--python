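"""Run-level configuration shared by the pipeline and the CLI."""

from __future__ import annotations

from dataclasses import dataclass, field

from .offtarget_search import DEFAULT_PAM_SET

__all__ = ["ScoringConfig", "default_budget", "MAX_BATCH_ENTRIES", "SEQUENCE_MAX_BASES"]

#: batch cap: at most this many queries per run
MAX_BATCH_ENTRIES = 100
#: longest raw-DNA query accepted
SEQUENCE_MAX_BASES = 20000


def default_budget(guide_length: int) -> int:
    """Default off-target mismatch budget: 4 for 20-nt guides, 3 for 18-nt.

    Off-target alignments grow rapidly with the budget; truncated 18-nt
    guides with more than 3 mismatches rarely show detectable cleavage, so
    their search stops one mismatch earlier.
    """
    if guide_length == 20:
        return 4
    if guide_length == 18:
        return 3
    raise ValueError(f"no default budget for guide length {guide_length}")


@dataclass
class ScoringConfig:
    """Guide-design parameters: lengths, budgets, PAM sets, limits."""

    guide_length: int = 20
    budget: int | None = None  # None -> default_budget(guide_length)
    pam_pattern: str = "NGG"  # on-target PAM
    offtarget_pams: tuple[str, ...] = DEFAULT_PAM_SET  # NGG + non-canonical NAG
    include_repeats: bool = False
    pam_multipliers: dict[str, float] = field(
        default_factory=lambda: {"NGG": 1.0, "NAG": 1.0}
    )
    sequence_max_bases: int = SEQUENCE_MAX_BASES
    max_entries: int = MAX_BATCH_ENTRIES
    promoter: str | None = None  # U6 / T7; metadata only, no sequence rule

    def resolved_budget(self) -> int:
        return self.budget if self.budget is not None else default_budget(
            self.guide_length
        )
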