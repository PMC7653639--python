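"""Breeding-system classification for dioecious, potentially apomictic taxa.

The decision logic codifies how clone counts, geography, growth habit, male
sightings and ploidy combine into a sexual-vs-apomictic call for a dioecious
plant taxon:

1. Recorded males prove functional sexual reproduction.
2. Where clonality is testable (several samples from known distinct
   localities), multiple clones indicate sexual recruitment, while a single
   clone spread over two or more localities in a *solitary* (non-stoloniferous)
   taxon can only be explained by clonal seed — apomixis.
3. Where clonality cannot be tested (a single sample, or material without
   distinct wild localities, e.g. cultivated accessions), the call falls back
   to ploidy: odd-numbered ploidy (3x, 5x) marks gametophytic apomixis and
   even ploidy defaults to sexual.  Such calls are flagged ``inferred``.
4. A uniclonal *stoloniferous* taxon is flagged inconclusive: vegetative
   spread mimics the genetic footprint of apomixis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import InconclusiveError, ValidationError
from .io import HABITS


@dataclass(frozen=True)
class TaxonEvidence:
    """Per-taxon inputs to the classification.

    ``n_localities`` is None when distinct wild localities are unknown
    (cultivated or imported material); ``males_recorded`` is None when male
    occurrence was not assessed.
    """

    taxon: str
    n_clones: int
    n_localities: int | None
    habit: str
    males_recorded: bool | None
    ploidy: int | None
    n_samples: int

    def __post_init__(self) -> None:
        if self.habit not in HABITS:
            raise ValidationError(f"unknown habit {self.habit!r} for {self.taxon}")
        if self.n_clones > self.n_samples:
            raise ValidationError(
                f"{self.taxon}: n_clones ({self.n_clones}) exceeds n_samples "
                f"({self.n_samples})"
            )


@dataclass
class SystemCall:
    call: str  # "sexual" | "apomictic"
    inferred: bool
    flagged_inconclusive: bool = False
    rationale: list[str] = field(default_factory=list)


def clonality_testable(e: TaxonEvidence) -> bool:
    """Clonality is testable with >= 2 samples from known, >= 2 distinct
    localities (a single multi-sampled population also counts: distinct
    individuals from one known locality can still reveal multiple clones)."""
    if e.n_samples < 2:
        return False
    if e.n_localities is None:
        return False
    return True


def classify(e: TaxonEvidence) -> SystemCall:
    """Apply the rule cascade in the module docstring to one taxon."""
    rationale: list[str] = []

    if e.males_recorded:
        rationale.append("males recorded: functional sexual reproduction")
        return SystemCall("sexual", inferred=False, rationale=rationale)

    if not clonality_testable(e):
        rationale.append(
            "clonality untestable (single sample or unknown wild localities)"
        )
        if e.ploidy is None:
            raise InconclusiveError(
                f"{e.taxon}: clonality untestable and ploidy unknown — no call possible"
            )
        if e.ploidy % 2 == 1:
            rationale.append(
                f"odd ploidy ({e.ploidy}x) consistent with gametophytic apomixis"
            )
            return SystemCall("apomictic", inferred=True, rationale=rationale)
        rationale.append(f"even ploidy ({e.ploidy}x): sexual origin assumed")
        return SystemCall("sexual", inferred=True, rationale=rationale)

    if e.n_clones >= 2:
        rationale.append(f"{e.n_clones} clones among {e.n_samples} samples: "
                         "sexual recruitment")
        return SystemCall("sexual", inferred=False, rationale=rationale)

    # single clone, testable
    if e.habit == "stoloniferous":
        rationale.append(
            "uniclonal but stoloniferous: vegetative spread confounds apomixis"
        )
        return SystemCall(
            "apomictic", inferred=False, flagged_inconclusive=True, rationale=rationale
        )
    if e.n_localities is not None and e.n_localities >= 2:
        rationale.append(
            f"one clone across {e.n_localities} distinct localities in a solitary "
            "herb: clonal seed dispersal (apomixis)"
        )
        return SystemCall("apomictic", inferred=False, rationale=rationale)

    # solitary, uniclonal, single locality: fall back to ploidy
    rationale.append("uniclonal at a single locality: clone spread untestable")
    if e.ploidy is None:
        raise InconclusiveError(
            f"{e.taxon}: single-locality uniclonal taxon with unknown ploidy"
        )
    if e.ploidy % 2 == 1:
        rationale.append(f"odd ploidy ({e.ploidy}x) consistent with gametophytic apomixis")
        return SystemCall("apomictic", inferred=True, rationale=rationale)
    rationale.append(f"even ploidy ({e.ploidy}x): sexual origin assumed")
    return SystemCall("sexual", inferred=True, rationale=rationale)
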