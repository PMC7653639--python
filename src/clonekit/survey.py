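"""Published summary data for the Singapore *Hanguana* survey.

These records reproduce the per-taxon summary of the island-wide survey of
Hanguanaceae (a dioecious tropical monocot family): sample and locality
counts, growth habit, male sightings, clones detected, estimated ploidy and
flow-cytometric genome sizes.  They serve as reference inputs for the
genome-size arithmetic and for the breeding-system classifier — printed
evidence in, classification out.

``n_localities`` is None for non-native accessions without distinct wild
localities; ``males_recorded`` is None where male occurrence was not
assessed locally.
"""

from __future__ import annotations

from dataclasses import dataclass

from .breeding import TaxonEvidence


@dataclass(frozen=True)
class SurveyRecord:
    taxon: str
    n_samples: int
    n_duplicates: int
    n_localities: int | None
    native: bool
    habit: str
    n_clones: int
    males_recorded: bool | None
    system: str  # "sexual" | "apomictic"
    system_inferred: bool  # clonality untestable, call inferred from ploidy/males
    ploidy: int
    two_c_pg: float
    one_cx_pg: float


SURVEY: tuple[SurveyRecord, ...] = (
    SurveyRecord("Hanguana anthelminthica", 5, 0, None, False, "stoloniferous",
                 2, None, "sexual", True, 4, 2.290, 0.573),
    SurveyRecord("Hanguana corneri", 1, 0, None, False, "solitary",
                 1, None, "sexual", True, 2, 1.493, 0.747),
    SurveyRecord("Hanguana fraseriana", 1, 0, None, False, "solitary",
                 1, None, "apomictic", True, 3, 2.099, 0.700),
    SurveyRecord("Hanguana neglecta", 23, 7, 11, True, "solitary",
                 1, False, "apomictic", False, 5, 3.561, 0.712),
    SurveyRecord("Hanguana nitens", 12, 3, 1, True, "stoloniferous",
                 8, True, "sexual", False, 2, 1.276, 0.638),
    SurveyRecord("Hanguana podzolicola", 8, 1, 5, True, "solitary",
                 1, False, "apomictic", False, 3, 2.050, 0.683),
    SurveyRecord("Hanguana rubinea", 75, 4, 47, True, "solitary",
                 1, False, "apomictic", False, 3, 2.027, 0.676),
    SurveyRecord("Hanguana triangulata", 9, 3, 8, True, "solitary",
                 1, False, "apomictic", False, 3, 2.001, 0.667),
    SurveyRecord("Hanguana sp. 'MacRitchie'", 2, 1, 2, True, "solitary",
                 1, False, "apomictic", False, 3, 1.990, 0.663),
    SurveyRecord("Hanguana sp. 'Mandai'", 1, 1, 1, True, "solitary",
                 1, False, "apomictic", True, 3, 1.995, 0.665),
)

# Diploid anchor taxa whose 1Cx values span the expected monoploid size range.
DIPLOID_ANCHOR_TAXA = ("Hanguana nitens", "Hanguana corneri")

# Earlier literature 2C estimate for H. neglecta (Feulgen densitometry,
# different calibration standard), against which the survey value is ~8 % higher.
LITERATURE_2C_PG = {"Hanguana neglecta": 3.29}


def evidence_from_record(rec: SurveyRecord) -> TaxonEvidence:
    """Strip a survey record down to classifier inputs (the detected-system
    columns are withheld so the classification is genuinely recomputed)."""
    return TaxonEvidence(
        taxon=rec.taxon,
        n_clones=rec.n_clones,
        n_localities=rec.n_localities,
        habit=rec.habit,
        males_recorded=rec.males_recorded,
        ploidy=rec.ploidy,
        n_samples=rec.n_samples,
    )


def diploid_anchor_cx() -> list[float]:
    by_taxon = {rec.taxon: rec for rec in SURVEY}
    return [by_taxon[t].one_cx_pg for t in DIPLOID_ANCHOR_TAXA]
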