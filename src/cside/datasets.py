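"""Published cohort summaries for the Swedish colour-sidedness survey.

These are the breed/period cohort sizes and marker counts from the published
survey of Swedish native cattle (multiplex breakpoint-PCR genotyping of
animals born 1976–2015 plus contemporary 2023–2024 samples, and 30
whole-genome-sequenced animals).  Counts are integers recovered from the
printed cohort sizes and frequencies: for a codominant allele frequency f
over n animals, ``k = f × 2n`` allele copies; for a dominant positive
fraction, ``k = f × n`` animals.  Per-animal genotype records are not
reproduced here — only these summary counts, which are what the frequency
tables and confidence intervals are computed from.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["CohortSummary", "SWEDISH_COHORTS", "WGS_DEPTH_COHORT"]


@dataclass(frozen=True)
class CohortSummary:
    """One survey cohort: Cs29 allele copies out of 2n, Cs6 positives out of n."""

    label: str
    breed: str
    period: str
    n_animals: int
    cs29_allele_copies: int  # of 2 × n_animals allele draws (codominant marker)
    cs6_positive: int  # of n_animals animals (dominant presence marker)


SWEDISH_COHORTS: tuple[CohortSummary, ...] = (
    CohortSummary(
        "Swedish Mountain 1990s-2015", "Swedish Mountain (Fjäll)",
        "1990s and 2004-2015", 25, 28, 10,
    ),
    CohortSummary(
        "Swedish Mountain 2023-2024", "Swedish Mountain (Fjäll)",
        "2023-2024", 60, 53, 21,
    ),
    CohortSummary(
        "Fjällnära 1990s", "Fjällnära", "1990s", 16, 9, 5,
    ),
    CohortSummary(
        "Fjällnära 2023-2024", "Fjällnära", "2023-2024", 20, 6, 9,
    ),
    CohortSummary(
        "Bohus Polled 1990s", "Bohus Polled (Bohuskulla)", "1990s", 9, 12, 3,
    ),
    CohortSummary(
        "Swedish Polled", "Swedish Polled (Svensk Kullig Boskap)", "mixed", 8, 5, 2,
    ),
    CohortSummary(
        "Väne 1990s", "Väne", "1990s", 10, 8, 0,
    ),
)

# Depth-of-coverage genotyping of the 30 whole-genome-sequenced animals found
# five Cs29 homozygotes and eight heterozygotes; re-deriving these counts
# from raw reads requires the sequencing archive (ENA PRJEB60564) and is not
# bundled — only the published summary is.
WGS_DEPTH_COHORT = {"hom": 5, "het": 8, "non-carrier": 17}
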