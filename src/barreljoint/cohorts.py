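"""Reference survey cohorts used for the counting identities.

The descriptor was characterised on two curated cohorts of non-homologous
X-ray beta-barrel structures: 29 transmembrane barrels (4-26 strands) and
51 cytoplasmic barrels (4-14 strands).  For each strand-count group the
survey reports the number of structures and the total number of beta- and
gamma-type angles analysed.  Those tallies are a direct check of the
counting law: a structure with n strands carries exactly n-1 beta and
n-2 gamma angles, so each group's angle totals must equal the per-
structure counts times the number of structures.

One reported row is internally inconsistent: the 8-strand TM group lists
30 beta and 24 gamma angles for 6 structures (5 and 4 per structure, not
the 7 and 6 that 8 strands force).  The row is kept verbatim, flagged
``consistent=False``, and excluded from identity checks; the counting law
itself is never special-cased.
"""

from __future__ import annotations

from dataclasses import dataclass

from .descriptor import expected_counts

__all__ = ["CohortGroup", "TM_COHORT", "CYTO_COHORT", "counting_identity"]


@dataclass(frozen=True)
class CohortGroup:
    """One strand-count group of a survey cohort, as reported."""

    label: str
    n_strands: int
    n_structures: int
    reported_beta_total: int
    reported_gamma_total: int

    @property
    def consistent(self) -> bool:
        """Whether the reported totals obey the counting law."""
        b, g = expected_counts(self.n_strands)
        return (
            self.reported_beta_total == b * self.n_structures
            and self.reported_gamma_total == g * self.n_structures
        )


#: transmembrane cohort: 29 structures, 4-26 strands
TM_COHORT: tuple[CohortGroup, ...] = (
    CohortGroup("4TM", 4, 3, 9, 6),
    CohortGroup("8TM", 8, 6, 30, 24),  # reported row breaks the counting law
    CohortGroup("10TM", 10, 2, 18, 16),
    CohortGroup("12TM", 12, 6, 66, 60),
    CohortGroup("14TM", 14, 2, 26, 24),
    CohortGroup("16TM", 16, 3, 45, 42),
    CohortGroup("18TM", 18, 3, 51, 48),
    CohortGroup("19TM", 19, 1, 18, 17),
    CohortGroup("22TM", 22, 1, 21, 20),
    CohortGroup("24TM", 24, 1, 23, 22),
    CohortGroup("26TM", 26, 1, 25, 24),
)

#: cytoplasmic cohort: 51 structures, 4-14 strands; totals 312 beta, 261 gamma
CYTO_COHORT: tuple[CohortGroup, ...] = (
    CohortGroup("4N", 4, 2, 6, 4),
    CohortGroup("5N", 5, 8, 32, 24),
    CohortGroup("6N", 6, 12, 60, 48),
    CohortGroup("7N", 7, 9, 54, 45),
    CohortGroup("8N", 8, 15, 105, 90),
    CohortGroup("10N", 10, 1, 9, 8),
    CohortGroup("11N", 11, 1, 10, 9),
    CohortGroup("12N", 12, 1, 11, 10),
    CohortGroup("13N", 13, 1, 12, 11),
    CohortGroup("14N", 14, 1, 13, 12),
)


def counting_identity(group: CohortGroup) -> tuple[int, int]:
    """Angle totals the counting law predicts for a cohort group."""
    b, g = expected_counts(group.n_strands)
    return b * group.n_structures, g * group.n_structures
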