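"""Bundled reference numbers from the 13-disease rare-disease case study.

The pipeline was designed around a case study of 13 rare diseases drawn
from a 2021 disease-knowledge-base snapshot.  The per-disease candidate
and literature-verification counts of that study are bundled here so the
validation bookkeeping can be exercised without the (non-redistributable)
snapshot itself.  One of the 13 diseases (Lown-Ganong-Levine syndrome) was
discarded from verification in the study because its 965 candidates came
from a single approach and were highly non-specific, leaving 12 rows.

Gene/symptom set sizes for the 13 diseases live in
:data:`raredr.synthetic_data.CASE_STUDY_DISEASES`.
"""

from __future__ import annotations

import pandas as pd

from .downstream_stats import ValidationSummary, summary_from_counts

__all__ = ["case_study_validation_counts", "case_study_validation_summary"]

_VALIDATION_ROWS = (
    # disease_id, computational, checked, therapeutic, toxic
    ("C0011195", 2, 2, 1, 1),      # Dejerine-Sottas syndrome
    ("C0023944", 80, 11, 2, 9),    # Locked-In Syndrome
    ("C0024901", 4, 4, 3, 1),      # Diffuse cutaneous mastocytosis
    ("C0027877", 48, 7, 5, 2),     # Congenital neuronal ceroid lipofuscinosis
    ("C0036391", 14, 1, 1, 0),     # Schwartz-Jampel syndrome
    ("C0265202", 2, 1, 0, 1),      # Seckel syndrome
    ("C0268059", 91, 8, 3, 5),     # Neonatal hemochromatosis
    ("C0549463", 1, 0, 0, 0),      # X-Linked Lymphoproliferative Disorder
    ("C0751337", 126, 15, 11, 4),  # X-Linked Emery-Dreifuss Muscular Dystrophy
    ("C0869083", 8, 8, 0, 8),      # Dahlberg-Borer-Newcomer syndrome
    ("C1852146", 2, 2, 0, 2),      # Vibratory urticaria
    ("C0796280", 2, 1, 1, 0),      # Acromegaloid facial appearance syndrome
)


def case_study_validation_counts() -> pd.DataFrame:
    """The 12-row per-disease verification count table of the case study."""
    return pd.DataFrame(
        list(_VALIDATION_ROWS),
        columns=["disease_id", "computational", "checked", "therapeutic", "toxic"],
    )


def case_study_validation_summary() -> ValidationSummary:
    """The count table wrapped in a validated :class:`ValidationSummary`."""
    return summary_from_counts(case_study_validation_counts())
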