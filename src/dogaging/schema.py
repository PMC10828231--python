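"""Column schema of the raw survey table."""

from .config import BEHAVIOR_ITEMS, CCD_ITEMS

#: The questionnaire columns.  Exact-duplicate detection during cleaning
#: operates on these columns only; simulator bookkeeping columns (dog_id,
#: sim_group, sim_provenance) are ignored.
SURVEY_COLUMNS = (
    "age_years",
    "sex",
    "neuter_status",
    "breed_answer",
    "height_cm",
    "weight_kg",
    *BEHAVIOR_ITEMS,
    *CCD_ITEMS,
    "owner_says_old",
)

#: Simulator provenance labels.
PROVENANCE_BASE = "base"
PROVENANCE_DUPLICATE = "duplicate"
PROVENANCE_BAD_AGE = "bad_age"
PROVENANCE_UNDERAGE = "underage"
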