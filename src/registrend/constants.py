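"""Category vocabularies shared across the pipeline."""

from __future__ import annotations

# Six histology groups at the resolution the analysis runs on.
SMC = "SMC"
SQC = "SQC"
ADC = "ADC"
LAC = "LAC"
OTHER_NSCLC = "other_NSCLC"
OTHER_UNSPEC = "other_unspecified"

HIST_GROUPS: tuple[str, ...] = (SMC, SQC, ADC, LAC, OTHER_NSCLC, OTHER_UNSPEC)

# Nonspecific morphology codes that carry a candidate set instead of a group.
CODE_CARCINOMA_NOS = 8010  # carcinoma NOS: anything but the other/unspecified group
CODE_NSC_CARCINOMA = 8046  # non-small-cell carcinoma: additionally excludes SMC

CANDIDATES_8010: tuple[str, ...] = (SMC, SQC, ADC, LAC, OTHER_NSCLC)
CANDIDATES_8046: tuple[str, ...] = (SQC, ADC, LAC, OTHER_NSCLC)

# SEER summary-stage categories.
STAGES: tuple[str, ...] = ("localized", "regional", "distant")

SEXES: tuple[str, ...] = ("male", "female")

# Default diagnosis-period grouping used for descriptive tabulations.
DEFAULT_PERIODS: tuple[tuple[int, int], ...] = (
    (1993, 1999),
    (2000, 2004),
    (2005, 2009),
    (2010, 2015),
)

RESTRICTION_SEP = "|"


def restriction_to_str(cats) -> str:
    return RESTRICTION_SEP.join(cats)


def restriction_from_str(s: str) -> tuple[str, ...]:
    if not s:
        return ()
    return tuple(s.split(RESTRICTION_SEP))
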