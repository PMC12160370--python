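"""The five TCM constitution classes handled by this package.

The Constitution in Chinese Medicine Questionnaire distinguishes one balanced
type (Gentleness) and eight imbalanced types.  Four imbalanced types —
Qi-deficiency, Yang-deficiency, Wetness-heat and Qi-depression — together with
Gentleness cover the large majority of the population and are the classes this
package models end to end.  The remaining four imbalanced types are only
scored, never predicted.
"""

from __future__ import annotations

from enum import Enum


class Constitution(str, Enum):
    """The five studied constitution classes."""

    GENTLENESS = "gentleness"
    QI_DEFICIENCY = "qi_deficiency"
    YANG_DEFICIENCY = "yang_deficiency"
    WETNESS_HEAT = "wetness_heat"
    QI_DEPRESSION = "qi_depression"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Study cohort per-class sizes (1374 subjects total).
STUDY_CLASS_COUNTS: dict[Constitution, int] = {
    Constitution.GENTLENESS: 380,
    Constitution.QI_DEFICIENCY: 248,
    Constitution.YANG_DEFICIENCY: 449,
    Constitution.WETNESS_HEAT: 152,
    Constitution.QI_DEPRESSION: 145,
}

#: Stable ordering used for label encoding throughout the package.
CONSTITUTION_ORDER: list[Constitution] = list(Constitution)
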