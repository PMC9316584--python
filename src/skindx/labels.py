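"""Diagnostic classes and the tissue label-code table.

The four diagnostic classes follow the MPATH-Dx simplified categories after
merging classes I and II (both carry very low clinical risk): MMD (mild and
moderately dysplastic nevi), MIS (melanoma in situ / severely dysplastic
nevi), T1a (invasive melanoma stage T1a) and T1b (invasive melanoma stage
>= T1b).  The integer value of each member is its severity rank, so the
built-in ordering of the enum is the clinical severity ordering used by
max-voting.

Ground-truth masks use a fixed integer code table; ``DMN`` is a derived
union view of the two dermal-nest sub-types (the merged class a coarse
segmentation model would emit).
"""

from __future__ import annotations

import enum
from typing import FrozenSet


class DiagnosisClass(enum.IntEnum):
    """Four-class diagnosis, ordered by severity (MMD < MIS < T1a < T1b)."""

    MMD = 0
    MIS = 1
    T1a = 2
    T1b = 3

    @property
    def severity_rank(self) -> int:
        return int(self)

    @property
    def invasive(self) -> bool:
        """True for invasive melanoma stages (T1a and above)."""
        return self >= DiagnosisClass.T1a

    @classmethod
    def from_string(cls, name: str) -> "DiagnosisClass":
        try:
            return cls[name.strip()]
        except KeyError:
            raise ValueError(
                f"unknown diagnosis class {name!r}; expected one of "
                f"{[m.name for m in cls]}"
            ) from None


#: All four classes in severity order.
DIAGNOSIS_CLASSES = tuple(DiagnosisClass)

#: Ground-truth mask code table (generator output).
MASK_CODES = {
    "BG": 0,      # background / slide glass
    "COR": 1,     # stratum corneum
    "EP": 2,      # epidermis
    "DE": 3,      # dermis
    "EPN": 4,     # epidermal nest
    "DMN_N": 5,   # nevus dermal nest
    "DMN_M": 6,   # melanoma dermal nest
}

#: Highest valid code in a ground-truth mask.
MAX_MASK_CODE = max(MASK_CODES.values())


class TissueKind(enum.Enum):
    """Tissue selectors for binarization; DMN is the union of both nest types."""

    BG = "BG"
    COR = "COR"
    EP = "EP"
    DE = "DE"
    EPN = "EPN"
    DMN = "DMN"
    DMN_M = "DMN_M"
    DMN_N = "DMN_N"

    @property
    def code_set(self) -> FrozenSet[int]:
        if self is TissueKind.DMN:
            return frozenset({MASK_CODES["DMN_N"], MASK_CODES["DMN_M"]})
        return frozenset({MASK_CODES[self.value]})

    @classmethod
    def from_string(cls, name: str) -> "TissueKind":
        key = name.strip().upper().replace("-", "_")
        try:
            return cls[key]
        except KeyError:
            raise ValueError(
                f"unknown tissue kind {name!r}; expected one of "
                f"{[m.name for m in cls]}"
            ) from None


#: Tissues whose code sets partition the mask (exclusive codes).
EXCLUSIVE_TISSUES = (
    TissueKind.BG,
    TissueKind.COR,
    TissueKind.EP,
    TissueKind.DE,
    TissueKind.EPN,
    TissueKind.DMN,
)
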