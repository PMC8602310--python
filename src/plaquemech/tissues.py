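"""Tissue classes of the diseased arterial wall.

Five material regions are distinguished: healthy wall tissue (artery) and
four intra-plaque components (mixed, fibrous, lipid, calcium). Every mesh
element carries exactly one of these labels; the integer codes below are
also the values stored in the ``tissue`` cell-data field of exported meshes.
"""

from __future__ import annotations

from enum import IntEnum


class Tissue(IntEnum):
    """Tissue class of a wall element."""

    ARTERY = 1
    MIXED = 2
    FIBROUS = 3
    LIPID = 4
    CALCIUM = 5

    @property
    def label(self) -> str:
        return self.name.lower()

    @classmethod
    def from_label(cls, label: "str | int | Tissue") -> "Tissue":
        if isinstance(label, Tissue):
            return label
        if isinstance(label, str):
            return cls[label.upper()]
        return cls(int(label))


#: Soft tissue classes whose parameters are recovered in the standard studies
#: (calcium is excluded when its volume fraction is below one percent).
SOFT_TISSUES = (Tissue.ARTERY, Tissue.MIXED, Tissue.FIBROUS, Tissue.LIPID)

#: Canonical ordering of node-set names: tissues first, then the two surfaces.
SET_ORDER = tuple(t.label for t in Tissue) + ("inner", "outer")
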