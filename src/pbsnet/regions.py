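"""Subunit roles and the core/rod region vocabulary.

Phycobilisome (PBS) chains are described by a *role* (which gene product the
chain is: ApcA, ApcB, the terminal-emitter variants ApcD / ApcE / ApcF, the
core linker ApcC, the phycocyanin subunits CpcA / CpcB, and the rod and
rod-core linkers CpcC / CpcG) and a *region*: where the chain sits in the
assembly.  The core of a hemidiscoidal PBS is a stack of cylinders (basal
cylinders A and A', top cylinder B, and in penta-cylindrical cores the
shoulder half-cylinders C and C'), each built from trimer layers numbered
1-4 from the outside in.  Rods are named R1-R3 (and primed partners) or, in
penta-cylindrical species, Rb/Rs1/Rs2/Rt.

The vocabulary is deliberately permissive free text validated against
controlled lists: region names exist in the literature as prose, not as
fields of the deposited coordinate files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

from .errors import AnnotationError


class Role(str, Enum):
    """Subunit role of a polymer chain."""

    APCA = "ApcA"
    APCB = "ApcB"
    APCC = "ApcC"
    APCD = "ApcD"
    APCE = "ApcE"
    APCF = "ApcF"
    CPCA = "CpcA"
    CPCB = "CpcB"
    CPCC = "CpcC"  # rod linker L_R
    CPCG = "CpcG"  # rod-core linker L_RC
    OTHER = "other"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Roles of alpha-type phycobiliprotein subunits (one bilin each in APC).
ALPHA_ROLES = frozenset({Role.APCA, Role.APCD, Role.APCE, Role.CPCA})
#: Roles of beta-type phycobiliprotein subunits.
BETA_ROLES = frozenset({Role.APCB, Role.APCF, Role.CPCB})
#: Roles whose bilins are terminal emitters of the PBS core.
TERMINAL_EMITTER_ROLES = frozenset({Role.APCD, Role.APCE})

#: Default compartment implied by a role when no explicit region is given.
ROLE_COMPARTMENT = {
    Role.APCA: "core",
    Role.APCB: "core",
    Role.APCC: "core",
    Role.APCD: "core",
    Role.APCE: "core",
    Role.APCF: "core",
    Role.CPCA: "rod",
    Role.CPCB: "rod",
    Role.CPCC: "rod",
    Role.CPCG: "rod",
}

VALID_COMPARTMENTS = ("core", "rod")
VALID_CYLINDERS = ("A", "A'", "B", "B'", "C", "C'")
VALID_ROD_NAMES = (
    "R1", "R1'", "R2", "R2'", "R3", "R3'",
    "Rb", "Rb'", "Rs1", "Rs1'", "Rs2", "Rs2'", "Rt", "Rt'",
)


@dataclass(frozen=True)
class Region:
    """Location of a chain within the assembly.

    ``compartment`` is ``"core"`` or ``"rod"`` (or ``None`` for chains whose
    placement is unknown).  Core chains carry a cylinder letter and a trimer
    layer number 1-4; rod chains carry a rod name and optionally a hexamer
    index (1 = core-proximal).
    """

    compartment: Optional[str] = None
    cylinder: Optional[str] = None
    layer: Optional[int] = None
    rod_name: Optional[str] = None
    hexamer_index: Optional[int] = None

    def __post_init__(self) -> None:
        if self.compartment is not None and self.compartment not in VALID_COMPARTMENTS:
            raise AnnotationError(
                f"unknown compartment {self.compartment!r}; expected one of {VALID_COMPARTMENTS}"
            )
        if self.cylinder is not None and self.cylinder not in VALID_CYLINDERS:
            raise AnnotationError(
                f"unknown cylinder {self.cylinder!r}; expected one of {VALID_CYLINDERS}"
            )
        if self.rod_name is not None and self.rod_name not in VALID_ROD_NAMES:
            raise AnnotationError(
                f"unknown rod name {self.rod_name!r}; expected one of {VALID_ROD_NAMES}"
            )
        if self.layer is not None and not 1 <= int(self.layer) <= 4:
            raise AnnotationError(f"layer must be 1..4, got {self.layer}")
        if self.compartment == "rod" and self.rod_name is None:
            raise AnnotationError("rod regions require a rod_name")

    @property
    def label(self) -> str:
        """Compact human-readable label, e.g. ``core/A4`` or ``rod/R2:1``."""
        if self.compartment == "core":
            cyl = self.cylinder or "?"
            lay = str(self.layer) if self.layer is not None else "?"
            return f"core/{cyl}{lay}"
        if self.compartment == "rod":
            hx = f":{self.hexamer_index}" if self.hexamer_index is not None else ""
            return f"rod/{self.rod_name}{hx}"
        return "unplaced"

    def __str__(self) -> str:
        return self.label


#: A region with nothing known.
UNPLACED = Region()


@dataclass(frozen=True)
class SubunitAnnotation:
    """Role and region assigned to one chain."""

    chain_id: str
    role: Role
    region: Region = field(default_factory=Region)

    @property
    def compartment(self) -> Optional[str]:
        """Explicit compartment, falling back to the role's default."""
        if self.region.compartment is not None:
            return self.region.compartment
        return ROLE_COMPARTMENT.get(self.role)


def parse_role(text: str) -> Role:
    """Parse a role name case-insensitively, accepting linker synonyms."""
    synonyms = {
        "lr": Role.CPCC, "l_r": Role.CPCC,
        "lrc": Role.CPCG, "l_rc": Role.CPCG,
        "lc": Role.APCC, "l_c": Role.APCC,
        "lcm": Role.APCE, "l_cm": Role.APCE,
    }
    key = text.strip().lower()
    if key in synonyms:
        return synonyms[key]
    for role in Role:
        if role.value.lower() == key:
            return role
    raise AnnotationError(f"unknown subunit role {text!r}")
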