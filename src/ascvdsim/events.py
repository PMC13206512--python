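"""Clinical event vocabulary shared by the hazard and simulation layers."""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum


class EventType(str, Enum):
    """The five competing event types tracked over a lifetime."""

    MI = "MI"  # myocardial infarction (ICD-10 I21/I22)
    IHD = "IHD"  # ischaemic heart disease (I25)
    IS = "IS"  # ischaemic stroke (I63)
    HF = "HF"  # heart failure (I50)
    OTHER_DEATH = "OTHER_DEATH"  # death from any non-ASCVD cause


#: Clinical (potentially non-fatal) event types, in the fixed competing order
#: used by the simulation engine.
CLINICAL_EVENTS = (EventType.MI, EventType.IHD, EventType.IS, EventType.HF)


@dataclass(frozen=True)
class EventRecord:
    """One dated, typed, fatal or non-fatal event in a person's history."""

    event_type: EventType
    age_at_event: float
    fatal: bool

    def __post_init__(self) -> None:
        if self.age_at_event < 0:
            raise ValueError("age_at_event must be non-negative")
        if self.event_type is EventType.OTHER_DEATH and not self.fatal:
            raise ValueError("OTHER_DEATH is always fatal")
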