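"""Core domain types shared across the pipeline.

The state space is the five most commonly used biologic / targeted-synthetic
DMARD classes; every sequence the pipeline manipulates is a list of integer
state indices into :data:`STATE_LABELS`.
"""
from __future__ import annotations

import datetime as dt
import re
from dataclasses import dataclass, field

N_STATES = 5

STATE_LABELS: tuple[str, ...] = ("TNFi", "CTLA4-Ig", "IL6R", "JAKi", "anti-CD20")

#: Default drug-name -> class-index map. Lowercase generic names only.
DEFAULT_DRUG_CLASS_MAP: dict[str, int] = {
    # TNF inhibitors
    "adalimumab": 0,
    "certolizumab": 0,
    "etanercept": 0,
    "infliximab": 0,
    "golimumab": 0,
    # CTLA4-Ig
    "abatacept": 1,
    # IL-6 receptor blockade
    "tocilizumab": 2,
    "sarilumab": 2,
    # JAK inhibitors
    "tofacitinib": 3,
    "baricitinib": 3,
    "upadacitinib": 3,
    # anti-CD20
    "rituximab": 4,
}

#: Diagnosis-code prefixes counted as rheumatoid arthritis.
DEFAULT_RA_CODE_PREFIXES: tuple[str, ...] = ("714", "M05", "M06")


class UnknownDrugError(KeyError):
    """Raised when a prescription's drug name has no class mapping."""

    def __init__(self, drug_name: str):
        self.drug_name = drug_name
        super().__init__(f"unknown drug name: {drug_name!r}")


@dataclass(frozen=True)
class PrescriptionEvent:
    patient_id: str
    date: dt.date
    drug_name: str

    def __post_init__(self):
        if not self.drug_name:
            raise ValueError("drug_name must be non-empty")


@dataclass(frozen=True)
class DiagnosisEvent:
    patient_id: str
    date: dt.date
    code: str

    def is_ra(self, prefixes: tuple[str, ...] = DEFAULT_RA_CODE_PREFIXES) -> bool:
        return self.code.startswith(tuple(prefixes))


@dataclass(frozen=True)
class ClinicalVisit:
    patient_id: str
    date: dt.date
    cdai: float

    def __post_init__(self):
        if not 0.0 <= self.cdai <= 76.0:
            raise ValueError(f"CDAI {self.cdai} outside [0, 76]")


@dataclass(frozen=True)
class StateSequence:
    """One patient's ordered drug-class states.

    ``window_index[i]`` records which 3-month window (counted from the first
    prescription) state ``i`` was observed in.  Within a window consecutive
    equal states have already been collapsed, so ``states[i] == states[i+1]``
    implies the two came from different windows.
    """

    patient_id: str
    first_rx_date: dt.date
    states: tuple[int, ...]
    window_index: tuple[int, ...]

    def __post_init__(self):
        if len(self.states) == 0:
            raise ValueError("states must be nonempty")
        if len(self.states) != len(self.window_index):
            raise ValueError("states and window_index must have equal length")
        if any(not 0 <= s < N_STATES for s in self.states):
            raise ValueError("state index out of range")
        if any(b < a for a, b in zip(self.window_index, self.window_index[1:])):
            raise ValueError("window_index must be non-decreasing")
        for i in range(len(self.states) - 1):
            if (
                self.states[i] == self.states[i + 1]
                and self.window_index[i] == self.window_index[i + 1]
            ):
                raise ValueError("consecutive equal states within one window")

    def __len__(self) -> int:
        return len(self.states)

    @property
    def n_windows(self) -> int:
        return self.window_index[-1] + 1

    def label_string(self, sep: str = "-") -> str:
        return sep.join(STATE_LABELS[s] for s in self.states)


_LABELS_BY_LENGTH = sorted(STATE_LABELS, key=len, reverse=True)
_LABEL_TO_STATE = {lab: i for i, lab in enumerate(STATE_LABELS)}


def parse_label_string(text: str) -> tuple[int, ...]:
    """Parse a hyphen-joined class-label string back into state indices.

    Class labels themselves contain hyphens ("CTLA4-Ig", "anti-CD20"), so
    parsing matches the longest known label at each position.
    """
    states: list[int] = []
    i = 0
    while i < len(text):
        for lab in _LABELS_BY_LENGTH:
            if text.startswith(lab, i):
                states.append(_LABEL_TO_STATE[lab])
                i += len(lab)
                break
        else:
            raise ValueError(f"unparseable sequence label at {text[i:]!r}")
        if i < len(text):
            if text[i] != "-":
                raise ValueError(f"expected '-' separator at {text[i:]!r}")
            i += 1
    if not states:
        raise ValueError("empty sequence label")
    return tuple(states)


@dataclass
class FilterConfig:
    """Cohort inclusion rules applied before sequence construction."""

    study_start: dt.date = dt.date(2008, 1, 1)
    icd_lead_days: int = 90
    min_rx_gap_days: int = 90
    require_icd: bool = True  # False = sensitivity mode without the RA-code filter
    window_days: int = 91
    end_date: dt.date | None = None  # optional truncation of prescriptions
    ra_code_prefixes: tuple[str, ...] = DEFAULT_RA_CODE_PREFIXES
    ignore_unknown_drugs: bool = False

    def __post_init__(self):
        for name in ("icd_lead_days", "min_rx_gap_days", "window_days"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def parse_date(value) -> dt.date:
    """Coerce ISO-8601 strings / datetimes / dates to ``datetime.date``."""
    if isinstance(value, dt.datetime):
        return value.date()
    if isinstance(value, dt.date):
        return value
    if isinstance(value, str):
        m = re.fullmatch(r"(\d{4})-(\d{2})-(\d{2})", value.strip())
        if not m:
            raise ValueError(f"unparseable date: {value!r}")
        return dt.date(int(m.group(1)), int(m.group(2)), int(m.group(3)))
    raise TypeError(f"cannot interpret {value!r} as a date")
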