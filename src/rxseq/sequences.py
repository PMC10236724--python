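"""Cohort inclusion filters and prescription -> state-sequence construction.

Starting at each eligible patient's first biologic/tsDMARD prescription,
time is divided into consecutive fixed-length windows (default 91 days).
A window with no prescriptions contributes nothing; a window whose
prescriptions all map to one drug class contributes that single state; a
multi-class window contributes its classes in date order with consecutive
duplicates collapsed.  Collapsing never crosses a window boundary, so the
same class repeated across adjacent windows is retained.
"""
from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .types import (
    DEFAULT_DRUG_CLASS_MAP,
    DiagnosisEvent,
    FilterConfig,
    PrescriptionEvent,
    StateSequence,
    UnknownDrugError,
    parse_date,
    parse_label_string,
)

logger = logging.getLogger(__name__)

# exclusion reason codes, in the order the criteria are evaluated
REASON_PRE_STUDY = "pre_study_rx"
REASON_NO_ICD = "no_icd_lead"
REASON_INSUFFICIENT = "insufficient_rx"


def map_drug_to_class(
    drug_name: str, drug_map: Mapping[str, int] | None = None
) -> int:
    """Class index for a drug name (case-insensitive, whitespace-trimmed)."""
    drug_map = DEFAULT_DRUG_CLASS_MAP if drug_map is None else drug_map
    key = drug_name.strip().lower()
    try:
        return drug_map[key]
    except KeyError:
        raise UnknownDrugError(drug_name) from None


def _by_patient(events: Iterable) -> dict[str, list]:
    grouped: dict[str, list] = {}
    for e in events:
        grouped.setdefault(e.patient_id, []).append(e)
    for lst in grouped.values():
        lst.sort(key=lambda e: e.date)
    return grouped


@dataclass
class ExclusionRecord:
    patient_id: str
    reason: str


def apply_cohort_filters(
    prescriptions: Iterable[PrescriptionEvent],
    diagnoses: Iterable[DiagnosisEvent],
    config: FilterConfig,
) -> tuple[list[str], list[ExclusionRecord]]:
    """Evaluate the inclusion criteria per patient.

    Eligible iff, in order: (a) the first prescription falls on/after
    ``study_start`` (equivalently, nothing precedes it), (b) when
    ``require_icd``, an RA diagnosis code is dated at least ``icd_lead_days``
    before the first prescription, and (c) at least two prescriptions are
    ``min_rx_gap_days`` or more apart.  The exclusion log records the first
    failing criterion per patient.
    """
    rx_by_pat = _by_patient(prescriptions)
    dx_by_pat = _by_patient(diagnoses)
    eligible: list[str] = []
    excluded: list[ExclusionRecord] = []
    for pid in sorted(rx_by_pat):
        rx = rx_by_pat[pid]
        if config.end_date is not None:
            rx = [e for e in rx if e.date <= config.end_date]
            if not rx:
                excluded.append(ExclusionRecord(pid, REASON_INSUFFICIENT))
                continue
        first = rx[0].date
        if first < config.study_start:
            excluded.append(ExclusionRecord(pid, REASON_PRE_STUDY))
            continue
        if config.require_icd:
            cutoff = first - dt.timedelta(days=config.icd_lead_days)
            ra = [
                d
                for d in dx_by_pat.get(pid, [])
                if d.is_ra(config.ra_code_prefixes) and d.date <= cutoff
            ]
            if not ra:
                excluded.append(ExclusionRecord(pid, REASON_NO_ICD))
                continue
        if (rx[-1].date - first).days < config.min_rx_gap_days:
            excluded.append(ExclusionRecord(pid, REASON_INSUFFICIENT))
            continue
        eligible.append(pid)
    return eligible, excluded


def build_sequence(
    prescriptions: Iterable[PrescriptionEvent],
    drug_map: Mapping[str, int] | None = None,
    config: FilterConfig | None = None,
) -> StateSequence:
    """Construct one patient's state sequence via the window encounter rules.

    Same-day prescriptions of different drugs are ordered by class index
    (deterministic tie-break).  Unknown drugs raise unless
    ``config.ignore_unknown_drugs`` is set, in which case they are logged
    and skipped.
    """
    config = config or FilterConfig()
    events = sorted(prescriptions, key=lambda e: e.date)
    if config.end_date is not None:
        events = [e for e in events if e.date <= config.end_date]
    if not events:
        raise ValueError("no prescriptions to build a sequence from")
    pid = events[0].patient_id

    dated_classes: list[tuple[dt.date, int]] = []
    for e in events:
        try:
            dated_classes.append((e.date, map_drug_to_class(e.drug_name, drug_map)))
        except UnknownDrugError:
            if config.ignore_unknown_drugs:
                logger.warning(
                    "patient %s: skipping unmapped drug %r", pid, e.drug_name
                )
            else:
                raise
    if not dated_classes:
        raise ValueError(f"patient {pid}: no mappable prescriptions")

    first_date = dated_classes[0][0]
    per_window: dict[int, list[tuple[dt.date, int]]] = {}
    for date, cls in dated_classes:
        w = (date - first_date).days // config.window_days
        per_window.setdefault(w, []).append((date, cls))

    states: list[int] = []
    windows: list[int] = []
    for w in sorted(per_window):
        entries = sorted(per_window[w], key=lambda dc: (dc[0], dc[1]))
        last = None
        for _, cls in entries:
            if cls != last:  # collapse consecutive duplicates within window
                states.append(cls)
                windows.append(w)
                last = cls
    return StateSequence(
        patient_id=pid,
        first_rx_date=first_date,
        states=tuple(states),
        window_index=tuple(windows),
    )


@dataclass
class BuildSummary:
    n_input_patients: int
    n_eligible: int
    n_prescriptions: int
    n_unique_sequences: int
    exclusions: list[ExclusionRecord]


def build_all(
    prescriptions: Iterable[PrescriptionEvent],
    diagnoses: Iterable[DiagnosisEvent],
    drug_map: Mapping[str, int] | None = None,
    config: FilterConfig | None = None,
) -> tuple[list[StateSequence], BuildSummary]:
    """Filter the cohort, then build every eligible patient's sequence."""
    config = config or FilterConfig()
    rx_list = list(prescriptions)
    rx_by_pat = _by_patient(rx_list)
    eligible, excluded = apply_cohort_filters(rx_list, diagnoses, config)
    sequences = [
        build_sequence(rx_by_pat[pid], drug_map, config) for pid in eligible
    ]
    n_rx = sum(len(rx_by_pat[pid]) for pid in eligible)
    unique = len({seq.states for seq in sequences})
    summary = BuildSummary(
        n_input_patients=len(rx_by_pat),
        n_eligible=len(eligible),
        n_prescriptions=n_rx,
        n_unique_sequences=unique,
        exclusions=excluded,
    )
    return sequences, summary


# ---------------------------------------------------------------------------
# CSV adapters


def read_prescriptions(path: str | Path) -> list[PrescriptionEvent]:
    df = pd.read_csv(path, dtype=str)
    return [
        PrescriptionEvent(r.patient_id, parse_date(r.date), r.drug_name)
        for r in df.itertuples()
    ]


def read_diagnoses(path: str | Path) -> list[DiagnosisEvent]:
    df = pd.read_csv(path, dtype=str)
    return [
        DiagnosisEvent(r.patient_id, parse_date(r.date), r.code)
        for r in df.itertuples()
    ]


def sequences_to_frame(sequences: Iterable[StateSequence]) -> pd.DataFrame:
    rows = [
        (
            s.patient_id,
            s.first_rx_date.isoformat(),
            s.label_string(),
            "-".join(str(w) for w in s.window_index),
        )
        for s in sequences
    ]
    return pd.DataFrame(
        rows, columns=["patient_id", "first_rx_date", "sequence", "windows"]
    )


def write_sequences(sequences: Iterable[StateSequence], path: str | Path) -> None:
    sequences_to_frame(sequences).to_csv(path, index=False)


def read_sequences(path: str | Path) -> list[StateSequence]:
    df = pd.read_csv(path, dtype=str)
    out = []
    for r in df.itertuples():
        states = parse_label_string(r.sequence)
        windows = tuple(int(w) for w in str(r.windows).split("-"))
        out.append(
            StateSequence(
                patient_id=r.patient_id,
                first_rx_date=parse_date(r.first_rx_date),
                states=states,
                window_index=windows,
            )
        )
    return out


def write_exclusions(excluded: Iterable[ExclusionRecord], path: str | Path) -> None:
    pd.DataFrame(
        [(e.patient_id, e.reason) for e in excluded],
        columns=["patient_id", "reason"],
    ).to_csv(path, index=False)
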