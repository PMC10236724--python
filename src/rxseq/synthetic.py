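"""Synthetic EHR-style cohort generator.

Patients' drug-class paths are drawn from a known mixture of first-order
Markov chains and then rendered as dated prescription rows (concrete drug
names inside consecutive 91-day windows), RA diagnosis codes preceding the
first biologic, and yearly CDAI visits with component-specific means.  The
nuisance knobs (duplicate prescriptions, two-state windows, empty windows)
exercise the encounter rules in :mod:`rxseq.sequences` without altering the
underlying true state path, so the builder's reconstruction is exact by
construction.
"""
from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .mixture import MixtureMarkovParams
from .types import (
    DEFAULT_DRUG_CLASS_MAP,
    N_STATES,
    STATE_LABELS,
    ClinicalVisit,
    DiagnosisEvent,
    PrescriptionEvent,
    StateSequence,
)

#: drug names available to render each class, in class order
CLASS_MEMBERS: tuple[tuple[str, ...], ...] = tuple(
    tuple(sorted(d for d, c in DEFAULT_DRUG_CLASS_MAP.items() if c == k))
    for k in range(N_STATES)
)

CDAI_MAX = 76.0
WINDOW_DAYS = 91
YEAR_DAYS = 365.25


@dataclass
class GeneratorConfig:
    n_patients: int
    params: MixtureMarkovParams
    seq_length_range: tuple[int, int] = (8, 20)
    dup_rx_prob: float = 0.0
    multi_drug_prob: float = 0.0
    gap_prob: float = 0.0
    study_start: dt.date = dt.date(2008, 1, 1)
    cdai_profiles: np.ndarray | None = None  # (K, 8) yearly means, years -1..6
    cdai_sd: float = 0.0
    seed: int = 0
    #: fraction of patients whose RA code is dated only 10 days pre-biologic,
    #: deliberately violating the ICD lead-time filter (for filter tests)
    icd_violation_frac: float = 0.0

    def __post_init__(self):
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        lo, hi = self.seq_length_range
        if not (2 <= lo <= hi):
            raise ValueError("seq_length_range must satisfy 2 <= min <= max")
        for name in ("dup_rx_prob", "multi_drug_prob", "gap_prob",
                     "icd_violation_frac"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")
        if self.cdai_sd < 0:
            raise ValueError("cdai_sd must be >= 0")
        if self.params.S != N_STATES:
            raise ValueError("generator requires the 5-class state space")
        if self.cdai_profiles is not None:
            self.cdai_profiles = np.asarray(self.cdai_profiles, dtype=float)
            if self.cdai_profiles.shape != (self.params.K, 8):
                raise ValueError("cdai_profiles must be (K, 8)")
            if np.any(self.cdai_profiles < 0) or np.any(self.cdai_profiles > CDAI_MAX):
                raise ValueError("cdai_profiles values outside [0, 76]")


@dataclass
class SyntheticCohort:
    prescriptions: list[PrescriptionEvent]
    diagnoses: list[DiagnosisEvent]
    visits: list[ClinicalVisit]
    true_labels: dict[str, int]
    true_sequences: dict[str, StateSequence]


def _draw_path(rng: np.random.Generator, params: MixtureMarkovParams,
               z: int, length: int) -> list[int]:
    path = [int(rng.choice(params.S, p=params.initial[z]))]
    for _ in range(length - 1):
        path.append(int(rng.choice(params.S, p=params.transition[z, path[-1]])))
    return path


def simulate_cohort(config: GeneratorConfig) -> SyntheticCohort:
    """Forward-simulate one cohort; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    params = config.params
    lo, hi = config.seq_length_range

    prescriptions: list[PrescriptionEvent] = []
    diagnoses: list[DiagnosisEvent] = []
    visits: list[ClinicalVisit] = []
    true_labels: dict[str, int] = {}
    true_sequences: dict[str, StateSequence] = {}

    for i in range(config.n_patients):
        pid = f"P{i:06d}"
        z = int(rng.choice(params.K, p=params.mixing))
        length = int(rng.integers(lo, hi + 1))
        path = _draw_path(rng, params, z, length)

        first_rx = config.study_start + dt.timedelta(days=int(rng.integers(0, 3651)))

        # pack states into 91-day windows; a two-state window consumes two
        # consecutive *distinct* path states, a gap shifts later windows.
        window_of_state: list[int] = []
        window_entries: list[tuple[int, list[int]]] = []  # (window, states)
        w = 0
        t = 0
        occupied = 0
        while t < length:
            if occupied > 0 and rng.random() < config.gap_prob:
                w += 1  # empty window, invisible to the chain
            here = [path[t]]
            t += 1
            can_merge = (
                t < length
                and path[t] != here[0]
                and (occupied >= 1 or length - t >= 2)
            )
            if can_merge and rng.random() < config.multi_drug_prob:
                here.append(path[t])
                t += 1
            window_entries.append((w, here))
            window_of_state.extend([w] * len(here))
            occupied += 1
            w += 1

        for w, states_here in window_entries:
            base = first_rx + dt.timedelta(days=WINDOW_DAYS * w)
            for j, s in enumerate(states_here):
                drug = CLASS_MEMBERS[s][int(rng.integers(len(CLASS_MEMBERS[s])))]
                jitter = 0 if (w == 0 and j == 0) else int(rng.integers(0, 10))
                offset = j * 20 + jitter
                prescriptions.append(
                    PrescriptionEvent(pid, base + dt.timedelta(days=offset), drug)
                )
                if rng.random() < config.dup_rx_prob:
                    prescriptions.append(
                        PrescriptionEvent(
                            pid, base + dt.timedelta(days=offset + 5), drug
                        )
                    )

        violate = rng.random() < config.icd_violation_frac
        lead = 10 if violate else int(rng.integers(90, 366))
        diagnoses.append(
            DiagnosisEvent(pid, first_rx - dt.timedelta(days=lead), "714.0")
        )

        if config.cdai_profiles is not None:
            for y in range(-1, 7):
                mean = config.cdai_profiles[z, y + 1]
                value = mean + (
                    rng.normal(0.0, config.cdai_sd) if config.cdai_sd > 0 else 0.0
                )
                value = float(np.clip(value, 0.0, CDAI_MAX))
                vdate = first_rx + dt.timedelta(
                    days=int(round(YEAR_DAYS * y + YEAR_DAYS / 2))
                )
                visits.append(ClinicalVisit(pid, vdate, value))

        true_labels[pid] = z
        true_sequences[pid] = StateSequence(
            patient_id=pid,
            first_rx_date=first_rx,
            states=tuple(path),
            window_index=tuple(window_of_state),
        )

    return SyntheticCohort(prescriptions, diagnoses, visits, true_labels,
                           true_sequences)


# ---------------------------------------------------------------------------
# presets

# "paper_default": four components qualitatively mirroring the published
# cluster phenotypes -- (1) TNFi-dominant persisters, (2) early switch to
# abatacept which then dominates, (3) rituximab-dominant, (4) high switching
# with elevated tocilizumab occupancy -- with mixing (0.65, 0.08, 0.14, 0.13)
# and disease-activity profiles ordered so component 1 is lowest.  The exact
# matrices are repository constants chosen so that every transition row keeps
# enough occupancy to be recoverable from n=2000 patients.
_PD_MIXING = np.array([0.65, 0.08, 0.14, 0.13])

_PD_INITIAL = np.array([
    [0.95, 0.015, 0.010, 0.005, 0.020],
    [0.78, 0.160, 0.020, 0.020, 0.020],
    [0.30, 0.020, 0.020, 0.020, 0.640],
    [0.40, 0.140, 0.300, 0.120, 0.040],
])

_PD_TRANSITION = np.array([
    [  # component 0: near-absorbing on TNFi; excursions return immediately
        [0.95, 0.0125, 0.0125, 0.0125, 0.0125],
        [1.00, 0.00, 0.00, 0.00, 0.00],
        [1.00, 0.00, 0.00, 0.00, 0.00],
        [1.00, 0.00, 0.00, 0.00, 0.00],
        [1.00, 0.00, 0.00, 0.00, 0.00],
    ],
    [  # component 1: TNFi run, then abatacept near-absorbing
        [0.80, 0.20, 0.00, 0.00, 0.00],
        [0.04, 0.81, 0.05, 0.05, 0.05],
        [0.00, 1.00, 0.00, 0.00, 0.00],
        [0.00, 1.00, 0.00, 0.00, 0.00],
        [0.00, 1.00, 0.00, 0.00, 0.00],
    ],
    [  # component 2: rituximab near-absorbing hub
        [0.85, 0.00, 0.00, 0.00, 0.15],
        [0.00, 0.00, 0.00, 0.00, 1.00],
        [0.00, 0.00, 0.00, 0.00, 1.00],
        [0.00, 0.00, 0.00, 0.00, 1.00],
        [0.04, 0.03, 0.03, 0.03, 0.87],
    ],
    [  # component 3: high switching around a tocilizumab (IL6R) hub
        [0.10, 0.00, 0.90, 0.00, 0.00],
        [0.00, 0.00, 1.00, 0.00, 0.00],
        [0.10, 0.10, 0.45, 0.20, 0.15],
        [0.00, 0.00, 0.90, 0.10, 0.00],
        [0.00, 0.00, 1.00, 0.00, 0.00],
    ],
])

_PD_CDAI = np.array([
    [12.0, 9.0, 7.0, 6.0, 6.0, 5.0, 5.0, 5.0],
    [22.0, 18.0, 14.0, 11.0, 9.0, 8.0, 7.0, 7.0],
    [24.0, 21.0, 20.0, 19.0, 19.0, 18.0, 18.0, 17.0],
    [26.0, 24.0, 23.0, 22.0, 22.0, 21.0, 21.0, 20.0],
])


def _paper_default(seed: int, n_patients: int) -> GeneratorConfig:
    params = MixtureMarkovParams(
        mixing=_PD_MIXING.copy(),
        initial=_PD_INITIAL.copy(),
        transition=_PD_TRANSITION.copy(),
        state_labels=tuple(STATE_LABELS),
    )
    return GeneratorConfig(
        n_patients=n_patients,
        params=params,
        seq_length_range=(8, 20),
        dup_rx_prob=0.15,
        multi_drug_prob=0.10,
        gap_prob=0.10,
        cdai_profiles=_PD_CDAI.copy(),
        cdai_sd=6.0,
        seed=seed,
    )


def _single_class(seed: int, n_patients: int) -> GeneratorConfig:
    """K=1 degenerate preset: everyone starts and stays on TNFi."""
    params = MixtureMarkovParams(
        mixing=np.array([1.0]),
        initial=np.array([[1.0, 0.0, 0.0, 0.0, 0.0]]),
        transition=np.eye(N_STATES)[None, :, :],
        state_labels=tuple(STATE_LABELS),
    )
    return GeneratorConfig(
        n_patients=n_patients,
        params=params,
        cdai_profiles=np.full((1, 8), 10.0),
        cdai_sd=0.0,
        seed=seed,
    )


_PRESETS = {
    "paper_default": _paper_default,
    "single_class": _single_class,
}


def preset_scenario(name: str, seed: int = 0, n_patients: int = 2000,
                    **overrides) -> GeneratorConfig:
    """Return a fully specified generator config for a registered preset."""
    if name not in _PRESETS:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(_PRESETS)}"
        )
    config = _PRESETS[name](seed=seed, n_patients=n_patients)
    return replace(config, **overrides) if overrides else config


# ---------------------------------------------------------------------------
# CSV output


def cohort_frames(cohort: SyntheticCohort) -> dict[str, pd.DataFrame]:
    rx = pd.DataFrame(
        [(e.patient_id, e.date.isoformat(), e.drug_name)
         for e in cohort.prescriptions],
        columns=["patient_id", "date", "drug_name"],
    )
    dx = pd.DataFrame(
        [(e.patient_id, e.date.isoformat(), e.code) for e in cohort.diagnoses],
        columns=["patient_id", "date", "code"],
    )
    vis = pd.DataFrame(
        [(v.patient_id, v.date.isoformat(), v.cdai) for v in cohort.visits],
        columns=["patient_id", "date", "cdai"],
    )
    truth = pd.DataFrame(
        [
            (
                pid,
                cohort.true_labels[pid],
                cohort.true_sequences[pid].label_string(),
            )
            for pid in sorted(cohort.true_labels)
        ],
        columns=["patient_id", "component", "state_path"],
    )
    return {"prescriptions": rx, "diagnoses": dx, "visits": vis, "truth": truth}


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, frame in cohort_frames(cohort).items():
        p = outdir / f"{name}.csv"
        frame.to_csv(p, index=False)
        paths[name] = p
    return paths
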