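"""Cluster characterization: composition summaries, CDAI trajectories, and
across-cluster hypothesis tests."""
from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .mixture import Assignment
from .types import N_STATES, ClinicalVisit, StateSequence, parse_date

YEAR_DAYS = 365.25

N_CLASS_BUCKETS = ("1", "2", "3-5")


@dataclass
class ClusterProfile:
    cluster: int
    n: int
    share: float
    first_state_dist: np.ndarray | None  # (5,)
    last_state_dist: np.ndarray | None
    n_classes_dist: dict[str, float] | None  # buckets "1", "2", "3-5"
    single_class_frac: float | None
    empty: bool = False


def profile_clusters(
    sequences: Sequence[StateSequence], assignments: Sequence[Assignment]
) -> list[ClusterProfile]:
    """Per-cluster composition summary.

    The number of clusters is taken from the assignments' posterior length,
    so a component that captured nobody still yields an (empty-flagged)
    profile.
    """
    by_id = {a.patient_id: a for a in assignments}
    missing = [s.patient_id for s in sequences if s.patient_id not in by_id]
    if missing:
        raise ValueError(f"sequences without an assignment: {missing[:5]}")
    K = len(assignments[0].posterior)
    total = len(sequences)
    members: dict[int, list[StateSequence]] = {k: [] for k in range(K)}
    for s in sequences:
        members[by_id[s.patient_id].cluster].append(s)

    profiles = []
    for k in range(K):
        seqs = members[k]
        if not seqs:
            profiles.append(
                ClusterProfile(k, 0, 0.0, None, None, None, None, empty=True)
            )
            continue
        n = len(seqs)
        first = np.bincount([s.states[0] for s in seqs], minlength=N_STATES)
        last = np.bincount([s.states[-1] for s in seqs], minlength=N_STATES)
        n_classes = np.array([len(set(s.states)) for s in seqs])
        dist = {
            "1": float(np.mean(n_classes == 1)),
            "2": float(np.mean(n_classes == 2)),
            "3-5": float(np.mean(n_classes >= 3)),
        }
        profiles.append(
            ClusterProfile(
                cluster=k,
                n=n,
                share=n / total,
                first_state_dist=first / n,
                last_state_dist=last / n,
                n_classes_dist=dist,
                single_class_frac=dist["1"],
            )
        )
    return profiles


def cdai_yearly_means(
    visits: Iterable[ClinicalVisit],
    sequences: Sequence[StateSequence],
    assignments: Sequence[Assignment],
    years: Sequence[int] = tuple(range(-1, 7)),
) -> pd.DataFrame:
    """Mean CDAI per cluster-year, years anchored at the first prescription.

    Year ``y`` spans ``[first_rx + 365.25*y, first_rx + 365.25*(y+1))`` days.
    Patient-year means are computed first, then averaged across the cluster's
    patients (so visit-dense patients do not dominate); patient-years without
    visits are excluded, not imputed.  Returns columns
    cluster, year, mean_cdai, n.
    """
    first_rx = {s.patient_id: s.first_rx_date for s in sequences}
    cluster_of = {a.patient_id: a.cluster for a in assignments}
    years = sorted(years)

    # cluster -> year -> list of patient means
    patient_year: dict[tuple[str, int], list[float]] = {}
    for v in visits:
        if v.patient_id not in first_rx:
            continue
        offset = (v.date - first_rx[v.patient_id]).days
        y = int(np.floor(offset / YEAR_DAYS))
        if y in years:
            patient_year.setdefault((v.patient_id, y), []).append(v.cdai)

    acc: dict[tuple[int, int], list[float]] = {}
    for (pid, y), vals in patient_year.items():
        k = cluster_of.get(pid)
        if k is None:
            continue
        acc.setdefault((k, y), []).append(float(np.mean(vals)))

    clusters = sorted({a.cluster for a in assignments})
    rows = []
    for k in clusters:
        for y in years:
            vals = acc.get((k, y), [])
            rows.append(
                {
                    "cluster": k,
                    "year": y,
                    "mean_cdai": float(np.mean(vals)) if vals else np.nan,
                    "n": len(vals),
                }
            )
    return pd.DataFrame(rows)


def anova_oneway(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Classical one-way ANOVA: F = MS_between / MS_within, p from
    F(K-1, n-K).  For proportions, pass 0/1 indicator values."""
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2:
        raise ValueError("need at least 2 groups")
    if any(a.size < 2 for a in arrs):
        raise ValueError("each group needs at least 2 values")
    n = sum(a.size for a in arrs)
    if n <= len(arrs):
        raise ValueError("total n must exceed the number of groups")
    grand = np.concatenate(arrs).mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrs)
    ss_within = sum(float(np.sum((a - a.mean()) ** 2)) for a in arrs)
    if ss_within == 0.0 and ss_between == 0.0:
        raise ValueError("all values identical; F undefined")
    f_stat, p = stats.f_oneway(*arrs)
    return float(f_stat), float(p)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Kruskal-Wallis rank test with tie correction; p from chi2(K-1).

    When every value is identical the statistic is 0 by convention (scipy
    raises in that degenerate case) and p = 1.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2:
        raise ValueError("need at least 2 groups")
    if any(a.size == 0 for a in arrs):
        raise ValueError("each group must be nonempty")
    pooled = np.concatenate(arrs)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*arrs)
    return float(h), float(p)


# ---------------------------------------------------------------------------
# IO helpers


def read_visits(path) -> list[ClinicalVisit]:
    df = pd.read_csv(path, dtype={"patient_id": str})
    return [
        ClinicalVisit(str(r.patient_id), parse_date(r.date), float(r.cdai))
        for r in df.itertuples()
    ]


def profiles_to_records(profiles: Sequence[ClusterProfile]) -> list[dict]:
    out = []
    for p in profiles:
        out.append(
            {
                "cluster": p.cluster,
                "n": p.n,
                "share": p.share,
                "first_state_dist": None
                if p.first_state_dist is None
                else p.first_state_dist.tolist(),
                "last_state_dist": None
                if p.last_state_dist is None
                else p.last_state_dist.tolist(),
                "n_classes_dist": p.n_classes_dist,
                "single_class_frac": p.single_class_frac,
                "empty": p.empty,
            }
        )
    return out
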