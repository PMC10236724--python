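"""Choice of the number of mixture components.

AIC on the mixture likelihood is the primary selector; the Calinski-Harabasz
score, computed on per-patient yearly drug-class encounter rates under each
candidate's hard assignment, is reported alongside and checked for
agreement.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .mixture import FitResult, fit_em, posterior_assign
from .types import N_STATES, StateSequence

YEAR_DAYS = 365.25


def count_free_params(K: int, S: int) -> int:
    """Dimension of the simplex-constrained parameter space:
    (K-1) mixing + K(S-1) initial + K*S(S-1) transition entries."""
    if K < 1 or S < 2:
        raise ValueError("need K >= 1 and S >= 2")
    return (K - 1) + K * (S - 1) + K * S * (S - 1)


def aic(log_likelihood: float, p: int) -> float:
    if p < 0:
        raise ValueError("p must be >= 0")
    return 2.0 * p - 2.0 * log_likelihood


@dataclass
class RateFeatures:
    patient_ids: list[str]
    rates: np.ndarray  # (n, S) encounters per year, by drug class
    followup_years: np.ndarray  # (n,)


def yearly_rate_features(
    sequences: Sequence[StateSequence], window_days: int = 91
) -> RateFeatures:
    """Per-patient yearly rate of encounters in each drug class.

    Follow-up is the span of occupied windows: (max window index + 1) windows
    of ``window_days``, in 365.25-day years.
    """
    if not sequences:
        raise ValueError("sequences must be nonempty")
    n = len(sequences)
    rates = np.zeros((n, N_STATES))
    followup = np.zeros(n)
    ids = []
    for i, seq in enumerate(sequences):
        counts = np.bincount(seq.states, minlength=N_STATES).astype(float)
        followup[i] = seq.n_windows * window_days / YEAR_DAYS
        rates[i] = counts / followup[i]
        ids.append(seq.patient_id)
    return RateFeatures(patient_ids=ids, rates=rates, followup_years=followup)


def calinski_harabasz(features: np.ndarray, labels: Sequence[int]) -> float:
    """Variance-ratio cluster validity score (higher = better separated).

    CH = [B/(K-1)] / [W/(n-K)] with B the between-cluster and W the
    within-cluster sum of squared distances.  W == 0 returns +inf.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    n = X.shape[0]
    uniq = np.unique(y)
    K = uniq.size
    if K < 2:
        raise ValueError("need at least 2 nonempty clusters")
    if n <= K:
        raise ValueError("need n > K")
    grand = X.mean(axis=0)
    B = 0.0
    W = 0.0
    for lab in uniq:
        sub = X[y == lab]
        m = sub.mean(axis=0)
        B += sub.shape[0] * float(np.sum((m - grand) ** 2))
        W += float(np.sum((sub - m) ** 2))
    if W == 0.0:
        return float("inf")
    return (B / (K - 1)) / (W / (n - K))


@dataclass
class KFitRow:
    k: int
    fit: FitResult | None
    free_params: int
    aic: float
    ch_score: float  # nan when unavailable
    selected: bool = False
    error: str | None = None


@dataclass
class ModelSelectionTable:
    rows: list[KFitRow]
    selected_k: int
    ch_best_k: int | None
    ch_agrees: bool | None

    def row(self, k: int) -> KFitRow:
        return next(r for r in self.rows if r.k == k)

    @property
    def best_fit(self) -> FitResult:
        return self.row(self.selected_k).fit

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "K": r.k,
                    "log_likelihood": r.fit.log_likelihood if r.fit else np.nan,
                    "p": r.free_params,
                    "aic": r.aic,
                    "ch_score": r.ch_score,
                    "selected": r.selected,
                    "ch_agrees": self.ch_agrees,
                }
                for r in self.rows
            ]
        )


def select_k(
    sequences: Sequence[StateSequence],
    k_candidates: Iterable[int] = (2, 3, 4, 5),
    n_restarts: int = 20,
    tol: float = 1e-8,
    max_iter: int = 500,
    pseudocount: float = 1e-6,
    seed: int = 0,
    window_days: int = 91,
) -> ModelSelectionTable:
    """Fit each candidate K and select the AIC minimizer.

    Each K gets its own deterministic seed stream derived from ``seed``.
    Fit failures are recorded per K and selection runs over the successes.
    """
    candidates = sorted(set(int(k) for k in k_candidates))
    if not candidates:
        raise ValueError("k_candidates must be nonempty")
    feats = yearly_rate_features(sequences, window_days=window_days)
    rows: list[KFitRow] = []
    for k in candidates:
        p = count_free_params(k, N_STATES)
        try:
            fit = fit_em(
                sequences,
                K=k,
                n_restarts=n_restarts,
                tol=tol,
                max_iter=max_iter,
                pseudocount=pseudocount,
                seed=int(np.random.default_rng([seed, k]).integers(2**31)),
            )
        except Exception as exc:  # recorded, selection proceeds over successes
            rows.append(
                KFitRow(k=k, fit=None, free_params=p, aic=np.nan,
                        ch_score=np.nan, error=str(exc))
            )
            continue
        labels = [a.cluster for a in posterior_assign(sequences, fit.params)]
        try:
            ch = calinski_harabasz(feats.rates, labels)
        except ValueError:
            ch = float("nan")
        rows.append(
            KFitRow(
                k=k,
                fit=fit,
                free_params=p,
                aic=aic(fit.log_likelihood, p),
                ch_score=ch,
            )
        )
    ok = [r for r in rows if r.fit is not None]
    if not ok:
        raise RuntimeError("every candidate K failed to fit")
    selected = min(ok, key=lambda r: r.aic)
    selected.selected = True
    with_ch = [r for r in ok if np.isfinite(r.ch_score)]
    ch_best = max(with_ch, key=lambda r: r.ch_score).k if with_ch else None
    return ModelSelectionTable(
        rows=rows,
        selected_k=selected.k,
        ch_best_k=ch_best,
        ch_agrees=(ch_best == selected.k) if ch_best is not None else None,
    )
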