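"""Mixture of first-order Markov chains over a finite state space.

A sequence's probability under component ``k`` factorizes into an initial
term and transition terms, so a sequence is fully summarized by its first
state and its transition-count matrix.  All likelihood and EM computations
here run on those sufficient statistics; identical statistics are pooled
with multiplicity weights, which makes fitting cost scale with the number
of *distinct* sequences rather than the cohort size.
"""
from __future__ import annotations

import itertools
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence as TypingSequence

import numpy as np
from scipy.special import logsumexp

from .types import N_STATES, STATE_LABELS, StateSequence

logger = logging.getLogger(__name__)

_ROW_SUM_TOL = 1e-12

StatesLike = TypingSequence[int] | StateSequence


@dataclass
class MixtureMarkovParams:
    """Mixing proportions plus per-component initial and transition rows."""

    mixing: np.ndarray  # (K,)
    initial: np.ndarray  # (K, S)
    transition: np.ndarray  # (K, S, S)
    state_labels: tuple[str, ...] | None = None

    def __post_init__(self):
        self.mixing = np.asarray(self.mixing, dtype=float)
        self.initial = np.asarray(self.initial, dtype=float)
        self.transition = np.asarray(self.transition, dtype=float)
        self.validate()

    @property
    def K(self) -> int:
        return self.mixing.shape[0]

    @property
    def S(self) -> int:
        return self.initial.shape[1]

    def validate(self) -> None:
        K = self.mixing.shape[0]
        if K < 1:
            raise ValueError("K must be >= 1")
        if self.initial.shape[0] != K or self.transition.shape[0] != K:
            raise ValueError("component-count mismatch across parameter arrays")
        S = self.initial.shape[1]
        if S < 2:
            raise ValueError("S must be >= 2")
        if self.transition.shape[1:] != (S, S):
            raise ValueError("transition must be (K, S, S)")
        for name, arr, axis in (
            ("mixing", self.mixing, None),
            ("initial", self.initial, 1),
            ("transition", self.transition, 2),
        ):
            if np.any(arr < 0):
                raise ValueError(f"{name} has negative entries")
            sums = arr.sum() if axis is None else arr.sum(axis=axis)
            if not np.allclose(sums, 1.0, rtol=0, atol=_ROW_SUM_TOL):
                raise ValueError(f"{name} rows must sum to 1 within {_ROW_SUM_TOL}")

    def permuted(self, perm: TypingSequence[int]) -> "MixtureMarkovParams":
        """Return a copy with components reordered so new k = old perm[k]."""
        p = np.asarray(perm, dtype=int)
        return MixtureMarkovParams(
            mixing=self.mixing[p],
            initial=self.initial[p],
            transition=self.transition[p],
            state_labels=self.state_labels,
        )


@dataclass
class FitResult:
    params: MixtureMarkovParams
    log_likelihood: float
    ll_trace: list[float]
    n_iter: int
    converged: bool
    n_restarts: int
    best_restart: int
    seed: int
    pseudocount: float


@dataclass
class Assignment:
    patient_id: str
    posterior: np.ndarray
    cluster: int


# ---------------------------------------------------------------------------
# sufficient statistics


def _as_state_tuples(sequences: Iterable[StatesLike]) -> list[tuple[int, ...]]:
    out = []
    for s in sequences:
        if isinstance(s, StateSequence):
            out.append(s.states)
        else:
            out.append(tuple(int(x) for x in s))
        if len(out[-1]) == 0:
            raise ValueError("empty sequence")
    return out


def _suff_stats(seqs: list[tuple[int, ...]], S: int):
    """First-state vector and per-sequence transition-count matrices."""
    n = len(seqs)
    first = np.empty(n, dtype=np.intp)
    counts = np.zeros((n, S, S), dtype=float)
    for i, s in enumerate(seqs):
        arr = np.asarray(s, dtype=np.intp)
        if arr.min() < 0 or arr.max() >= S:
            raise ValueError(f"state out of range in sequence {i}: {s}")
        first[i] = arr[0]
        if arr.size > 1:
            np.add.at(counts[i], (arr[:-1], arr[1:]), 1.0)
    return first, counts


def _log_component_matrix(
    first: np.ndarray, counts: np.ndarray, params: MixtureMarkovParams
) -> np.ndarray:
    """(n, K) matrix of log p(sequence_i | component k).

    Zero-probability entries contribute -inf exactly when their count is
    positive; matmul runs on a zero-masked copy to avoid 0 * -inf = nan.
    """
    K, S = params.K, params.S
    n = first.shape[0]
    with np.errstate(divide="ignore"):
        log_init = np.log(params.initial)  # (K, S)
        log_trans = np.log(params.transition)  # (K, S, S)
    flat = counts.reshape(n, S * S)
    lt = log_trans.reshape(K, S * S)
    finite = np.isfinite(lt)
    core = flat @ np.where(finite, lt, 0.0).T
    blocked = (flat > 0).astype(float) @ (~finite).astype(float).T
    core[blocked > 0] = -np.inf
    return log_init[:, first].T + core


def component_log_likelihood(
    seq: StatesLike, k: int, params: MixtureMarkovParams
) -> float:
    """Log-probability of one sequence under component ``k`` (-inf allowed)."""
    states = _as_state_tuples([seq])[0]
    if any(not 0 <= s < params.S for s in states):
        raise ValueError(f"state out of range: {states}")
    if not 0 <= k < params.K:
        raise ValueError(f"component index {k} out of range")
    with np.errstate(divide="ignore"):
        total = float(np.log(params.initial[k, states[0]]))
        for a, b in zip(states, states[1:]):
            total += float(np.log(params.transition[k, a, b]))
    return total


def _weighted_mixture_ll(
    log_comp: np.ndarray, mixing: np.ndarray, weights: np.ndarray
) -> float:
    with np.errstate(divide="ignore"):
        log_mix = np.log(mixing)
    per_seq = logsumexp(log_comp + log_mix[None, :], axis=1)
    return float(np.dot(weights, per_seq))


def mixture_log_likelihood(
    sequences: Iterable[StatesLike], params: MixtureMarkovParams
) -> float:
    """Total log-likelihood Σ_i log Σ_k π_k p_k(x_i), log-sum-exp stabilized.

    An empty sequence list returns 0.0 (log of an empty product).
    """
    seqs = _as_state_tuples(sequences)
    if not seqs:
        return 0.0
    first, counts = _suff_stats(seqs, params.S)
    log_comp = _log_component_matrix(first, counts, params)
    return _weighted_mixture_ll(log_comp, params.mixing, np.ones(len(seqs)))


def _responsibilities(
    log_comp: np.ndarray, mixing: np.ndarray, ids: list | None = None
) -> np.ndarray:
    with np.errstate(divide="ignore"):
        weighted = log_comp + np.log(mixing)[None, :]
    norm = logsumexp(weighted, axis=1)
    dead = ~np.isfinite(norm)
    if np.any(dead):
        i = int(np.argmax(dead))
        name = ids[i] if ids is not None else i
        raise ValueError(
            f"sequence {name!r} has zero likelihood under every component; "
            "check for zero transition probabilities (pseudocount misuse)"
        )
    gamma = np.exp(weighted - norm[:, None])
    return gamma / gamma.sum(axis=1, keepdims=True)


def e_step(
    sequences: Iterable[StatesLike], params: MixtureMarkovParams
) -> np.ndarray:
    """Posterior responsibility matrix (n, K); rows sum to 1."""
    seqs = _as_state_tuples(sequences)
    first, counts = _suff_stats(seqs, params.S)
    log_comp = _log_component_matrix(first, counts, params)
    return _responsibilities(log_comp, params.mixing)


def _m_step_core(
    first: np.ndarray,
    counts: np.ndarray,
    gamma: np.ndarray,
    weights: np.ndarray,
    S: int,
    pseudocount: float,
) -> MixtureMarkovParams:
    K = gamma.shape[1]
    wg = gamma * weights[:, None]  # (n, K)
    mixing = wg.sum(axis=0) / weights.sum()
    mixing = mixing / mixing.sum()

    onehot = np.zeros((first.shape[0], S))
    onehot[np.arange(first.shape[0]), first] = 1.0
    init_counts = wg.T @ onehot + pseudocount  # (K, S)
    trans_counts = np.einsum("ik,iab->kab", wg, counts) + pseudocount

    initial = _normalize_rows(init_counts, "initial")
    transition = _normalize_rows(
        trans_counts.reshape(K * S, S), "transition"
    ).reshape(K, S, S)
    return MixtureMarkovParams(mixing=mixing, initial=initial, transition=transition)


def _normalize_rows(rows: np.ndarray, what: str) -> np.ndarray:
    sums = rows.sum(axis=1)
    zero = sums == 0
    if np.any(zero):
        logger.warning(
            "%d %s row(s) had zero weighted count; set to uniform", zero.sum(), what
        )
        rows = rows.copy()
        rows[zero] = 1.0
        sums = rows.sum(axis=1)
    return rows / sums[:, None]


def m_step(
    sequences: Iterable[StatesLike],
    responsibilities: np.ndarray,
    pseudocount: float = 0.0,
    S: int | None = None,
) -> MixtureMarkovParams:
    """Weighted-count closed-form maximizer given fixed responsibilities."""
    seqs = _as_state_tuples(sequences)
    gamma = np.asarray(responsibilities, dtype=float)
    if gamma.shape[0] != len(seqs):
        raise ValueError("responsibilities row count != number of sequences")
    if not np.allclose(gamma.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("responsibility rows must sum to 1")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if S is None:
        S = max(N_STATES, max(max(s) for s in seqs) + 1)
    first, counts = _suff_stats(seqs, S)
    return _m_step_core(first, counts, gamma, np.ones(len(seqs)), S, pseudocount)


# ---------------------------------------------------------------------------
# EM


def _dedupe(first: np.ndarray, counts: np.ndarray):
    n, S, _ = counts.shape
    flat = np.column_stack([first.astype(float), counts.reshape(n, S * S)])
    uniq, inverse, mult = np.unique(
        flat, axis=0, return_inverse=True, return_counts=True
    )
    ufirst = uniq[:, 0].astype(np.intp)
    ucounts = uniq[:, 1:].reshape(-1, S, S)
    return ufirst, ucounts, mult.astype(float), inverse


def _random_params(rng: np.random.Generator, K: int, S: int) -> MixtureMarkovParams:
    return MixtureMarkovParams(
        mixing=rng.dirichlet(np.ones(K)),
        initial=rng.dirichlet(np.ones(S), size=K),
        transition=rng.dirichlet(np.ones(S), size=(K, S)),
    )


def fit_em(
    sequences: Iterable[StatesLike],
    K: int,
    n_restarts: int = 20,
    tol: float = 1e-8,
    max_iter: int = 500,
    pseudocount: float = 1e-6,
    seed: int = 0,
    S: int = N_STATES,
) -> FitResult:
    """Fit a K-component mixture of Markov chains by multi-restart EM.

    Each restart draws starting parameters from flat Dirichlet distributions
    and alternates E and M steps until the relative log-likelihood change
    falls below ``tol``.  The restart with the highest final log-likelihood
    wins.  With ``pseudocount > 0`` the M-step maximizes a slightly smoothed
    objective, so a raw-likelihood step can in principle be (negligibly)
    downhill; such a step is rejected and treated as convergence, which keeps
    the reported trace non-decreasing.
    """
    seqs = _as_state_tuples(sequences)
    if not seqs:
        raise ValueError("no sequences to fit")
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > len(seqs):
        warnings.warn(f"K={K} exceeds the number of sequences ({len(seqs)})")
    first_all, counts_all = _suff_stats(seqs, S)
    first, counts, weights, _ = _dedupe(first_all, counts_all)

    best: tuple[float, int, MixtureMarkovParams, list[float], bool, int] | None = None
    for restart in range(n_restarts):
        rng = np.random.default_rng([seed, restart])
        params = _random_params(rng, K, S)
        log_comp = _log_component_matrix(first, counts, params)
        ll = _weighted_mixture_ll(log_comp, params.mixing, weights)
        trace = [ll]
        converged = False
        n_iter = 0
        for n_iter in range(1, max_iter + 1):
            gamma = _responsibilities(log_comp, params.mixing)
            cand = _m_step_core(first, counts, gamma, weights, S, pseudocount)
            cand_comp = _log_component_matrix(first, counts, cand)
            cand_ll = _weighted_mixture_ll(cand_comp, cand.mixing, weights)
            if cand_ll < ll:  # smoothing artefact: reject and stop
                converged = True
                break
            if cand_ll - ll <= tol * max(1.0, abs(ll)):
                converged = True
                if cand_ll > ll:
                    params, log_comp, ll = cand, cand_comp, cand_ll
                    trace.append(ll)
                break
            params, log_comp, ll = cand, cand_comp, cand_ll
            trace.append(ll)
        if best is None or ll > best[0]:
            best = (ll, restart, params, trace, converged, n_iter)

    ll, restart, params, trace, converged, n_iter = best
    params.state_labels = tuple(STATE_LABELS) if S == N_STATES else None
    return FitResult(
        params=params,
        log_likelihood=ll,
        ll_trace=trace,
        n_iter=n_iter,
        converged=converged,
        n_restarts=n_restarts,
        best_restart=restart,
        seed=seed,
        pseudocount=pseudocount,
    )


def posterior_assign(
    sequences: Iterable[StatesLike], params: MixtureMarkovParams
) -> list[Assignment]:
    """Hard cluster assignment by maximum posterior (ties -> lowest index)."""
    seq_list = list(sequences)
    ids = [
        s.patient_id if isinstance(s, StateSequence) else str(i)
        for i, s in enumerate(seq_list)
    ]
    seqs = _as_state_tuples(seq_list)
    first, counts = _suff_stats(seqs, params.S)
    log_comp = _log_component_matrix(first, counts, params)
    gamma = _responsibilities(log_comp, params.mixing, ids=ids)
    clusters = np.argmax(gamma, axis=1)  # argmax takes the lowest index on ties
    return [
        Assignment(patient_id=pid, posterior=gamma[i], cluster=int(clusters[i]))
        for i, pid in enumerate(ids)
    ]


def match_components(
    estimated: MixtureMarkovParams, truth: MixtureMarkovParams
) -> tuple[int, ...]:
    """Label-switching resolution: permutation ``perm`` minimizing total L1
    distance such that ``estimated.transition[perm[k]]`` matches
    ``truth.transition[k]``.  Exhaustive over K! (fine for K <= 6)."""
    if estimated.K != truth.K or estimated.S != truth.S:
        raise ValueError("K/S mismatch between estimated and truth parameters")
    K = truth.K
    cost = np.zeros((K, K))
    for k in range(K):
        for j in range(K):
            cost[k, j] = np.abs(truth.transition[k] - estimated.transition[j]).sum()
    best_perm, best_cost = None, np.inf
    for perm in itertools.permutations(range(K)):
        c = sum(cost[k, perm[k]] for k in range(K))
        if c < best_cost:
            best_perm, best_cost = perm, c
    return best_perm


# ---------------------------------------------------------------------------
# serialization


def save_model(fit: FitResult, path: str | Path) -> None:
    doc = {
        "K": fit.params.K,
        "S": fit.params.S,
        "state_labels": list(fit.params.state_labels or STATE_LABELS),
        "mixing": fit.params.mixing.tolist(),
        "initial": fit.params.initial.tolist(),
        "transition": fit.params.transition.tolist(),
        "fit": {
            "log_likelihood": fit.log_likelihood,
            "n_iter": fit.n_iter,
            "converged": fit.converged,
            "seed": fit.seed,
            "pseudocount": fit.pseudocount,
            "n_restarts": fit.n_restarts,
            "best_restart": fit.best_restart,
        },
    }
    Path(path).write_text(json.dumps(doc, indent=2))


def load_model(path: str | Path) -> FitResult:
    doc = json.loads(Path(path).read_text())
    params = MixtureMarkovParams(
        mixing=np.array(doc["mixing"]),
        initial=np.array(doc["initial"]),
        transition=np.array(doc["transition"]),
        state_labels=tuple(doc["state_labels"]),
    )
    f = doc["fit"]
    return FitResult(
        params=params,
        log_likelihood=f["log_likelihood"],
        ll_trace=[f["log_likelihood"]],
        n_iter=f["n_iter"],
        converged=f["converged"],
        n_restarts=f.get("n_restarts", 0),
        best_restart=f.get("best_restart", 0),
        seed=f["seed"],
        pseudocount=f["pseudocount"],
    )
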