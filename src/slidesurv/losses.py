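"""Censoring-aware training objectives for case-level survival prediction.

Three objectives are provided, all written as losses to *minimise* (printed
maximisation objectives are negated):

* **Censored cross-entropy** — survival as classification over K discrete
  time intervals.  Events contribute the standard cross-entropy of their
  interval ``Y``; censored cases contribute the log-probability that the
  event falls in any interval after the last interval ``Z`` fully observed
  before censorship:

  ``- mean_i [ O_i log f(X_i)[Y_i] + (1 - O_i) log sum_{y > Z_i} f(X_i)[y] ]``

* **Cox partial likelihood** (Breslow ties) — the negative log partial
  likelihood over a batch, with the risk set at each event time containing
  every batch case whose time is >= that event time.

* **Concordance lower bound** — the negated exponential lower bound
  ``sum_{(i,j) in E} 1 - exp(f(X_i) - f(X_j))`` over the comparable pairs
  ``E = {(i, j) : O_i = 1, T_j > T_i}``.  Note the raw output this objective
  trains is *survival*-oriented (larger for longer-lived cases); prediction
  code negates it so every loss yields a higher-is-worse risk score.

Interval schemes are per-study quartiles (by default) of the *event* times
among observed-event cases, in months.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .cohort import SurvivalRecord

PROBABILITY_FLOOR = 1e-12


@dataclass(frozen=True)
class IntervalScheme:
    """K intervals partitioning [0, inf): [0, b1], (b1, b2], ..., (b_{K-1}, inf).

    Finite intervals are right-closed; boundaries are in months.
    """

    boundaries: tuple[float, ...]
    study: str = ""

    def __post_init__(self):
        b = np.asarray(self.boundaries, dtype=np.float64)
        if b.size and not np.all(np.diff(b) > 0):
            raise ValueError(f"interval boundaries must be strictly increasing: {b}")

    @property
    def n_intervals(self) -> int:
        return len(self.boundaries) + 1


@dataclass(frozen=True)
class DiscreteLabel:
    """Event cases carry ``Y`` (the interval containing the event); censored
    cases carry ``Z`` (the latest interval whose right endpoint is strictly
    before the censorship time; -1 if censored inside the first interval)."""

    event: bool
    index: int  # Y for events, Z for censored

    @property
    def Y(self) -> int:
        if not self.event:
            raise AttributeError("Y is defined only for event labels")
        return self.index

    @property
    def Z(self) -> int:
        if self.event:
            raise AttributeError("Z is defined only for censored labels")
        return self.index


def build_interval_scheme(records: list[SurvivalRecord], K: int = 4,
                          study: str | None = None) -> IntervalScheme:
    """Interval boundaries at the {i/K : i=1..K-1} quantiles (linear
    interpolation) of observed-event times, in months.

    Only observed events enter the quantiles; with fewer events than K, or
    tied quantiles (a mass of tied event times), the scheme is degenerate and
    an error is raised.
    """
    if study is not None:
        records = [r for r in records if r.study == study]
    event_months = np.array([r.time_months for r in records if r.event == 1],
                            dtype=np.float64)
    if K < 1:
        raise ValueError("K must be >= 1")
    if K == 1:
        return IntervalScheme(boundaries=(), study=study or "")
    if event_months.size < K:
        raise ValueError(
            f"need at least K={K} observed events to build a {K}-interval "
            f"scheme, got {event_months.size}")
    qs = np.quantile(event_months, np.arange(1, K) / K)
    if np.any(np.diff(qs) <= 0):
        raise ValueError(f"tied interval boundaries {qs.tolist()}: the event-time "
                         f"distribution is too concentrated for K={K} intervals")
    return IntervalScheme(boundaries=tuple(float(q) for q in qs), study=study or "")


def assign_label(time_months: float, event: int, scheme: IntervalScheme) -> DiscreteLabel:
    """Discretize one case.  Events: Y = index of the (right-closed) interval
    containing the time.  Censored: Z = number of boundaries strictly below
    the censorship time, minus one."""
    b = np.asarray(scheme.boundaries, dtype=np.float64)
    if event == 1:
        y = int(np.searchsorted(b, time_months, side="left"))
        return DiscreteLabel(event=True, index=y)
    z = int(np.sum(b < time_months)) - 1
    return DiscreteLabel(event=False, index=z)


def assign_labels(records: list[SurvivalRecord], scheme: IntervalScheme) -> list[DiscreteLabel]:
    return [assign_label(r.time_months, r.event, scheme) for r in records]


# ---------------------------------------------------------------------------
# Losses

def censored_cross_entropy(probs: np.ndarray, labels: list[DiscreteLabel],
                           eps: float = PROBABILITY_FLOOR) -> float:
    """Mean negative censored log-likelihood of interval distributions.

    ``probs`` is (n, K), each row a probability distribution over intervals.
    Reduces exactly to the standard cross-entropy when every label is an
    event; a case censored before the first boundary (Z = -1) contributes
    ``-log(1) = 0``.
    """
    probs = np.asarray(probs, dtype=np.float64)
    if probs.ndim != 2 or len(labels) != probs.shape[0]:
        raise ValueError("probs must be (n_cases, K) matching labels")
    K = probs.shape[1]
    vals = np.empty(len(labels))
    for i, (p, lab) in enumerate(zip(probs, labels)):
        if lab.event:
            vals[i] = p[lab.Y]
        elif lab.Z < 0:
            vals[i] = 1.0   # every interval qualifies: -log(1) = 0 exactly
        else:
            vals[i] = p[lab.Z + 1:].sum() if lab.Z + 1 < K else 0.0
    floored = int((vals < eps).sum())
    if floored:
        warnings.warn(f"censored_cross_entropy: probability floor {eps} hit "
                      f"{floored} time(s)")
        vals = np.maximum(vals, eps)
    return float(-np.mean(np.log(vals)))


def cox_partial_likelihood_loss(scores: np.ndarray,
                                times: np.ndarray, events: np.ndarray) -> float:
    """Negative Breslow partial log-likelihood of a batch.

    The risk set at event time t is every batch case with time >= t; tied
    event times share that common denominator (Breslow's approximation).
    Higher score means higher hazard.  The loss only makes sense per batch
    (n <= 128 in training) — it approximates the full-cohort likelihood.
    """
    scores = np.asarray(scores, dtype=np.float64)
    times = np.asarray(times, dtype=np.float64)
    events = np.asarray(events)
    if not np.any(events == 1):
        raise ValueError("no observed event in batch: Cox partial likelihood "
                         "is undefined (resample the batch)")
    # numerically stable log-sum-exp over each risk set
    shift = scores.max()
    exp_s = np.exp(scores - shift)
    ll = 0.0
    for i in np.flatnonzero(events == 1):
        risk = times >= times[i]
        ll += (scores[i] - shift) - np.log(exp_s[risk].sum())
    return float(-ll)


def risk_pairs(times: np.ndarray, events: np.ndarray) -> list[tuple[int, int]]:
    """E = ordered pairs (i, j) with an observed event for i and T_j > T_i."""
    times = np.asarray(times, dtype=np.float64)
    events = np.asarray(events)
    return [(int(i), int(j))
            for i in np.flatnonzero(events == 1)
            for j in np.flatnonzero(times > times[i])]


def concordance_lower_bound_loss(outputs: np.ndarray,
                                 times: np.ndarray, events: np.ndarray) -> float:
    """Negated exponential lower bound on the concordance index.

    ``outputs`` here are the network's raw, survival-oriented values f(X):
    the objective sum_{(i,j) in E} (1 - exp(f_i - f_j)) rewards f_j > f_i for
    the longer-lived case j.  Returns 0 with a warning when E is empty
    (e.g. an all-censored batch).
    """
    outputs = np.asarray(outputs, dtype=np.float64)
    E = risk_pairs(times, events)
    if not E:
        warnings.warn("concordance_lower_bound_loss: no comparable pairs in batch")
        return 0.0
    i_idx = np.array([i for i, _ in E])
    j_idx = np.array([j for _, j in E])
    objective = np.sum(1.0 - np.exp(outputs[i_idx] - outputs[j_idx]))
    return float(-objective)


def risk_score_from_distribution(probs: np.ndarray) -> float | np.ndarray:
    """Scalar risk from an interval distribution: the negated expectation of
    the interval index, ``-sum_y y * f[y]``.  Later predicted intervals mean
    longer survival, so negation makes higher values mean higher risk."""
    probs = np.asarray(probs, dtype=np.float64)
    idx = np.arange(probs.shape[-1], dtype=np.float64)
    val = -(probs * idx).sum(axis=-1)
    return float(val) if val.ndim == 0 else val


LOSS_NAMES = ("censored_ce", "cox", "concordance_bound")


def unified_risk(outputs: np.ndarray, loss_name: str) -> np.ndarray:
    """Predict-time adapter: a higher-is-worse risk score for any head.

    censored_ce: negative expected interval index of the softmax distribution;
    cox: the raw scalar (already risk-oriented); concordance_bound: the
    negated raw scalar (the trained output is survival-oriented).
    """
    outputs = np.asarray(outputs, dtype=np.float64)
    if loss_name == "censored_ce":
        return np.atleast_1d(risk_score_from_distribution(outputs))
    if loss_name == "cox":
        return np.atleast_1d(outputs).ravel()
    if loss_name == "concordance_bound":
        return -np.atleast_1d(outputs).ravel()
    raise ValueError(f"unknown loss {loss_name!r}; expected one of {LOSS_NAMES}")
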