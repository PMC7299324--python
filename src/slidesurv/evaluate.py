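"""Survival-evaluation protocol: concordance with within-study pair pooling,
quantile risk groups, Kaplan-Meier / logrank, multivariable Cox harnesses,
leave-one-out added-value analysis, bootstrap intervals and 5-year AUC.

All statistics operate on times in months (``floor(days / 30.44)``, applied
once when a :class:`~slidesurv.cohort.SurvivalRecord` is converted), so that
clinically irrelevant day-level comparisons never enter a pair count.

Concordance conventions (documented, since the pair bookkeeping is what the
within-study pooling arithmetic rests on): a pair is informative iff the
member with the earlier time has an observed event (for tied times, one
event vs one censored case is informative — the censored case outlived the
event); a pair is concordant when the earlier event has the higher risk
score; score ties earn 0.5.  The *combined* c-index over several studies
sums concordant and informative pair counts within each study and never
forms cross-study pairs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .cohort import SurvivalRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CIndexResult:
    """Concordant (score ties count 0.5) and informative pair counts plus
    their ratio, for one study or the pooled 'combined' cohort."""

    concordant: float
    informative: int
    study: str = "combined"

    @property
    def c_index(self) -> float:
        return self.concordant / self.informative

    def __post_init__(self):
        if self.informative <= 0:
            raise ValueError(f"{self.study}: no informative pairs")


def concordance_index(scores: np.ndarray, times: np.ndarray, events: np.ndarray,
                      study: str = "combined") -> CIndexResult:
    """Harrell-style concordance over one cohort (vectorised pair count)."""
    s = np.asarray(scores, dtype=np.float64)
    t = np.asarray(times, dtype=np.float64)
    o = np.asarray(events).astype(int)
    n = len(s)
    if not (len(t) == len(o) == n):
        raise ValueError("scores, times, events must have equal length")
    # informative[i, j]: i is the earlier event of pair (i, j)
    lt = t[:, None] < t[None, :]
    eq = t[:, None] == t[None, :]
    ev_i = (o[:, None] == 1)
    informative = (lt & ev_i) | (eq & ev_i & (o[None, :] == 0))
    higher = s[:, None] > s[None, :]
    tied = s[:, None] == s[None, :]
    concordant = float((informative & higher).sum() + 0.5 * (informative & tied).sum())
    n_inf = int(informative.sum())
    if n_inf == 0:
        raise ValueError(f"{study}: no informative pairs")
    return CIndexResult(concordant=concordant, informative=n_inf, study=study)


def concordance_by_study(scores, times, events, studies) -> list[CIndexResult]:
    df = pd.DataFrame({"s": scores, "t": times, "o": events, "study": studies})
    return [concordance_index(g["s"].to_numpy(), g["t"].to_numpy(),
                              g["o"].to_numpy(), study=str(name))
            for name, g in df.groupby("study")]


def pooled_concordance(per_study: list[CIndexResult]) -> CIndexResult:
    """Combined c-index = (sum of concordant pairs) / (sum of informative
    pairs), summed solely within each study: cross-study pairs (which would
    mostly reflect between-cancer-type prognosis differences) never form."""
    if not per_study:
        raise ValueError("pooled_concordance needs at least one study result")
    return CIndexResult(concordant=sum(r.concordant for r in per_study),
                        informative=sum(r.informative for r in per_study),
                        study="combined")


# ---------------------------------------------------------------------------
# Risk groups

RISK_GROUPS = ("low", "medium", "high")


@dataclass
class RiskGroupAssignment:
    mapping: dict[str, str]                  # case_id -> low/medium/high
    group_by: tuple[str, ...]
    cuts: dict[tuple, tuple[float, float]]   # grouping cell -> (q25, q75)


def assign_risk_groups(scores: pd.DataFrame, records: list[SurvivalRecord],
                       group_by: tuple[str, ...] = ("study",),
                       quantiles: tuple[float, float] = (0.25, 0.75)
                       ) -> RiskGroupAssignment:
    """Quantile risk groups *within* each grouping cell (study, or study and
    stage): scores strictly below that cell's 25th percentile are low risk,
    strictly above its 75th are high risk, the rest medium.  Grouping within
    cells keeps every cell's composition identical across risk groups, so
    pooled curves cannot differ merely because one group over-represents a
    worse-prognosis study.  A cell whose scores are all tied yields all
    medium (the degenerate-quantile rule)."""
    rec_map = {r.case_id: r for r in records}
    df = scores.copy()
    df["study"] = [rec_map[c].study for c in df["case_id"]]
    if "stage" in group_by:
        df["stage"] = [rec_map[c].stage for c in df["case_id"]]
    mapping: dict[str, str] = {}
    cuts: dict[tuple, tuple[float, float]] = {}
    for cell, g in df.groupby(list(group_by)):
        if len(g) < 4:
            warnings.warn(f"risk-group cell {cell} has only {len(g)} cases")
        lo, hi = np.quantile(g["risk_score"].to_numpy(), quantiles)
        cuts[cell if isinstance(cell, tuple) else (cell,)] = (float(lo), float(hi))
        for cid, s in zip(g["case_id"], g["risk_score"]):
            mapping[cid] = "low" if s < lo else ("high" if s > hi else "medium")
    return RiskGroupAssignment(mapping=mapping, group_by=tuple(group_by), cuts=cuts)


# ---------------------------------------------------------------------------
# KM / logrank

def km_curve(records: list[SurvivalRecord]) -> tuple[np.ndarray, np.ndarray]:
    """Product-limit survival estimate; returns (months, S(months)) as a
    right-continuous step function starting at (0, 1)."""
    if not records:
        raise ValueError("km_curve: empty input")
    kmf = KaplanMeierFitter()
    kmf.fit(durations=[r.time_months for r in records],
            event_observed=[r.event for r in records])
    sf = kmf.survival_function_
    return sf.index.to_numpy(dtype=np.float64), sf.iloc[:, 0].to_numpy()


def logrank_test(group_a: list[SurvivalRecord], group_b: list[SurvivalRecord]) -> float:
    """Two-group logrank chi-square (1 df) p-value."""
    if not group_a or not group_b:
        raise ValueError("both groups must be nonempty")
    if not any(r.event for r in group_a + group_b):
        raise ValueError("logrank test undefined with no events")
    res = _ll_logrank([r.time_months for r in group_a],
                      [r.time_months for r in group_b],
                      event_observed_A=[r.event for r in group_a],
                      event_observed_B=[r.event for r in group_b])
    return float(res.p_value)


# ---------------------------------------------------------------------------
# Cox harness

@dataclass
class CoxFit:
    """Hazard ratios with Wald 95% CIs and p-values; covariates dropped for
    being constant are reported in ``dropped``."""

    summary: pd.DataFrame          # index covariate; columns HR, HR_lo, HR_hi, p
    dropped: list[str]
    fitter: CoxPHFitter


def build_design(features: pd.DataFrame, records: list[SurvivalRecord],
                 study_dummies: bool = False, interactions: bool = False,
                 age_scale: float = 10.0) -> pd.DataFrame:
    """Apply the protocol's covariate encodings to a per-case feature table.

    Recognised columns of ``features`` (all optional except case_id): any
    numeric model features (e.g. a risk score) are passed through.  Clinical
    covariates come from the records: stage as a numeric 1-4, age divided by
    ``age_scale`` (so its HR reads per 10 years), sex as an indicator
    (male=1).  With several studies, ``study_dummies`` adds cancer-type
    indicator columns (first study as reference) and ``interactions`` adds
    study x stage and study x age terms.
    """
    rec_map = {r.case_id: r for r in records}
    df = features.set_index("case_id").copy() if "case_id" in features else features.copy()
    ids = list(df.index)
    stage = pd.Series({c: rec_map[c].stage for c in ids}, dtype="float64")
    age = pd.Series({c: rec_map[c].age for c in ids}, dtype="float64")
    sex = pd.Series({c: rec_map[c].sex for c in ids})
    study = pd.Series({c: rec_map[c].study for c in ids})
    if stage.notna().all():
        df["stage"] = stage
    if age.notna().all():
        df["age_per10"] = age / age_scale
    if sex.notna().all():
        df["sex_male"] = (sex == "M").astype(float)
    studies = sorted(study.unique())
    if study_dummies and len(studies) > 1:
        for s in studies[1:]:
            df[f"study_{s}"] = (study == s).astype(float)
            if interactions:
                if "stage" in df:
                    df[f"study_{s}_x_stage"] = df[f"study_{s}"] * df["stage"]
                if "age_per10" in df:
                    df[f"study_{s}_x_age"] = df[f"study_{s}"] * df["age_per10"]
    return df


def fit_cox(features: pd.DataFrame, records: list[SurvivalRecord],
            study_dummies: bool = False, interactions: bool = False,
            truncate_months: float | None = None) -> CoxFit:
    """Multivariable Cox proportional-hazards fit (Breslow ties) of the
    encoded covariates against months/event.  Constant covariates are dropped
    with a warning and listed in the result.  ``truncate_months`` censors
    follow-up at that horizon (e.g. 60 for 5-year analyses)."""
    rec_map = {r.case_id: r for r in records}
    X = build_design(features, records, study_dummies=study_dummies,
                     interactions=interactions)
    t = np.array([rec_map[c].time_months for c in X.index], dtype=np.float64)
    o = np.array([rec_map[c].event for c in X.index], dtype=np.float64)
    if truncate_months is not None:
        o = np.where(t > truncate_months, 0.0, o)
        t = np.minimum(t, truncate_months)
    if o.sum() == 0:
        raise ValueError("fit_cox: no events")
    dropped = [c for c in X.columns if X[c].nunique() <= 1]
    for c in dropped:
        warnings.warn(f"fit_cox: dropping constant covariate {c!r}")
    X = X.drop(columns=dropped)
    data = X.copy()
    data["time_months"] = t
    data["event"] = o
    cph = CoxPHFitter()
    cph.fit(data, duration_col="time_months", event_col="event")
    s = cph.summary
    out = pd.DataFrame({
        "HR": s["exp(coef)"],
        "HR_lo": s["exp(coef) lower 95%"],
        "HR_hi": s["exp(coef) upper 95%"],
        "p": s["p"],
    })
    return CoxFit(summary=out, dropped=dropped, fitter=cph)


# ---------------------------------------------------------------------------
# LOO added-value analysis

def _loo_linear_predictors(X: pd.DataFrame, t: np.ndarray, o: np.ndarray
                           ) -> tuple[np.ndarray, int]:
    """Out-of-fold Cox linear predictors via leave-one-out: fit on n-1 cases,
    score the held-out case; each fold's predictor is centred on its own
    training mean so folds share a scale (rank statistics are unaffected)."""
    n = len(X)
    lp = np.full(n, np.nan)
    skipped = 0
    cols = list(X.columns)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        data = X.iloc[mask].copy()
        data["time_months"] = t[mask]
        data["event"] = o[mask]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph = CoxPHFitter(penalizer=1e-6)
                cph.fit(data, duration_col="time_months", event_col="event")
            beta = cph.params_.reindex(cols).to_numpy()
            centre = X.iloc[mask].to_numpy() @ beta
            lp[i] = (X.iloc[[i]].to_numpy() @ beta).item() - centre.mean()
        except Exception:
            skipped += 1
    return lp, skipped


def loo_cox_added_value(feature_sets: dict[str, pd.DataFrame],
                        records: list[SurvivalRecord],
                        drop_collinear: bool = True) -> pd.DataFrame:
    """Predictive c-index of Cox models under leave-one-out cross-validation,
    one row per feature set, plus the delta of every set against the first
    (the baseline).  Guards against the mechanical fit improvement of larger
    models: each case is scored by a model that never saw it.

    ``feature_sets`` maps a name (e.g. "baseline", "baseline+dls") to a
    per-case feature table indexed by / containing case_id.
    """
    rec_map = {r.case_id: r for r in records}
    if sum(r.event for r in records) < 2:
        raise ValueError("need at least 2 events for the LOO analysis")
    rows = []
    base_c = None
    for name, feats in feature_sets.items():
        X = feats.set_index("case_id").copy() if "case_id" in feats else feats.copy()
        if drop_collinear:
            dup, seen = [], []
            for c in X.columns:
                if any(np.allclose(X[c], X[c2]) for c2 in seen):
                    dup.append(c)
                else:
                    seen.append(c)
            if dup:
                logger.info("loo_cox_added_value[%s]: dropping collinear %s", name, dup)
                X = X.drop(columns=dup)
        ids = list(X.index)
        t = np.array([rec_map[c].time_months for c in ids], dtype=np.float64)
        o = np.array([rec_map[c].event for c in ids])
        studies = [rec_map[c].study for c in ids]
        lp, skipped = _loo_linear_predictors(X, t, o)
        if skipped > max(1, 0.01 * len(ids)):
            raise RuntimeError(f"{name}: {skipped} LOO folds failed")
        ok = ~np.isnan(lp)
        per_study = concordance_by_study(lp[ok], t[ok], np.asarray(o)[ok],
                                         np.asarray(studies)[ok])
        c = pooled_concordance(per_study).c_index
        if base_c is None:
            base_c = c
        rows.append({"feature_set": name, "c_index": c, "delta_vs_first": c - base_c,
                     "n_folds_skipped": skipped})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Bootstrap / AUC

def bootstrap_ci(statistic, data, B: int = 9999, seed: int = 0,
                 strata=None, alpha: float = 0.05) -> tuple[float, float]:
    """Percentile bootstrap interval for ``statistic(data[indices])`` over
    ``B`` case-level resamples with replacement.  With ``strata`` (one label
    per case), resampling is stratified so that e.g. a pooled c-index keeps
    every study's case count fixed.  Resamples on which the statistic is
    undefined are redrawn (count logged)."""
    n = len(data)
    rng = np.random.default_rng(seed)
    if strata is not None:
        strata = np.asarray(strata)
        groups = [np.flatnonzero(strata == s) for s in np.unique(strata)]
    vals = np.empty(B)
    redrawn = 0
    for b in range(B):
        for _attempt in range(100):
            if strata is None:
                idx = rng.integers(n, size=n)
            else:
                idx = np.concatenate([g[rng.integers(len(g), size=len(g))]
                                      for g in groups])
            try:
                vals[b] = statistic(idx)
                break
            except Exception:
                redrawn += 1
        else:
            raise RuntimeError("bootstrap statistic failed on 100 consecutive resamples")
    if redrawn:
        logger.info("bootstrap_ci: %d undefined resamples redrawn", redrawn)
    lo, hi = np.quantile(vals, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def auc_5yr(scores: np.ndarray, records: list[SurvivalRecord],
            horizon_months: float = 60.0) -> float:
    """AUC for 5-year disease-specific survival.  Positives: event within the
    horizon.  Negatives: event-free follow-up past the horizon (later events
    count as 5-year survivors).  Cases censored before the horizon are
    excluded — their 5-year status is unknown.  Score ties earn 0.5."""
    s = np.asarray(scores, dtype=np.float64)
    t = np.array([r.time_months for r in records], dtype=np.float64)
    o = np.array([r.event for r in records])
    pos = (o == 1) & (t <= horizon_months)
    neg = t >= horizon_months
    neg &= ~pos  # an event exactly at the horizon is a positive
    if pos.sum() == 0 or neg.sum() == 0:
        raise ValueError("auc_5yr: need at least one positive and one negative "
                         "after the eligibility filter")
    sp, sn = s[pos], s[neg]
    wins = (sp[:, None] > sn[None, :]).sum() + 0.5 * (sp[:, None] == sn[None, :]).sum()
    return float(wins / (len(sp) * len(sn)))
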