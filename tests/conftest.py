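"""Shared fixtures.

The heavyweight fixtures (a desk-scale synthetic cohort and the trained
weak-supervision model on it, plus its permuted-label control) are
session-scoped: they are built once and shared by the end-to-end tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from slidesurv.cohort import Case, SurvivalRecord, stratified_split
from slidesurv.mil import MILSurvivalModel, ModelConfig
from slidesurv.simulate import SimulationConfig, generate_cohort

# Study conditions of the end-to-end weak-supervision recovery experiment:
# two studies, 2:1:1 split, informative fraction 0.2, unit log-hazard per
# latent-risk unit, desk-scale 128 px slides with 32 px patches.
E2E_SIM = dict(studies={"SYNA": 250, "SYNB": 250}, slide_size_px=128,
               patch_px=32, slides_per_case_range=(1, 3),
               informative_fraction=0.2, risk_effect=1.0, seed=11)
E2E_MODEL = dict(patch_px=32, n_patches_train=16, n_patches_eval=256,
                 conv_block_spec=((16, 2), (32, 2), (64, 2), (64, 2)),
                 batch_size_cases=16, learning_rate=2e-3, total_steps=2000,
                 eval_every_steps=100, tune_eval_patches=64, seed=5)
E2E_SPLIT_SEED = 1
E2E_ENSEMBLE_K = 10
E2E_PRED_PATCHES = 256
E2E_PRED_SEED = 99


@pytest.fixture(scope="session")
def e2e_cohort():
    return generate_cohort(SimulationConfig(**E2E_SIM))


@pytest.fixture(scope="session")
def e2e_records(e2e_cohort):
    return [c.record for c in e2e_cohort]


@pytest.fixture(scope="session")
def e2e_split(e2e_records):
    return stratified_split(e2e_records, seed=E2E_SPLIT_SEED)


@pytest.fixture(scope="session")
def e2e_results(e2e_cohort, e2e_split):
    cases = [c.as_case() for c in e2e_cohort]
    model = MILSurvivalModel(cases, e2e_split, ModelConfig(**E2E_MODEL))
    return model.fit()


@pytest.fixture(scope="session")
def e2e_predictions(e2e_results):
    return e2e_results.predict_risk(split="test", k=E2E_ENSEMBLE_K,
                                    n_patches=E2E_PRED_PATCHES, seed=E2E_PRED_SEED)


@pytest.fixture(scope="session")
def e2e_null_results(e2e_cohort, e2e_split):
    """The identical pipeline trained on permuted survival labels: the
    negative control for the weak-supervision recovery check."""
    rng = np.random.default_rng(777)
    records = [c.record for c in e2e_cohort]
    perm = rng.permutation(len(records))
    shuffled = [
        SurvivalRecord(case_id=r.case_id, study=r.study,
                       time_days=records[j].time_days, event=records[j].event,
                       stage=r.stage, age=r.age, sex=r.sex)
        for r, j in zip(records, perm)]
    cases = [Case(record=s, slides=c.as_case().slides)
             for s, c in zip(shuffled, e2e_cohort)]
    model = MILSurvivalModel(cases, e2e_split, ModelConfig(**E2E_MODEL))
    res = model.fit()
    preds = res.predict_risk(split="test", k=E2E_ENSEMBLE_K,
                             n_patches=E2E_PRED_PATCHES, seed=E2E_PRED_SEED)
    return res, preds, {s.case_id: s for s in shuffled}


def make_survival_records(n, rng, hazard=0.003, beta=0.0, covariate=None,
                          censor_rate=0.0015, study="SIM"):
    """Tabular exponential proportional-hazards records for Cox-harness
    tests; ``covariate`` (length n) enters the log hazard with weight beta."""
    x = np.zeros(n) if covariate is None else np.asarray(covariate, dtype=float)
    t_event = rng.exponential(1.0 / (hazard * np.exp(beta * x)))
    t_cens = (rng.exponential(1.0 / censor_rate, size=n) if censor_rate > 0
              else np.full(n, np.inf))
    t = np.minimum(t_event, t_cens)
    o = (t_event <= t_cens).astype(int)
    return [SurvivalRecord(case_id=f"{study}-{i}", study=study,
                           time_days=max(1.0, round(ti)), event=int(oi))
            for i, (ti, oi) in enumerate(zip(t, o))]
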