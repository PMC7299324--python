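"""Weakly-supervised multiple-instance survival model.

Architecture: a small CNN of depthwise-separable convolution blocks applied
with *shared weights* to every patch in a case's bag, per-patch global
average pooling, a per-channel mean across the bag (so the case-level
representation is invariant to patch order and count), and a final linear
("logistic regression") head — K-way softmax over survival intervals for the
censored cross-entropy loss, a scalar for the Cox and concordance-bound
losses.

The network, RMSProp optimizer, exponential-moving-average (EMA) weights and
backpropagation are implemented directly in NumPy: at desk scale (tens of
pixels per patch, a few tens of thousands of parameters) this trains in
minutes on one CPU and is bit-for-bit deterministic under a fixed seed.

The public surface follows the model/results idiom: build a
:class:`MILSurvivalModel` from cases + split + config, call :meth:`fit`, and
work with the returned :class:`MILSurvivalResults` (checkpoints, ensemble
selection, risk prediction, summary).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .cohort import Case, SplitAssignment, augment, sample_patches
from .losses import (IntervalScheme, assign_label, build_interval_scheme,
                     risk_pairs, unified_risk)

DEFAULT_CONV_BLOCKS = ((16, 2), (32, 2), (64, 2), (64, 2))


@dataclass
class ModelConfig:
    """Hyperparameters of the MIL survival network and its training loop.

    ``conv_block_spec`` lists (output channels, stride) per depthwise-separable
    block.  ``n_patches_train``/``n_patches_eval`` are the bag sizes: few
    patches during training for case diversity, many at evaluation for slide
    coverage.  ``ema_decay`` is the weight-averaging constant (0 disables
    averaging: the EMA then tracks the raw weights exactly).
    """

    patch_px: int = 256
    n_patches_train: int = 16
    n_patches_eval: int = 1024
    conv_block_spec: tuple[tuple[int, int], ...] = DEFAULT_CONV_BLOCKS
    n_intervals: int = 4
    learning_rate: float = 1e-3
    batch_size_cases: int = 32
    ema_decay: float = 0.999
    total_steps: int = 2000
    eval_every_steps: int = 100
    rmsprop_decay: float = 0.9
    rmsprop_eps: float = 1e-8
    augment_brightness: float = 0.1
    augment_contrast: float = 0.1
    augment_saturation: float = 0.1
    augment_hue: float = 0.0
    tune_eval_patches: int = 128   # bag size for the tune c-index at checkpoints
    dtype: str = "float32"         # network arithmetic; float64 for exactness
    seed: int = 0

    def __post_init__(self):
        if self.n_patches_train < 1:
            raise ValueError("n_patches_train must be >= 1")
        if self.batch_size_cases > 128:
            raise ValueError("batch_size_cases is capped at 128: the batch is "
                             "the unit over which the survival losses are "
                             "approximated")


# ---------------------------------------------------------------------------
# NumPy CNN

def _out_hw(hp: int, stride: int) -> int:
    return (hp - 3) // stride + 1


def _dw_conv(xp: np.ndarray, dw: np.ndarray, stride: int) -> np.ndarray:
    """Depthwise 3x3 convolution of a padded (N, C, Hp, Wp) tensor, written
    as nine shifted multiply-adds (vectorised; no im2col copy)."""
    N, C, Hp, Wp = xp.shape
    Ho, Wo = _out_hw(Hp, stride), _out_hw(Wp, stride)
    out = np.zeros((N, C, Ho, Wo), dtype=xp.dtype)
    for ki in range(3):
        for kj in range(3):
            out += xp[:, :, ki:ki + stride * Ho:stride,
                      kj:kj + stride * Wo:stride] * dw[:, ki, kj][None, :, None, None]
    return out


def _pw_conv(d: np.ndarray, W: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pointwise (1x1) convolution via BLAS: (N, C, H, W) x (O, C) -> (N, O, H, W)."""
    N, C, H, Wd = d.shape
    y = np.matmul(W[None], d.reshape(N, C, H * Wd))
    return y.reshape(N, -1, H, Wd) + b[None, :, None, None]


class PatchCNN:
    """Shared-weight patch encoder + linear head, with manual backprop.

    Parameters live in ``self.params`` (name -> array): per block i a
    depthwise kernel ``dw{i}`` (C, 3, 3), pointwise ``pw{i}_W`` (Cout, Cin)
    and bias ``pw{i}_b``; plus ``head_W`` (n_out, F) and ``head_b``.
    """

    def __init__(self, conv_block_spec, n_out: int, rng: np.random.Generator,
                 dtype=np.float32):
        self.spec = tuple((int(c), int(s)) for c, s in conv_block_spec)
        self.n_out = int(n_out)
        self.dtype = np.dtype(dtype)
        self.params: dict[str, np.ndarray] = {}
        c_in = 3
        for i, (c_out, _) in enumerate(self.spec):
            self.params[f"dw{i}"] = rng.normal(0.0, 1.0 / 3.0, (c_in, 3, 3))
            self.params[f"pw{i}_W"] = rng.normal(0.0, math.sqrt(2.0 / c_in), (c_out, c_in))
            self.params[f"pw{i}_b"] = np.zeros(c_out)
            c_in = c_out
        self.n_features = c_in
        self.params["head_W"] = rng.normal(0.0, math.sqrt(1.0 / c_in), (n_out, c_in))
        self.params["head_b"] = np.zeros(n_out)
        self.params = {k: v.astype(self.dtype) for k, v in self.params.items()}

    # -- forward -----------------------------------------------------------
    def preprocess(self, patches: np.ndarray) -> np.ndarray:
        """uint8 (N, P, P, 3) -> centred (N, 3, P, P) in the net's dtype."""
        x = (patches.astype(self.dtype) - 128.0) / 128.0
        return np.ascontiguousarray(x.transpose(0, 3, 1, 2))

    def forward(self, x: np.ndarray, n_per_case: int,
                params: dict[str, np.ndarray] | None = None,
                want_cache: bool = False):
        """x: (B * n_per_case, 3, P, P) -> case-level outputs (B, n_out).

        The bag reduction is a per-channel mean over each case's patches, so
        the output is exactly invariant to patch order and to duplicating
        the whole bag.
        """
        p = self.params if params is None else params
        cache: dict = {"inputs": [], "relu": [], "mid": []}
        a = x
        for i, (_, stride) in enumerate(self.spec):
            xp = np.pad(a, ((0, 0), (0, 0), (1, 1), (1, 1)))
            d = _dw_conv(xp, p[f"dw{i}"], stride)
            y = _pw_conv(d, p[f"pw{i}_W"], p[f"pw{i}_b"])
            mask = y > 0
            a_next = y * mask
            if want_cache:
                cache["inputs"].append(xp)
                cache["mid"].append(d)
                cache["relu"].append(mask)
            a = a_next
        feat = a.mean(axis=(2, 3))                       # (N, F)
        N = feat.shape[0]
        B = N // n_per_case
        # canonical (sorted) reduction order: the bag mean is then exactly
        # invariant to patch permutation even in floating point
        case_feat = np.sort(feat.reshape(B, n_per_case, -1), axis=1).mean(axis=1)
        out = case_feat @ p["head_W"].T + p["head_b"]
        if want_cache:
            cache["spatial"] = a.shape
            cache["case_feat"] = case_feat
            cache["n_per_case"] = n_per_case
            return out, cache
        return out

    # -- backward ----------------------------------------------------------
    def backward(self, dout: np.ndarray, cache: dict,
                 params: dict[str, np.ndarray] | None = None) -> dict[str, np.ndarray]:
        p = self.params if params is None else params
        grads: dict[str, np.ndarray] = {}
        grads["head_W"] = dout.T @ cache["case_feat"]
        grads["head_b"] = dout.sum(axis=0)
        dcase = dout @ p["head_W"]                       # (B, F)
        n = cache["n_per_case"]
        dfeat = np.repeat(dcase / n, n, axis=0)          # (N, F)
        _, C, H, W = cache["spatial"]
        da = np.broadcast_to(dfeat[:, :, None, None] / (H * W),
                             cache["spatial"]).copy()
        for i in reversed(range(len(self.spec))):
            stride = self.spec[i][1]
            dy = da * cache["relu"][i]
            d = cache["mid"][i]
            N, O, Ho, Wo = dy.shape
            C = d.shape[1]
            dy2 = dy.reshape(N, O, Ho * Wo)
            d2 = d.reshape(N, C, Ho * Wo)
            grads[f"pw{i}_b"] = dy.sum(axis=(0, 2, 3))
            grads[f"pw{i}_W"] = np.matmul(dy2, d2.transpose(0, 2, 1)).sum(axis=0)
            dd = np.matmul(p[f"pw{i}_W"].T[None], dy2).reshape(N, C, Ho, Wo)
            xp = cache["inputs"][i]
            dxp = np.zeros_like(xp)
            dw = p[f"dw{i}"]
            gdw = np.empty_like(dw)
            for ki in range(3):
                for kj in range(3):
                    sl = xp[:, :, ki:ki + stride * Ho:stride,
                            kj:kj + stride * Wo:stride]
                    gdw[:, ki, kj] = (sl * dd).sum(axis=(0, 2, 3))
                    dxp[:, :, ki:ki + stride * Ho:stride,
                        kj:kj + stride * Wo:stride] += dd * dw[:, ki, kj][None, :, None, None]
            grads[f"dw{i}"] = gdw
            da = dxp[:, :, 1:-1, 1:-1]
        return grads


# ---------------------------------------------------------------------------
# Loss gradients at the head

def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _censored_ce_grad(logits, labels):
    p = _softmax(logits)
    B, K = p.shape
    g = np.zeros_like(p)
    loss = 0.0
    for b, lab in enumerate(labels):
        if lab.event:
            loss -= math.log(max(p[b, lab.Y], 1e-12))
            g[b] = p[b]
            g[b, lab.Y] -= 1.0
        else:
            m = np.zeros(K)
            m[lab.Z + 1:] = 1.0
            q = float((p[b] * m).sum())
            loss -= math.log(max(q, 1e-12))
            g[b] = p[b] - p[b] * m / max(q, 1e-12)
    return loss / B, g / B


def _cox_grad(scores, times, events):
    s = scores.ravel()
    shift = s.max()
    e = np.exp(s - shift)
    g = np.zeros_like(s)
    loss = 0.0
    ev = np.flatnonzero(events == 1)
    if ev.size == 0:
        raise ValueError("no event in batch")
    for i in ev:
        risk = times >= times[i]
        denom = e[risk].sum()
        loss -= (s[i] - shift) - math.log(denom)
        g[i] -= 1.0
        g[risk] += e[risk] / denom
    B = len(s)
    return loss / B, (g / B)[:, None]


def _concordance_bound_grad(outputs, times, events):
    f = outputs.ravel()
    E = risk_pairs(times, events)
    B = len(f)
    g = np.zeros_like(f)
    if not E:
        return 0.0, g[:, None]
    i_idx = np.array([i for i, _ in E])
    j_idx = np.array([j for _, j in E])
    expd = np.exp(np.clip(f[i_idx] - f[j_idx], -50, 50))
    loss = -np.sum(1.0 - expd)
    np.add.at(g, i_idx, expd)
    np.add.at(g, j_idx, -expd)
    return loss / B, (g / B)[:, None]


# ---------------------------------------------------------------------------
# Checkpoints and ensembles

@dataclass
class Checkpoint:
    """EMA parameter snapshot at a training step, tagged with its tuning-set
    concordance index."""

    params: dict[str, np.ndarray]
    step: int
    tune_cindex: float
    config_id: int = 0

    def __post_init__(self):
        if not 0.0 <= self.tune_cindex <= 1.0:
            raise ValueError("tune c-index must lie in [0, 1]")


@dataclass
class Ensemble:
    """Checkpoints sorted by tune c-index descending; prediction is the
    member median (even count: mean of the two middle values)."""

    checkpoints: list[Checkpoint]

    def __post_init__(self):
        if not self.checkpoints:
            raise ValueError("ensemble must be nonempty")
        self.checkpoints = sorted(
            self.checkpoints,
            key=lambda c: (-c.tune_cindex, -c.step, -c.config_id))


def select_checkpoints(pool: list[Checkpoint], k: int = 50) -> Ensemble:
    """Top-k checkpoints by tune c-index; ties broken by later training step,
    then by configuration id.  A pool smaller than k is used whole."""
    if len(pool) < k:
        warnings.warn(f"checkpoint pool has {len(pool)} < k={k} members; using all")
        k = len(pool)
    ordered = sorted(pool, key=lambda c: (-c.tune_cindex, -c.step, -c.config_id))
    return Ensemble(checkpoints=ordered[:k])


# ---------------------------------------------------------------------------
# Model / Results

class MILSurvivalModel:
    """Case-level survival model over bags of slide patches.

    Parameters
    ----------
    cases : list of Case
        The cohort (records + slides).
    split : SplitAssignment
        train/tune/test assignment over the cohort's case ids.
    config : ModelConfig
    loss : {"censored_ce", "cox", "concordance_bound"}
        Training objective; decides the head (K-way softmax vs scalar).
    schemes : dict study -> IntervalScheme, optional
        Time discretizations for the censored cross-entropy; built from the
        *training* split (per study, event-time quartiles) when omitted.
        When a batch mixes studies, each case is labelled with its own
        study's scheme.
    """

    def __init__(self, cases: list[Case], split: SplitAssignment,
                 config: ModelConfig | None = None, loss: str = "censored_ce",
                 schemes: dict[str, IntervalScheme] | None = None):
        self.cases = {c.case_id: c for c in cases}
        self.split = split
        self.config = config or ModelConfig()
        self.loss = loss
        self.train_ids = [cid for cid in split.cases("train") if cid in self.cases]
        self.tune_ids = [cid for cid in split.cases("tune") if cid in self.cases]
        if not self.train_ids or not self.tune_ids:
            raise ValueError("split must provide nonempty train and tune sets")
        if loss == "censored_ce":
            if schemes is None:
                train_records = [self.cases[cid].record for cid in self.train_ids]
                schemes = {
                    s: build_interval_scheme(train_records, K=self.config.n_intervals,
                                             study=s)
                    for s in sorted({r.study for r in train_records})}
            self.schemes = schemes
            self.n_out = self.config.n_intervals
        else:
            self.schemes = schemes or {}
            self.n_out = 1

    # -- helpers -----------------------------------------------------------
    def _labels_for(self, ids):
        out = []
        for cid in ids:
            r = self.cases[cid].record
            out.append(assign_label(r.time_months, r.event, self.schemes[r.study]))
        return out

    def _batch_arrays(self, ids):
        recs = [self.cases[cid].record for cid in ids]
        t = np.array([r.time_months for r in recs], dtype=np.float64)
        o = np.array([r.event for r in recs])
        return t, o

    def _sample_bag(self, case: Case, n: int, rng, do_augment: bool):
        ps = sample_patches(case, n, rng, patch_px=self.config.patch_px)
        if do_augment:
            cfg = self.config
            for k in range(len(ps.patches)):
                ps.patches[k] = augment(
                    ps.patches[k], rng,
                    brightness=cfg.augment_brightness, contrast=cfg.augment_contrast,
                    saturation=cfg.augment_saturation, hue=cfg.augment_hue)
        return ps.patches

    # -- training ----------------------------------------------------------
    def fit(self, verbose: bool = False) -> "MILSurvivalResults":
        cfg = self.config
        ss = np.random.SeedSequence(cfg.seed)
        s_init, s_batch, s_patch, s_eval = ss.spawn(4)
        net = PatchCNN(cfg.conv_block_spec, self.n_out,
                       np.random.default_rng(s_init), dtype=cfg.dtype)
        rng_batch = np.random.default_rng(s_batch)
        rng_patch = np.random.default_rng(s_patch)
        eval_seed = int(np.random.default_rng(s_eval).integers(2 ** 31))

        cache_v = {k: np.zeros_like(v) for k, v in net.params.items()}
        ema = {k: v.copy() for k, v in net.params.items()}
        checkpoints: list[Checkpoint] = []
        log_rows = []
        n_resampled = 0
        B = min(cfg.batch_size_cases, len(self.train_ids))

        for step in range(1, cfg.total_steps + 1):
            ids = list(rng_batch.choice(self.train_ids, size=B, replace=False))
            if self.loss == "cox":
                tries = 0
                while not any(self.cases[c].record.event for c in ids):
                    ids = list(rng_batch.choice(self.train_ids, size=B, replace=False))
                    n_resampled += 1
                    tries += 1
                    if tries > 1000:
                        raise RuntimeError("could not draw a batch containing an event")
            bags = [self._sample_bag(self.cases[c], cfg.n_patches_train, rng_patch, True)
                    for c in ids]
            x = net.preprocess(np.concatenate(bags, axis=0))
            out, fcache = net.forward(x, cfg.n_patches_train, want_cache=True)
            if self.loss == "censored_ce":
                loss_val, dout = _censored_ce_grad(out, self._labels_for(ids))
            else:
                t, o = self._batch_arrays(ids)
                if self.loss == "cox":
                    loss_val, dout = _cox_grad(out, t, o)
                else:
                    loss_val, dout = _concordance_bound_grad(out, t, o)
            grads = net.backward(dout.astype(net.dtype), fcache)
            for k, v in net.params.items():
                g = grads[k]
                cache_v[k] = cfg.rmsprop_decay * cache_v[k] + (1 - cfg.rmsprop_decay) * g * g
                v -= cfg.learning_rate * g / (np.sqrt(cache_v[k]) + cfg.rmsprop_eps)
                ema[k] = cfg.ema_decay * ema[k] + (1 - cfg.ema_decay) * v
            row = {"step": step, "loss": float(loss_val), "tune_cindex": np.nan}
            if step % cfg.eval_every_steps == 0 or step == cfg.total_steps:
                snap = {k: v.copy() for k, v in ema.items()}
                tune_c = self._tune_cindex(net, snap, eval_seed)
                checkpoints.append(Checkpoint(params=snap, step=step,
                                              tune_cindex=tune_c))
                row["tune_cindex"] = tune_c
                if verbose:
                    print(f"step {step:>6d}  loss {loss_val:8.4f}  tune c-index {tune_c:.3f}")
            log_rows.append(row)
        return MILSurvivalResults(model=self, net=net, checkpoints=checkpoints,
                                  log=pd.DataFrame(log_rows),
                                  n_resampled_batches=n_resampled)

    def _tune_cindex(self, net: PatchCNN, params, eval_seed: int) -> float:
        from .evaluate import concordance_index, pooled_concordance
        tune_cases = [self.cases[cid] for cid in self.tune_ids]
        risks = _predict_cases(net, [params], tune_cases, self.config, self.loss,
                               eval_seed,
                               n_patches=min(self.config.n_patches_eval,
                                             self.config.tune_eval_patches))
        df = pd.DataFrame({
            "study": [c.record.study for c in tune_cases],
            "risk": risks,
            "time": [c.record.time_months for c in tune_cases],
            "event": [c.record.event for c in tune_cases]})
        per_study = [concordance_index(g["risk"].to_numpy(), g["time"].to_numpy(),
                                       g["event"].to_numpy(), study=s)
                     for s, g in df.groupby("study")]
        return pooled_concordance(per_study).c_index


def _predict_cases(net: PatchCNN, param_sets, cases, config: ModelConfig,
                   loss: str, seed: int, n_patches: int | None = None) -> np.ndarray:
    """Median-over-members risk for each case; one patch sampling per case per
    evaluation (seed-controlled), shared across all ensemble members."""
    n = n_patches or config.n_patches_eval
    risks = np.empty(len(cases))
    children = np.random.SeedSequence(seed).spawn(len(cases))
    for i, case in enumerate(cases):
        rng = np.random.default_rng(children[i])
        ps = sample_patches(case, n, rng, patch_px=config.patch_px)
        x = net.preprocess(ps.patches)
        member = np.empty(len(param_sets))
        for m, params in enumerate(param_sets):
            out = net.forward(x, n, params=params)
            member[m] = float(unified_risk(out[0], loss)[0])
        risks[i] = float(np.median(member))
    return risks


def ensemble_predict(ensemble: Ensemble, net: PatchCNN, case: Case,
                     config: ModelConfig, loss: str, seed: int,
                     n_patches: int | None = None) -> float:
    """Risk score for one case: median of the ensemble members' predictions
    on one shared sampled patch bag."""
    return float(_predict_cases(net, [c.params for c in ensemble.checkpoints],
                                [case], config, loss, seed, n_patches)[0])


@dataclass
class MILSurvivalResults:
    """Fitted-model artefacts: the network, its checkpoint pool and the
    training log; prediction and ensembling hang off this object."""

    model: MILSurvivalModel
    net: PatchCNN
    checkpoints: list[Checkpoint]
    log: pd.DataFrame
    n_resampled_batches: int = 0

    @property
    def best_tune_cindex(self) -> float:
        return max(c.tune_cindex for c in self.checkpoints)

    def select_checkpoints(self, k: int = 50) -> Ensemble:
        return select_checkpoints(self.checkpoints, k)

    def predict_risk(self, cases: list[Case] | None = None, split: str = "test",
                     ensemble: Ensemble | None = None, k: int = 50,
                     n_patches: int | None = None, seed: int = 0) -> pd.DataFrame:
        """Ensemble risk scores (higher = worse prognosis) for the given cases
        (default: the model's test split)."""
        if cases is None:
            cases = [self.model.cases[cid] for cid in self.model.split.cases(split)
                     if cid in self.model.cases]
        if ensemble is None:
            ensemble = self.select_checkpoints(k)
        risks = _predict_cases(self.net, [c.params for c in ensemble.checkpoints],
                               cases, self.model.config, self.model.loss, seed,
                               n_patches)
        return pd.DataFrame({"case_id": [c.case_id for c in cases],
                             "study": [c.record.study for c in cases],
                             "risk_score": risks})

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "MIL survival model results",
            "==========================",
            f"loss:                {self.model.loss}",
            f"conv blocks:         {cfg.conv_block_spec}",
            f"patch size:          {cfg.patch_px} px",
            f"patches train/eval:  {cfg.n_patches_train}/{cfg.n_patches_eval}",
            f"train / tune cases:  {len(self.model.train_ids)} / {len(self.model.tune_ids)}",
            f"steps:               {cfg.total_steps} (lr={cfg.learning_rate}, "
            f"batch={cfg.batch_size_cases}, ema={cfg.ema_decay})",
            f"checkpoints:         {len(self.checkpoints)}",
            f"best tune c-index:   {self.best_tune_cindex:.3f}",
        ]
        if self.n_resampled_batches:
            lines.append(f"event-less batches resampled: {self.n_resampled_batches}")
        return "\n".join(lines)


def hyperparameter_search(cases: list[Case], split: SplitAssignment,
                          base_config: ModelConfig, space: dict[str, list],
                          n_configs: int, seed: int, loss: str = "censored_ce"
                          ) -> list[tuple[ModelConfig, MILSurvivalResults]]:
    """Random hyperparameter search: sample ``n_configs`` configurations
    uniformly from the declared (finite) space, train one model per
    configuration and return all results; checkpoints are tagged with their
    configuration id so a cross-configuration pool can be ensembled."""
    if not space or any(len(v) == 0 for v in space.values()):
        raise ValueError("hyperparameter space must be nonempty")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_configs):
        overrides = {k: v[int(rng.integers(len(v)))] for k, v in sorted(space.items())}
        cfg = replace(base_config, **overrides, seed=int(rng.integers(2 ** 31)))
        res = MILSurvivalModel(cases, split, cfg, loss=loss).fit()
        for c in res.checkpoints:
            c.config_id = i
        out.append((cfg, res))
    return out
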