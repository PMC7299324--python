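"""Patch-level risk maps over slides and extreme-patch galleries.

Scoring a slide one patch at a time localises the case-level risk signal:
the map records, for every tissue-eligible grid position, the risk the model
assigns to that single patch.  Galleries collect each case's top and bottom
quantile of patch scores for qualitative review, with cases ordered by their
case-level risk prediction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .cohort import DEFAULT_MIN_TISSUE_FRACTION, Slide

logger = logging.getLogger(__name__)


@dataclass
class RiskMap:
    """Per-position risk scores on a regular grid over one slide; positions
    outside tissue are NaN (missing), never a score."""

    scores: np.ndarray          # (gh, gw) float, NaN = non-tissue
    stride: int
    patch_px: int
    slide_id: str

    def scored_positions(self) -> list[tuple[int, int, float]]:
        """(x, y, score) for every scored grid position, pixel coordinates."""
        out = []
        for gy, gx in zip(*np.nonzero(~np.isnan(self.scores))):
            out.append((int(gx * self.stride), int(gy * self.stride),
                        float(self.scores[gy, gx])))
        return out


def batch_scorer(net, param_sets, loss: str):
    """Adapter: a callable scoring a stack of single patches (N, P, P, 3)
    with the ensemble-median unified risk, one patch at a time."""
    from .losses import unified_risk

    def score(patches: np.ndarray) -> np.ndarray:
        x = net.preprocess(patches)
        member = np.stack([unified_risk(net.forward(x, 1, params=p), loss)
                           for p in param_sets])
        return np.median(member, axis=0)

    return score


def patch_risk_map(scorer, slide: Slide, patch_px: int, stride: int | None = None,
                   min_tissue_fraction: float = DEFAULT_MIN_TISSUE_FRACTION,
                   chunk: int = 256) -> RiskMap:
    """Score every tissue-eligible grid position of a slide with single-patch
    bags.  ``scorer`` maps a patch stack (N, P, P, 3) to N risk scores (see
    :func:`batch_scorer`); the grid stride defaults to ``patch_px``
    (non-overlapping)."""
    stride = stride or patch_px
    H, W = slide.shape
    gh = (H - patch_px) // stride + 1 if H >= patch_px else 0
    gw = (W - patch_px) // stride + 1 if W >= patch_px else 0
    scores = np.full((max(gh, 0), max(gw, 0)), np.nan)
    eligible = slide.eligible_mask(patch_px, min_tissue_fraction)
    positions = [(gy, gx) for gy in range(gh) for gx in range(gw)
                 if eligible[gy * stride, gx * stride]]
    if not positions:
        logger.warning("patch_risk_map: slide %s has no tissue-eligible grid "
                       "position", slide.slide_id)
        return RiskMap(scores=scores, stride=stride, patch_px=patch_px,
                       slide_id=slide.slide_id)
    for start in range(0, len(positions), chunk):
        block = positions[start:start + chunk]
        patches = np.stack([slide.patch(gx * stride, gy * stride, patch_px)
                            for gy, gx in block])
        vals = scorer(patches)
        for (gy, gx), v in zip(block, vals):
            scores[gy, gx] = v
    return RiskMap(scores=scores, stride=stride, patch_px=patch_px,
                   slide_id=slide.slide_id)


@dataclass
class GalleryEntry:
    case_id: str
    case_risk: float
    kind: str                   # "top" or "bottom"
    slide_id: str
    x: int
    y: int
    patch_score: float
    patch_px: int = 0


def extract_extreme_patches(riskmaps: dict[str, list[RiskMap]],
                            case_risks: dict[str, float],
                            fraction: float = 0.25,
                            min_positions: int = 4) -> list[GalleryEntry]:
    """Per case: the top and bottom ``fraction`` of scored grid positions by
    patch-level risk.  Rows are ordered by case-level risk descending; cases
    with fewer than ``min_positions`` scored positions are skipped.  With
    fraction 0.5 the scored positions are partitioned at their median."""
    if not 0 < fraction <= 0.5:
        raise ValueError("fraction must be in (0, 0.5]")
    entries: list[GalleryEntry] = []
    order = sorted(case_risks, key=lambda c: -case_risks[c])
    for cid in order:
        maps = riskmaps.get(cid, [])
        pos = [(m.slide_id, x, y, s, m.patch_px) for m in maps
               for x, y, s in m.scored_positions()]
        if len(pos) < min_positions:
            logger.info("extract_extreme_patches: case %s has %d < %d scored "
                        "positions; skipped", cid, len(pos), min_positions)
            continue
        pos.sort(key=lambda e: e[3])
        k = max(1, int(fraction * len(pos)))
        for sid, x, y, sc, pp in pos[-k:][::-1]:
            entries.append(GalleryEntry(cid, case_risks[cid], "top", sid, x, y, sc, pp))
        for sid, x, y, sc, pp in pos[:k]:
            entries.append(GalleryEntry(cid, case_risks[cid], "bottom", sid, x, y, sc, pp))
    return entries


def save_overlay_png(riskmap: RiskMap, slide: Slide, path, alpha: float = 0.45):
    """Diverging blue-red overlay of a risk map on its slide, centred on the
    map's median score."""
    import matplotlib
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(slide.image)
    centre = np.nanmedian(riskmap.scores) if np.any(~np.isnan(riskmap.scores)) else 0.0
    span = np.nanmax(np.abs(riskmap.scores - centre)) if np.any(~np.isnan(riskmap.scores)) else 1.0
    span = span or 1.0
    H, W = slide.shape
    up = np.full((H, W), np.nan)
    P, st = riskmap.patch_px, riskmap.stride
    for gy in range(riskmap.scores.shape[0]):
        for gx in range(riskmap.scores.shape[1]):
            v = riskmap.scores[gy, gx]
            if not np.isnan(v):
                up[gy * st:gy * st + P, gx * st:gx * st + P] = v
    ax.imshow(up, cmap="coolwarm", alpha=alpha,
              norm=matplotlib.colors.Normalize(centre - span, centre + span))
    ax.set_axis_off()
    fig.savefig(path, bbox_inches="tight", dpi=120)
    plt.close(fig)



def save_gallery_png(entries: list[GalleryEntry], slides: dict[str, Slide],
                     path, max_cases: int = 12):
    """Contact sheet of extreme patches: one row per case (cases ordered by
    case-level risk, highest first), top-quartile patches left of the
    bottom-quartile ones."""
    import matplotlib.pyplot as plt

    by_case: dict[str, list[GalleryEntry]] = {}
    for e in entries:
        by_case.setdefault(e.case_id, []).append(e)
    case_ids = list(by_case)[:max_cases]
    if not case_ids:
        raise ValueError("no gallery entries to render")
    ncol = max(len(v) for v in by_case.values())
    fig, axes = plt.subplots(len(case_ids), ncol,
                             figsize=(1.2 * ncol, 1.4 * len(case_ids)),
                             squeeze=False)
    for row, cid in enumerate(case_ids):
        es = sorted(by_case[cid], key=lambda e: (e.kind != "top", -e.patch_score))
        for col in range(ncol):
            ax = axes[row][col]
            ax.set_axis_off()
            if col >= len(es):
                continue
            e = es[col]
            ax.imshow(slides[e.slide_id].patch(e.x, e.y, e.patch_px))
            ax.set_title(f"{cid} {e.kind} {e.patch_score:.2f}", fontsize=5)
    fig.savefig(path, bbox_inches="tight", dpi=150)
    plt.close(fig)
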