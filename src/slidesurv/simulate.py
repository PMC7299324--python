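"""Synthetic pseudo-slide cohort generator with a planted prognostic signal.

Each case gets a latent risk ``r ~ N(0, 1)``.  Survival follows a
proportional-hazards model: the event time is exponential with rate
``lambda0 * exp(beta * r)`` and censoring is an independent exponential.
Slides show tissue blobs on a bright background; a fraction ``p`` of
patch-grid positions inside tissue are *informative*: their nuclei-like dot
texture encodes ``r``.  Higher risk means more, fainter dots; the expected
total darkening per patch is held (approximately) constant, so the signal
lives in local texture rather than in the slide's global mean intensity and
can only be read out at patch level — the weak-supervision setting these
cohorts exist to exercise.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy.stats import norm

from .cohort import (Case, Slide, SurvivalRecord, records_to_frame,
                     frame_to_records, write_clinical_csv)


@dataclass
class SimulationConfig:
    """Cohort-level knobs; the defaults are the study conditions used by the
    package's own tests and examples.

    ``informative_fraction`` is the per-position probability that a tissue
    patch carries the risk-encoding texture.  ``risk_effect`` (beta) is the
    log-hazard per unit latent risk; ``baseline_hazard`` and
    ``censoring_rate`` are exponential rates per day.
    """

    n_cases: int = 100
    studies: dict[str, int] | None = None        # study code -> case count
    slides_per_case_range: tuple[int, int] = (1, 10)
    slide_size_px: int = 384
    patch_px: int = 256
    informative_fraction: float = 0.2
    risk_effect: float = 1.0                     # beta
    baseline_hazard: float = 0.002               # lambda0, events/day
    censoring_rate: float = 0.001                # events/day; 0 = no censoring
    background_level: int = 242
    tissue_level: int = 185
    weibull_shape: float = 1.0                   # 1.0 = exponential hazards
    # informative texture: expected dots per patch runs linearly in Phi(r)
    dots_low: float = 8.0
    dots_high: float = 44.0
    dot_radius: int = 2
    dot_depth: float = 70.0                      # darkening at baseline density
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.informative_fraction <= 1.0:
            raise ValueError("informative_fraction must be in [0, 1]")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be > 0")
        if self.censoring_rate < 0:
            raise ValueError("censoring_rate must be >= 0")
        lo, hi = self.slides_per_case_range
        if not (1 <= lo <= hi <= 10):
            raise ValueError("slides_per_case_range must lie within [1, 10]")
        if self.weibull_shape <= 0:
            raise ValueError("weibull_shape must be > 0")
        if self.studies is None:
            self.studies = {"SYN0": self.n_cases}
        else:
            self.n_cases = sum(self.studies.values())


@dataclass
class SyntheticCase:
    case_id: str
    study: str
    latent_risk: float
    slides: list[Slide]
    tissue_masks: list[np.ndarray]
    informative_grids: list[np.ndarray]   # per-slide bool grid over patch cells
    record: SurvivalRecord

    def as_case(self) -> Case:
        return Case(record=self.record, slides=self.slides)


def _dot_density(r: float, cfg: SimulationConfig) -> float:
    """Expected dots per patch cell for an informative cell: linear in Phi(r),
    so it is a bounded, strictly monotone function of the latent risk."""
    return cfg.dots_low + (cfg.dots_high - cfg.dots_low) * norm.cdf(r)


def _baseline_density(cfg: SimulationConfig) -> float:
    return 0.5 * (cfg.dots_low + cfg.dots_high)


def _stamp_dots(img: np.ndarray, tissue: np.ndarray, y0: int, x0: int,
                cell: int, n_dots: int, depth: float, radius: int,
                rng: np.random.Generator) -> None:
    """Darken ``n_dots`` disc-shaped spots inside one patch cell in place;
    dots are only placed on tissue pixels (nuclei live in tissue)."""
    if n_dots <= 0:
        return
    H, W = img.shape[:2]
    ys = rng.integers(radius, cell - radius, size=n_dots) + y0
    xs = rng.integers(radius, cell - radius, size=n_dots) + x0
    dy, dx = np.mgrid[-radius:radius + 1, -radius:radius + 1]
    disc = (dy ** 2 + dx ** 2) <= radius ** 2
    for y, x in zip(ys, xs):
        if y + radius >= H or x + radius >= W or not tissue[y, x]:
            continue
        win = img[y - radius:y + radius + 1, x - radius:x + radius + 1]
        win[disc] = np.clip(win[disc].astype(np.float64) - depth, 0, 255).astype(img.dtype)


def _render_slide(r: float, cfg: SimulationConfig, rng: np.random.Generator
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Render one slide: tissue blob on background, nuclei-dot texture, and an
    informative-cell grid whose dot density encodes the latent risk."""
    S, P = cfg.slide_size_px, cfg.patch_px
    if S < P:
        raise ValueError("slide_size_px must be >= patch_px")
    img = np.full((S, S, 3), cfg.background_level, dtype=np.float64)

    # one large irregular tissue blob; eosin-leaning tint
    yy, xx = np.mgrid[0:S, 0:S].astype(np.float64)
    cy, cx = rng.uniform(0.4 * S, 0.6 * S, size=2)
    ry, rx = rng.uniform(0.38 * S, 0.48 * S, size=2)
    theta = rng.uniform(0, np.pi)
    yr = (yy - cy) * np.cos(theta) + (xx - cx) * np.sin(theta)
    xr = -(yy - cy) * np.sin(theta) + (xx - cx) * np.cos(theta)
    wobble = 1.0 + 0.12 * np.sin(6 * np.arctan2(yr, xr) + rng.uniform(0, 2 * np.pi))
    tissue = (yr / ry) ** 2 + (xr / rx) ** 2 <= wobble
    tint = np.array([1.06, 0.88, 1.0])
    noise = rng.normal(0.0, 6.0, size=(S, S, 3))
    img[tissue] = cfg.tissue_level * tint + noise[tissue]
    img = np.clip(img, 0, 255).astype(np.uint8)

    # patch-cell grid; informative cells carry the risk-dependent density
    G = S // P
    informative = np.zeros((G, G), dtype=bool)
    base = _baseline_density(cfg)
    for gy in range(G):
        for gx in range(G):
            y0, x0 = gy * P, gx * P
            cell_tissue = tissue[y0:y0 + P, x0:x0 + P].mean()
            if cell_tissue < 0.5:
                continue
            is_inf = rng.random() < cfg.informative_fraction
            lam = _dot_density(r, cfg) if is_inf else base
            # per-dot darkening scaled inversely with expected count: the
            # expected total dark mass per cell is density-independent
            depth = np.clip(cfg.dot_depth * base / lam, 0, cfg.tissue_level - 10)
            n = rng.poisson(lam)
            _stamp_dots(img, tissue, y0, x0, P, n, depth, cfg.dot_radius, rng)
            informative[gy, gx] = is_inf
    return img, tissue, informative


def _simulate_survival(r: float, cfg: SimulationConfig, rng: np.random.Generator
                       ) -> tuple[float, int]:
    rate = cfg.baseline_hazard * np.exp(cfg.risk_effect * r)
    u = rng.uniform()
    if cfg.weibull_shape == 1.0:
        t_event = -np.log(u) / rate
    else:  # Weibull with the same scale parameterisation, shape k
        t_event = (-np.log(u) / rate) ** (1.0 / cfg.weibull_shape)
    if cfg.censoring_rate > 0:
        t_cens = rng.exponential(1.0 / cfg.censoring_rate)
    else:
        t_cens = np.inf
    t = min(t_event, t_cens)
    event = int(t_event <= t_cens)
    return max(1.0, float(np.round(t))), event


def _simulate_covariates(r: float, rng: np.random.Generator) -> tuple[int, float, str]:
    # stage ordinal 1-4, correlated with latent risk via noisy thresholds:
    # a realistic confounder for the multivariable Cox harness
    z = r + rng.normal(0.0, 1.0)
    stage = 1 + int(z > -0.5) + int(z > 0.5) + int(z > 1.5)
    age = float(np.round(np.clip(rng.normal(62.0, 10.0) + 2.0 * r, 25.0, 90.0), 1))
    sex = "F" if rng.random() < 0.5 else "M"
    return stage, age, sex


def generate_cohort(config: SimulationConfig) -> list[SyntheticCase]:
    """Generate a full synthetic cohort; byte-identical for a given seed."""
    root = np.random.SeedSequence(config.seed)
    cases: list[SyntheticCase] = []
    idx = 0
    study_items = sorted(config.studies.items())
    child_seeds = root.spawn(sum(n for _, n in study_items))
    for study, n_cases in study_items:
        for _ in range(n_cases):
            rng = np.random.default_rng(child_seeds[idx])
            case_id = f"{study}-{idx:05d}"
            r = float(rng.standard_normal())
            t, event = _simulate_survival(r, config, rng)
            stage, age, sex = _simulate_covariates(r, rng)
            record = SurvivalRecord(case_id=case_id, study=study, time_days=t,
                                    event=event, stage=stage, age=age, sex=sex)
            n_slides = int(rng.integers(config.slides_per_case_range[0],
                                        config.slides_per_case_range[1] + 1))
            slides, masks, grids = [], [], []
            for s in range(n_slides):
                img, mask, grid = _render_slide(r, config, rng)
                slides.append(Slide(img, slide_id=f"{case_id}-s{s}"))
                masks.append(mask)
                grids.append(grid)
            cases.append(SyntheticCase(case_id=case_id, study=study, latent_risk=r,
                                       slides=slides, tissue_masks=masks,
                                       informative_grids=grids, record=record))
            idx += 1
    return cases


def write_cohort(cohort: list[SyntheticCase], directory: str | Path,
                 overwrite: bool = False, config: SimulationConfig | None = None) -> Path:
    """Write slides as PNG, the clinical table as CSV and a JSON manifest."""
    directory = Path(directory)
    clinical = directory / "clinical.csv"
    if clinical.exists() and not overwrite:
        raise FileExistsError(f"{clinical} exists; pass overwrite=True to replace it")
    directory.mkdir(parents=True, exist_ok=True)
    slide_dir = directory / "slides"
    slide_dir.mkdir(exist_ok=True)
    manifest: dict = {"cases": {}}
    if config is not None:
        cfg = asdict(config)
        cfg["slides_per_case_range"] = list(config.slides_per_case_range)
        manifest["config"] = cfg
        manifest["seed"] = config.seed
    for case in cohort:
        paths = []
        for slide in case.slides:
            p = slide_dir / f"{slide.slide_id}.png"
            iio.imwrite(p, slide.image)
            paths.append(str(p.relative_to(directory)))
        manifest["cases"][case.case_id] = {"slides": paths,
                                           "latent_risk": case.latent_risk}
    write_clinical_csv([c.record for c in cohort], clinical)
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return directory


def load_cohort(directory: str | Path) -> list[Case]:
    """Read a written cohort back into in-memory cases."""
    directory = Path(directory)
    records = frame_to_records(pd.read_csv(directory / "clinical.csv"))
    manifest = json.loads((directory / "manifest.json").read_text())
    cases = []
    for rec in records:
        info = manifest["cases"][rec.case_id]
        slides = [Slide(np.asarray(iio.imread(directory / p)),
                        slide_id=Path(p).stem) for p in info["slides"]]
        cases.append(Case(record=rec, slides=slides))
    return cases
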