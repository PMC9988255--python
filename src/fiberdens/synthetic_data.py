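"""Ground-truth-bearing synthetic micrographs and behavioral datasets.

Two families of generators:

* **Fiber scenes** — brightfield-like RGB images of thin, tortuous,
  brown-stained fibers on a pale background, with optional large dark
  stains, per-channel sensor noise and optional defocus blur, plus the
  exact pre-noise fiber mask.  Fibers are rendered as persistent random
  walks (von Mises step angles); only the detector-facing statistics
  matter (thin, elongated, dark structures of known pixel fraction), not
  any biological growth model.

* **Factorial behavior tables** — lever-press rates for mixed
  between x within designs (e.g. group x treatment between subjects,
  devaluation within), generated as baseline + subject random effect +
  cell effect + residual noise, Gaussian on rates to match the ANOVA
  assumptions of the planned-contrast analysis.  A separate point-process
  simulator produces training-session records under fixed/random-ratio
  reinforcement schedules with time and outcome caps.

Everything is deterministic given its seed.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .micrograph_io import Micrograph

__all__ = [
    "FiberSceneParams",
    "FiberScene",
    "BehaviorSimParams",
    "SessionSchedule",
    "GenerationError",
    "generate_fiber_scene",
    "generate_depletion_cohort",
    "generate_behavior_table",
    "simulate_training_sessions",
]

logger = logging.getLogger(__name__)


class GenerationError(RuntimeError):
    """Raised when a generator cannot reach its target within budget."""


@dataclass
class FiberSceneParams:
    """Parameters of one synthetic fiber micrograph.

    Defaults emulate the study ROIs: a 300x300 um^2 window at
    ~0.227 um/px (here at half the linear resolution, 660 px, same pixel
    statistics), 1-3 px wide fibers, bright background near gray level
    230, occasional large dark stains and mild sensor noise.
    """

    image_size_px: tuple[int, int] = (660, 660)
    pixel_size_um: float = 300.0 / 1320.0
    target_density: float = 0.02
    fiber_width_px: int = 2
    tortuosity: float = 0.25  # SD (radians) of the step-angle increments
    stain_count: int = 1
    stain_radius_px: int = 35
    noise_sd: float = 3.0
    blur_sigma_px: float = 0.0
    fiber_color: tuple[float, float, float] = (120.0, 80.0, 40.0)  # RGB brown
    background_color: tuple[float, float, float] = (230.0, 225.0, 220.0)
    stain_color: tuple[float, float, float] = (70.0, 45.0, 25.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.target_density < 0.2):
            raise ValueError("target_density must lie in [0, 0.2)")
        if self.image_size_px[0] < 8 or self.image_size_px[1] < 8:
            raise ValueError("image too small")
        if not (1 <= self.fiber_width_px <= 3):
            raise ValueError("fiber_width_px must be 1, 2 or 3")
        if self.noise_sd < 0 or self.blur_sigma_px < 0:
            raise ValueError("noise_sd and blur_sigma_px must be >= 0")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")


@dataclass
class FiberScene:
    """A rendered scene: image, exact pre-noise fiber mask, realized density."""

    image: Micrograph
    truth_mask: np.ndarray
    realized_density: float
    params: FiberSceneParams = field(repr=False, default=None)


def _walk(rng: np.random.Generator, shape: tuple[int, int], n_steps: int,
          tortuosity: float) -> tuple[np.ndarray, np.ndarray]:
    """One persistent random walk; returns integer row/col indices in bounds."""
    h, w = shape
    y = rng.uniform(0, h)
    x = rng.uniform(0, w)
    theta = rng.uniform(0, 2 * np.pi)
    # wrapped-normal step angles ~ von Mises with kappa ≈ 1/tortuosity^2
    dtheta = rng.normal(0.0, tortuosity, size=n_steps)
    thetas = theta + np.cumsum(dtheta)
    ys = y + np.cumsum(np.sin(thetas))
    xs = x + np.cumsum(np.cos(thetas))
    rr = np.round(ys).astype(int)
    cc = np.round(xs).astype(int)
    keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
    return rr[keep], cc[keep]


_WIDTH_STRUCTS = {
    1: None,
    2: np.ones((2, 2), dtype=bool),
    3: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool),
}


def generate_fiber_scene(params: FiberSceneParams) -> FiberScene:
    """Render a synthetic fiber micrograph with known ground truth.

    Fiber walks are added until the mask density reaches
    ``target_density`` (walk length shrinks near the target to limit
    overshoot); large stains are stamped as dark disks; Gaussian noise and
    optional defocus blur are applied to the rendered image only — the
    truth mask is exact and pre-noise.

    Raises
    ------
    GenerationError
        If the walker budget is exhausted before the target density is
        reached.
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.image_size_px
    n_px = h * w
    mask = np.zeros((h, w), dtype=bool)
    struct = _WIDTH_STRUCTS[params.fiber_width_px]
    # rough yield of new mask pixels per walk step, used to size walks
    px_per_step = {1: 1.0, 2: 2.6, 3: 3.6}[params.fiber_width_px]

    target_px = int(round(params.target_density * n_px))
    budget = max(50, 20 * target_px // 50 + 50)
    n_walks = 0
    while np.count_nonzero(mask) < target_px:
        if n_walks >= budget:
            raise GenerationError(
                f"walker budget exhausted ({budget} walks) before reaching "
                f"density {params.target_density}"
            )
        remaining = target_px - np.count_nonzero(mask)
        n_steps = int(np.clip(remaining / px_per_step, 12, 400))
        rr, cc = _walk(rng, (h, w), n_steps, params.tortuosity)
        if rr.size == 0:
            n_walks += 1
            continue
        stroke = np.zeros((h, w), dtype=bool)
        stroke[rr, cc] = True
        if struct is not None:
            stroke = ndimage.binary_dilation(stroke, structure=struct)
        mask |= stroke
        n_walks += 1

    realized = np.count_nonzero(mask) / n_px

    img = np.empty((h, w, 3), dtype=np.float64)
    for c in range(3):
        img[:, :, c] = params.background_color[c]

    # large dark stains (nuisance blobs the detector must exclude)
    yy, xx = np.ogrid[:h, :w]
    for _ in range(params.stain_count):
        cy = rng.uniform(0.15 * h, 0.85 * h)
        cx = rng.uniform(0.15 * w, 0.85 * w)
        r = params.stain_radius_px * rng.uniform(0.8, 1.2)
        blob = (yy - cy) ** 2 + (xx - cx) ** 2 <= r ** 2
        for c in range(3):
            img[:, :, c][blob] = params.stain_color[c]

    for c in range(3):
        img[:, :, c][mask] = params.fiber_color[c]

    if params.blur_sigma_px > 0:
        for c in range(3):
            img[:, :, c] = ndimage.gaussian_filter(
                img[:, :, c], sigma=params.blur_sigma_px, mode="reflect"
            )
    if params.noise_sd > 0:
        img += rng.normal(0.0, params.noise_sd, size=img.shape)
    np.clip(img, 0, 255, out=img)
    np.rint(img, out=img)  # 8-bit sensor quantization

    micro = Micrograph(
        pixels=img,
        pixel_size_um=params.pixel_size_um,
        subject_id="synthetic",
        region="other",
    )
    return FiberScene(
        image=micro, truth_mask=mask, realized_density=realized, params=params
    )


def generate_depletion_cohort(
    densities: Mapping[tuple[str, str], float],
    n_per_group: int = 10,
    rois_per_cell: int = 3,
    image_size_px: tuple[int, int] = (330, 330),
    group_factor: str = "group",
    seed: int = 0,
    scene_kwargs: Mapping | None = None,
) -> list[Micrograph]:
    """Synthetic cohort of micrographs for a depletion-study simulation.

    ``densities`` maps (group level, region label) to the ground-truth
    fiber density of that cell, e.g. ``{("CTL", "VO"): 0.05, ("CTL",
    "LO"): 0.04, ("SAP", "VO"): 0.01, ("SAP", "LO"): 0.01}`` — a
    noradrenergic-depletion pattern with the normal VO > LO gradient in
    controls.  Each subject contributes ``rois_per_cell`` ROIs per region
    (emulating multiple sections), to be averaged downstream.  Scene seeds
    derive from ``seed``; the cohort is fully deterministic.
    """
    rng = np.random.default_rng(seed)
    groups = sorted({g for g, _ in densities})
    regions = sorted({r for _, r in densities})
    extra = dict(scene_kwargs or {})
    images: list[Micrograph] = []
    sid = 0
    ap_levels = (4.4, 3.7, 3.0)
    for grp in groups:
        for _ in range(n_per_group):
            sid += 1
            for region in regions:
                for k in range(rois_per_cell):
                    p = FiberSceneParams(
                        image_size_px=image_size_px,
                        target_density=densities[(grp, region)],
                        seed=int(rng.integers(0, 2**31 - 1)),
                        **extra,
                    )
                    scene = generate_fiber_scene(p)
                    img = scene.image
                    images.append(Micrograph(
                        pixels=img.pixels,
                        pixel_size_um=img.pixel_size_um,
                        subject_id=f"s{sid:03d}",
                        region=region,
                        hemisphere="left",
                        ap_mm=ap_levels[k % len(ap_levels)],
                        group_labels={group_factor: grp},
                    ))
    return images


# ---------------------------------------------------------------------------
# factorial behavior generator
# ---------------------------------------------------------------------------

@dataclass
class BehaviorSimParams:
    """Parameters of a synthetic mixed-factorial behavior dataset.

    The design mirrors an instrumental outcome-devaluation experiment:
    between-subject factors (e.g. group: Pre/Post lesion timing; treatment:
    CTL/SAP toxin) crossed with a two-level within-subject factor
    (devaluation: Ndev/Dev lever).  Responses are lever-press rates
    (presses/min) during a 10-min extinction choice test, modeled as

        rate = baseline + subject_effect + cell_effect + residual,

    with ``devaluation_effect`` subtracted from the ``effect_level``
    response in the cells listed in ``affected_cells`` (all cells when
    None) — goal-directed subjects press less on the devalued lever.
    Negative draws are truncated at zero (count logged).
    """

    n_per_cell: int = 14
    between_factors: Mapping[str, Sequence[str]] = field(
        default_factory=lambda: {
            "group": ("Pre", "Post"),
            "treatment": ("CTL", "SAP"),
        }
    )
    within_factor: Mapping[str, Sequence] = field(
        default_factory=lambda: {"devaluation": ("Ndev", "Dev")}
    )
    baseline_rate: float = 12.0
    devaluation_effect: float = 0.0
    effect_level: object = "Dev"
    affected_cells: Sequence[Mapping[str, str]] | None = None
    subject_sd: float = 3.0
    residual_sd: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_cell < 2:
            raise ValueError(
                "n_per_cell must be >= 2 (no within-cell variance estimate otherwise)"
            )
        if self.subject_sd < 0 or self.residual_sd < 0:
            raise ValueError("variance components must be >= 0")
        if len(self.within_factor) != 1:
            raise ValueError("exactly one within-subject factor is supported")


def _cell_is_affected(cell: Mapping[str, str],
                      affected: Sequence[Mapping[str, str]] | None) -> bool:
    if affected is None:
        return True
    for spec in affected:
        if all(cell.get(k) == v for k, v in spec.items()):
            return True
    return False


def generate_behavior_table(params: BehaviorSimParams) -> pd.DataFrame:
    """Long-format subject x factor x response table.

    Columns: ``subject``, one column per between factor, the within factor
    column, and ``response`` (presses/min, truncated at 0).
    """
    rng = np.random.default_rng(params.seed)
    within_name, within_levels = next(iter(params.within_factor.items()))
    bf_names = list(params.between_factors)
    cells = list(itertools.product(*(params.between_factors[f] for f in bf_names)))

    rows = []
    n_truncated = 0
    sid = 0
    for cell in cells:
        cell_map = dict(zip(bf_names, cell))
        affected = _cell_is_affected(cell_map, params.affected_cells)
        for _ in range(params.n_per_cell):
            sid += 1
            subj_eff = rng.normal(0.0, params.subject_sd)
            for lev in within_levels:
                resp = params.baseline_rate + subj_eff + rng.normal(0.0, params.residual_sd)
                if affected and lev == params.effect_level:
                    resp -= params.devaluation_effect
                if resp < 0:
                    resp = 0.0
                    n_truncated += 1
                row = {"subject": f"s{sid:03d}", **cell_map, within_name: lev,
                       "response": resp}
                rows.append(row)
    if n_truncated:
        logger.info("behavior generator truncated %d negative rates at 0", n_truncated)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# operant training-session point-process simulator
# ---------------------------------------------------------------------------

#: reinforcement probability per press by schedule stage
_STAGE_PROB = {"FR1": 1.0, "RR5": 0.2, "RR10": 0.1, "RR20": 0.05}


@dataclass
class SessionSchedule:
    """One training session's schedule structure.

    Each of the two levers is presented twice (4 presentations per
    session), each presentation lasting at most ``presentation_cap_min``
    minutes or until ``outcome_cap`` outcomes are earned, with
    ``iti_min`` minutes between presentations.  ``stage`` fixes the
    per-press reinforcement probability (FR1: 1; RR-N: 1/N).
    """

    stage: str = "FR1"
    presentations_per_lever: int = 2
    presentation_cap_min: float = 10.0
    outcome_cap: int = 20
    iti_min: float = 2.5

    def __post_init__(self) -> None:
        if self.stage not in _STAGE_PROB:
            raise ValueError(f"unknown stage {self.stage!r}; expected {sorted(_STAGE_PROB)}")

    @property
    def reinforcement_prob(self) -> float:
        return _STAGE_PROB[self.stage]


def simulate_training_sessions(
    schedule: SessionSchedule, press_rate: float, seed: int = 0
) -> pd.DataFrame:
    """Simulate one session of Poisson lever pressing under the schedule.

    Presses arrive as a Poisson process at ``press_rate`` presses/min;
    each press is reinforced with the stage's ratio probability; each
    presentation ends at the time cap or the outcome cap, whichever comes
    first.  Returns one row per presentation: lever, presses, outcomes,
    duration_min.
    """
    if not press_rate > 0:
        raise ValueError("press_rate must be > 0")
    rng = np.random.default_rng(seed)
    p = schedule.reinforcement_prob
    rows = []
    levers = ["left", "right"] * schedule.presentations_per_lever
    for i, lever in enumerate(levers):
        t = 0.0
        presses = 0
        outcomes = 0
        while True:
            t_next = t + rng.exponential(1.0 / press_rate)
            if t_next > schedule.presentation_cap_min:
                t = schedule.presentation_cap_min
                break
            t = t_next
            presses += 1
            if rng.random() < p:
                outcomes += 1
                if outcomes >= schedule.outcome_cap:
                    break
        rows.append({
            "presentation": i,
            "lever": lever,
            "presses": presses,
            "outcomes": outcomes,
            "duration_min": t,
        })
    return pd.DataFrame(rows)
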