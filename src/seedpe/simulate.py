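"""Synthetic experiment and detection-scene generators.

``generate_experiment`` emulates the structure of the factorial
seed-processing study: 5 varieties x 2 processing methods x 5 nominal pod
sample masses (1-5 g) x 10 replicates = 500 samples. Total object counts
grow roughly linearly with pod mass at a per-variety rate (mean 46.12
objects/g across the default varieties) with a small negative offset for
impact dehulling; the intact-pod proportion rises with mass; split seeds
are nearly absent under belt threshing and substantial but mass-declining
under impact dehulling. Counts are negative-binomial totals split
multinomially across classes; the split-seed count is stored doubled so
that the downstream SS/2 rule is exercised end to end. Default parameter
values are illustrative calibrations to the study's printed marginal
means, not estimates.

``generate_detection_scene`` builds box-level ground-truth/prediction pairs
(~40 x 40 px seed objects on a large canvas) for exercising the detection
evaluator without a detector.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .boxes import BoundingBox, ImageAnnotationSet
from .traits import SeedObjectCounts

DEFAULT_VARIETIES = (
    "AAC Mountainview",
    "Delaney",
    "Eski",
    "Rocky Mountain Remont",
    "Shoshone",
)


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic factorial experiment.

    ``objects_per_gram`` spans 32-60 across varieties (mean 46.12);
    ``method_count_offset`` removes ~4 objects under impact dehulling.
    ``p_ip_center`` gives each variety x method its mid-mass intact-pod
    proportion; ``p_ip_mass_slope`` is the (positive) per-gram logit slope.
    ``ss_share_belt`` is the near-constant split-seed share under belt
    threshing; ``ss_share_impact`` the mid-mass share under impact
    dehulling, declining with mass at ``ss_mass_slope_impact`` per gram on
    the logit scale. ``nb_dispersion`` is the negative-binomial size
    parameter (None = Poisson limiting case); ``sample_logit_sd`` adds
    per-sample over-dispersion to the class proportions.
    """

    varieties: tuple[str, ...] = DEFAULT_VARIETIES
    methods: tuple[str, str] = ("belt_thresher", "impact_dehuller")
    masses_g: tuple[int, ...] = (1, 2, 3, 4, 5)
    replicates: int = 10
    objects_per_gram: dict[str, float] = field(
        default_factory=lambda: {
            "AAC Mountainview": 60.0,
            "Delaney": 32.0,
            "Eski": 60.0,
            "Rocky Mountain Remont": 42.0,
            "Shoshone": 36.6,
        }
    )
    method_count_offset: dict[str, float] = field(
        default_factory=lambda: {"belt_thresher": 0.0, "impact_dehuller": -4.0}
    )
    p_ip_center: dict[tuple[str, str], float] = field(
        default_factory=lambda: {
            ("AAC Mountainview", "belt_thresher"): 0.299,
            ("Delaney", "belt_thresher"): 0.484,
            ("Eski", "belt_thresher"): 0.622,
            ("Rocky Mountain Remont", "belt_thresher"): 0.661,
            ("Shoshone", "belt_thresher"): 0.662,
            ("AAC Mountainview", "impact_dehuller"): 0.316,
            ("Delaney", "impact_dehuller"): 0.371,
            ("Eski", "impact_dehuller"): 0.491,
            ("Rocky Mountain Remont", "impact_dehuller"): 0.550,
            ("Shoshone", "impact_dehuller"): 0.577,
        }
    )
    p_ip_mass_slope: float = 0.15
    ss_share_belt: dict[str, float] = field(
        default_factory=lambda: {
            "AAC Mountainview": 0.015,
            "Delaney": 0.012,
            "Eski": 0.005,
            "Rocky Mountain Remont": 0.004,
            "Shoshone": 0.006,
        }
    )
    ss_share_impact: dict[str, float] = field(
        default_factory=lambda: {
            "AAC Mountainview": 0.338,
            "Delaney": 0.282,
            "Eski": 0.215,
            "Rocky Mountain Remont": 0.132,
            "Shoshone": 0.088,
        }
    )
    ss_mass_slope_impact: float = -0.276  # logit(0.301)->logit(0.125) over 1-5 g
    nb_dispersion: float | None = 200.0
    sample_logit_sd: float = 0.12
    pod_mass_jitter_sd: float = 0.02
    mixture_yield: dict[str, float] = field(
        default_factory=lambda: {"belt_thresher": 0.85, "impact_dehuller": 0.75}
    )
    mixture_yield_sd: float = 0.03

    def validate(self) -> None:
        if any(v <= 0 for v in self.objects_per_gram.values()):
            raise ValueError("objects_per_gram rates must be positive")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.nb_dispersion is not None and self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive or None")
        for v in self.varieties:
            for m in self.methods:
                for mass in self.masses_g:
                    p = self.expected_proportions(v, m, mass)
                    if min(p) < 0 or abs(sum(p) - 1) > 1e-9:
                        raise ValueError(
                            f"proportion parameters leave the simplex for "
                            f"({v}, {m}, {mass} g): {p}"
                        )

    def expected_total(self, variety: str, method: str, mass_g: float) -> float:
        return (
            self.objects_per_gram[variety] * mass_g
            + self.method_count_offset[method]
        )

    def expected_proportions(
        self, variety: str, method: str, mass_g: float
    ) -> tuple[float, float, float]:
        """Intended (P_IP, P_WS, P_SS) at a design point (mid-mass = 3 g)."""
        a = _logit(self.p_ip_center[(variety, method)])
        p_ip = float(_expit(np.array(a + self.p_ip_mass_slope * (mass_g - 3.0))))
        if method == "belt_thresher":
            p_ss = self.ss_share_belt[variety]
        else:
            c = _logit(self.ss_share_impact[variety])
            p_ss = float(
                _expit(np.array(c + self.ss_mass_slope_impact * (mass_g - 3.0)))
            )
        p_ws = 1.0 - p_ip - p_ss
        return p_ip, p_ws, p_ss


def generate_experiment(
    config: GeneratorConfig | None = None, seed: int = 0
) -> tuple[pd.DataFrame, dict[str, SeedObjectCounts]]:
    """Draw one full synthetic experiment.

    Returns the sample metadata table (sample-table column names) and a
    mapping sample_id -> SeedObjectCounts. Bit-identical for identical
    (config, seed).
    """
    config = config or GeneratorConfig()
    config.validate()
    rng = np.random.default_rng(seed)

    rows = []
    counts: dict[str, SeedObjectCounts] = {}
    sid = 0
    for variety in config.varieties:
        for method in config.methods:
            for mass in config.masses_g:
                for rep in range(1, config.replicates + 1):
                    sid += 1
                    sample_id = f"S{sid:04d}"
                    pod_mass = max(
                        0.05, mass + rng.normal(0.0, config.pod_mass_jitter_sd)
                    )
                    yld = np.clip(
                        config.mixture_yield[method]
                        + rng.normal(0.0, config.mixture_yield_sd),
                        0.05, 1.0,
                    )
                    mixture_mass = pod_mass * float(yld)

                    mu = config.expected_total(variety, method, pod_mass)
                    mu = max(mu, 1.0)
                    if config.nb_dispersion is None:
                        total = int(rng.poisson(mu))
                    else:
                        k = config.nb_dispersion
                        total = int(rng.negative_binomial(k, k / (k + mu)))

                    p_ip, p_ws, p_ss = config.expected_proportions(
                        variety, method, pod_mass
                    )
                    # per-sample over-dispersion: jitter the class log-odds
                    logits = np.log(
                        np.clip(np.array([p_ip, p_ws, p_ss]), 1e-9, None)
                    ) + rng.normal(0.0, config.sample_logit_sd, size=3)
                    p = np.exp(logits)
                    p /= p.sum()

                    n_ip, n_ws, n_ss_half = rng.multinomial(total, p)
                    # store the doubled raw split count: the SS/2 rule will
                    # recover n_ss_half and the intended proportions
                    counts[sample_id] = SeedObjectCounts(
                        n_ip=int(n_ip),
                        n_ws=int(n_ws),
                        n_ss_raw=int(2 * n_ss_half),
                    )
                    rows.append(
                        {
                            "sample_id": sample_id,
                            "variety": variety,
                            "processing_method": method,
                            "nominal_mass_g": mass,
                            "legume_fruit_pod_mass_g": round(pod_mass, 4),
                            "processed_mixture_mass_g": round(mixture_mass, 4),
                            "replicate": rep,
                        }
                    )
    return pd.DataFrame(rows), counts


def generate_detection_scene(
    n_objects: int = 30,
    class_mix: tuple[float, float, float] = (0.49, 0.34, 0.17),
    box_size: float = 40.0,
    jitter: float = 0.0,
    fp_rate: float = 0.0,
    fn_rate: float = 0.0,
    seed: int = 0,
    image_id: str = "scene",
) -> tuple[ImageAnnotationSet, ImageAnnotationSet]:
    """Build one (ground truth, predictions) scene.

    Ground-truth boxes of ~``box_size`` px are laid out on a jittered grid,
    so they never overlap. Predictions are the ground truth translated by
    up to ``jitter`` px per axis with confidences in [0.5, 1], minus a
    ``fn_rate`` fraction (missed objects), plus false positives at rate
    ``fp_rate`` (random well-separated boxes). With zero jitter/fp/fn the
    predicted geometry equals the ground truth exactly.
    """
    if n_objects < 1:
        raise ValueError("n_objects must be >= 1")
    rng = np.random.default_rng(seed)
    mix = np.asarray(class_mix, dtype=float)
    mix = mix / mix.sum()
    labels = rng.choice(["IP", "WS", "SS"], size=n_objects, p=mix)

    # grid layout with one free cell per possible false positive
    n_cells = n_objects + max(1, int(np.ceil(n_objects * max(fp_rate, 0.0))) + 4)
    side = int(np.ceil(np.sqrt(n_cells)))
    pitch = box_size * 2.0
    canvas = side * pitch + box_size
    cells = rng.permutation(side * side)
    gt_boxes: list[BoundingBox] = []
    for i in range(n_objects):
        cx = (cells[i] % side) * pitch + box_size
        cy = (cells[i] // side) * pitch + box_size
        dx, dy = rng.uniform(-box_size * 0.2, box_size * 0.2, size=2)
        w, h = rng.uniform(0.9, 1.1, size=2) * box_size
        gt_boxes.append(
            BoundingBox(cx + dx, cy + dy, cx + dx + w, cy + dy + h, str(labels[i]))
        )

    pred_boxes: list[BoundingBox] = []
    kept = rng.random(n_objects) >= fn_rate
    for i, b in enumerate(gt_boxes):
        if not kept[i]:
            continue
        dx = rng.uniform(-jitter, jitter) if jitter > 0 else 0.0
        dy = rng.uniform(-jitter, jitter) if jitter > 0 else 0.0
        pred_boxes.append(
            BoundingBox(
                b.x_min + dx, b.y_min + dy, b.x_max + dx, b.y_max + dy,
                b.class_label, confidence=float(rng.uniform(0.5, 1.0)),
            )
        )
    n_fp = int(rng.binomial(n_objects, fp_rate)) if fp_rate > 0 else 0
    for j in range(n_fp):
        cell = cells[n_objects + j % max(1, side * side - n_objects)]
        cx = (cell % side) * pitch + box_size
        cy = (cell // side) * pitch + box_size
        w, h = rng.uniform(0.9, 1.1, size=2) * box_size
        pred_boxes.append(
            BoundingBox(
                cx, cy, cx + w, cy + h,
                str(rng.choice(["IP", "WS", "SS"], p=mix)),
                confidence=float(rng.uniform(0.5, 1.0)),
            )
        )

    gt = ImageAnnotationSet(image_id, canvas, canvas, gt_boxes)
    pred = ImageAnnotationSet(image_id, canvas, canvas, pred_boxes)
    return gt, pred
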