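"""Seeded synthetic tongue-image cohorts.

No tongue-image dataset with constitution labels is publicly deposited, so
every downstream stage of the pipeline is exercised on images produced here.
A sample is a superellipse-shaped tongue with a smoothly perturbed boundary on
a skin-toned background with a darker oval rim (emulating a capture chamber
opening).  Constitution-conditioned appearance follows classical tongue
diagnosis:

* Yang-deficiency — pale body (lower CIELAB a*) and a larger tongue;
  tooth indentations along the margins.
* Wetness-heat  — yellow (higher b*), greasy (more opaque) coating.
* Qi-deficiency — cracks through the central body.
* Qi-depression — reddened tongue tip.
* Gentleness    — pink body, thin whitish coating, no lesions.

Every lesion is rendered inside the tongue mask and its ground-truth sub-mask
is recorded on the sample, which is what makes Grad-CAM localization testable.
Effect sizes are package defaults (the source cohort is private and only
qualitative descriptions exist); all are overridable per
:class:`PhenotypeSpec`.

All generators are pure functions of (spec, seed): per-sample seeds are
derived from the cohort seed with a counter-based ``SeedSequence`` scheme, so
cohorts are order-independent and bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.measure import label as cc_label

from .ccmq import SUBSCALE_ENTRIES, score_questionnaire
from .constitutions import Constitution, STUDY_CLASS_COUNTS

__all__ = [
    "PhenotypeSpec",
    "CohortSpec",
    "TongueSample",
    "DEFAULT_PHENOTYPES",
    "generate_sample",
    "generate_cohort",
    "generate_questionnaire",
]

MIN_SIZE = 32


@dataclass(frozen=True)
class PhenotypeSpec:
    """Appearance parameters for one constitution class."""

    constitution: Constitution
    body_color: tuple[int, int, int]
    coating_color: tuple[int, int, int]
    coating_opacity: float
    crack_intensity: float = 0.0
    toothmark_count: int = 0
    red_tip_intensity: float = 0.0
    body_scale: float = 0.5

    def __post_init__(self):
        for name in ("coating_opacity", "crack_intensity", "red_tip_intensity", "body_scale"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.toothmark_count < 0:
            raise ValueError("toothmark_count must be >= 0")


#: Default per-class phenotypes (package choices; qualitative structure only).
#: Only Yang-deficiency alters the tongue *body* (classically pale and large);
#: every other imbalanced class keeps the Gentleness body and differs through
#: its class-defining lesion — so lesions, not incidental body-color offsets,
#: carry the class signal.
DEFAULT_PHENOTYPES: dict[Constitution, PhenotypeSpec] = {
    Constitution.GENTLENESS: PhenotypeSpec(
        Constitution.GENTLENESS, (186, 108, 112), (228, 222, 214), 0.12
    ),
    Constitution.QI_DEFICIENCY: PhenotypeSpec(
        Constitution.QI_DEFICIENCY, (186, 108, 112), (228, 222, 214), 0.15,
        crack_intensity=0.8,
    ),
    Constitution.YANG_DEFICIENCY: PhenotypeSpec(
        Constitution.YANG_DEFICIENCY, (208, 152, 154), (232, 228, 222), 0.15,
        toothmark_count=6, body_scale=0.8,
    ),
    Constitution.WETNESS_HEAT: PhenotypeSpec(
        Constitution.WETNESS_HEAT, (186, 108, 112), (205, 178, 92), 0.65,
    ),
    Constitution.QI_DEPRESSION: PhenotypeSpec(
        Constitution.QI_DEPRESSION, (186, 108, 112), (228, 222, 214), 0.12,
        red_tip_intensity=0.85,
    ),
}


@dataclass(frozen=True)
class CohortSpec:
    class_counts: dict[Constitution, int]
    image_size: tuple[int, int] = (128, 128)
    seed: int = 0
    phenotypes: dict[Constitution, PhenotypeSpec] = field(default_factory=lambda: dict(DEFAULT_PHENOTYPES))
    questionnaire_noise: float = 0.15

    def __post_init__(self):
        if any(v < 0 for v in self.class_counts.values()):
            raise ValueError("class counts must be >= 0")
        if sum(self.class_counts.values()) < 1:
            raise ValueError("total cohort count must be >= 1")

    @property
    def total(self) -> int:
        return sum(self.class_counts.values())


@dataclass
class TongueSample:
    """One subject: image, ground-truth mask, label, lesion sub-masks."""

    image: np.ndarray  # (H, W, 3) uint8
    mask: np.ndarray  # (H, W) uint8 in {0,1}; 1 = tongue
    label: Constitution
    questionnaire: dict[str, int] | None = None
    lesions: dict[str, np.ndarray] = field(default_factory=dict)
    sample_id: str = ""
    seed: int = 0


def _superellipse_mask(h: int, w: int, rng: np.random.Generator, body_scale: float):
    """Tongue region: randomized superellipse with smooth angular perturbation."""
    scale = 0.8 + 0.4 * body_scale  # body_scale 0.5 -> 1.0
    cy = h * (0.52 + rng.uniform(-0.02, 0.02))
    cx = w * (0.5 + rng.uniform(-0.02, 0.02))
    a = w * 0.30 * scale * (1 + rng.uniform(-0.04, 0.04))
    b = h * 0.405 * scale * (1 + rng.uniform(-0.04, 0.04))
    p = rng.uniform(2.2, 2.8)
    yy, xx = np.mgrid[0:h, 0:w]
    dy = (yy - cy) / b
    dx = (xx - cx) / a
    rho = (np.abs(dx) ** p + np.abs(dy) ** p) ** (1.0 / p)
    theta = np.arctan2(dy, dx)
    wobble = np.ones_like(theta)
    for k in range(2, 5):
        wobble += 0.015 * rng.uniform(0.3, 1.0) * np.sin(k * theta + rng.uniform(0, 2 * np.pi))
    mask = (rho <= wobble).astype(np.uint8)
    # keep the largest 4-connected component (wobble could in principle pinch)
    lab = cc_label(mask, connectivity=1)
    if lab.max() > 1:
        sizes = np.bincount(lab.ravel())[1:]
        mask = (lab == (1 + int(np.argmax(sizes)))).astype(np.uint8)
    geom = {"cy": cy, "cx": cx, "a": a, "b": b, "rho": rho, "theta": theta}
    return mask, geom


def _background(h: int, w: int, rng: np.random.Generator) -> np.ndarray:
    base = np.array([212, 176, 150], dtype=np.float32)
    grad = np.linspace(-14, 14, h, dtype=np.float32)[:, None, None]
    img = np.clip(base[None, None, :] + grad + rng.normal(0, 3, (h, w, 3)), 0, 255)
    # darker oval rim (capture-chamber opening)
    yy, xx = np.mgrid[0:h, 0:w]
    r = ((yy - h / 2) / (0.52 * h)) ** 2 + ((xx - w / 2) / (0.52 * w)) ** 2
    rim = np.clip((r - 0.8) / 0.4, 0, 1)
    return img * (1.0 - 0.65 * rim[:, :, None])


def generate_sample(
    spec: PhenotypeSpec, size: tuple[int, int] = (128, 128), seed: int = 0
) -> TongueSample:
    """Render one synthetic tongue image with mask and lesion sub-masks."""
    h, w = size
    if h < MIN_SIZE or w < MIN_SIZE:
        raise ValueError(
            f"image size {size} too small to render a tongue; minimum is "
            f"{MIN_SIZE}x{MIN_SIZE}"
        )
    rng = np.random.default_rng(seed)
    img = _background(h, w, rng)
    mask, geom = _superellipse_mask(h, w, rng, spec.body_scale)
    inside = mask.astype(bool)
    rho, dy_n = geom["rho"], (np.mgrid[0:h, 0:w][0] - geom["cy"]) / geom["b"]

    # tongue body: base color + smooth texture + gentle radial shading
    body = np.array(spec.body_color, dtype=np.float32)
    tex = gaussian_filter(rng.normal(0, 1, (h, w)), sigma=max(1.5, h / 48))
    tex = tex / (np.abs(tex).max() + 1e-9) * 10.0
    shade = 1.0 - 0.12 * np.clip(rho, 0, 1) ** 2
    tongue_rgb = body[None, None, :] * shade[:, :, None] + tex[:, :, None]
    img[inside] = tongue_rgb[inside]

    lesions: dict[str, np.ndarray] = {}

    # coating: central-posterior patch, alpha-blended, grainy alpha = "greasy"
    coat_region = inside & (rho <= 0.72) & (dy_n < 0.30)
    if spec.coating_opacity > 0 and coat_region.any():
        grain = gaussian_filter(rng.random((h, w)), sigma=1.2)
        grain = 0.6 + 0.4 * (grain - grain.min()) / (np.ptp(grain) + 1e-9)
        alpha = (spec.coating_opacity * grain)[:, :, None]
        cc = np.array(spec.coating_color, dtype=np.float32)[None, None, :]
        img = np.where(coat_region[:, :, None], (1 - alpha) * img + alpha * cc, img)
        lesions["coating"] = coat_region.astype(np.uint8)

    # cracks: dark random-walk polylines through the central body
    if spec.crack_intensity > 0:
        crack = np.zeros((h, w), dtype=bool)
        n_cracks = 1 + int(round(2 * spec.crack_intensity))
        for _ in range(n_cracks):
            y = int(geom["cy"] - 0.45 * geom["b"])
            x = int(geom["cx"] + rng.integers(-w // 10, w // 10 + 1))
            while y < geom["cy"] + 0.45 * geom["b"]:
                y2 = y + int(rng.integers(2, max(3, h // 24)))
                x2 = x + int(rng.integers(-2, 3))
                rr = np.clip(np.linspace(y, y2, 8).astype(int), 0, h - 1)
                cs = np.clip(np.linspace(x, x2, 8).astype(int), 0, w - 1)
                crack[rr, cs] = True
                if w >= 64:  # widen to 2 px at higher resolutions
                    crack[rr, np.clip(cs + 1, 0, w - 1)] = True
                y, x = y2, x2
        crack &= inside
        img[crack] = img[crack] * (1.0 - 0.55 * spec.crack_intensity)
        lesions["crack"] = crack.astype(np.uint8)

    # tooth marks: pale scallops just inside the lateral margins
    if spec.toothmark_count > 0:
        tm = np.zeros((h, w), dtype=bool)
        radius = max(2, min(h, w) // 24)
        angles = np.concatenate(
            [
                np.linspace(-0.45 * np.pi, 0.45 * np.pi, (spec.toothmark_count + 1) // 2),
                np.linspace(0.55 * np.pi, 1.45 * np.pi, spec.toothmark_count // 2),
            ]
        )[: spec.toothmark_count]
        yy, xx = np.mgrid[0:h, 0:w]
        for th in angles:
            ex = geom["cx"] + 0.88 * geom["a"] * np.cos(th)
            ey = geom["cy"] + 0.88 * geom["b"] * np.sin(th)
            tm |= (yy - ey) ** 2 + (xx - ex) ** 2 <= radius**2
        tm &= inside
        pale = np.array([228, 214, 208], dtype=np.float32)
        img = np.where(tm[:, :, None], 0.45 * img + 0.55 * pale[None, None, :], img)
        if tm.any():
            lesions["toothmark"] = tm.astype(np.uint8)

    # red tip
    if spec.red_tip_intensity > 0:
        tip = inside & (dy_n > 0.55)
        if tip.any():
            red = np.array([198, 36, 52], dtype=np.float32)
            a = 0.65 * spec.red_tip_intensity
            img = np.where(tip[:, :, None], (1 - a) * img + a * red[None, None, :], img)
            lesions["red_tip"] = tip.astype(np.uint8)

    img = np.clip(img, 0, 255).astype(np.uint8)
    return TongueSample(image=img, mask=mask, label=spec.constitution, lesions=lesions, seed=seed)


def _sample_seed(master: int, class_index: int, within_index: int) -> int:
    """Counter-based per-sample seed derivation (order-independent)."""
    ss = np.random.SeedSequence(entropy=master, spawn_key=(class_index, within_index))
    return int(ss.generate_state(1)[0] % (2**31))


def generate_cohort(cohort: CohortSpec) -> list[TongueSample]:
    """Generate a labelled cohort with exact per-class counts."""
    samples: list[TongueSample] = []
    for ci, constitution in enumerate(Constitution):
        count = cohort.class_counts.get(constitution, 0)
        spec = cohort.phenotypes[constitution]
        for si in range(count):
            seed = _sample_seed(cohort.seed, ci, si)
            s = generate_sample(spec, cohort.image_size, seed)
            s.questionnaire = generate_questionnaire(
                constitution, cohort.questionnaire_noise, seed
            )
            s.sample_id = f"{constitution.value}_{si:04d}"
            samples.append(s)
    return samples


def study_cohort_spec(image_size=(128, 128), seed: int = 0) -> CohortSpec:
    """The study's per-class sample sizes (1374 subjects in total)."""
    return CohortSpec(dict(STUDY_CLASS_COUNTS), image_size, seed)


def generate_questionnaire(
    label: Constitution, noise: float, seed: int = 0
) -> dict[str, int]:
    """Item responses whose noiseless CCMQ call is exactly ``label``.

    The base pattern sets the target subscale's items to a level that fires
    the determination rule (all 5s for Gentleness; all 3s, i.e. a
    transformation score of 50, for imbalanced types) and all other items to
    the pattern that keeps other rules silent.  ``noise`` adds integer jitter
    to every item; at ``noise = 0`` the scored call always equals ``label``.
    """
    if not 0.0 <= noise <= 1.0:
        raise ValueError(f"noise must be in [0, 1], got {noise}")
    rng = np.random.default_rng(seed)
    items: dict[str, int] = {}
    for sub, n in SUBSCALE_ENTRIES.items():
        if label is Constitution.GENTLENESS:
            base = 5 if sub == "gentleness" else 1
        elif sub == label.value:
            base = 3
        elif sub == "gentleness":
            base = 3  # keeps the balanced score at 50, below the >= 60 rule
        else:
            base = 1
        for i in range(1, n + 1):
            jitter = rng.normal(0.0, 2.0 * noise) if noise > 0 else 0.0
            items[f"{sub}_{i}"] = int(np.clip(round(base + jitter), 1, 5))
    return items


def questionnaire_call(items: dict[str, int]):
    """Convenience: score a generated questionnaire with the CCMQ rules."""
    return score_questionnaire(items).call
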