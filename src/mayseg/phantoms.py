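"""Seeded brain-phantom generator with ground-truth tumor masks and labels.

Each phantom is an 8-bit grayscale image holding an elliptical "brain" of
several tissue-intensity modes on a dark background, plus one compact tumor
blob whose shape, location and intensity polarity encode a class label:

    0  "pituitary-like"   — disc,            lower-central,  hyper-intense
    1  "glioma-like"      — lobed blob,      upper-left,     hyper-intense
    2  "meningioma-like"  — elongated ellipse, upper-right,  hypo-intense

The labels are synthetic stand-ins coded by geometry and polarity, not
clinical claims.  The ground-truth mask is exact by construction, so a
perfect segmenter scores Tanimoto = Dice = 1 on a noise-free phantom.

Tissue texture is Gaussian around each mode mean; additive Gaussian pixel
noise is clipped to [0, 255].  With ``mode_sigma = noise_sigma = 0`` the
image takes exactly ``n_tissue_modes + 2`` distinct gray values
(background, tissues, tumor).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["PhantomSpec", "PhantomSample", "generate_phantom", "generate_dataset", "LABEL_NAMES"]

LABEL_NAMES = {0: "pituitary-like", 1: "glioma-like", 2: "meningioma-like"}

# class code -> (shape, location quadrant, intensity polarity)
_CLASS_RULES = {
    0: ("disc", "lower-central", "hyper"),
    1: ("lobed", "upper-left", "hyper"),
    2: ("ellipse", "upper-right", "hypo"),
}


@dataclass(frozen=True)
class PhantomSpec:
    """Generation parameters for one phantom.

    ``mode_means`` are the tissue gray-level means inside the brain ellipse.
    The tumor mean depends on the class: ``tumor_intensity`` (class 0,
    hyper), ``secondary_hyper_intensity`` (class 1, hyper) or
    ``hypo_intensity`` (class 2, hypo); each must sit at least
    ``contrast_margin`` gray levels from every tissue mean, and the three
    class levels are mutually separated by the same margin so the classes
    stay distinguishable by intensity alone.
    """

    image_side: int = 256
    n_tissue_modes: int = 3
    mode_means: tuple[float, ...] = (80.0, 120.0, 160.0)
    mode_sigma: float = 6.0
    tumor_intensity: float = 250.0
    secondary_hyper_intensity: float = 205.0
    hypo_intensity: float = 40.0
    tumor_radius_range: tuple[float, float] = (10.0, 16.0)
    tumor_shape: str = "disc"
    noise_sigma: float = 4.0
    contrast_margin: float = 40.0
    background_level: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.mode_means) != self.n_tissue_modes:
            raise ValueError("mode_means length must equal n_tissue_modes")
        class_levels = (
            self.tumor_intensity,
            self.secondary_hyper_intensity,
            self.hypo_intensity,
        )
        for mean in self.mode_means:
            for tum in class_levels:
                if abs(tum - mean) < self.contrast_margin:
                    raise ValueError(
                        f"tumor intensity {tum} within contrast_margin "
                        f"{self.contrast_margin} of tissue mean {mean}"
                    )
        for i, a in enumerate(class_levels):
            if not 0 <= a <= 255:
                raise ValueError("tumor intensities must fit the 8-bit gray range")
            for b in class_levels[i + 1 :]:
                if abs(a - b) < self.contrast_margin:
                    raise ValueError(
                        "class tumor intensities must be mutually separated "
                        f"by contrast_margin {self.contrast_margin}"
                    )
        if self.tumor_shape not in ("disc", "ellipse", "lobed"):
            raise ValueError(f"unknown tumor shape {self.tumor_shape!r}")


@dataclass(frozen=True)
class PhantomSample:
    image: np.ndarray  # uint8, (side, side)
    tumor_mask: np.ndarray  # uint8 0/1, ground truth
    label: int
    spec_used: PhantomSpec


def _brain_ellipse(side: int) -> np.ndarray:
    yy, xx = np.mgrid[0:side, 0:side]
    cy = cx = (side - 1) / 2
    ay, ax = 0.42 * side, 0.36 * side
    return ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0


def _tumor_center(label: int, side: int, rng: np.random.Generator) -> tuple[float, float]:
    # quadrant per class rule, jittered, kept well inside the brain ellipse
    jitter = lambda: rng.uniform(-0.05, 0.05) * side
    if label == 0:  # lower-central
        return 0.68 * side + jitter(), 0.50 * side + jitter()
    if label == 1:  # upper-left
        return 0.34 * side + jitter(), 0.36 * side + jitter()
    return 0.34 * side + jitter(), 0.64 * side + jitter()  # upper-right


def _tumor_mask(label: int, spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    side = spec.image_side
    shape = _CLASS_RULES[label][0]
    r = rng.uniform(*spec.tumor_radius_range)
    cy, cx = _tumor_center(label, side, rng)
    yy, xx = np.mgrid[0:side, 0:side]
    if shape == "disc":
        mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
    elif shape == "ellipse":
        theta = rng.uniform(0, np.pi)
        a, b = 1.4 * r, 0.7 * r
        dy, dx = yy - cy, xx - cx
        u = dy * np.cos(theta) + dx * np.sin(theta)
        v = -dy * np.sin(theta) + dx * np.cos(theta)
        mask = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    else:  # lobed: union of overlapping discs
        mask = np.zeros((side, side), dtype=bool)
        n_lobes = 3
        for _ in range(n_lobes):
            oy = cy + rng.uniform(-0.6, 0.6) * r
            ox = cx + rng.uniform(-0.6, 0.6) * r
            rr = rng.uniform(0.55, 0.8) * r
            mask |= (yy - oy) ** 2 + (xx - ox) ** 2 <= rr**2
    return mask & _brain_ellipse(side)


def generate_phantom(spec: PhantomSpec, label: int | None = None) -> PhantomSample:
    """Render one phantom; byte-identical for a fixed ``spec.seed``.

    When ``label`` is None it is drawn (seeded) uniformly from the three
    classes; the tumor's shape and polarity always follow the class rule,
    overriding ``spec.tumor_shape`` when a label is given or drawn.
    """
    rng = np.random.default_rng(spec.seed)
    side = spec.image_side
    if label is None:
        label = int(rng.integers(0, 3))
    shape, _, polarity = _CLASS_RULES[label]
    spec = replace(spec, tumor_shape=shape)

    brain = _brain_ellipse(side)
    img = np.full((side, side), spec.background_level, dtype=float)

    # concentric tissue bands: outer -> inner mode means
    yy, xx = np.mgrid[0:side, 0:side]
    cy = cx = (side - 1) / 2
    rho = np.sqrt(((yy - cy) / (0.42 * side)) ** 2 + ((xx - cx) / (0.36 * side)) ** 2)
    n_modes = spec.n_tissue_modes
    edges = np.linspace(1.0, 0.0, n_modes + 1)
    for k, mean in enumerate(spec.mode_means):
        band = brain & (rho <= edges[k]) & (rho > edges[k + 1] - (1e-9 if k == n_modes - 1 else 0))
        img[band] = mean
        if spec.mode_sigma > 0:
            img[band] += rng.normal(0.0, spec.mode_sigma, size=int(band.sum()))

    mask = _tumor_mask(label, spec, rng)
    if polarity == "hyper":
        tumor_level = spec.tumor_intensity if label == 0 else spec.secondary_hyper_intensity
    else:
        tumor_level = spec.hypo_intensity
    img[mask] = tumor_level
    if spec.mode_sigma > 0:
        img[mask] += rng.normal(0.0, spec.mode_sigma, size=int(mask.sum()))

    if spec.noise_sigma > 0:
        img += rng.normal(0.0, spec.noise_sigma, size=img.shape)
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return PhantomSample(
        image=img,
        tumor_mask=mask.astype(np.uint8),
        label=label,
        spec_used=spec,
    )


def generate_dataset(
    n_per_class: int, spec_template: PhantomSpec | None = None, seed: int = 0
) -> list[PhantomSample]:
    """Balanced, reproducible phantom dataset (``3 * n_per_class`` samples).

    Per-sample seeds are spawned from the master seed, so the dataset is
    identical across calls with the same arguments.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if spec_template is None:
        spec_template = PhantomSpec()
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(3 * n_per_class) % (2**31)
    samples = []
    i = 0
    for label in range(3):
        for _ in range(n_per_class):
            spec = replace(spec_template, seed=int(child_seeds[i]))
            samples.append(generate_phantom(spec, label=label))
            i += 1
    return samples
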