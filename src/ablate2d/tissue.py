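"""Tissue images: procedural LGE-like intensity fields, thresholding,
and the synthetic-augmentation operations.

Real late-gadolinium-enhancement (LGE) images are not shipped; smooth
Gaussian random fields with a stated correlation length stand in for
unfolded LGE intensity.  The field generator is calibrated so that
image-intensity-ratio (IIR) thresholding yields a requested fibrosis
burden.  Everything downstream (augmentation, simulation, labelling)
is agnostic to whether the intensities are real or procedural.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .geometry import DiskTemplate, PV_NAMES, GeometryError

logger = logging.getLogger(__name__)

VOID, HEALTHY, FIBROTIC = 0, 1, 2

# IIR (LGE intensity / mean blood-pool intensity) segmentation thresholds:
# ratio > 1.24 -> dense fibrosis; ratio < 1.08 -> healthy.  The
# intermediate band maps to healthy because downstream images are binary.
IIR_FIBROTIC = 1.24
IIR_HEALTHY = 1.08

DEFAULT_BLOOD_POOL_MEAN = 0.5


@dataclass
class IntensityImage:
    """Real-valued intensity field in [0, 1] on a disk template."""

    values: np.ndarray
    template: DiskTemplate

    def tissue_values(self) -> np.ndarray:
        return self.values[self.template.tissue_mask()]


@dataclass
class TissueImage:
    """Label grid over {VOID, HEALTHY, FIBROTIC} on a disk template."""

    labels: np.ndarray
    template: DiskTemplate
    id: str = ""
    origin: str = "base"   # "base" | "synthetic"

    def validate(self) -> None:
        tm = self.template.tissue_mask()
        if (self.labels[~tm] != VOID).any():
            raise ValueError("non-void labels outside the tissue mask")
        if (self.labels[tm] == VOID).any():
            raise ValueError("void labels inside the tissue mask")
        if not (self.labels == HEALTHY).any():
            raise ValueError("tissue has no healthy pixels")

    def fibrotic_fraction(self) -> float:
        tm = self.template.tissue_mask()
        n = int(tm.sum())
        return float((self.labels[tm] == FIBROTIC).sum()) / n if n else 0.0


def synth_base_intensity(
    template: DiskTemplate,
    seed: int,
    correlation_length: float = 7.5,
    burden: float = 0.2,
    blood_pool_mean: float = DEFAULT_BLOOD_POOL_MEAN,
    contrast: float = 0.25,
) -> IntensityImage:
    """Procedural stand-in for one unfolded LGE intensity image.

    White noise is smoothed by a Gaussian of ``correlation_length`` mm
    (patch scale of atrial fibrosis), standardised over tissue pixels,
    and mapped linearly so that exactly a ``burden`` fraction of tissue
    pixels exceeds the dense-fibrosis IIR cut for the given blood-pool
    mean.  ``contrast`` sets the intensity spread per unit z-score.
    Deterministic per seed; void pixels are set to 0.
    """
    if not 0.0 <= burden < 1.0:
        raise ValueError("burden must be in [0, 1)")
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(template.grid_shape)
    sigma_px = correlation_length / template.pixel_size
    smooth = ndimage.gaussian_filter(noise, sigma_px, mode="reflect")
    tm = template.tissue_mask()
    z = (smooth - smooth[tm].mean()) / smooth[tm].std()
    if burden == 0.0:
        cut = z[tm].max() + 1.0
    else:
        cut = np.quantile(z[tm], 1.0 - burden)
    values = IIR_FIBROTIC * blood_pool_mean + contrast * (z - cut)
    values = np.clip(values, 0.0, 1.0)
    values[~tm] = 0.0
    return IntensityImage(values=values, template=template)


def iir_threshold(intensity: IntensityImage,
                  blood_pool_mean: float = DEFAULT_BLOOD_POOL_MEAN,
                  tissue_id: str = "", origin: str = "base") -> TissueImage:
    """Segment an intensity image into healthy vs dense-fibrotic tissue.

    ratio = intensity / blood_pool_mean; strictly above 1.24 is
    fibrotic, everything else on tissue (including the 1.08-1.24
    intermediate band) is healthy; void is preserved.
    """
    if blood_pool_mean <= 0:
        raise ValueError("blood_pool_mean must be positive")
    tm = intensity.template.tissue_mask()
    ratio = intensity.values / blood_pool_mean
    labels = np.full(intensity.values.shape, VOID, dtype=np.uint8)
    labels[tm] = HEALTHY
    labels[tm & (ratio > IIR_FIBROTIC)] = FIBROTIC
    return TissueImage(labels=labels, template=intensity.template,
                       id=tissue_id, origin=origin)


def weighted_average(images: list[IntensityImage], seed: int,
                     weights: np.ndarray | None = None) -> IntensityImage:
    """Blend intensity images with independent uniform(0, 1) weights.

    Each image is multiplied by its weight and the sum is renormalised
    by its maximum over tissue pixels (keeping [0, 1]).  ``weights``
    overrides the random draw (used by tests and degenerate cases).
    """
    if len(images) < 2:
        raise ValueError("need at least two images to blend")
    template = images[0].template
    for img in images[1:]:
        if img.template is not template and img.template != template:
            raise ValueError("images must share a template")
    if weights is None:
        rng = np.random.default_rng(seed)
        weights = rng.uniform(0.0, 1.0, size=len(images))
    weights = np.asarray(weights, dtype=float)
    acc = np.zeros(template.grid_shape, dtype=float)
    for wgt, img in zip(weights, images):
        acc += wgt * img.values
    tm = template.tissue_mask()
    peak = acc[tm].max()
    if peak > 0:
        acc = acc / peak
    acc[~tm] = 0.0
    return IntensityImage(values=acc, template=template)


# ---------------------------------------------------------------------------
# Augmentation cases


@dataclass(frozen=True)
class AugmentationCase:
    """One of the 10 threshold/transform combinations.

    ``threshold`` is the fibrosis-extraction offset (see
    :func:`extract_fibrosis`); ``transforms`` is a tuple of
    ("flip_h"|"flip_v"|("rotate", deg)|("translate", dx_mm, dy_mm)).
    """

    case_id: int
    threshold: float
    transforms: tuple

    def __post_init__(self):
        if not 0.065 <= self.threshold <= 0.095:
            raise ValueError("threshold outside [0.065, 0.095]")
        if not self.transforms:
            raise ValueError("case needs at least one transform")


def default_cases() -> list[AugmentationCase]:
    """The default table of 10 augmentation cases.

    Thresholds are evenly spaced on [0.065, 0.095]; transforms cycle
    through flips, rotations, translations and their combinations.
    """
    thresholds = np.linspace(0.065, 0.095, 10)
    transform_table = [
        ("flip_h",),
        ("flip_v",),
        (("rotate", 90),),
        (("rotate", 180),),
        (("translate", 10.0, 0.0),),
        ("flip_h", ("rotate", 90)),
        ("flip_v", ("translate", 0.0, 10.0)),
        (("rotate", 180), ("translate", -10.0, 0.0)),
        ("flip_h", ("rotate", 90), ("translate", 0.0, -10.0)),
        (("rotate", 45),),
    ]
    return [AugmentationCase(i + 1, float(thresholds[i]), transform_table[i])
            for i in range(10)]


def extract_fibrosis(blend: IntensityImage, threshold: float,
                     blood_pool_mean: float = DEFAULT_BLOOD_POOL_MEAN) -> np.ndarray:
    """Binary fibrosis mask from a blended intensity image.

    The case threshold (0.065-0.095) is an absolute offset above the
    healthy IIR cut: fibrotic iff intensity > 1.08 * blood_pool_mean +
    threshold.  For the default blood pool (0.5) the cuts straddle the
    dense-fibrosis cut of :func:`iir_threshold`, so different cases
    erode or dilate the extracted pattern.
    """
    tm = blend.template.tissue_mask()
    return tm & (blend.values > IIR_HEALTHY * blood_pool_mean + threshold)


def _transform_mask(mask: np.ndarray, transforms, template: DiskTemplate,
                    scale: float = 1.0) -> np.ndarray:
    """Apply flips/rotations/translations to a binary pattern about the
    disk centre (nearest-neighbour, grid-aligned)."""
    out = mask.astype(np.uint8)
    ny, nx = out.shape
    for tr in transforms:
        if tr == "flip_h":
            out = out[:, ::-1]
        elif tr == "flip_v":
            out = out[::-1, :]
        elif tr[0] == "rotate":
            angle = float(tr[1])
            if angle % 90 == 0:
                out = np.rot90(out, k=int(angle // 90) % 4)
            else:
                out = ndimage.rotate(out, angle, reshape=False, order=0,
                                     mode="constant", cval=0)
        elif tr[0] == "translate":
            dx_px = int(round(scale * tr[1] / template.pixel_size))
            dy_px = int(round(scale * tr[2] / template.pixel_size))
            out = ndimage.shift(out, (dy_px, dx_px), order=0,
                                mode="constant", cval=0)
        else:
            raise ValueError(f"unknown transform {tr!r}")
    return out.astype(bool)


def augment_fibrosis(blend: IntensityImage, case: AugmentationCase, seed: int,
                     blood_pool_mean: float = DEFAULT_BLOOD_POOL_MEAN,
                     tissue_id: str = "", ) -> TissueImage:
    """Threshold a blended image and transform its fibrosis pattern.

    The void geometry is untouched: transforms move only the fibrosis
    pattern, which is then clipped back onto the template's tissue
    mask.  If a translation pushes all fibrosis off the tissue, it is
    retried at half amplitude, then dropped with a warning.
    """
    mask = extract_fibrosis(blend, case.threshold, blood_pool_mean)
    template = blend.template
    tm = template.tissue_mask()
    had_fibrosis = bool(mask.any())
    moved = _transform_mask(mask, case.transforms, template) & tm
    if had_fibrosis and not moved.any():
        moved = _transform_mask(mask, case.transforms, template, scale=0.5) & tm
        if not moved.any():
            logger.warning("case %d pushed all fibrosis off tissue; kept "
                           "untransformed pattern", case.case_id)
            moved = mask & tm
    labels = np.full(mask.shape, VOID, dtype=np.uint8)
    labels[tm] = HEALTHY
    labels[moved] = FIBROTIC
    return TissueImage(labels=labels, template=template, id=tissue_id,
                       origin="synthetic")


# ---------------------------------------------------------------------------
# PV variants


@dataclass(frozen=True)
class PVVariant:
    """How PV size (and, for variants 4-6, position) is randomised.

    Variants 1/4: one common size factor for all four PVs; 2/5: one per
    left pair and one per right pair; 3/6: four independent factors.
    Variants 4-6 additionally shift each PV randomly in x and y.
    """

    variant_id: int

    def __post_init__(self):
        if self.variant_id not in range(1, 7):
            raise ValueError("variant_id must be 1..6")

    @property
    def varies_position(self) -> bool:
        return self.variant_id >= 4

    @property
    def size_grouping(self) -> str:
        return {1: "all", 2: "pairs", 3: "independent"}[(self.variant_id - 1) % 3 + 1]


_PAIRS = {"left": ("LSPV", "LIPV"), "right": ("RSPV", "RIPV")}


def _size_factors(variant: PVVariant, rng: np.random.Generator) -> dict[str, float]:
    def draw():
        magnitude = rng.uniform(0.05, 0.50)   # 5-50% diameter change
        sign = rng.choice([-1.0, 1.0])
        return 1.0 + sign * magnitude

    grouping = variant.size_grouping
    if grouping == "all":
        f = draw()
        return {name: f for name in PV_NAMES}
    if grouping == "pairs":
        f_left, f_right = draw(), draw()
        return {"LSPV": f_left, "LIPV": f_left, "RSPV": f_right, "RIPV": f_right}
    return {name: draw() for name in PV_NAMES}


def vary_pvs(template: DiskTemplate, variant: PVVariant, seed: int,
             max_shift: float = 10.0, max_tries: int = 40) -> DiskTemplate:
    """Resize (and for variants 4-6 reposition) the PV openings.

    Size factors scale each PV diameter by 5-50% up or down according
    to the variant's grouping rule.  Shifts are uniform in
    [-max_shift, max_shift] mm per axis and are resampled (with
    shrinking amplitude) until the openings stay inside the disk and
    pairwise disjoint.  Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    for attempt in range(max_tries):
        shrink = 0.5 ** (attempt // 10)   # back off every 10 failures
        factors = _size_factors(variant, rng)
        radii = {name: template.pv_radii[name] * factors[name]
                 for name in PV_NAMES}
        centres = None
        if variant.varies_position:
            centres = {}
            for name in PV_NAMES:
                x0, y0 = template.pv_centres[name]
                centres[name] = (
                    x0 + rng.uniform(-max_shift, max_shift) * shrink,
                    y0 + rng.uniform(-max_shift, max_shift) * shrink,
                )
        try:
            return template.with_openings(pv_centres=centres, pv_radii=radii)
        except GeometryError:
            continue
    logger.warning("variant %d: no collision-free draw found; keeping the "
                   "original openings", variant.variant_id)
    return template
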