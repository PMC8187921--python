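"""Cohort generation: base stand-in tissues plus synthetic augmentation.

Mirrors the three-stage augmentation recipe: (1) weighted averaging of
the base intensity images with fresh uniform(0,1) weights, (2) fibrosis
extraction/thresholding followed by affine transforms drawn from a
table of ten cases, (3) pulmonary-vein size/position variation applied
to half of the synthetic tissues via one of six variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .geometry import DiskTemplate, make_disk_template
from .tissue import (
    AugmentationCase, IntensityImage, PVVariant, TissueImage,
    augment_fibrosis, default_cases, iir_threshold, synth_base_intensity,
    vary_pvs, weighted_average, VOID, HEALTHY, FIBROTIC,
)

# palette per the unfolded-LA convention: white healthy, red fibrotic, grey void
PALETTE = {VOID: (128, 128, 128), HEALTHY: (255, 255, 255), FIBROTIC: (220, 30, 30)}


@dataclass
class CohortConfig:
    """Counts and generation parameters for one cohort."""

    n_base: int = 122
    n_synthetic: int = 157
    seed: int = 0
    burden_range: tuple[float, float] = (0.05, 0.35)
    correlation_length: float = 7.5
    blend_pool: int = 65          # how many base images each blend draws from
    template: DiskTemplate | None = None

    def __post_init__(self):
        if self.n_base < 1 or self.n_synthetic < 1:
            raise ValueError("n_base and n_synthetic must be >= 1")


def generate_cohort(config: CohortConfig) -> tuple[list[TissueImage], pd.DataFrame]:
    """Generate base + synthetic tissues and a provenance manifest.

    Base tissues: procedural intensity fields thresholded by IIR.
    Synthetic tissues: weighted average of a random subset of base
    intensities -> fibrosis augmentation with a random case -> PV
    variation on a seeded random half (floor(n/2)) of the synthetic
    set.  Deterministic per config seed; manifest rows record ids,
    per-tissue seeds, case and variant ids.
    """
    rng = np.random.default_rng(config.seed)
    template = config.template or make_disk_template()
    cases = default_cases()
    rows = []
    tissues: list[TissueImage] = []
    base_intensities: list[IntensityImage] = []

    for i in range(config.n_base):
        seed_i = int(rng.integers(0, 2**31 - 1))
        burden = float(rng.uniform(*config.burden_range))
        intensity = synth_base_intensity(
            template, seed_i, config.correlation_length, burden)
        base_intensities.append(intensity)
        tid = f"base{i:03d}"
        tissue = iir_threshold(intensity, tissue_id=tid, origin="base")
        tissues.append(tissue)
        rows.append(dict(id=tid, origin="base", seed=seed_i, burden=burden,
                         case_id=-1, variant_id=-1))

    n_syn = config.n_synthetic
    pv_varied = np.zeros(n_syn, dtype=bool)
    order = rng.permutation(n_syn)
    pv_varied[order[: n_syn // 2]] = True   # exactly floor(n/2) PV-varied

    pool = min(config.blend_pool, len(base_intensities))
    for i in range(n_syn):
        seed_i = int(rng.integers(0, 2**31 - 1))
        subset_idx = rng.choice(len(base_intensities), size=pool, replace=False) \
            if pool >= 2 else np.arange(len(base_intensities))
        subset = [base_intensities[j] for j in subset_idx]
        blend = weighted_average(subset, seed=seed_i) if len(subset) >= 2 \
            else subset[0]
        case = cases[int(rng.integers(0, len(cases)))]
        tid = f"syn{i:03d}"
        tissue = augment_fibrosis(blend, case, seed=seed_i, tissue_id=tid)
        variant_id = -1
        if pv_varied[i]:
            variant = PVVariant(int(rng.integers(1, 7)))
            variant_id = variant.variant_id
            new_template = vary_pvs(template, variant, seed=seed_i)
            tissue = _rebase_on_template(tissue, new_template, tid)
        tissues.append(tissue)
        rows.append(dict(id=tid, origin="synthetic", seed=seed_i,
                         burden=np.nan, case_id=case.case_id,
                         variant_id=variant_id))

    manifest = pd.DataFrame(rows)
    return tissues, manifest


def _rebase_on_template(tissue: TissueImage, template: DiskTemplate,
                        tissue_id: str) -> TissueImage:
    """Re-impose a new template's void geometry on an existing label grid."""
    tm = template.tissue_mask()
    labels = np.full(tissue.labels.shape, VOID, dtype=np.uint8)
    labels[tm] = HEALTHY
    fib = (tissue.labels == FIBROTIC) & tm
    labels[fib] = FIBROTIC
    return TissueImage(labels=labels, template=template, id=tissue_id,
                       origin="synthetic")


def export_png(tissue: TissueImage, path) -> None:
    """Palette PNG (white healthy / red fibrotic / grey void), lossless."""
    img = Image.fromarray(tissue.labels, mode="P")
    palette = [0] * 768
    for value, rgb in PALETTE.items():
        palette[3 * value: 3 * value + 3] = rgb
    img.putpalette(palette)
    img.save(path, format="PNG")


def load_png(path, template: DiskTemplate, tissue_id: str = "",
             origin: str = "base") -> TissueImage:
    """Read a palette PNG written by :func:`export_png`."""
    labels = np.asarray(Image.open(path), dtype=np.uint8)
    return TissueImage(labels=labels, template=template, id=tissue_id,
                       origin=origin)


def export_cohort(tissues: list[TissueImage], manifest: pd.DataFrame,
                  out_dir) -> None:
    """Write PNGs, lossless label arrays (npz) and the manifest CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for tissue in tissues:
        export_png(tissue, out / f"{tissue.id}.png")
    np.savez_compressed(out / "labels.npz",
                        **{t.id: t.labels for t in tissues})
    manifest.to_csv(out / "manifest.csv", index=False)
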