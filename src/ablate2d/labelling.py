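"""Ground-truth labels, dataset assembly and cross-validation splits.

A tissue's label is the catheter-ablation class to use on it, derived
from the simulated outcomes by one of two rules: *minimum percentage*
(the successful class with the least ablated tissue) or *class
availability* (prefer the rarest classes: PVI over Fibro over Rotor).
Tissues with no successful strategy are discarded.

For the combined A+B scenario the dataset is doubled: each tissue's
original image carries its Scenario A label and a binary-inverted copy
(healthy and fibrotic swapped, void untouched) carries its Scenario B
label, so the network never sees one image with two labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .tissue import TissueImage, VOID, HEALTHY, FIBROTIC

CLASSES = ("PVI", "FIBRO", "ROTOR")
# class-availability priority: prefer the scarcest class
PRIORITY = ("PVI", "FIBRO", "ROTOR")
DISCARDED = "DISCARDED"


@dataclass(frozen=True)
class LabelRecord:
    """Label decision for one (tissue, scenario)."""

    tissue_id: str
    scenario: str
    successful: dict             # class -> ablated percent (successful only)
    label: str                   # one of CLASSES or DISCARDED
    method: str                  # "min_percentage" | "class_availability"

    @property
    def discarded(self) -> bool:
        return self.label == DISCARDED


def label_min_percentage(successes: dict) -> str:
    """Successful class with the minimum ablated percentage.

    Ties go to the scarcer class (PVI > FIBRO > ROTOR priority); no
    successful class -> DISCARDED.
    """
    if not successes:
        return DISCARDED
    best = min(successes.values())
    for cls in PRIORITY:
        if cls in successes and successes[cls] == best:
            return cls
    raise ValueError(f"unknown classes in {successes}")


def label_class_availability(successes) -> str:
    """First successful class in scarcity order PVI > FIBRO > ROTOR."""
    present = set(successes)
    for cls in PRIORITY:
        if cls in present:
            return cls
    return DISCARDED


def make_label_record(tissue_id: str, scenario: str, successes: dict,
                      method: str) -> LabelRecord:
    if method == "min_percentage":
        label = label_min_percentage(successes)
    elif method == "class_availability":
        label = label_class_availability(successes)
    else:
        raise ValueError(f"unknown labelling method {method!r}")
    return LabelRecord(tissue_id=tissue_id, scenario=scenario,
                       successful=dict(successes), label=label, method=method)


def invert_labels(labels: np.ndarray) -> np.ndarray:
    """Binary inversion of a tissue image: healthy <-> fibrotic, void kept.

    Void is anatomy (background and openings), not signal, so it is
    left unchanged; the operation is an involution.
    """
    out = labels.copy()
    out[labels == HEALTHY] = FIBROTIC
    out[labels == FIBROTIC] = HEALTHY
    return out


@dataclass
class LabelledSample:
    """One CNN training sample: an image with its strategy label."""

    tissue_id: str
    scenario: str
    image: np.ndarray            # uint8 label grid (possibly inverted)
    label: str                   # one of CLASSES
    origin: str = "base"
    inverted: bool = False


def assemble_dataset(records: list[LabelRecord],
                     tissues: dict[str, TissueImage],
                     mode: str = "A+B") -> list[LabelledSample]:
    """Pair images with scenario labels; discarded records are dropped.

    mode "A" or "B": images with that scenario's labels.  Mode "A+B":
    original images with A labels plus inverted images with B labels.
    """
    mode = mode.upper()
    if mode not in ("A", "B", "A+B"):
        raise ValueError(f"unknown mode {mode!r}")
    samples: list[LabelledSample] = []
    for rec in records:
        if rec.discarded:
            continue
        if mode in ("A", "B") and rec.scenario != mode:
            continue
        tissue = tissues[rec.tissue_id]
        invert = mode == "A+B" and rec.scenario == "B"
        image = invert_labels(tissue.labels) if invert else tissue.labels.copy()
        samples.append(LabelledSample(
            tissue_id=rec.tissue_id, scenario=rec.scenario, image=image,
            label=rec.label, origin=tissue.origin, inverted=invert))
    return samples


@dataclass
class DatasetSplit:
    """Stratified k-fold CV folds plus a fixed holdout test set.

    Indices refer to the sample list passed to :func:`make_splits`;
    holdout samples are excluded from every fold.
    """

    folds: list[tuple[np.ndarray, np.ndarray]]   # (train_idx, val_idx)
    holdout: np.ndarray

    def n_folds(self) -> int:
        return len(self.folds)


def default_holdout(samples: list[LabelledSample], seed: int,
                    fraction: float = 0.1) -> list[str]:
    """Pick ~``fraction`` of tissue ids for holdout, stratified by origin."""
    rng = np.random.default_rng(seed)
    ids_by_origin: dict[str, list[str]] = {}
    for s in samples:
        ids_by_origin.setdefault(s.origin, [])
        if s.tissue_id not in ids_by_origin[s.origin]:
            ids_by_origin[s.origin].append(s.tissue_id)
    chosen: list[str] = []
    for origin in sorted(ids_by_origin):
        ids = sorted(ids_by_origin[origin])
        n = max(1, int(round(fraction * len(ids))))
        chosen.extend(rng.choice(ids, size=min(n, len(ids)), replace=False))
    return chosen


def make_splits(samples: list[LabelledSample], holdout_ids, k: int = 5,
                seed: int = 0) -> DatasetSplit:
    """Remove the holdout, then seeded stratified k-fold (80/20 at k=5)."""
    holdout_ids = set(holdout_ids)
    sample_ids = {s.tissue_id for s in samples}
    missing = holdout_ids - sample_ids
    if missing:
        raise ValueError(f"holdout ids not in dataset: {sorted(missing)}")
    holdout_idx = np.array([i for i, s in enumerate(samples)
                            if s.tissue_id in holdout_ids], dtype=int)
    keep_idx = np.array([i for i, s in enumerate(samples)
                         if s.tissue_id not in holdout_ids], dtype=int)
    labels = np.array([samples[i].label for i in keep_idx])
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = [(keep_idx[tr], keep_idx[va])
             for tr, va in skf.split(np.zeros(len(keep_idx)), labels)]
    return DatasetSplit(folds=folds, holdout=holdout_idx)
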