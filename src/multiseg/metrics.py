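"""Comparison of segmentations: difference maps, volumes, Dice, leak rates.

The methodology mirrors how multimodal and unimodal segmentations are
compared in practice: average the tissue probability maps over replicates,
subtract (configuration B minus A), integrate per-class probability mass into
compartment volumes in ml, and — on phantoms with ground truth — score
accuracy (Dice) and confound "leak" (the probability mass a confound
structure receives in the gray-matter map).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy.ndimage import binary_dilation

from .mixture import TissueProbabilityMaps
from .phantom import PhantomTruth
from .volumes import Volume, check_grid


def average_maps(maps_list: list[TissueProbabilityMaps]) -> TissueProbabilityMaps:
    """Voxel-wise mean of matched tissue probability maps."""
    if len(maps_list) < 1:
        raise ValueError("need at least one TissueProbabilityMaps")
    ref = maps_list[0]
    for other in maps_list[1:]:
        if other.class_names != ref.class_names:
            raise ValueError("class rosters differ")
        check_grid(ref.grid, other.grid)
    out = []
    for ci in range(len(ref.class_names)):
        mean = np.mean([m.maps[ci].data for m in maps_list], axis=0)
        out.append(ref.grid.like(mean))
    return TissueProbabilityMaps(out, list(ref.class_names))


@dataclass
class ComparisonResult:
    """Per-class difference maps (B − A) and integrated volume deltas (ml)."""

    difference: dict[str, Volume]
    volume_delta_ml: dict[str, float]
    label_a: str = "A"
    label_b: str = "B"
    extra: dict = field(default_factory=dict)


def tpm_difference(
    a: TissueProbabilityMaps,
    b: TissueProbabilityMaps,
    label_a: str = "A",
    label_b: str = "B",
) -> ComparisonResult:
    """Difference of tissue probability maps, b − a, with ml bookkeeping."""
    if a.class_names != b.class_names:
        raise ValueError("class rosters differ")
    check_grid(a.grid, b.grid)
    vox_ml = a.grid.voxel_volume_mm3 / 1000.0
    diff = {}
    deltas = {}
    for name in a.class_names:
        d = b.get(name).data - a.get(name).data
        diff[name] = a.grid.like(d)
        deltas[name] = float(d.sum() * vox_ml)
    return ComparisonResult(diff, deltas, label_a, label_b)


def compartment_volume(
    maps: TissueProbabilityMaps, class_name: str, mask: Volume | None = None
) -> float:
    """Soft compartment volume in ml: sum of posteriors × voxel volume."""
    if class_name not in maps.class_names:
        raise KeyError(f"unknown class {class_name!r}")
    data = maps.get(class_name).data
    if mask is not None:
        check_grid(maps.grid, mask)
        data = data * mask.data.astype(bool)
    return float(data.sum() * maps.grid.voxel_volume_mm3 / 1000.0)


def dice_masks(pred: np.ndarray, truth: np.ndarray) -> float:
    """Dice = 2|P∩T| / (|P|+|T|) for two boolean arrays."""
    pred = pred.astype(bool)
    truth = truth.astype(bool)
    denom = pred.sum() + truth.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(pred, truth).sum() / denom)


def dice(
    maps: TissueProbabilityMaps,
    truth: PhantomTruth,
    class_name: str,
    threshold: float = 0.5,
) -> float:
    """Dice of the thresholded posterior against the ground-truth class."""
    if not (0 < threshold < 1):
        raise ValueError("threshold must be in (0, 1)")
    t = truth.class_mask(class_name).data.astype(bool)
    if not t.any():
        raise ValueError(f"truth has no {class_name} voxels")
    p = maps.get(class_name).data > threshold
    return dice_masks(p, t)


class LeakRate(NamedTuple):
    """Confound leak into a tissue map: thresholded rate and mean posterior."""

    rate: float
    mean_posterior: float
    n_voxels: int


def leak_rate(
    gm_map: Volume, confound_mask: Volume, threshold: float = 0.5
) -> LeakRate:
    """Fraction of confound voxels whose GM posterior exceeds ``threshold``.

    The mean posterior over the mask is reported alongside, since overlay
    figures in practice show the continuous probability rather than a hard
    cutoff.
    """
    check_grid(gm_map, confound_mask)
    m = confound_mask.data.astype(bool)
    n = int(m.sum())
    if n == 0:
        raise ValueError("empty confound mask")
    vals = gm_map.data[m]
    return LeakRate(
        rate=float(np.mean(vals > threshold)),
        mean_posterior=float(vals.mean()),
        n_voxels=n,
    )


def negative_mass_fraction_on_labels(
    diff: Volume, label_mask: Volume, dilate: int = 1
) -> float:
    """Share of a difference map's negative mass lying on given labels.

    The label mask may be dilated by ``dilate`` voxels to absorb boundary
    discretisation.  Returns 1.0 when there is no negative mass at all.
    """
    check_grid(diff, label_mask)
    neg = np.clip(-diff.data, 0.0, None)
    total = neg.sum()
    if total == 0:
        return 1.0
    m = label_mask.data.astype(bool)
    if dilate > 0:
        m = binary_dilation(m, iterations=dilate)
    return float(neg[m].sum() / total)


def replicate_volume_deltas(
    results: list[ComparisonResult], class_name: str
) -> tuple[float, float]:
    """Mean ± SD of a class's volume delta across phantom replicates (ml)."""
    vals = np.array([r.volume_delta_ml[class_name] for r in results])
    return float(vals.mean()), float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
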