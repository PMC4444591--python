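"""Cell-viability quantification from dual nuclear staining.

Viability is the percentage ratio between dead cells (propidium-iodide
positive nuclei) and all cells (bisBenzimide / Hoechst positive nuclei).
Nuclei are counted as connected components above an intensity threshold;
counts may also be supplied directly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from skimage import measure
from skimage.filters import threshold_otsu


@dataclass
class ViabilityCounts:
    """Dead (PI-positive) and total (bisBenzimide-positive) nucleus counts."""

    n_dead: int
    n_total: int

    def __post_init__(self):
        if not (0 <= self.n_dead <= self.n_total):
            raise ValueError("need 0 <= n_dead <= n_total")


def count_nuclei(image, min_area: int = 5, threshold="otsu") -> int:
    """Count stained nuclei as thresholded connected components.

    ``threshold`` is either ``"otsu"`` or a fixed intensity value.  Components
    smaller than ``min_area`` pixels are discarded as noise.  Touching nuclei
    merged by the threshold count as one component — a documented limitation
    of this simple auditable method (no watershed splitting).
    """
    img = np.asarray(image)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("image must be a non-empty 2-D array")
    if threshold == "otsu":
        if np.ptp(img) == 0:
            return 0  # constant image: nothing to segment
        thr = threshold_otsu(img)
    else:
        thr = float(threshold)
    fg = img > thr
    labels = measure.label(fg, connectivity=2)
    if labels.max() == 0:
        return 0
    areas = np.bincount(labels.ravel())[1:]
    return int(np.sum(areas >= min_area))


def viability_ratio(counts: ViabilityCounts) -> float:
    """Dead-cell percentage: ``100 * n_dead / n_total``."""
    if counts.n_total == 0:
        raise ValueError("n_total must be positive")
    return 100.0 * counts.n_dead / counts.n_total


def analyze_viability_image(
    image, min_area: int = 5, threshold="otsu"
) -> dict:
    """Count nuclei in a (2, h, w) image: channel 0 = all cells, 1 = dead.

    With ``threshold="otsu"`` the threshold is learned on the total-stain
    channel (reliably bimodal: background vs nuclei) and reused for the
    dead-stain channel, which may contain no nuclei at all — Otsu on such a
    unimodal background image would split the noise into spurious objects.
    Both stains are imaged on the same intensity scale, so one threshold
    serves both.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[0] != 2:
        raise ValueError("expected a two-channel image of shape (2, h, w)")
    if threshold == "otsu" and np.ptp(image[0]) > 0:
        threshold = float(threshold_otsu(image[0]))
    n_total = count_nuclei(image[0], min_area=min_area, threshold=threshold)
    n_dead = count_nuclei(image[1], min_area=min_area, threshold=threshold)
    n_dead = min(n_dead, n_total)
    counts = ViabilityCounts(n_dead=n_dead, n_total=n_total)
    return {
        "n_dead": counts.n_dead,
        "n_total": counts.n_total,
        "percent_dead": viability_ratio(counts) if n_total else None,
    }


def save_viability(result: dict, path) -> None:
    with open(path, "w") as f:
        json.dump(result, f, indent=2)
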