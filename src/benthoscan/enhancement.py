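"""Three-step visibility improvement for deep-sea photo collections.

Artificial lighting through water leaves seafloor photographs with a
greenish haze, low contrast, a radial intensity drop-off towards the edges
(vignetting) and uneven scene brightness. The workflow here addresses each
in turn, on chronologically sorted batches of images:

1. batch z-score normalisation — per-pixel, per-channel statistics across
   the batch remove static spatial patterns (vignette) and the shared colour
   cast;
2. contrast-limited adaptive histogram equalisation (CLAHE) on local tiles
   restores contrast;
3. histogram matching to a manually chosen reference image equalises scene
   brightness across the collection.

Batches are small (default 32 images) because altitude — and hence the
degradation pattern — is roughly constant over short track distances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import exposure


@dataclass
class EnhancementConfig:
    batch_size: int = 32
    tile_grid: tuple = (8, 8)
    clip_fraction: float = 0.01
    reference_image_id: str | None = None
    epsilon: float = 1e-6

    def __post_init__(self):
        if self.batch_size < 2:
            raise ValueError("batch_size must be >= 2")
        if self.tile_grid[0] < 2 or self.tile_grid[1] < 2:
            raise ValueError("tile_grid must be at least (2, 2)")
        if not 0.0 < self.clip_fraction <= 1.0:
            raise ValueError("clip_fraction must be in (0, 1]")


def batch_zscore(batch, epsilon: float = 1e-6) -> list:
    """Z-score a batch of images with per-pixel statistics across the batch.

    For each pixel and channel, the mean and standard deviation are computed
    over the batch; z = (x - mean) / (sd + epsilon) is then affinely mapped
    from [-3, 3] to [0, 1] with clipping. Patterns shared by every image in
    the batch (vignette, colour cast) cancel exactly; a zero-variance batch
    maps to constant mid-grey.
    """
    if len(batch) < 2:
        raise ValueError("batch must contain at least 2 images")
    shapes = {np.asarray(b).shape for b in batch}
    if len(shapes) != 1:
        raise ValueError(f"images in a batch must share dimensions, got {shapes}")
    stack = np.stack([np.asarray(b, dtype=float) for b in batch])
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0)
    z = (stack - mean) / (sd + epsilon)
    rescaled = np.clip((z + 3.0) / 6.0, 0.0, 1.0)
    return [rescaled[i] for i in range(len(batch))]


def adaptive_hist_eq(image: np.ndarray, config: EnhancementConfig | None = None) -> np.ndarray:
    """Contrast-limited adaptive histogram equalisation on local tiles.

    Tile mappings are bilinearly interpolated (scikit-image CLAHE); colour
    images are equalised channel-wise. Output stays in [0, 1].
    """
    config = config or EnhancementConfig()
    image = np.asarray(image, dtype=float)
    rows, cols = config.tile_grid
    h, w = image.shape[:2]
    if h < rows or w < cols:
        raise ValueError("tile grid larger than image")
    kernel = (max(h // rows, 1), max(w // cols, 1))
    if image.ndim == 2:
        if image.std() == 0:  # constant image: nothing to equalise
            return image.copy()
        return exposure.equalize_adapthist(image, kernel_size=kernel, clip_limit=config.clip_fraction)
    out = np.empty_like(image)
    for c in range(image.shape[2]):
        chan = image[..., c]
        if chan.std() == 0:
            out[..., c] = chan
        else:
            out[..., c] = exposure.equalize_adapthist(chan, kernel_size=kernel, clip_limit=config.clip_fraction)
    return out


def histogram_match(image: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Monotone quantile mapping of each channel onto the reference CDF."""
    image = np.asarray(image, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if reference.size == 0:
        raise ValueError("reference image is empty")
    if image.ndim != reference.ndim:
        raise ValueError("image and reference must have the same channel count")
    if image.ndim == 3 and image.shape[2] != reference.shape[2]:
        raise ValueError("image and reference must have the same channel count")
    kwargs = {"channel_axis": -1} if image.ndim == 3 else {}
    return exposure.match_histograms(image, reference, **kwargs)


def batch_indices(n: int, batch_size: int) -> list:
    """Consecutive batch slices; a trailing batch of <2 merges into the previous."""
    if n < 2:
        raise ValueError("need at least 2 images")
    edges = list(range(0, n, batch_size)) + [n]
    if len(edges) > 2 and edges[-1] - edges[-2] < 2:
        edges.pop(-2)
    return [slice(a, b) for a, b in zip(edges[:-1], edges[1:])]


def enhance_collection(records, images, config: EnhancementConfig | None = None) -> list:
    """Run the full three-step workflow over a chronologically sorted collection.

    ``records`` must be sorted by timestamp (grouping is purely positional:
    consecutive batches of ``batch_size``). The reference for histogram
    matching is the post-CLAHE version of ``config.reference_image_id``
    (first image if unset). Output order matches input order.
    """
    config = config or EnhancementConfig()
    ids = list(records["image_id"]) if hasattr(records, "columns") else list(records)
    if hasattr(records, "columns"):
        ts = records["timestamp_s"].to_numpy()
        by_dive = records.groupby("dive_id", sort=False)["timestamp_s"]
        if any((np.diff(g.to_numpy()) < 0).any() for _, g in by_dive):
            raise ValueError("records must be sorted by timestamp within dives")
    if len(images) != len(ids):
        raise ValueError("records and images length mismatch")
    equalised: list = [None] * len(ids)
    for sl in batch_indices(len(ids), config.batch_size):
        z = batch_zscore([images[i] for i in range(sl.start, sl.stop)], config.epsilon)
        for offset, img in enumerate(z):
            equalised[sl.start + offset] = adaptive_hist_eq(img, config)
    ref_idx = ids.index(config.reference_image_id) if config.reference_image_id else 0
    reference = equalised[ref_idx]
    return [histogram_match(img, reference) for img in equalised]
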