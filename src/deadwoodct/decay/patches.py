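"""Patch extraction, overlap-tile recombination and threshold selection.

Decay prediction operates on 48 x 48 pixel patches extracted with a 12-pixel
offset between neighboring patches, i.e. each patch shares 75% of its pixels
with its row/column neighbor. Per-patch probability maps are recombined into
a full slice by distance-from-center cosine weighting: every pixel's value is
the weighted average of all patch predictions covering it, which suppresses
the less reliable patch borders. The binarization threshold is chosen to
maximize the F1 score on a validation set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from ..ctvolume import NormalizedVolume, ParameterError

DEFAULT_PATCH_SIZE = 48
DEFAULT_STRIDE = 12


@dataclass(frozen=True)
class PatchGrid:
    """Anchor positions of overlapping patches covering one slice."""

    patch_size: int
    stride: int
    rows: tuple[int, ...]
    cols: tuple[int, ...]

    @property
    def positions(self) -> list[tuple[int, int]]:
        return [(r, c) for r in self.rows for c in self.cols]

    def __len__(self) -> int:
        return len(self.rows) * len(self.cols)


def _axis_anchors(dim: int, patch_size: int, stride: int) -> tuple[int, ...]:
    anchors = list(range(0, dim - patch_size + 1, stride))
    last = dim - patch_size
    if anchors[-1] != last:
        anchors.append(last)  # clamp the final patch to the border
    return tuple(anchors)


def build_patch_grid(
    slice_shape: tuple[int, int],
    patch_size: int = DEFAULT_PATCH_SIZE,
    stride: int = DEFAULT_STRIDE,
) -> PatchGrid:
    """Regular anchors at stride multiples, plus border-clamped final anchors.

    Every pixel of the slice is covered by at least one patch; edge patches
    end exactly at the image border (no padding, no fabricated context).
    """
    if not 0 < stride <= patch_size:
        raise ParameterError("need 0 < stride <= patch_size")
    h, w = slice_shape
    if patch_size > h or patch_size > w:
        raise ParameterError(f"patch size {patch_size} exceeds slice shape {slice_shape}")
    return PatchGrid(
        patch_size=patch_size,
        stride=stride,
        rows=_axis_anchors(h, patch_size, stride),
        cols=_axis_anchors(w, patch_size, stride),
    )


def overlap_percent(patch_size: int, stride: int) -> float:
    """Percent of a patch's pixels shared with its row/column neighbor.

    48 px patches at a 12 px offset share 75% of their pixels.
    """
    if stride > patch_size or stride <= 0:
        raise ParameterError("need 0 < stride <= patch_size")
    return 100.0 * (patch_size - stride) / patch_size


def cosine_weight_window(patch_size: int, floor: float = 1e-3) -> np.ndarray:
    """Center-peaked radial raised-cosine weight map for patch recombination.

    ``w(p) = cos(pi * d(p) / D) + 1`` with ``d`` the Euclidean distance from
    the patch center and ``D`` the corner distance, rescaled so the center
    has weight 1. The raw cosine vanishes exactly at the corners, so the map
    is floored at a small positive value: recombination renormalizes per
    pixel, hence any strictly positive center-peaked window is valid.
    """
    if patch_size < 2:
        raise ParameterError("patch_size must be >= 2")
    c = (patch_size - 1) / 2
    idx = np.arange(patch_size) - c
    d = np.hypot(idx[:, None], idx[None, :])
    w = (np.cos(np.pi * d / d.max()) + 1.0) / 2.0
    return np.maximum(w, floor)


def predict_slice(
    model,
    image: np.ndarray,
    grid: PatchGrid | None = None,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Overlap-tile prediction: weighted average of patch predictions per pixel.

    ``model`` maps a batch of patches ``(n, s, s)`` to probabilities of the
    same shape (see :class:`~deadwoodct.decay.model.DecayModel`). The output
    at pixel p is ``sum_k w(p) pred_k(p) / sum_k w(p)`` over the patches k
    covering p; the weight map cancels for a constant predictor.
    """
    if grid is None:
        grid = build_patch_grid(image.shape)
    s = grid.patch_size
    if image.shape[0] < s or image.shape[1] < s:
        raise ParameterError("slice smaller than the patch size")
    if weights is None:
        weights = cosine_weight_window(s)
    patches = np.stack([image[r : r + s, c : c + s] for r, c in grid.positions])
    preds = model.predict(patches)
    num = np.zeros(image.shape, dtype=np.float64)
    den = np.zeros(image.shape, dtype=np.float64)
    for (r, c), pred in zip(grid.positions, preds):
        num[r : r + s, c : c + s] += weights * pred
        den[r : r + s, c : c + s] += weights
    return (num / den).astype(np.float32)


@dataclass
class ProbabilityVolume:
    """Per-voxel decay probability in [0, 1] with provenance."""

    values: np.ndarray
    pixel_spacing: tuple[float, float]
    slice_thickness: float
    model_digest: str = ""
    weighting: str = "cosine"

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


def predict_volume(
    model,
    vol: NormalizedVolume,
    patch_size: int = DEFAULT_PATCH_SIZE,
    stride: int = DEFAULT_STRIDE,
) -> ProbabilityVolume:
    """Slice-wise overlap-tile prediction over a whole normalized volume."""
    grid = build_patch_grid(vol.shape[1:], patch_size, stride)
    weights = cosine_weight_window(patch_size)
    prob = np.stack([predict_slice(model, sl, grid, weights) for sl in vol.values])
    return ProbabilityVolume(
        values=prob,
        pixel_spacing=vol.pixel_spacing,
        slice_thickness=vol.slice_thickness,
        model_digest=getattr(model, "digest", ""),
    )


@dataclass(frozen=True)
class BinarizationThreshold:
    """F1-optimal probability cutoff and the F1 it achieved on selection data."""

    threshold: float
    f1: float

    def __post_init__(self) -> None:
        if not 0 < self.threshold < 1:
            raise ParameterError("threshold must be strictly inside (0, 1)")


def select_threshold(
    probabilities: np.ndarray,
    labels: np.ndarray,
    candidates: np.ndarray | None = None,
) -> BinarizationThreshold:
    """Exhaustive F1-maximizing threshold search over a candidate grid.

    Binarization uses ``probability >= threshold``. Ties are broken toward
    the lower threshold (the more sensitive segmentation). Raises when the
    labels contain no positives (the F1 score is undefined there).
    """
    if candidates is None:
        candidates = np.round(np.arange(0.01, 1.0, 0.01), 2)
    probs = np.asarray(probabilities, dtype=float).ravel()
    truth = np.asarray(labels).ravel().astype(bool)
    if probs.shape != truth.shape:
        raise ParameterError("probabilities and labels must align")
    n_pos = int(truth.sum())
    if n_pos == 0:
        raise ParameterError("threshold undefined: no positive labels")
    pos_sorted = np.sort(probs[truth])
    neg_sorted = np.sort(probs[~truth])
    cand = np.asarray(candidates, dtype=float)
    tp = n_pos - np.searchsorted(pos_sorted, cand, side="left")
    fp = neg_sorted.size - np.searchsorted(neg_sorted, cand, side="left")
    fn = n_pos - tp
    denom = 2 * tp + fp + fn
    f1 = np.where(denom > 0, 2 * tp / np.maximum(denom, 1), 0.0)
    best = int(np.argmax(f1))  # argmax returns the first (lowest) maximizer
    return BinarizationThreshold(threshold=float(cand[best]), f1=float(f1[best]))


def smooth_longitudinal(prob_volume: ProbabilityVolume, sigma_slices: float) -> ProbabilityVolume:
    """Gaussian blur along the stem axis only; evens out slice-to-slice jitter.

    Fungal decay spreads preferentially along the grain, so longitudinal
    smoothing is consistent with the biology. ``sigma`` is in slices; 0 is
    the identity.
    """
    if sigma_slices < 0:
        raise ParameterError("sigma must be >= 0")
    values = prob_volume.values
    if sigma_slices > 0:
        values = ndi.gaussian_filter1d(values.astype(np.float64), sigma_slices,
                                       axis=0, mode="nearest").astype(np.float32)
    return ProbabilityVolume(
        values=values,
        pixel_spacing=prob_volume.pixel_spacing,
        slice_thickness=prob_volume.slice_thickness,
        model_digest=prob_volume.model_digest,
        weighting=prob_volume.weighting,
    )


def quantify_decay(
    prob_volume: ProbabilityVolume,
    threshold: BinarizationThreshold | float,
    wood_mask: np.ndarray,
    crack_mask: np.ndarray | None = None,
) -> float:
    """Relative decay volume [%]: decayed wood voxels / wood voxels x 100.

    Voxels in ``crack_mask`` are never counted toward decay (cracks are not
    decayed wood, they are missing wood). ``wood_mask`` should cover the
    whole wood compartment including decayed wood.
    """
    t = threshold.threshold if isinstance(threshold, BinarizationThreshold) else float(threshold)
    if not wood_mask.any():
        raise ParameterError("empty wood mask: relative decay volume undefined")
    decayed = (prob_volume.values >= t) & wood_mask
    if crack_mask is not None:
        decayed &= ~crack_mask
    return 100.0 * float(decayed.sum()) / float(wood_mask.sum())
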