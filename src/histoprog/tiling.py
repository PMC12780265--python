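"""Slide tiling and background flagging.

Two tiling conventions are used downstream: non-overlapping patches
(``stride == patch_size``) when fitting the visual codebook, and overlapping
patches (``stride < patch_size``) at inference.  Right/bottom remainders
smaller than a full patch are dropped; coordinates are 0-based with
half-open pixel intervals ``[x0, x0 + patch_size)``.

Background removal is an HSV rule: a patch counts as tissue iff the
fraction of its pixels that are saturated (S > s_min) and not near-white
(V < v_max) exceeds ``f_min``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from skimage.color import rgb2hsv

__all__ = ["PatchSet", "tile", "flag_tissue"]


@dataclass
class PatchSet:
    """Tiled patches of one slide: origins on the stride lattice plus flags."""

    slide_id: str
    patch_size: int
    stride: int
    origins: np.ndarray            # (n, 2) int array of (x0, y0)
    image: np.ndarray              # reference to the source image
    tissue: np.ndarray | None = None  # boolean flags, None until flagged

    @property
    def n_patches(self) -> int:
        return len(self.origins)

    @property
    def n_tissue(self) -> int:
        if self.tissue is None:
            raise ValueError("tissue flags not computed; run flag_tissue first")
        return int(self.tissue.sum())

    def patch(self, i: int) -> np.ndarray:
        x0, y0 = self.origins[i]
        return self.image[y0:y0 + self.patch_size, x0:x0 + self.patch_size]

    def iter_patches(self):
        for i in range(self.n_patches):
            yield self.patch(i)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "slide_id": self.slide_id,
                "x0": self.origins[:, 0],
                "y0": self.origins[:, 1],
            }
        )
        if self.tissue is not None:
            df["tissue"] = self.tissue
        return df


def tile(image: np.ndarray, patch_size: int, stride: int | None = None,
         slide_id: str = "slide") -> PatchSet:
    """Tile ``image`` into ``patch_size`` squares at the given stride.

    Origins enumerate ``x0 in {0, stride, 2*stride, ...}`` with
    ``x0 + patch_size <= width`` (same in y), in row-major order.
    ``stride == patch_size`` yields disjoint patches; smaller strides
    overlap.
    """
    if stride is None:
        stride = patch_size
    if patch_size < 1:
        raise ValueError("patch_size must be >= 1")
    if not 1 <= stride <= patch_size:
        raise ValueError("stride must satisfy 1 <= stride <= patch_size")
    image = np.asarray(image)
    if image.ndim < 2:
        raise ValueError("image must be at least 2-D")
    height, width = image.shape[:2]
    if height < patch_size or width < patch_size:
        raise ValueError(
            f"image {width}x{height} smaller than patch_size {patch_size}"
        )
    xs = np.arange(0, width - patch_size + 1, stride)
    ys = np.arange(0, height - patch_size + 1, stride)
    gx, gy = np.meshgrid(xs, ys)
    origins = np.column_stack([gx.ravel(), gy.ravel()]).astype(int)
    return PatchSet(slide_id=slide_id, patch_size=patch_size, stride=stride,
                    origins=origins, image=image)


def flag_tissue(patchset: PatchSet, s_min: float = 0.08, v_max: float = 0.95,
                f_min: float = 0.5) -> PatchSet:
    """Flag patches as tissue by the HSV stain rule.

    A pixel is "stained" when saturation > ``s_min`` and value < ``v_max``;
    a patch is tissue when the stained fraction exceeds ``f_min``.  Requires
    an RGB image.
    """
    image = np.asarray(patchset.image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("tissue flagging requires an RGB image")
    hsv = rgb2hsv(image)
    stained = (hsv[..., 1] > s_min) & (hsv[..., 2] < v_max)
    p = patchset.patch_size
    flags = np.empty(patchset.n_patches, dtype=bool)
    for i, (x0, y0) in enumerate(patchset.origins):
        frac = stained[y0:y0 + p, x0:x0 + p].mean()
        flags[i] = frac > f_min
    return replace(patchset, tissue=flags)
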