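"""Nodule image-patch extraction.

Five steps: intersect the readers' contours into a consensus region R,
take its minimum square bounding box, enlarge the box by a 5-pixel
margin, crop the grayscale image G and the binary image B with the same
box, and resize both to 64 x 64 (bilinear for G, nearest-neighbour for
B so it stays binary).

Coordinate convention: row-major, 0-based, boxes half-open
[r0, r1) x [c0, c1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.draw import polygon as draw_polygon
from skimage.draw import polygon_perimeter
from skimage.transform import resize

PATCH_SIZE = 64
DEFAULT_MARGIN = 5


class NoConsensusRegion(Exception):
    """The readers' contours have an empty pixelwise intersection."""


@dataclass
class NodulePatch:
    """Paired 64x64 grayscale image G and binary mask B."""

    G: np.ndarray
    B: np.ndarray
    case_id: str = ""
    slice_index: int = 0
    box: tuple = ()  # (r0, r1, c0, c1) half-open crop box in source coordinates

    def __post_init__(self):
        if self.G.shape != (PATCH_SIZE, PATCH_SIZE) or self.B.shape != (PATCH_SIZE, PATCH_SIZE):
            raise ValueError("G and B must both be 64x64")
        vals = np.unique(self.B)
        if not np.all(np.isin(vals, [0, 1])):
            raise ValueError("B must be binary")
        if self.B.sum() == 0:
            raise ValueError("B must contain at least one foreground pixel")


def fill_polygon(contour: np.ndarray, image_shape: tuple) -> np.ndarray:
    """Rasterize one closed polygon (x, y vertices) including its boundary."""
    contour = np.asarray(contour, dtype=float)
    if contour.ndim != 2 or contour.shape[1] != 2 or len(contour) < 3:
        raise ValueError("polygon needs >= 3 (x, y) vertices")
    xs, ys = contour[:, 0], contour[:, 1]
    mask = np.zeros(image_shape, dtype=bool)
    rr, cc = draw_polygon(ys, xs, shape=image_shape)
    mask[rr, cc] = True
    rr, cc = polygon_perimeter(ys, xs, shape=image_shape)
    mask[rr, cc] = True
    return mask


def intersection_region(contours: list, image_shape: tuple) -> np.ndarray:
    """Pixelwise AND of the filled reader polygons.

    Raises :class:`NoConsensusRegion` when the readers share no pixel.
    """
    if not contours:
        raise ValueError("need at least one reader contour")
    region = np.ones(image_shape, dtype=bool)
    for contour in contours:
        region &= fill_polygon(contour, image_shape)
    if not region.any():
        raise NoConsensusRegion("empty intersection of reader contours")
    return region


def square_box(mask: np.ndarray, margin: int = DEFAULT_MARGIN) -> tuple:
    """Minimum square bounding box of the mask, padded by ``margin``.

    The shorter side is expanded symmetrically (an odd expansion puts
    the extra pixel toward the top/left); the margin is added on all
    four sides. Returned box is half-open and may extend beyond the
    image (callers zero-pad).
    """
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    if rows.size == 0:
        raise ValueError("empty mask")
    r0, r1 = int(rows[0]), int(rows[-1]) + 1
    c0, c1 = int(cols[0]), int(cols[-1]) + 1
    h, w = r1 - r0, c1 - c0
    side = max(h, w)
    dr, dc = side - h, side - w
    r0 -= dr - dr // 2
    r1 += dr // 2
    c0 -= dc - dc // 2
    c1 += dc // 2
    return (r0 - margin, r1 + margin, c0 - margin, c1 + margin)


def _crop_padded(image: np.ndarray, box: tuple, dtype=float) -> np.ndarray:
    """Crop a half-open box, zero-padding where it leaves the image."""
    r0, r1, c0, c1 = box
    out = np.zeros((r1 - r0, c1 - c0), dtype=dtype)
    sr0, sr1 = max(r0, 0), min(r1, image.shape[0])
    sc0, sc1 = max(c0, 0), min(c1, image.shape[1])
    if sr0 < sr1 and sc0 < sc1:
        out[sr0 - r0:sr1 - r0, sc0 - c0:sc1 - c0] = image[sr0:sr1, sc0:sc1]
    return out


def extract_patch(
    image: np.ndarray,
    region: np.ndarray,
    margin: int = DEFAULT_MARGIN,
    case_id: str = "",
    slice_index: int = 0,
) -> NodulePatch:
    """Crop and resize the consensus region into a 64x64 G/B patch pair."""
    if image.shape != region.shape:
        raise ValueError("image and region must share a shape")
    if not region.any():
        raise ValueError("empty consensus region")
    box = square_box(region, margin=margin)
    g_crop = _crop_padded(image.astype(float), box)
    b_crop = _crop_padded(region.astype(np.uint8), box, dtype=np.uint8)
    g = resize(g_crop, (PATCH_SIZE, PATCH_SIZE), order=1, mode="constant",
               anti_aliasing=False, preserve_range=True)
    b = resize(b_crop, (PATCH_SIZE, PATCH_SIZE), order=0, mode="constant",
               anti_aliasing=False, preserve_range=True).astype(np.uint8)
    if b.sum() == 0:
        # a region of a few pixels can vanish under nearest resampling;
        # keep the contract by marking the patch centre
        b[PATCH_SIZE // 2, PATCH_SIZE // 2] = 1
    return NodulePatch(G=g, B=b, case_id=case_id, slice_index=slice_index, box=box)


def patches_from_case(case, margin: int = DEFAULT_MARGIN) -> list:
    """Extract one patch per slice of a phantom (or adapter) case.

    Skips nothing: raises :class:`NoConsensusRegion` if any slice has an
    empty reader intersection, so callers can drop the nodule.
    """
    out = []
    for s, image in enumerate(case.slices):
        contours = [case.reader_contours[r][s] for r in range(len(case.reader_contours))]
        region = intersection_region(contours, image.shape)
        out.append(extract_patch(image, region, margin=margin,
                                 case_id=case.case_id, slice_index=s))
    return out
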