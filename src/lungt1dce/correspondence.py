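"""Spatial correspondence between T1 and perfusion maps.

Two routes are provided:

* registration-based — apply a precomputed deformation field (identity by
  default; the registration itself is external) by pull-back resampling,
  and
* registration-free — subdivide each lung into 10 vertical strips of equal
  voxel count, each split horizontally into 10 blocks, giving 100 areas per
  lung that correspond across grids/respiratory states by (side, strip,
  block) index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grid import ImageGrid

N_STRIPS = 10
N_BLOCKS = 10


@dataclass
class SubdivisionMap:
    """Per-lung-voxel area labels.

    ``strips``/``blocks`` hold 1-based indices (0 outside); an area id is
    ``strip*100 + block`` (unique within one lung).
    """

    strips: np.ndarray
    blocks: np.ndarray
    grid: ImageGrid | None = None
    n_strips: int = N_STRIPS
    n_blocks: int = N_BLOCKS

    @property
    def area_ids(self) -> np.ndarray:
        return np.where(self.strips > 0, self.strips * 100 + self.blocks, 0)

    def area_mask(self, strip: int, block: int) -> np.ndarray:
        return (self.strips == strip) & (self.blocks == block)


@dataclass
class DeformationField:
    """Per-target-voxel displacement, in source-grid voxel units."""

    displacement: np.ndarray         # (ndim, *target_shape)
    source_grid: ImageGrid
    target_grid: ImageGrid

    def __post_init__(self):
        d = np.asarray(self.displacement, dtype=float)
        if d.shape != (self.target_grid.ndim,) + self.target_grid.shape:
            raise ValueError(
                f"displacement shape {d.shape} does not match target grid "
                f"{self.target_grid.shape}"
            )
        self.displacement = d


def identity_field(source_grid: ImageGrid, target_grid: ImageGrid | None = None
                   ) -> DeformationField:
    tg = target_grid or source_grid
    return DeformationField(
        displacement=np.zeros((tg.ndim,) + tg.shape),
        source_grid=source_grid, target_grid=tg,
    )


def region_grow_segment(image: np.ndarray, seeds, tolerance: float,
                        fill_holes: bool = True, max_fraction: float = 0.5
                        ) -> np.ndarray:
    """Segment the connected region around ``seeds`` whose intensities stay
    within ``tolerance`` of the running region mean.

    Growth proceeds in sweeps: all face-neighbours of the current region
    within tolerance of its current mean are admitted, then the mean is
    updated.  Morphological hole-filling is applied afterwards.  A region
    that reaches the image border or exceeds ``max_fraction`` of the image
    aborts (the seed leaked out of the target structure).
    """
    image = np.asarray(image, dtype=float)
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    region = np.zeros(image.shape, dtype=bool)
    for s in np.atleast_2d(np.asarray(seeds, dtype=int)):
        if np.any(s < 0) or np.any(s >= np.array(image.shape)):
            raise ValueError(f"seed {tuple(s)} outside the image")
        region[tuple(s)] = True
    seed_vals = image[region]
    if np.ptp(seed_vals) > tolerance:
        raise ValueError("seed intensities span more than the tolerance window")
    structure = ndimage.generate_binary_structure(image.ndim, 1)
    border = np.zeros(image.shape, dtype=bool)
    for ax in range(image.ndim):
        sl = [slice(None)] * image.ndim
        for edge in (0, -1):
            sl[ax] = edge
            border[tuple(sl)] = True
    while True:
        mean = image[region].mean()
        frontier = ndimage.binary_dilation(region, structure) & ~region
        accept = frontier & (np.abs(image - mean) <= tolerance)
        if not accept.any():
            break
        region |= accept
        if region.sum() > max_fraction * image.size:
            raise ValueError("region growing leaked: exceeded "
                             f"{max_fraction:.0%} of the image")
        if (region & border).any():
            raise ValueError("region growing leaked: region reached the image border")
    if fill_holes:
        region = ndimage.binary_fill_holes(region, structure=structure)
    return region


def split_left_right(mask: np.ndarray) -> np.ndarray:
    """Label the two largest components 1 (left, smaller column centroid)
    and 2 (right); a single component is split at its column midline."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    lab, n = ndimage.label(mask)
    if n == 1:
        warnings.warn("single connected component: splitting at the midline",
                      stacklevel=2)
        cols = np.nonzero(mask)[-1]
        mid = np.median(cols)
        out = np.zeros(mask.shape, dtype=np.uint8)
        col_idx = np.arange(mask.shape[-1])
        left = mask & (col_idx[None, :] <= mid) if mask.ndim == 2 else \
            mask & (col_idx[None, None, :] <= mid)
        out[left] = 1
        out[mask & (out == 0)] = 2
        return out
    sizes = ndimage.sum_labels(mask, lab, index=np.arange(1, n + 1))
    keep = np.argsort(sizes)[::-1][:2] + 1
    centroids = ndimage.center_of_mass(mask, lab, index=keep)
    col_axis = mask.ndim - 1
    order = np.argsort([c[col_axis] for c in centroids])
    out = np.zeros(mask.shape, dtype=np.uint8)
    out[lab == keep[order[0]]] = 1
    out[lab == keep[order[1]]] = 2
    return out


def _rank_partition(order_keys, n_parts: int) -> np.ndarray:
    """Part index (1-based) for items sorted lexicographically by keys."""
    n = len(order_keys[0])
    order = np.lexsort(order_keys[::-1])   # first key is primary
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(1, n + 1)
    # part k holds ranks in (N(k-1)/P, Nk/P]
    return np.ceil(ranks * n_parts / n).astype(int)


def subdivide_lung(mask: np.ndarray, n_strips: int = N_STRIPS,
                   n_blocks: int = N_BLOCKS, grid: ImageGrid | None = None
                   ) -> SubdivisionMap:
    """Equal-voxel-count subdivision of one 2D lung mask.

    Voxels ordered by row (vertical, head-foot) split into ``n_strips``
    strips of equal count; within each strip, ordering by column yields
    ``n_blocks`` blocks.  Ties break by the other coordinate then raster
    order, making the partition deterministic and enumeration-invariant.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2:
        raise ValueError("subdivision operates on 2D masks")
    n = int(mask.sum())
    if n < n_strips * n_blocks:
        raise ValueError(
            f"lung has {n} voxels; need at least {n_strips * n_blocks}"
        )
    rows, cols = np.nonzero(mask)
    strip_of = _rank_partition((rows, cols), n_strips)
    blocks_of = np.zeros_like(strip_of)
    for k in range(1, n_strips + 1):
        in_strip = strip_of == k
        blocks_of[in_strip] = _rank_partition(
            (cols[in_strip], rows[in_strip]), n_blocks
        )
    strips = np.zeros(mask.shape, dtype=np.int16)
    blocks = np.zeros(mask.shape, dtype=np.int16)
    strips[rows, cols] = strip_of
    blocks[rows, cols] = blocks_of
    return SubdivisionMap(strips=strips, blocks=blocks, grid=grid,
                          n_strips=n_strips, n_blocks=n_blocks)


def corresponding_areas(sub_a: SubdivisionMap, sub_b: SubdivisionMap
                        ) -> list[tuple[int, int]]:
    """(strip, block) pairs present in both subdivisions, index-matched."""
    if (sub_a.n_strips, sub_a.n_blocks) != (sub_b.n_strips, sub_b.n_blocks):
        raise ValueError("subdivision schemes do not match")
    pairs = []
    for s in range(1, sub_a.n_strips + 1):
        for b in range(1, sub_a.n_blocks + 1):
            if sub_a.area_mask(s, b).any() and sub_b.area_mask(s, b).any():
                pairs.append((s, b))
    return pairs


def apply_deformation(data: np.ndarray, source_grid: ImageGrid,
                      field: DeformationField, mode: str = "linear"
                      ) -> np.ndarray:
    """Pull-back resampling: each target voxel samples the source image at
    its own physical position plus the displacement (source voxel units).

    ``mode='linear'`` interpolates continuous maps (out-of-domain -> NaN);
    ``mode='nearest'`` resamples label maps (out-of-domain -> -1), and never
    invents labels.
    """
    if mode not in ("linear", "nearest"):
        raise ValueError(f"unknown interpolation mode {mode!r}")
    if not np.all(np.isfinite(field.displacement)):
        raise ValueError("deformation field contains non-finite values")
    data = np.asarray(data)
    if data.shape != source_grid.shape:
        raise ValueError("data shape does not match the source grid")
    tg, sg = field.target_grid, field.source_grid
    if sg.ndim != source_grid.ndim:
        raise ValueError("field source grid is incompatible with the data grid")
    # physical coordinates of target voxel centres -> source continuous index
    mesh = np.meshgrid(*[np.arange(s) for s in tg.shape], indexing="ij")
    coords = []
    for ax in range(tg.ndim):
        phys = tg.origin[ax] + (mesh[ax] + 0.5) * tg.spacing[ax]
        idx = (phys - sg.origin[ax]) / sg.spacing[ax] - 0.5
        coords.append(idx + field.displacement[ax])
    coords = np.stack(coords)
    inside = np.ones(tg.shape, dtype=bool)
    for ax in range(tg.ndim):
        inside &= (coords[ax] >= -0.5) & (coords[ax] <= source_grid.shape[ax] - 0.5)
    if mode == "linear":
        out = ndimage.map_coordinates(data.astype(float), coords, order=1,
                                      mode="nearest")
        out[~inside] = np.nan
    else:
        out = ndimage.map_coordinates(data, coords, order=0, mode="nearest",
                                      output=data.dtype)
        out = out.astype(np.int64 if data.dtype.kind in "ui" else data.dtype)
        out[~inside] = -1
    return out
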