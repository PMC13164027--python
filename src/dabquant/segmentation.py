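"""Nucleus instance masks: loading, postprocessing, fallback segmentation.

The classifier only needs a label raster (0 = background, k >= 1 = nucleus
k).  Masks may come from three sources: a file produced by any external
segmenter, the built-in classical fallback (Otsu + watershed on the combined
nuclear od), or an optional adapter around an installed flow-based
segmenter.  All three routes share the same postprocessing: small-object
removal (area < 20 px by default), hole filling and fragment merging,
followed by deterministic relabeling to 1..N.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Protocol

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.segmentation import watershed

from .errors import FormatError, OptionalDependencyError, ParameterError, ShapeError
from .stains import StainModel, deconvolve

__all__ = [
    "InstanceMask",
    "load_instance_mask",
    "save_instance_mask",
    "postprocess_instances",
    "fallback_segment",
    "run_external_segmenter",
    "CellposeAdapter",
]

#: 8-connectivity structuring element shared by all labeling steps.
_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class InstanceMask:
    """Label raster assigning each pixel to background (0) or one nucleus."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 2:
            raise FormatError(f"instance mask must be 2-D, got {lab.ndim}-D")
        if not np.issubdtype(lab.dtype, np.integer):
            raise FormatError(f"instance mask must be integer-typed, got {lab.dtype}")
        if lab.size and lab.min() < 0:
            raise FormatError("instance mask labels must be >= 0")
        object.__setattr__(self, "labels", lab)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def ids(self) -> np.ndarray:
        """Sorted array of nucleus labels present (excluding background)."""
        u = np.unique(self.labels)
        return u[u > 0]

    @property
    def n_nuclei(self) -> int:
        return int(self.ids.size)

    def areas(self) -> dict[int, int]:
        """Pixel count per nucleus label."""
        counts = np.bincount(self.labels.ravel())
        return {i: int(counts[i]) for i in self.ids}


def load_instance_mask(path: str | Path) -> InstanceMask:
    """Read a label raster from a single-channel integer PNG/TIFF."""
    import imageio.v3 as iio

    arr = iio.imread(path)
    if arr.ndim != 2:
        raise FormatError(
            f"{path}: instance masks must be single-channel, got shape {arr.shape}"
        )
    if not np.issubdtype(arr.dtype, np.integer):
        raise FormatError(
            f"{path}: instance masks must be integer rasters, got dtype {arr.dtype}"
        )
    return InstanceMask(labels=arr.astype(np.int32))


def save_instance_mask(mask: InstanceMask, path: str | Path) -> None:
    """Write a label raster as a 16-bit single-channel PNG/TIFF."""
    import imageio.v3 as iio

    lab = mask.labels
    if lab.size and lab.max() > np.iinfo(np.uint16).max:
        raise FormatError("too many labels for a 16-bit mask file")
    iio.imwrite(path, lab.astype(np.uint16))


def _relabel_by_scan_order(labels: np.ndarray) -> np.ndarray:
    """Relabel objects 1..N by first-pixel occurrence in raster-scan order."""
    out = np.zeros_like(labels, dtype=np.int32)
    flat = labels.ravel()
    order: dict[int, int] = {}
    nonzero = np.flatnonzero(flat)
    for idx in nonzero:
        v = flat[idx]
        if v not in order:
            order[v] = len(order) + 1
    for old, new in order.items():
        out[labels == old] = new
    return out


def postprocess_instances(
    mask: InstanceMask,
    min_area: int = 20,
    fill_holes: bool = True,
    merge_fragments: bool = True,
) -> InstanceMask:
    """Clean an instance mask: drop small objects, fill holes, merge fragments.

    Objects with total area strictly below ``min_area`` are removed.  Holes
    (background enclosed by one label) are filled without stealing pixels
    from other labels.  With ``merge_fragments`` on, disconnected fragments
    carrying the same input label become one object when hole filling makes
    them 8-adjacent; otherwise each 8-connected fragment becomes its own
    object.  Output labels are contiguous 1..N in raster-scan order of first
    pixel occurrence, which makes the operation idempotent.
    """
    if min_area < 1:
        raise ParameterError(f"min_area must be >= 1, got {min_area}")
    labels = mask.labels.copy()

    counts = np.bincount(labels.ravel())
    small = np.flatnonzero(counts < min_area)
    small = small[small > 0]
    if small.size:
        labels[np.isin(labels, small)] = 0

    ids = np.unique(labels)
    ids = ids[ids > 0]

    pieces: list[np.ndarray] = []  # binary masks of final objects
    for lab_id in ids:
        obj = labels == lab_id
        if merge_fragments:
            regions = [obj]  # treat all fragments of the label jointly
        else:
            frag_lab = cc_label(obj, connectivity=2)
            regions = [frag_lab == k for k in range(1, frag_lab.max() + 1)]
        for region in regions:
            if fill_holes:
                filled = ndi.binary_fill_holes(region, structure=None)
                # only claim true background; never overwrite other nuclei
                region = region | (filled & (labels == 0))
            # after filling, previously separate fragments may have fused;
            # each remaining 8-connected component is one final object
            comp = cc_label(region, connectivity=2)
            for k in range(1, comp.max() + 1):
                piece = comp == k
                # splitting can leave sub-min_area pieces; filter them here
                # too so the output invariant holds and the op is idempotent
                if int(piece.sum()) >= min_area:
                    pieces.append(piece)

    out = np.zeros_like(labels, dtype=np.int32)
    # deterministic label order: first pixel in raster-scan order
    pieces.sort(key=lambda m: int(np.flatnonzero(m.ravel())[0]))
    for new_id, piece in enumerate(pieces, start=1):
        out[piece] = new_id
    return InstanceMask(labels=out)


def fallback_segment(
    rgb: np.ndarray,
    model: StainModel | None = None,
    min_area: int = 20,
    min_seed_distance: int = 7,
    min_nuclear_od: float = 0.1,
) -> InstanceMask:
    """Classical nucleus segmentation: Otsu on nuclear od + seeded watershed.

    The combined nuclear absorbance (hematoxylin + DAB od) is thresholded by
    Otsu's method (floored at ``min_nuclear_od`` so blank tiles yield an
    empty mask), split by watershed on the negated distance transform with
    local-maximum seeds, then passed through :func:`postprocess_instances`.
    Deterministic for fixed input and parameters.
    """
    if model is None:
        model = StainModel()
    hem, dab, _ = deconvolve(rgb, model)
    nuclear = hem + dab
    if nuclear.max() <= min_nuclear_od:
        return InstanceMask(labels=np.zeros(nuclear.shape, dtype=np.int32))
    thr = max(float(threshold_otsu(nuclear)), min_nuclear_od)
    fg = nuclear > thr
    if not fg.any():
        return InstanceMask(labels=np.zeros(nuclear.shape, dtype=np.int32))
    dist = ndi.distance_transform_edt(fg)
    peaks = peak_local_max(
        dist, min_distance=min_seed_distance, labels=fg, exclude_border=False
    )
    markers = np.zeros(fg.shape, dtype=np.int32)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    if markers.max() == 0:  # tiny foreground with no peak: one seed at max
        r, c = np.unravel_index(int(np.argmax(dist)), dist.shape)
        markers[r, c] = 1
    labels = watershed(-dist, markers, mask=fg, connectivity=2)
    return postprocess_instances(InstanceMask(labels=labels.astype(np.int32)), min_area=min_area)


class SegmenterAdapter(Protocol):
    """Anything that maps an RGB tile to an integer label raster."""

    def segment(self, rgb: np.ndarray) -> np.ndarray: ...


class CellposeAdapter:
    """Adapter around an installed Cellpose model (optional dependency).

    The flow-based model itself is external; this wrapper only converts its
    label output to an :class:`InstanceMask`.  Import happens lazily so the
    package imports cleanly without the dependency.
    """

    def __init__(self, model_name: str = "nuclei", **eval_kwargs) -> None:
        self.model_name = model_name
        self.eval_kwargs = eval_kwargs

    def segment(self, rgb: np.ndarray) -> np.ndarray:
        try:
            from cellpose import models  # type: ignore
        except ImportError as exc:
            raise OptionalDependencyError(
                "the external segmenter requires the optional 'cellpose' "
                "package; install it or use --segmenter fallback"
            ) from exc
        model = models.Cellpose(model_type=self.model_name)
        masks, *_ = model.eval(rgb, **self.eval_kwargs)
        return np.asarray(masks)


def run_external_segmenter(
    rgb: np.ndarray,
    adapter: SegmenterAdapter | Callable[[np.ndarray], np.ndarray] | None = None,
    min_area: int = 20,
) -> InstanceMask:
    """Run an external instance segmenter and apply the shared postprocessing."""
    if adapter is None:
        adapter = CellposeAdapter()
    seg = adapter.segment if hasattr(adapter, "segment") else adapter
    labels = np.asarray(seg(rgb))
    if not np.issubdtype(labels.dtype, np.integer):
        labels = labels.astype(np.int32)
    mask = InstanceMask(labels=labels)
    return postprocess_instances(mask, min_area=min_area)
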