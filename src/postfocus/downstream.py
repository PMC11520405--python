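"""Downstream analysis fidelity: cell segmentation, contact regions, counts.

The segmenter here is a deterministic classical stand-in (background-deviation
threshold + hole filling + watershed split), adequate for the synthetic
imagery produced by :mod:`postfocus.synth`.  It reproduces the mechanism of
interest — defocus blur thickens apparent object boundaries, inflating masks
and producing spurious contacts — without any learned weights.

Contact regions are pixels where the dilations (configurable ``touch_radius``)
of two distinct instances intersect; with ``touch_radius = 0`` the criterion
degenerates to literal 8-neighbour boundary adjacency.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage as ndi
from skimage import feature, filters, morphology, segmentation

from .metrics import mse as _mse, pcc as _pcc

__all__ = [
    "SegmentationParams",
    "LabelMask",
    "ContactMask",
    "ContactMetrics",
    "segment_cells",
    "detect_contacts",
    "contact_fidelity",
    "count_error",
    "match_instances",
]


@dataclass(frozen=True)
class SegmentationParams:
    smooth_sigma: float = 1.2
    threshold: Optional[float] = None   # None -> Otsu on the deviation image
    min_threshold: float = 0.025        # floor under Otsu (guards empty scenes)
    min_area_px: int = 40
    border_margin_px: int = 4           # blank strip at the image border
    min_distance_px: int = 7            # watershed seed separation
    split_touching: bool = True
    suppress_well_wall: bool = True     # cut the square wall ridge near the rim
    wall_cut_px: int = 5                # band width removed inside the ridge


@dataclass
class LabelMask:
    """Instance labels: 0 = background, k >= 1 = cell k (contiguous)."""

    labels: np.ndarray
    areas: np.ndarray          # pixel area per instance, index k-1

    @property
    def n_instances(self) -> int:
        return len(self.areas)

    def instance(self, k: int) -> np.ndarray:
        return self.labels == k


@dataclass
class ContactMask:
    mask: np.ndarray                       # bool contact pixels
    pairs: List[Tuple[int, int]]           # contributing instance pairs


@dataclass
class ContactMetrics:
    pcc: Optional[float]
    mse: float
    cell_count_error: Optional[int] = None


def _relabel(labels: np.ndarray) -> LabelMask:
    out = np.zeros_like(labels, dtype=np.int32)
    areas = []
    nxt = 1
    for val in np.unique(labels):
        if val == 0:
            continue
        m = labels == val
        out[m] = nxt
        areas.append(int(m.sum()))
        nxt += 1
    return LabelMask(labels=out, areas=np.asarray(areas, dtype=np.int64))


def segment_cells(image: np.ndarray,
                  params: SegmentationParams = SegmentationParams()) -> LabelMask:
    """Deterministic instance segmentation of a [0,1] nanowell image.

    Foreground is where the smoothed absolute deviation from the background
    median exceeds a threshold (Otsu unless fixed); the well wall is
    suppressed by masking a border margin and the wall's own deviation ridge;
    holes are filled, small objects removed, and touching objects split by
    watershed on the distance transform.  An empty mask is a valid result.
    """
    img = np.asarray(image, dtype=np.float64)
    bg = np.median(img)
    dev = ndi.gaussian_filter(np.abs(img - bg), params.smooth_sigma)

    # suppress image border / well wall band
    m = params.border_margin_px
    if m > 0:
        dev[:m, :] = 0
        dev[-m:, :] = 0
        dev[:, :m] = 0
        dev[:, -m:] = 0
    if params.suppress_well_wall:
        # the wall reads as a square ridge of deviation concentric with the
        # image; find its radius in the outer half and cut everything outside
        h, w = img.shape
        cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
        yy, xx = np.mgrid[0:h, 0:w]
        cheb = np.maximum(np.abs(yy - cy), np.abs(xx - cx)).astype(np.int64)
        rmax = int(cheb.max())
        profile = ndi.mean(dev, labels=cheb, index=np.arange(rmax + 1))
        lo = int(0.55 * min(h, w) / 2)
        if rmax > lo and np.any(profile[lo:] > 0):
            ridge = lo + int(np.argmax(profile[lo:]))
            if profile[ridge] > 2.0 * np.median(profile[:lo] + 1e-12):
                dev[cheb >= ridge - params.wall_cut_px] = 0

    if params.threshold is not None:
        thr = params.threshold
    else:
        finite = dev[dev > 1e-6]
        if finite.size < 16 or float(finite.max() - finite.min()) < 1e-3:
            return LabelMask(labels=np.zeros(img.shape, np.int32),
                             areas=np.zeros(0, np.int64))
        thr = max(filters.threshold_otsu(dev), params.min_threshold)
    fg = dev > thr
    # drop ring/wall-like components BEFORE hole filling: the well wall is a
    # closed thin curve whose filled interior would swallow the whole field
    lbl, nlab = ndi.label(fg)
    for region in range(1, nlab + 1):
        rm = lbl == region
        area = int(rm.sum())
        if area < params.min_area_px:
            fg[rm] = False
            continue
        ys, xs = np.nonzero(rm)
        h = ys.max() - ys.min() + 1
        w = xs.max() - xs.min() + 1
        if area < 0.25 * h * w:
            fg[rm] = False
    fg = ndi.binary_fill_holes(fg)
    if not fg.any():
        return LabelMask(labels=np.zeros(img.shape, np.int32),
                         areas=np.zeros(0, np.int64))

    if params.split_touching:
        distance = ndi.distance_transform_edt(fg)
        coords = feature.peak_local_max(distance, min_distance=params.min_distance_px,
                                        labels=fg, exclude_border=False)
        markers = np.zeros(img.shape, dtype=np.int32)
        for i, (y, x) in enumerate(coords, start=1):
            markers[y, x] = i
        if markers.max() == 0:
            labels, _ = ndi.label(fg)
        else:
            labels = segmentation.watershed(-distance, markers, mask=fg)
    else:
        labels, _ = ndi.label(fg)
    for val in np.unique(labels):
        if val and (labels == val).sum() < params.min_area_px:
            labels[labels == val] = 0
    return _relabel(labels)


def detect_contacts(mask: LabelMask, touch_radius_px: int = 1) -> ContactMask:
    """Contact pixels: intersections of per-instance dilations.

    Invariant under instance relabeling.  With fewer than two instances the
    contact mask is empty.
    """
    shape = mask.labels.shape
    n = mask.n_instances
    if n < 2:
        return ContactMask(mask=np.zeros(shape, dtype=bool), pairs=[])
    if touch_radius_px > 0:
        selem = morphology.disk(touch_radius_px)
    else:
        selem = np.ones((3, 3), dtype=bool)   # 8-neighbour adjacency
    dil = [ndi.binary_dilation(mask.instance(k), structure=selem)
           for k in range(1, n + 1)]
    contact = np.zeros(shape, dtype=bool)
    pairs = []
    for (i, a), (j, b) in combinations(enumerate(dil, start=1), 2):
        if touch_radius_px > 0:
            inter = a & b
        else:
            # adjacency: a dilated instance reaches the other's actual pixels
            inter = (a & mask.instance(j)) | (b & mask.instance(i))
        if inter.any():
            contact |= inter
            pairs.append((i, j))
    return ContactMask(mask=contact, pairs=pairs)


def contact_fidelity(reference: ContactMask, test: ContactMask) -> ContactMetrics:
    """PCC and MSE between two binary contact masks (PCC ``None`` if either
    mask is constant)."""
    a = reference.mask.astype(np.float64)
    b = test.mask.astype(np.float64)
    if a.shape != b.shape:
        raise ValueError("contact masks differ in shape")
    return ContactMetrics(pcc=_pcc(a, b), mse=_mse(a, b))


def count_error(reference_masks_per_frame: Sequence,
                test_masks_per_frame: Sequence):
    """Per-frame |Δn| of instance counts, plus video-level sum and mean.

    Accepts sequences of :class:`LabelMask`, of stacked ground-truth boolean
    masks (n, H, W), or of plain integer counts.
    """

    def n_of(x) -> int:
        if isinstance(x, LabelMask):
            return x.n_instances
        if isinstance(x, np.ndarray):
            return int(x.shape[0])
        return int(x)

    refs = [n_of(x) for x in reference_masks_per_frame]
    tests = [n_of(x) for x in test_masks_per_frame]
    if len(refs) != len(tests):
        raise ValueError("sequences differ in length")
    per_frame = np.abs(np.asarray(refs) - np.asarray(tests))
    return per_frame, int(per_frame.sum()), float(per_frame.mean())


def match_instances(truth_masks: np.ndarray, detected: LabelMask,
                    iou_floor: float = 0.1) -> List[Tuple[int, int, float]]:
    """Greedy greatest-IoU matching of ground-truth masks to detected instances.

    Returns (truth_index, detected_label, iou) triples with IoU above the
    floor; each detected instance is used at most once.
    """
    triples = []
    for ti, tmask in enumerate(truth_masks):
        for k in range(1, detected.n_instances + 1):
            dmask = detected.instance(k)
            inter = np.logical_and(tmask, dmask).sum()
            union = np.logical_or(tmask, dmask).sum()
            if union:
                iou = inter / union
                if iou >= iou_floor:
                    triples.append((ti, k, float(iou)))
    triples.sort(key=lambda t: -t[2])
    used_t, used_d, out = set(), set(), []
    for ti, k, iou in triples:
        if ti not in used_t and k not in used_d:
            out.append((ti, k, iou))
            used_t.add(ti)
            used_d.add(k)
    return out
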