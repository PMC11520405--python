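"""Image-quality metrics for focus restoration.

Four quantities are used throughout the package: the Tenenbaum gradient
(sharpness), PSNR, the Pearson correlation coefficient over all pixels or
restricted to Canny edge pixels, and MSE.

Conventions
-----------
* Images are 2-D float arrays; PSNR defaults to ``max_val=1.0``.
* ``tenengrad`` is the *mean* (not sum) of squared Sobel gradient magnitude,
  so scores are comparable across image sizes.
* A Pearson correlation of a constant image is undefined; these functions
  return ``None`` in that case rather than coercing to 0, and batch summaries
  count the exclusions.
* ``edge_pcc`` computes the Canny edge mask on the *reference* image only, so
  that degraded and restored images are scored on identical pixel support.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage import feature, morphology

__all__ = [
    "EdgeParams",
    "MetricReport",
    "tenengrad",
    "psnr",
    "mse",
    "pcc",
    "edge_pcc",
    "evaluate_pairs",
    "summarize_reports",
]


@dataclass(frozen=True)
class EdgeParams:
    """Parameters of the Canny edge mask used by :func:`edge_pcc`."""

    gaussian_sigma: float = 1.0
    low_threshold: float = 0.1
    high_threshold: float = 0.2
    dilation_radius_px: int = 1

    def __post_init__(self):
        if not self.low_threshold < self.high_threshold:
            raise ValueError("low_threshold must be < high_threshold")
        if self.dilation_radius_px < 0:
            raise ValueError("dilation_radius_px must be >= 0")


@dataclass
class MetricReport:
    """Metrics for one (reference, test) image pair."""

    tenengrad: float
    psnr_db: float
    pcc: Optional[float]
    edge_pcc: Optional[float]
    mse: float
    tenengrad_ref: Optional[float] = None

    def __post_init__(self):
        if self.tenengrad < 0 or self.mse < 0:
            raise ValueError("tenengrad and mse must be non-negative")
        for r in (self.pcc, self.edge_pcc):
            if r is not None and not -1.0 - 1e-9 <= r <= 1.0 + 1e-9:
                raise ValueError("correlation outside [-1, 1]")


def _as2d(image) -> np.ndarray:
    a = np.asarray(image, dtype=np.float64)
    if a.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {a.shape}")
    return a


def tenengrad(image) -> float:
    """Mean squared Sobel gradient magnitude; higher means sharper."""
    a = _as2d(image)
    if min(a.shape) < 3:
        raise ValueError("image smaller than the 3x3 Sobel kernel")
    gx = ndi.sobel(a, axis=1, mode="reflect")
    gy = ndi.sobel(a, axis=0, mode="reflect")
    return float(np.mean(gx * gx + gy * gy))


def mse(reference, test) -> float:
    a, b = _as2d(reference), _as2d(test)
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    d = a - b
    return float(np.mean(d * d))


def psnr(reference, test, max_val: float = 1.0) -> float:
    """10*log10(max_val^2 / MSE) in dB; returns ``math.inf`` for identical images."""
    if max_val <= 0:
        raise ValueError("max_val must be positive")
    err = mse(reference, test)
    if err == 0.0:
        return math.inf
    return float(10.0 * math.log10(max_val * max_val / err))


def pcc(j, k) -> Optional[float]:
    """Pearson correlation over flattened pixels; ``None`` if either is constant."""
    a, b = _as2d(j), _as2d(k)
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    if a.size < 2:
        raise ValueError("need at least 2 pixels")
    da = a - a.mean()
    db = b - b.mean()
    va = np.sum(da * da)
    vb = np.sum(db * db)
    if va == 0.0 or vb == 0.0:
        return None
    r = float(np.sum(da * db) / math.sqrt(va * vb))
    return min(1.0, max(-1.0, r))


def edge_mask(reference, params: EdgeParams = EdgeParams()) -> np.ndarray:
    """Canny edges of the reference image, optionally dilated."""
    a = _as2d(reference)
    edges = feature.canny(a, sigma=params.gaussian_sigma,
                          low_threshold=params.low_threshold,
                          high_threshold=params.high_threshold)
    if params.dilation_radius_px > 0:
        edges = ndi.binary_dilation(
            edges, structure=morphology.disk(params.dilation_radius_px))
    return edges


def edge_pcc(j, k, params: EdgeParams = EdgeParams()) -> Optional[float]:
    """PCC restricted to the Canny edge pixels of the reference image ``j``."""
    a, b = _as2d(j), _as2d(k)
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    mask = edge_mask(a, params)
    if mask.sum() < 2:
        return None
    return pcc(a[mask].reshape(1, -1), b[mask].reshape(1, -1))


def evaluate_pairs(reference_set: Sequence, test_set: Sequence,
                   params: EdgeParams = EdgeParams()):
    """Per-pair :class:`MetricReport` list plus a summary dict.

    The summary holds median and IQR per metric; pairs whose PCC/edge-PCC is
    undefined are excluded from that metric's summary and counted.
    """
    refs = list(reference_set)
    tests = list(test_set)
    if len(refs) != len(tests):
        raise ValueError("reference and test sets differ in length")
    reports = []
    for ref, test in zip(refs, tests):
        reports.append(MetricReport(
            tenengrad=tenengrad(test),
            tenengrad_ref=tenengrad(ref),
            psnr_db=psnr(ref, test),
            pcc=pcc(ref, test),
            edge_pcc=edge_pcc(ref, test, params),
            mse=mse(ref, test),
        ))
    return reports, summarize_reports(reports)


def summarize_reports(reports: Sequence[MetricReport]) -> dict:
    summary = {}
    for name in ("tenengrad", "psnr_db", "pcc", "edge_pcc", "mse"):
        values = [getattr(r, name) for r in reports]
        defined = [v for v in values if v is not None and not math.isinf(v)]
        n_inf = sum(1 for v in values if v is not None and math.isinf(v))
        excluded = len(values) - len(defined) - n_inf
        entry = {"n": len(defined), "n_undefined": excluded, "n_inf": n_inf}
        if defined:
            q1, med, q3 = np.percentile(defined, [25, 50, 75])
            entry.update(median=float(med), iqr=float(q3 - q1))
        summary[name] = entry
    return summary
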