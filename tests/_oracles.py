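"""Independent brute-force metric oracles shared by unit and acceptance tests.

These are deliberately naive reimplementations (explicit loops, textbook
formulas) kept separate from the package code paths they check.
"""

import math

import numpy as np


def oracle_tenengrad(img):
    """Explicit-loop Sobel with edge-duplicating padding."""
    kx = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], float)
    ky = kx.T
    # scipy's "reflect" boundary duplicates the edge sample, which numpy
    # calls "symmetric"
    a = np.pad(np.asarray(img, float), 1, mode="symmetric")
    h, w = np.asarray(img).shape
    total = 0.0
    for i in range(h):
        for j in range(w):
            patch = a[i:i + 3, j:j + 3]
            # correlation with the flipped kernel == convolution
            gx = float((patch * kx[::-1, ::-1]).sum())
            gy = float((patch * ky[::-1, ::-1]).sum())
            total += gx * gx + gy * gy
    return total / (h * w)


def oracle_mse(ref, test):
    a = np.asarray(ref, float).ravel()
    b = np.asarray(test, float).ravel()
    return float(sum((x - y) ** 2 for x, y in zip(a, b)) / a.size)


def oracle_psnr(ref, test, max_val=1.0):
    err = oracle_mse(ref, test)
    return math.inf if err == 0 else 10 * math.log10(max_val ** 2 / err)


def oracle_pcc(j, k):
    a = np.asarray(j, float).ravel()
    b = np.asarray(k, float).ravel()
    da, db = a - a.mean(), b - b.mean()
    denom = math.sqrt((da ** 2).sum() * (db ** 2).sum())
    return None if denom == 0 else float((da * db).sum() / denom)
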