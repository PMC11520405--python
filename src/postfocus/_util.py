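"""Small shared helpers: seeding, resizing, checkpoint (de)serialization."""

from __future__ import annotations

import json

import numpy as np
from skimage.transform import resize

_MASK64 = (1 << 64) - 1


def subseed(seed: int, k: int) -> int:
    """Derive the k-th child seed from ``seed`` (splitmix64-style mixing).

    Deterministic in (seed, k) and independent of call order, so e.g. the K
    samples of an averaged restoration are reproducible individually.
    """
    z = (int(seed) + (k + 1) * 0x9E3779B97F4A7C15) & _MASK64
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & _MASK64
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & _MASK64
    return (z ^ (z >> 31)) & _MASK64


def as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def resize_image(image: np.ndarray, size_px: int) -> np.ndarray:
    """Resize a 2-D [0,1] image to ``size_px`` squared (anti-aliased)."""
    if image.shape == (size_px, size_px):
        return np.asarray(image, dtype=np.float64)
    out = resize(np.asarray(image, dtype=np.float64), (size_px, size_px),
                 anti_aliasing=True, preserve_range=True)
    return np.clip(out, 0.0, 1.0)


def save_checkpoint(path, params: dict, meta: dict) -> None:
    """Write a single ``.npz`` checkpoint holding arrays plus a JSON meta blob."""
    arrays = {f"param::{k}": v for k, v in params.items()}
    arrays["__meta__"] = np.frombuffer(
        json.dumps(meta).encode("utf-8"), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path):
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"].tobytes()).decode("utf-8"))
        params = {k[len("param::"):]: data[k] for k in data.files
                  if k.startswith("param::")}
    return params, meta
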