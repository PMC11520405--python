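"""Synthetic nanowell scenes, defocus degradation, paired datasets and videos.

The simulator emulates label-free nanowell microscopy at the statistical
level needed by the rest of the package: a square well (default 50 µm edge)
containing a few non-overlapping objects — round cells, wall-adherent
elongated cells, or beads — rendered with a bright phase-contrast-like halo
rim, plus additive acquisition noise.  Axial defocus is modelled
parametrically: a point-spread blur whose width grows linearly with |Δz|,
followed by contrast loss toward the image mean and fresh noise.  Ground-truth
instance masks are kept for every object so downstream segmentation can be
scored exactly.

All operations are pure functions of their inputs and a seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage as ndi
from skimage import morphology

from ._util import as_rng, subseed

__all__ = [
    "SceneSpec",
    "DefocusModel",
    "VideoSpec",
    "FramePair",
    "PairRecord",
    "PairDataset",
    "VideoSim",
    "PlacementError",
    "DatasetValidationError",
    "render_scene",
    "defocus_sigma",
    "apply_defocus",
    "make_pair_dataset",
    "simulate_video",
    "write_dataset",
    "read_dataset",
    "classifier_frames",
]

OBJECT_KINDS = ("round_cell", "elongated_cell", "bead")
FOCUS_LABELS = ("in_focus", "oof")


class PlacementError(RuntimeError):
    """Could not place non-overlapping objects within the retry budget."""


class DatasetValidationError(ValueError):
    """A dataset record violates the manifest invariants."""


# ---------------------------------------------------------------------------
# specs


@dataclass(frozen=True)
class SceneSpec:
    """Geometry and photometry of one synthetic nanowell field."""

    image_size_px: int = 160
    pixel_pitch_um: float = 0.325
    well_edge_um: float = 50.0
    n_cells: int = 3
    object_kind: str = "round_cell"
    radius_um_range: Tuple[float, float] = (4.0, 6.0)
    intensity_fg: float = 0.65
    intensity_bg: float = 0.40
    noise_sigma: float = 0.01
    halo_strength: float = 0.25

    def __post_init__(self):
        if self.image_size_px < 8:
            raise ValueError("image_size_px too small")
        if self.object_kind not in OBJECT_KINDS:
            raise ValueError(f"object_kind must be one of {OBJECT_KINDS}")
        if self.well_edge_um / self.pixel_pitch_um > self.image_size_px:
            raise ValueError("well does not fit inside the image")
        lo, hi = self.radius_um_range
        if not (0 < lo <= hi):
            raise ValueError("radius_um_range must be positive and ordered")
        for v in (self.intensity_fg, self.intensity_bg, self.halo_strength):
            if not 0.0 <= v <= 1.0:
                raise ValueError("intensities must lie in [0, 1]")
        if self.n_cells < 0 or self.noise_sigma < 0:
            raise ValueError("n_cells and noise_sigma must be >= 0")

    @property
    def well_edge_px(self) -> float:
        return self.well_edge_um / self.pixel_pitch_um


@dataclass(frozen=True)
class DefocusModel:
    """Parametric defocus: blur width linear in |Δz|, plus contrast decay."""

    sigma_per_um: float = 0.5
    psf_family: str = "gaussian"
    contrast_decay_per_um: float = 0.06
    min_contrast: float = 0.2

    def __post_init__(self):
        if self.sigma_per_um <= 0:
            raise ValueError("sigma_per_um must be > 0")
        if self.psf_family not in ("gaussian", "disk"):
            raise ValueError("psf_family must be 'gaussian' or 'disk'")
        if self.contrast_decay_per_um < 0:
            raise ValueError("contrast_decay_per_um must be >= 0")


@dataclass(frozen=True)
class VideoSpec:
    """Time-lapse parameters: cell motion and intermittent defocus bursts."""

    n_frames: int = 20
    motion_step_px: float = 1.5
    oof_event_rate: float = 0.05
    oof_burst_len_frames: Tuple[int, int] = (2, 4)
    burst_delta_z_um: Tuple[float, ...] = (5.0, 10.0)

    def __post_init__(self):
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if not 0.0 <= self.oof_event_rate <= 1.0:
            raise ValueError("oof_event_rate must be in [0, 1]")
        lo, hi = self.oof_burst_len_frames
        if not (1 <= lo <= hi):
            raise ValueError("burst length bounds must satisfy 1 <= lo <= hi")
        if not self.burst_delta_z_um:
            raise ValueError("burst_delta_z_um must be non-empty")


# ---------------------------------------------------------------------------
# data containers


@dataclass
class FramePair:
    """One in-focus/OOF training pair with ground-truth masks."""

    in_focus: np.ndarray
    oof: np.ndarray
    delta_z_um: float
    is_identity: bool
    masks: np.ndarray  # (n_objects, H, W) bool

    def __post_init__(self):
        if self.in_focus.shape != self.oof.shape:
            raise ValueError("in_focus and oof must have the same shape")
        identical = self.delta_z_um == 0 and np.array_equal(self.in_focus, self.oof)
        if self.is_identity != identical:
            raise ValueError(
                "is_identity must hold exactly when delta_z_um == 0 and the "
                "images are bit-identical")


@dataclass
class PairRecord:
    pair_id: str
    delta_z_um: float
    is_identity: bool
    focus_label: str
    split: str
    seed: int
    in_focus_path: str = ""
    oof_path: str = ""
    masks_path: str = ""


@dataclass
class PairDataset:
    """In-memory paired dataset plus its manifest records."""

    records: List[PairRecord]
    pairs: List[FramePair]

    def __len__(self) -> int:
        return len(self.records)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.records])


@dataclass
class VideoSim:
    in_focus_frames: np.ndarray   # (T, H, W)
    observed_frames: np.ndarray   # (T, H, W)
    masks_per_frame: List[np.ndarray]
    z_trace: np.ndarray           # (T,)


# ---------------------------------------------------------------------------
# scene rendering


@dataclass
class _SceneObject:
    kind: str
    y: float
    x: float
    r_px: float
    axis_ratio: float
    angle: float

    @property
    def major_px(self) -> float:
        return self.r_px * np.sqrt(self.axis_ratio)

    @property
    def minor_px(self) -> float:
        return self.r_px / np.sqrt(self.axis_ratio)


_MAX_PLACEMENT_TRIES = 200
_HALO_WIDTH_PX = 2


def _well_bounds(spec: SceneSpec) -> Tuple[float, float, float, float]:
    c = spec.image_size_px / 2.0
    half = spec.well_edge_px / 2.0
    return c - half, c + half, c - half, c + half  # y0, y1, x0, x1


def _sample_objects(spec: SceneSpec, rng: np.random.Generator) -> List[_SceneObject]:
    y0, y1, x0, x1 = _well_bounds(spec)
    lo_um, hi_um = spec.radius_um_range
    objects: List[_SceneObject] = []
    for _ in range(spec.n_cells):
        r_px_nominal = rng.uniform(lo_um, hi_um) / spec.pixel_pitch_um
        if spec.object_kind == "elongated_cell":
            ratio = rng.uniform(1.8, 3.0)
        else:
            ratio = 1.0
        placed = False
        for _try in range(_MAX_PLACEMENT_TRIES):
            obj = _propose_placement(spec, rng, r_px_nominal, ratio,
                                     (y0, y1, x0, x1))
            if all(np.hypot(obj.y - o.y, obj.x - o.x)
                   > obj.major_px + o.major_px + 2 * _HALO_WIDTH_PX + 6.0
                   for o in objects):
                objects.append(obj)
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place object {len(objects)} after "
                f"{_MAX_PLACEMENT_TRIES} tries (n_cells={spec.n_cells})")
    return objects


def _propose_placement(spec, rng, r_px, ratio, bounds) -> _SceneObject:
    y0, y1, x0, x1 = bounds
    margin = r_px * np.sqrt(ratio) + _HALO_WIDTH_PX + 1
    if spec.object_kind == "elongated_cell":
        # wall-adherent: hug one well wall, long axis parallel to it
        side = rng.integers(4)
        minor = r_px / np.sqrt(ratio)
        off = minor + _HALO_WIDTH_PX + 1
        along = rng.uniform(margin, (x1 - x0) - margin)
        jitter = rng.uniform(-0.15, 0.15)
        if side == 0:   # top
            return _SceneObject(spec.object_kind, y0 + off, x0 + along, r_px, ratio, jitter)
        if side == 1:   # bottom
            return _SceneObject(spec.object_kind, y1 - off, x0 + along, r_px, ratio, jitter)
        if side == 2:   # left
            return _SceneObject(spec.object_kind, y0 + along, x0 + off, r_px, ratio,
                                np.pi / 2 + jitter)
        return _SceneObject(spec.object_kind, y0 + along, x1 - off, r_px, ratio,
                            np.pi / 2 + jitter)
    y = rng.uniform(y0 + margin, y1 - margin)
    x = rng.uniform(x0 + margin, x1 - margin)
    return _SceneObject(spec.object_kind, y, x, r_px, ratio, 0.0)


def _object_mask(obj: _SceneObject, size: int) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    dy = yy - obj.y
    dx = xx - obj.x
    ca, sa = np.cos(obj.angle), np.sin(obj.angle)
    u = dx * ca + dy * sa
    v = -dx * sa + dy * ca
    return (u / obj.major_px) ** 2 + (v / obj.minor_px) ** 2 <= 1.0


def _rasterize(spec: SceneSpec, objects: Sequence[_SceneObject],
               rng: Optional[np.random.Generator]) -> Tuple[np.ndarray, np.ndarray]:
    size = spec.image_size_px
    img = np.full((size, size), spec.intensity_bg, dtype=np.float64)

    # well border: dark wall with a faint bright inner rim
    c = size / 2.0
    half = spec.well_edge_px / 2.0
    yy, xx = np.mgrid[0:size, 0:size]
    cheb = np.maximum(np.abs(yy - c), np.abs(xx - c))
    wall = (cheb >= half - 1.0) & (cheb <= half + 1.5)
    rim = (cheb >= half - 3.0) & (cheb < half - 1.0)
    img[wall] = max(spec.intensity_bg - 0.25, 0.0)
    img[rim] = min(spec.intensity_bg + 0.08, 1.0)

    masks = np.zeros((len(objects), size, size), dtype=bool)
    for i, obj in enumerate(objects):
        mask = _object_mask(obj, size)
        masks[i] = mask
        if obj.kind == "bead":
            img[mask] = spec.intensity_fg
            dy = yy - obj.y
            dx = xx - obj.x
            rr = np.hypot(dy, dx)
            ring = mask & (np.abs(rr - 0.7 * obj.r_px) <= 1.0)
            img[ring] = np.minimum(img[ring] + 0.3, 1.0)
        else:
            # darker interior with a mild radial shading for internal features
            dy = yy - obj.y
            dx = xx - obj.x
            rad = np.hypot(dy, dx)[mask] / max(obj.major_px, 1e-9)
            img[mask] = spec.intensity_fg - 0.08 * (1.0 - rad ** 2)
        halo = ndi.binary_dilation(
            mask, structure=morphology.disk(_HALO_WIDTH_PX)) & ~mask
        img[halo] = np.minimum(img[halo] + spec.halo_strength, 1.0)

    if rng is not None and spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, img.shape)
    return np.clip(img, 0.0, 1.0), masks


def render_scene(spec: SceneSpec, seed: int) -> Tuple[np.ndarray, np.ndarray]:
    """Render one nanowell scene; deterministic in (spec, seed).

    Returns ``(image, masks)`` where ``masks`` has one boolean layer per
    object.  Raises :class:`PlacementError` if non-overlapping placement
    fails within the retry budget.
    """
    rng = as_rng(seed)
    objects = _sample_objects(spec, rng)
    return _rasterize(spec, objects, rng)


# ---------------------------------------------------------------------------
# defocus


def defocus_sigma(delta_z_um: float, model: DefocusModel) -> float:
    """Blur kernel scale in px: ``sigma_per_um * |delta_z|`` (even in Δz)."""
    return model.sigma_per_um * abs(float(delta_z_um))


def apply_defocus(image: np.ndarray, delta_z_um: float, model: DefocusModel,
                  seed=None, noise_sigma: float = 0.0) -> np.ndarray:
    """Degrade an image as if acquired ``delta_z_um`` away from focus.

    PSF blur of width :func:`defocus_sigma`, then contrast compression toward
    the image mean by ``contrast_decay_per_um * |Δz|`` (floored at
    ``min_contrast`` of the original contrast), then fresh additive Gaussian
    noise.  ``Δz = 0`` with ``noise_sigma = 0`` returns the input exactly.
    """
    img = np.asarray(image, dtype=np.float64)
    sigma = defocus_sigma(delta_z_um, model)
    if sigma > 0:
        if model.psf_family == "gaussian":
            radius = int(np.ceil(3.0 * sigma))
            if 2 * radius + 1 > min(img.shape):
                raise ValueError(
                    f"PSF kernel ({2 * radius + 1} px) larger than image "
                    f"{img.shape}")
            out = ndi.gaussian_filter(img, sigma, mode="reflect", truncate=3.0)
        else:
            radius = max(1, int(round(sigma)))
            if 2 * radius + 1 > min(img.shape):
                raise ValueError(
                    f"PSF kernel ({2 * radius + 1} px) larger than image "
                    f"{img.shape}")
            kernel = morphology.disk(radius).astype(np.float64)
            kernel /= kernel.sum()
            out = ndi.convolve(img, kernel, mode="reflect")
        contrast = max(1.0 - model.contrast_decay_per_um * abs(delta_z_um),
                       model.min_contrast)
        m = out.mean()
        out = m + (out - m) * contrast
    else:
        out = img.copy()
    if noise_sigma > 0:
        rng = as_rng(seed)
        out = out + rng.normal(0.0, noise_sigma, out.shape)
    return np.clip(out, 0.0, 1.0)


# ---------------------------------------------------------------------------
# paired datasets


def make_pair_dataset(spec: SceneSpec, model: DefocusModel, n_pairs: int,
                      identity_fraction: float = 0.25,
                      offsets_um: Sequence[float] = (10.0,),
                      seed: int = 0, val_fraction: float = 0.2) -> PairDataset:
    """Generate in-focus/OOF pairs with a fixed fraction of identity pairs.

    ``round(n_pairs * identity_fraction)`` pairs are exact in-focus copies
    (Δz = 0); the rest draw Δz uniformly from ``offsets_um x {-1, +1}``.
    Splits are assigned train/val by a seeded shuffle (default 4:1).
    """
    if n_pairs <= 0:
        raise ValueError("n_pairs must be positive")
    if not 0.0 <= identity_fraction < 1.0:
        raise ValueError("identity_fraction must lie in [0, 1)")
    if not offsets_um:
        raise ValueError("offsets_um must be non-empty")

    master = as_rng(seed)
    n_identity = int(round(n_pairs * identity_fraction))
    identity_idx = set(master.choice(n_pairs, size=n_identity, replace=False).tolist())
    n_train = int(np.ceil(n_pairs * (1.0 - val_fraction)))
    order = master.permutation(n_pairs)
    split_of = {int(i): ("train" if rank < n_train else "val")
                for rank, i in enumerate(order)}

    records, pairs = [], []
    offsets = np.asarray(offsets_um, dtype=np.float64)
    for i in range(n_pairs):
        pair_seed = subseed(seed, i)
        rng = as_rng(pair_seed)
        objects = _sample_objects(spec, rng)
        in_focus, masks = _rasterize(spec, objects, rng)
        if i in identity_idx:
            dz = 0.0
            oof = in_focus.copy()
            is_identity = True
        else:
            dz = float(rng.choice(offsets) * rng.choice((-1.0, 1.0)))
            oof = apply_defocus(in_focus, dz, model, rng,
                                noise_sigma=spec.noise_sigma)
            is_identity = False
        label = "oof" if (abs(dz) > 0 and not is_identity) else "in_focus"
        records.append(PairRecord(
            pair_id=f"pair_{i:05d}", delta_z_um=dz, is_identity=is_identity,
            focus_label=label, split=split_of[i], seed=pair_seed))
        pairs.append(FramePair(in_focus=in_focus, oof=oof, delta_z_um=dz,
                               is_identity=is_identity, masks=masks))
    return PairDataset(records=records, pairs=pairs)


def classifier_frames(dataset: PairDataset, ratio: Tuple[int, int] = (21, 20),
                      seed: int = 0) -> Tuple[np.ndarray, np.ndarray]:
    """Flatten a paired dataset into labelled classifier frames.

    Every degraded-slot image contributes with its focus label; in-focus
    partners are subsampled so the overall OOF:IF count approximates
    ``ratio`` (default 21:20, near-balanced).
    Returns ``(frames (N, H, W), labels (N,))`` with 1 = OOF.
    """
    rng = as_rng(seed)
    oof_imgs = [p.oof for p, r in zip(dataset.pairs, dataset.records)
                if r.focus_label == "oof"]
    if_imgs = [p.oof for p, r in zip(dataset.pairs, dataset.records)
               if r.focus_label == "in_focus"]
    extra_if = [p.in_focus for p, r in zip(dataset.pairs, dataset.records)
                if not r.is_identity]
    n_oof = len(oof_imgs)
    target_if = int(round(n_oof * ratio[1] / ratio[0])) if n_oof else len(if_imgs)
    need = max(0, target_if - len(if_imgs))
    if need and extra_if:
        take = rng.choice(len(extra_if), size=min(need, len(extra_if)),
                          replace=False)
        if_imgs = if_imgs + [extra_if[int(j)] for j in take]
    frames = np.stack(oof_imgs + if_imgs)
    labels = np.concatenate([np.ones(n_oof, dtype=np.int64),
                             np.zeros(len(if_imgs), dtype=np.int64)])
    perm = rng.permutation(len(labels))
    return frames[perm], labels[perm]


# ---------------------------------------------------------------------------
# videos


def _reflect(value: float, lo: float, hi: float) -> float:
    span = hi - lo
    if span <= 0:
        return lo
    v = (value - lo) % (2 * span)
    return lo + (v if v <= span else 2 * span - v)


def simulate_video(scene: SceneSpec, video: VideoSpec, model: DefocusModel,
                   seed: int) -> VideoSim:
    """Simulate a nanowell time lapse with intermittent defocus bursts.

    Cells perform a reflected random walk inside the well (per-frame steps
    clipped to 3x ``motion_step_px``); the axial trace is zero outside bursts
    and holds a constant drawn offset (±{burst_delta_z_um}) inside them.
    """
    rng = as_rng(seed)
    objects = _sample_objects(scene, rng)
    y0, y1, x0, x1 = _well_bounds(scene)

    z_trace = np.zeros(video.n_frames, dtype=np.float64)
    lo, hi = video.oof_burst_len_frames
    remaining = 0
    current_dz = 0.0
    for i in range(video.n_frames):
        if remaining == 0 and rng.random() < video.oof_event_rate:
            remaining = int(rng.integers(lo, hi + 1))
            current_dz = float(rng.choice(np.asarray(video.burst_delta_z_um))
                               * rng.choice((-1.0, 1.0)))
        if remaining > 0:
            z_trace[i] = current_dz
            remaining -= 1

    in_focus_frames = []
    observed_frames = []
    masks_per_frame = []
    step = video.motion_step_px
    for i in range(video.n_frames):
        if i > 0 and step > 0:
            for obj in objects:
                dy, dx = np.clip(rng.normal(0.0, step, 2), -3 * step, 3 * step)
                margin = obj.minor_px + 1
                obj.y = _reflect(obj.y + dy, y0 + margin, y1 - margin)
                obj.x = _reflect(obj.x + dx, x0 + margin, x1 - margin)
        frame, masks = _rasterize(scene, objects, rng)
        in_focus_frames.append(frame)
        masks_per_frame.append(masks)
        observed_frames.append(apply_defocus(frame, z_trace[i], model, rng,
                                             noise_sigma=scene.noise_sigma))
    return VideoSim(in_focus_frames=np.stack(in_focus_frames),
                    observed_frames=np.stack(observed_frames),
                    masks_per_frame=masks_per_frame,
                    z_trace=z_trace)


# ---------------------------------------------------------------------------
# disk round trip (16-bit TIFF + CSV manifest)

_MANIFEST_COLUMNS = ["pair_id", "in_focus_path", "oof_path", "delta_z_um",
                     "is_identity", "focus_label", "split", "seed", "masks_path"]


def quantize16(image: np.ndarray) -> np.ndarray:
    return np.round(np.clip(image, 0.0, 1.0) * 65535).astype(np.uint16)


def dequantize16(raw: np.ndarray) -> np.ndarray:
    return raw.astype(np.float64) / 65535.0


def write_dataset(dataset: PairDataset, out_dir) -> str:
    """Write 16-bit TIFF images plus ``manifest.csv``; returns the manifest path.

    Quantization to 16 bits is the only lossy step; a read-back of the written
    directory reproduces the quantized pixel data exactly.
    """
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    for rec, pair in zip(dataset.records, dataset.pairs):
        rec.in_focus_path = f"{rec.pair_id}_if.tif"
        rec.oof_path = f"{rec.pair_id}_oof.tif"
        rec.masks_path = f"{rec.pair_id}_masks.tif"
        tifffile.imwrite(os.path.join(out_dir, rec.in_focus_path),
                         quantize16(pair.in_focus), photometric='minisblack')
        tifffile.imwrite(os.path.join(out_dir, rec.oof_path),
                         quantize16(pair.oof), photometric='minisblack')
        masks = pair.masks.astype(np.uint8)
        if masks.size == 0:
            masks = np.zeros((1,) + pair.in_focus.shape, dtype=np.uint8)
        tifffile.imwrite(os.path.join(out_dir, rec.masks_path), masks,
                         photometric='minisblack')
    manifest_path = os.path.join(out_dir, "manifest.csv")
    if dataset.records:
        df = dataset.to_dataframe()[_MANIFEST_COLUMNS]
    else:
        df = pd.DataFrame(columns=_MANIFEST_COLUMNS)
    df.to_csv(manifest_path, index=False)
    return manifest_path


def _read_image(path: str) -> np.ndarray:
    if path.lower().endswith((".png", ".jpg", ".jpeg")):
        import imageio.v3 as iio
        raw = iio.imread(path)
        if raw.ndim == 3:
            raw = raw[..., 0]
        denom = 255.0 if raw.dtype == np.uint8 else 65535.0
        return raw.astype(np.float64) / denom
    raw = tifffile.imread(path)
    return dequantize16(raw) if raw.dtype == np.uint16 else raw.astype(np.float64)


def read_dataset(in_dir) -> PairDataset:
    """Load a written dataset, validating every manifest invariant.

    Raises :class:`DatasetValidationError` naming the offending record when a
    file is missing, a focus label disagrees with Δz, or an identity pair is
    not bit-identical at the stored quantization.
    """
    in_dir = os.fspath(in_dir)
    manifest_path = os.path.join(in_dir, "manifest.csv")
    if not os.path.exists(manifest_path):
        raise DatasetValidationError(f"missing manifest: {manifest_path}")
    df = pd.read_csv(manifest_path)
    records, pairs = [], []
    for _, row in df.iterrows():
        pid = str(row["pair_id"])
        for col in ("in_focus_path", "oof_path"):
            path = os.path.join(in_dir, str(row[col]))
            if not os.path.exists(path):
                raise DatasetValidationError(f"{pid}: missing file {path}")
        dz = float(row["delta_z_um"])
        is_identity = bool(row["is_identity"])
        label = str(row["focus_label"])
        expected = "oof" if (abs(dz) > 0 and not is_identity) else "in_focus"
        if label != expected:
            raise DatasetValidationError(
                f"{pid}: focus_label={label!r} inconsistent with "
                f"delta_z_um={dz} and is_identity={is_identity}")
        in_focus = _read_image(os.path.join(in_dir, str(row["in_focus_path"])))
        oof = _read_image(os.path.join(in_dir, str(row["oof_path"])))
        masks_path = str(row.get("masks_path", ""))
        if masks_path and os.path.exists(os.path.join(in_dir, masks_path)):
            masks = tifffile.imread(os.path.join(in_dir, masks_path)).astype(bool)
            if masks.ndim == 2:
                masks = masks[None]
            if not masks.any():
                masks = np.zeros((0,) + in_focus.shape, dtype=bool)
        else:
            masks = np.zeros((0,) + in_focus.shape, dtype=bool)
        if is_identity and not np.array_equal(in_focus, oof):
            raise DatasetValidationError(
                f"{pid}: flagged is_identity but images differ")
        records.append(PairRecord(
            pair_id=pid, delta_z_um=dz, is_identity=is_identity,
            focus_label=label, split=str(row["split"]), seed=int(row["seed"]),
            in_focus_path=str(row["in_focus_path"]),
            oof_path=str(row["oof_path"]), masks_path=masks_path))
        pairs.append(FramePair(in_focus=in_focus, oof=oof, delta_z_um=dz,
                               is_identity=is_identity, masks=masks))
    return PairDataset(records=records, pairs=pairs)
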