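"""CT volume I/O and preprocessing.

Pipeline: load a DICOM series or NIfTI file into Hounsfield units, resample to
(1, 1, 3) mm, segment the lungs (pluggable segmenter; rule-based default),
drop slices with less than 2% lung area, crop the union lung bounding box, and
resize/window each retained slice into a normalized fixed-size stack carrying
each slice's relative axial position (0 = most apical retained slice,
1 = most basal).

Axial convention: ``voxels[z, y, x]`` with index 0 the most superior slice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage
from skimage.transform import resize as _sk_resize

from . import _dicom

__all__ = [
    "CTVolume",
    "LungMask",
    "SliceStack",
    "AugmentConfig",
    "EmptyMaskWarning",
    "ThresholdLungSegmenter",
    "PassthroughSegmenter",
    "load_ct_volume",
    "save_nifti",
    "resample_volume",
    "resample_mask",
    "segment_lungs",
    "lung_fraction_per_slice",
    "filter_slices",
    "crop_roi",
    "resize_and_normalize",
    "augment_slice",
    "preprocess_volume",
]


class EmptyMaskWarning(UserWarning):
    """Raised as a warning when lung segmentation finds no lung-like component."""


@dataclass
class CTVolume:
    """3D scalar field in Hounsfield units.

    ``voxels`` has shape (nz, ny, nx); axial index 0 is the most superior
    retained slice. ``spacing`` is (x, y, z) in mm.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    patient_id: str = "anon"
    axial_order: str = "apex-first"

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise ValueError(f"voxel array must be 3D, got {self.voxels.ndim}D")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]


@dataclass
class LungMask:
    """Binary mask aligned voxel-for-voxel with a CTVolume."""

    mask: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.mask)
        if m.ndim != 3:
            raise ValueError("mask must be 3D")
        if not np.isin(m, (0, 1)).all():
            raise ValueError("mask values must be in {0, 1}")
        self.mask = m.astype(np.uint8)

    @property
    def is_empty(self) -> bool:
        return not self.mask.any()


@dataclass
class SliceStack:
    """Normalized fixed-size slices ready for the encoder."""

    slices: list[np.ndarray]
    relative_positions: np.ndarray
    source_indices: np.ndarray
    patient_id: str = "anon"

    def __post_init__(self):
        if len(self.slices) < 1:
            raise ValueError("need at least one slice")
        shapes = {s.shape for s in self.slices}
        if len(shapes) != 1:
            raise ValueError(f"all slices must share one shape, got {shapes}")
        self.relative_positions = np.asarray(self.relative_positions, dtype=np.float64)
        self.source_indices = np.asarray(self.source_indices, dtype=np.int64)
        rp = self.relative_positions
        if len(rp) != len(self.slices) or len(self.source_indices) != len(self.slices):
            raise ValueError("positions and indices must match slice count")
        if np.any(np.diff(rp) < 0):
            raise ValueError("relative positions must be nondecreasing")
        if len(rp) > 1 and (abs(rp[0]) > 1e-12 or abs(rp[-1] - 1) > 1e-12):
            raise ValueError("relative positions must span [0, 1] when R > 1")

    @property
    def R(self) -> int:
        return len(self.slices)


@dataclass(frozen=True)
class AugmentConfig:
    flip_probability: float = 0.5
    rotation_range_degrees: float = 20.0
    apply_probability: float = 0.2

    def __post_init__(self):
        for name in ("flip_probability", "apply_probability"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.rotation_range_degrees < 0:
            raise ValueError("rotation_range_degrees must be nonnegative")


# ---------------------------------------------------------------------------
# Loading and saving
# ---------------------------------------------------------------------------

def load_ct_volume(path: str | Path, format: str | None = None) -> CTVolume:
    """Read a DICOM series directory or a NIfTI file into Hounsfield units.

    Slices are sorted superior-first; rescale slope/intercept are applied;
    spacing is populated from metadata. A DICOM series with a gap in its
    z positions or inconsistent in-plane geometry raises.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if format is None:
        format = "dicom-series" if path.is_dir() else "nifti"
    if format == "nifti":
        return _load_nifti(path)
    if format == "dicom-series":
        return _load_dicom_series(path)
    raise ValueError(f"unknown format {format!r}; use 'dicom-series' or 'nifti'")


def _load_nifti(path: Path) -> CTVolume:
    img = nib.as_closest_canonical(nib.load(str(path)))
    sx, sy, sz = (float(z) for z in img.header.get_zooms()[:3])
    data = np.asarray(img.dataobj, dtype=np.float64)
    # canonical RAS: axis 2 ascends toward the head; flip to superior-first
    voxels = data.transpose(2, 1, 0)[::-1]
    pid = path.name.split(".")[0]
    return CTVolume(voxels=voxels, spacing=(sx, sy, sz), patient_id=pid)


def save_nifti(vol: CTVolume, path: str | Path) -> Path:
    """Inverse of :func:`_load_nifti`: round-trips voxels and spacing."""
    path = Path(path)
    data = vol.voxels[::-1].transpose(2, 1, 0)
    affine = np.diag([*vol.spacing, 1.0])
    nib.save(nib.Nifti1Image(data.astype(np.float32), affine), str(path))
    return path


def _load_dicom_series(path: Path) -> CTVolume:
    files = sorted(p for p in path.iterdir() if p.is_file() and not p.name.startswith("."))
    if not files:
        raise ValueError(f"{path}: no files in DICOM series directory")
    slices = [_dicom.read_dicom_slice(p) for p in files]

    shapes = {s.pixels.shape for s in slices}
    spacings = {s.pixel_spacing for s in slices}
    if len(shapes) != 1 or len(spacings) != 1:
        raise ValueError(f"{path}: inconsistent geometry across series "
                         f"(shapes {shapes}, pixel spacings {spacings})")

    slices.sort(key=lambda s: -s.z)  # superior (largest z) first
    zs = np.array([s.z for s in slices])
    if len(slices) > 1:
        gaps = -np.diff(zs)
        step = np.median(gaps)
        if step <= 0:
            raise ValueError(f"{path}: duplicate or non-monotone slice positions")
        bad = np.nonzero(np.abs(gaps - step) > 0.01 * step + 1e-6)[0]
        if len(bad):
            i = int(bad[0])
            raise ValueError(
                f"{path}: missing slice(s) between z={zs[i]:.3f} and z={zs[i+1]:.3f} "
                f"(gap {gaps[i]:.3f} mm, expected {step:.3f} mm)"
            )
        sz = float(step)
    else:
        sz = float(slices[0].slice_thickness)

    row_sp, col_sp = slices[0].pixel_spacing
    voxels = np.stack([s.hu for s in slices])
    return CTVolume(voxels=voxels, spacing=(float(col_sp), float(row_sp), sz),
                    patient_id=slices[0].patient_id)


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def _target_shape(shape, spacing, target) -> tuple[int, ...]:
    nz, ny, nx = shape
    sx, sy, sz = spacing
    tx, ty, tz = target
    return (int(round(nz * sz / tz)), int(round(ny * sy / ty)), int(round(nx * sx / tx)))


def resample_volume(vol: CTVolume, target_spacing=(1.0, 1.0, 3.0)) -> CTVolume:
    """Linearly interpolate onto the target grid; output shape per axis is
    round(physical extent / target spacing)."""
    if any(t <= 0 for t in target_spacing):
        raise ValueError(f"target spacing must be positive, got {target_spacing}")
    new_shape = _target_shape(vol.voxels.shape, vol.spacing, target_spacing)
    factors = [n / o for n, o in zip(new_shape, vol.voxels.shape)]
    out = ndimage.zoom(vol.voxels, factors, order=1, mode="nearest", grid_mode=True)
    return CTVolume(out, tuple(float(t) for t in target_spacing), vol.patient_id)


def resample_mask(mask: LungMask, spacing, target_spacing=(1.0, 1.0, 3.0)) -> LungMask:
    """Nearest-neighbour counterpart of :func:`resample_volume` for masks."""
    new_shape = _target_shape(mask.mask.shape, spacing, target_spacing)
    factors = [n / o for n, o in zip(new_shape, mask.mask.shape)]
    out = ndimage.zoom(mask.mask, factors, order=0, mode="nearest", grid_mode=True)
    return LungMask(out)


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------

class ThresholdLungSegmenter:
    """Rule-based default: threshold HU below `threshold`, discard components
    connected to the volume border (outside air), keep the two largest
    remaining 3D components, then morphological closing."""

    def __init__(self, threshold: float = -320.0, closing_iterations: int = 2):
        self.threshold = threshold
        self.closing_iterations = closing_iterations

    def __call__(self, vol: CTVolume) -> LungMask:
        air = vol.voxels < self.threshold
        labels, n = ndimage.label(air)
        if n == 0:
            return LungMask(np.zeros_like(air, dtype=np.uint8))
        border_labels = set()
        for axis in range(3):
            for face in (0, -1):
                border_labels |= set(np.unique(np.take(labels, face, axis=axis)))
        border_labels.discard(0)
        sizes = ndimage.sum_labels(air, labels, index=np.arange(1, n + 1))
        candidates = [(sz, lab) for lab, sz in zip(range(1, n + 1), sizes)
                      if lab not in border_labels and sz > 0]
        candidates.sort(reverse=True)
        keep = [lab for _, lab in candidates[:2]]
        mask = np.isin(labels, keep)
        if self.closing_iterations and mask.any():
            mask = ndimage.binary_closing(mask, iterations=self.closing_iterations)
        return LungMask(mask.astype(np.uint8))


class PassthroughSegmenter:
    """Returns a pre-computed mask (e.g. a phantom's ground truth)."""

    def __init__(self, mask: LungMask):
        self.mask = mask

    def __call__(self, vol: CTVolume) -> LungMask:
        if self.mask.mask.shape != vol.voxels.shape:
            raise ValueError("pass-through mask shape does not match the volume")
        return self.mask


def segment_lungs(vol: CTVolume, segmenter=None) -> LungMask:
    segmenter = segmenter or ThresholdLungSegmenter()
    mask = segmenter(vol)
    if mask.mask.shape != vol.voxels.shape:
        raise ValueError("segmenter returned a mask misaligned with the volume")
    if mask.is_empty:
        warnings.warn(
            f"no lung-like component found for patient {vol.patient_id!r}",
            EmptyMaskWarning, stacklevel=2,
        )
    return mask


# ---------------------------------------------------------------------------
# Slice selection and ROI
# ---------------------------------------------------------------------------

def lung_fraction_per_slice(mask: LungMask) -> np.ndarray:
    """Per-slice fraction of lung pixels over total pixels, in [0, 1]."""
    m = mask.mask
    return m.reshape(m.shape[0], -1).mean(axis=1)


def filter_slices(vol: CTVolume, mask: LungMask, min_fraction: float = 0.02,
                  mode: str = "all") -> list[int]:
    """Indices of retained slices: lung fraction >= min_fraction.

    ``mode='all'`` drops every sub-threshold slice; ``mode='trim_ends'`` drops
    only the apical/basal runs, keeping interior sub-threshold slices.
    """
    if vol.voxels.shape != mask.mask.shape:
        raise ValueError("volume and mask are not aligned")
    frac = lung_fraction_per_slice(mask)
    above = frac >= min_fraction
    if mode == "all":
        retained = np.nonzero(above)[0]
    elif mode == "trim_ends":
        idx = np.nonzero(above)[0]
        retained = np.arange(idx[0], idx[-1] + 1) if len(idx) else idx
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if len(retained) == 0:
        raise ValueError(
            f"no slices retained for patient {vol.patient_id!r} "
            f"(max lung fraction {frac.max():.4f} < {min_fraction})"
        )
    return retained.tolist()


def crop_roi(vol: CTVolume, mask: LungMask, retained: list[int]) -> CTVolume:
    """Drop non-retained slices and crop all of them to the union of per-slice
    lung bounding boxes (one in-plane box for the whole volume)."""
    retained = sorted(retained)
    if not retained:
        raise ValueError("retained slice set must be nonempty")
    sub = mask.mask[retained]
    if not sub.any():
        raise ValueError(f"mask is empty on all retained slices for {vol.patient_id!r}")
    rows = np.nonzero(sub.any(axis=(0, 2)))[0]
    cols = np.nonzero(sub.any(axis=(0, 1)))[0]
    r0, r1 = rows[0], rows[-1]
    c0, c1 = cols[0], cols[-1]
    cropped = vol.voxels[retained, r0 : r1 + 1, c0 : c1 + 1]
    return CTVolume(cropped, vol.spacing, vol.patient_id)


def resize_and_normalize(vol: CTVolume, out_size: int = 224,
                         hu_window: tuple[float, float] = (-1000.0, 400.0),
                         source_indices: list[int] | None = None) -> SliceStack:
    """Resize each slice to out_size x out_size (bilinear, aspect ratio not
    preserved), clip to the HU window and map linearly to [0, 1]. Relative
    positions are i / (R - 1) over retained order (0 when R = 1)."""
    if out_size < 8:
        raise ValueError(f"out_size must be >= 8, got {out_size}")
    lo, hi = hu_window
    if hi <= lo:
        raise ValueError("hu_window must satisfy low < high")
    r = vol.n_slices
    slices = []
    for i in range(r):
        s = vol.voxels[i]
        if s.shape != (out_size, out_size):
            s = _sk_resize(s, (out_size, out_size), order=1, mode="edge",
                           anti_aliasing=False, preserve_range=True)
        s = (np.clip(s, lo, hi) - lo) / (hi - lo)
        slices.append(s.astype(np.float64))
    positions = np.arange(r) / (r - 1) if r > 1 else np.zeros(1)
    src = np.asarray(source_indices) if source_indices is not None else np.arange(r)
    if len(src) != r:
        raise ValueError("source_indices length must match slice count")
    return SliceStack(slices=slices, relative_positions=positions,
                      source_indices=src, patient_id=vol.patient_id)


def augment_slice(slice_2d: np.ndarray, cfg: AugmentConfig,
                  rng: np.random.Generator) -> np.ndarray:
    """Training-time augmentation: with probability ``apply_probability`` the
    slice is (possibly) flipped and rotated by an angle drawn uniformly within
    the rotation range. Deterministic under a fixed rng state."""
    if rng.random() >= cfg.apply_probability:
        return slice_2d
    out = slice_2d
    if rng.random() < cfg.flip_probability:
        out = out[:, ::-1]
    angle = rng.uniform(-cfg.rotation_range_degrees, cfg.rotation_range_degrees)
    if angle != 0.0:
        out = ndimage.rotate(out, angle, reshape=False, order=1, mode="nearest")
    return np.ascontiguousarray(out)


# ---------------------------------------------------------------------------
# Pipeline convenience
# ---------------------------------------------------------------------------

def preprocess_volume(vol: CTVolume, *, segmenter=None,
                      target_spacing=(1.0, 1.0, 3.0), min_fraction: float = 0.02,
                      out_size: int = 224, hu_window=(-1000.0, 400.0),
                      filter_mode: str = "all") -> tuple[SliceStack, dict]:
    """Full deterministic pipeline from a raw HU volume to a SliceStack.

    Returns the stack plus a metadata dict (retained indices, per-slice lung
    fractions, bounding box, spacing) suitable for a JSON sidecar.
    """
    res = resample_volume(vol, target_spacing)
    mask = segment_lungs(res, segmenter)
    retained = filter_slices(res, mask, min_fraction, mode=filter_mode)
    fractions = lung_fraction_per_slice(mask)
    sub = mask.mask[retained]
    rows = np.nonzero(sub.any(axis=(0, 2)))[0]
    cols = np.nonzero(sub.any(axis=(0, 1)))[0]
    cropped = crop_roi(res, mask, retained)
    stack = resize_and_normalize(cropped, out_size=out_size, hu_window=hu_window,
                                 source_indices=retained)
    meta = {
        "patient_id": vol.patient_id,
        "retained_indices": list(map(int, retained)),
        "lung_fractions": [float(f) for f in fractions],
        "bounding_box": {"rows": [int(rows[0]), int(rows[-1])],
                         "cols": [int(cols[0]), int(cols[-1])]},
        "spacing": list(res.spacing),
        "out_size": out_size,
        "hu_window": list(hu_window),
    }
    return stack, meta
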