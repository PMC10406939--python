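"""Image/mask readers-writers and acquisition-side preprocessing.

2-D slices arrive as PNG/TIFF files, volumes as NIfTI; every slice is
resized to a square ``target_size`` (bilinear for images, nearest-neighbor
for masks, so masks stay binary) and intensity-normalized to [0, 255] by
percentile clip-and-rescale of the per-slice histogram (robust for CT/MRI;
full histogram equalization is available by flag).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np
from skimage import exposure, transform

from .errors import ConfigurationError, InputError

__all__ = ["PreprocessSpec", "load_image", "preprocess_slice", "load_and_preprocess",
           "write_outputs", "write_mask_png", "write_prob_png"]

_2D_SUFFIXES = {".png", ".tif", ".tiff", ".jpg", ".jpeg", ".bmp"}


@dataclass(frozen=True)
class PreprocessSpec:
    """Target geometry and intensity normalization for model input."""

    target_size: int = 256
    normalization: str = "percentile_rescale"  # | "hist_equalize" | "none"
    clip_percentiles: tuple[float, float] = (1.0, 99.0)
    slab_depth: int = 16  # axial chunking for volumes

    def validate(self, model_depth: int = 4) -> None:
        if self.target_size % (2 ** model_depth):
            raise ConfigurationError(
                f"target_size {self.target_size} not divisible by 2^{model_depth}"
            )
        if self.normalization not in ("percentile_rescale", "hist_equalize", "none"):
            raise ConfigurationError(f"unknown normalization {self.normalization!r}")
        lo, hi = self.clip_percentiles
        if not 0 <= lo < hi <= 100:
            raise ConfigurationError(f"bad clip_percentiles {self.clip_percentiles}")


def load_image(path) -> np.ndarray | list[np.ndarray]:
    """Read a 2-D image (one array) or a NIfTI volume (list of axial slices)."""
    p = Path(path)
    if not p.exists():
        raise InputError(f"no such file: {p}")
    suffix = "".join(p.suffixes[-2:]).lower()
    if suffix.endswith((".nii", ".nii.gz")):
        vol = np.asanyarray(nib.load(str(p)).dataobj).astype(np.float64)
        if vol.ndim != 3:
            raise InputError(f"expected a 3-D NIfTI volume in {p}, got ndim={vol.ndim}")
        return [vol[:, :, k] for k in range(vol.shape[2])]
    if p.suffix.lower() in _2D_SUFFIXES:
        img = iio.imread(p)
        if img.ndim == 3:  # RGB(A) -> luminance
            img = img[..., :3].mean(axis=-1)
        return img.astype(np.float64)
    raise InputError(f"unsupported image format: {p}")


def _normalize(img: np.ndarray, spec: PreprocessSpec) -> np.ndarray:
    if spec.normalization == "none":
        return np.clip(img, 0, 255)
    if spec.normalization == "hist_equalize":
        return exposure.equalize_hist(img) * 255.0
    lo, hi = np.percentile(img, spec.clip_percentiles)
    if hi <= lo:  # degenerate histogram (constant slice): map to mid-gray
        return np.full_like(img, 127.0)
    return (np.clip(img, lo, hi) - lo) / (hi - lo) * 255.0


def preprocess_slice(img: np.ndarray, spec: PreprocessSpec = PreprocessSpec(),
                     is_mask: bool = False) -> np.ndarray:
    """Resize + normalize one slice; masks use nearest-neighbor and stay {0,1}."""
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2:
        raise InputError(f"expected a 2-D slice, got shape {img.shape}")
    t = spec.target_size
    if is_mask:
        out = transform.resize(img, (t, t), order=0, preserve_range=True,
                               anti_aliasing=False)
        return (out > 0.5).astype(np.uint8)
    out = transform.resize(img, (t, t), order=1, preserve_range=True,
                           anti_aliasing=img.shape[0] > t)
    return np.clip(np.rint(_normalize(out, spec)), 0, 255).astype(np.uint8)


def load_and_preprocess(path, spec: PreprocessSpec = PreprocessSpec(),
                        is_mask: bool = False):
    """File -> preprocessed slice (2-D input) or list of slices (NIfTI)."""
    spec.validate()
    loaded = load_image(path)
    if isinstance(loaded, list):
        return [preprocess_slice(s, spec, is_mask=is_mask) for s in loaded]
    return preprocess_slice(loaded, spec, is_mask=is_mask)


def write_mask_png(mask: np.ndarray, path) -> Path:
    """Binary mask -> 8-bit PNG with foreground 255."""
    path = Path(path)
    iio.imwrite(path, (np.asarray(mask) > 0).astype(np.uint8) * 255)
    return path


def write_prob_png(prob: np.ndarray, path) -> Path:
    """Probability map -> 16-bit grayscale PNG, value = round(p * 65535)."""
    path = Path(path)
    data = np.clip(np.rint(np.asarray(prob, dtype=np.float64) * 65535), 0, 65535)
    iio.imwrite(path, data.astype(np.uint16))
    return path


def write_outputs(prob: np.ndarray, mask: np.ndarray, out_dir, stem: str = "output",
                  affine: np.ndarray | None = None) -> list[Path]:
    """Persist a probability map and its thresholded mask; returns paths.

    With ``affine`` given, the probability map is additionally written as a
    NIfTI carrying that affine unchanged.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / f".write_test_{stem}"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise InputError(f"output directory {out_dir} is not writable: {exc}") from exc
    paths = [
        write_prob_png(prob, out_dir / f"{stem}_prob.png"),
        write_mask_png(mask, out_dir / f"{stem}_mask.png"),
    ]
    if affine is not None:
        nii = nib.Nifti1Image(np.asarray(prob, dtype=np.float32), affine)
        nii_path = out_dir / f"{stem}_prob.nii.gz"
        nib.save(nii, str(nii_path))
        paths.append(nii_path)
    return paths
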