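"""Reading and writing cine sequences, masks and label maps.

NIfTI is the primary container (cardiac-MRI convention; time on the third
axis), with numbered PNG/TIFF stacks as a quick-inspection alternative.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np

from cineclust.phantom import CineSequence

_FRAME_EXTS = (".png", ".tif", ".tiff")
_PNG_SCALE = 65535  # 16-bit PNG quantization


def _is_nifti(path: Path) -> bool:
    return path.name.endswith(".nii") or path.name.endswith(".nii.gz")


def read_sequence(path: str | Path, normalize: bool = True) -> CineSequence:
    """Load a cine sequence from NIfTI or a directory of ordered frames.

    NIfTI volumes are interpreted as H x W x T; frame directories are read
    in lexicographic order.  Intensities are min-max normalized to [0, 1]
    unless ``normalize`` is False (then they must already lie in [0, 1]).
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir()
                       if p.suffix.lower() in _FRAME_EXTS)
        if not files:
            raise FileNotFoundError(f"no frames found in {path}")
        frames = []
        for f in files:
            raw = np.asarray(iio.imread(f))
            img = raw.astype(np.float64)
            if np.issubdtype(raw.dtype, np.integer):
                img /= np.iinfo(raw.dtype).max
            if img.ndim == 3:  # collapse RGB to luminance
                img = img.mean(axis=-1)
            frames.append(img)
        shapes = {f.shape for f in frames}
        if len(shapes) > 1:
            raise ValueError(f"mixed frame shapes in {path}: {sorted(shapes)}")
        data = np.stack(frames)
    elif _is_nifti(path):
        vol = np.asarray(nib.load(str(path)).get_fdata(), dtype=np.float64)
        if vol.ndim != 3:
            raise ValueError(f"{path}: expected a 3-D volume, got shape {vol.shape}")
        data = np.moveaxis(vol, 2, 0)  # H x W x T -> T x H x W
    else:
        raise FileNotFoundError(f"cannot read sequence from {path}: not a NIfTI "
                                "file or frame directory")
    if normalize:
        lo, hi = data.min(), data.max()
        data = (data - lo) / (hi - lo) if hi > lo else np.zeros_like(data)
    T = data.shape[0]
    return CineSequence(frames=np.clip(data, 0.0, 1.0),
                        frame_phase=np.arange(T) / T)


def write_sequence(seq: CineSequence, path: str | Path) -> Path:
    """Write a sequence as NIfTI (.nii/.nii.gz) or a 16-bit PNG stack."""
    path = Path(path)
    if _is_nifti(path):
        vol = np.moveaxis(seq.frames, 0, 2).astype(np.float32)
        affine = np.diag([seq.pixel_spacing, seq.pixel_spacing, 1.0, 1.0])
        path.parent.mkdir(parents=True, exist_ok=True)
        nib.save(nib.Nifti1Image(vol, affine), str(path))
    else:
        path.mkdir(parents=True, exist_ok=True)
        for t, frame in enumerate(seq.frames):
            img = np.round(frame * _PNG_SCALE).astype(np.uint16)
            iio.imwrite(path / f"frame_{t:03d}.png", img)
    return path


def write_mask_stack(masks: np.ndarray, path: str | Path) -> Path:
    """Write a (T, H, W) binary stack or (H, W) mask as NIfTI or PNG(s)."""
    path = Path(path)
    masks = np.asarray(masks)
    if _is_nifti(path):
        vol = masks.astype(np.uint8)
        if vol.ndim == 3:
            vol = np.moveaxis(vol, 0, 2)
        path.parent.mkdir(parents=True, exist_ok=True)
        nib.save(nib.Nifti1Image(vol, np.eye(4)), str(path))
    elif masks.ndim == 2:
        path.parent.mkdir(parents=True, exist_ok=True)
        iio.imwrite(path, (masks.astype(np.uint8) * 255))
    else:
        path.mkdir(parents=True, exist_ok=True)
        for t, m in enumerate(masks):
            iio.imwrite(path / f"mask_{t:03d}.png", m.astype(np.uint8) * 255)
    return path


def write_label_map(labels: np.ndarray, path: str | Path) -> Path:
    """Write an integer label map (noise -1 stored as 0, labels shifted +1)."""
    path = Path(path)
    labels = np.asarray(labels, dtype=np.int32)
    path.parent.mkdir(parents=True, exist_ok=True)
    if _is_nifti(path):
        nib.save(nib.Nifti1Image(labels, np.eye(4)), str(path))
    else:
        shifted = (labels + 1).astype(np.uint16)
        iio.imwrite(path, shifted)
    return path


def read_mask(path: str | Path) -> np.ndarray:
    """Read a binary mask (2-D image or 3-D NIfTI stack)."""
    path = Path(path)
    if _is_nifti(path):
        vol = np.asarray(nib.load(str(path)).get_fdata())
        if vol.ndim == 3:
            vol = np.moveaxis(vol, 2, 0)
        return vol > 0.5
    return np.asarray(iio.imread(path)) > 0


def write_flow(vectors: np.ndarray, path: str | Path) -> Path:
    """Write a (T-1, H, W, 2) flow field as a 4-D NIfTI volume."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    vol = np.moveaxis(vectors.astype(np.float32), 0, 2)  # H,W,(T-1),2
    nib.save(nib.Nifti1Image(vol, np.eye(4)), str(path))
    return path


def read_flow(path: str | Path) -> np.ndarray:
    vol = np.asarray(nib.load(str(Path(path))).get_fdata(), dtype=np.float64)
    return np.moveaxis(vol, 2, 0)
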