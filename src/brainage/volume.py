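"""Reading, writing and resampling of 3-D gray-matter-density volumes.

Volumes are NIfTI-1 images holding voxelwise gray-matter density (roughly in
[0, 1]); the native resolution produced by segmentation pipelines is
169x205x169 at 1 mm isotropic, and models consume 84x102x84 at 2 mm after
trilinear downsampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .nn.functional import resize_trilinear_np

NATIVE_SHAPE = (169, 205, 169)
MODEL_SHAPE = (84, 102, 84)


@dataclass
class VolumeGrid:
    """A 3-D scalar field with per-axis voxel spacing in millimetres."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    space: str = "unknown"

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3-D volume, got {self.data.ndim}-D")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite voxels")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"voxel spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


def read_volume(path) -> VolumeGrid:
    """Load a NIfTI-1 volume; intensities are passed through unchanged."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"expected 3-D volume, got {data.ndim}-D in {path}")
    data = data.astype(np.float32, copy=False)
    if not np.all(np.isfinite(data)):
        raise ValueError(f"volume {path} contains NaN/Inf voxels")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return VolumeGrid(data, spacing, space=str(path))


def write_volume(vol: VolumeGrid, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    affine = np.diag(list(vol.spacing) + [1.0])
    nib.save(nib.Nifti1Image(vol.data.astype(np.float32), affine), str(path))
    return path


def downsample_volume(vol: VolumeGrid, target_shape=MODEL_SHAPE) -> VolumeGrid:
    """Trilinear downsampling under the half-pixel-center convention.

    Only reduction is supported; spacing is rescaled so the physical field of
    view is preserved (169x205x169 @ 1 mm -> 84x102x84 @ ~2 mm).
    """
    target_shape = tuple(int(t) for t in target_shape)
    if any(t < 1 for t in target_shape):
        raise ValueError(f"target shape must be positive, got {target_shape}")
    if any(t > s for t, s in zip(target_shape, vol.shape)):
        raise ValueError(
            f"upsampling not supported: target {target_shape} exceeds source {vol.shape}")
    data = resize_trilinear_np(vol.data.astype(np.float64), target_shape).astype(np.float32)
    spacing = tuple(sp * s / t for sp, s, t in zip(vol.spacing, vol.shape, target_shape))
    return VolumeGrid(data, spacing, space=vol.space)
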