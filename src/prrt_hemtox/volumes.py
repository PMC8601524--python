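"""3D SUV volume container with voxel spacing and named organ/lesion masks.

The voxel intensity unit throughout is the standardized uptake value (SUV):
tissue activity concentration normalized to injected activity per body
weight.  Coordinates are 0-based voxel indices; physical position of a voxel
center is ``index * spacing`` in mm; volumes in mL are ``mm^3 / 1000``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["SUVVolume", "load_suv_volume", "load_mask"]


@dataclass
class SUVVolume:
    """A 3D scalar field of SUV values plus named boolean masks.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Non-negative SUV values.
    spacing : tuple of float
        Voxel edge lengths in mm, one per axis; all > 0.
    masks : dict of str -> bool ndarray
        Named voxel sets (e.g. ``"liver"``, ``"lesion_0"``) on the same grid.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    masks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D volume, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive lengths in mm, got {self.spacing}")
        if np.any(self.data < 0):
            raise ValueError("SUV values must be non-negative")
        for name, m in self.masks.items():
            m = np.asarray(m, dtype=bool)
            if m.shape != self.data.shape:
                raise ValueError(f"mask {name!r} shape {m.shape} does not match grid {self.data.shape}")
            self.masks[name] = m

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in mL."""
        return float(np.prod(self.spacing)) / 1000.0

    @property
    def affine(self) -> np.ndarray:
        return np.diag(list(self.spacing) + [1.0])

    def mask(self, name: str) -> np.ndarray:
        try:
            return self.masks[name]
        except KeyError:
            raise KeyError(f"no mask named {name!r}; available: {sorted(self.masks)}") from None

    def mask_volume_ml(self, name: str) -> float:
        return float(self.mask(name).sum()) * self.voxel_volume_ml

    def save_nifti(self, out_dir: str | os.PathLike, stem: str = "volume") -> dict[str, str]:
        """Write the volume and one mask file per structure; return path map."""
        os.makedirs(out_dir, exist_ok=True)
        paths: dict[str, str] = {}
        img = nib.Nifti1Image(self.data.astype(np.float32), self.affine)
        p = os.path.join(out_dir, f"{stem}.nii")
        nib.save(img, p)
        paths[stem] = p
        for name, m in self.masks.items():
            mp = os.path.join(out_dir, f"mask_{name}.nii")
            nib.save(nib.Nifti1Image(m.astype(np.uint8), self.affine), mp)
            paths[f"mask_{name}"] = mp
        return paths


def _spacing_from_img(img: nib.Nifti1Image) -> tuple[float, float, float]:
    zooms = img.header.get_zooms()[:3]
    return tuple(float(z) for z in zooms)


def load_suv_volume(path: str | os.PathLike, masks: dict[str, str | os.PathLike] | None = None) -> SUVVolume:
    """Read a NIfTI SUV volume (spacing from the header) plus optional mask files."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    vol = SUVVolume(data, _spacing_from_img(img))
    for name, mp in (masks or {}).items():
        vol.masks[name] = load_mask(mp, expected_shape=vol.shape)
    return vol


def load_mask(path: str | os.PathLike, expected_shape: tuple[int, ...] | None = None) -> np.ndarray:
    img = nib.load(str(path))
    m = np.asarray(img.dataobj) > 0
    if expected_shape is not None and m.shape != expected_shape:
        raise ValueError(f"mask {path} shape {m.shape} does not match volume shape {expected_shape}")
    return m
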