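"""In-memory containers for 4-D DWI data and 3-D scalar metric maps."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .scheme import GradientScheme

__all__ = ["DwiVolume", "ScalarMap", "affine_from_voxel_size", "voxel_sizes"]


def affine_from_voxel_size(voxel_size) -> np.ndarray:
    """RAS+ affine with the given voxel sizes and origin at voxel (0,0,0)."""
    vs = np.asarray(voxel_size, dtype=float)
    if vs.shape != (3,) or np.any(vs <= 0):
        raise ValueError("voxel_size must be three positive lengths (mm)")
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = vs
    return aff


def voxel_sizes(affine: np.ndarray) -> np.ndarray:
    """Voxel edge lengths in mm from an affine (norms of its columns)."""
    return np.linalg.norm(np.asarray(affine, dtype=float)[:3, :3], axis=0)


@dataclass
class DwiVolume:
    """4-D diffusion-weighted signal plus its scheme and geometry.

    ``data`` is (X, Y, Z, n_volumes), one 3-D volume per scheme entry.
    """

    data: np.ndarray
    scheme: GradientScheme
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("DWI data must be 4-D (X, Y, Z, volume)")
        if self.data.shape[3] != self.scheme.n_volumes:
            raise ValueError(
                f"data has {self.data.shape[3]} volumes but scheme expects "
                f"{self.scheme.n_volumes}"
            )
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def shape(self) -> tuple:
        return self.data.shape[:3]

    @property
    def voxel_size(self) -> np.ndarray:
        return voxel_sizes(self.affine)


@dataclass
class ScalarMap:
    """3-D metric map (FA, GFA or MD) with an explicit validity mask.

    Voxels where the metric is undefined (no signal, degenerate profile)
    are flagged in ``valid`` rather than stored as zeros — zero is a
    meaningful anisotropy value.
    """

    data: np.ndarray
    affine: np.ndarray
    name: str
    valid: np.ndarray = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("ScalarMap data must be 3-D")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if self.valid is None:
            self.valid = np.isfinite(self.data)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != self.data.shape:
                raise ValueError("valid mask must match data shape")

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def voxel_size(self) -> np.ndarray:
        return voxel_sizes(self.affine)
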