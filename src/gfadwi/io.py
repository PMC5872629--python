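"""NIfTI, FSL bval/bvec and JSON-sidecar readers/writers.

All on-disk formats are the field's plain standards: NIfTI-1 for
volumes, the FSL dialect for gradient tables (three rows of direction
components, one row of b-values), a JSON sidecar for ROI label tables.
Scalar-map validity is encoded as NaN in the NIfTI image and recovered
on load.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .roi import RoiMask
from .scheme import GradientScheme
from .volumes import DwiVolume, ScalarMap

__all__ = [
    "save_dwi",
    "load_dwi",
    "save_scalar_map",
    "load_scalar_map",
    "save_roi_mask",
    "load_roi_mask",
    "write_bval_bvec",
    "read_bval_bvec",
]


def write_bval_bvec(scheme: GradientScheme, bval_path, bvec_path) -> None:
    """Write a gradient table in FSL dialect (bvecs as three rows)."""
    np.savetxt(bval_path, scheme.bvalues[None, :], fmt="%.6g")
    np.savetxt(bvec_path, scheme.directions.T, fmt="%.10f")


def read_bval_bvec(bval_path, bvec_path) -> GradientScheme:
    bvals = np.loadtxt(bval_path).reshape(-1)
    bvecs = np.loadtxt(bvec_path)
    if bvecs.shape[0] == 3:
        bvecs = bvecs.T
    return GradientScheme(directions=bvecs, bvalues=bvals)


def save_dwi(volume: DwiVolume, nifti_path, bval_path=None, bvec_path=None) -> None:
    nifti_path = Path(nifti_path)
    nib.save(nib.Nifti1Image(volume.data.astype(np.float32), volume.affine), nifti_path)
    stem = nifti_path.name.removesuffix(".gz").removesuffix(".nii")
    if bval_path is None:
        bval_path = nifti_path.with_name(stem + ".bval")
    if bvec_path is None:
        bvec_path = nifti_path.with_name(stem + ".bvec")
    write_bval_bvec(volume.scheme, bval_path, bvec_path)


def load_dwi(nifti_path, bval_path=None, bvec_path=None) -> DwiVolume:
    nifti_path = Path(nifti_path)
    stem = nifti_path.name.removesuffix(".gz").removesuffix(".nii")
    if bval_path is None:
        bval_path = nifti_path.with_name(stem + ".bval")
    if bvec_path is None:
        bvec_path = nifti_path.with_name(stem + ".bvec")
    img = nib.load(nifti_path)
    scheme = read_bval_bvec(bval_path, bvec_path)
    return DwiVolume(data=np.asarray(img.dataobj, dtype=float), scheme=scheme, affine=img.affine)


def save_scalar_map(scalar_map: ScalarMap, path) -> None:
    """Invalid voxels are stored as NaN."""
    data = np.where(scalar_map.valid, scalar_map.data, np.nan).astype(np.float32)
    nib.save(nib.Nifti1Image(data, scalar_map.affine), path)


def load_scalar_map(path, name: str | None = None) -> ScalarMap:
    img = nib.load(path)
    data = np.asarray(img.dataobj, dtype=float)
    if name is None:
        name = Path(path).name.removesuffix(".gz").removesuffix(".nii")
    return ScalarMap(data=data, affine=img.affine, name=name, valid=np.isfinite(data))


def save_roi_mask(mask: RoiMask, nifti_path, sidecar_path=None) -> None:
    nifti_path = Path(nifti_path)
    nib.save(nib.Nifti1Image(mask.labels.astype(np.int16), mask.affine), nifti_path)
    if sidecar_path is None:
        stem = nifti_path.name.removesuffix(".gz").removesuffix(".nii")
        sidecar_path = nifti_path.with_name(stem + ".labels.json")
    Path(sidecar_path).write_text(json.dumps(mask.label_table, indent=2, sort_keys=True))


def load_roi_mask(nifti_path, sidecar_path=None) -> RoiMask:
    nifti_path = Path(nifti_path)
    if sidecar_path is None:
        stem = nifti_path.name.removesuffix(".gz").removesuffix(".nii")
        sidecar_path = nifti_path.with_name(stem + ".labels.json")
    img = nib.load(nifti_path)
    table = json.loads(Path(sidecar_path).read_text())
    return RoiMask(
        labels=np.asarray(img.dataobj).astype(np.int16),
        label_table={str(k): int(v) for k, v in table.items()},
        affine=img.affine,
    )
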