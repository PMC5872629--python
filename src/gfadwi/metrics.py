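"""Voxelwise diffusion metrics: ADC profiles, GFA, tensor fit, FA, MD.

The generalized fractional anisotropy (GFA) used here is the ratio of
the sample standard deviation to the root mean square of the per-axis
apparent diffusion coefficients,

    GFA = std(Psi) / rms(Psi)
        = sqrt( n_s * sum_i (Psi_i - <Psi>)^2 / ((n_s - 1) * sum_i Psi_i^2) ),

with Psi(u_i) = -ln(S_i / S0) / b_i the ADC along MPG axis u_i.  For a
nonnegative profile the ratio lies in [0, 1]: 0 for isotropic profiles,
1 when all diffusion concentrates on a single axis.  Unlike tensor FA it
is computed directly from the directional ADC profile, so it does not
collapse where fiber populations cross.

Tensor FA is computed from the eigenvalues of the log-linear
least-squares tensor fit via the standard closed form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .scheme import GradientScheme
from .volumes import DwiVolume, ScalarMap

__all__ = [
    "AdcProfile",
    "DiffusionTensor",
    "adc_profile",
    "gfa_from_adc_profile",
    "fit_tensor",
    "fa_from_eigenvalues",
    "mean_diffusivity",
    "metric_map",
]


@dataclass(frozen=True)
class AdcProfile:
    """Per-axis apparent diffusion coefficients of one voxel, mm^2/s."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1:
            raise ValueError("an ADC profile is a 1-D vector of per-axis ADCs")
        if not np.all(np.isfinite(values)):
            raise ValueError("ADC profile contains non-finite values")
        object.__setattr__(self, "values", values)

    @property
    def n_s(self) -> int:
        return self.values.shape[0]

    @property
    def mean(self) -> float:
        """<Psi>, the mean per-axis ADC."""
        return float(self.values.mean())


def adc_profile(signals, scheme: GradientScheme, clamp: bool = True) -> AdcProfile:
    """Per-axis ADCs of one voxel from its signal vector.

    Psi(u_i) = -ln(S_i / S0bar) / b_i, with S0bar the mean over all b0
    volumes.  With ``clamp`` (the default) negative ADCs — possible when
    magnitude noise pushes S_i above S0 — are clipped to zero, keeping
    the profile physical and GFA within [0, 1]; disable for raw
    comparisons against external implementations.
    """
    signals = np.asarray(signals, dtype=float)
    if signals.shape != (scheme.n_volumes,):
        raise ValueError("signals must have one entry per scheme volume")
    s0 = signals[scheme.b0_mask].mean()
    if not s0 > 0:
        raise ValueError("voxel undefined: mean b0 signal is not positive")
    dw = signals[scheme.dw_mask]
    if np.any(dw <= 0):
        raise ValueError("voxel undefined: nonpositive diffusion-weighted signal")
    psi = -np.log(dw / s0) / scheme.dw_bvalues
    if clamp:
        psi = np.maximum(psi, 0.0)
    return AdcProfile(values=psi)


def gfa_from_adc_profile(profile) -> float:
    """Generalized fractional anisotropy of an ADC profile.

    Accepts an :class:`AdcProfile` or a plain 1-D array.  Returns NaN
    for the degenerate all-zero profile (0/0), for which GFA is
    undefined.
    """
    psi = profile.values if isinstance(profile, AdcProfile) else np.asarray(profile, dtype=float)
    n = psi.shape[0]
    if n < 2:
        raise ValueError("GFA requires at least two axes")
    scale = float(np.max(np.abs(psi)))
    if scale == 0.0:
        return float("nan")
    psi = psi / scale  # GFA is scale-invariant; avoids under/overflow in squares
    ssq = float(np.sum(psi * psi))
    dev = float(np.sum((psi - psi.mean()) ** 2))
    return float(np.sqrt(n * dev / ((n - 1) * ssq)))


@dataclass(frozen=True)
class DiffusionTensor:
    """Symmetric 3x3 diffusion tensor with sorted eigensystem."""

    tensor: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.tensor, dtype=float)
        if t.shape != (3, 3):
            raise ValueError("tensor must be 3x3")
        if not np.allclose(t, t.T, atol=1e-12):
            raise ValueError("tensor must be symmetric")
        object.__setattr__(self, "tensor", (t + t.T) / 2.0)

    @property
    def eigenvalues(self) -> np.ndarray:
        """(λ1, λ2, λ3) sorted descending, mm^2/s."""
        return np.linalg.eigvalsh(self.tensor)[::-1]

    @property
    def eigenvectors(self) -> np.ndarray:
        """Unit eigenvectors as columns, ordered to match eigenvalues."""
        _, vecs = np.linalg.eigh(self.tensor)
        return vecs[:, ::-1]


def _design_matrix(scheme: GradientScheme) -> np.ndarray:
    g = scheme.dw_directions
    b = scheme.dw_bvalues[:, None]
    # unique tensor elements ordered (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz)
    return b * np.column_stack(
        [
            g[:, 0] ** 2,
            g[:, 1] ** 2,
            g[:, 2] ** 2,
            2 * g[:, 0] * g[:, 1],
            2 * g[:, 0] * g[:, 2],
            2 * g[:, 1] * g[:, 2],
        ]
    )


def _tensor_from_elements(d: np.ndarray) -> np.ndarray:
    dxx, dyy, dzz, dxy, dxz, dyz = d
    return np.array([[dxx, dxy, dxz], [dxy, dyy, dyz], [dxz, dyz, dzz]])


def fit_tensor(signals, scheme: GradientScheme) -> DiffusionTensor:
    """Ordinary log-linear least-squares tensor fit of one voxel.

    Solves ln(S_i / S0bar) = -b_i g_i^T D g_i for the six unique tensor
    elements.  Requires at least six non-collinear DW axes; a
    rank-deficient design matrix raises.
    """
    design = _design_matrix(scheme)
    if design.shape[0] < 6 or np.linalg.matrix_rank(design) < 6:
        raise ValueError("degenerate gradient scheme: tensor fit is rank-deficient")
    prof = adc_profile(signals, scheme, clamp=False)
    y = prof.values * scheme.dw_bvalues  # -ln(S/S0) per axis
    d, *_ = np.linalg.lstsq(design, y, rcond=None)
    return DiffusionTensor(tensor=_tensor_from_elements(d))


def fa_from_eigenvalues(l1: float, l2: float, l3: float) -> float:
    """Fractional anisotropy from sorted tensor eigenvalues.

    FA = sqrt(1/2) * sqrt((λ1-λ2)^2 + (λ2-λ3)^2 + (λ3-λ1)^2)
                   / sqrt(λ1^2 + λ2^2 + λ3^2);
    NaN for the all-zero (undefined) case.
    """
    if not (l1 >= l2 >= l3):
        raise ValueError("eigenvalues must be sorted: λ1 >= λ2 >= λ3")
    norm = l1 * l1 + l2 * l2 + l3 * l3
    if norm == 0.0:
        return float("nan")
    num = (l1 - l2) ** 2 + (l2 - l3) ** 2 + (l3 - l1) ** 2
    return float(np.sqrt(0.5 * num / norm))


def mean_diffusivity(l1: float, l2: float, l3: float) -> float:
    """MD = (λ1 + λ2 + λ3) / 3, mm^2/s."""
    return (l1 + l2 + l3) / 3.0


def _voxel_adcs(flat: np.ndarray, scheme: GradientScheme, clamp: bool):
    """Vectorized per-voxel ADC profiles; returns (psi, valid)."""
    s0 = flat[:, scheme.b0_mask].mean(axis=1)
    dw = flat[:, scheme.dw_mask]
    valid = (s0 > 0) & np.all(dw > 0, axis=1)
    psi = np.full(dw.shape, np.nan)
    if np.any(valid):
        with np.errstate(divide="ignore", invalid="ignore"):
            psi[valid] = -np.log(dw[valid] / s0[valid, None]) / scheme.dw_bvalues
        if clamp:
            psi[valid] = np.maximum(psi[valid], 0.0)
    return psi, valid


def metric_map(
    volume: DwiVolume,
    metric: str,
    mask: np.ndarray | None = None,
    clamp: bool = True,
) -> ScalarMap:
    """Voxelwise metric map over a DWI volume.

    Parameters
    ----------
    metric : {"FA", "GFA", "MD"}
        GFA applies :func:`gfa_from_adc_profile` to each voxel's ADC
        profile; FA and MD come from the log-linear tensor fit.
    mask : optional boolean array in the volume's grid; voxels outside
        it are flagged invalid in the returned map.

    Undefined voxels (no b0 signal, nonpositive DW signal, all-zero
    profile) are flagged in the map's validity mask, never written as
    zeros.
    """
    metric = metric.upper()
    if metric not in ("FA", "GFA", "MD"):
        raise ValueError(f"unknown metric {metric!r}")
    shape = volume.shape
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != shape:
            raise ValueError("mask geometry does not match the volume")

    flat = volume.data.reshape(-1, volume.scheme.n_volumes)
    sel = mask.ravel()
    psi, valid = _voxel_adcs(flat[sel], volume.scheme, clamp=clamp)

    out_sel = np.full(sel.sum(), np.nan)
    if metric == "GFA":
        n = volume.scheme.n_s
        ok = valid.copy()
        if np.any(valid):
            pv = psi[valid]
            ssq = np.einsum("vi,vi->v", pv, pv)
            dev = np.sum((pv - pv.mean(axis=1, keepdims=True)) ** 2, axis=1)
            good = ssq > 0
            vals = np.full(pv.shape[0], np.nan)
            vals[good] = np.sqrt(n * dev[good] / ((n - 1) * ssq[good]))
            out_sel[valid] = vals
            ok[valid] = good
        valid = ok
    else:
        design = _design_matrix(volume.scheme)
        if np.linalg.matrix_rank(design) < 6:
            raise ValueError("degenerate gradient scheme: tensor fit is rank-deficient")
        # unclamped log-signal fit, as in fit_tensor
        psi_fit, fit_valid = (psi, valid) if not clamp else _voxel_adcs(
            flat[sel], volume.scheme, clamp=False
        )
        valid = valid & fit_valid
        y = np.nan_to_num(psi_fit) * volume.scheme.dw_bvalues
        d = np.linalg.lstsq(design, y.T, rcond=None)[0].T  # (n_vox, 6)
        tensors = np.zeros((d.shape[0], 3, 3))
        tensors[:, 0, 0], tensors[:, 1, 1], tensors[:, 2, 2] = d[:, 0], d[:, 1], d[:, 2]
        tensors[:, 0, 1] = tensors[:, 1, 0] = d[:, 3]
        tensors[:, 0, 2] = tensors[:, 2, 0] = d[:, 4]
        tensors[:, 1, 2] = tensors[:, 2, 1] = d[:, 5]
        lam = np.linalg.eigvalsh(tensors)[:, ::-1]
        if metric == "MD":
            out_sel[valid] = lam[valid].mean(axis=1)
        else:
            norm = np.einsum("vi,vi->v", lam, lam)
            ok = valid & (norm > 0)
            num = (
                (lam[:, 0] - lam[:, 1]) ** 2
                + (lam[:, 1] - lam[:, 2]) ** 2
                + (lam[:, 2] - lam[:, 0]) ** 2
            )
            with np.errstate(divide="ignore", invalid="ignore"):
                out_sel[ok] = np.sqrt(0.5 * num[ok] / norm[ok])
            valid = ok

    data = np.full(shape, np.nan).ravel()
    vmask = np.zeros(sel.shape, dtype=bool)
    data[sel] = out_sel
    vmask[sel] = valid
    return ScalarMap(
        data=data.reshape(shape),
        affine=volume.affine,
        name=metric,
        valid=vmask.reshape(shape),
    )
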