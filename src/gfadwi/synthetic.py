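"""Multi-tensor DWI phantoms with known ground truth.

Each phantom voxel contains one or more Gaussian diffusion compartments
(single fibers, crossing fibers, isotropic media).  The forward model is
the standard multi-tensor signal equation

    S(g, b) = S0 * sum_k f_k * exp(-b * g^T D_k g),

with magnitude (Rician) noise added on top.  Four disjoint rectangular
ROI blocks stand in for the motor-area white-matter masks (lesioned and
nonlesioned BA4 and BA6); background voxels follow the free-water limit
(full signal at b0, fully attenuated under diffusion weighting).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .scheme import GradientScheme
from .volumes import DwiVolume, affine_from_voxel_size

__all__ = [
    "TensorSpec",
    "PhantomTruth",
    "ROI_NAMES",
    "tensor_signal",
    "add_rician_noise",
    "build_phantom",
    "default_blocks",
    "SINGLE_FIBER_EIGENVALUES",
]

ROI_NAMES = ("BA4_lesioned", "BA4_nonlesioned", "BA6_lesioned", "BA6_nonlesioned")

#: canonical healthy white-matter single-fiber diffusivities, mm^2/s
SINGLE_FIBER_EIGENVALUES = (1.7e-3, 0.2e-3, 0.2e-3)


def _orthonormal_frame(e1: np.ndarray) -> np.ndarray:
    """Deterministic right-handed frame whose first axis is ``e1``."""
    e1 = np.asarray(e1, dtype=float)
    e1 = e1 / np.linalg.norm(e1)
    # seed the Gram-Schmidt step with the world axis least aligned with e1
    seed = np.zeros(3)
    seed[np.argmin(np.abs(e1))] = 1.0
    e2 = seed - np.dot(seed, e1) * e1
    e2 /= np.linalg.norm(e2)
    e3 = np.cross(e1, e2)
    return np.column_stack([e1, e2, e3])


@dataclass(frozen=True)
class TensorSpec:
    """One Gaussian diffusion compartment of a voxel.

    Parameters
    ----------
    eigenvalues : (λ1, λ2, λ3) in mm^2/s, sorted descending, nonnegative.
    principal_direction : unit 3-vector of the λ1 eigenvector.
    fraction : volume fraction of this compartment (compartments of one
        voxel must sum to 1).
    """

    eigenvalues: tuple
    principal_direction: tuple = (1.0, 0.0, 0.0)
    fraction: float = 1.0

    def __post_init__(self) -> None:
        lam = tuple(float(v) for v in self.eigenvalues)
        if len(lam) != 3:
            raise ValueError("eigenvalues must be a triple (λ1, λ2, λ3)")
        if not (lam[0] >= lam[1] >= lam[2] >= 0.0):
            raise ValueError("eigenvalues must satisfy λ1 >= λ2 >= λ3 >= 0")
        if self.fraction < 0:
            raise ValueError("fraction must be nonnegative")
        d = np.asarray(self.principal_direction, dtype=float)
        n = np.linalg.norm(d)
        if n == 0:
            raise ValueError("principal_direction must be nonzero")
        object.__setattr__(self, "eigenvalues", lam)
        object.__setattr__(self, "principal_direction", tuple(d / n))

    @property
    def tensor(self) -> np.ndarray:
        """The 3x3 symmetric diffusion tensor in mm^2/s."""
        frame = _orthonormal_frame(np.asarray(self.principal_direction))
        return frame @ np.diag(self.eigenvalues) @ frame.T


def _as_compartments(spec) -> list:
    specs = [spec] if isinstance(spec, TensorSpec) else list(spec)
    if not specs:
        raise ValueError("at least one tensor compartment required")
    total = sum(s.fraction for s in specs)
    if abs(total - 1.0) > 1e-12:
        raise ValueError(f"compartment fractions must sum to 1 (got {total})")
    return specs


def tensor_signal(spec, scheme: GradientScheme, S0: float) -> np.ndarray:
    """Noise-free multi-tensor signal for every volume of ``scheme``.

    ``spec`` is a :class:`TensorSpec` or a sequence of them (fractions
    summing to 1).  b0 volumes return ``S0`` exactly.
    """
    if S0 <= 0:
        raise ValueError("S0 must be positive")
    specs = _as_compartments(spec)
    g = scheme.directions  # (V, 3); zero rows for b0 give exponent 0
    b = scheme.bvalues
    signal = np.zeros(scheme.n_volumes)
    for s in specs:
        adc = np.einsum("vi,ij,vj->v", g, s.tensor, g)
        signal += s.fraction * np.exp(-b * adc)
    return S0 * signal


def add_rician_noise(signals, sigma: float, seed=None) -> np.ndarray:
    """Magnitude-MRI noise: sqrt((s + n1)^2 + n2^2), n1, n2 ~ N(0, sigma).

    ``sigma = 0`` returns the input unchanged.  ``seed`` may be an int or
    a ``numpy.random.Generator``; a fixed seed reproduces the noise.
    """
    signals = np.asarray(signals, dtype=float)
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    if sigma == 0:
        return signals.copy()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n1 = rng.normal(0.0, sigma, size=signals.shape)
    n2 = rng.normal(0.0, sigma, size=signals.shape)
    return np.sqrt((signals + n1) ** 2 + n2**2)


@dataclass
class PhantomTruth:
    """Ground truth of a simulated volume.

    ``models`` maps each ROI name to its tensor compartments; ``labels``
    is the integer ROI volume (0 = background) with ``label_table``
    naming the nonzero labels.
    """

    models: dict
    labels: np.ndarray
    label_table: dict
    S0: float
    sigma: float
    affine: np.ndarray


def default_blocks(shape) -> dict:
    """Four disjoint rectangular ROI blocks spanning the volume interior.

    Blocks are laid out in the four XY quadrants with a one-voxel margin,
    covering all slices: single fibers along x and y in the two BA4
    blocks, a two-fiber perpendicular crossing in lesioned BA6 and an
    oblique single fiber in nonlesioned BA6.
    """
    nx, ny, nz = shape
    if nx < 8 or ny < 8 or nz < 1:
        raise ValueError("shape must be at least 8 x 8 x 1 to fit the four ROI blocks")
    mx, my = nx // 2, ny // 2
    lam = SINGLE_FIBER_EIGENVALUES
    crossing = (
        TensorSpec(lam, principal_direction=(1, 0, 0), fraction=0.5),
        TensorSpec(lam, principal_direction=(0, 1, 0), fraction=0.5),
    )
    oblique = TensorSpec(lam, principal_direction=(1, 1, 0))
    return {
        "BA4_lesioned": {
            "slices": (slice(1, mx - 1), slice(1, my - 1), slice(0, nz)),
            "model": TensorSpec(lam, principal_direction=(1, 0, 0)),
        },
        "BA4_nonlesioned": {
            "slices": (slice(mx + 1, nx - 1), slice(1, my - 1), slice(0, nz)),
            "model": TensorSpec(lam, principal_direction=(0, 1, 0)),
        },
        "BA6_lesioned": {
            "slices": (slice(1, mx - 1), slice(my + 1, ny - 1), slice(0, nz)),
            "model": crossing,
        },
        "BA6_nonlesioned": {
            "slices": (slice(mx + 1, nx - 1), slice(my + 1, ny - 1), slice(0, nz)),
            "model": oblique,
        },
    }


def build_phantom(
    shape,
    scheme: GradientScheme,
    blocks: dict | None = None,
    S0: float = 1000.0,
    sigma: float = 0.0,
    seed=None,
    voxel_size=(0.9, 0.9, 5.0),
):
    """Simulate a DWI volume with block-wise tensor ground truth.

    Parameters
    ----------
    shape : (nx, ny, nz) voxel grid.
    blocks : mapping ``name -> {"slices": 3-tuple of slices, "model":
        TensorSpec or sequence}``; ``None`` uses :func:`default_blocks`.
        An empty dict gives an all-background phantom.  Overlapping
        blocks are rejected.
    sigma : Rician noise level in signal units (0 = noiseless).
    voxel_size : anisotropic voxel edge lengths in mm, recorded in the
        affine (default 0.9 x 0.9 x 5 mm, a 5 mm slice protocol).

    Returns
    -------
    (DwiVolume, PhantomTruth)
    """
    if blocks is None:
        blocks = default_blocks(shape)
    affine = affine_from_voxel_size(voxel_size)

    labels = np.zeros(shape, dtype=np.int16)
    label_table = {}
    models = {}
    for idx, (name, spec) in enumerate(sorted(blocks.items()), start=1):
        region = spec["slices"]
        if np.any(labels[region] != 0):
            raise ValueError(f"ROI block {name!r} overlaps a previously placed block")
        labels[region] = idx
        label_table[name] = idx
        models[name] = _as_compartments(spec["model"])

    data = np.zeros(shape + (scheme.n_volumes,))
    # free-water background: full signal at b0, none under diffusion weighting
    data[..., scheme.b0_mask] = S0
    data[..., scheme.dw_mask] = 0.0
    for name, idx in label_table.items():
        data[labels == idx] = tensor_signal(models[name], scheme, S0)
    noisy = add_rician_noise(data, sigma, seed=seed)

    truth = PhantomTruth(
        models=models,
        labels=labels,
        label_table=label_table,
        S0=float(S0),
        sigma=float(sigma),
        affine=affine,
    )
    return DwiVolume(data=noisy, scheme=scheme, affine=affine), truth
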