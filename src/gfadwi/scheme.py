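"""Diffusion gradient schemes.

A scheme is the list of motion-probing-gradient (MPG) directions and
b-values describing one DWI acquisition.  The clinical protocol emulated
throughout this package is a 21-axis, b = 1000 s/mm^2 spin-echo EPI
acquisition with a single unweighted (b0) reference volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GradientScheme", "make_scheme", "fibonacci_sphere"]

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


@dataclass(frozen=True)
class GradientScheme:
    """Per-volume gradient directions and diffusion weightings.

    Parameters
    ----------
    directions : (n_volumes, 3) array
        Unit gradient vectors; rows for b0 volumes are zero.
    bvalues : (n_volumes,) array
        Diffusion weighting per volume in s/mm^2.  Volumes with
        ``bvalue == 0`` are b0 reference volumes; at least one must exist.
    """

    directions: np.ndarray
    bvalues: np.ndarray

    def __post_init__(self) -> None:
        directions = np.asarray(self.directions, dtype=float)
        bvalues = np.asarray(self.bvalues, dtype=float)
        if directions.ndim != 2 or directions.shape[1] != 3:
            raise ValueError("directions must be an (n_volumes, 3) array")
        if bvalues.shape != (directions.shape[0],):
            raise ValueError("bvalues must have one entry per volume")
        if not np.any(bvalues == 0):
            raise ValueError("scheme must contain at least one b0 volume")
        dw = bvalues > 0
        norms = np.linalg.norm(directions[dw], axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("diffusion-weighted directions must be unit vectors")
        object.__setattr__(self, "directions", directions)
        object.__setattr__(self, "bvalues", bvalues)

    @property
    def n_volumes(self) -> int:
        return self.bvalues.shape[0]

    @property
    def b0_mask(self) -> np.ndarray:
        """Boolean mask over volumes, True for b0 volumes."""
        return self.bvalues == 0

    @property
    def dw_mask(self) -> np.ndarray:
        """Boolean mask over volumes, True for diffusion-weighted volumes."""
        return self.bvalues > 0

    @property
    def n_s(self) -> int:
        """Number of MPG axes (diffusion-weighted volumes)."""
        return int(np.count_nonzero(self.dw_mask))

    @property
    def dw_directions(self) -> np.ndarray:
        return self.directions[self.dw_mask]

    @property
    def dw_bvalues(self) -> np.ndarray:
        return self.bvalues[self.dw_mask]


def fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform layout of ``n`` unit vectors.

    Golden-angle spiral over the full sphere; reproducible and close to
    the electrostatic-repulsion layouts scanners use.
    """
    i = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = i * _GOLDEN_ANGLE
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    pts = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    # exact renormalization guards against rounding at the poles
    return pts / np.linalg.norm(pts, axis=1, keepdims=True)


def icosahedral_directions() -> np.ndarray:
    """The six non-antipodal icosahedron vertices.

    The classical minimal DTI scheme: exactly determines the six tensor
    elements with the best possible conditioning for six axes.
    """
    p = (1.0 + np.sqrt(5.0)) / 2.0
    pts = np.array(
        [[0, 1, p], [0, 1, -p], [1, p, 0], [1, -p, 0], [p, 0, 1], [-p, 0, 1]],
        dtype=float,
    )
    return pts / np.linalg.norm(pts, axis=1, keepdims=True)


def make_scheme(n_directions: int, b: float = 1000.0) -> GradientScheme:
    """Build an acquisition scheme of ``n_directions`` DW axes plus one b0.

    Parameters
    ----------
    n_directions : int
        Number of MPG axes; at least 6 (a diffusion tensor has six free
        elements, so fewer directions leave the fit underdetermined).
    b : float
        Diffusion weighting in s/mm^2 applied to every DW volume.

    Returns
    -------
    GradientScheme
        ``n_directions + 1`` volumes: the b0 first, then the DW axes on a
        deterministic quasi-uniform sphere layout (golden-angle spiral;
        for the minimal six-axis case the icosahedral vertex scheme,
        since the six-point spiral is degenerate for a tensor fit).
    """
    if n_directions < 6:
        raise ValueError(
            f"n_directions must be >= 6 (got {n_directions}): "
            "the tensor fit is underdetermined below six axes"
        )
    if b <= 0:
        raise ValueError("b must be positive")
    layout = icosahedral_directions() if n_directions == 6 else fibonacci_sphere(n_directions)
    dirs = np.vstack([np.zeros(3), layout])
    bvals = np.concatenate([[0.0], np.full(n_directions, float(b))])
    return GradientScheme(directions=dirs, bvalues=bvals)
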