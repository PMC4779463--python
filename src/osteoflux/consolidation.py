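"""Closed-form 1D consolidation (Terzaghi) reference solution.

Verification oracle for the transient Biot solver: a saturated column under
a suddenly applied constant axial stress, drained at one end and sealed at
the other, develops the classic pore-pressure diffusion profile

    p(z, t) = p0 * sum_m  4 / ((2m+1) pi) * sin((2m+1) pi z / (2H))
                           * exp(-(2m+1)^2 pi^2 / 4 * c t / H^2)

with ``z`` the distance from the drained end, ``p0`` the undrained
(Skempton-type) initial pressure and ``c`` the consolidation coefficient.
For a compressible-constituent Biot material under uniaxial strain,

    p0 = alpha M / (K_v + alpha^2 M) * sigma0,      K_v = lambda + 2 G,
    c  = (kappa/mu) * M K_v / (K_v + alpha^2 M).

Used only in tests and verification studies.
"""

from __future__ import annotations

import numpy as np

from .materials import PoroelasticMaterial

__all__ = [
    "loading_efficiency",
    "consolidation_coefficient",
    "terzaghi_reference",
]


def _confined_modulus(material: PoroelasticMaterial) -> float:
    return material.lam + 2.0 * material.G


def loading_efficiency(material: PoroelasticMaterial) -> float:
    """Undrained pore-pressure build-up per unit applied axial stress."""
    kv = _confined_modulus(material)
    am = material.alpha * material.M
    return am / (kv + material.alpha * am)


def consolidation_coefficient(material: PoroelasticMaterial) -> float:
    """Diffusivity c of the uniaxial consolidation equation, mm^2/s."""
    kv = _confined_modulus(material)
    a2m = material.alpha**2 * material.M
    return material.mobility * material.M * kv / (kv + a2m)


def terzaghi_reference(
    column_height: float,
    material: PoroelasticMaterial,
    applied_stress: float,
    times: np.ndarray,
    z: np.ndarray | None = None,
    n_terms: int = 200,
) -> tuple[np.ndarray, np.ndarray]:
    """Pore-pressure profiles of the step-loaded consolidation column.

    Parameters
    ----------
    column_height : drainage path length H, mm (drained end at z = 0,
        impermeable end at z = H).
    applied_stress : magnitude of the suddenly applied axial stress, N/mm^2.
    times : evaluation times, s.
    z : distances from the drained end (default: 101 uniform points).
    n_terms : series truncation.

    Returns
    -------
    z : (nz,) evaluation points.
    p : (nt, nz) pore pressure, N/mm^2.
    """
    if z is None:
        z = np.linspace(0.0, column_height, 101)
    z = np.asarray(z, dtype=float)
    times = np.atleast_1d(np.asarray(times, dtype=float))
    p0 = loading_efficiency(material) * applied_stress
    c = consolidation_coefficient(material)
    m = np.arange(n_terms)
    lam = (2 * m + 1) * np.pi / 2.0  # (n_terms,)
    zz = np.sin(np.outer(lam, z / column_height))  # (n_terms, nz)
    tv = c * times / column_height**2  # (nt,)
    decay = np.exp(-np.outer(tv, lam**2))  # (nt, n_terms)
    coef = 4.0 / ((2 * m + 1) * np.pi)
    p = p0 * np.einsum("tm,m,mz->tz", decay, coef, zz)
    return z, p
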