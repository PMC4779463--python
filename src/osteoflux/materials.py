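"""Poroelastic and elastic material definitions for trabecular bone.

Bone tissue is treated as a fluid-saturated isotropic Biot medium: a drained
elastic skeleton (``E``, ``nu``) with compressible solid grains (``K_s``) and
pore fluid (``K_f``), porosity ``phi``, and Darcy transport governed by the
mobility ``kappa / mu``.  The effective-stress coefficient and storage modulus
follow the standard relations

    alpha = 1 - K / K_s,        1 / M = phi / K_f + (alpha - phi) / K_s.

Unit system: N, mm, s (stresses and moduli in N/mm^2 = MPa).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "PoroelasticMaterial",
    "ElasticMaterial",
    "bone_poroelastic",
    "derived_coefficients",
]


@dataclass(frozen=True)
class ElasticMaterial:
    """Linear isotropic elastic material (used for the bone plates)."""

    E: float  # Young's modulus, N/mm^2
    nu: float  # Poisson's ratio

    def __post_init__(self) -> None:
        if self.E <= 0:
            raise ValueError(f"Young's modulus must be positive, got {self.E}")
        if not 0 < self.nu < 0.5:
            raise ValueError(f"Poisson's ratio must lie in (0, 0.5), got {self.nu}")

    @property
    def G(self) -> float:
        """Shear modulus, N/mm^2."""
        return self.E / (2.0 * (1.0 + self.nu))

    @property
    def K(self) -> float:
        """Bulk modulus, N/mm^2."""
        return self.E / (3.0 * (1.0 - 2.0 * self.nu))

    @property
    def lam(self) -> float:
        """Lame's first parameter, N/mm^2."""
        return self.E * self.nu / ((1.0 + self.nu) * (1.0 - 2.0 * self.nu))


@dataclass(frozen=True)
class PoroelasticMaterial:
    """Fluid-saturated isotropic Biot material.

    Parameters
    ----------
    E, nu : drained Young's modulus (N/mm^2) and Poisson's ratio.
    K_s, K_f : solid-matrix and fluid bulk moduli, N/mm^2.
    phi : pore volume fraction (porosity).
    kappa : intrinsic permeability, mm^2.
    mu : pore fluid dynamic viscosity, N s/mm^2.
    gamma_f : fluid specific weight, N/mm^3 (only relevant for head-driven
        formulations; mechanical loading alone does not use it).
    """

    E: float
    nu: float
    K_s: float
    K_f: float
    phi: float
    kappa: float
    mu: float
    gamma_f: float = 9.8e-6

    def __post_init__(self) -> None:
        if self.E <= 0 or self.K_s <= 0 or self.K_f <= 0:
            raise ValueError("all moduli must be strictly positive")
        if not 0 < self.nu < 0.5:
            raise ValueError(f"Poisson's ratio must lie in (0, 0.5), got {self.nu}")
        if not 0 < self.phi < 1:
            raise ValueError(f"porosity must lie in (0, 1), got {self.phi}")
        if self.kappa <= 0 or self.mu <= 0 or self.gamma_f <= 0:
            raise ValueError("kappa, mu and gamma_f must be strictly positive")
        if self.K >= self.K_s:
            raise ValueError(
                "drained bulk modulus K >= solid bulk modulus K_s gives a "
                "non-positive Biot coefficient; unphysical for this model"
            )

    # ---- derived elastic constants -------------------------------------
    @property
    def G(self) -> float:
        """Drained shear modulus, N/mm^2."""
        return self.E / (2.0 * (1.0 + self.nu))

    @property
    def K(self) -> float:
        """Drained bulk modulus, N/mm^2."""
        return self.E / (3.0 * (1.0 - 2.0 * self.nu))

    @property
    def lam(self) -> float:
        """Drained Lame's first parameter, N/mm^2."""
        return self.E * self.nu / ((1.0 + self.nu) * (1.0 - 2.0 * self.nu))

    # ---- derived Biot constants ----------------------------------------
    @property
    def alpha(self) -> float:
        """Biot effective-stress coefficient, dimensionless."""
        return 1.0 - self.K / self.K_s

    @property
    def M(self) -> float:
        """Biot storage modulus, N/mm^2 (1/M = phi/K_f + (alpha - phi)/K_s)."""
        inv = self.phi / self.K_f + (self.alpha - self.phi) / self.K_s
        return 1.0 / inv

    @property
    def mobility(self) -> float:
        """Darcy mobility kappa/mu, mm^4 / (N s)."""
        return self.kappa / self.mu

    def drained(self) -> ElasticMaterial:
        """The drained elastic skeleton as a plain elastic material."""
        return ElasticMaterial(E=self.E, nu=self.nu)

    def with_mobility(self, mobility: float) -> "PoroelasticMaterial":
        """Copy of this material with ``kappa`` set so kappa/mu == mobility."""
        return replace(self, kappa=mobility * self.mu)


def derived_coefficients(material: PoroelasticMaterial) -> tuple[float, float, float, float]:
    """Return the derived constants (G, K, alpha, M) of a Biot material."""
    return material.G, material.K, material.alpha, material.M


#: Trabecular bone constants: E = 18 kN/mm^2, nu = 0.3, compressible
#: constituents (K_s = 20, K_f = 2.3 kN/mm^2), 5 % porosity, salt-water-like
#: fluid (mu = 1e-9 N s/mm^2, gamma_f = 9.8e-6 N/mm^3).
BONE_E = 18_000.0
BONE_NU = 0.3
BONE_KS = 20_000.0
BONE_KF = 2_300.0
BONE_PHI = 0.05
BONE_MU = 1.0e-9
BONE_GAMMA_F = 9.8e-6

#: Intrinsic permeability of the lacunar-canalicular network quoted in the
#: literature: 1e-20 m^2 = 1e-14 mm^2.
KAPPA_INTRINSIC = 1.0e-14
#: The same number read as a soil-mechanics hydraulic conductivity (mm/s),
#: converted back to an intrinsic permeability kappa = k * mu / gamma_f.
#: See docs/methods.md: only this reading makes the surface-remodelling loop
#: self-limiting, and it is therefore the remodelling default.
KAPPA_CONDUCTIVITY_READING = 1.0e-14 * BONE_MU / BONE_GAMMA_F


def bone_poroelastic(permeability_reading: str = "conductivity") -> PoroelasticMaterial:
    """Trabecular bone as a Biot material with the literature constants.

    Parameters
    ----------
    permeability_reading : {"conductivity", "intrinsic"}
        How the quoted permeability of 1e-20 m^2 enters Darcy's law.
        ``"intrinsic"`` uses kappa = 1e-14 mm^2 directly (mobility
        kappa/mu = 1e-5 mm^4/(N s)); ``"conductivity"`` treats the printed
        value as a hydraulic conductivity in mm/s, giving
        kappa = k mu / gamma_f (mobility ~1.02e-9 mm^4/(N s)).  The latter
        places the load pulse in the short-drainage-boundary-layer regime in
        which surface fluid velocity decreases as the strut thickens, which
        is the regime in which flow-driven surface adaptation is stable.
    """
    if permeability_reading == "intrinsic":
        kappa = KAPPA_INTRINSIC
    elif permeability_reading == "conductivity":
        kappa = KAPPA_CONDUCTIVITY_READING
    else:
        raise ValueError(
            f"unknown permeability_reading {permeability_reading!r}; "
            "expected 'conductivity' or 'intrinsic'"
        )
    return PoroelasticMaterial(
        E=BONE_E,
        nu=BONE_NU,
        K_s=BONE_KS,
        K_f=BONE_KF,
        phi=BONE_PHI,
        kappa=kappa,
        mu=BONE_MU,
        gamma_f=BONE_GAMMA_F,
    )
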