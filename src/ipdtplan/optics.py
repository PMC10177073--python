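"""Tissue optical properties for the diffusion approximation.

All lengths are in cm, so absorption/scattering coefficients are 1/cm,
the diffusion length ``D`` is cm, and ``alpha_n = c_n * D`` is cm^2/s.
Fluence-rate fields built on these properties are mW/cm^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

#: Vacuum speed of light, cm/s.
C0_CM_PER_S = 2.99792458e10


@dataclass(frozen=True)
class OpticalProperties:
    """Homogeneous-region optical coefficients at the treatment wavelength.

    Either construct from (``mu_a``, ``mu_s``, ``g``) or use
    :meth:`from_reduced` when only the reduced scattering coefficient
    mu_s' = (1-g)*mu_s is known (the usual case for published tissue data);
    then ``g`` is recorded as unspecified and ``mu_s`` is unused.

    Parameters
    ----------
    mu_a:
        Linear absorption coefficient, 1/cm.
    mu_s:
        Linear scattering coefficient, 1/cm (optional if ``mu_s_prime`` given).
    g:
        Scattering anisotropy in [0, 1); ``None`` when constructed from
        mu_s' directly.
    refractive_index:
        Tissue refractive index (>= 1); sets the in-tissue light speed.
    """

    mu_a: float
    mu_s: float | None = None
    g: float | None = None
    refractive_index: float = 1.37
    _mu_s_prime: float | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.mu_a < 0:
            raise ValueError(f"mu_a must be >= 0, got {self.mu_a}")
        if self.refractive_index < 1:
            raise ValueError(
                f"refractive_index must be >= 1, got {self.refractive_index}"
            )
        if self._mu_s_prime is None:
            if self.mu_s is None or self.g is None:
                raise ValueError(
                    "provide (mu_s, g) or use OpticalProperties.from_reduced"
                )
            if self.mu_s < 0:
                raise ValueError(f"mu_s must be >= 0, got {self.mu_s}")
            if not 0 <= self.g < 1:
                raise ValueError(f"g must be in [0, 1), got {self.g}")
        else:
            if self._mu_s_prime < 0:
                raise ValueError(f"mu_s_prime must be >= 0, got {self._mu_s_prime}")
        if self.mu_a + self.mu_s_prime <= 0:
            raise ValueError("mu_a + mu_s_prime must be positive (D would diverge)")

    @classmethod
    def from_reduced(
        cls, mu_a: float, mu_s_prime: float, refractive_index: float = 1.37
    ) -> "OpticalProperties":
        """Construct from the reduced scattering coefficient mu_s' (1/cm)."""
        return cls(
            mu_a=mu_a,
            mu_s=None,
            g=None,
            refractive_index=refractive_index,
            _mu_s_prime=mu_s_prime,
        )

    @property
    def mu_s_prime(self) -> float:
        """Reduced scattering coefficient (1-g)*mu_s, 1/cm."""
        if self._mu_s_prime is not None:
            return self._mu_s_prime
        return (1.0 - self.g) * self.mu_s  # type: ignore[operator]

    @property
    def c_n(self) -> float:
        """Speed of light in the tissue, cm/s."""
        return C0_CM_PER_S / self.refractive_index

    @property
    def D(self) -> float:
        """Diffusion length 1 / (3 (mu_a + mu_s')), cm."""
        return 1.0 / (3.0 * (self.mu_a + self.mu_s_prime))

    @property
    def alpha_n(self) -> float:
        """Optical diffusion coefficient c_n * D, cm^2/s."""
        return self.c_n * self.D

    @property
    def mu_eff(self) -> float:
        """Effective attenuation sqrt(3 mu_a (mu_a + mu_s')), 1/cm."""
        return math.sqrt(3.0 * self.mu_a * (self.mu_a + self.mu_s_prime))


# Published 630 nm properties used for planning: soft tissue (tumor and
# surrounding normal tissue) and whole blood (major vessels).
TUMOR_TISSUE = OpticalProperties.from_reduced(0.2, 5.0, refractive_index=1.37)
NORMAL_TISSUE = TUMOR_TISSUE
BLOOD = OpticalProperties.from_reduced(50.0, 2.32, refractive_index=1.33)

# Solid polyurethane calibration phantom at 630 nm; refractive index is the
# typical polyurethane value (only c_n depends on it, and c_n cancels at
# steady state for a uniform-index domain).
PHANTOM = OpticalProperties.from_reduced(0.224, 4.99, refractive_index=1.52)

#: Default per-region properties keyed by region name.
DEFAULT_PROPERTIES: dict[str, OpticalProperties] = {
    "tumor": TUMOR_TISSUE,
    "normal_tissue": NORMAL_TISSUE,
    "critical_structure": BLOOD,
    "phantom": PHANTOM,
}
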