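"""Analytic model potentials for the synthetic binding landscape.

The default landscape mimics the free-energy profile of a protein binding a
DNA duplex along the cylindrical radial coordinate r (the xy-projection of
the protein-DNA axis distance): a Gaussian attractive well at the bound
distance, a flat plateau representing the unbound state, and a weak harmonic
confinement along the DNA axis z.  The radial well is clamped to exactly
zero beyond ``r_plateau`` so the plateau is flat by construction, which the
standard-state integrals downstream rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = ["ModelPotential"]


@dataclass(frozen=True)
class ModelPotential:
    """A separable model potential U(x, y, z) = U_r(r) + U_z(z).

    ``u_r``/``du_r`` operate on the cylindrical radius r = sqrt(x^2 + y^2)
    (nm -> kJ/mol and kJ/mol/nm); ``u_z``/``du_z`` on the axial coordinate.
    ``params`` keeps the defining scalars so oracles can re-derive closed
    forms.  All callables must be vectorized over numpy arrays.
    """

    u_r: Callable[[np.ndarray], np.ndarray]
    du_r: Callable[[np.ndarray], np.ndarray]
    u_z: Callable[[np.ndarray], np.ndarray]
    du_z: Callable[[np.ndarray], np.ndarray]
    params: dict = field(default_factory=dict)

    # -- factories ---------------------------------------------------------

    @classmethod
    def gaussian_funnel(
        cls,
        depth: float = 25.0,
        r_min: float = 1.8,
        width: float = 0.25,
        r_plateau: float = 3.0,
        z_spring: float = 10.0,
    ) -> "ModelPotential":
        """Gaussian binding well with a strictly flat unbound plateau.

        Parameters
        ----------
        depth : well depth D at ``r_min``, kJ/mol (positive = attractive).
        r_min : radial location of the bound-state minimum, nm.
        width : Gaussian standard deviation of the well, nm.
        r_plateau : radius beyond which U_r is exactly 0, nm.
        z_spring : harmonic spring confining z around 0, kJ mol^-1 nm^-2.

        The Gaussian tail value at ``r_plateau`` is subtracted inside the
        well region so U_r is continuous (to ~1e-4 kJ/mol for the defaults)
        and exactly constant on the plateau.
        """
        tail = np.exp(-0.5 * ((r_plateau - r_min) / width) ** 2)

        def u_r(r):
            r = np.asarray(r, dtype=float)
            well = -depth * (np.exp(-0.5 * ((r - r_min) / width) ** 2) - tail)
            return np.where(r < r_plateau, well, 0.0)

        def du_r(r):
            r = np.asarray(r, dtype=float)
            g = np.exp(-0.5 * ((r - r_min) / width) ** 2)
            grad = depth * g * (r - r_min) / width**2
            return np.where(r < r_plateau, grad, 0.0)

        def u_z(z):
            return 0.5 * z_spring * np.asarray(z, dtype=float) ** 2

        def du_z(z):
            return z_spring * np.asarray(z, dtype=float)

        return cls(
            u_r=u_r,
            du_r=du_r,
            u_z=u_z,
            du_z=du_z,
            params={
                "kind": "gaussian_funnel",
                "depth": depth,
                "r_min": r_min,
                "width": width,
                "r_plateau": r_plateau,
                "z_spring": z_spring,
            },
        )

    @classmethod
    def radial_harmonic(
        cls, kappa: float, r0: float, z_spring: float = 10.0
    ) -> "ModelPotential":
        """U_r = 1/2 kappa (r - r0)^2 — closed-form integrable test case."""

        def u_r(r):
            return 0.5 * kappa * (np.asarray(r, dtype=float) - r0) ** 2

        def du_r(r):
            return kappa * (np.asarray(r, dtype=float) - r0)

        def u_z(z):
            return 0.5 * z_spring * np.asarray(z, dtype=float) ** 2

        def du_z(z):
            return z_spring * np.asarray(z, dtype=float)

        return cls(
            u_r=u_r,
            du_r=du_r,
            u_z=u_z,
            du_z=du_z,
            params={"kind": "radial_harmonic", "kappa": kappa, "r0": r0,
                    "z_spring": z_spring},
        )

    @classmethod
    def flat(cls, z_spring: float = 10.0) -> "ModelPotential":
        """Zero radial potential (free 2D diffusion, confined in z)."""

        def zero(r):
            return np.zeros_like(np.asarray(r, dtype=float))

        def u_z(z):
            return 0.5 * z_spring * np.asarray(z, dtype=float) ** 2

        def du_z(z):
            return z_spring * np.asarray(z, dtype=float)

        return cls(u_r=zero, du_r=zero, u_z=u_z, du_z=du_z,
                   params={"kind": "flat", "z_spring": z_spring})

    # -- derived quantities ------------------------------------------------

    def effective_1d(self, r: np.ndarray, kT: float, r_ref: float = 1.0) -> np.ndarray:
        """Effective 1D potential governing the radial marginal.

        The equilibrium marginal of r in the xy-plane carries the 2D
        Jacobian, p(r) ∝ r exp(-U_r(r)/kT), so the free-energy profile a
        radial WHAM recovers is U_eff(r) = U_r(r) - kT ln(r / r_ref) up to
        an additive constant.
        """
        r = np.asarray(r, dtype=float)
        return self.u_r(r) - kT * np.log(r / r_ref)

    def boltzmann_radial_density(
        self, r: np.ndarray, kT: float, bias_center: float | None = None,
        bias_k: float = 0.0,
    ) -> np.ndarray:
        """Unnormalized equilibrium density of r, optionally under a bias."""
        r = np.asarray(r, dtype=float)
        u = self.u_r(r)
        if bias_center is not None and bias_k > 0:
            u = u + 0.5 * bias_k * (r - bias_center) ** 2
        return r * np.exp(-u / kT)
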