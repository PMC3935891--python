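"""Overdamped Brownian sampler on model potentials.

Only equilibrium statistics matter downstream, so inertial dynamics is not
integrated; the sampler targets the Boltzmann distribution of
U(x,y,z) = U_r(r) + U_z(z) [+ harmonic umbrella bias on r] using
Euler-Maruyama proposals with a Metropolis accept step (MALA), which makes
the stationary distribution exactly Boltzmann at any stable timestep.
Biased runs start from the analytic biased marginal (inverse-CDF draw), so
bistable windows (binding well vs plateau under a displaced bias) carry the
correct basin occupancy from the first frame.

The step budget ``n_steps`` is split across ``n_walkers`` independent
walkers that are burned in and then propagated in lock-step as one
vectorized batch, which keeps multi-window datasets at 10^5 saved samples
per window in the seconds range while leaving the stationary distribution
untouched.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

from .potentials import ModelPotential

if TYPE_CHECKING:  # pragma: no cover
    from .umbrella import UmbrellaWindow

__all__ = ["LangevinParams", "sample_langevin", "IntegrationInstabilityError"]


class IntegrationInstabilityError(RuntimeError):
    """Raised when a walker leaves the allowed domain (time step too large)."""


@dataclass(frozen=True)
class LangevinParams:
    """Parameters of the overdamped sampler.

    kT : thermal energy, kJ/mol.
    diffusion : diffusion coefficient D_c, nm^2/ps.
    timestep : Euler-Maruyama step, ps.  Stability requires the drift per
        step beta*D_c*|F|*dt to stay well below the narrowest feature width;
        for a harmonic well of spring k this means dt << kT/(k*D_c).
    n_steps : total step budget (split across walkers).
    stride : save every ``stride``-th step.
    seed : fully determines the trajectory.
    n_walkers : number of independent walkers sharing the budget.
    burn_in : discarded steps per walker before saving starts.
    r_max_domain : radius at which the integration is declared divergent.
    """

    kT: float = 2.49433863
    diffusion: float = 0.1
    timestep: float = 0.01
    n_steps: int = 1_000_000
    stride: int = 10
    seed: int = 0
    n_walkers: int = 16
    burn_in: int = 2_000
    r_max_domain: float = 50.0

    def __post_init__(self):
        if self.timestep <= 0 or self.diffusion <= 0 or self.kT <= 0:
            raise ValueError("timestep, diffusion and kT must be positive")
        if self.n_steps < self.n_walkers:
            raise ValueError("n_steps must be at least n_walkers")
        if self.stride < 1 or self.n_walkers < 1:
            raise ValueError("stride and n_walkers must be >= 1")


def _energy(potential: ModelPotential, xyz: np.ndarray,
            bias_center: float | None, bias_k: float) -> np.ndarray:
    r = np.hypot(xyz[:, 0], xyz[:, 1])
    u = potential.u_r(r) + potential.u_z(xyz[:, 2])
    if bias_center is not None and bias_k != 0.0:
        u = u + 0.5 * bias_k * (r - bias_center) ** 2
    return u


def _forces(potential: ModelPotential, xyz: np.ndarray,
            bias_center: float | None, bias_k: float) -> np.ndarray:
    """-grad U for a batch of walkers, shape (n, 3)."""
    x, y, z = xyz[:, 0], xyz[:, 1], xyz[:, 2]
    r = np.hypot(x, y)
    dur = potential.du_r(r)
    if bias_center is not None and bias_k != 0.0:
        dur = dur + bias_k * (r - bias_center)
    # radial force projected on x, y; guard r=0 (radial force vanishes there
    # only for smooth potentials, but the direction is undefined either way)
    with np.errstate(invalid="ignore", divide="ignore"):
        inv_r = np.where(r > 1e-12, 1.0 / r, 0.0)
    f = np.empty_like(xyz)
    f[:, 0] = -dur * x * inv_r
    f[:, 1] = -dur * y * inv_r
    f[:, 2] = -potential.du_z(z)
    return f


def _inverse_cdf_draw(grid: np.ndarray, log_dens: np.ndarray, n: int,
                      rng: np.random.Generator) -> np.ndarray:
    dens = np.exp(log_dens - log_dens.max())
    cdf = np.cumsum(dens)
    cdf /= cdf[-1]
    return np.interp(rng.random(n), cdf, grid)


def _equilibrium_start(potential, bias_center, bias_k, params, rng, nw):
    """Walker start points drawn from the biased Boltzmann distribution."""
    kT = params.kT
    sigma = np.sqrt(kT / bias_k)
    r_hi = max(bias_center + 6 * sigma,
               float(potential.params.get("r_plateau", bias_center)) + 1.0)
    grid = np.linspace(1e-4, r_hi, 4001)
    log_dens = (np.log(grid) - (potential.u_r(grid)
                + 0.5 * bias_k * (grid - bias_center) ** 2) / kT)
    r = _inverse_cdf_draw(grid, log_dens, nw, rng)
    phi = rng.uniform(0, 2 * np.pi, nw)
    zgrid = np.linspace(-10.0, 10.0, 4001)
    z = _inverse_cdf_draw(zgrid, -potential.u_z(zgrid) / kT, nw, rng)
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


def sample_langevin(
    potential: ModelPotential,
    bias: "UmbrellaWindow | None",
    params: LangevinParams,
    start: np.ndarray | None = None,
) -> np.ndarray:
    """Sample a 3D trajectory, returned as an array of shape (n_saved, 3).

    The long-run marginal of r = sqrt(x^2+y^2) converges to
    p(r) ∝ r exp(-[U_r(r) + w(r)]/kT) (the factor r is the 2D Jacobian).
    Identical ``params.seed`` gives a bit-identical trajectory.

    Parameters
    ----------
    bias : umbrella window supplying w(r) = 1/2 k (r - r_i)^2, or None.
    start : optional (3,) start point; defaults to the bias center (or the
        potential's ``r_min``/1.0 nm) on the x axis.
    """
    bias_center = bias.center if bias is not None else None
    bias_k = bias.force_constant if bias is not None else 0.0

    rng = np.random.default_rng(params.seed)
    nw = params.n_walkers
    steps_per_walker = params.n_steps // nw
    n_saved = steps_per_walker // params.stride
    if n_saved < 1:
        raise ValueError("n_steps too small for the requested stride/walkers")

    if start is None and bias_center is not None and bias_k > 0:
        # draw walker starts from the exact biased equilibrium marginal
        # (inverse CDF on a grid); a biased window can be bistable (well vs
        # plateau basin) with hopping times far beyond the burn-in, so
        # starting all walkers at the bias center would skew basin occupancy
        xyz = _equilibrium_start(potential, bias_center, bias_k, params, rng, nw)
    else:
        if start is None:
            r0 = float(potential.params.get("r_min", 1.0))
            start = np.array([r0, 0.0, 0.0])
        start = np.asarray(start, dtype=float)
        if not np.all(np.isfinite(potential.u_r(
                np.atleast_1d(np.hypot(start[0], start[1]))))):
            raise ValueError("potential not finite at the start point")
        xyz = np.tile(start, (nw, 1))
        # decorrelate walkers at the start
        xyz += rng.normal(scale=0.02, size=xyz.shape)

    dt = params.timestep
    mobility = params.diffusion / params.kT  # beta * D
    noise_sigma = np.sqrt(2.0 * params.diffusion * dt)

    out = np.empty((n_saved, nw, 3))
    total = params.burn_in + steps_per_walker
    save_idx = 0
    check_every = 200
    beta = 1.0 / params.kT
    n_accepted = 0
    u_cur = _energy(potential, xyz, bias_center, bias_k)
    f_cur = _forces(potential, xyz, bias_center, bias_k)
    for step in range(total):
        # Metropolis-adjusted Brownian proposal: the accept step removes the
        # O(dt) discretization bias, so the saved marginal is exactly
        # Boltzmann regardless of the timestep
        noise = noise_sigma * rng.standard_normal(xyz.shape)
        prop = xyz + mobility * dt * f_cur + noise
        u_prop = _energy(potential, prop, bias_center, bias_k)
        f_prop = _forces(potential, prop, bias_center, bias_k)
        fwd = prop - xyz - mobility * dt * f_cur
        rev = xyz - prop - mobility * dt * f_prop
        log_q = (np.sum(fwd**2, axis=1) - np.sum(rev**2, axis=1)) \
            / (2.0 * noise_sigma**2)
        log_alpha = -beta * (u_prop - u_cur) + log_q
        acc = np.log(rng.random(nw)) < log_alpha
        n_accepted += int(acc.sum())
        xyz = np.where(acc[:, None], prop, xyz)
        u_cur = np.where(acc, u_prop, u_cur)
        f_cur = np.where(acc[:, None], f_prop, f_cur)
        if step % check_every == 0 and not np.all(
                np.abs(xyz) < params.r_max_domain):
            raise IntegrationInstabilityError(
                f"walker left the domain (|coord| >= {params.r_max_domain} nm); "
                f"timestep dt={dt} ps is too large for this potential")
        if step == 500 and n_accepted < 0.05 * nw * (step + 1):
            raise IntegrationInstabilityError(
                f"acceptance rate {n_accepted / (nw * (step + 1)):.3f} after "
                f"{step + 1} steps; timestep dt={dt} ps is too large for "
                "this potential")
        k = step - params.burn_in
        if k >= 0 and (k + 1) % params.stride == 0 and save_idx < n_saved:
            out[save_idx] = xyz
            save_idx += 1
    # concatenate walkers back to back so the saved series keeps each
    # walker's autocorrelation structure (needed by inefficiency estimates)
    return out.transpose(1, 0, 2).reshape(n_saved * nw, 3)
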