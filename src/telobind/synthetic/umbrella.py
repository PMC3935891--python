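"""Umbrella-window scheduling and biased dataset generation."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .langevin import LangevinParams, sample_langevin
from .potentials import ModelPotential

__all__ = ["UmbrellaWindow", "make_windows", "generate_umbrella_dataset",
           "OverlapReport"]


@dataclass(frozen=True, order=True)
class UmbrellaWindow:
    """Harmonic umbrella bias w(r) = 1/2 k (r - center)^2.

    center : bias center r_i, nm.
    force_constant : k, kJ mol^-1 nm^-2.
    """

    center: float
    force_constant: float

    def __post_init__(self):
        if self.force_constant < 0:
            raise ValueError("force constant must be non-negative")

    def bias(self, r: np.ndarray) -> np.ndarray:
        """Bias energy at r, kJ/mol."""
        return 0.5 * self.force_constant * (np.asarray(r, dtype=float)
                                            - self.center) ** 2


def make_windows(r_start: float, r_stop: float, step: float,
                 k: float) -> list[UmbrellaWindow]:
    """Evenly spaced umbrella windows from ``r_start`` to ``r_stop``.

    Centers are r_start, r_start+step, ..., the last one <= r_stop (+ a
    floating-point epsilon); the count is floor((r_stop-r_start)/step) + 1.
    The standard protein-DNA setup of 1.5 to 4.5 nm with a 0.2 nm step
    yields 16 windows.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if k <= 0:
        raise ValueError("force constant must be positive")
    if r_stop < r_start:
        raise ValueError("r_stop must be >= r_start")
    n = int(np.floor((r_stop - r_start) / step + 1e-9)) + 1
    centers = r_start + step * np.arange(n)
    return [UmbrellaWindow(center=float(c), force_constant=float(k))
            for c in centers]


@dataclass
class OverlapReport:
    """Pairwise histogram overlaps between adjacent windows.

    ``overlaps[i]`` is the shared-area coefficient (0..1, integral of the
    bin-wise minimum of the two normalized histograms) between windows i and
    i+1; ``isolated`` lists windows with zero overlap with both neighbours.
    """

    overlaps: list[float] = field(default_factory=list)
    isolated: list[int] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.isolated


def _pair_overlap(a: np.ndarray, b: np.ndarray, n_bins: int = 100) -> float:
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    if hi <= lo:
        return 1.0
    edges = np.linspace(lo, hi, n_bins + 1)
    pa, _ = np.histogram(a, bins=edges, density=True)
    pb, _ = np.histogram(b, bins=edges, density=True)
    return float(np.sum(np.minimum(pa, pb)) * (edges[1] - edges[0]))


def generate_umbrella_dataset(
    potential: ModelPotential,
    windows: list[UmbrellaWindow],
    params: LangevinParams,
    return_xyz: bool = False,
):
    """One biased reaction-coordinate series per umbrella window.

    Window i is sampled with seed ``params.seed + i`` so the dataset is
    reproducible window-by-window.  Returns ``(samples, report)`` where
    ``samples`` is a list of :class:`telobind.wham.WindowSamples` and
    ``report`` an :class:`OverlapReport`; with ``return_xyz=True`` a third
    element carries the raw (n, 3) trajectories (needed for axial-fluctuation
    and angle analyses).

    A window whose r-histogram shares no probability mass with either
    neighbour is recorded in the report and a warning is emitted — WHAM
    cannot stitch disconnected windows.
    """
    from ..wham import WindowSamples  # local import to avoid a cycle

    centers = [w.center for w in windows]
    if any(c2 <= c1 for c1, c2 in zip(centers, centers[1:])):
        raise ValueError("window centers must be strictly increasing")

    series, trajs = [], []
    for i, w in enumerate(windows):
        p = LangevinParams(
            kT=params.kT, diffusion=params.diffusion, timestep=params.timestep,
            n_steps=params.n_steps, stride=params.stride,
            seed=params.seed + i, n_walkers=params.n_walkers,
            burn_in=params.burn_in, r_max_domain=params.r_max_domain,
        )
        bias = w if w.force_constant > 0 else None
        xyz = sample_langevin(potential, bias, p)
        r = np.hypot(xyz[:, 0], xyz[:, 1])
        series.append(WindowSamples(window=w, values=r, kT=params.kT,
                                    seed=p.seed))
        if return_xyz:
            trajs.append(xyz)

    report = OverlapReport()
    n = len(series)
    for i in range(n - 1):
        report.overlaps.append(_pair_overlap(series[i].values,
                                             series[i + 1].values))
    for i in range(n):
        left = report.overlaps[i - 1] if i > 0 else 0.0
        right = report.overlaps[i] if i < n - 1 else 0.0
        if n > 1 and left <= 0.0 and right <= 0.0:
            report.isolated.append(i)
    if report.isolated:
        warnings.warn(
            f"umbrella windows {report.isolated} have zero histogram overlap "
            "with both neighbours; the WHAM solution will be disconnected",
            stacklevel=2)

    if return_xyz:
        return series, report, trajs
    return series, report
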