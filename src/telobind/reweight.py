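"""Unbiasing of umbrella-sampling frames for equilibrium observables.

A frame j sampled in window i (bias w_i, WHAM constant F_i) carries the
unbiasing factor

    weight_j  propto  exp[(w_i(r_j) - F_i) / kT]

which maps the biased window density back onto the unbiased equilibrium
density; because exp(-F_i/kT) is exactly the biased partition function of
window i, each window's weighted sum estimates N_i * <A>, so frames from
all windows pool directly into one global estimator.  Equilibrium profiles
of any per-frame observable along r, and 2D free-energy surfaces over
(r, rotation angle), follow by weighted binning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .wham import PMFProfile, WindowSamples

__all__ = ["FrameWeights", "ReweightedProfile", "Surface2D",
           "frame_weights", "observable_profile", "fes_2d",
           "reweighted_pmf"]

#: bins with Kish effective sample size below this are masked
DEFAULT_NEFF_MIN = 20.0


@dataclass
class FrameWeights:
    """Per-frame unbiasing weights, aligned to the concatenated windows."""

    weights: np.ndarray
    window_ids: np.ndarray
    r: np.ndarray
    kT: float

    def __post_init__(self):
        if not (np.all(np.isfinite(self.weights))
                and np.all(self.weights > 0)):
            raise ValueError("weights must be positive and finite")

    @property
    def normalized(self) -> np.ndarray:
        return self.weights / self.weights.sum()


@dataclass
class ReweightedProfile:
    """Weighted observable mean per r bin with errors and effective counts."""

    bin_centers: np.ndarray
    mean: np.ndarray
    err: np.ndarray
    n_eff: np.ndarray

    @property
    def mask(self) -> np.ndarray:
        """True where the bin had enough effective samples to report."""
        return np.isfinite(self.mean)


@dataclass
class Surface2D:
    """Free-energy surface over (r, angle), gauge-fixed to min 0."""

    r_centers: np.ndarray
    angle_centers: np.ndarray
    G: np.ndarray           # (n_r, n_angle), NaN where masked
    kT: float

    @property
    def mask(self) -> np.ndarray:
        return ~np.isfinite(self.G)


def frame_weights(samples: list[WindowSamples], pmf: PMFProfile) -> FrameWeights:
    """Unbiasing weights for every frame of every window.

    ``pmf.F`` must come from a converged WHAM solve on the same windows (the
    count must match; window identity is checked via the bias parameters).
    """
    if len(samples) != pmf.F.size:
        raise ValueError(
            f"{len(samples)} windows but {pmf.F.size} WHAM constants")
    kT = pmf.kT
    w_all, ids, r_all = [], [], []
    for i, s in enumerate(samples):
        log_w = (s.window.bias(s.values) - pmf.F[i]) / kT
        w_all.append(log_w)
        ids.append(np.full(len(s), i))
        r_all.append(s.values)
    log_w = np.concatenate(w_all)
    log_w -= log_w.max()  # stabilize; normalization is immaterial
    return FrameWeights(weights=np.exp(log_w),
                        window_ids=np.concatenate(ids),
                        r=np.concatenate(r_all), kT=kT)


def reweighted_pmf(
    samples: list[WindowSamples],
    pmf: PMFProfile,
    n_boot: int = 16,
    seed: int = 0,
):
    """Free-energy profile by Boltzmann inversion of the frame-level
    reweighted r-histogram, on the PMF's own bin grid, with block-bootstrap
    errors.

    This is the WHAM solution's independent consistency check: the two
    estimators discretize the bias differently (per-frame vs bin-center), so
    they agree within their combined statistical errors plus a second-order
    midpoint-rule term kT (beta w' dr)^2 / 8, not identically.
    Returns ``(G_rw, err_rw, n_eff)`` arrays aligned to ``pmf.bin_centers``
    (NaN where empty); ``n_eff`` is the per-bin Kish effective size — bins
    dominated by one or two high-weight frames are not usable.
    """
    from .wham import statistical_inefficiency

    kT = pmf.kT
    bw = pmf.bin_centers[1] - pmf.bin_centers[0]
    edges = np.concatenate([pmf.bin_centers - bw / 2,
                            [pmf.bin_centers[-1] + bw / 2]])

    def invert(samp):
        w = frame_weights(samp, pmf)
        hist, _ = np.histogram(w.r, bins=edges, weights=w.weights)
        with np.errstate(divide="ignore"):
            return np.where(hist > 0, -kT * np.log(hist), np.nan)

    g_rw = invert(samples)
    w0 = frame_weights(samples, pmf)
    h1, _ = np.histogram(w0.r, bins=edges, weights=w0.weights)
    h2, _ = np.histogram(w0.r, bins=edges, weights=w0.weights**2)
    with np.errstate(divide="ignore", invalid="ignore"):
        n_eff = np.where(h2 > 0, h1**2 / h2, 0.0)
    rng = np.random.default_rng(seed)
    blocks = [max(int(np.ceil(statistical_inefficiency(s.values))), 1)
              if len(s) >= 10 else 1 for s in samples]
    reps = []
    for _ in range(n_boot):
        resampled = []
        for s, bl in zip(samples, blocks):
            n = len(s)
            if bl >= n:
                vals = s.values.copy()
            else:
                nb = int(np.ceil(n / bl))
                starts = rng.integers(0, n - bl + 1, size=nb)
                vals = np.concatenate([s.values[st:st + bl]
                                       for st in starts])[:n]
            resampled.append(WindowSamples(window=s.window, values=vals,
                                           kT=s.kT))
        rep = invert(resampled)
        both = np.isfinite(rep) & np.isfinite(g_rw)
        reps.append(rep - np.mean(rep[both] - g_rw[both]))
    import warnings as _warnings
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        err_rw = np.nanstd(np.array(reps), axis=0, ddof=1)
    return g_rw, err_rw, n_eff


def _kish(w: np.ndarray) -> float:
    s = w.sum()
    return float(s * s / np.dot(w, w)) if s > 0 else 0.0


def observable_profile(
    observable: np.ndarray,
    weights: FrameWeights,
    bin_edges: np.ndarray,
    n_eff_min: float = DEFAULT_NEFF_MIN,
    n_boot: int = 50,
    seed: int = 0,
) -> ReweightedProfile:
    """Weighted mean of a per-frame observable in bins of r.

    The error per bin is a weighted bootstrap (resampling frames within the
    bin with probability proportional to their weights).  Bins whose Kish
    effective sample size (sum w)^2 / sum w^2 falls below ``n_eff_min`` are
    masked (NaN) rather than silently reported.
    """
    obs = np.asarray(observable, dtype=float).ravel()
    if obs.size != weights.r.size:
        raise ValueError(
            f"observable length {obs.size} != frame count {weights.r.size}")
    edges = np.asarray(bin_edges, dtype=float)
    centers = 0.5 * (edges[:-1] + edges[1:])
    idx = np.digitize(weights.r, edges) - 1
    rng = np.random.default_rng(seed)

    mean = np.full(centers.size, np.nan)
    err = np.full(centers.size, np.nan)
    n_eff = np.zeros(centers.size)
    for b in range(centers.size):
        sel = idx == b
        if not sel.any():
            continue
        w, x = weights.weights[sel], obs[sel]
        n_eff[b] = _kish(w)
        if n_eff[b] < n_eff_min:
            continue
        mean[b] = np.average(x, weights=w)
        # frame bootstrap: resample frames uniformly, recompute the weighted
        # mean, so uneven weights propagate into the error
        boots = np.empty(n_boot)
        for k in range(n_boot):
            take = rng.integers(0, x.size, size=x.size)
            boots[k] = np.average(x[take], weights=w[take])
        err[b] = boots.std(ddof=1)
    return ReweightedProfile(bin_centers=centers, mean=mean, err=err,
                             n_eff=n_eff)


def fes_2d(
    r_series: np.ndarray,
    angle_series: np.ndarray,
    weights: FrameWeights,
    r_edges: np.ndarray,
    angle_edges: np.ndarray | None = None,
    n_eff_min: float = 1.0,
) -> Surface2D:
    """2D free-energy surface by Boltzmann inversion of the weighted joint
    histogram: dG = -kT ln(weighted counts), gauge-fixed so the minimum over
    populated cells is zero; empty (or under-populated) cells are NaN.

    Angles are expected in radians in (-pi, pi]; the default angular grid is
    24 bins of 15 degrees.
    """
    r = np.asarray(r_series, dtype=float).ravel()
    th = np.asarray(angle_series, dtype=float).ravel()
    if r.size != th.size or r.size != weights.weights.size:
        raise ValueError("r, angle and weight series must be frame-aligned")
    if angle_edges is None:
        angle_edges = np.linspace(-np.pi, np.pi, 25)
    hist, re, ae = np.histogram2d(r, th, bins=[np.asarray(r_edges),
                                               np.asarray(angle_edges)],
                                  weights=weights.weights)
    # Kish n_eff per cell for masking
    hist2, _, _ = np.histogram2d(r, th, bins=[re, ae],
                                 weights=weights.weights**2)
    with np.errstate(divide="ignore", invalid="ignore"):
        n_eff = np.where(hist2 > 0, hist**2 / hist2, 0.0)
    if not (n_eff >= n_eff_min).any():
        raise ValueError("no populated cells in the 2D grid")
    with np.errstate(divide="ignore"):
        G = np.where(n_eff >= n_eff_min,
                     -weights.kT * np.log(np.where(hist > 0, hist, 1.0)),
                     np.nan)
    G -= np.nanmin(G)
    return Surface2D(r_centers=0.5 * (re[:-1] + re[1:]),
                     angle_centers=0.5 * (ae[:-1] + ae[1:]),
                     G=G, kT=weights.kT)
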