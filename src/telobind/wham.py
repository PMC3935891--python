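"""Weighted histogram analysis of umbrella-sampling data.

Reconstructs the potential of mean force G(r) along the cylindrical
reaction coordinate from harmonically biased windows by self-consistent
iteration of the WHAM equations

    P(b) = sum_i n_i(b) / sum_i N_i exp[(F_i - w_i(r_b)) / kT]
    F_i  = -kT ln sum_b P(b) exp(-w_i(r_b) / kT)

where n_i(b) are per-window histogram counts, N_i the (autocorrelation-
corrected) effective sample counts and w_i the bias evaluated at the bin
center.  Uncertainties come from a block bootstrap with block length set by
the statistical inefficiency of each window's time series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .constants import KB, DEFAULT_T
from .synthetic.umbrella import UmbrellaWindow

__all__ = ["WindowSamples", "PMFProfile", "statistical_inefficiency",
           "wham_solve", "bootstrap_pmf_errors", "WhamConvergenceError"]

DEFAULT_BIN_WIDTH = 0.05  # nm; >= 4 bins per bias std dev at k=700, 300 K


class WhamConvergenceError(RuntimeError):
    """WHAM iteration failed to reach tolerance within max_iter."""


@dataclass
class WindowSamples:
    """Reaction-coordinate series sampled under one umbrella bias."""

    window: UmbrellaWindow
    values: np.ndarray
    kT: float = KB * DEFAULT_T
    seed: int | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size == 0:
            raise ValueError("empty sample series")
        if np.any(self.values < 0):
            raise ValueError("reaction coordinate r must be non-negative")

    def __len__(self):
        return self.values.size


@dataclass
class PMFProfile:
    """Binned free-energy profile with per-window WHAM constants.

    G is gauge-fixed to min(G) = 0 over covered bins; NaN marks bins inside
    the grid with no counts (gaps are reported, never interpolated).
    """

    bin_centers: np.ndarray
    G: np.ndarray
    err: np.ndarray
    kT: float
    F: np.ndarray
    counts: np.ndarray = field(default=None)
    n_iter: int = 0

    @property
    def covered(self) -> np.ndarray:
        return np.isfinite(self.G)

    def interp(self, r: np.ndarray) -> np.ndarray:
        """Linear interpolation of G over covered bins."""
        m = self.covered
        return np.interp(r, self.bin_centers[m], self.G[m])


def statistical_inefficiency(series: np.ndarray) -> float:
    """Integrated autocorrelation factor g = 1 + 2*sum_t C(t) (g >= 1).

    The normalized autocorrelation C(t) is summed over positive lags and
    truncated at the first non-positive value (initial positive sequence
    estimator).  The effective number of independent samples is n/g.
    A constant series is fully correlated: g = n, with a warning.
    """
    x = np.asarray(series, dtype=float).ravel()
    n = x.size
    if n < 10:
        raise ValueError("series too short for autocorrelation analysis")
    x = x - x.mean()
    var = np.dot(x, x) / n
    if var <= 0 or not np.isfinite(var):
        warnings.warn("constant series: statistical inefficiency set to n",
                      stacklevel=2)
        return float(n)
    # FFT autocovariance, biased normalization (1/n) for summability
    m = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(x, m)
    acov = np.fft.irfft(f * np.conj(f), m)[:n].real / n
    c = acov / acov[0]
    g = 1.0
    for t in range(1, n):
        if c[t] <= 0:
            break
        g += 2.0 * c[t] * (1.0 - t / n)
    return float(max(g, 1.0))


def _bin_grid(samples, bin_width):
    lo = min(s.values.min() for s in samples)
    hi = max(s.values.max() for s in samples)
    n_bins = max(int(np.ceil((hi - lo) / bin_width)), 1)
    edges = lo + bin_width * np.arange(n_bins + 1)
    return edges, 0.5 * (edges[:-1] + edges[1:])


def wham_solve(
    samples: list[WindowSamples],
    bin_width: float = DEFAULT_BIN_WIDTH,
    tol: float = 1e-8,
    max_iter: int = 100_000,
    use_inefficiency: bool = True,
    bin_edges: np.ndarray | None = None,
) -> PMFProfile:
    """Self-consistent WHAM solution over a regular bin grid.

    Parameters
    ----------
    samples : one :class:`WindowSamples` per umbrella window (>= 1, shared kT).
    bin_width : histogram resolution, nm (ignored if ``bin_edges`` given).
    tol : convergence threshold on max |delta F_i|, in units of kT.
    max_iter : direct-iteration cap; exceeding it raises
        :class:`WhamConvergenceError` with the last residual.
    use_inefficiency : weight each window by its effective sample count
        N_i/g_i, the standard correction for autocorrelated series.

    Gauge: F_0 = 0 during iteration; the returned G is shifted to min 0.
    """
    if not samples:
        raise ValueError("at least one window required")
    kT = samples[0].kT
    if any(abs(s.kT - kT) > 1e-9 for s in samples):
        raise ValueError("all windows must share one kT")

    if bin_edges is None:
        edges, centers = _bin_grid(samples, bin_width)
    else:
        edges = np.asarray(bin_edges, dtype=float)
        centers = 0.5 * (edges[:-1] + edges[1:])

    n_win, n_bins = len(samples), centers.size
    counts = np.stack([np.histogram(s.values, bins=edges)[0]
                       for s in samples]).astype(float)
    if use_inefficiency:
        eff = np.array([len(s) / statistical_inefficiency(s.values)
                        if len(s) >= 10 else float(len(s)) for s in samples])
        # scale counts so each window carries its effective weight
        counts = counts * (eff / counts.sum(axis=1))[:, None]
    n_eff = counts.sum(axis=1)

    beta_w = np.stack([s.window.bias(centers) for s in samples]) / kT
    total = counts.sum(axis=0)
    occupied = total > 0

    log_f = np.zeros(n_win)              # beta * F_i
    log_num = np.log(np.where(occupied, total, 1.0))
    log_n = np.log(n_eff)
    resid = np.inf
    for it in range(1, max_iter + 1):
        # log P(b) = log sum_i n_i(b) - logsumexp_i [log N_i + beta(F_i - w_ib)]
        log_den = logsumexp(log_n[:, None] + log_f[:, None] - beta_w, axis=0)
        log_p = np.where(occupied, log_num - log_den, -np.inf)
        new_log_f = -logsumexp(log_p[None, :] - beta_w, axis=1)
        new_log_f -= new_log_f[0]
        resid = np.max(np.abs(new_log_f - log_f))
        log_f = new_log_f
        if resid < tol:
            break
    else:
        raise WhamConvergenceError(
            f"WHAM did not converge in {max_iter} iterations; "
            f"last max|delta F| = {resid * kT:.3e} kJ/mol")

    with np.errstate(divide="ignore"):
        G = np.where(occupied, -kT * log_p, np.nan)
    G -= np.nanmin(G)
    gaps = ~occupied & (centers > centers[occupied][0]) \
        & (centers < centers[occupied][-1])
    if gaps.any():
        warnings.warn(f"{int(gaps.sum())} empty bins inside the covered "
                      "range (reported as NaN, not interpolated)", stacklevel=2)
    return PMFProfile(bin_centers=centers, G=G, err=np.zeros_like(G),
                      kT=kT, F=kT * log_f, counts=counts, n_iter=it)


def bootstrap_pmf_errors(
    samples: list[WindowSamples],
    n_boot: int = 32,
    seed: int = 0,
    bin_width: float = DEFAULT_BIN_WIDTH,
    tol: float = 1e-7,
    max_iter: int = 100_000,
    return_replicates: bool = False,
):
    """Block-bootstrap standard errors for the WHAM profile.

    Each replicate resamples every window's series in contiguous blocks of
    length ceil(g) (g = statistical inefficiency), preserving short-range
    autocorrelation, and re-solves WHAM on the fixed bin grid of the point
    estimate.  Returns the point-estimate profile with ``err`` filled;
    with ``return_replicates=True`` also the (n_boot, n_bins) array of
    gauge-aligned replicate profiles, for propagating the error into any
    derived functional of G.
    """
    if n_boot < 10:
        raise ValueError("n_boot must be >= 10 for a usable error estimate")
    base = wham_solve(samples, bin_width=bin_width, tol=tol,
                      max_iter=max_iter)
    bw = base.bin_centers[1] - base.bin_centers[0] if base.bin_centers.size > 1 \
        else bin_width
    edges = np.concatenate([base.bin_centers - bw / 2,
                            [base.bin_centers[-1] + bw / 2]])

    rng = np.random.default_rng(seed)
    blocks = [max(int(np.ceil(statistical_inefficiency(s.values))), 1)
              if len(s) >= 10 else 1 for s in samples]
    reps = np.full((n_boot, base.bin_centers.size), np.nan)
    for b in range(n_boot):
        resampled = []
        for s, bl in zip(samples, blocks):
            n = len(s)
            if bl >= n:
                vals = s.values.copy()  # single block: no resampling freedom
            else:
                n_blocks = int(np.ceil(n / bl))
                starts = rng.integers(0, n - bl + 1, size=n_blocks)
                vals = np.concatenate([s.values[st:st + bl]
                                       for st in starts])[:n]
            resampled.append(WindowSamples(window=s.window, values=vals,
                                           kT=s.kT))
        prof = wham_solve(resampled, tol=tol, max_iter=max_iter,
                          bin_edges=edges)
        # align gauge to the point estimate over shared covered bins
        both = prof.covered & base.covered
        reps[b] = prof.G - np.mean(prof.G[both] - base.G[both])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN bins
        base.err = np.nanstd(reps, axis=0, ddof=1)
    base.err = np.where(base.covered, base.err, np.nan)
    if return_replicates:
        return base, reps
    return base
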