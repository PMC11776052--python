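"""Umbrella-sampling free-energy machinery: window layout, WHAM, error
estimation, and the two profile fits (quadratic nucleation coefficient and
line tension).

The free-energy profile of pore formation has two regimes: a quadratic
nucleation region, G ~ k * CV^2 + c fitted for CV <= 0.5, and a linear
expansion region fitted for CV >= 1.2 whose slope encodes the line tension
through G(r) = 2 pi r gamma for a circular pore (Full-Path mode) or
G = m L with m = 2 gamma for the two rims of a stripe (Rapid mode).

WHAM is solved self-consistently in the window free energies with
log-sum-exp stabilisation; convergence is measured as the largest change of
any window free energy between iterations.  Unsampled bins are flagged, never
silently interpolated.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.special import logsumexp

from .cv_rapid import LineTensionResult, line_tension_from_slope

__all__ = [
    "UmbrellaWindow",
    "FreeEnergyProfile",
    "QuadraticFit",
    "make_window_centers",
    "seed_windows",
    "wham_solve",
    "fit_quadratic",
    "fit_line_tension_profile",
    "halves_error",
    "bootstrap_error",
    "block_convergence",
]

KB = 0.00831446  # kJ mol^-1 K^-1


@dataclass
class UmbrellaWindow:
    """One umbrella window: harmonic bias centre, force constant and the CV
    samples collected under the bias."""

    center: float
    kappa: float
    samples: np.ndarray
    temperature: float = 310.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.samples.size and not np.all(np.isfinite(self.samples)):
            raise ValueError("window samples must be finite")

    def bias(self, x: np.ndarray) -> np.ndarray:
        return 0.5 * self.kappa * (np.asarray(x) - self.center) ** 2

    def log_mean_boltzmann(self, edges: np.ndarray, kT: float) -> np.ndarray:
        """log of the bin-averaged bias Boltzmann factor,
        ln[(1/dx) int_bin exp(-U/kT) dx], evaluated stably via Gaussian
        log-CDFs.  Using the bin average instead of the bin-centre value
        removes the discretisation error of stiff biases on wide bins."""
        from scipy.special import log_ndtr

        s = np.sqrt(kT / self.kappa)
        z = (edges - self.center) / s
        mid = 0.5 * (z[:-1] + z[1:])
        # log(Phi(b) - Phi(a)); mirror bins right of the centre through the
        # survival function to avoid catastrophic cancellation
        lo = np.where(mid <= 0, z[:-1], -z[1:])
        hi = np.where(mid <= 0, z[1:], -z[:-1])
        la = log_ndtr(lo)
        lb = log_ndtr(hi)
        with np.errstate(divide="ignore", invalid="ignore"):
            ldiff = lb + np.log1p(-np.exp(np.clip(la - lb, None, -1e-12)))
        width = np.diff(edges)
        return ldiff + 0.5 * np.log(2.0 * np.pi) + np.log(s) - np.log(width)


@dataclass
class FreeEnergyProfile:
    """G(CV) on a bin grid, shifted so the sampled minimum is zero.

    grid      bin centres
    G         kJ/mol (NaN on unsampled bins)
    err       per-bin uncertainty, kJ/mol (zeros unless bootstrapped)
    reference index of the zero bin
    sampled   mask of bins with any samples
    """

    grid: np.ndarray
    G: np.ndarray
    err: np.ndarray
    reference: int
    sampled: np.ndarray
    temperature: float = 310.0


@dataclass
class QuadraticFit:
    """G ~ k * CV^2 + c on the nucleation region CV <= cv_max."""

    k: float
    c: float
    cv_max: float
    residual_rms: float
    n_bins: int


def make_window_centers(lo: float, hi: float, spacing: Optional[float] = None,
                        count: Optional[int] = None) -> np.ndarray:
    """Evenly spaced inclusive window-centre grid.

    Give either a spacing (must divide hi - lo) or a centre count.
    """
    if hi <= lo:
        raise ValueError("hi must exceed lo")
    if (spacing is None) == (count is None):
        raise ValueError("give exactly one of spacing or count")
    if spacing is not None:
        if spacing <= 0:
            raise ValueError("spacing must be positive")
        n_int = (hi - lo) / spacing
        if spacing > (hi - lo) or abs(n_int - round(n_int)) > 1e-6:
            raise ValueError("spacing must divide the interval")
        n = int(round(n_int)) + 1
    else:
        if count < 2:
            raise ValueError("count must be at least 2")
        n = int(count)
    return np.linspace(lo, hi, n)


def seed_windows(cv_values: Sequence[float], centers: Sequence[float]) -> np.ndarray:
    """Frame index per window centre: the frame whose recorded CV is nearest
    (ties resolved to the earliest frame).  Raises if a centre lies outside
    the sampled CV range."""
    cv = np.asarray(cv_values, dtype=float)
    centers = np.asarray(centers, dtype=float)
    if cv.size == 0:
        raise ValueError("empty CV series")
    lo, hi = cv.min(), cv.max()
    out = np.empty(len(centers), dtype=int)
    for i, c in enumerate(centers):
        if c < lo or c > hi:
            raise ValueError(
                f"window centre {c} outside sampled CV range [{lo:.4f}, {hi:.4f}]")
        out[i] = int(np.argmin(np.abs(cv - c)))
    return out


def _histogram_overlap(windows: Sequence[UmbrellaWindow],
                       edges: np.ndarray) -> Tuple[float, int]:
    """Smallest shared histogram weight between adjacent windows (sorted by
    centre); returns (overlap, index of the left window of the worst pair)."""
    order = np.argsort([w.center for w in windows])
    worst, worst_i = np.inf, -1
    hists = []
    for w in windows:
        h, _ = np.histogram(w.samples, bins=edges)
        tot = h.sum()
        hists.append(h / tot if tot else h.astype(float))
    for a, b in zip(order[:-1], order[1:]):
        ov = np.minimum(hists[a], hists[b]).sum()
        if ov < worst:
            worst, worst_i = ov, int(a)
    return float(worst), worst_i


def wham_solve(windows: Sequence[UmbrellaWindow],
               bins: Optional[np.ndarray] = None, n_bins: int = 200,
               tol: float = 1e-8, max_iter: int = 100_000,
               overlap_warn: float = 0.05) -> FreeEnergyProfile:
    """Self-consistent WHAM reconstruction of G(CV) from umbrella windows.

    ``bins`` may supply explicit bin edges; otherwise ``n_bins`` equal bins
    span the sampled range.  Iterates the window free energies until the
    largest change is below ``tol`` (kJ/mol) or ``max_iter`` is reached; on
    non-convergence raises with a diagnostic naming the worst histogram gap.
    All windows must share one temperature.  The profile minimum is shifted
    to zero at the reference bin; unsampled bins carry G = NaN.
    """
    if not windows:
        raise ValueError("no umbrella windows")
    temps = {w.temperature for w in windows}
    if len(temps) > 1:
        raise ValueError("mixed-temperature windows are not supported")
    kT = KB * windows[0].temperature

    all_samples = np.concatenate([w.samples for w in windows])
    if all_samples.size == 0:
        raise ValueError("windows contain no samples")
    if bins is None:
        lo, hi = all_samples.min(), all_samples.max()
        pad = 1e-9 * max(1.0, abs(hi - lo))
        edges = np.linspace(lo - pad, hi + pad, n_bins + 1)
    else:
        edges = np.asarray(bins, dtype=float)
    centers = 0.5 * (edges[:-1] + edges[1:])

    if len(windows) > 1:
        overlap, worst_i = _histogram_overlap(windows, edges)
        if overlap < overlap_warn:
            warnings.warn(
                f"adjacent umbrella windows share only {overlap:.1%} histogram "
                f"weight (worst pair starts at window {worst_i}); WHAM may be "
                "poorly conditioned", stacklevel=2)

    counts = np.array([np.histogram(w.samples, bins=edges)[0]
                       for w in windows], dtype=float)  # (W, B)
    M = counts.sum(axis=0)
    N = counts.sum(axis=1)
    sampled = M > 0
    # log of the bin-averaged bias Boltzmann factor, (W, B)
    log_c = np.array([w.log_mean_boltzmann(edges, kT) for w in windows])

    g = np.zeros(len(windows))  # window free energies / kT
    with np.errstate(divide="ignore"):
        log_M = np.log(M)
    log_N = np.log(np.maximum(N, 1e-300))
    for _ in range(max_iter):
        # log P(b) = log M(b) - logsumexp_i [log N_i + g_i + log_c_ib]
        denom = logsumexp(log_N[:, None] + g[:, None] + log_c, axis=0)
        log_p = np.where(sampled, log_M - denom, -np.inf)
        log_p -= logsumexp(log_p[sampled])
        g_new = -logsumexp(log_p[None, :] + log_c, axis=1)
        g_new -= g_new[0]
        delta = np.max(np.abs(g_new - g)) * kT
        g = g_new
        if delta < tol:
            break
    else:
        overlap, worst_i = _histogram_overlap(windows, edges)
        raise RuntimeError(
            f"WHAM did not converge in {max_iter} iterations (last |dF| = "
            f"{delta:.2e} kJ/mol); worst adjacent histogram overlap "
            f"{overlap:.2%} at window {worst_i}")

    G = np.where(sampled, -kT * log_p, np.nan)
    ref = int(np.nanargmin(G))
    G -= G[ref]
    return FreeEnergyProfile(grid=centers, G=G, err=np.zeros_like(G),
                             reference=ref, sampled=sampled,
                             temperature=windows[0].temperature)


def fit_quadratic(profile: FreeEnergyProfile, cv_max: float = 0.5) -> QuadraticFit:
    """Ordinary least squares of G against CV^2 on the region CV <= cv_max."""
    mask = profile.sampled & (profile.grid <= cv_max) & np.isfinite(profile.G)
    if mask.sum() < 3:
        raise ValueError("need at least 3 sampled bins with CV <= cv_max")
    x = profile.grid[mask] ** 2
    y = profile.G[mask]
    A = np.column_stack([x, np.ones_like(x)])
    (k, c), *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - (k * x + c)
    return QuadraticFit(k=float(k), c=float(c), cv_max=cv_max,
                        residual_rms=float(np.sqrt(np.mean(resid ** 2))),
                        n_bins=int(mask.sum()))


def fit_line_tension_profile(profile: FreeEnergyProfile, mode: str,
                             cv_min: Optional[float] = None,
                             r_unit: float = 1.0) -> LineTensionResult:
    """Linear fit of the expansion region and conversion to a line tension.

    mode='fullpath': G(r) = 2 pi r gamma for a single circular rim with
    r = CV * r_unit, fitted by default for CV >= 1.2, so
    gamma = slope / (2 pi r_unit).
    mode='rapid': G = m L for a stripe, gamma = m / 2 (two rims), fitted on
    the whole sampled profile by default.
    """
    if mode not in ("fullpath", "rapid"):
        raise ValueError("mode must be 'fullpath' or 'rapid'")
    if cv_min is None:
        cv_min = 1.2 if mode == "fullpath" else -np.inf
    mask = profile.sampled & (profile.grid >= cv_min) & np.isfinite(profile.G)
    if mask.sum() < 3:
        raise ValueError("need at least 3 sampled bins in the linear range")
    x = profile.grid[mask]
    y = profile.G[mask]
    A = np.column_stack([x, np.ones_like(x)])
    (m, _b), *_ = np.linalg.lstsq(A, y, rcond=None)
    if not np.isfinite(m):
        raise ValueError("non-finite slope")
    if mode == "fullpath":
        gamma_kj = m / (2.0 * np.pi * r_unit)
        res = line_tension_from_slope(float(gamma_kj), n_rims=1)
        res.slope_m = float(m)
        return res
    return line_tension_from_slope(float(m), n_rims=2)


def halves_error(windows: Sequence[UmbrellaWindow],
                 estimator: Callable[[Sequence[UmbrellaWindow]], float]) -> float:
    """Half the absolute difference between the estimator evaluated on the
    first and second halves of every window's production samples."""
    halves = ([], [])
    for w in windows:
        n = len(w.samples)
        if n < 2:
            raise ValueError("windows need at least 2 samples to split")
        halves[0].append(UmbrellaWindow(w.center, w.kappa, w.samples[: n // 2],
                                        w.temperature))
        halves[1].append(UmbrellaWindow(w.center, w.kappa, w.samples[n // 2:],
                                        w.temperature))
    a = estimator(halves[0])
    b = estimator(halves[1])
    return abs(a - b) / 2.0


def bootstrap_error(windows: Sequence[UmbrellaWindow], n_boot: int = 200,
                    seed: int = 0, bins: Optional[np.ndarray] = None,
                    n_bins: int = 200, tol: float = 1e-6,
                    max_failure_fraction: float = 0.1) -> np.ndarray:
    """Per-bin bootstrap standard deviation of the WHAM profile.

    Samples are resampled with replacement within each window; every
    replicate is re-solved on a common bin grid.  With ``n_boot = 1`` the
    error is identically zero (degenerate case).  Individual replicate
    failures are tolerated up to ``max_failure_fraction``.
    """
    if len(windows) < 2:
        raise ValueError("bootstrap needs at least 2 windows")
    rng = np.random.default_rng(seed)
    if bins is None:
        alls = np.concatenate([w.samples for w in windows])
        pad = 1e-9
        bins = np.linspace(alls.min() - pad, alls.max() + pad, n_bins + 1)
    profiles = []
    failures = 0
    for _ in range(n_boot):
        rep = [UmbrellaWindow(w.center, w.kappa,
                              rng.choice(w.samples, size=len(w.samples),
                                         replace=True), w.temperature)
               for w in windows]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                profiles.append(wham_solve(rep, bins=bins, tol=tol).G)
        except (RuntimeError, ValueError):
            failures += 1
            if failures > max_failure_fraction * n_boot:
                raise
    arr = np.array(profiles)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return np.nanstd(arr, axis=0, ddof=0)


def block_convergence(windows: Sequence[UmbrellaWindow], n_blocks: int,
                      bins: Optional[np.ndarray] = None, n_bins: int = 200,
                      tol: float = 1e-8):
    """WHAM per contiguous time block of every window's samples.

    Each window's sample count must divide evenly into ``n_blocks`` equal
    blocks (unequal blocks are rejected).  Returns (profiles, max pairwise
    |dG| over commonly sampled bins).
    """
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    for w in windows:
        if len(w.samples) == 0 or len(w.samples) % n_blocks:
            raise ValueError("window samples must divide evenly into blocks")
    if bins is None:
        alls = np.concatenate([w.samples for w in windows])
        pad = 1e-9
        bins = np.linspace(alls.min() - pad, alls.max() + pad, n_bins + 1)
    profiles = []
    for b in range(n_blocks):
        block = [UmbrellaWindow(
            w.center, w.kappa,
            w.samples[b * len(w.samples) // n_blocks:
                      (b + 1) * len(w.samples) // n_blocks],
            w.temperature) for w in windows]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            profiles.append(wham_solve(block, bins=bins, tol=tol))
    max_dev = 0.0
    for i in range(len(profiles)):
        for j in range(i + 1, len(profiles)):
            common = profiles[i].sampled & profiles[j].sampled
            if common.any():
                max_dev = max(max_dev, float(np.nanmax(
                    np.abs(profiles[i].G[common] - profiles[j].G[common]))))
    return profiles, max_dev
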