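"""Ks density curve construction and Gaussian multipeak fitting.

The per-block median Ks values of one comparison are smoothed into a
probability-density curve with a fixed-bandwidth Gaussian kernel (default
bandwidth 0.025 Ks units), and a sum of Gaussian components is fitted to that
curve by nonlinear least squares.  Components are added one at a time until
the coefficient of determination against the curve reaches the configured
threshold (default R^2 >= 0.95) or a component cap is hit; each event peak is
then read off as a fitted component mean.

Fitting the smoothed curve (rather than running EM on the raw values) mirrors
the curve-fitting workflow this procedure reproduces; the KDE bandwidth is
therefore part of the model, not a nuisance parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import find_peaks

DEFAULT_BANDWIDTH = 0.025
DEFAULT_R2_MIN = 0.95
DEFAULT_MAX_COMPONENTS = 5
GRID_POINTS = 512


@dataclass
class KdeCurve:
    grid: np.ndarray
    density: np.ndarray
    bandwidth: float

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))


@dataclass(frozen=True)
class GaussianComponent:
    mu: float
    sigma: float
    weight: float


@dataclass
class MixtureFit:
    components: list[GaussianComponent]
    r_squared: float
    below_threshold: bool = False

    def predict(self, grid: np.ndarray) -> np.ndarray:
        return _mixture(grid, *_flatten(self.components))


def kde(
    ks_values, bandwidth: float = DEFAULT_BANDWIDTH, n_grid: int = GRID_POINTS
) -> KdeCurve:
    """Gaussian-kernel density of Ks values on an even grid [0, max + 4*bw]."""
    values = np.asarray(ks_values, dtype=float)
    if values.size < 5:
        raise ValueError(f"need at least 5 Ks values for a density curve, got {values.size}")
    if bandwidth <= 0:
        raise ValueError("bandwidth must be > 0")
    grid = np.linspace(0.0, float(values.max()) + 4.0 * bandwidth, n_grid)
    z = (grid[:, None] - values[None, :]) / bandwidth
    density = np.exp(-0.5 * z * z).sum(axis=1) / (
        values.size * bandwidth * np.sqrt(2.0 * np.pi)
    )
    return KdeCurve(grid, density, bandwidth)


def _flatten(components: list[GaussianComponent]) -> list[float]:
    out: list[float] = []
    for c in components:
        out.extend((c.weight, c.mu, c.sigma))
    return out


def _mixture(x: np.ndarray, *params: float) -> np.ndarray:
    y = np.zeros_like(x)
    for w, mu, sigma in zip(params[0::3], params[1::3], params[2::3]):
        y = y + w * np.exp(-0.5 * ((x - mu) / sigma) ** 2) / (
            sigma * np.sqrt(2.0 * np.pi)
        )
    return y


def _r_squared(curve: KdeCurve, params: list[float]) -> float:
    resid = curve.density - _mixture(curve.grid, *params)
    ss_res = float(resid @ resid)
    centred = curve.density - curve.density.mean()
    ss_tot = float(centred @ centred)
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0


def _initial_means(curve: KdeCurve, k: int) -> list[float]:
    """k candidate component means: density local maxima ranked by prominence,
    leftmost first on ties; padded with quantile positions if maxima are few."""
    idx, props = find_peaks(curve.density, prominence=0.0)
    order = sorted(
        range(len(idx)), key=lambda i: (-props["prominences"][i], curve.grid[idx[i]])
    )
    means = [float(curve.grid[idx[i]]) for i in order[:k]]
    q = 1
    while len(means) < k:
        means.append(float(np.quantile(curve.grid, q / (k + 1))))
        q += 1
    return sorted(means[:k])


def _fit_k(curve: KdeCurve, init: list[GaussianComponent]) -> list[float] | None:
    p0 = _flatten(init)
    mass = curve.integral()
    lo = [0.0, float(curve.grid[0]), 1e-4] * len(init)
    hi = [2.0 * mass, float(curve.grid[-1]), float(curve.grid[-1])] * len(init)
    p0 = [min(max(p, l), h) for p, l, h in zip(p0, lo, hi)]
    try:
        popt, _ = curve_fit(
            _mixture, curve.grid, curve.density, p0=p0, bounds=(lo, hi), maxfev=20000
        )
    except RuntimeError:
        return None
    return list(popt)


def fit_mixture(
    curve: KdeCurve,
    max_components: int = DEFAULT_MAX_COMPONENTS,
    r2_min: float = DEFAULT_R2_MIN,
) -> MixtureFit:
    """Fit a Gaussian mixture to the density curve by least squares.

    The component count grows from 1 until R^2 >= ``r2_min`` or
    ``max_components``; each richer fit is warm-started from the previous
    solution (plus a component at the largest residual), so R^2 is
    non-decreasing in the component count.  If no fit reaches the threshold
    the best one is returned flagged ``below_threshold``.
    """
    if not 0.0 < r2_min <= 1.0:
        raise ValueError("r2_min must be in (0, 1]")
    mass = curve.integral()
    best_params: list[float] | None = None
    best_r2 = -np.inf
    prev: list[float] | None = None
    for k in range(1, max_components + 1):
        sigma0 = max(4.0 * curve.bandwidth, float(curve.grid[-1]) / 40.0)
        inits = []
        cold = [
            GaussianComponent(m, sigma0, mass / k) for m in _initial_means(curve, k)
        ]
        inits.append(cold)
        if prev is not None:
            resid = curve.density - _mixture(curve.grid, *prev)
            extra_mu = float(curve.grid[int(np.argmax(resid))])
            warm = [
                GaussianComponent(mu, sigma, w)
                for w, mu, sigma in zip(prev[0::3], prev[1::3], prev[2::3])
            ] + [GaussianComponent(extra_mu, sigma0, max(1e-6, mass / (10 * k)))]
            inits.append(warm)
        k_best: list[float] | None = None
        k_r2 = -np.inf
        for init in inits:
            params = _fit_k(curve, init)
            if params is None:
                continue
            r2 = _r_squared(curve, params)
            if r2 > k_r2:
                k_r2, k_best = r2, params
        if k_best is None:
            continue
        prev = k_best
        if k_r2 > best_r2:
            best_r2, best_params = k_r2, k_best
        if best_r2 >= r2_min:
            break
    if best_params is None:
        raise RuntimeError("mixture fit failed to converge for any component count")
    comps = sorted(
        (
            GaussianComponent(mu, sigma, w)
            for w, mu, sigma in zip(best_params[0::3], best_params[1::3], best_params[2::3])
        ),
        key=lambda c: c.mu,
    )
    return MixtureFit(comps, best_r2, below_threshold=best_r2 < r2_min)


def dominant_component(fit: MixtureFit) -> GaussianComponent:
    """The comparison's divergence peak: the largest-weight component."""
    return max(fit.components, key=lambda c: c.weight)
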