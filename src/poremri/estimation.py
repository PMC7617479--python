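"""MRI-side estimation pipelines: spherical means, T2 and diffusion fits.

The measurement side mirrors the synthetic side: the directional signal at
each (b, TE) is averaged over gradient directions into the spherical mean, a
rotational invariant independent of the fiber orientation distribution.  The
T2 branch fits a mono-exponential decay across TEs and inverts the
Brownstein-Tarr relation into a radius; the diffusion branch fits the
single-cylinder spherical-mean model across b-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import optimize, stats

from .core_models import (
    AcquisitionProtocol,
    DiffusionParams,
    RelaxationParams,
)
from .effective_radius import EffectiveRadiusFit, fit_single_cylinder_diffusion

__all__ = [
    "SphericalMeanSeries",
    "RegressionReport",
    "MonoExpFit",
    "spherical_mean",
    "fit_monoexp_t2",
    "radius_from_t2",
    "fit_diffusion_radius",
    "estimate_snr",
    "compare_radii",
]


@dataclass
class SphericalMeanSeries:
    """Orientation-averaged signal versus TE (ms) or b (s/mm^2).

    ``axis_kind`` is "TE" or "b"; the axis must be strictly increasing and
    the signals positive.  ``sd_signal`` carries the across-voxel spread when
    the series was aggregated from an image; ``n_voxels`` how many voxels
    entered the average.
    """

    axis_kind: str
    axis: np.ndarray
    mean_signal: np.ndarray
    sd_signal: np.ndarray | None = None
    n_voxels: int = 1

    def __post_init__(self) -> None:
        if self.axis_kind not in ("TE", "b"):
            raise ValueError(f"axis_kind must be 'TE' or 'b', got {self.axis_kind!r}")
        self.axis = np.atleast_1d(np.asarray(self.axis, float))
        self.mean_signal = np.atleast_1d(np.asarray(self.mean_signal, float))
        if self.axis.shape != self.mean_signal.shape:
            raise ValueError("axis and mean_signal must have the same length")
        if self.axis.size < 1:
            raise ValueError("series must be nonempty")
        if np.any(np.diff(self.axis) <= 0):
            raise ValueError("axis must be strictly increasing")
        if np.any(self.mean_signal <= 0):
            raise ValueError("signals must be positive")
        if self.sd_signal is not None:
            self.sd_signal = np.atleast_1d(np.asarray(self.sd_signal, float))
            if self.sd_signal.shape != self.axis.shape:
                raise ValueError("sd_signal must match the axis in length")

    def __len__(self) -> int:
        return int(self.axis.size)


@dataclass(frozen=True)
class RegressionReport:
    """Ordinary-least-squares comparison of two radius sets (y on x)."""

    slope: float
    intercept: float
    R: float
    p: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("regression needs at least 2 points")
        if np.isfinite(self.R) and abs(self.R) > 1 + 1e-12:
            raise ValueError("|R| cannot exceed 1")


class MonoExpFit(NamedTuple):
    """Mono-exponential fit K exp(-TE/T2i) of a multi-TE series."""

    K: float
    T2i: float
    loss: float
    converged: bool
    bounds_hit: bool


def spherical_mean(directional_signals: np.ndarray, axis: int = -1) -> np.ndarray | float:
    """Arithmetic mean of the signal over gradient directions.

    For a sufficiently uniform direction set this estimates the powder
    average regardless of the underlying fiber configuration.
    """
    arr = np.asarray(directional_signals, float)
    if arr.size == 0:
        raise ValueError("need at least one direction")
    out = arr.mean(axis=axis)
    return float(out) if np.ndim(out) == 0 else out


def fit_monoexp_t2(
    series: SphericalMeanSeries,
    t2_bounds: tuple[float, float] = (1.0, 3000.0),
) -> MonoExpFit:
    """Fit S(TE) = K exp(-TE/T2i) by bounded least squares (L-BFGS-B).

    Initialized from the log-linear regression of ln S on TE.  A T2i landing
    within 1% of either bound (e.g. for a flat series) sets ``bounds_hit``.
    """
    if series.axis_kind != "TE":
        raise ValueError("fit_monoexp_t2 requires a TE-axis series")
    TE = series.axis
    y = series.mean_signal
    if TE.size < 2:
        raise ValueError("need at least two TE points")
    lo, hi = t2_bounds
    # log-linear init: ln y = ln K - TE/T2
    slope, intercept = np.polyfit(TE, np.log(y), 1)
    t2_init = np.clip(-1.0 / slope if slope < 0 else hi, lo, hi)
    k_init = float(np.exp(intercept))

    def loss(params):
        K, T2 = params
        return float(np.mean((y - K * np.exp(-TE / T2)) ** 2))

    res = optimize.minimize(
        loss,
        x0=np.array([k_init, t2_init]),
        method="L-BFGS-B",
        bounds=[(1e-12, 10.0 * float(y.max())), (lo, hi)],
        options={"ftol": 1e-15, "gtol": 1e-14, "maxiter": 500},
    )
    K_opt, t2_opt = res.x
    return MonoExpFit(
        K=float(K_opt),
        T2i=float(t2_opt),
        loss=float(res.fun),
        converged=bool(res.success),
        bounds_hit=bool(t2_opt <= lo * 1.01 or t2_opt >= hi * 0.99),
    )


def radius_from_t2(T2i: float, relax: RelaxationParams) -> float:
    """Invert the Brownstein-Tarr relation: r = 2 rho2 / (1/T2i - 1/T2b).

    rho2 in nm/ms gives r in um through the 1e-3 unit factor.  Requires
    0 < T2i < T2b (the surface term must be positive) and rho2 > 0, else the
    radius is unidentifiable.
    """
    if relax.rho2 <= 0:
        raise ValueError("rho2 must be positive to invert T2 into a radius")
    if T2i <= 0:
        raise ValueError(f"T2i must be positive, got {T2i}")
    if T2i >= relax.T2b:
        raise ValueError(
            f"T2i ({T2i} ms) must be below T2b ({relax.T2b} ms): the surface "
            "relaxation contribution is otherwise nonpositive"
        )
    return 2.0 * relax.rho2 * 1e-3 / (1.0 / T2i - 1.0 / relax.T2b)


def fit_diffusion_radius(
    series: SphericalMeanSeries,
    protocol: AcquisitionProtocol,
    diff: DiffusionParams = DiffusionParams(),
    **kwargs,
) -> EffectiveRadiusFit:
    """Effective radius from a measured multi-b spherical-mean series.

    Thin wrapper over the single-cylinder diffusion fit; the scale beta
    absorbs the absolute signal level, so the result is invariant to
    rescaling the series.
    """
    if series.axis_kind != "b":
        raise ValueError("fit_diffusion_radius requires a b-axis series")
    return fit_single_cylinder_diffusion(series, protocol, diff, **kwargs)


def estimate_snr(
    b0_stack: np.ndarray,
    mask: np.ndarray | None = None,
) -> float:
    """Mean voxelwise SNR of repeated b0 images.

    ``b0_stack`` has shape (n_voxels, n_repeats); the voxelwise SNR is the
    mean over repeats divided by their SD (ddof=1), averaged over the mask.
    With few repeats the reciprocal of the sample SD overestimates 1/sigma
    by the known chi-distribution factor sqrt(nu/2) Gamma((nu-1)/2) /
    Gamma(nu/2) (nu = n_repeats - 1, about 1.25 for five repeats); the
    voxelwise ratios are divided by it so the estimate targets the
    underlying Gaussian SNR.  Zero-variance voxels are excluded with a
    warning; if all are excluded a ValueError is raised.
    """
    arr = np.asarray(b0_stack, float)
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise ValueError("b0_stack must be (n_voxels, n_repeats) with >= 2 repeats")
    if mask is not None:
        mask = np.asarray(mask, bool)
        if mask.shape != (arr.shape[0],):
            raise ValueError("mask must be a boolean vector over voxels")
        if not mask.any():
            raise ValueError("mask is empty")
        arr = arr[mask]
    sd = arr.std(axis=1, ddof=1)
    ok = sd > 0
    if not ok.all():
        warnings.warn(
            f"excluding {np.count_nonzero(~ok)} zero-variance voxel(s) from SNR",
            RuntimeWarning,
            stacklevel=2,
        )
    if not ok.any():
        raise ValueError("all voxels have zero variance; SNR undefined")
    nu = arr.shape[1] - 1
    from scipy.special import gammaln

    if nu >= 2:
        debias = np.sqrt(nu / 2.0) * np.exp(
            gammaln((nu - 1) / 2.0) - gammaln(nu / 2.0)
        )
    else:
        debias = 1.0  # two repeats: the correction factor is undefined
    snr = arr[ok].mean(axis=1) / sd[ok] / debias
    return float(snr.mean())


def compare_radii(x: np.ndarray, y: np.ndarray) -> RegressionReport:
    """OLS regression of y on x with Pearson R and two-sided p-value.

    The p-value follows the t distribution with n-2 degrees of freedom and
    is reported as NaN when fewer than 3 pairs are supplied.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size < 2:
        raise ValueError("need at least two pairs")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("values must be finite")
    if np.ptp(x) == 0:
        raise ValueError("x has zero variance; regression undefined")
    if x.size == 2:
        slope, intercept = np.polyfit(x, y, 1)
        r = 1.0 if np.ptp(y) > 0 else 0.0
        return RegressionReport(float(slope), float(intercept), r, float("nan"), 2)
    res = stats.linregress(x, y)
    return RegressionReport(
        slope=float(res.slope),
        intercept=float(res.intercept),
        R=float(res.rvalue),
        p=float(res.pvalue),
        n=int(x.size),
    )
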