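"""Surface-relaxivity calibration against known radius distributions.

The T2 branch needs two material constants: the bulk relaxation time T2b
(measured once from a free-water control tube) and the surface relaxivity
rho2, which couples the pore surface-to-volume ratio to the transverse
relaxation rate.  rho2 is calibrated per phantom by matching the measured
multi-TE spherical-mean series to the volume-weighted synthetic relaxation
series generated from the known radii, minimizing the mean squared
difference over (rho2, K).  The scale K is profiled out in closed form, so
the search is one-dimensional: a coarse grid over the rho2 interval followed
by bounded local refinement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize

from .core_models import RadiusSample, RelaxationParams
from .effective_radius import synth_relaxation_series
from .estimation import MonoExpFit, SphericalMeanSeries, fit_monoexp_t2

__all__ = [
    "CalibrationResult",
    "PooledRelaxivity",
    "calibrate_rho2",
    "pooled_relaxivity",
    "estimate_t2b",
    "DEFAULT_RHO2_BOUNDS",
]

DEFAULT_RHO2_BOUNDS = (0.1, 20.0)
_GRID_POINTS = 200
_BOUND_MARGIN = 0.01


@dataclass(frozen=True)
class CalibrationResult:
    """Per-phantom surface-relaxivity fit: rho2 (nm/ms), scale K and loss."""

    rho2: float
    K: float
    loss: float
    bounds_hit: bool
    label: str = ""


@dataclass(frozen=True)
class PooledRelaxivity:
    """Mean/SD of per-phantom relaxivities, with the per-phantom values kept."""

    rho2_mean: float
    rho2_sd: float
    per_phantom: dict


def _profiled_loss(y: np.ndarray, f: np.ndarray) -> tuple[float, float]:
    """Least-squares scale K and mean squared residual of y ~ K f."""
    denom = float(np.dot(f, f))
    K = float(np.dot(y, f)) / denom if denom > 0 else 0.0
    resid = y - K * f
    return K, float(np.mean(resid**2))


def calibrate_rho2(
    measured: SphericalMeanSeries,
    sample: RadiusSample,
    T2b: float = 3000.0,
    bounds: tuple[float, float] = DEFAULT_RHO2_BOUNDS,
    grid_points: int = _GRID_POINTS,
) -> CalibrationResult:
    """Estimate rho2 by matching a measured TE series to the synthetic one.

    Parameters
    ----------
    measured : multi-TE spherical-mean series (>= 3 points).
    sample : the known radius distribution of the same specimen.
    T2b : bulk relaxation time, ms.
    bounds : rho2 search interval, nm/ms.
    grid_points : size of the coarse search grid before local refinement.

    The fit is scale-invariant: multiplying the series by any positive
    constant changes K, not rho2.  An optimum within 1% of either bound is
    flagged.
    """
    if measured.axis_kind != "TE":
        raise ValueError("calibration requires a TE-axis series")
    if len(measured) < 3:
        raise ValueError("need at least three TE points to calibrate rho2")
    if T2b <= 0:
        raise ValueError(f"T2b must be positive, got {T2b}")
    TE = measured.axis
    y = measured.mean_signal
    if np.ptp(y) == 0:
        raise ValueError("series is constant; rho2 is unidentifiable")
    lo, hi = bounds

    def loss_of(rho2: float) -> float:
        f = synth_relaxation_series(sample, TE, RelaxationParams(T2b, rho2))
        return _profiled_loss(y, f)[1]

    grid = np.linspace(lo, hi, grid_points)
    losses = np.array([loss_of(r) for r in grid])
    i = int(np.argmin(losses))
    left = grid[max(i - 1, 0)]
    right = grid[min(i + 1, grid_points - 1)]
    res = optimize.minimize_scalar(
        loss_of, bounds=(left, right), method="bounded",
        options={"xatol": 1e-6},
    )
    rho2_opt = float(res.x) if res.fun <= losses[i] else float(grid[i])
    f_opt = synth_relaxation_series(sample, TE, RelaxationParams(T2b, rho2_opt))
    K_opt, loss_opt = _profiled_loss(y, f_opt)
    return CalibrationResult(
        rho2=rho2_opt,
        K=K_opt,
        loss=loss_opt,
        bounds_hit=bool(
            rho2_opt <= lo * (1 + _BOUND_MARGIN)
            or rho2_opt >= hi * (1 - _BOUND_MARGIN)
        ),
        label=sample.label,
    )


def pooled_relaxivity(
    per_phantom: Sequence[CalibrationResult],
    exclude: Iterable[str] = (),
) -> PooledRelaxivity:
    """Arithmetic mean and SD (ddof=1) of per-phantom rho2 values.

    ``exclude`` removes phantoms by label before pooling (e.g. a specimen
    whose material visibly degraded).  A single surviving value has SD 0.
    """
    excluded = set(exclude)
    kept = [c for c in per_phantom if c.label not in excluded]
    if not kept:
        raise ValueError("no calibration results left after exclusion")
    values = np.array([c.rho2 for c in kept])
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    return PooledRelaxivity(
        rho2_mean=float(values.mean()),
        rho2_sd=sd,
        per_phantom={c.label: (c.rho2, c.loss) for c in kept},
    )


def estimate_t2b(
    control: SphericalMeanSeries,
    t2_bounds: tuple[float, float] = (1.0, 10000.0),
) -> MonoExpFit:
    """Bulk T2 from a free-water control series (mono-exponential fit).

    The default bounds extend well beyond free-water T2 (~3 s) so that a
    genuine bulk value does not sit on the search boundary; a flat series
    still pins T2 at the upper bound and is flagged.
    """
    return fit_monoexp_t2(control, t2_bounds=t2_bounds)
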