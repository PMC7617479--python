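"""Closed-form and series signal physics for water in cylindrical pores.

Unit conventions (canonical internal system)
--------------------------------------------
radii           micrometres (um)
times           milliseconds (ms); gradient timings delta, Delta and TE
diffusivities   um^2/ms
b-values        accepted in s/mm^2 at the API surface, converted internally
                to ms/um^2 (factor 1e-3)
gradients       mT/m
surface relaxivity rho2   nm/ms (converted to um/ms with a 1e-3 factor
                inside the Brownstein-Tarr relation)

The forward model for the spherical-mean (powder-average) signal of a
distribution of water-filled cylinders is

    S(b, TE) = k * sum_i w_i * exp(-TE / T2i(r_i)) * S_diff(b, r_i),

with volume weights w_i = r_i^2 / sum_j r_j^2 (signal is proportional to the
water volume of each cylinder), the Brownstein-Tarr intra-pore relaxation
time 1/T2i = 1/T2b + 2*rho2/r, and S_diff the spherical-mean signal of an
axisymmetric diffusion tensor whose radial diffusivity D_perp(r) follows the
van Gelderen Gaussian-phase-distribution model for restricted diffusion
inside a cylinder.
"""

from __future__ import annotations

from dataclasses import dataclass


import numpy as np
from scipy import special

__all__ = [
    "GYROMAGNETIC_RATIO",
    "BESSEL_J1PRIME_ZEROS",
    "ProtocolError",
    "AcquisitionProtocol",
    "RelaxationParams",
    "DiffusionParams",
    "RadiusSample",
    "b_value",
    "gradient_from_b",
    "radial_diffusivity_vg",
    "radial_diffusivity_neuman",
    "radial_diffusivity_medium_pulse",
    "smt_diffusion",
    "t2_intra",
    "joint_signal",
    "protocol_preset",
    "PROTOCOL_PRESETS",
]

#: Proton gyromagnetic ratio, rad s^-1 T^-1.
GYROMAGNETIC_RATIO = 2.6752218744e8

#: Positive zeros of J1', the derivative of the first-order Bessel function.
#: 256 roots cover any practical series truncation (default m = 18) with
#: ample headroom for high-order convergence checks.
BESSEL_J1PRIME_ZEROS = special.jnp_zeros(1, 256)


class ProtocolError(ValueError):
    """Raised for physically inconsistent acquisition parameters."""


def b_value(G: float, delta: float, Delta: float) -> float:
    """Diffusion weighting b = gamma^2 G^2 delta^2 (Delta - delta/3).

    Parameters
    ----------
    G : gradient amplitude, mT/m.
    delta : gradient pulse duration, ms.
    Delta : pulse separation, ms.

    Returns
    -------
    b-value in s/mm^2 for a rectangular PGSE pulse pair.
    """
    if delta <= 0:
        raise ProtocolError(f"delta must be positive, got {delta}")
    if Delta <= delta:
        raise ProtocolError(f"Delta ({Delta}) must exceed delta ({delta})")
    if G < 0:
        raise ProtocolError(f"gradient amplitude must be nonnegative, got {G}")
    g_si = G * 1e-3            # T/m
    d_si = delta * 1e-3        # s
    sep_si = Delta * 1e-3      # s
    b_si = GYROMAGNETIC_RATIO**2 * g_si**2 * d_si**2 * (sep_si - d_si / 3.0)
    return b_si * 1e-6         # s/m^2 -> s/mm^2


def gradient_from_b(b: float, delta: float, Delta: float) -> float:
    """Invert :func:`b_value`: gradient amplitude (mT/m) for a target b (s/mm^2)."""
    if b < 0:
        raise ProtocolError(f"b must be nonnegative, got {b}")
    unit = b_value(1.0, delta, Delta)
    return float(np.sqrt(b / unit))


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Rectangular-pulse PGSE timing and weighting parameters.

    delta, Delta in ms; G in mT/m; b in s/mm^2; TE in ms.  When both G and b
    are supplied they must agree through the PGSE relation within
    ``b_tolerance`` (relative); when only G is given, b is derived.
    """

    delta: float
    Delta: float
    G: float | None = None
    b: float | None = None
    TE: float | None = None
    n_directions: int = 48
    b_tolerance: float = 0.05

    def __post_init__(self) -> None:
        if self.delta <= 0:
            raise ProtocolError(f"delta must be positive, got {self.delta}")
        if self.Delta <= self.delta:
            raise ProtocolError(
                f"Delta ({self.Delta}) must exceed delta ({self.delta})"
            )
        if self.TE is not None and self.TE <= 0:
            raise ProtocolError(f"TE must be positive, got {self.TE}")
        if self.n_directions < 1:
            raise ProtocolError("n_directions must be at least 1")
        if self.b is not None and self.b < 0:
            raise ProtocolError(f"b must be nonnegative, got {self.b}")
        if self.G is not None:
            b_from_g = b_value(self.G, self.delta, self.Delta)
            if self.b is None:
                object.__setattr__(self, "b", b_from_g)
            elif self.b > 0 and abs(b_from_g - self.b) > self.b_tolerance * self.b:
                raise ProtocolError(
                    f"stated b={self.b:.0f} s/mm^2 disagrees with the value "
                    f"{b_from_g:.0f} implied by G={self.G} mT/m beyond "
                    f"{100 * self.b_tolerance:.0f}% tolerance"
                )

    @property
    def diffusion_time(self) -> float:
        """Effective diffusion time Delta - delta/3, ms."""
        return self.Delta - self.delta / 3.0


@dataclass(frozen=True)
class RelaxationParams:
    """Bulk relaxation time T2b (ms) and surface relaxivity rho2 (nm/ms)."""

    T2b: float = 3000.0
    rho2: float = 3.7

    def __post_init__(self) -> None:
        if self.T2b <= 0:
            raise ValueError(f"T2b must be positive, got {self.T2b}")
        if self.rho2 < 0:
            raise ValueError(f"rho2 must be nonnegative, got {self.rho2}")


@dataclass(frozen=True)
class DiffusionParams:
    """Intrinsic (axial) diffusivity D_par (um^2/ms) and series truncation.

    D_par defaults to 2.0 um^2/ms, free water near room temperature; m_terms
    is the number of terms kept in the van Gelderen series (default 18).
    """

    D_par: float = 2.0
    m_terms: int = 18

    def __post_init__(self) -> None:
        if self.D_par <= 0:
            raise ValueError(f"D_par must be positive, got {self.D_par}")
        if self.m_terms < 1:
            raise ValueError(f"m_terms must be at least 1, got {self.m_terms}")
        if self.m_terms > BESSEL_J1PRIME_ZEROS.size:
            raise ValueError(
                f"m_terms cannot exceed the tabulated "
                f"{BESSEL_J1PRIME_ZEROS.size} Bessel roots"
            )


@dataclass
class RadiusSample:
    """A set of inner pore radii (um) standing for the distribution P(r).

    ``counts`` allows binned histograms to act as weighted samples (bin
    centre, multiplicity); when omitted every radius counts once.  Radii are
    conventionally circular-equivalent, r = sqrt(A/pi), from cross-sectional
    areas.
    """

    radii: np.ndarray
    counts: np.ndarray | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.radii = np.atleast_1d(np.asarray(self.radii, dtype=float))
        if self.radii.size == 0:
            raise ValueError("radius sample must be nonempty")
        if not np.all(np.isfinite(self.radii)):
            raise ValueError("radii must be finite")
        if np.any(self.radii <= 0):
            raise ValueError("all radii must be positive")
        if self.counts is not None:
            self.counts = np.atleast_1d(np.asarray(self.counts, dtype=float))
            if self.counts.shape != self.radii.shape:
                raise ValueError("counts must match radii in shape")
            if np.any(self.counts <= 0) or not np.all(np.isfinite(self.counts)):
                raise ValueError("counts must be positive and finite")

    def __len__(self) -> int:
        return int(self.radii.size)

    @property
    def effective_counts(self) -> np.ndarray:
        if self.counts is None:
            return np.ones_like(self.radii)
        return self.counts

    @property
    def volume_weights(self) -> np.ndarray:
        """Normalized volume weights w_i proportional to count_i * r_i^2."""
        w = self.effective_counts * self.radii**2
        return w / w.sum()

    def moment(self, p: float) -> float:
        """Count-weighted raw moment <r^p> of the sample."""
        c = self.effective_counts
        return float(np.sum(c * self.radii**p) / np.sum(c))


def radial_diffusivity_vg(
    r: float | np.ndarray,
    protocol: AcquisitionProtocol,
    diff: DiffusionParams = DiffusionParams(),
) -> float | np.ndarray:
    """Apparent radial diffusivity D_perp(r) of a cylinder, van Gelderen model.

    Gaussian-phase-distribution series for restricted diffusion perpendicular
    to a cylinder of radius r (um) under rectangular PGSE pulses:

        D_perp = 2 / (delta^2 (Delta - delta/3)) * sum_m N_m / D_m,
        N_m = 2 t_m delta - 2 + 2 e^{-t_m delta} + 2 e^{-t_m Delta}
              - e^{-t_m (Delta - delta)} - e^{-t_m (Delta + delta)},
        D_m = a_m^6 D_par^2 (a_m^2 r^2 - 1),    t_m = D_par a_m^2,

    with a_m = beta_m / r and beta_m the m-th zero of J1'.  The gradient
    amplitude cancels because the attenuation and the b-value are both
    quadratic in G.  The result is clamped to [0, D_par].

    Returns a scalar for scalar input, else an ndarray.
    """
    r_arr = np.atleast_1d(np.asarray(r, dtype=float))
    if np.any(r_arr <= 0):
        raise ValueError("radius must be positive")
    delta, Delta = protocol.delta, protocol.Delta
    D0 = diff.D_par
    beta = BESSEL_J1PRIME_ZEROS[: diff.m_terms][None, :]
    a2 = (beta / r_arr[:, None]) ** 2              # 1/um^2
    t = D0 * a2                                    # 1/ms
    num = (
        2.0 * t * delta
        - 2.0
        + 2.0 * np.exp(-t * delta)
        + 2.0 * np.exp(-t * Delta)
        - np.exp(-t * (Delta - delta))
        - np.exp(-t * (Delta + delta))
    )
    den = D0**2 * a2**3 * (beta**2 - 1.0)
    d_perp = 2.0 * np.sum(num / den, axis=1) / (delta**2 * (Delta - delta / 3.0))
    d_perp = np.clip(d_perp, 0.0, D0)
    return float(d_perp[0]) if np.isscalar(r) or np.ndim(r) == 0 else d_perp


def radial_diffusivity_neuman(
    r: float | np.ndarray,
    protocol: AcquisitionProtocol,
    diff: DiffusionParams = DiffusionParams(),
) -> float | np.ndarray:
    """Wide-pulse (Neuman) closed form D_perp = 7 r^4 / (48 D_par delta (Delta - delta/3)).

    Valid only in the regime Delta >> delta >> r^2/D_par, i.e. for small
    radii; overestimates the van Gelderen value increasingly with r.  The
    result is clamped to D_par.
    """
    r_arr = np.atleast_1d(np.asarray(r, dtype=float))
    if np.any(r_arr <= 0):
        raise ValueError("radius must be positive")
    d_perp = 7.0 * r_arr**4 / (
        48.0 * diff.D_par * protocol.delta * (protocol.Delta - protocol.delta / 3.0)
    )
    d_perp = np.clip(d_perp, 0.0, diff.D_par)
    return float(d_perp[0]) if np.isscalar(r) or np.ndim(r) == 0 else d_perp


def radial_diffusivity_medium_pulse(
    r: float | np.ndarray,
    protocol: AcquisitionProtocol,
    diff: DiffusionParams = DiffusionParams(),
) -> float | np.ndarray:
    """Medium-pulse-regime approximation (Delta >> delta >~ r^2/D_par).

    Not implemented: the closed form for this regime is not available to this
    package; use :func:`radial_diffusivity_vg`, which is accurate for both
    small and large radii.
    """
    raise NotImplementedError(
        "the medium-pulse approximation is not available; use "
        "radial_diffusivity_vg instead"
    )


# Below this value of b*(D_par - D_perp) the erf-based form of the spherical
# mean is evaluated by its Taylor expansion to avoid 0/0.
_SMT_TAYLOR_THRESHOLD = 1e-12


def smt_diffusion(
    b: float | np.ndarray,
    D_par: float,
    D_perp: float | np.ndarray,
) -> float | np.ndarray:
    """Spherical-mean signal of an axisymmetric (prolate) diffusion tensor.

        S(b) = sqrt(pi)/2 * exp(-b D_perp) * erf(sqrt(b (D_par - D_perp)))
                                             / sqrt(b (D_par - D_perp))

    Parameters
    ----------
    b : b-value in s/mm^2 (converted internally to ms/um^2).
    D_par, D_perp : axial and radial diffusivities, um^2/ms, with
        ``D_perp <= D_par`` (prolate axisymmetry).

    At the isotropic limit D_perp = D_par the expression reduces to
    exp(-b D); at b = 0 it returns 1.  A second-order Taylor expansion of
    erf(x)/x is used when b (D_par - D_perp) falls below 1e-12.
    """
    b_arr = np.atleast_1d(np.asarray(b, dtype=float)) * 1e-3  # -> ms/um^2
    dp_arr = np.atleast_1d(np.asarray(D_perp, dtype=float))
    if np.any(b_arr < 0):
        raise ValueError("b must be nonnegative")
    if np.any(dp_arr < 0):
        raise ValueError("D_perp must be nonnegative")
    if np.any(dp_arr > D_par * (1.0 + 1e-12)):
        raise ValueError("D_perp must not exceed D_par (prolate model)")
    dp_arr = np.minimum(dp_arr, D_par)
    y = b_arr * (D_par - dp_arr)
    small = y < _SMT_TAYLOR_THRESHOLD
    y_safe = np.where(small, 1.0, y)
    x = np.sqrt(y_safe)
    factor = np.where(
        small,
        1.0 - y / 3.0 + y**2 / 10.0,
        np.sqrt(np.pi) / 2.0 * special.erf(x) / x,
    )
    out = np.exp(-b_arr * dp_arr) * factor
    if np.ndim(b) == 0 and np.ndim(D_perp) == 0:
        return float(out[0])
    return out


def t2_intra(
    r: float | np.ndarray,
    relax: RelaxationParams,
) -> float | np.ndarray:
    """Intra-pore transverse relaxation time of a cylinder (Brownstein-Tarr).

        1/T2i = 1/T2b + 2 rho2 / r

    with rho2 in nm/ms and r in um (hence the 1e-3 conversion).  T2i is
    strictly increasing in r and tends to T2b as r -> infinity.
    """
    r_arr = np.atleast_1d(np.asarray(r, dtype=float))
    if np.any(r_arr <= 0):
        raise ValueError("radius must be positive")
    rate = 1.0 / relax.T2b + 2.0 * relax.rho2 * 1e-3 / r_arr
    t2i = 1.0 / rate
    return float(t2i[0]) if np.isscalar(r) or np.ndim(r) == 0 else t2i


def joint_signal(
    b: float,
    TE: float,
    sample: RadiusSample,
    relax: RelaxationParams,
    diff: DiffusionParams,
    protocol: AcquisitionProtocol,
    k: float = 1.0,
) -> float:
    """Discretized unified diffusion-relaxation spherical-mean signal.

        S(b, TE) = k * sum_i w_i exp(-TE/T2i(r_i)) S_diff(b, r_i),
        w_i = count_i r_i^2 / sum_j count_j r_j^2.

    b in s/mm^2, TE in ms.  The weights are the volume fractions of the
    cylinders, so the signal is non-increasing in both b and TE.
    """
    if k <= 0:
        raise ValueError(f"scale k must be positive, got {k}")
    w = sample.volume_weights
    relax_factor = np.exp(-TE / t2_intra(sample.radii, relax))
    d_perp = radial_diffusivity_vg(sample.radii, protocol, diff)
    diff_factor = smt_diffusion(b, diff.D_par, np.atleast_1d(d_perp))
    return float(k * np.sum(w * relax_factor * diff_factor))


# Acquisition presets used throughout: a multi-TE block at fixed b for the
# T2 branch and a multi-b block at fixed TE for the diffusion branch.
PROTOCOL_PRESETS: dict[str, dict] = {
    "phantom_t2_block": {
        "delta": 9.0,
        "Delta": 35.0,
        "b": 5000.0,
        "G": 166.8,
        "TE_list": [51.0, 75.0, 100.0, 150.0, 200.0, 250.0],
        "n_directions": 48,
    },
    "phantom_dmri_block": {
        "delta": 9.0,
        "Delta": 35.0,
        "TE": 51.0,
        "b_list": [5000.0, 6000.0, 7000.0, 8000.0, 10000.0],
        "G_list": [166.8, 182.7, 197.3, 210.95, 235.85],
        "n_directions": 48,
    },
}


def protocol_preset(name: str) -> dict:
    """Return a copy of a named acquisition preset.

    ``phantom_t2_block``: b = 5000 s/mm^2 (G = 166.8 mT/m, Delta/delta =
    35/9 ms), 48 directions, six TEs from 51 to 250 ms.
    ``phantom_dmri_block``: TE = 51 ms, five shells b = 5000..10000 s/mm^2.
    """
    try:
        preset = PROTOCOL_PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(PROTOCOL_PRESETS)}"
        ) from None
    return {k: (list(v) if isinstance(v, list) else v) for k, v in preset.items()}


def protocol_from_preset(name: str) -> AcquisitionProtocol:
    """Build the base :class:`AcquisitionProtocol` (timings) of a preset."""
    p = protocol_preset(name)
    return AcquisitionProtocol(
        delta=p["delta"],
        Delta=p["Delta"],
        b=p.get("b"),
        n_directions=p.get("n_directions", 48),
    )
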