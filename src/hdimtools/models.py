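"""Forward photophysical models for multi-channel fluorescence detection.

A pulsed-excitation fluorescence microscope partitions detected photons over
channels indexed by arrival time (time gates within the laser period),
emission wavelength (spectral bins) and polarization (analyzer orientation).
This module computes, in closed form, the expected fraction of detected
photons falling in each channel for a fluorophore described by a
mono-exponential excited-state decay with lifetime ``tau``, a single-exponential
anisotropy decay ``r(t) = r0 * exp(-t / theta)`` and a unimodal emission
spectrum (gamma-shaped by default, optionally Gaussian).

The per-channel fraction vector of one fluorophore over the full grid is its
hyper-dimensional spectral signature (:class:`HDSS`); mixtures of fluorophores
produce expected counts that are linear in the abundances.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize as _sciopt
from scipy import stats as _stats

from .errors import (
    DegenerateSpectrumError,
    DomainError,
    IncompatibleEndmembersError,
    InvalidPartitionError,
)

__all__ = [
    "FluorophoreModel",
    "DetectionGrid",
    "HDSS",
    "POLARIZATION_STATES",
    "decay_fractions",
    "polarized_time_fractions",
    "spectrum_fractions",
    "gamma_spectrum_distribution",
    "build_hdss",
    "expected_counts",
]

POLARIZATION_STATES = ("parallel", "perpendicular", "unpolarized")

#: Default gamma shape parameter for emission spectra.  A gamma density with
#: shape k has skewness 2/sqrt(k); k = 16 gives a visibly asymmetric
#: (skewness 0.5) but still spectrum-like profile with a red tail.
DEFAULT_GAMMA_SHAPE = 16.0

_ZERO_TOL = 1e-12


@dataclass(frozen=True)
class FluorophoreModel:
    """Photophysical parameters of a single emitter.

    Parameters
    ----------
    lifetime_tau :
        Excited-state (fluorescence) lifetime in ns; must be positive.
    limiting_anisotropy_r0 :
        Fluorescence anisotropy at time zero, in [0, 0.4] for one-photon
        excitation.
    rot_corr_theta :
        Rotational correlation time in ns governing the anisotropy decay.
    spectral_peak :
        Emission-spectrum mode in nm.
    spectral_fwhm :
        Emission-spectrum full width at half maximum in nm.
    brightness :
        Relative brightness weight (arbitrary units, default 1).
    """

    lifetime_tau: float
    limiting_anisotropy_r0: float = 0.0
    rot_corr_theta: float = 1.0
    spectral_peak: float = 500.0
    spectral_fwhm: float = 50.0
    brightness: float = 1.0
    name: str = ""

    def __post_init__(self) -> None:
        if self.lifetime_tau <= 0:
            raise DomainError(f"lifetime_tau must be > 0, got {self.lifetime_tau}")
        if not 0.0 <= self.limiting_anisotropy_r0 <= 0.4:
            raise DomainError(
                "limiting_anisotropy_r0 must be in [0, 0.4], got "
                f"{self.limiting_anisotropy_r0}"
            )
        if self.rot_corr_theta <= 0:
            raise DomainError(f"rot_corr_theta must be > 0, got {self.rot_corr_theta}")
        if self.spectral_fwhm <= 0:
            raise DomainError(f"spectral_fwhm must be > 0, got {self.spectral_fwhm}")
        if self.brightness <= 0:
            raise DomainError(f"brightness must be > 0, got {self.brightness}")


@dataclass(frozen=True)
class DetectionGrid:
    """Channel partition along time, wavelength and polarization.

    ``time_edges`` are gate boundaries in ns within ``[0, laser_period_T]``;
    ``wavelength_edges`` are spectral-bin boundaries in nm;
    ``polarization_states`` is an ordered subset of
    ``("parallel", "perpendicular", "unpolarized")``.

    Channel ordering is polarization-major, then wavelength, then time; all
    bins are half-open ``[lo, hi)``.
    """

    time_edges: tuple[float, ...]
    laser_period_T: float
    wavelength_edges: tuple[float, ...]
    polarization_states: tuple[str, ...] = ("parallel", "perpendicular")

    def __post_init__(self) -> None:
        t = np.asarray(self.time_edges, dtype=float)
        w = np.asarray(self.wavelength_edges, dtype=float)
        object.__setattr__(self, "time_edges", tuple(t.tolist()))
        object.__setattr__(self, "wavelength_edges", tuple(w.tolist()))
        if self.laser_period_T <= 0:
            raise DomainError("laser_period_T must be positive")
        _check_edges(t, "time_edges")
        _check_edges(w, "wavelength_edges")
        if t[0] < -_ZERO_TOL or t[-1] > self.laser_period_T + _ZERO_TOL:
            raise InvalidPartitionError(
                f"time_edges must lie within [0, T={self.laser_period_T}]"
            )
        if len(self.polarization_states) == 0:
            raise InvalidPartitionError("at least one polarization state required")
        for p in self.polarization_states:
            if p not in POLARIZATION_STATES:
                raise DomainError(
                    f"unknown polarization state {p!r}; expected one of "
                    f"{POLARIZATION_STATES}"
                )

    @classmethod
    def paper_default(cls) -> "DetectionGrid":
        """The 2 x 16 x 64 reference grid: 64 time gates over 12.5 ns, 16
        spectral bins over 440-630 nm, two polarization channels."""
        return cls(
            time_edges=tuple(np.linspace(0.0, 12.5, 65)),
            laser_period_T=12.5,
            wavelength_edges=tuple(np.linspace(440.0, 630.0, 17)),
            polarization_states=("parallel", "perpendicular"),
        )

    @property
    def n_time(self) -> int:
        return len(self.time_edges) - 1

    @property
    def n_wavelength(self) -> int:
        return len(self.wavelength_edges) - 1

    @property
    def n_polarization(self) -> int:
        return len(self.polarization_states)

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.n_polarization, self.n_wavelength, self.n_time)

    @property
    def n_channels(self) -> int:
        return self.n_polarization * self.n_wavelength * self.n_time


@dataclass(frozen=True)
class HDSS:
    """Hyper-dimensional spectral signature: per-channel detection
    probabilities of one fluorophore on a :class:`DetectionGrid`.

    ``fractions`` has shape ``(n_polarization, n_wavelength, n_time)``, is
    non-negative and sums to 1 over the whole grid.
    """

    grid: DetectionGrid
    fractions: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.fractions, dtype=float)
        if f.shape != self.grid.shape:
            raise InvalidPartitionError(
                f"fractions shape {f.shape} does not match grid shape "
                f"{self.grid.shape}"
            )
        if np.any(f < -_ZERO_TOL):
            raise DomainError("signature fractions must be non-negative")
        total = float(f.sum())
        if abs(total - 1.0) > 1e-9:
            raise DomainError(f"signature fractions must sum to 1, got {total}")
        object.__setattr__(self, "fractions", f)

    def ravel(self) -> np.ndarray:
        """Flat channel vector in polarization-major, wavelength, time order."""
        return self.fractions.reshape(-1)


def _check_edges(edges: np.ndarray, name: str) -> None:
    if edges.ndim != 1 or len(edges) < 2:
        raise InvalidPartitionError(f"{name} needs at least two edges")
    if not np.all(np.diff(edges) > 0):
        raise InvalidPartitionError(f"{name} must be strictly increasing")


def _wrapped_exp_gate_integrals(
    edges: np.ndarray, rate_time: float, T: float
) -> np.ndarray:
    """Per-gate integrals of the periodically wrapped exponential
    ``exp(-t/rate_time)`` observed within one laser period of length ``T``.

    Under repetitive pulsed excitation the steady-state signal within one
    period is ``exp(-t/rate) / (1 - exp(-T/rate))``; the gate integral is
    returned without the leading ``rate`` factor absorbed, i.e. it integrates
    to ``rate`` over a full cover of [0, T].
    """
    a = np.exp(-edges[:-1] / rate_time) - np.exp(-edges[1:] / rate_time)
    return rate_time * a / (-np.expm1(-T / rate_time))


def decay_fractions(time_edges, tau: float, T: float) -> np.ndarray:
    """Fractions of detected photons falling in each time gate for a
    mono-exponential decay with lifetime ``tau`` under a laser period ``T``.

    The gate ``[t_a, t_b)`` receives
    ``(exp(-t_a/tau) - exp(-t_b/tau)) / (1 - exp(-T/tau))``,
    i.e. photon arrival times from earlier pulses are wrapped into the
    current period (steady-state TCSPC histogram); a full cover of
    ``[0, T]`` sums to exactly 1.
    """
    if tau <= 0:
        raise DomainError(f"tau must be > 0, got {tau}")
    if T <= 0:
        raise DomainError(f"T must be > 0, got {T}")
    edges = np.asarray(time_edges, dtype=float)
    _check_edges(edges, "time_edges")
    if edges[0] < -_ZERO_TOL or edges[-1] > T + _ZERO_TOL:
        raise InvalidPartitionError(f"time_edges must lie within [0, T={T}]")
    num = np.exp(-edges[:-1] / tau) - np.exp(-edges[1:] / tau)
    return num / (-np.expm1(-T / tau))


def polarized_time_fractions(
    time_edges, tau: float, r0: float, theta: float, T: float
) -> np.ndarray:
    """Joint polarization x time-gate photon fractions.

    Models the analyzer-resolved decays (Lakowicz convention)

    .. math::

        I_\\parallel(t) \\propto e^{-t/\\tau}\\,(1 + 2 r(t))/3, \\qquad
        I_\\perp(t) \\propto e^{-t/\\tau}\\,(1 - r(t))/3,

    with anisotropy decay ``r(t) = r0 * exp(-t/theta)``.  Each polarization
    row is a sum of two exponentials (rates ``tau`` and
    ``tau*theta/(tau+theta)``); gate integrals are evaluated in closed form
    with periodic wrapping, and the returned 2 x n_gates matrix is normalized
    so that both rows over a full cover of ``[0, T]`` sum to 1.
    """
    if not 0.0 <= r0 <= 0.4:
        raise DomainError(f"r0 must be in [0, 0.4], got {r0}")
    if theta <= 0:
        raise DomainError(f"theta must be > 0, got {theta}")
    if tau <= 0:
        raise DomainError(f"tau must be > 0, got {tau}")
    edges = np.asarray(time_edges, dtype=float)
    _check_edges(edges, "time_edges")
    if edges[0] < -_ZERO_TOL or edges[-1] > T + _ZERO_TOL:
        raise InvalidPartitionError(f"time_edges must lie within [0, T={T}]")

    # decay component rates: pure lifetime and lifetime (x) rotation
    rate_iso = tau
    rate_rot = tau * theta / (tau + theta)
    g_iso = _wrapped_exp_gate_integrals(edges, rate_iso, T)
    g_rot = _wrapped_exp_gate_integrals(edges, rate_rot, T)

    par = g_iso / 3.0 + (2.0 * r0 / 3.0) * g_rot
    perp = g_iso / 3.0 - (r0 / 3.0) * g_rot
    # total detected intensity over a full period (both analyzer channels)
    total = (2.0 / 3.0) * rate_iso + (r0 / 3.0) * rate_rot
    return np.vstack([par, perp]) / total


def _gamma_half_width_roots(shape: float) -> tuple[float, float]:
    """Positions (in scale units) where a unit-scale gamma density with the
    given shape falls to half its modal value."""
    if shape <= 1.0:
        raise DomainError("gamma shape must be > 1 for a well-defined mode")
    mode = shape - 1.0

    def log_ratio(x: float) -> float:
        # log( f(x) / f(mode) ) + log 2
        return (shape - 1.0) * np.log(x / mode) - (x - mode) + np.log(2.0)

    lo = _sciopt.brentq(log_ratio, 1e-12 * mode + 1e-300, mode)
    hi = _sciopt.brentq(log_ratio, mode, mode * 50.0 + 50.0)
    return lo, hi


def gamma_spectrum_distribution(
    peak: float, fwhm: float, shape: float = DEFAULT_GAMMA_SHAPE
):
    """A frozen scipy gamma distribution reparameterized so its mode sits at
    ``peak`` (nm) and its FWHM equals ``fwhm`` (nm).

    The shape parameter controls the asymmetry (skewness ``2/sqrt(shape)``);
    the tail extends toward longer wavelengths, as in typical emission
    spectra.
    """
    if fwhm <= 0:
        raise DomainError(f"fwhm must be > 0, got {fwhm}")
    lo, hi = _gamma_half_width_roots(shape)
    scale = fwhm / (hi - lo)
    loc = peak - (shape - 1.0) * scale
    return _stats.gamma(a=shape, loc=loc, scale=scale)


def _gaussian_spectrum_distribution(peak: float, fwhm: float):
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    return _stats.norm(loc=peak, scale=sigma)


def spectrum_fractions(
    wavelength_edges,
    peak: float,
    fwhm: float,
    shape: str = "gamma",
    gamma_shape: float = DEFAULT_GAMMA_SHAPE,
) -> np.ndarray:
    """Per-spectral-bin photon fractions of a unimodal emission spectrum.

    The spectral density (``shape="gamma"`` by default, or ``"gaussian"``)
    is integrated over each wavelength bin and renormalized so the fractions
    over the stated detection range sum to 1.
    """
    edges = np.asarray(wavelength_edges, dtype=float)
    _check_edges(edges, "wavelength_edges")
    if shape == "gamma":
        dist = gamma_spectrum_distribution(peak, fwhm, gamma_shape)
    elif shape == "gaussian":
        dist = _gaussian_spectrum_distribution(peak, fwhm)
    else:
        raise DomainError(f"unknown spectrum shape {shape!r}")
    cdf = dist.cdf(edges)
    in_band = cdf[-1] - cdf[0]
    if in_band < 1e-6:
        raise DegenerateSpectrumError(
            f"spectrum peaked at {peak} nm places mass {in_band:.2e} inside "
            f"the detection range [{edges[0]}, {edges[-1]}] nm"
        )
    return np.diff(cdf) / in_band


def build_hdss(
    fluorophore: FluorophoreModel,
    grid: DetectionGrid,
    spectrum_shape: str = "gamma",
    gamma_shape: float = DEFAULT_GAMMA_SHAPE,
) -> HDSS:
    """Expected per-channel photon fractions of one fluorophore on a grid.

    The signature separates into a spectral factor and a joint
    polarization/time factor:
    ``fractions[pol, bin, gate] = spectrum[bin] * pol_time[pol, gate]``.
    The ``"unpolarized"`` state is the analyzer-free sum of the parallel and
    perpendicular channels.  When the grid selects only a subset of
    polarization components (e.g. a single analyzer orientation), fractions
    are renormalized over the detected subset.
    """
    spec = spectrum_fractions(
        grid.wavelength_edges,
        fluorophore.spectral_peak,
        fluorophore.spectral_fwhm,
        shape=spectrum_shape,
        gamma_shape=gamma_shape,
    )
    pt = polarized_time_fractions(
        grid.time_edges,
        fluorophore.lifetime_tau,
        fluorophore.limiting_anisotropy_r0,
        fluorophore.rot_corr_theta,
        grid.laser_period_T,
    )
    rows = {
        "parallel": pt[0],
        "perpendicular": pt[1],
        "unpolarized": pt[0] + pt[1],
    }
    pol_time = np.vstack([rows[p] for p in grid.polarization_states])
    pol_time = pol_time / pol_time.sum()
    fractions = spec[None, :, None] * pol_time[:, None, :]
    return HDSS(grid=grid, fractions=fractions)


def expected_counts(endmembers, abundances, N: float) -> np.ndarray:
    """Expected per-channel counts of a linear mixture.

    ``G = N * sum_j a_j * g_j`` where ``g_j`` are the endmember signatures.
    With fractional abundances (``sum a_j = 1``) the total expected count
    equals ``N``.
    """
    a = np.asarray(abundances, dtype=float)
    if len(endmembers) != len(a):
        raise DomainError("one abundance per endmember required")
    if np.any(a < 0):
        raise DomainError("abundances must be non-negative")
    grid = endmembers[0].grid
    for e in endmembers[1:]:
        if e.grid != grid:
            raise IncompatibleEndmembersError(
                "endmembers were built on different detection grids"
            )
    stack = np.stack([e.fractions for e in endmembers], axis=0)
    return N * np.tensordot(a, stack, axes=1)
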