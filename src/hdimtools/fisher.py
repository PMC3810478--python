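"""Poisson-channel Fisher information and photon-economy figures of merit.

For ``m`` independent photon-counting channels with expected counts
``G_i(x) = N f_i(x)`` the Fisher information on a scalar parameter ``x`` is

.. math:: I(x) = \\sum_i \\frac{(\\partial G_i/\\partial x)^2}{G_i},

and the photon economy (F-value) of an efficient estimator is
``F = (sigma_x / x) * sqrt(N)``, with ``sigma_x = I^{-1/2}``; ``F = 1``
means shot-noise-limited precision.  Refining the channel partition can only
increase ``I`` (photon partitioning), which is the basis of all optimization
in this package.

For linear unmixing of several fluorophore abundances the information is a
matrix whose inverse bounds the abundance covariance; the combined F-value
averages the per-abundance relative errors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize as _sciopt

from .errors import DomainError, IncompatibleEndmembersError, SingularModelError
from .models import HDSS, DetectionGrid, FluorophoreModel, build_hdss, decay_fractions

__all__ = [
    "FisherResult",
    "ExponentialDecaySignature",
    "MixtureSignature",
    "fisher_scalar",
    "f_value_scalar",
    "two_gate_f_curve",
    "two_gate_optimum",
    "split_gain",
    "fisher_matrix",
    "marginalize",
    "TECHNIQUES",
    "technique_fvalue_scan",
    "technique_minima",
    "photon_efficiency",
    "separability",
    "resolution_and_power",
    "cost_from_dark_counts",
]

#: Channels with fractions below this are dropped from information sums;
#: their contribution vanishes in the limit but the division is unstable.
ZERO_FRACTION = 1e-12

_DIM_AXES = {"polarization": 0, "wavelength": 1, "time": 2}

#: The seven nonempty marginalizations of a polarization x wavelength x time
#: grid, named by the detection technique they represent.
TECHNIQUES: dict[str, tuple[str, ...]] = {
    "FLIM": ("time",),
    "SPEC": ("wavelength",),
    "ANISO": ("polarization",),
    "SLIM": ("time", "wavelength"),
    "TR-ANISO": ("time", "polarization"),
    "SR-ANISO": ("wavelength", "polarization"),
    "HDIM": ("time", "wavelength", "polarization"),
}


@dataclass(frozen=True)
class FisherResult:
    """Fisher matrix, covariance and F-values for a multi-parameter model.

    ``information`` is the total (not per-photon) matrix; ``covariance`` is
    its inverse; ``per_param_F[j] = sigma_j * sqrt(N a_j) / a_j`` with
    ``a_j`` the fractional abundance, i.e. the relative error of abundance
    ``j`` referenced to the shot noise of the ``a_j N`` photons that
    component contributes; ``combined_F`` is the unweighted mean of the
    per-parameter F-values.
    """

    information: np.ndarray
    covariance: np.ndarray
    per_param_F: np.ndarray
    combined_F: float
    N: float
    abundances: np.ndarray
    meta: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        """JSON-serializable representation."""
        return {
            "information": self.information.tolist(),
            "covariance": self.covariance.tolist(),
            "per_param_F": self.per_param_F.tolist(),
            "combined_F": self.combined_F,
            "N": self.N,
            "abundances": self.abundances.tolist(),
            "meta": dict(self.meta),
        }


class ExponentialDecaySignature:
    """Signature function tau -> time-gate fractions of a mono-exponential
    decay on fixed gates (periodic wrapping at the laser period ``T``)."""

    def __init__(self, time_edges, T: float):
        self.time_edges = np.asarray(time_edges, dtype=float)
        self.T = float(T)

    def __call__(self, tau: float) -> np.ndarray:
        return decay_fractions(self.time_edges, tau, self.T)


class MixtureSignature:
    """Signature function a -> a * gA + (1 - a) * gB for two fixed
    endmember fraction vectors (sum-to-one constrained mixture)."""

    def __init__(self, g_a, g_b):
        self.g_a = np.asarray(g_a, dtype=float)
        self.g_b = np.asarray(g_b, dtype=float)

    def __call__(self, a: float) -> np.ndarray:
        return a * self.g_a + (1.0 - a) * self.g_b


def _validate_fractions(f: np.ndarray) -> None:
    if np.any(f < -ZERO_FRACTION):
        raise DomainError("signature returned negative fractions")


def fisher_scalar(sig, x0: float, N: float = 1.0, delta: float = 0.01) -> float:
    """Total Fisher information on a scalar parameter from Poisson channels.

    Derivatives of the channel fractions are taken by central finite
    differences with relative step ``delta`` (absolute step ``delta * x0``).
    Channels with negligible fractions are excluded from the sum.
    """
    if delta <= 0:
        raise DomainError("delta must be positive")
    if N <= 0:
        raise DomainError("N must be positive")
    f0 = np.asarray(sig(x0), dtype=float)
    _validate_fractions(f0)
    h = delta * x0
    fp = np.asarray(sig(x0 + h), dtype=float)
    fm = np.asarray(sig(x0 - h), dtype=float)
    df = (fp - fm) / (2.0 * h)
    mask = f0 > ZERO_FRACTION
    return float(N * np.sum(df[mask] ** 2 / f0[mask]))


def f_value_scalar(sig, x0: float, N: float = 1.0, delta: float = 0.01) -> float:
    """Photon economy ``F = sqrt(N / I) / x0`` of estimating ``x`` at ``x0``.

    Independent of ``N`` (the information is proportional to ``N``).
    Returns ``inf`` with a warning for an information-free partition.
    """
    info_per_photon = fisher_scalar(sig, x0, N=1.0, delta=delta)
    if info_per_photon <= 0.0:
        warnings.warn(
            "partition carries no information on the parameter; F is infinite",
            RuntimeWarning,
            stacklevel=2,
        )
        return float("inf")
    return 1.0 / (x0 * np.sqrt(info_per_photon))


def two_gate_f_curve(u):
    """F-value of a two-adjacent-gate lifetime measurement as a function of
    the reduced boundary ``u = t_boundary / tau`` (laser period >> tau):

    .. math:: F(u) = \\sqrt{e^u - 1} / u.
    """
    u = np.asarray(u, dtype=float)
    if np.any(u <= 0):
        raise DomainError("reduced boundary u must be > 0")
    return np.sqrt(np.expm1(u)) / u


def two_gate_optimum() -> tuple[float, float]:
    """Optimal reduced boundary and minimal F for the two-gate system.

    The optimum solves ``u * exp(u) = 2 * (exp(u) - 1)`` (approximately
    u* = 1.59, F* = 1.24).
    """
    res = _sciopt.minimize_scalar(
        lambda u: float(two_gate_f_curve(u)), bounds=(0.1, 10.0), method="bounded",
        options={"xatol": 1e-12},
    )
    return float(res.x), float(res.fun)


def split_gain(G: float, phi: float, dphi_dx: float) -> float:
    """Information gained by splitting one channel of expected count ``G``
    with a partitioning function ``phi(x)``:

    .. math:: \\Delta I = G \\, (\\partial\\phi/\\partial x)^2 \\,/\\,
              (\\phi (1 - \\phi)) \\ge 0,

    zero exactly when the split is trivial (``dphi_dx = 0``).
    """
    if G <= 0:
        raise DomainError("channel count G must be positive")
    if not 0.0 < phi < 1.0:
        raise DomainError(f"partition fraction phi must be in (0, 1), got {phi}")
    return float(G * dphi_dx**2 / (phi * (1.0 - phi)))


def _as_channel_matrix(endmembers) -> np.ndarray:
    cols = []
    grid = None
    for e in endmembers:
        if isinstance(e, HDSS):
            if grid is not None and e.grid != grid:
                raise IncompatibleEndmembersError(
                    "endmembers were built on different detection grids"
                )
            grid = e.grid
            cols.append(e.ravel())
        else:
            cols.append(np.asarray(e, dtype=float).reshape(-1))
    if len({c.shape for c in cols}) > 1:
        raise IncompatibleEndmembersError("endmember signatures differ in length")
    return np.column_stack(cols)


def fisher_matrix(endmembers, abundances, N: float = 1.0) -> FisherResult:
    """Fisher information matrix for the abundances of a linear mixture.

    The forward model ``G_i = N * sum_j a_j g_ij`` is linear, so derivatives
    are analytic and

    .. math:: I_{jk} = N \\sum_i \\frac{g_{ij} g_{ik}}{\\sum_l a_l g_{il}}.

    The abundances are treated as free parameters (no sum constraint).  The
    per-parameter F-value compares the relative error of abundance ``j``
    with the Poisson noise of the photons that component itself contributes
    (``a_j N`` with ``a_j = a_j / sum(a)``):

    .. math:: F_j = \\frac{\\sigma_j}{a_j} \\sqrt{a_j N}
              = \\sigma_j \\sqrt{N / a_j},

    so that two fluorophores with fully disjoint channel support — where
    each abundance is estimated from its own independent Poisson counts —
    give exactly ``F_j = 1`` (shot-limited) at any mixture.
    """
    if len(endmembers) < 2:
        raise DomainError("at least two endmembers required")
    a = np.asarray(abundances, dtype=float)
    if np.any(a <= 0):
        raise DomainError("abundances must be strictly positive")
    if N <= 0:
        raise DomainError("N must be positive")
    g = _as_channel_matrix(endmembers)  # channels x J
    if g.shape[1] != len(a):
        raise DomainError("one abundance per endmember required")
    G = g @ a  # per-photon expected fractions of the mixture
    mask = G > ZERO_FRACTION
    gm = g[mask]
    info = N * (gm.T / G[mask]) @ gm
    cond = np.linalg.cond(info)
    if not np.isfinite(cond) or cond > 1e12:
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(g.T)
        dup = np.unravel_index(
            np.argmax(np.abs(corr) - 2 * np.eye(len(a))), corr.shape
        )
        raise SingularModelError(
            "Fisher matrix is singular: endmembers "
            f"{dup[0]} and {dup[1]} are (near-)identical"
        )
    cov = np.linalg.inv(info)
    frac = a / a.sum()
    per_param_F = np.sqrt(np.diag(cov) * N / frac)
    return FisherResult(
        information=info,
        covariance=cov,
        per_param_F=per_param_F,
        combined_F=float(per_param_F.mean()),
        N=N,
        abundances=a,
        meta={"information_scale": "total"},
    )


def marginalize(x, keep_dims) -> np.ndarray:
    """Sum a signature or count tensor over dropped detection dimensions.

    ``keep_dims`` is a nonempty subset of
    ``{"time", "wavelength", "polarization"}``; the result keeps the
    surviving axes in (polarization, wavelength, time) order and preserves
    the total exactly.  Mirrors post-hoc binning of photons on acquired
    data (e.g. SLIM and SPEC datasets derived from an HDIM acquisition).
    """
    keep = set(keep_dims)
    if not keep:
        raise DomainError("keep_dims must be nonempty")
    unknown = keep - set(_DIM_AXES)
    if unknown:
        raise DomainError(f"unknown dimensions: {sorted(unknown)}")
    arr = x.fractions if isinstance(x, HDSS) else np.asarray(x, dtype=float)
    if arr.ndim < 3:
        raise DomainError("expected a (pol, wavelength, time) tensor")
    drop = tuple(
        arr.ndim - 3 + ax for name, ax in _DIM_AXES.items() if name not in keep
    )
    return arr.sum(axis=drop) if drop else arr


def technique_fvalue_scan(
    fluoro_a: FluorophoreModel,
    fluoro_b: FluorophoreModel,
    grid: DetectionGrid,
    abundance_grid,
    techniques: dict[str, tuple[str, ...]] | None = None,
    spectrum_shape: str = "gamma",
) -> pd.DataFrame:
    """Combined F-value of two-fluorophore unmixing for every detection
    technique (marginalization of the full grid), across relative abundances.

    Returns a tidy frame with columns ``technique``, ``abundance``, ``F``
    and ``p`` (photon efficiency).  Lower F means a more photon-efficient
    technique; the full-grid HDIM row can never be beaten by any
    marginalization (photon partitioning).
    """
    abundances = np.asarray(abundance_grid, dtype=float)
    if np.any(abundances <= 0) or np.any(abundances >= 1):
        raise DomainError("abundance grid must lie strictly inside (0, 1)")
    techniques = TECHNIQUES if techniques is None else techniques
    h_a = build_hdss(fluoro_a, grid, spectrum_shape=spectrum_shape)
    h_b = build_hdss(fluoro_b, grid, spectrum_shape=spectrum_shape)
    rows = []
    for name, dims in techniques.items():
        g_a = marginalize(h_a, dims).reshape(-1)
        g_b = marginalize(h_b, dims).reshape(-1)
        for a in abundances:
            try:
                res = fisher_matrix([g_a, g_b], [a, 1.0 - a], N=1.0)
                F = res.combined_F
            except SingularModelError:
                F = float("inf")
            rows.append(
                {
                    "technique": name,
                    "abundance": float(a),
                    "F": F,
                    "p": photon_efficiency(F) if np.isfinite(F) else 0.0,
                }
            )
    return pd.DataFrame(rows)


def technique_minima(scan: pd.DataFrame) -> pd.DataFrame:
    """Minimum F per technique over the scanned abundances, plus the
    F-value at the abundance closest to 0.5."""
    out = []
    for name, sub in scan.groupby("technique", sort=False):
        i_min = sub["F"].idxmin()
        i_half = (sub["abundance"] - 0.5).abs().idxmin()
        out.append(
            {
                "technique": name,
                "min_F": sub.loc[i_min, "F"],
                "argmin_abundance": sub.loc[i_min, "abundance"],
                "F_at_half": sub.loc[i_half, "F"],
            }
        )
    return pd.DataFrame(out).sort_values("min_F").reset_index(drop=True)


def photon_efficiency(F: float) -> float:
    """Photon efficiency ``p = F**-2``: the fraction of photons effectively
    used relative to a shot-noise-limited measurement."""
    if F <= 0:
        raise DomainError("F must be positive")
    return float(F) ** -2


def separability(x1: float, sigma1: float, x2: float, sigma2: float) -> float:
    """Statistical separability of two parameter estimates,
    ``S = |x1 - x2| / sqrt(sigma1^2 + sigma2^2)``; ``S = 2`` plays the role
    of the Rayleigh criterion for biochemical resolution."""
    if sigma1 <= 0 or sigma2 <= 0:
        raise DomainError("uncertainties must be positive")
    return abs(x1 - x2) / np.sqrt(sigma1**2 + sigma2**2)


def resolution_and_power(x0: float, p: float, N: float) -> tuple[float, float]:
    """Smallest resolvable parameter difference and resolving power.

    At separability 2 (Rayleigh-equivalent) with ``N`` photons per estimate,
    ``delta_x = 2 sqrt(2) x0 / sqrt(p N)`` and ``R = x0 / delta_x``.
    """
    if not 0 < p <= 1:
        raise DomainError("photon efficiency p must be in (0, 1]")
    if N <= 0:
        raise DomainError("N must be positive")
    delta_x = 2.0 * np.sqrt(2.0) * x0 / np.sqrt(p * N)
    return float(delta_x), float(x0 / delta_x)


def cost_from_dark_counts(dcr: float, mcr: float, N: float) -> float:
    """Relative cost of adding a photon-counting channel with dark-count
    rate ``dcr`` given a maximum count rate ``mcr`` and ``N`` photons:
    ``epsilon = (dcr / mcr) / N``.  ``dcr = 0`` is the noiseless limit."""
    if dcr < 0 or mcr <= 0 or N <= 0:
        raise DomainError("rates must be non-negative (mcr, N positive)")
    return (dcr / mcr) / N
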