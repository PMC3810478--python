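"""First-harmonic phasor transforms for time, spectral and joint data.

A phasor maps a photon-count histogram to its first-harmonic cosine/sine
projections.  Here the transforms are *unnormalized* (plain projections),
so they are exactly linear in the counts and linear unmixing carries over
to phasor space unchanged; divide by the total count for the conventional
display normalization.

The hyper-dimensional phasor (HDPH) reduces a full
2 polarization x n_wavelength x n_time channel tensor to 16 coefficients:
time phasors per polarization per spectral half (8), spectral phasors per
polarization (4) and joint 2-D time-spectrum phasors per polarization (4).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError

__all__ = [
    "PhasorSet",
    "time_phasor",
    "spectral_phasor",
    "hd_phasor_2d",
    "hdph_transform",
    "HDPH_LABELS",
]


def _angles(n: int, harmonic: int) -> np.ndarray:
    return 2.0 * np.pi * harmonic * (np.arange(n) + 0.5) / n


def _phasor_1d(counts: np.ndarray, harmonic: int, axis: int = -1):
    counts = np.asarray(counts, dtype=float)
    n = counts.shape[axis]
    if n < 2:
        raise DomainError("phasor needs at least two bins")
    w = _angles(n, harmonic)
    cos = np.tensordot(counts, np.cos(w), axes=([axis], [0]))
    sin = np.tensordot(counts, np.sin(w), axes=([axis], [0]))
    return cos, sin


def time_phasor(band_counts, harmonic: int = 1, normalized: bool = False):
    """Cosine/sine first-harmonic projections of a time-gate histogram.

    Operates on the last axis; leading axes (pixels) are preserved.
    ``normalized=True`` divides by the total count (display convention).
    """
    cos, sin = _phasor_1d(band_counts, harmonic)
    if normalized:
        total = np.asarray(band_counts, dtype=float).sum(axis=-1)
        with np.errstate(divide="ignore", invalid="ignore"):
            cos, sin = cos / total, sin / total
    return cos, sin


def spectral_phasor(spectral_counts, harmonic: int = 1, normalized: bool = False):
    """As :func:`time_phasor`, along the spectral axis (last axis)."""
    return time_phasor(spectral_counts, harmonic=harmonic, normalized=normalized)


def hd_phasor_2d(time_spectral_counts, harmonic: int = 1):
    """Joint first-harmonic 2-D phasor of a wavelength x time plane.

    Separable products ``cos_l * cos_t`` and ``sin_l * sin_t`` over the last
    two axes; for separable input the 2-D coefficients factor into the 1-D
    ones.
    """
    counts = np.asarray(time_spectral_counts, dtype=float)
    if counts.ndim < 2:
        raise DomainError("expected a wavelength x time plane")
    n_l, n_t = counts.shape[-2], counts.shape[-1]
    wl, wt = _angles(n_l, harmonic), _angles(n_t, harmonic)
    cos = np.einsum("...lt,l,t->...", counts, np.cos(wl), np.cos(wt))
    sin = np.einsum("...lt,l,t->...", counts, np.sin(wl), np.sin(wt))
    return cos, sin


def _hdph_labels(n_pol: int = 2) -> tuple[str, ...]:
    pols = ("par", "perp")[:n_pol]
    labels = []
    for p in pols:
        for half in ("blue", "red"):
            for comp in ("cos", "sin"):
                labels.append(f"time_{half}_{p}_{comp}")
    for p in pols:
        for comp in ("cos", "sin"):
            labels.append(f"spectral_{p}_{comp}")
    for p in pols:
        for comp in ("cos", "sin"):
            labels.append(f"joint2d_{p}_{comp}")
    return tuple(labels)


HDPH_LABELS = _hdph_labels()


@dataclass(frozen=True)
class PhasorSet:
    """The 16 hyper-dimensional phasor coefficients (per pixel).

    ``coefficients`` has shape ``(..., 16)``; ``labels`` names each
    coefficient (transform family, polarization, spectral half, cos/sin).
    Unnormalized, hence exactly linear in the input counts.
    """

    coefficients: np.ndarray
    labels: tuple[str, ...] = HDPH_LABELS

    def __post_init__(self) -> None:
        c = np.asarray(self.coefficients, dtype=float)
        if c.shape[-1] != len(self.labels):
            raise DomainError(
                f"expected {len(self.labels)} coefficients, got {c.shape[-1]}"
            )
        object.__setattr__(self, "coefficients", c)


def hdph_transform(pixel_counts, split_index: int | None = None) -> PhasorSet:
    """Hyper-dimensional phasor reduction of a (2, n_wavelength, n_time)
    count tensor (leading pixel axes allowed) to 16 coefficients.

    Components: first-harmonic time phasors computed separately over the
    short- and long-wavelength halves of the spectrum for each polarization
    (8 coefficients); spectral phasors per polarization (4); joint 2-D
    time-spectrum phasors per polarization (4).  ``split_index`` is the
    spectral bin where the two halves meet (default: the middle bin,
    i.e. 535 nm on the 16-bin 440-630 nm grid).
    """
    counts = np.asarray(pixel_counts, dtype=float)
    if counts.ndim < 3 or counts.shape[-3] != 2:
        raise DomainError(
            "expected a (..., 2, n_wavelength, n_time) tensor with two "
            "polarization planes"
        )
    n_l = counts.shape[-2]
    if split_index is None:
        split_index = n_l // 2
    if not 0 < split_index < n_l:
        raise DomainError("split_index must fall strictly inside the spectral axis")

    coeffs = []
    # 8: time phasors per polarization per spectral half
    for p in range(2):
        for sl in (slice(0, split_index), slice(split_index, n_l)):
            band = counts[..., p, sl, :].sum(axis=-2)
            cos, sin = time_phasor(band)
            coeffs += [cos, sin]
    # 4: spectral phasors per polarization
    for p in range(2):
        spectral = counts[..., p, :, :].sum(axis=-1)
        cos, sin = spectral_phasor(spectral)
        coeffs += [cos, sin]
    # 4: joint 2-D phasors per polarization
    for p in range(2):
        cos, sin = hd_phasor_2d(counts[..., p, :, :])
        coeffs += [cos, sin]
    return PhasorSet(coefficients=np.stack(coeffs, axis=-1))
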