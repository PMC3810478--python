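"""Linear abundance unmixing of multi-channel fluorescence images.

Per pixel, observed counts follow ``counts ~ Poisson(N * E @ a)`` with
``E`` the channels x fluorophores endmember matrix and ``a`` the abundance
vector; unmixing inverts this by (non-negative) least squares.  The module
also provides the accuracy (bias) and precision (replicate-noise) figures
of merit used to benchmark detection techniques on gradient images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize as _sciopt

from .errors import DomainError, SingularModelError
from .models import HDSS, DetectionGrid
from .simulate import SyntheticImage

__all__ = [
    "EndmemberMatrix",
    "lstsq_unmix",
    "estimate_endmembers_from_rows",
    "accuracy_bias",
    "precision_sigma",
]


@dataclass(frozen=True)
class EndmemberMatrix:
    """Endmember signatures as a channels x n_fluorophores matrix.

    Columns of count-space signatures sum to 1; set ``normalized=False``
    for transformed spaces (e.g. phasor coefficients) where that invariant
    does not apply.
    """

    signatures: np.ndarray
    grid: DetectionGrid | None = None
    names: tuple[str, ...] = ()
    normalized: bool = True

    def __post_init__(self) -> None:
        s = np.asarray(self.signatures, dtype=float)
        if s.ndim != 2:
            raise DomainError("signatures must be a channels x fluorophores matrix")
        if self.normalized:
            sums = s.sum(axis=0)
            if np.any(np.abs(sums - 1.0) > 1e-6):
                raise DomainError(
                    f"endmember columns must sum to 1, got {sums.tolist()}"
                )
        if np.linalg.matrix_rank(s) < s.shape[1]:
            raise SingularModelError("endmember matrix is rank deficient")
        object.__setattr__(self, "signatures", s)

    @classmethod
    def from_hdss(cls, endmembers, names: tuple[str, ...] = ()) -> "EndmemberMatrix":
        sig = np.column_stack([e.ravel() for e in endmembers])
        grid = endmembers[0].grid if isinstance(endmembers[0], HDSS) else None
        return cls(signatures=sig, grid=grid, names=names)

    @property
    def n_channels(self) -> int:
        return self.signatures.shape[0]

    @property
    def n_fluorophores(self) -> int:
        return self.signatures.shape[1]


def _counts_array(image) -> np.ndarray:
    if isinstance(image, SyntheticImage):
        return image.counts
    return np.asarray(image, dtype=float)


def lstsq_unmix(image, endmembers: EndmemberMatrix, nonneg: bool = False) -> np.ndarray:
    """Per-pixel least-squares abundance estimation.

    Solves ``counts = E @ c`` per pixel (``c = N * a``) and reports
    fractional abundances ``a_j = c_j / sum(c)``.  The unconstrained path
    uses one precomputed pseudo-inverse; ``nonneg=True`` solves NNLS per
    pixel.  Negative unconstrained estimates are kept (not clipped) so
    downstream bias/precision metrics stay unbiased.
    """
    counts = _counts_array(image)
    *lead, n_ch = counts.shape
    if n_ch != endmembers.n_channels:
        raise DomainError(
            f"image has {n_ch} channels but endmembers have "
            f"{endmembers.n_channels}"
        )
    flat = counts.reshape(-1, n_ch)
    E = endmembers.signatures
    if nonneg:
        coeff = np.empty((flat.shape[0], endmembers.n_fluorophores))
        for i, y in enumerate(flat):
            coeff[i], _ = _sciopt.nnls(E, y)
    else:
        pinv = np.linalg.pinv(E)
        coeff = flat @ pinv.T
    total = coeff.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = coeff / total[:, None]
    return frac.reshape(*lead, endmembers.n_fluorophores)


def estimate_endmembers_from_rows(image: SyntheticImage) -> EndmemberMatrix:
    """Endmember signatures from the pure-abundance ends of a gradient image.

    The gradient runs along columns with replicate rows, so the pixels with
    fractional abundance exactly 0 and 1 are the first and last columns;
    the endmember for each fluorophore is the replicate-mean signature at
    its pure end, renormalized to sum to 1.  Column order matches the
    ``true_abundances`` component order (fluorophore A first).
    """
    counts = image.counts
    pure_b = counts[:, 0, :].mean(axis=0)  # abundance of A = 0
    pure_a = counts[:, -1, :].mean(axis=0)  # abundance of A = 1
    for label, v in (("A", pure_a), ("B", pure_b)):
        if v.sum() <= 0:
            raise DomainError(
                f"no photons at the pure-{label} end; cannot estimate endmember"
            )
    sig = np.column_stack([pure_a / pure_a.sum(), pure_b / pure_b.sum()])
    return EndmemberMatrix(signatures=sig, grid=image.grid, names=("A", "B"))


def accuracy_bias(true_fractions, estimated_fractions) -> float:
    """Mean of ``true - estimated`` for the reference (first) fluorophore
    over all pixels; 0 for a perfectly accurate estimator."""
    t = np.asarray(true_fractions, dtype=float)
    e = np.asarray(estimated_fractions, dtype=float)
    if t.shape != e.shape:
        raise DomainError("true and estimated fraction maps must share a shape")
    return float(np.mean(t[..., 0] - e[..., 0]))


def precision_sigma(estimated_fractions, N: float) -> float:
    """Replicate noise of the abundance estimates, normalized to shot noise.

    Per gradient column, the standard deviation of the reference-fluorophore
    fraction over the replicate rows; reported as the column mean multiplied
    by ``sqrt(N)`` (dimensionless; lower is better, shot-limited disjoint
    unmixing would approach its Fisher bound).
    """
    e = np.asarray(estimated_fractions, dtype=float)
    if e.ndim != 3:
        raise DomainError("expected a rows x cols x fluorophores fraction map")
    if e.shape[0] < 2:
        raise DomainError("precision needs at least two replicate rows")
    if N <= 0:
        raise DomainError("N must be positive")
    sd_per_col = np.std(e[..., 0], axis=0, ddof=1)
    return float(np.mean(sd_per_col) * np.sqrt(N))
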